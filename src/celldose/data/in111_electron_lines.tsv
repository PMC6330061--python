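# In-111 electron emission spectrum, condensed to 12 lines.
# Columns: E_keV  yield_per_decay
# Synthetic condensation assembled from published evaluated decay data for
# In-111 -> Cd-111 (electron-capture decay): internal-conversion electron
# intensities for the 171.28 and 245.35 keV transitions and K/L/M-shell Auger
# and Coster-Kronig yields as evaluated in standard compilations (ICRP
# Publication 107 class data; unabridged Auger cascades pooled into mean-energy
# lines per shell). Not a verbatim copy of any single table.
# Total electron energy per decay: 34.9 keV; electrons per decay: 14.5.
# Photons (gamma, X-ray) intentionally excluded: negligible absorbed fraction
# at cellular scale.
0.08	11.3	# M/N-shell Auger + Coster-Kronig (pooled)
0.35	2	# M-shell Auger (pooled)
2.73	0.94	# L-shell Auger (pooled)
18.6	0.106	# K-shell Auger KLL
21.6	0.0415	# K-shell Auger KLX
24.4	0.0046	# K-shell Auger KXY
144.57	0.0825	# conversion electron K (171 keV gamma)
167.4	0.0105	# conversion electron L (171 keV gamma)
170.6	0.0022	# conversion electron M+ (171 keV gamma)
218.64	0.0495	# conversion electron K (245 keV gamma)
241.4	0.01	# conversion electron L (245 keV gamma)
244.6	0.002	# conversion electron M+ (245 keV gamma)
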