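"""Single-cell cellular S values for In-111.

Builds the In-111 electron dose-point kernel in liquid water and computes
the mean absorbed dose to the nucleus per decay (the MIRD cellular S value)
for decays in the nucleus (N), cytoplasm (Cy) and on the cell surface (Cs),
at the mean measured radii of three carcinoma cell lines.
"""

from celldose.pipeline import single_cell_table

table = single_cell_table()
print(table.to_string(index=False, float_format=lambda v: f"{v:.3g}"))
print()
print("S(N<-N) >> S(N<-Cy) > S(N<-Cs): most of the In-111 electron energy is")
print("carried by short-range Auger electrons, so decays inside the nucleus")
print("deposit an order of magnitude more nuclear dose per decay than decays")
print("in the cytoplasm or on the membrane.  Units are Gy per decay (Bq s).")
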