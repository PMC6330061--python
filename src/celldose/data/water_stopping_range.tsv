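# Electron collisional stopping power and CSDA range in liquid water (unit density).
# Columns: E_keV  S_col_keV_per_um  R_csda_um
# E >= 10 keV: collisional stopping powers interpolated from ICRU Report 37 /
#   NIST ESTAR tabulations for liquid water.
# E < 10 keV: analytic branch matched to the Cole (1969) empirical electron
#   range-energy relation, scaled for continuity at 10 keV (sub-10-keV stopping
#   in condensed water is uncertain at the 10-20% level in the literature).
# CSDA ranges are computed by integrating dE/S_col over this table and are
# therefore self-consistent with the stopping-power column.
0.05	26.785	0.0018667
0.0543	26.574	0.0020279
0.059	26.348	0.0022055
0.064	26.112	0.0023962
0.0695	25.859	0.0026078
0.0755	25.588	0.0028411
0.082	25.302	0.0030965
0.089	25.003	0.0033749
0.0967	24.683	0.0036848
0.105	24.348	0.0040234
0.114	23.996	0.0043958
0.1238	23.626	0.0048074
0.1345	23.237	0.005264
0.146	22.835	0.0057633
0.1586	22.412	0.0063203
0.1722	21.976	0.0069331
0.187	21.522	0.0076137
0.2031	21.053	0.0083701
0.2206	20.568	0.0092112
0.2395	20.073	0.010141
0.2601	19.563	0.011181
0.2824	19.044	0.012336
0.3067	18.513	0.013631
0.3331	17.973	0.015078
0.3617	17.427	0.016695
0.3928	16.875	0.018508
0.4266	16.319	0.020545
0.4632	15.762	0.022828
0.503	15.204	0.025399
0.5463	14.646	0.028302
0.5932	14.092	0.031567
0.6442	13.542	0.03526
0.6996	12.997	0.039437
0.7597	12.459	0.044161
0.825	11.931	0.049518
0.8959	11.411	0.055597
0.9729	10.903	0.062502
1.056	10.407	0.070353
1.147	9.9227	0.079291
1.246	9.4522	0.089476
1.353	8.9957	0.10109
1.469	8.5537	0.11436
1.596	8.1266	0.12951
1.733	7.7149	0.14683
1.882	7.3185	0.16666
2.043	6.9374	0.18936
2.219	6.5717	0.21538
2.41	6.2214	0.24522
2.617	5.8861	0.27946
2.842	5.5658	0.31877
3.086	5.2601	0.36394
3.351	4.9687	0.41584
3.639	4.6913	0.47552
3.952	4.4275	0.54419
4.292	4.1768	0.6232
4.66	3.9387	0.7142
5.061	3.713	0.81898
5.496	3.499	0.93973
5.968	3.2964	1.0789
6.481	3.1046	1.2393
7.038	2.9231	1.4243
7.643	2.7516	1.6377
8.3	2.5896	1.8839
9.013	2.4366	2.1681
9.788	2.2922	2.4961
10.63	2.1517	2.875
11.54	2.0183	3.3136
12.53	1.8932	3.8214
13.61	1.7759	4.4093
14.78	1.6658	5.0899
16.05	1.5624	5.8779
17.43	1.4655	6.7902
18.93	1.3745	7.8465
20.56	1.2896	9.0694
22.32	1.2106	10.484
24.24	1.1365	12.121
26.33	1.0669	14.014
28.59	1.0016	16.204
31.05	0.94082	18.738
33.71	0.88445	21.664
36.61	0.83146	25.045
39.76	0.78164	28.951
43.18	0.73557	33.46
46.89	0.69228	38.663
50.92	0.65179	44.666
55.29	0.61453	51.585
60.04	0.57941	59.553
65.2	0.54748	68.72
70.81	0.51732	79.256
76.89	0.48882	91.365
83.5	0.46264	105.27
90.68	0.4385	121.22
98.47	0.41563	139.48
106.9	0.3955	160.37
116.1	0.37669	184.19
126.1	0.35877	211.35
136.9	0.3417	242.32
148.7	0.32545	277.63
161.5	0.31174	317.79
175.4	0.29881	363.28
190.5	0.28641	414.83
206.8	0.27515	473.2
224.6	0.2652	539.02
243.9	0.25561	613.18
264.9	0.24719	696.64
287.6	0.23939	790.25
312.3	0.23248	895.13
339.2	0.22643	1012.2
368.3	0.22054	1142.6
400	0.2148	1288.1
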