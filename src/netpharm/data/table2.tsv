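# Published per-metric medians of the full 39-node PPI centrality table
# (the 13 rows below are only the nodes that exceeded every median):
# median	dc=8	ec=0.1181	lac=3.75	bc=16.4307	cc=0.5067	nc=6.1431
gene	dc	ec	lac	bc	cc	nc
FOS	24	0.30	8.58	379.38	0.73	19.12
CASP3	19	0.28	9.68	75.48	0.63	15.54
VEGFA	19	0.28	9.68	56.57	0.61	16.07
ESR1	19	0.28	9.79	52.61	0.60	16.30
PTGS2	17	0.26	9.18	65.09	0.61	13.13
RELA	17	0.25	8.47	70.93	0.59	13.15
AR	16	0.25	9.25	38.73	0.58	13.01
CYCS	16	0.24	8.25	62.59	0.60	12.18
HIF1A	14	0.22	7.29	45.81	0.57	9.76
PGR	13	0.20	7.69	26.13	0.55	10.18
PPARG	15	0.19	5.47	108.42	0.58	8.28
NCOA1	10	0.14	5.40	22.35	0.53	7.01
NCOA2	10	0.14	5.40	22.35	0.53	7.01
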