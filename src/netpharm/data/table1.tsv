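id	name	ob	dl	source	manual_add
MOL002421	Ignavine	84.08	0.25	Fuzi	false
MOL002419	(R)-norcoclaurine	82.54	0.21	Fuzi	false
MOL002398	karanjin	69.56	0.34	Fuzi	false
MOL002388	Delphin_qt	57.76	0.28	Fuzi	false
MOL002395	Deoxyandrographolide	56.3	0.31	Fuzi	false
MOL002415	6-Demethyldesoline	51.87	0.66	Fuzi	false
MOL002397	Karakoline	51.73	0.73	Fuzi	false
MOL002422	Isotalatizidine	50.82	0.73	Fuzi	false
MOL002392	Deltoin	46.69	0.37	Fuzi	false
MOL002401	Neokadsuranic acid B	43.1	0.85	Fuzi	false
MOL002433	(3R, 8S, 9R, 10R, 13R, 14S, 17R)-3-hydroxy-4, 4, 9, 13, 14-pentamethyl-17-[(E, 2R)-6-methyl-7-[(2R, 3R, 4S, 5S, 6R)-3, 4, 5-trihydroxy-6-[[(2R, 3R, 4S, 5S, 6R)-3, 4, 5-trihydroxy-6-(hydroxymethyl)oxan-2-yl]oxymethyl]oxan-2-yl]oxyhept-5-en-2-yl]-1, 2, 3, 7, 8, 10, 12, 15, 16, 17-decahydr	41.52	0.22	Fuzi	false
MOL002211	11, 14-Eicosadienoic acid	39.99	0.2	Fuzi	false
MOL002406	2, 7-Dideacetyl-2, 7-dibenzoyl-taxayunnanine F	39.43	0.38	Fuzi	false
MOL002434	Carnosifloside I_qt	38.16	0.8	Fuzi	false
MOL000359	Sitosterol	36.91	0.75	Fuzi	false
MOL002393	Demethyldelavaine A	34.52	0.18	Fuzi	false
MOL002394	Demethyldelavaine B	34.52	0.18	Fuzi	false
MOL002410	Benzoylnapelline	34.06	0.53	Fuzi	false
MOL002423	Jesaconitine	33.41	0.19	Fuzi	false
MOL000538	Hypaconitine	31.39	0.26	Fuzi	false
MOL002416	Deoxyaconitine	30.96	0.24	Fuzi	false
MOL002089	Mesaconitine	8.7	0.25	Fuzi	true
MOL002424	Aconitine	7.87	0.23	Fuzi	true
MOL002408	Benzoylaconine	12.83	0.25	Fuzi	true
MOL002409	Benzoylhypaconine	8.7	0.29	Fuzi	true
MOL002093	Benzoylmesaconine	8.55	0.27	Fuzi	true
MOL006957	(3S, 6S)-3-(benzyl)-6-(4-hydroxybenzyl) piperazine-2, 5-quinone	46.89	0.27	Banxia	false
MOL006967	beta-D-ribofuranoside, xanthine-9	44.72	0.21	Banxia	false
MOL000449	Stigmasterol	43.83	0.76	Banxia	false
MOL006937	12, 13-Epoxy-9-hydroxynonadeca-7, 10-dienoic acid	42.15	0.24	Banxia	false
MOL002776	Baicalin	40.12	0.75	Banxia	false
MOL006936	10, 13-Eicosadienoic	39.99	0.2	Banxia	false
MOL003578	Cycloartenol	38.69	0.78	Banxia	false
MOL000358	Beta-sitosterol	36.91	0.75	Banxia	false
MOL001755	24-Ethylcholest-4-en-3-one	36.08	0.76	Banxia	false
MOL002670	Cavidine	35.64	0.81	Banxia	false
MOL002714	Baicalein	33.52	0.21	Banxia	false
MOL000519	Coniferin	31.11	0.32	Banxia	false
MOL005030	Gondoic acid	30.7	0.2	Banxia	false
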