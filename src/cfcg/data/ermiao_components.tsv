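name	source	MW	RBN	nHAcc	nHDon	ClogP
Undecenal	PAR	168.28	8	1	0	3.41
Furol	PAR	96.08	1	2	0	0.69
Myrcene	PAR	136.23	4	0	0	3.43
(S)-(+)-α-Phellandrene	PAR	136.23	1	0	0	2.97
L-Limonen	PAR	136.23	1	0	0	3.35
Eugenol	PAR	164.2	3	2	1	2.25
Caprylic acid	PAR	144.21	6	2	1	2.23
4-[(Z)-3-hydroxyprop-1-enyl]-2,6-dimethoxyphenol	PAR	210.23	4	4	2	1.47
Ferulic Acid (CIS)	PAR	194.18	3	4	2	1.36
Magnograndiolide	PAR	266.33	0	4	2	1.7
Vanillin	PAR	152.15	2	3	1	1.2
Pentylfuran	PAR	138.21	4	1	0	2.83
WLN: VHR	PAR	106.12	1	1	0	1.57
Trans-2-nonenal	PAR	140.22	6	1	0	2.66
(2S,3S)-3,5,7-trihydroxy-2-(4-hydroxyphenyl)chroman-4-one	PAR	288.25	1	6	4	1
Magnoflorine	PAR	342.41	2	4	2	1.89
Menisporphine	PAR	321.33	3	5	0	2.98
Palmatine	PAR	352.4	4	4	0	2.51
STOCK1N-14407	PAR	355.43	4	5	0	3.1
Fumarine	PAR	353.37	0	6	0	2.67
Jatrorrizine	PAR	338.38	3	4	1	2.23
Isocorypalmine	PAR	341.4	3	5	1	2.75
Menisperine	PAR	356.44	3	4	1	2.19
Paeonol	PAR	166.17	2	3	1	1.63
Beta-elemene	PAR	204.35	3	0	0	4.65
Mnk	PAR	170.29	8	1	0	3.48
Phellamurin_qt	PAR	356.37	3	6	4	2.59
Pisol	PAR	186.33	10	1	1	3.94
Oxophorone	PAR	152.19	0	2	0	1.47
Berberine	PAR	336.36	2	4	0	2.41
(S)-Canadine	PAR	339.39	2	5	0	2.96
Columbamine	PAR	338.38	3	4	1	2.23
Coptisine	PAR	320.32	0	4	0	2.32
EUG	PAR	150.17	2	2	1	2.14
Isovanillin	PAR	152.15	2	3	1	1.12
Methyl 3-furoate	PAR	126.11	2	3	0	1.06
N-Methylflindersine	PAR	241.29	0	2	0	2.65
Homocresol	PAR	152.19	2	2	1	2.02
(s)-carvone	PAR	150.22	1	1	0	2.43
Beta-Rhodinol	PAR	156.27	5	1	1	2.93
Phlorol	PAR	122.16	1	1	1	2.11
(±)-lyoniresinol	PAR	420.45	7	8	4	2
Obacunoic acid	PAR	472.53	4	8	2	2.65
Phellodendrine	PAR	342.41	2	4	2	1.68
Phellopterin	PAR	300.31	4	5	0	3.36
PEA	PAR	121.18	2	1	1	1.6
Vanillyl alcohol	PAR	154.16	2	3	2	0.86
(4R)-limonene 1beta, 2beta-epoxide	PAR	152.23	1	1	0	2.71
Coniferol	PAR	180.2	3	3	2	1.62
Dehydrotanshinone II A	PAR	292.33	0	3	0	3.61
Delta7-Dehydrosophoramine	PAR	242.32	0	2	0	1.81
Dictamine	PAR	199.21	1	3	0	2.63
Kihadanin A	PAR	486.51	1	9	1	2
Rutaecarpine	PAR	287.32	0	2	1	3.1
Skimmianin	PAR	259.26	3	5	0	2.58
Fagarine	PAR	229.23	2	4	0	2.59
Ferulic Acid	PAR	192.21	3	3	2	2.15
Chelerythrine	PAR	332.35	2	4	0	4.37
Worenine	PAR	334.35	0	4	0	2.52
Cavidine	PAR	353.41	2	5	0	3.23
Hispidone	PAR	472.7	1	4	2	4.86
Berberrubine	PAR	322.33	1	4	1	2.14
Noroxyhydrastinine	PAR	191.18	0	3	1	1.23
Ethyl caffeate	PAR	208.21	4	4	2	1.82
Guasol	PAR	124.14	1	2	1	1.4
IPH	PAR	94.11	0	1	1	1.41
Nonanoic acid	PAR	158.24	7	2	1	2.6
Dodec-2-enal	PAR	182.3	9	1	0	3.78
Naphthalene	PAR	128.17	0	0	0	3.1
Limonin	PAR	470.51	1	8	0	2.54
5-Methylfurfural	PAR	110.11	1	2	0	1.02
Maruzen M	PAR	122.16	1	1	1	2.11
O-cresol	PAR	108.14	0	1	1	1.78
Creosol	PAR	138.16	1	2	1	1.7
Methyl naphthalene	PAR	142.2	0	0	0	3.46
Isoferulic acid	PAR	194.18	3	4	2	1.39
Cyclopentenone	PAR	82.1	0	1	0	0.96
Methyl caffeate	PAR	194.18	3	4	2	1.35
Clorius	PAR	136.15	2	2	0	1.84
Ptelein	PAR	229.23	2	4	0	2.62
SMR000232320	PAR	474.72	5	4	3	4.86
Canthin-6-one	PAR	220.23	0	2	0	2.39
4,10-dimethylene-7-isopropyl-5(E)-cyclodecenol	PAR	220.35	1	1	1	3.47
4-[(1R,3aS,4R,6aS)-4-(4-hydroxy-3,5-dimethoxyphenyl)-1,3,3a,4,6,6a-hexahydrofuro (4,3-c)furan-1-yl]-2,6-dimethoxyphenol	PAR	418.44	6	8	2	2.33
Guanidine	PAR	59.07	0	1	3	-1.01
7-hydroxy-6-(2-hydroxyethyl)coumarin	PAR	206.19	2	4	2	1.35
Thalifendine	PAR	322.33	1	4	1	2.14
Furfuranol	PAR	98.1	1	2	1	0.62
(S)-4-Nonanolide	PAR	156.22	4	2	0	2.24
2,4,6-trimethyl-Octane	PAR	156.31	5	0	0	4.26
Methyl atratate	PAR	196.2	2	4	2	1.77
Acetylfuran	PAR	110.11	1	2	0	1.01
Candicine	PAR	180.27	3	1	1	1.19
2-undecenoic acid	PAR	184.28	8	2	1	3.18
Homoveratrole	PAR	152.19	2	2	0	2.05
Obacunone	PAR	454.51	1	7	0	3.19
Auraptene	PAR	298.38	6	3	0	4.51
Tetrahydropalmatine	PAR	355.43	4	5	0	3.08
Jatrorrhizine	PAR	380.46	6	4	1	3.05
Obaculactone	PAR	470.51	1	8	0	2.54
Alpha-humulene	ALD	204.35	0	0	0	4.26
Beta-Eudesmol	ALD	222.37	1	1	1	3.61
2-[(1R,3S,4S)-3-isopropenyl-4-methyl-4-vinylcyclohexyl]propan-2-ol	ALD	222.37	3	1	1	3.77
Atractylenolide i	ALD	230.3	0	2	0	3.25
Atractylenolide II	ALD	232.32	0	2	0	3.2
Selina-4(14),7(11)-dien-8-one	ALD	218.33	0	1	0	3.65
Vanillic acid	ALD	168.15	2	4	2	1.08
Beta-Chamigrene	ALD	204.35	0	0	0	4.39
Atractylone	ALD	216.32	0	1	0	3.81
2-[(2S,5S,6S)-6,10-dimethylspiro [4.5]dec-9-en-2-yl]propan-2-ol	ALD	222.37	1	1	1	3.54
ZINC01609418	ALD	222.37	4	1	1	3.76
3β-hydroxyatractylone	ALD	232.32	0	2	1	2.87
()-2-Carene	ALD	136.23	0	0	0	3.12
Alpha-Guaiene	ALD	204.35	1	0	0	4.3
Guaiene	ALD	204.35	0	0	0	4.23
Guaiol	ALD	222.37	1	1	1	3.42
Furol	ALD	96.08	1	2	0	0.69
Wogonin	ALD	284.26	2	5	2	2.54
Cyperene	ALD	204.35	0	0	0	4.4
Atractylenolide iii	ALD	248.32	0	3	1	2.65
2-Hydroxyisoxypropyl-3-hydroxy-7-isopentene-2,3-dihydrobenzofuran-5-carboxylic	ALD	306.35	4	5	3	2.37
Beta-Eudesmol	ALD	222.37	1	1	1	3.61
Butenolide B	ALD	234.29	0	3	1	2.21
3β-acetoxyatractylone	ALD	274.35	2	3	0	3.3
3,5-dimethoxy-4-glucosyloxyphenylallylalcohol_qt	ALD	210.23	4	4	2	1.55
(Z)-caryophyllene	ALD	204.35	0	0	0	4.25
Patchoulene	ALD	204.35	0	0	0	4.35
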