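component	concentration_mg_per_g
Chlorogenic acid	3.884
Ferulic acid	4.058
Berberine	69.857
Phellodendrine	7.002
Palmatine	1.045
Magnoflorine	2.221
Jatrorrhizine	0.894
Tetrahydropalmatine	0.0165
Tetrahydroberberine	0.0035
Obaculactone	3.244
Obacunone	0.213
Atractylenolide I	0.3295
Atractylenolide II	0.131
Atractylenolide III	0.144
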