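taxon	genome_size	lsc_length	ssc_length	ir_length	gc_content
Schima argentea	157245	87222	18091	25966	37.43
Schima brevipedicellata	157227	87202	18089	25968	37.44
Schima crenata	157288	87232	18104	25976	37.44
Schima khasiana	157252	87208	18112	25966	37.43
Schima multibracteata	157278	87233	18103	25971	37.44
Schima noronhae	157278	87217	18091	25985	37.43
Schima remotiserrata	157284	87229	18103	25976	37.43
Schima sericans	157302	87272	18122	25954	37.45
Schima sinensis	157297	87243	18102	25976	37.45
Schima superba	157254	87202	18100	25976	37.44
Schima wallichii	157240	87204	18104	25966	37.44
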