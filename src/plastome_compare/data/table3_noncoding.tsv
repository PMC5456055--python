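region	length_bp	aligned_length	variable_positions	substitutions	indels	indel_length	percent_variability
trnH (GUG)-psbA	395-426	428	37	4	1	33	1.17
psbA-trnK (UUU)	220	220	1	1	0	0	0.45
trnK (UUU)-matK	270	270	2	2	0	0	0.74
matK-trnK (UUU)	712-713	713	2	1	1	1	0.28
trnK (UUU)-rps16	809-818	819	22	10	4	12	1.71
rps16 intron	838-844	845	10	3	2	7	0.59
rps16-trnQ (UUG)	1689-1698	1700	36	18	4	18	1.29
trnQ (UUG)-psbK	333	333	2	2	0	0	0.60
psbK-psbI	345	345	3	3	0	0	0.87
trnS (GCU)-trnG (UCC)	681-682	682	3	3	0	0	0.44
trnG (UCC) intron	690-696	696	8	2	1	6	0.43
trnG (UCC)-trnR (UCU)	276-311	311	37	2	1	35	0.96
atpF intron	701	701	2	2	0	0	0.29
atpF-atpH	387-389	389	7	5	1	2	1.54
atpH-atpI	1143-1153	1153	15	4	4	11	0.69
rps2-rpoC2	254-255	255	1	0	1	1	0.39
rpoC1 intron	732-734	734	2	0	1	2	0.14
rpoB-trnC (GCA)	1211-1222	1222	26	9	4	17	1.06
trnC (GCA)-petN	722-727	727	8	3	1	5	0.55
petN-psbM	1123-1125	1125	15	13	1	2	1.24
psbM-trnD (GUC)	1136-1153	1153	27	8	5	19	1.13
trnE (UUC)-trnT (GGU)	473	473	5	5	0	0	1.06
trnT (GGU)-psbD	1513-1517	1519	19	11	3	8	0.92
psbC-trnS (UGA)	234-239	239	6	1	1	5	0.84
psbZ-trnG (UCC)	283	283	1	1	0	0	0.35
trnG (UCC)-trnfM (CAU)	157-159	160	5	2	2	3	2.50
trnfM (CAU)-rps14	154	154	2	2	0	0	1.30
psaA-ycf3	747-755	755	17	3	3	14	0.79
ycf3 intron1	721	721	2	2	0	0	0.28
ycf3 intron2	726	726	2	2	0	0	0.28
ycf3-trnS (GGA)	839-842	842	8	4	3	4	0.83
trnS (GGA)-rps4	293	293	1	1	0	0	0.34
trnT (UGU)-trnL (UAA)	982-999	999	46	19	6	27	2.50
trnL (UAA) intron	522-529	529	7	0	1	7	0.19
trnF (GAA)-ndhJ	704-714	715	21	3	4	18	0.98
ndhC-trnV (UAC)	400-414	417	36	3	6	33	2.16
trnV (UAC) intron	585	585	2	2	0	0	0.34
trnV (UAC)-trnM (CAU)	166	166	1	1	0	0	0.60
trnM (CAU)-atpE	229-238	240	13	0	2	13	0.83
atpB-rbcL	765-768	768	5	2	1	3	0.39
rbcL-accD	525-526	526	4	3	1	1	0.76
accD-psaI	681-683	683	4	2	1	2	0.44
psaI-ycf4	423-425	425	3	1	1	2	0.47
ycf4-cemA	909-915	915	13	7	1	6	0.87
cemA-petA	220-228	228	8	0	2	8	0.88
petA-psbJ	1035-1042	1043	12	4	3	8	0.67
psbE-petL	1277-1287	1287	22	12	2	10	1.09
petL-petG	185-186	186	1	0	1	1	0.54
trnW (CCA)-trnP (UGG)	170-175	175	9	4	1	5	2.86
trnP (UGG)-psaJ	391-393	393	2	0	1	2	0.25
psaJ-rpl33	455-457	457	5	3	1	2	0.88
rpl33-rps18	175-176	176	2	1	1	1	1.14
rps18-rpl20	284	284	1	1	0	0	0.35
rpl20-rps12	786	786	4	4	0	0	0.51
clpP intron1	598-605	607	13	3	5	10	1.32
clpP intron2	797-798	798	3	2	1	1	0.38
clpP-psbB	473-479	479	8	2	1	6	0.63
psbB-psbT	172-174	174	5	3	1	2	2.30
petB intron	787	787	3	3	0	0	0.38
petD intron	711	711	7	7	0	0	0.98
petD-rpoA	200-213	215	15	0	5	15	2.33
rps8-rpl14	196	196	1	1	0	0	0.51
rpl16 intron	996-998	998	13	11	1	2	1.20
rpl16-rps3	150-200	200	52	2	1	50	1.50
rps12 intron	536	536	2	2	0	0	0.37
rps12-trnV (GAC)	1602-1619	1619	29	2	5	27	0.43
trnI (GAU) intron	938	938	1	1	0	0	0.11
trnA (UGC)-rrn23	152	152	1	1	0	0	0.66
rrn4.5-rrn5	256-275	275	19	0	1	19	0.36
rrn5-trnR (ACG)	248-249	249	2	1	1	1	0.80
trnR (ACG)-trnN (GUU)	595	595	7	7	0	0	1.18
ndhF-rpl32	825-847	851	32	6	4	26	1.18
rpl32-trnL (UAG)	908-926	928	36	13	6	23	2.05
ccsA-ndhD	240-244	245	6	1	2	5	1.22
psaC-ndhE	251-254	254	4	1	1	3	0.79
ndhE-ndhG	230	230	5	5	0	0	2.17
ndhG-ndhI	359-360	360	6	5	1	1	1.67
ndhA intron	1106-1111	1112	16	8	3	8	0.99
rps15-ycf1	379	379	5	5	0	0	1.32
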