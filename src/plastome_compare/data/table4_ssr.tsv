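no	motif	location	region	repeat_length
1	A	trnH-psbA	LSC	12-43
2	A	trnK (UUU) intron	LSC	10-11
3	A	trnK (UUU)-rps16	LSC	9-10
4	A	trnK (UUU)-rps16	LSC	11-14
5	A	trnK (UUU)-rps16	LSC	8-10
6	T	rps16-trnQ (UUG)	LSC	9-14
7	A	rps16-trnQ (UUG)	LSC	8-10
8	T	rps16-trnQ (UUG)	LSC	8-11
9	T	psbI	LSC	10,13
10	A	atpA-atpF	LSC	14,15
11	T	atpF-atpH	LSC	9-12
12	AT	atpF-atpH	LSC	12,14
13	A	atpH-atpI	LSC	13-20
14	T	atpH-atpI	LSC	12,13
15	A	rps2-rpoC2	LSC	10,11
16	A	rpoC2-trnC (GCA)	LSC	9,10
17	T	psbM-trnD (GUC)	LSC	10,11
18	T	trnT (GGU)-psbD	LSC	9,10
19	A	trnT (GGU)-psbD	LSC	9-14
20	T	psbC-trnS (UGA)	LSC	11-16
21	C	trnG (UCC)-trnfM (CAU)	LSC	8,10
22	A	trnG (UCC)-trnfM (CAU)	LSC	9,10
23	A	psaA-ycf3	LSC	10-14
24	A	ycf3-trnS (GGA)	LSC	11,12
25	A	ycf3-trnS (GGA)	LSC	11,12
26	A	trnT (UGU)-trnL (UAA)	LSC	13,14
27	T	trnF (GAA)-ndhJ	LSC	9,10
28	T	ndhC-trnV (UAC)	LSC	8-16
29	T	ndhC-trnV (UAC)	LSC	9-12
30	TTA	ndhC-trnV (UAC)	LSC	3,12
31	T	ndhC-trnV (UAC)	LSC	9,10
32	T	trnM (CAU)-atpE	LSC	9-12
33	T	atpB-rbcL	LSC	12-15
34	T	rbcL-accD	LSC	11,12
35	T	accD-psaI	LSC	13-15
36	T	psaI-ycf4	LSC	10-12
37	T	petA-psbJ	LSC	10-13
38	T	petA-psbJ	LSC	10,11
39	T	petL-petG	LSC	10,11
40	T	trnP (UGG)-psaJ	LSC	10-12
41	T	rpl20-rps12	LSC	6,10
42	T	clpP intron	LSC	10,11
43	A	clpP intron	LSC	9-11
44	A	clpP intron	LSC	9,10
45	ATT	clpP-psbB	LSC	6,12
46	A	psbB-psbT	LSC	8-10
47	T	petD-rpoA	LSC	9,10
48	A	petD-rpoA	LSC	9-11
49	A	petD-rpoA	LSC	9,10
50	A	rrn5-trnR (ACG)	IR	9,10
51	T	ndhF-rpl32	SSC	9-12
52	T	ndhF-rpl32	SSC	10,11
53	A	rpl32-trnL (UAG)	SSC	10,11
54	T	rpl32-trnL (UAG)	SSC	10-13
55	T	ccsA-ndhD	SSC	10-13
56	T	psaC-ndhE	SSC	9-12
57	T	ndhG-ndhI	SSC	10,11
58	A	ndhA intron	SSC	9,10
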