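region	length_bp	aligned_length	variable_positions	substitutions	indels	indel_length	percent_variability
matK	1527	1527	5	5	0	0	0.33
psbK	186	186	1	1	0	0	0.54
psbI	153-156	156	3	0	1	3	0.64
atpA	1524	1524	3	3	0	0	0.20
atpF	567	567	2	2	0	0	0.35
atpI	744	744	1	1	0	0	0.13
rps2	711	711	1	1	0	0	0.14
rpoC2	4137	4137	11	11	0	0	0.27
rpoC1	2061	2061	3	3	0	0	0.15
rpoB	3213	3213	11	11	0	0	0.34
psbC	1422	1422	3	3	0	0	0.21
psaB	2205	2205	2	2	0	0	0.09
psaA	2253	2253	6	6	0	0	0.27
rps4	606	606	2	2	0	0	0.33
ndhK	678	678	1	1	0	0	0.15
ndhC	363	363	2	2	0	0	0.55
atpE	402	402	1	1	0	0	0.25
atpB	1497	1497	1	1	0	0	0.07
rbcL	1428	1428	3	3	0	0	0.21
accD	1542	1542	4	4	0	0	0.26
ycf4	555	555	3	3	0	0	0.54
cemA	690	690	2	2	0	0	0.29
petA	963	963	2	2	0	0	0.21
rpl20	354	354	1	1	0	0	0.28
rps12	372	372	1	1	0	0	0.27
clpP	645	645	3	3	0	0	0.47
psbB	1527	1527	2	2	0	0	0.13
petB	663	663	4	4	0	0	0.60
rpoA	1014	1014	2	2	0	0	0.20
rps11	417	417	3	3	0	0	0.72
infA	234	234	1	1	0	0	0.43
rps8	408	408	1	1	0	0	0.25
rpl14	369	369	3	3	0	0	0.81
rpl16	411	411	2	2	0	0	0.49
rps3	657	657	2	2	0	0	0.30
rpl22	474	474	1	1	0	0	0.21
ycf2	6867-6873	6873	8	2	1	6	0.04
rps7	468	468	1	1	0	0	0.21
ndhF	2247-2253	2253	26	14	2	12	0.71
rpl32	162	162	1	1	0	0	0.62
ccsA	963	963	10	10	0	0	1.04
ndhD	1530	1530	3	3	0	0	0.20
psaC	246	246	1	1	0	0	0.41
ndhE	306	306	1	1	0	0	0.33
ndhG	531	531	3	3	0	0	0.56
ndhA	1092	1092	2	2	0	0	0.18
ndhH	1182	1182	2	2	0	0	0.17
rps15	273	273	3	3	0	0	1.10
ycf1	5652-5658	5658	43	37	1	6	0.67
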