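chrom	arm	start	end	centromere	acrocentric
1	p	0	1234000	1234000	False
1	q	1234000	2489564	1234000	False
2	p	0	939000	939000	False
2	q	939000	2421935	939000	False
3	p	0	909000	909000	False
3	q	909000	1982955	909000	False
4	p	0	500000	500000	False
4	q	500000	1902145	500000	False
5	p	0	488000	488000	False
5	q	488000	1815382	488000	False
6	p	0	598000	598000	False
6	q	598000	1708059	598000	False
7	p	0	601000	601000	False
7	q	601000	1593459	601000	False
8	p	0	452000	452000	False
8	q	452000	1451386	452000	False
9	p	0	430000	430000	False
9	q	430000	1383947	430000	False
10	p	0	398000	398000	False
10	q	398000	1337974	398000	False
11	p	0	534000	534000	False
11	q	534000	1350866	534000	False
12	p	0	355000	355000	False
12	q	355000	1332753	355000	False
13	p	0	177000	177000	True
13	q	177000	1143643	177000	False
14	p	0	172000	172000	True
14	q	172000	1070437	172000	False
15	p	0	190000	190000	True
15	q	190000	1019911	190000	False
16	p	0	368000	368000	False
16	q	368000	903383	368000	False
17	p	0	251000	251000	False
17	q	251000	832574	251000	False
18	p	0	185000	185000	False
18	q	185000	803732	185000	False
19	p	0	262000	262000	False
19	q	262000	586176	262000	False
20	p	0	281000	281000	False
20	q	281000	644441	281000	False
21	p	0	120000	120000	True
21	q	120000	467099	120000	False
22	p	0	150000	150000	True
22	q	150000	508184	150000	False
X	p	0	610000	610000	False
X	q	610000	1560408	610000	False
Y	p	0	104000	104000	False
Y	q	104000	572274	104000	False
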