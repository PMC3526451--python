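row	gene	srsf_genome_z	srsf_secondary_z	secondary_flag	hfa_genome_z	hfa_flag	tertiary_z	tertiary_flag
1	dome	-7.9	-7.1		-8.0		-6.7
2	Stat92E	-6.8	-11.4		-6.5		-6.8
3	hop	-5.7	-10.0		-2.6		-4.4
4	mask	-4.3	-6.6		-3.8			NS
5	Mov34	-3.2	-4.1		-3.0		0.1
6	RpL24	-2.6	-2.5		-6.8		0.1
7	Ptp61F	2.3	3.6		5.0		4.1
8	CKIalpha	4.1	2.6		4.8		2.5
9	chinmo	6.6	4.8		7.0		2.7
10	TfIIA-L	-3.8	-5.5		-1.8	hash		NS
11	Chd1	-2.2	-1.7	hash	-2.4			NS
12	Saf-B	2.5	1.8	hash	4.6			NS
13	Socs36E	2.8	1.8	hash	2.5		3.9
14	shrb	2.3	3.0			na1	-0.4
15	dom	-3.4	-2.4			na2	0.9
16	RpLP2	-2.4	-2.2			na2	-0.5
17	CG7185	2.6	1.7			na3	1.6
18	RpII215	-2.2	-2.2			na3	-1.1
19	Dp	-2.2	-2.8		-2.8	single_rep	-0.8
20	CG32269	-3.1	-1.7	hash	-1.7	single_rep	0.2
21	E2f	-3.1	-4.9		-1.0		-1.3
22	CG11873	2.2	2.2		0.0		2.5
23	TSG101	2.3	6.0		1.6		-1.1
24	ftz-f1	2.3	2.7		0.5		2.0
25	kis	2.3	2.5		0.9		0.0
26	lola	3.1	4.0		-0.8		-1.1
27	srp	8.6	8.5		-0.5			NS
28	ctrip	-2.6	-1.9	hash	0.0		-1.1
29	ham	4.5	1.8	hash	-0.5		1.7	hash
30	Tbp	-4.5	0.5		-1.3		-2.0
31	CG40121	-3.6	-1.1		1.4		-3.3
32	Dcp2	-2.0	-0.6		-0.6		-0.4
33	CG9723	-2.0	1.3		-0.5		0.0
34	pcnr017:3R	-2.0	-0.4		1.2		-0.4
35	Cnot4	2.1	0.7		0.5		0.4
36	qkr54B	2.2	0.4		0.3		0.7
37	l(3)mbt	2.6	0.5		-0.4		0.8
38	Hsp60B	2.7	0.1		0.0		0.0
39	Sin	2.7	1.2		1.5		-0.1
40	CG11399	2.8	1.4		0.3		0.2
41	Surf4	3.1	0.8		1.3		-0.7
42	zfh1	5.2	0.8		0.6		0.6
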