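screen	on_target_dsrna	on_target_gene	on_target_score	off_target_fbgn	off_target_gene	off_target_dsrna	off_target_score	hit_flag
HFA	HFA16984	larp	-3.1	FBgn0003013	osa	HFA17022	-4.2	*
HFA	HFA18710	RpS14a	-6.1	FBgn0004404	RpS14b	HFA18711	-4.9	*
HFA	HFA19901	CG4411	-2.3	FBgn0039633	CG11873	BKN26700	2.2
HFA	HFA19901	CG4411	-2.3	FBgn0028991	CG4055	HFA06863	-3.7	*
HFA	HFA19901	CG4411	-2.3	FBgn0043884	mask	HFA16018	-5.6	*
HFA	HFA19901	CG4411	-2.3	FBgn0043884	mask	HFA16005	-5.8	*
HFA	HFA19901	CG4411	-2.3	FBgn0043884	mask	BKN20625	-4.3	*
HFA	HFA19901	CG4411	-2.3	FBgn0004656	fs(1)h	HFA18778	-4.1	*
HFA	HFA19901	CG4411	-2.3	FBgn0086902	kis	BKN20986	2.3
HFA	HFA19901	CG4411	-2.3	FBgn0004864	hop	HFA20340	-5.8	*
HFA	HFA19901	CG4411	-2.3	FBgn0004864	hop	BKN24272	-5.7	*
HFA	HFA12365	Rm62	3.1	FBgn0035720	CG10077	HFA09691	3.1	*
HFA	HFA07091	CG8179	4.9	FBgn0020306	dom	BKN21379	-3.4
HFA	HFA07091	CG8179	4.9	FBgn0015618	Cdk8	HFA11113	-2.3
HFA	HFA07091	CG8179	4.9	FBgn0015903	apt	HFA04671	3.2	*
HFA	HFA07091	CG8179	4.9	FBgn0026575	CG4411	HFA19901	-2.1
HFA	HFA07091	CG8179	4.9	FBgn0260794	ctrip	BKN20611	-2.6
HFA	HFA07091	CG8179	4.9	FBgn0028991	CG4055	HFA06863	-3.7
HFA	HFA07091	CG8179	4.9	FBgn0039633	CG11873	BKN26700	2.2	*
HFA	HFA07091	CG8179	4.9	FBgn0000008	CG14169	HFA10170	-2.2
HFA	HFA07091	CG8179	4.9	FBgn0003013	osa	HFA17022	-4.2
HFA	HFA07091	CG8179	4.9	FBgn0051716	Cnot4	BKN22063	2.1	*
HFA	HFA07091	CG8179	4.9	FBgn0260724	larp	HFA16984	-2.9
HFA	HFA07091	CG8179	4.9	FBgn0035720	CG10077	HFA09691	3.1	*
HFA	HFA07091	CG8179	4.9	FBgn0011666	msi	HFA17003	-2.6
HFA	HFA07091	CG8179	4.9	FBgn0003507	srp	HFA17068	13.6	*
HFA	HFA07091	CG8179	4.9	FBgn0003507	srp	BKN45799	8.6	*
HFA	HFA07091	CG8179	4.9	FBgn0004656	fs(1)h	HFA18778	-4.1
HFA	HFA07091	CG8179	4.9	FBgn0003687	Tbp	BKN20836	-4.5
HFA	HFA07091	CG8179	4.9	FBgn0012049	msi	HFA17003	-2.6
HFA	HFA07091	CG8179	4.9	FBgn0004606	zfh1	BKN29931	5.2	*
HFA	HFA07091	CG8179	4.9	FBgn0001078	ftz-f1	BKN28995	2.3	*
HFA	HFA07091	CG8179	4.9	FBgn0086902	kis	BKN20986	2.3	*
HFA	HFA07091	CG8179	4.9	FBgn0034258	CG4954	HFA06905	-5.5
HFA	HFA07091	CG8179	4.9	FBgn0027492	CkIIbeta	HFA20230	-2.2
HFA	HFA07091	CG8179	4.9	FBgn0032633	CG4055	HFA06863	-3.7
HFA	HFA07091	CG8179	4.9	FBgn0043884	mask	HFA16018	-5.6
HFA	HFA07091	CG8179	4.9	FBgn0043884	CG6268	HFA16005	-5.8
HFA	HFA07091	CG8179	4.9	FBgn0043884	mask	BKN20625	-4.3
HFA	HFA06863	CG4055	-4.2	FBgn0015618	Cdk8	HFA11113	-2.3	*
HFA	HFA06863	CG4055	-4.2	FBgn0000008	CG14169	HFA10170	-2.2	*
HFA	HFA06863	CG4055	-4.2	FBgn0003507	srp	HFA17068	13.6
HFA	HFA06863	CG4055	-4.2	FBgn0003507	srp	BKN45799	8.6
HFA	HFA06863	CG4055	-4.2	FBgn0039633	CG11873	BKN26700	2.2
HFA	HFA06863	CG4055	-4.2	FBgn0001078	ftz-f1	BKN28995	2.3
HFA	HFA06863	CG4055	-4.2	FBgn0086902	kis	BKN20986	2.3
HFA	HFA04671	apt	2.7	FBgn0001078	ftz-f1	BKN28995	2.3	*
HFA	HFA04671	apt	2.7	FBgn0030636	cngl	HFA19089	-2.7
HFA	HFA04671	apt	2.7	FBgn0003507	srp	HFA17068	13.6	*
HFA	HFA04671	apt	2.7	FBgn0003507	srp	BKN45799	8.6	*
HFA	HFA18711	RpS14b	-6.0	FBgn0004403	RpS14a	HFA18710	-4.9	*
HFA	HFA17068	srp	8.5	FBgn0030636	cngl	HFA19089	-2.7
HFA	HFA17068	srp	8.5	FBgn0020306	dom	BKN21379	-3.4
HFA	HFA17068	srp	8.5	FBgn0015618	Cdk8	HFA11113	-2.3
HFA	HFA17068	srp	8.5	FBgn0039633	CG11873	BKN26700	2.2	*
HFA	HFA17068	srp	8.5	FBgn0260794	ctrip	BKN20611	-2.6
HFA	HFA17068	srp	8.5	FBgn0003016	kis	BKN20986	2.3	*
HFA	HFA17068	srp	8.5	FBgn0086758	CG17156	HFA00485	7.0	*
HFA	HFA17068	srp	8.5	FBgn0086758	CG17649	HFA00509	7.0	*
HFA	HFA17068	srp	8.5	FBgn0086758	chinmo	BKN45751	6.6	*
HFA	HFA17068	srp	8.5	FBgn0005630	lola	BKN30256	3.1	*
HFA	HFA17068	srp	8.5	FBgn0000259	CkIIbeta	HFA20230	-2.2
HFA	HFA17068	srp	8.5	FBgn0028371	CG13525	HFA04167	-2.9
HFA	HFA17068	srp	8.5	FBgn0032633	CG4055	HFA06863	-3.7
HFA	HFA17068	srp	8.5	FBgn0015903	apt	HFA04671	3.2	*
HFA	HFA17068	srp	8.5	FBgn0026575	CG4411	HFA19901	-2.1
HFA	HFA17068	srp	8.5	FBgn0001078	ftz-f1	BKN28995	2.3	*
HFA	HFA17068	srp	8.5	FBgn0011666	msi	HFA17003	-2.6
HFA	HFA17068	srp	8.5	FBgn0028991	CG4055	HFA06863	-3.7
HFA	HFA17068	srp	8.5	FBgn0035720	CG10077	HFA09691	3.1	*
HFA	HFA17068	srp	8.5	FBgn0000008	CG14169	HFA10170	-2.2
HFA	HFA17068	srp	8.5	FBgn0086902	kis	BKN20986	2.3	*
HFA	HFA09691	CG10077	2.6	FBgn0003261	Rm62	HFA12365	3.8	*
SRSF	BKN41059	CG40121	-3.6	FBgn0043903	dome	BKN25660	-7.9	*
SRSF	BKN41059	CG40121	-3.6	FBgn0000259	CkIIbeta	HFA20230	-2.2	*
SRSF	BKN41059	CG40121	-3.6	FBgn0004656	fs(1)h	HFA18778	-4.8	*
SRSF	BKN41059	CG40121	-3.6	FBgn0043903	dome	HFA19583	-13.5	*
SRSF	BKN41059	CG40121	-3.6	FBgn0010412	RpS19	HFA20281	-7.0	*
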