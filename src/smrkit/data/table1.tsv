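tissue	chrom	bp	snp	a1	a2	gene	b_gwas	se_gwas	p_gwas	b_eqtl	se_eqtl	p_eqtl	b_smr	se_smr	p_smr	p_heidi
blood	1	161156033	rs11585858	A	C	B4GALT3	0.016	0.003	5.58E-10	-0.168	0.011	1.07E-57	-0.093	0.016	7.33E-09	3.33E-03
blood	1	161186313	rs4379692	T	C	NDUFS2	0.012	0.002	8.25E-08	-0.231	0.009	4.34E-132	-0.053	0.010	1.63E-07	1.22E-01
blood	2	127839474	rs11682128	A	G	BIN1	0.031	0.006	2.21E-08	0.742	0.009	0.00E+00	0.042	0.008	2.36E-08	2.12E-03
blood	6	32573415	rs601945	G	A	HLA-DRA	-0.019	0.003	1.38E-10	-0.117	0.014	1.39E-16	0.160	0.032	3.99E-07	4.25E-03
blood	7	99803412	rs2950517	G	C	CASTOR3	-0.014	0.002	2.15E-09	0.124	0.009	3.30E-42	-0.114	0.021	4.26E-08	8.74E-03
blood	7	143104331	rs3935067	C	G	EPHA1-AS1	0.015	0.002	6.52E-11	-0.466	0.011	0.00E+00	-0.031	0.005	1.11E-10	6.94E-03
blood	14	92955385	rs17783630	C	A	SLC24A4	0.011	0.002	6.71E-07	-0.503	0.008	0.00E+00	-0.021	0.004	7.31E-07	3.28E-02
blood	14	92955385	rs17783630	C	A	RIN3	0.011	0.002	6.71E-07	-0.165	0.009	9.12E-77	-0.064	0.013	1.58E-06	6.15E-02
blood	15	63571820	rs75763893	T	C	APH1B	0.017	0.003	9.15E-08	0.681	0.018	0.00E+00	0.025	0.005	1.22E-07	5.00E-02
blood	17	5014212	rs73976310	A	G	AC012146.7	0.018	0.003	7.04E-08	-0.743	0.013	0.00E+00	-0.024	0.004	8.00E-08	1.55E-02
blood	17	5014212	rs73976310	A	G	ZNF232	0.018	0.003	7.04E-08	-0.305	0.013	8.16E-114	-0.058	0.011	1.57E-07	7.88E-02
blood	19	51731176	rs7245846	A	G	SIGLEC22P	-0.012	0.002	1.19E-07	0.166	0.009	2.38E-70	-0.072	0.014	3.91E-07	1.05E-01
blood	19	51726911	rs1710398	C	A	CD33	0.011	0.002	4.46E-07	0.290	0.009	3.60E-221	0.037	0.007	6.18E-07	4.27E-03
blood	20	54989833	rs6014722	A	T	CASS4	-0.022	0.004	2.62E-09	-0.141	0.016	3.81E-19	0.159	0.032	7.20E-07	4.18E-03
blood	20	54987216	rs17462136	C	G	RPL39P	-0.022	0.004	6.43E-09	-0.208	0.017	5.07E-33	0.106	0.020	1.76E-07	2.50E-03
brain	1	207750568	rs679515	C	T	CR1	-0.025	0.003	1.10E-18	-0.587	0.067	2.10E-18	0.042	0.007	5.17E-10	4.67E-02
brain	17	5014212	rs73976310	G	A	AC012146.7	-0.018	0.003	7.04E-08	0.721	0.062	6.19E-31	-0.025	0.005	1.03E-06	2.73E-01
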