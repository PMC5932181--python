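rsid	chrom	pos	ref_allele	minor_allele	maf	disease	p_value	odds_ratio	is_reported_lead	gene	eqtl	eqtl_direction
rs7559479	2	102452327	A	G	0.22	Crohn's disease	2.2e-10	1.15	False	IL18RAP	Yes	up
rs7559479	2	102452327	A	G	0.22	Celiac disease	1.4e-16	1.19	False	IL18RAP	Yes	up
rs7559479	2	102452327	A	G	0.22	Inflammatory bowel disease	NA	NA	False	IL18RAP	Yes	up
rs7603250	2	102452374	A	T	0.22	Crohn's disease	1.6e-10	0.8	False	IL18RAP	Yes	up
rs7603250	2	102452374	A	T	0.22	Inflammatory bowel disease	1.8e-09	0.8	False	IL18RAP	Yes	up
rs7603250	2	102452374	A	T	0.22	Celiac disease	NA	NA	False	IL18RAP	Yes	up
rs3732421	3	119431242	A	G	0.16	Multiple sclerosis	3.5e-12	0.85	False	TMEM39A	No	NA
rs3732421	3	119431242	A	G	0.16	Primary biliary cirrhosis	1.7e-11	0.72	False	TMEM39A	No	NA
rs57271503	3	119525746	G	A	0.16	Multiple sclerosis	4.1e-15	0.84	False	CD80	No	NA
rs57271503	3	119525746	G	A	0.16	Primary biliary cirrhosis	9.4e-13	0.71	False	CD80	No	NA
rs1054037	4	102631552	T	C	0.49	Primary biliary cirrhosis	8.3e-10	0.82	True	MANBA	Yes	down/up
rs1054037	4	102631552	T	C	0.49	Multiple sclerosis	NA	NA	False	MANBA	Yes	down/up
rs4013	4	102631656	T	C	0.51	Primary biliary cirrhosis	NA	NA	False	MANBA	Yes	down/up
rs4013	4	102631656	T	C	0.51	Multiple sclerosis	NA	NA	False	MANBA	Yes	down/up
rs1054029	4	102631896	A	G	0.51	Primary biliary cirrhosis	NA	NA	False	MANBA	Yes	down/up
rs1054029	4	102631896	A	G	0.51	Multiple sclerosis	NA	NA	False	MANBA	Yes	down/up
rs39602	5	97028750	G	C	0.41	Ankylosing spondylitis	NA	NA	False	LNPEP	Yes	down
rs39602	5	97028750	G	C	0.41	Crohn's disease	6.9e-11	1.1	False	LNPEP	Yes	down
rs39602	5	97028750	G	C	0.41	Juvenile idiopathic arthritis	NA	NA	False	LNPEP	Yes	down
rs2070197	7	128948946	T	C	0.1	Systemic lupus erythematosus	3.0e-40	1.7	True	IRF5	Yes	up
rs2070197	7	128948946	T	C	0.1	Primary biliary cirrhosis	1.8e-18	1.5	False	IRF5	Yes	up
rs10114470	9	114785492	C	T	0.33	Crohn's disease	1.5e-15	1.1	False	TNFSF15	Yes	up
rs10114470	9	114785492	C	T	0.33	Inflammatory bowel disease	1.5e-16	0.8	False	TNFSF15	Yes	up
rs3088081	9	136375697	A	G	0.42	Inflammatory bowel disease	1.9e-22	0.8	False	SNAPC4	Yes	down
rs3088081	9	136375697	A	G	0.42	Crohn's disease	2.1e-17	0.8	False	SNAPC4	Yes	down
rs3088081	9	136375697	A	G	0.42	Ulcerative colitis	1.0e-11	0.8	False	SNAPC4	Yes	down
rs9943	13	39752145	A	G	0.34	Juvenile idiopathic arthritis	NA	NA	False	COG6	Yes	down
rs9943	13	39752145	A	G	0.34	Rheumatoid arthritis	NA	NA	False	COG6	Yes	down
rs3839999	13	99385548	AT	A	0.22	Crohn's disease	NA	NA	False	UBAC2	No	NA
rs3839999	13	99385548	AT	A	0.22	Inflammatory bowel disease	NA	NA	False	UBAC2	No	NA
rs907091	17	39765489	C	T	0.51	Primary biliary cirrhosis	1.0e-10	0.79	False	IKZF3	Yes	down
rs907091	17	39765489	C	T	0.51	Type 1 diabetes mellitus	NA	NA	False	IKZF3	Yes	down
rs907091	17	39765489	C	T	0.51	Ulcerative colitis	8.1e-09	0.8	False	IKZF3	Yes	down
rs907091	17	39765489	C	T	0.51	Inflammatory bowel disease	3.3e-13	0.8	False	IKZF3	Yes	down
rs16940681	17	45834793	G	C	0.24	Primary biliary cirrhosis	NA	NA	False	CRHR1	Yes	up
rs16940681	17	45834793	G	C	0.24	Type 1 diabetes mellitus	NA	NA	False	CRHR1	Yes	up
rs2316765	17	45835088	T	C	0.24	Primary biliary cirrhosis	NA	NA	False	CRHR1	Yes	up
rs2316765	17	45835088	T	C	0.24	Type 1 diabetes mellitus	NA	NA	False	CRHR1	Yes	up
rs878886	17	45835124	C	G	0.24	Primary biliary cirrhosis	NA	NA	False	CRHR1	Yes	up
rs878886	17	45835124	C	G	0.24	Type 1 diabetes mellitus	NA	NA	False	CRHR1	Yes	up
rs878887	17	45835216	C	T	0.24	Primary biliary cirrhosis	NA	NA	False	CRHR1	Yes	up
rs878887	17	45835216	C	T	0.24	Type 1 diabetes mellitus	NA	NA	False	CRHR1	Yes	up
rs878888	17	45835269	A	G	0.24	Primary biliary cirrhosis	NA	NA	False	CRHR1	Yes	up
rs878888	17	45835269	A	G	0.24	Type 1 diabetes mellitus	NA	NA	False	CRHR1	Yes	up
rs4640231	17	45835420	G	C	0.24	Primary biliary cirrhosis	NA	NA	False	CRHR1	Yes	up
rs4640231	17	45835420	G	C	0.24	Type 1 diabetes mellitus	NA	NA	False	CRHR1	Yes	up
rs4482334	17	45835464	T	C	0.24	Primary biliary cirrhosis	NA	NA	False	CRHR1	Yes	up
rs4482334	17	45835464	T	C	0.24	Type 1 diabetes mellitus	NA	NA	False	CRHR1	Yes	up
rs12373168	17	45846971	A	C	0.24	Primary biliary cirrhosis	NA	NA	False	SPPL2C	No	NA
rs12373168	17	45846971	A	C	0.24	Type 1 diabetes mellitus	NA	NA	False	SPPL2C	No	NA
rs60474474	18	12792737	C	T	0.14	Inflammatory bowel disease	1.4e-10	1.1	False	PTPN2	No	NA
rs60474474	18	12792737	C	T	0.14	Crohn's disease	2.2e-12	1.2	False	PTPN2	No	NA
rs60474474	18	12792737	C	T	0.14	Type 1 diabetes mellitus	NA	NA	False	PTPN2	No	NA
rs60474474	18	12792737	C	T	0.14	Celiac disease	NA	NA	False	PTPN2	No	NA
rs60474474	18	12792737	C	T	0.14	Juvenile idiopathic arthritis	NA	NA	False	PTPN2	No	NA
rs45450798	18	12792941	C	G	0.14	Inflammatory bowel disease	2.0e-10	0.8	False	PTPN2	No	NA
rs45450798	18	12792941	C	G	0.14	Crohn's disease	2.9e-12	0.8	False	PTPN2	No	NA
rs45450798	18	12792941	C	G	0.14	Type 1 diabetes mellitus	NA	NA	False	PTPN2	No	NA
rs45450798	18	12792941	C	G	0.14	Celiac disease	NA	NA	False	PTPN2	No	NA
rs45450798	18	12792941	C	G	0.14	Juvenile idiopathic arthritis	NA	NA	False	PTPN2	No	NA
rs9950174	18	69846569	T	C	0.53	Psoriasis	NA	NA	False	CD226	Yes	up
rs727088	18	69863203	G	A	0.53	Inflammatory bowel disease	4.6e-9	1.08	True	CD226	Yes	up
rs727088	18	69863203	G	A	0.53	Ulcerative colitis	1.9e-8	1.1	True	CD226	Yes	up
rs727088	18	69863203	G	A	0.53	Psoriasis	NA	NA	False	CD226	Yes	up
rs571689	19	48704297	C	T	0.47	Crohn's disease	7.3e-09	1.1	False	FUT2	Yes	down
rs571689	19	48704297	C	T	0.47	Type 1 diabetes mellitus	NA	NA	False	FUT2	Yes	down
rs570794	19	48704394	T	C	0.47	Crohn's disease	1.0e-08	0.8	False	FUT2	Yes	down
rs570794	19	48704394	T	C	0.47	Type 1 diabetes mellitus	NA	NA	False	FUT2	Yes	down
rs507766	19	48705286	T	C	0.47	Crohn's disease	1.4e-08	0.8	False	FUT2	Yes	down
rs507766	19	48705286	T	C	0.47	Type 1 diabetes mellitus	NA	NA	False	FUT2	Yes	down
rs506897	19	48705372	G	C	0.47	Crohn's disease	7.3e-09	1.1	False	FUT2	Yes	down
rs506897	19	48705372	G	C	0.47	Type 1 diabetes mellitus	NA	NA	False	FUT2	Yes	down
rs503279	19	48705753	T	C	0.47	Crohn's disease	6.7e-09	0.8	False	FUT2	Yes	down
rs503279	19	48705753	T	C	0.47	Type 1 diabetes mellitus	NA	NA	False	FUT2	Yes	down
rs1056441	20	63738996	C	T	0.28	Crohn's disease	5.4e-11	0.8	False	LIME1	Yes	down
rs1056441	20	63738996	C	T	0.28	Inflammatory bowel disease	1.5e-15	0.8	False	LIME1	Yes	down
rs7444	22	21622645	T	C	0.2	Systemic lupus erythematosus	1.8e-22	1.27	True	UBE2L3	Yes	up
rs7444	22	21622645	T	C	0.2	Crohn's disease	1.3e-12	1.1	False	UBE2L3	Yes	up
rs7444	22	21622645	T	C	0.2	Inflammatory bowel disease	6.9e-10	0.8	False	UBE2L3	Yes	up
rs7445	22	21622758	C	T	0.19	Crohn's disease	6.3e-09	1.1	False	UBE2L3	Yes	up
rs7445	22	21622758	C	T	0.19	Inflammatory bowel disease	3.5e-10	1.1	False	UBE2L3	Yes	up
rs7445	22	21622758	C	T	0.19	Systemic lupus erythematosus	1.0e-12	1.27	False	UBE2L3	Yes	up
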