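rsid	gene	mirna	effect	nbc_score
rs7559479	IL18RAP	hsa-miR-3156-3p	C	0.79
rs7559479	IL18RAP	hsa-miR-4301	C	0.86
rs7559479	IL18RAP	hsa-miR-136	C	0.92
rs7603250	IL18RAP	hsa-miR-455-3p	C	0.94
rs3732421	TMEM39A	hsa-miR-449b-3p	D	0.72
rs3732421	TMEM39A	hsa-miR-4691-3p	D	0.82
rs3732421	TMEM39A	hsa-miR-449b	D	0.92
rs57271503	CD80	hsa-miR-769-5p	C	0.71
rs57271503	CD80	hsa-miR-4802-5p	C	0.80
rs57271503	CD80	hsa-miR-769-5p	C	0.71
rs1054037	MANBA	hsa-miR-660	D	0.90
rs1054037	MANBA	hsa-miR-5591-3p	D	0.95
rs1054037	MANBA	hsa-miR-660-5p	D	0.82
rs1054037	MANBA	hsa-miR-7151-5p	C	0.71
rs1054037	MANBA	hsa-miR-3686	C	0.94
rs4013	MANBA	hsa-miR-4742-3p	C	0.76
rs4013	MANBA	hsa-miR-4778-5p	C	0.91
rs4013	MANBA	hsa-miR-630	C	0.82
rs1054029	MANBA	hsa-miR-124-5p	D	0.80
rs1054029	MANBA	hsa-miR-4255	D	0.99
rs1054029	MANBA	hsa-miR-4766-5p	D	0.74
rs1054029	MANBA	hsa-miR-124	D	0.90
rs1054029	MANBA	hsa-miR-33a	D	0.77
rs39602	LNPEP	hsa-miR-6800-5p	D	0.99
rs2070197	IRF5	hsa-miR-3136-3p	D	0.91
rs2070197	IRF5	hsa-miR-7155-3p	D	0.89
rs10114470	TNFSF15	hsa-miR-376a-3p	D	0.84
rs10114470	TNFSF15	hsa-miR-4753-5p	D	0.74
rs3088081	SNAPC4	hsa-miR-3661	C	0.80
rs9943	COG6	hsa-miR-628-5p	C	0.98
rs3839999	UBAC2	hsa-miR-365a-3p	C	0.93
rs907091	IKZF3	hsa-miR-4497	D	0.97
rs907091	IKZF3	hsa-miR-3649	C	0.85
rs907091	IKZF3	hsa-miR-4518	C	0.92
rs907091	IKZF3	hsa-miR-330-5p	C	0.99
rs907091	IKZF3	hsa-miR-518c	C	0.86
rs907091	IKZF3	hsa-miR-4314	C	0.84
rs907091	IKZF3	hsa-miR-326	C	0.99
rs907091	IKZF3	hsa-miR-3192	C	0.73
rs16940681	CRHR1	hsa-miR-6740-5p	D	0.84
rs2316765	CRHR1	hsa-miR-3192	D	0.73
rs2316765	CRHR1	hsa-miR-30c-2-3p	D	0.97
rs2316765	CRHR1	hsa-miR-30c-1-3p	D	0.90
rs878886	CRHR1	hsa-miR-4685-5p	D	0.96
rs878886	CRHR1	hsa-miR-1915-3p	D	0.71
rs878886	CRHR1	hsa-miR-3918	D	0.86
rs878886	CRHR1	hsa-miR-7160-3p	D	0.76
rs878887	CRHR1	hsa-miR-198	C	0.85
rs878887	CRHR1	hsa-miR-3186-5p	D	0.88
rs878887	CRHR1	hsa-miR-136	C	0.92
rs878888	CRHR1	hsa-miR-5708	C	0.70
rs878888	CRHR1	hsa-miR-1226-5p	D	0.72
rs4640231	CRHR1	hsa-miR-6841-5p	D	0.81
rs4640231	CRHR1	hsa-miR-6755-5p	D	0.77
rs4482334	CRHR1	hsa-miR-6890-5p	D	0.93
rs4482334	CRHR1	hsa-miR-6742-5p	D	0.94
rs4482334	CRHR1	hsa-miR-4722-5p	D	0.77
rs4482334	CRHR1	hsa-miR-6796-5p	D	0.75
rs4482334	CRHR1	hsa-miR-4459	D	0.80
rs12373168	SPPL2C	hsa-miR-33b-3p	D	0.87
rs12373168	SPPL2C	hsa-miR-519e-3p	D	0.87
rs60474474	PTPN2	hsa-miR-4290	D	0.99
rs45450798	PTPN2	hsa-miR-4531	C	0.73
rs9950174	CD226	hsa-miR-5189-3p	D	0.85
rs727088	CD226	hsa-miR-513a-3p	D	0.75
rs727088	CD226	hsa-miR-181c	D	0.75
rs571689	FUT2	hsa-miR-648	D	0.89
rs571689	FUT2	hsa-miR-552-3p	C	0.92
rs570794	FUT2	hsa-miR-4430	D	0.71
rs570794	FUT2	hsa-miR-1295b-5p	C	0.79
rs570794	FUT2	hsa-miR-4463	C	0.95
rs570794	FUT2	hsa-miR-1912	C	0.94
rs507766	FUT2	hsa-miR-136-5p	C	0.83
rs507766	FUT2	hsa-miR-675	C	0.80
rs507766	FUT2	hsa-miR-887	C	0.92
rs507766	FUT2	hsa-miR-410	C	0.73
rs507766	FUT2	hsa-miR-191	C	0.75
rs506897	FUT2	hsa-miR-4530	C	0.81
rs503279	FUT2	hsa-miR-675-3p	C	0.86
rs1056441	LIME1	hsa-miR-4745-3p	C	0.97
rs1056441	LIME1	hsa-miR-1538	C	0.97
rs1056441	LIME1	hsa-miR-4467	C	0.87
rs1056441	LIME1	hsa-miR-6770-3p	C	0.78
rs1056441	LIME1	hsa-miR-3940-3p	D	0.82
rs1056441	LIME1	hsa-miR-762	D	0.94
rs7444	UBE2L3	hsa-miR-4741	D	0.90
rs7444	UBE2L3	hsa-miR-4763-3p	D	0.89
rs7444	UBE2L3	hsa-miR-3918	D	0.86
rs7444	UBE2L3	hsa-miR-1207-5p	D	0.92
rs7445	UBE2L3	hsa-miR-3064-5p	C	0.93
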