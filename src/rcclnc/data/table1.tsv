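probe_accession	lnc_type	host_refseq	host_symbol	coords	fdr_pct	lnc_fold_change	host_fold_change_raw
AW835362	Intronic	NM_001553	IGFBP7	chr4:57928550-57929060	0.00	4.88	-1.15 (2/4)
AW881130	Intronic	NM_006868	RAB31	chr18:9711672-9712160	0.00	3.72	**2.56 (5/5)**
BF881464	Intronic	NM_004930	CAPZB	chr1:19724054-19724494	0.00	2.03	1.34 (3/5)*
AW846722	Intronic	NM_024113	C11orf49	chr11:47169567-47169799	0.00	2.02	-0.34 (2/4)
AW815357	Intronic	NM_153326	AKR1A1	chr1:46029945-46030338	0.00	1.77	**-2.20 (3/3)**
AW937741	Intronic	NM_003137	SRPK1	chr6:35819568-35820194	2.46	1.7	-1.37 (3/4)
BF350736	Intronic	NM_025228	TRAF3IP3	chr1:209954933-209955401	1.93	1.65	1.39 (4/4)
CK327196	Intronic	NM_002581	PAPPA	chr9:119104917-119105402	1.86	1.63	**-3.49 (5/5)**
BF743551	Intronic	NM_005720	ARPC1B	chr7:98991157-98991537	1.37	1.6	**2.90 (5/5)**
AW748493	Intronic	NM_001098634	RBM47	chr4:40563872-40564416	3.16	-1.52	**-1.82 (4/4)**
CK327206	Intronic	NM_015995	KLF13	chr15:31628837-31629268	2.46	-1.53	1.19 (1/4)
CK327137	Intronic	NM_173355	UPP2	chr2:158886308-158886559	1.37	-1.55	**-6.05 (1/2)**
BE168993	Intronic	NM_005882	MAEA	chr4:1318234-1318651	1.68	-1.56	**-1.63 (2/4)**
BE181783	Intronic	NM_001893	CSNK1D	chr17:80226176-80226555	0.75	-1.63	-1.28 (3/3)*
AW836810	Intronic	NM_000314	PTEN	chr10:89630175-89630699	0.00	-1.63	**1.74 (4/4)**
BG010306	Intronic	NM_005474	HDAC5	chr17:42175003-42175469	0.75	-1.66	0.00 (0/3)
BF327015	Intronic	NM_003298	NR2C2	chr3:15052840-15053222	0.00	-1.7	-0.34 (0/5)
BF882783	Intronic	NM_004924	ACTN4	chr19:39203995-39204367	0.75	-1.74	-0.29 (1/5)
BF357721	Intronic	NM_002755	MAP2K1	chr15:66764897-66765436	0.00	-1.78	**1.52 (3/4)**
BF360792	Intronic	NM_020387	RAB25	chr1:156032114-156032418	0.75	-1.79	**-5.17 (4/4)**
CK327077	Intronic	NM_001170704	MBNL3	chrX:131621693-131622042	0.00	-1.9	-0.79 (0/5)
CK327106	Intronic	NM_005781	TNK2	chr3:195591793-195592189	0.00	-1.95	-1.16 (4/4)*
BF768459	Intronic	NM_004924	ACTN4	chr19:39200205-39200785	0.00	-2.01	-0.29 (1/5)*
BF368747	Intronic	NM_006516	SLC2A1	chr1:43409776-43410148	0.00	-2.01	**4.43 (5/5)**
BE080597	Intronic	NM_002829	PTPN3	chr9:112237298-112237614	0.00	-2.13	**-2.15 (5/5)**
BF332192	Intronic	NM_017890	VPS13B	chr8:100419550-100419768	0.00	-2.13	1.37 (3/5)
BE168995	Intronic	NM_018253	YY1AP1	chr1:155656314-155656660	0.00	-2.23	n.d.
CK327034	Intronic	NM_015575	GIGYF2	chr2:233592945-233593379	0.00	-2.45	1.16 (2/4)
BF368584	Intronic	NM_006260	DNAJC3	chr13:96432041-96432369	0.00	-2.81	**1.74 (1/1)**
BF368636	lincRNA1 RefSeq ncRNA	NR_028288	TCL6	chr14:96131134-96131552	0.00	1.92	-
AW880409	lincRNA2 RefSeq ncRNA	NR_003255 and NR_001564	TSIX and XIST	chrX:73042786-73043127	1.95	1.74	-
AW880864	lincRNA3	n.a.	n.a.	chr9:18430899-18431447	0.41	1.68	-
BF987841	lincRNA4	n.a.	n.a.	chr14:53107162-53107542	1.12	1.64	-
AW880828	lincRNA5	n.a.	n.a.	chr2:26955660-26956225	0.78	1.63	-
BF333219	lincRNA6	n.a.	n.a.	chr12:49324983-49325465	0.75	-1.63	-
BG009895	lincRNA7	n.a.	n.a.	chr21:19119867-19120311	0.00	-1.74	-
BE710971	lincRNA8	n.a.	n.a.	chr17:18176339-18176682	0.00	-1.93	-
BE718437	lincRNA9	n.a.	n.a.	chr17:56595754-56596085	0.00	-1.94	-
BF333731	lincRNA10	n.a.	n.a.	chr17:62118605-62119046	0.00	-2.19	-
AW996872	lincRNA11	n.a.	n.a.	chr15:58887770-58888280	0.00	-2.45	-
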