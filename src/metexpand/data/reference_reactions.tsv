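reaction_id	ec	native_substrate	substrate_type	organism	has_sequence	rule_id	substrate_smiles	product_smiles
RXN-R7OMT	2.1.1.291	reticuline	BIA	Papaver somniferum	true	omt-aromatic	COc1ccc(CC2N(C)CCc3cc(OC)c(O)cc23)cc1O	COc1ccc(CC2N(C)CCc3cc(OC)c(OC)cc23)cc1O
RXN-R7OMTb	2.1.1.291	N-methylcoclaurine	BIA	Papaver somniferum	true	omt-aromatic	Oc1ccc(CC2N(C)CCc3cc(OC)c(O)cc23)cc1	Oc1ccc(CC2N(C)CCc3cc(OC)c(OC)cc23)cc1
RXN-ColOMT	2.1.1.118	columbamine	BIA	Coptis japonica	true	omt-aromatic	COc1cc2c(cc1O)-c1cc3ccc(OC)c(OC)c3c[n+]1CC2	COc1cc2c(cc1OC)-c1cc3ccc(OC)c(OC)c3c[n+]1CC2
RXN-6OMT	2.1.1.128	norcoclaurine	BIA	Papaver somniferum	true	omt-aromatic	Oc1ccc(CC2NCCc3cc(O)c(O)cc23)cc1	Oc1ccc(CC2NCCc3cc(OC)c(O)cc23)cc1
RXN-4pOMT	2.1.1.116	3'-hydroxy-N-methylcoclaurine	BIA	Papaver somniferum	true	omt-aromatic	Oc1ccc(CC2N(C)CCc3cc(OC)c(O)cc23)cc1O	COc1ccc(CC2N(C)CCc3cc(OC)c(O)cc23)cc1O
RXN-IeOMT	2.1.1.146	isoeugenol	phenylpropanoid	Ocimum basilicum	true	omt-aromatic	COc1cc(C=CC)ccc1O	COc1cc(C=CC)ccc1OC
RXN-PurOMT	2.1.1.38	O-demethylpuromycin	antibiotic	Streptomyces alboniger	true	omt-aromatic	CN(C)c1ncnc2c1ncn2C1OC(CO)C(NC(=O)C(N)Cc2ccc(O)cc2)C1O	CN(C)c1ncnc2c1ncn2C1OC(CO)C(NC(=O)C(N)Cc2ccc(OC)cc2)C1O
RXN-COMT	2.1.1.6	catechol	phenol	Rattus norvegicus	true	omt-aromatic	Oc1ccccc1O	COc1ccccc1O
RXN-HI4OMT	2.1.1.212	2,4',7-trihydroxyisoflavanone	flavonoid	Lotus japonicus	true	omt-aromatic	O=C1c2ccc(O)cc2OC(O)C1c1ccc(O)cc1	O=C1c2ccc(O)cc2OC(O)C1c1ccc(OC)cc1
RXN-ASMT	2.1.1.4	N-acetylserotonin	neurotransmitter	Homo sapiens	true	omt-aromatic	CC(=O)NCCc1c[nH]c2ccc(O)cc12	CC(=O)NCCc1c[nH]c2ccc(OC)cc12
RXN-S9OMT	2.1.1.117	scoulerine	BIA	Papaver somniferum	true	omt-aromatic	COc1ccc2c(c1O)CN1CCc3cc(OC)c(O)cc3C1C2	COc1ccc2c(c1OC)CN1CCc3cc(OC)c(O)cc3C1C2
RXN-F4pOMT	2.1.1.231	4'-hydroxyflavone	flavonoid	Glycine max	true	omt-aromatic	O=c1cc(-c2ccc(O)cc2)oc2ccccc12	O=c1cc(-c2ccc(OC)cc2)oc2ccccc12
RXN-CaOMT	2.1.1.68	(E)-caffeate	phenylpropanoid	Arabidopsis thaliana	true	omt-aromatic	O=C(O)C=Cc1ccc(O)c(O)c1	O=C(O)C=Cc1ccc(O)c(OC)c1
RXN-CCoAOMT	2.1.1.104	caffeoyl-CoA	phenylpropanoid	Arabidopsis thaliana	true	omt-aromatic	CSC(=O)C=Cc1ccc(O)c(O)c1	CSC(=O)C=Cc1ccc(O)c(OC)c1
RXN-MsCaOMT	2.1.1.150	(E)-caffeate	phenylpropanoid	Medicago sativa	true	omt-aromatic	O=C(O)C=Cc1ccc(O)c(O)c1	O=C(O)C=Cc1ccc(O)c(OC)c1
RXN-UbiOMT	2.1.1.222	3-demethylubiquinol	quinone	Escherichia coli	true	omt-aromatic	Cc1c(O)c(O)c(OC)c(O)c1CC=C(C)C	Cc1c(O)c(OC)c(OC)c(O)c1CC=C(C)C
RXN-AIMT	2.1.1.279	trans-anol	phenol	Pimpinella anisum	true	omt-aromatic	CC=Cc1ccc(O)cc1	CC=Cc1ccc(OC)cc1
RXN-T16OMT	2.1.1.94	16-hydroxytabersonine	terpene indole alkaloid	Catharanthus roseus	true	omt-aromatic	COC(=O)c1[nH]c2ccc(O)cc2c1C	COC(=O)c1[nH]c2ccc(OC)cc2c1C
RXN-COQ3	2.1.1.114	3,4-dihydroxy-5-all-trans-polyprenylbenzoate	quinone	Saccharomyces cerevisiae	true	omt-aromatic	O=C(O)c1cc(O)c(O)c(CC=C(C)C)c1	O=C(O)c1cc(OC)c(O)c(CC=C(C)C)c1
RXN-THCB2OMT	2.1.1.89	tetrahydrocolumbamine	BIA	unknown (orphan)	false	omt-aromatic	COc1ccc2c(c1OC)CN1CCc3cc(OC)c(O)cc3C1C2	COc1ccc2c(c1OC)CN1CCc3cc(OC)c(OC)cc3C1C2
RXN-CAS	1.14.19.69	tetrahydrocolumbamine	BIA	Coptis japonica	true	methylenedioxy	COc1ccc2c(c1OC)CN1CCc3cc(OC)c(O)cc3C1C2	COc1ccc2c(c1OC)CN1CCc3cc4OCOc4cc3C1C2
RXN-CFS	1.14.19.71	scoulerine	BIA	Eschscholzia californica	true	methylenedioxy	COc1ccc2c(c1O)CN1CCc3cc(OC)c(O)cc3C1C2	COc1cc2c(cc1O)C1Cc3ccc4c(c3CN1CC2)OCO4
RXN-NDS	1.14.19.73	scoulerine	BIA	Nandina domestica	true	methylenedioxy	COc1ccc2c(c1O)CN1CCc3cc(OC)c(O)cc3C1C2	COc1ccc2c(c1O)CN1CCc3cc4c(cc3C1C2)OCO4
RXN-SPS	1.14.19.74	cheilanthifoline	BIA	Eschscholzia californica	true	methylenedioxy	COc1cc2c(cc1O)C1Cc3ccc4c(c3CN1CC2)OCO4	c1cc2c(c3c1CC1c4cc5c(cc4CCN1C3)OCO5)OCO2
RXN-CNMT	2.1.1.140	coclaurine	BIA	Papaver somniferum	true	nmt-secondary	Oc1ccc(CC2NCCc3cc(OC)c(O)cc23)cc1	Oc1ccc(CC2N(C)CCc3cc(OC)c(O)cc23)cc1
RXN-TNMT	2.1.1.122	canadine	BIA	Papaver somniferum	true	nmt-quaternary	COc1ccc2c(c1OC)CN1CCc3cc4OCOc4cc3C1C2	COc1ccc2c(c1OC)C[N+]1(C)CCc3cc4OCOc4cc3C1C2
RXN-BBE	1.21.3.3	reticuline	BIA	Papaver somniferum	true	bbe-bridge	COc1ccc(CC2N(C)CCc3cc(OC)c(O)cc23)cc1O	COc1ccc2c(c1O)CN1CCc3cc(OC)c(O)cc3C1C2
RXN-STOX	1.3.3.8	canadine	BIA	Berberis wilsoniae	true	thb-oxidase	COc1ccc2c(c1OC)CN1CCc3cc4OCOc4cc3C1C2	COc1ccc2cc3[n+](cc2c1OC)CCc1cc2c(cc1-3)OCO2
RXN-NMCH	1.14.14.102	N-methylcoclaurine	BIA	Papaver somniferum	true	arom-hydroxylation	Oc1ccc(CC2N(C)CCc3cc(OC)c(O)cc23)cc1	Oc1ccc(CC2N(C)CCc3cc(OC)c(O)cc23)cc1O
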