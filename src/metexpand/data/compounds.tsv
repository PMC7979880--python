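name	smiles
norcoclaurine	Oc1ccc(CC2NCCc3cc(O)c(O)cc23)cc1
coclaurine	Oc1ccc(CC2NCCc3cc(OC)c(O)cc23)cc1
N-methylcoclaurine	Oc1ccc(CC2N(C)CCc3cc(OC)c(O)cc23)cc1
3'-hydroxy-N-methylcoclaurine	Oc1ccc(CC2N(C)CCc3cc(OC)c(O)cc23)cc1O
reticuline	COc1ccc(CC2N(C)CCc3cc(OC)c(O)cc23)cc1O
scoulerine	COc1ccc2c(c1O)CN1CCc3cc(OC)c(O)cc3C1C2
tetrahydrocolumbamine	COc1ccc2c(c1OC)CN1CCc3cc(OC)c(O)cc3C1C2
canadine	COc1ccc2c(c1OC)CN1CCc3cc4OCOc4cc3C1C2
N-methylcanadine	COc1ccc2c(c1OC)C[N+]1(C)CCc3cc4OCOc4cc3C1C2
1-hydroxy-N-methylcanadine	COc1ccc2c(c1OC)C[N+]1(C)CCc3cc4OCOc4c(O)c3C1C2
1,13-dihydroxy-N-methylcanadine	COc1ccc2c(c1OC)C[N+]1(C)CCc3cc4OCOc4c(O)c3C1C2O
1-hydroxy-13-O-acetyl-N-methylcanadine	COc1ccc2c(c1OC)C[N+]1(C)CCc3cc4OCOc4c(O)c3C1C2OC(C)=O
1,8-dihydroxy-13-O-acetyl-N-methylcanadine	COc1ccc2c(c1OC)C(O)[N+]1(C)CCc3cc4OCOc4c(O)c3C1C2OC(C)=O
4'-O-desmethyl-3-O-acetylpapaveroxine	CN1CCc2cc3OCOc3c(O)c2C1C(OC(C)=O)c1ccc(OC)c(OC)c1C=O
3-O-acetylpapaveroxine	CN1CCc2cc3OCOc3c(OC)c2C1C(OC(C)=O)c1ccc(OC)c(OC)c1C=O
narcotine hemiacetal	CN1CCc2cc3OCOc3c(OC)c2C1C1OC(O)c2c(OC)c(OC)ccc21
noscapine	CN1CCc2cc3OCOc3c(OC)c2C1C1OC(=O)c2c(OC)c(OC)ccc21
tetrahydropalmatine	COc1ccc2c(c1OC)CN1CCc3cc(OC)c(OC)cc3C1C2
armepavine	Oc1ccc(CC2N(C)CCc3cc(OC)c(OC)cc23)cc1
laudanine	COc1ccc(CC2N(C)CCc3cc(OC)c(OC)cc23)cc1O
nandinine	COc1ccc2c(c1O)CN1CCc3cc4c(cc3C1C2)OCO4
codamine	COc1ccc(CC2N(C)CCc3cc(OC)c(O)cc23)cc1OC
norreticuline	COc1ccc(CC2NCCc3cc(OC)c(O)cc23)cc1O
norlaudanosoline	Oc1ccc(CC2NCCc3cc(O)c(O)cc23)cc1O
tetrahydropalmatrubine	COc1ccc2c(c1O)CN1CCc3cc(OC)c(OC)cc3C1C2
cheilanthifoline	COc1cc2c(cc1O)C1Cc3ccc4c(c3CN1CC2)OCO4
stylopine	c1cc2c(c3c1CC1c4cc5c(cc4CCN1C3)OCO5)OCO2
berberine	COc1ccc2cc3[n+](cc2c1OC)CCc1cc2c(cc1-3)OCO2
columbamine	COc1cc2c(cc1O)-c1cc3ccc(OC)c(OC)c3c[n+]1CC2
palmatine	COc1cc2c(cc1OC)-c1cc3ccc(OC)c(OC)c3c[n+]1CC2
salutaridine	CN1CCC23C=C(OC)C(=O)C=C2C1Cc1cc(OC)c(O)cc13
stepholidine	COc1ccc2c(c1O)CN1CCc3cc(O)c(OC)cc3C1C2
allocryptopine	CN1CCc2cc3OCOc3cc2CC(=O)c2ccc(OC)c(OC)c2C1
corytuberine	CN1CCc2cc(O)c(OC)c3c2C1Cc1ccc(OC)c(O)c1-3
lambertine	COc1ccc2cc3N(Cc2c1OC)CCc1cc2c(cc1-3)OCO2
1,2-dehydroreticuline	COc1ccc(CC2=[N+](C)CCc3cc(OC)c(O)cc32)cc1O
papaverine	COc1ccc(Cc2nccc3cc(OC)c(OC)cc23)cc1OC
bicuculline	CN1CCc2cc3OCOc3cc2C1C1OC(=O)c2ccc3OCOc3c21
4'-O-methyl-N-methylcoclaurine	COc1ccc(CC2N(C)CCc3cc(OC)c(O)cc23)cc1
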