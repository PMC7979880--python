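name	catalog_class	database	identifier
norcoclaurine	biological	BIODB	B0001
coclaurine	biological	BIODB	B0002
N-methylcoclaurine	biological	BIODB	B0003
3'-hydroxy-N-methylcoclaurine	biological	BIODB	B0004
reticuline	biological	BIODB	B0005
scoulerine	biological	BIODB	B0006
tetrahydrocolumbamine	biological	BIODB	B0007
canadine	biological	BIODB	B0008
N-methylcanadine	biological	BIODB	B0009
1-hydroxy-N-methylcanadine	biological	BIODB	B0010
1,13-dihydroxy-N-methylcanadine	biological	BIODB	B0011
1-hydroxy-13-O-acetyl-N-methylcanadine	biological	BIODB	B0012
1,8-dihydroxy-13-O-acetyl-N-methylcanadine	biological	BIODB	B0013
4'-O-desmethyl-3-O-acetylpapaveroxine	biological	BIODB	B0014
3-O-acetylpapaveroxine	biological	BIODB	B0015
narcotine hemiacetal	biological	BIODB	B0016
noscapine	biological	BIODB	B0017
tetrahydropalmatine	biological	BIODB	B0018
tetrahydropalmatine	bioactive	ACTDB	A0001
armepavine	biological	BIODB	B0019
laudanine	biological	BIODB	B0020
nandinine	biological	BIODB	B0021
codamine	biological	BIODB	B0022
norreticuline	biological	BIODB	B0023
norlaudanosoline	biological	BIODB	B0024
cheilanthifoline	biological	BIODB	B0025
stylopine	biological	BIODB	B0026
berberine	biological	BIODB	B0027
berberine	bioactive	ACTDB	A0002
berberine	chemical	CHEMDB	X0001
columbamine	biological	BIODB	B0028
palmatine	biological	BIODB	B0029
salutaridine	biological	BIODB	B0030
stepholidine	biological	BIODB	B0031
allocryptopine	biological	BIODB	B0032
corytuberine	biological	BIODB	B0033
lambertine	biological	BIODB	B0034
1,2-dehydroreticuline	biological	BIODB	B0035
papaverine	biological	BIODB	B0036
bicuculline	bioactive	ACTDB	A0003
tetrahydropalmatrubine	chemical	CHEMDB	X0002
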