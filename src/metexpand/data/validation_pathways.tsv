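pathway	compounds
cheilanthifoline	scoulerine > cheilanthifoline
stylopine	scoulerine > cheilanthifoline > stylopine
tetrahydropalmatine	tetrahydrocolumbamine > tetrahydropalmatine
palmatine	tetrahydrocolumbamine > tetrahydropalmatine > palmatine
columbamine	tetrahydrocolumbamine > columbamine
berberine	canadine > berberine
laudanine	reticuline > laudanine
codamine	reticuline > codamine
armepavine	N-methylcoclaurine > armepavine
norlaudanosoline	norcoclaurine > norlaudanosoline
nandinine	scoulerine > nandinine
tetrahydropalmatrubine	scoulerine > tetrahydropalmatrubine
papaverine	norreticuline > papaverine
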