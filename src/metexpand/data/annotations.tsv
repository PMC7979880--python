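name	citations	patents	reported_total
berberine	5430	6751	12154
tetrahydropalmatine	530	355	885
columbamine	131	235	366
salutaridine	85	264	349
norlaudanosoline	144	177	321
stepholidine	157	140	297
allocryptopine	111	159	270
laudanine	23	112	135
codamine	13	61	74
norreticuline	33	40	73
corytuberine	18	39	57
lambertine	30	23	53
armepavine	28	15	43
1,2-dehydroreticuline	3	40	43
nandinine	1	39	40
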