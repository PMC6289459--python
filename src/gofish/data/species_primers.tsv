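assay	common_name	target_taxon	group	primer_name	orientation	tm_printed	core	amplicon_size	annealing_c	cycles	nontarget_amplification
amee	American eel	Anguilla rostrata	bony_fish	M13ameeF	forward	47.7	GGGCTCAAATTGATATTACA	175	60	25	N
amee	American eel	Anguilla rostrata	bony_fish	M13ameeR	reverse	49.5	CGTGAGTTCAAAGGTGT	175	60	25	N
atme	Atlantic menhaden	Brevoortia tyrannus	bony_fish	M13atmeF	forward	48.2	GAGTGGTTATGGAGAACT	174	60	25	N
atme	Atlantic menhaden	Brevoortia tyrannus	bony_fish	M13atmeR	reverse	48.2	ATCCCAGTTTGTGTCCCG	174	60	25	N
baan	Bay anchovy	Anchoa mitchilli	bony_fish	M13baanF	forward	48.3	GTGGTTATGGAATTCTTTTCT	128	60	25	N
baan	Bay anchovy	Anchoa mitchilli	bony_fish	M13baanR	reverse	50.3	GATAAAGTCACTTTCGTGTGA	128	60	25	N
blsb	Black sea bass	Centropristis striata	bony_fish	M13blsbF	forward	51.2	GGGTGGTTAGGACATACTATT	150	60	25	N
blsb	Black sea bass	Centropristis striata	bony_fish	M13blsbR	reverse	51.2	CTTTCGTGGGTTCAGAATAAG	150	60	25	N
blfi	Bluefish	Pomatomus saltatrix	bony_fish	M13blfiF	forward	54.6	AGAGTGGTTAAGGAAAGCCTG	148	60	25	N
blfi	Bluefish	Pomatomus saltatrix	bony_fish	M13blfiR	reverse	57.1	TCGTGGGGTCAGGAATGG	148	60	25	N
cunn	Cunner	Tautogolabrus adspersus	bony_fish	M13cunnF	forward	54.6	GTAAAGAGTGGTTAGGGCAAACTA	156	65	25	N
cunn	Cunner	Tautogolabrus adspersus	bony_fish	M13cunnR	reverse	57.5	CTCTCGTGGGGTCAGGTG	156	65	25	N
oyto	Oyster toadfish	Opsanus tau	bony_fish	M13oytoF	forward	52.6	CGCGGTTACACGAATGA	192	60	25	N
oyto	Oyster toadfish	Opsanus tau	bony_fish	M13oytoR	reverse	50.3	ATAGTTTACGTGGTGTCAAAG	192	60	25	N
scup	Scup	Stenotomus chrysops	bony_fish	M13scupF	forward	48.7	GGGTGGTTAAGAATAAACTAAG	171	60	25	N
scup	Scup	Stenotomus chrysops	bony_fish	M13scupR	reverse	50.1	AATCCCAGTTTGTGTCTC	171	60	25	N
sego	Seaboard goby	Gobiosoma ginsburgii	bony_fish	M13segoF	forward	52.8	GCCCAAGTTGACAACTCA	176	60	25	N
sego	Seaboard goby	Gobiosoma ginsburgii	bony_fish	M13segoR	reverse	51.7	CTTTCGTGGGGTCATATGTA	176	60	25	N
stba	Striped bass	Morone saxatilis	bony_fish	M13stbaF	forward	53.0	GGTTAAGGGCCCAACTTTTAT	148	65	25	N
stba	Striped bass	Morone saxatilis	bony_fish	M13stbaR	reverse	57.4	TTTCGTGGGGTCAGGTTTGAG	148	65	25	N
taut	Tautog	Tautoga onitis	bony_fish	M13tautF	forward	50.4	GTAAAGAGTGGTTAGGATAAACAT	155	60	25	N
taut	Tautog	Tautoga onitis	bony_fish	M13tautR	reverse	55.7	CTCTCGTGGGGTCAGGTA	155	60	25	N
stsh	Sand tiger shark	Carcharias taurus	cartilaginous_fish	M13stshF	forward	50.8	CGAGTAACTTATATTAATACTTCC	189	60	35	N
stsh	Sand tiger shark	Carcharias taurus	cartilaginous_fish	M13stshR	reverse	51.6	TGACATCAAGATTTCTAGTAG	189	60	35	N
sbsh	Sandbar shark	Carcharhinus plumbeus	cartilaginous_fish	M13sbshF	forward	51.3	CGAGTAACTCACATTAACACAC	190	60	35	N
sbsh	Sandbar shark	Carcharhinus plumbeus	cartilaginous_fish	M13sbshR	reverse	50.4	GTGACATCAAGGTTCCTTAG	190	60	35	N
smdo	Smooth dogfish shark	Mustelus canis	cartilaginous_fish	M13smdoF	forward	50.9	CGAGTGACTCATATTAACACAC	186	60	35	N
smdo	Smooth dogfish shark	Mustelus canis	cartilaginous_fish	M13smdoR	reverse	52.2	GCATCAAGGCTCCTTGA	186	60	35	N
bura	Bullnose ray	Myliobatis freminvillei	cartilaginous_fish	M13buraF	forward	51.4	AGGGTGATTAGAATTAATCTCATCT	159	65	35	N
bura	Bullnose ray	Myliobatis freminvillei	cartilaginous_fish	M13buraR	reverse	50.1	TGTCGTGAGGTCAAAAAC	159	65	35	N
cora	Cownose ray	Rhinoptera bonasus	cartilaginous_fish	M13coraF	forward	50.2	GGTGATTAGAAATAATCTCACCA	155	60	35	N
cora	Cownose ray	Rhinoptera bonasus	cartilaginous_fish	M13coraR	reverse	51.3	CGTGAGGTCAAAAATTCTGTTTA	155	60	35	N
rost	Roughtail stingray	Dasyatis centroura	cartilaginous_fish	M13rostF	forward	50.8	ACGAGTGACACAAATTAATATCC	189	65	35	N
rost	Roughtail stingray	Dasyatis centroura	cartilaginous_fish	M13rostR	reverse	50.8	GTGAGGTCAAAAACTCTGTTAA	189	65	35	N
sbra	Spiny butterfly ray	Gymnura altavela	cartilaginous_fish	M13sbraF	forward	50.9	TAAGGGTGATTAGAAAAATCTCATTT	157	65	35	N
sbra	Spiny butterfly ray	Gymnura altavela	cartilaginous_fish	M13sbraR	reverse	50.6	AGGTCAAAAATTCTGTTGTGT	157	65	35	N
clsk	Clearnose skate	Raja eglanteria	cartilaginous_fish	M13clskF	forward	49.2	CGAGTAACTCATATTAATACTTCAC	175	65	35	Y
clsk	Clearnose skate	Raja eglanteria	cartilaginous_fish	M13clskR	reverse	52.6	GTCGTGAATTCAAAAGCTCTATTG	175	65	35	Y
lisk	Little skate	Leucoraja erinacea	cartilaginous_fish	M13liskF	forward	51.2	CGAGTAACTCACATTAATACTTCAC	191	65	35	Y
lisk	Little skate	Leucoraja erinacea	cartilaginous_fish	M13liskR	reverse	52.7	TGTCGTGAGGTCAAAAGC	191	65	35	Y
bodo	Bottlenose dolphin	Tursiops truncatus	mammal	M13bodoF	forward	49.2	TGACCCAAACTAATAGACAC	187	60	25	N
bodo	Bottlenose dolphin	Tursiops truncatus	mammal	M13bodoR	reverse	49.6	TCTTAGTTGTCGTGTATTCAG	187	60	25	N
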