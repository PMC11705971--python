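accession	length_bp	lifestyle	score	lysis_genes
AOIO01000029_pro	36084	Virulent	0.998265	0
AOLW01000047_pro	49137	Virulent	0.999848	0
AOMB01000030_pro	41349	Virulent	0.999867	0
BMOO01000003_pro	44293	Virulent	0.753929	0
CBVY010000007_pro	40868	Virulent	0.704037	0
CP001857_pro	33648	Virulent	0.999589	0
CP005290_pro	39989	Temperate	0.999859	1
CP025066_pro	37118	Virulent	0.999849	0
CP090371_pro	38176	Virulent	0.999856	0
CP094974_pro	59467	Virulent	0.999866	1
CP095390_pro	62752	Virulent	0.999865	0
DSLF01000001_pro	38584	Temperate	0.999857	1
DSXG01000013_pro	38223	Temperate	0.978087	0
DTQN01000007_pro	38397	Virulent	0.999835	1
FOZS01000002_pro	40261	Temperate	0.752539	0
JAAKEZ010000002_pro	33358	Temperate	0.994198	0
JAAKXY010000003_pro	55160	Virulent	0.999445	0
JAANTG010000004_pro	38551	Temperate	0.99937	0
JACIWB010000004_pro	22121	Virulent	0.992033	1
JADDUK010000002_pro	36487	Virulent	0.995403	1
JADHWN010000002_pro	40798	Temperate	0.999859	0
JAGTQY010000001_pro	55009	Temperate	0.781648	0
JAIWPJ010000001_pro	56518	Virulent	0.999216	1
JAJJZH010000007_pro	41968	Virulent	0.999865	0
JALHSQ010000084_pro	27026	Virulent	0.999742	0
JPES01000032_pro	40384	Virulent	0.993022	1
JXAO01000003_pro	40578	Virulent	0.999865	0
MTMI01000013_pro	34632	Virulent	0.99199	1
NHOV01000833_pro	36136	Virulent	0.923637	1
PSYY01000002_pro	40766	Virulent	0.99982	0
QMQO01000002.1_pro	55455	Temperate	0.960029	1
QPLT01000011_pro	54241	Virulent	0.99986	0
QZIT01000006	51544	Virulent	0.999866	0
RZIG01000002_pro	65939	Virulent	0.999867	0
SZNO01000001_pro	41994	Temperate	0.964508	0
WOWA01000002_pro	35464	Virulent	0.999858	0
WSZK01000015_pro	45795	Temperate	0.653216	1
WUAX01000016_pro	37912	Temperate	0.999857	0
JAGTQZ010000009_pro	10101	Temperate	0.99	0
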