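gene_id	gene_symbol	classification	tissues
ENSG00000219438	FAM19A5	ASE	testis
ENSG00000184985	SORCS2	ASE	brain
ENSG00000169604	ANTXR1	ASE	adipose
ENSG00000255339	NDUFB8	ASE	heart
ENSG00000166136	NDUFB8	ASE	adipose,adrenal,brain,breast,colon,heart,ovary,prostate,testis,thyroid
ENSG00000130600	H19	ASE	adipose,adrenal,breast,colon,kidney,ovary,prostate,skeletal muscle,testis,thyroid
ENSG00000175643	RMI2	ASE	testis
ENSG00000175643	RMI2	BE	ovary
ENSG00000122390	NAA60	ASE	brain
ENSG00000122390	NAA60	BE	adipose,adrenal,breast,colon,heart,kidney,liver,lymph node,ovary,thyroid
ENSG00000138641	HERC3	ASE	brain
ENSG00000138641	HERC3	BE	heart,leukocyte,ovary,prostate
ENSG00000155093	PTPRN2	ASE	brain
ENSG00000155093	PTPRN2	BE	prostate
ENSG00000182093	WRB	ASE	brain,liver
ENSG00000182093	WRB	BE	adrenal,heart,leukocyte,ovary,skeletal muscle,testis,thyroid
ENSG00000198300	PEG3/ZIM2	ASE	brain,ovary
ENSG00000198300	PEG3/ZIM2	BE	testis
ENSG00000183486	MX2	ASE	adipose,leukocyte
ENSG00000183486	MX2	BE	breast,ovary,testis,thyroid
ENSG00000130844	ZNF331	ASE	brain,ovary
ENSG00000130844	ZNF331	BE	lung
ENSG00000074181	NOTCH3	ASE	adipose,adrenal,breast,testis
ENSG00000074181	NOTCH3	BE	colon,heart,lymph node,ovary,skeletal muscle,thyroid
ENSG00000214265	SNURF	ASE	brain,lymph node,prostate,testis
ENSG00000214265	SNURF	BE	heart,thyroid
ENSG00000128739	SNRPN	ASE	adrenal,colon,leukocyte,lymph node,ovary,prostate,testis
ENSG00000128739	SNRPN	BE	brain
ENSG00000100138	NHP2L1	ASE	adrenal,brain,heart,kidney,leukocyte,ovary,prostate,testis
ENSG00000100138	NHP2L1	BE	adipose,breast,colon,liver,lung,lymph node,thyroid
ENSG00000087460	GNAS	ASE	adipose,adrenal,brain,breast,heart,kidney,leukocyte,lung,lymph node,ovary,prostate,testis,thyroid
ENSG00000087460	GNAS	BE	colon
ENSG00000235590	GNAS-AS1/SANG	BE	testis
ENSG00000087116	ADAMTS2	BE	adipose,breast,ovary
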