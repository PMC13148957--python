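canonical	synonyms	biopsy_site	cell_type	organ	disease	age	sex	ethnicity
HeLa	Hela|HELA|He-La	uterine cervix	epithelial cell	uterine cervix	cervical adenocarcinoma	31	female	black
MCF-7	MCF7|MCF 7|Michigan Cancer Foundation-7	mammary gland	epithelial cell	breast	breast adenocarcinoma	69	female	caucasian
HepG2	Hep G2|HEPG2|Hep-G2	liver	hepatocyte	liver	hepatocellular carcinoma	15	male	caucasian
A549	A-549|A 549	lung	epithelial cell	lung	lung adenocarcinoma	58	male	caucasian
K562	K-562|K 562	bone marrow	lymphoblast	bone marrow	chronic myeloid leukemia	53	female	caucasian
Jurkat	JURKAT|Jurkat E6.1	peripheral blood	T cell	blood	acute T cell leukemia	14	male	unknown
HEK293	HEK 293|293|HEK-293	kidney	epithelial cell	kidney	unknown	unknown	female	unknown
U-87 MG	U87|U-87|U87MG	brain	glial cell	brain	glioblastoma	44	male	caucasian
SK-MEL-28	SKMEL28|SK MEL 28	skin	melanocyte	skin	melanoma	51	male	unknown
PC-3	PC3|PC 3	bone	epithelial cell	prostate	prostate carcinoma	62	male	caucasian
HCT 116	HCT116|HCT-116	colon	epithelial cell	colon	colorectal carcinoma	48	male	unknown
MDA-MB-231	MDA MB 231|MDAMB231	pleural effusion	epithelial cell	breast	breast adenocarcinoma	51	female	caucasian
THP-1	THP1|THP 1	peripheral blood	monocyte	blood	acute monocytic leukemia	1	male	unknown
A375	A-375|A 375	skin	melanocyte	skin	melanoma	54	female	unknown
Raji	RAJI	jaw	B cell	lymph node	Burkitt lymphoma	11	male	black
SH-SY5Y	SHSY5Y|SH SY5Y	bone marrow	neuroblast	brain	neuroblastoma	4	female	caucasian
Caco-2	Caco2|CACO-2	colon	epithelial cell	colon	colorectal adenocarcinoma	72	male	caucasian
HL-60	HL60|HL 60	peripheral blood	promyeloblast	blood	acute promyelocytic leukemia	36	female	caucasian
U2OS	U-2 OS|U2-OS	bone	epithelial cell	bone	osteosarcoma	15	female	caucasian
PANC-1	PANC1|PANC 1	pancreas	epithelial cell	pancreas	pancreatic carcinoma	56	male	caucasian
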