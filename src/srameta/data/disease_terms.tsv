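term_id	preferred_name	synonyms	is_cancer
DIS:0001	tuberculosis	TB|phthisis	0
DIS:0002	melanoma	malignant melanoma|cutaneous melanoma	1
DIS:0003	lung adenocarcinoma	adenocarcinoma of lung|lung adeno	1
DIS:0004	breast adenocarcinoma	adenocarcinoma of breast	1
DIS:0005	hepatocellular carcinoma	liver cancer|HCC	1
DIS:0006	chronic myeloid leukemia	CML|chronic myelogenous leukemia	1
DIS:0007	acute T cell leukemia	T-ALL	1
DIS:0008	glioblastoma	glioblastoma multiforme|GBM	1
DIS:0009	prostate carcinoma	prostate cancer	1
DIS:0010	colorectal carcinoma	colorectal cancer|CRC	1
DIS:0011	Burkitt lymphoma	Burkitt's lymphoma	1
DIS:0012	neuroblastoma		1
DIS:0013	osteosarcoma	osteogenic sarcoma	1
DIS:0014	pancreatic carcinoma	pancreatic cancer	1
DIS:0015	colorectal adenocarcinoma		1
DIS:0016	acute monocytic leukemia	AMoL	1
DIS:0017	acute promyelocytic leukemia	APL	1
DIS:0018	cervical adenocarcinoma		1
DIS:0019	breast cancer	mammary carcinoma	1
DIS:0020	lung cancer	lung carcinoma	1
DIS:0021	pneumonia	lung inflammation	0
DIS:0022	influenza	flu	0
DIS:0023	hepatitis B	HBV infection	0
DIS:0024	type 2 diabetes	T2D|diabetes mellitus type 2	0
DIS:0025	rheumatoid arthritis	RA	0
DIS:0026	Crohn disease	Crohn's disease	0
DIS:0027	ulcerative colitis	UC	0
DIS:0028	asthma	bronchial asthma	0
DIS:0029	psoriasis		0
DIS:0030	Alzheimer disease	Alzheimer's disease|AD	0
DIS:0031	Parkinson disease	Parkinson's disease|PD	0
DIS:0032	multiple sclerosis	MS	0
DIS:0033	sepsis	septicemia	0
DIS:0034	cystic fibrosis	CF	0
DIS:0035	endometriosis		0
DIS:0036	atopic dermatitis	eczema	0
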