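term_id	preferred_name	synonyms
ANAT:0001	oral cavity	mouth|buccal cavity
ANAT:0002	lung	pulmonary tissue
ANAT:0003	liver	hepatic tissue
ANAT:0004	brain	encephalon
ANAT:0005	heart	cardiac muscle
ANAT:0006	kidney	renal tissue
ANAT:0007	skin	cutaneous tissue|epidermis
ANAT:0008	breast	mammary gland
ANAT:0009	colon	large intestine
ANAT:0010	stomach	gastric tissue
ANAT:0011	pancreas	pancreatic tissue
ANAT:0012	prostate	prostate gland
ANAT:0013	uterine cervix	cervix|cervix uteri
ANAT:0014	ovary	ovarian tissue
ANAT:0015	testis	testicle
ANAT:0016	bladder	urinary bladder
ANAT:0017	esophagus	oesophagus|gullet
ANAT:0018	thyroid gland	thyroid
ANAT:0019	spleen	splenic tissue
ANAT:0020	bone marrow	marrow
ANAT:0021	lymph node	lymphatic node
ANAT:0022	blood	peripheral blood|whole blood
ANAT:0023	bone	skeletal tissue
ANAT:0024	muscle	skeletal muscle
ANAT:0025	adipose tissue	fat tissue|body fat
ANAT:0026	small intestine	ileum
ANAT:0027	spinal cord	medulla spinalis
ANAT:0028	retina	retinal tissue
ANAT:0029	placenta	placental tissue
ANAT:0030	tongue	lingual tissue
ANAT:0031	larynx	voice box
ANAT:0032	trachea	windpipe
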