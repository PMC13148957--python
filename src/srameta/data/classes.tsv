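name	kind	allowed_values	definition_text	resolution_preference
study_accession	api_direct		Unique study identifier.	rule
instrument_platform	api_direct		Sequencing technology family (e.g. Illumina).	rule
number_of_base_pairs	api_direct		Total number of sequenced bases.	rule
library_strategy	api_direct		Assay type (e.g. RNA-seq).	rule
library_selection	discrete	polyA|inverse rRNA|hybrid selection|small RNA|other	based on the given context, determine the library selection fixed class by searching for specific keywords or synonyms that match one of the five strict classes: "polyA," "inverse rRNA," "hybrid selection," "small RNA," or "other." Assign "polyA" if the context contains any of the following terms or similar meaning that can be inferred: "PolyA," "poly.A," "oligo.dT," "oligodT," "truseq.mrna," "truseq.stranded.mrna," "truseq.standard.mrna," "smarter.mRNA," "stranded.mRNA." Assign "inverse rRNA" if the context mentions depletion of ribosomal RNA with any of these terms or similar meaning that can be inferred: "ribominus," "ribodep," "ribozero," "ribo.zero," "riboerase," "ribogone," "ribocop," "ribo-dep," "ribo-mi," "ribo minus," "depleted ribosom," "remove ribosom," "TruSeq.Stranded.Total," "TruSeq.Total," "SMARTer.Stranded.Total," "SMARTer.Total." Assign "hybrid selection" if the context refers to hybrid capture or exon selection using any of these terms or similar meaning that can be inferred: "Hybrid.Selection," "Exon.capture," "Exome.capture," "RNA.Exome," "geoMX." Assign "small RNA" if the context refers to small RNA isolation with keywords such as "TruSeq.Small," "size.fraction" or similar meaning that can be inferred. Assign "other" if none of the above terms are found. Return only the exact class name.	rule
sequencing_source	discrete	bulk|single cell|spatial	one of: "spatial," "bulk," "single cell." Spatial preserves in-tissue localization; bulk sequences a mixture of cells; single cell profiles individual cells.	llm
biopsy_site	open_vocab		organ, body part or fluid where tissue was sampled (same as organ if not cancer). Mention xenograft here if applicable. Not the disease; the sampled tissue. If possible, deduce from the cell line origin.	llm
biopsy_type	discrete	primary|metastasis|blood	"metastasis" if cancer and metastasis mentioned, or "blood" if blood-related and no metastasis; otherwise "primary." Do not assign metastasis or blood unless explicitly stated. Always choose one of the three.	llm
cell_line	open_vocab		standardized laboratory cell line name; otherwise "Primary tissue" if not a cell line.	llm
cell_type	open_vocab		the cellular type (e.g. neuron, fibroblast, CD8 T cell, NK cell, melanocyte, dendritic cell). If not provided, deduce from context; otherwise "primary tissue".	llm
organ	open_vocab		organ studied or affected (different from biopsy_site if applicable). Not the disease.	llm
disease	open_vocab		associated disease (be specific) or "healthy" (watch for cues like "adjacent," "normal").	llm
treatment	open_vocab		applied intervention (drug, molecule, surgery, implant, event). Infer if implicit. Do not restate the disease. Include planned pre-treatments.	rule
treatment_time	open_vocab		time or phase relative to treatment; if quantitative, indicate pre/on/post.	llm
response	discrete	no treatment|unknown|stable|progressive|success	reaction to treatment: "no treatment," "unknown," "stable," "progressive," "success".	llm
age	numeric_or_qualitative		human donor age (numeric range/exact or qualitative like child/teen/adult/senior). If unknown, return "unknown".	llm
sex	discrete	male|female	human donor sex; "unknown" if not inferable.	llm
ethnicity	open_vocab		human donor ethnicity (e.g. caucasian, black, asian); "unknown" if not inferable.	llm
is_cancer	boolean	True|False	"True" if the disease is cancer-related, "False" otherwise.	llm
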