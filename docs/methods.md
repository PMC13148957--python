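# Methods

This note documents the procedures implemented in `srameta`, the parameter
choices that matter, what the synthetic benchmark does and does not
emulate, and the known limitations.

## The metadata schema

Each run is described by 19 classes. Four are submission-mandatory and read
directly from the per-run API record (`study_accession`,
`instrument_platform`, `number_of_base_pairs`, `library_strategy`); the
other 15 are reconstructed. Classes carry a *value kind*:

- **discrete / boolean** — closed label sets (`library_selection`:
  polyA / inverse rRNA / hybrid selection / small RNA / other;
  `sequencing_source`: bulk / single cell / spatial; `biopsy_type`:
  primary / metastasis / blood; `response`: no treatment / unknown /
  stable / progressive / success; `is_cancer`: True / False; `sex`:
  male / female with `m`/`f` alias folding). Comparisons are
  case-insensitive; stored values use the canonical casing.
- **open vocabulary** — free text normalized downstream (organ, disease,
  biopsy site, cell line, cell type, treatment, treatment time,
  ethnicity).
- **numeric-or-qualitative** — donor age: a number or numeric range within
  [0, 120] years, or one of child/teen/adult/senior. The bounds and the
  qualitative terms are this package's choices for human donors; the
  validation contract only demands "plausible".

"unknown" is an out-of-band abstention token everywhere except `response`,
whose label set includes it as a legitimate clinical answer. The registry
ships as a five-column TSV data file so classes can be extended without
code changes.

## Record assembly and context building

Run XML is parsed tolerantly: each of the STUDY/SAMPLE/EXPERIMENT/RUN
blocks is flattened to a label→text mapping (TAG/VALUE attribute pairs
keyed by their tag; block-prefixed tags like `STUDY_TITLE` shortened).
BioSample accessions come from cross-reference elements first, then a
`SAMN\d+` regex over the raw text. All sources (XML blocks, BioSample
attributes, API row, user supplement) are merged *losslessly* — conflicts
coexist under distinct source tags and are reconciled later.

Contexts render each field group as labeled sentences in a fixed order
(study → sample → experiment → run → BioSample → API → user notes), with
placeholder values dropped. Token counting defaults to a word/punctuation
tokenizer (pluggable, so a model tokenizer can be injected); under it,
counts are additive over concatenation. Summarization triggers only above
the budget (default 2000 tokens): accession-shaped identifiers and
boilerplate sentences are removed, exact duplicates deleted, and remaining
sentences scored by the sum of inverse within-bundle term frequencies —
rare, informative phrasing scores high — then kept greedily (ties to the
earlier sentence) and emitted in document order. A single over-budget
sentence is truncated at a token boundary with a warning. The procedure is
extractive only and idempotent. The sentence-scoring rule and the
boilerplate list are this package's concrete choices for an intent-level
requirement ("keep rare informative phrases").

## Rule stage

Order of operations: (1) API-mandatory classes copied from the API row;
(2) alias-tagged extraction — per-class alias tables (e.g. biopsy site ←
tissue, body site, source_name) matched against attribute keys, values
validated and cross-checked across sources, agreements accepted,
disagreements retained and flagged into ambiguity notes that the prompts
later include; (3) gazetteer cell-line matching over the context text;
(4) keyword heuristics; (5) cell-line attribute propagation (fill missing
only, never overwrite); (6) disease/anatomy normalization to preferred
names and stable identifiers. The stage is deterministic, and a value only
enters the curated row if it passed validation.

The library-selection heuristic implements the printed keyword groups with
elastic separators (`.`/`-`/`_`/space are interchangeable or absent, so
`ribo.zero` matches "Ribo-Zero" and "ribozero") and precedence polyA →
inverse rRNA → hybrid selection → small RNA. A few stems (`ribodep`,
`ribo-mi`, `depleted ribosom`, `remove ribosom`) match word prefixes so
inflected forms ("ribodepletion", "ribosomal") hit. With no keyword the
rule stage *abstains* rather than answering "other": the "other" default
belongs to the model prompt, so genuinely undecided cases reach the model.
Biopsy type follows the three-way rule — metastasis only with an
established cancer context and an explicit metastasis keyword, else blood
on a blood keyword, else primary under a cancer context, else abstain. The
cancer context comes from a keyword list plus cancer-flagged disease
lexicon entries; that derivation is a package choice.

## Lexicons

Cell lines, diseases and anatomical terms load from simple TSVs (canonical
name, pipe-separated synonyms, attribute/identifier columns). The packaged
files are small curated fixtures — ~20 widely used cell lines with their
public attributes and ~30 terms per ontology under illustrative
`DIS:`/`ANAT:` identifiers — sized so the whole pipeline runs offline;
full-size registry/ontology releases can be converted into the same layout
and dropped in. The gazetteer lowercases names, purges a configurable
generic-term stoplist and phrases under 3 characters, and matches with
token boundaries (longest alternative first); entries missed exactly get a
separator-elastic fallback pass. Overlapping spans keep the longest match,
then the earliest; duplicate canonicals keep their first occurrence.

## Model stage and confidence

One prompt per class per run, four blocks in fixed order: run accession;
context summary plus ambiguity notes; the class's definition line from the
registry; a shared instruction block (extract if possible, return
"unknown" otherwise, disambiguate the current run, separate multiple
answers with ","/";"). Adapter routing is a pure per-class lookup with a
base-model fallback. Closed-class outputs snap to canonical labels by
case-insensitive exact match only — anything else becomes "unknown" with a
warning, because a silent fuzzy-snapped wrong label is worse than an
abstention. Confidence is computed over the generated answer tokens only:
`mean_nll` in nats/token and `ppl = exp(mean_nll)`, the identity holding to
1e-9 for every emitted prediction. Per-run predictions round-trip through
JSON files.

The **mock backend** exists so end-to-end behavior is testable without
weights: it parses the hidden `@@class=value@@` truth markers that
synthetic contexts embed and corrupts its answer at configurable seeded
rates — abstention (answer "unknown") and substitution (another allowed
label for closed classes, a decoy token for open ones). Output is fully
determined by (prompt, seed). Real local-model runners plug in behind the
same two-method contract; their absence changes nothing about install or
tests.

## Resolution

`locked` (default): rule-validated values are final; model predictions
fill only missing or flagged fields (a flagged field is a disagreement the
model was explicitly asked to review). `per_class_preference`: the winner
per class follows its registry preference — rules for library selection
and treatment, the model elsewhere — reflecting that deterministic
extraction is the more reliable route exactly for those two classes.
Losing values are preserved in `*_alt` columns. After resolution, newly
introduced cell lines are normalized and their attributes propagated into
still-missing fields, and disease/organ/biopsy-site values mapped to
preferred names and identifiers; the step is idempotent.

## Synthetic benchmark

Each generated sample has one label per class, balanced to within one
count over the class's label set *plus "unknown"*. Known labels are
phrased either *explicitly* (value next to its class keyword; also planted
as a BioSample attribute in the rendered fixtures) or as a *paraphrase*
(lexicon synonym or an indirect protocol cue — "oligo-dT beads" for polyA,
"mouth" for oral cavity); "unknown" means the absent mode, with a neutral
filler sentence instead of a cue so context length does not encode how
many fields are missing. Labels are drawn independently across classes.

Two disjoint phrasing families (boilerplate and sentence templates) encode
distance: the training reference and the ID stratum use family A, the OOD
stratum family B, the MID stratum a fixed A-heavy mixture with class
sentences alternating families. Open-vocabulary value pools are partitioned
four ways (reference / ID / MID / OOD strata) at generation time, so no
label string repeats across splits — a stricter version of keeping values
disjoint between training and evaluation. The proximity split scores each
pool sample by its maximum similarity to the reference and sorts: top 400 →
ID, middle 1200 → MID, bottom 400 → OOD, ties broken by sample id.
Similarity defaults to token-set Jaccard over lowercased words (markers
stripped); an embedding similarity can be passed in — Jaccard preserves
the rank structure the split needs without model downloads. The leakage
check counts cross-split near-duplicate pairs at a similarity threshold
and shared open-vocabulary labels.

What the generator does **not** emulate: real submitter typos and
free-form abbreviations, multi-sample studies whose study text mixes
several runs' attributes, correlated fields (the independent label draw
means a sample's organ need not match its cell line's organ — which is
precisely why the `locked` policy scores below `per_class_preference` on
synthetic truth: cell-line propagation supplies the registry's organ, not
the independently drawn one), long review-style abstracts, and non-English
text. Passing tests therefore demonstrate the machinery — routing,
validation, locking, scoring, reproducibility — not real-data accuracy,
which depends on the deployed model.

## Evaluation

Closed classes (and donor sex) score by exact case-insensitive equality of
the full label set. Open classes score any-overlap: a predicted value
matches a reference value if the normalized strings are equal, both map to
the same lexicon/ontology identifier, or they are a listed synonym pair.
Any-overlap for multiple answers is the default (strict full-set mode is a
flag away); "not applicable" is treated like "unknown" when excluding
unanswerable references. Accuracy over zero surviving pairs is reported as
undefined (`None`), never as zero. Baselines are the modal-label and
always-unknown constant classifiers; the error taxonomy partitions errors
into abstentions and substitutions, whose fractions sum to one and, under
the mock's seeded noise rates (a, s), concentrate around a/(a+s) and
s/(a+s).

## Problem sizes and numerical choices

The shipped analyses use a 2000-sample evaluation pool (400/1200/400) with
a 150-sample reference, 100-run end-to-end passes, and n=1000 for
noise-recovery checks at a three-standard-error tolerance; the mock
benchmark runs at 5% abstention / 10% substitution noise as a visible but
modest corruption level. The token budget defaults to 2000; leakage
threshold 0.95 for generated pools (whose legitimate texts share template
vocabulary), 0.9 for stricter audits. All randomness flows from explicit
integer seeds; runs are bit-reproducible.

## Limitations

- The packaged lexicons are deliberately small; coverage on real SRA text
  requires dropping in full registry/ontology conversions.
- Treatment and library selection remain structurally hard: treatment
  details are diluted in study-level text, and library-prep descriptions
  mix protocols and kit names — the per-class preference policy exists
  because rules, not models, are the safer route there.
- The live NCBI fetcher is a thin adapter and intentionally untested
  offline; schema drift in E-utilities output would surface there first.
- Jaccard proximity is a rank-preserving stand-in for embedding proximity;
  absolute similarity values are not comparable across similarity
  functions.
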