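# srameta

Hybrid reconstruction of Sequence Read Archive (SRA) run metadata for
transcriptomics reuse.

Public repositories hold millions of RNA-seq runs whose sample metadata are
fragmented, ambiguous or simply missing: fields left empty, filled with
placeholders ("unknown", "not collected"), filled incorrectly (an age column
holding a cell type), or phrased so inconsistently that cohort assembly
becomes manual archaeology. `srameta` reconstructs **19 metadata classes**
per run (organ, disease, cell line, cell type, donor age/sex/ethnicity,
library selection, sequencing source, biopsy site/type, treatment and its
timing, clinical response, cancer status, plus four submission-mandatory
record fields) by combining:

1. **Deterministic extraction** — SRA run XML, BioSample attributes, API
   fields and optional user notes are merged per run; class values are
   pulled from alias-tagged attributes, a cell-line gazetteer (exact
   token-boundary phrase matching with a regex fallback for variants such
   as `MCF7` / `MCF-7`), and printed keyword heuristics for library
   selection, sequencing source and biopsy type. Every candidate passes
   type/range validation and a cross-source consistency check; cell-line
   hits propagate registry attributes (organ, disease, sex, ...) into
   missing fields, and disease/anatomy terms are normalized to preferred
   names with stable identifiers.
2. **LLM completion** — the 15 non-mandatory classes are completed one
   prompt per class per run from a budgeted extractive context summary
   (default 2000 tokens). Backends are pluggable behind a two-method
   contract; the package ships a deterministic **mock backend** that
   answers from truth markers planted in synthetic fixtures, with seeded
   substitution/abstention noise, so every pipeline path runs offline.
   Each prediction carries the mean negative log-likelihood of its answer
   tokens and the perplexity `ppl = exp(mean_nll)` as confidence.
3. **Per-field resolution** — rule and model values are merged under a
   policy: `locked` (validated rule values are final; the model fills only
   missing or flagged fields) or `per_class_preference` (rules win for
   library selection and treatment, the model elsewhere; losing values are
   kept in `*_alt` columns).

A synthetic benchmark generator emulates the evaluation design: balanced
labels per class (including "unknown"), explicit/paraphrase/absent phrasing
modes, open-vocabulary value pools kept disjoint across splits, and a
2000-sample pool partitioned 400/1200/400 into **ID / MID / OOD** test sets
by text-similarity proximity to a training reference, with leakage
diagnostics. The evaluation harness scores closed classes by exact label
equality and open classes context-tolerantly (synonym or same-identifier
matches count, e.g. "mouth" vs "oral cavity"), reports majority and
always-unknown baselines, and partitions errors into abstentions vs
substitutions.

## Worked example

```bash
srameta simulate --n 50 --sizes 10,30,10 --n-reference 8 --seed 4 --out-dir fx
# ID: 10 samples, mean reference similarity 0.579
# MID: 30 samples, mean reference similarity 0.356
# OOD: 10 samples, mean reference similarity 0.177
# near-duplicates across splits: 0; label-pool violations: 0

srameta annotate --fixtures fx/pool --out-dir ann --backend mock \
    --resolution-policy per_class_preference --seed 2
# wrote tsv: ann/metadata.tsv
# wrote summary: ann/summary.tsv

srameta evaluate --table ann/metadata.tsv --truth fx/pool/truth.tsv --out eval.tsv
#             class  n  n_known_ref  accuracy  majority_baseline  unknown_baseline
# library_selection 50           43       1.0               0.18              0.14
# sequencing_source 50           39       1.0               0.28              0.22
#       biopsy_site 50           45       1.0               0.10              0.10
# ...
#         is_cancer 50           34       1.0               0.36              0.32
```

`simulate` reports the three proximity partitions with their mean
similarity to the training reference — decreasing from ID to OOD — and
confirms no near-duplicate texts or shared open-vocabulary labels across
splits. `annotate` writes one row per run with value, source, status,
confidence, identifier and alternate-value columns per class. `evaluate`
shows that with a noiseless mock backend the full pipeline recovers every
known reference value (`accuracy 1.0`), while the trivial baselines stay
near chance — the margin a real model must beat. Adding mock noise
(`--mock-substitution 0.1 --mock-abstention 0.05`) degrades accuracy
accordingly and populates the abstention/substitution columns.

## Layout

| module | role |
| --- | --- |
| `srameta.schema` | 19-class registry (packaged TSV), value validation, multi-value parsing |
| `srameta.sra_io` | SRA/BioSample XML parsing, accession resolution, source merging, fetchers |
| `srameta.lexicons` | cell-line registry, disease/anatomy term maps, gazetteer, propagation |
| `srameta.context` | paragraph context building, token counting, budgeted summarization |
| `srameta.rules` | alias extraction, keyword heuristics, cross-source checks, rule stage |
| `srameta.llm` | prompt assembly, backend contract, mock backend, confidence, prediction files |
| `srameta.resolve` | resolution policies, post-propagation, multi-format export, summaries |
| `srameta.synthetic` | labeled context generation, fixture XML rendering, proximity splits, leakage checks |
| `srameta.evaluation` | hybrid matching, per-class accuracy, baselines, error taxonomy |
| `srameta.cli` / `srameta.pipeline` | end-to-end wiring and the `srameta` command |

See `docs/methods.md` for the underlying procedures, parameter choices and
limitations.
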