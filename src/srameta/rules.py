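"""Deterministic extraction: aliases, gazetteer, keyword heuristics, checks.

The rule stage fills whatever the record supports explicitly before any
model is consulted: API-mandatory fields are copied through, alias-tagged
XML/BioSample attributes are extracted and validated, cell lines are found
by gazetteer matching and normalized, three protocol classes are inferred
from keyword heuristics, cell-line attributes are propagated, disease and
anatomy terms are normalized, and everything passes type/range validation
plus a cross-source consistency check.  Disagreements between sources are
flagged (not silently resolved) so the LLM stage can review them; the whole
stage is deterministic.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional, Sequence

from . import schema
from ._markers import strip_markers
from .context import ContextBundle
from .lexicons import LexiconSet, find_phrases, normalize_term, propagate_from_cell_line
from .sra_io import RunRecord

# --------------------------------------------------------------------------
# annotation containers


@dataclass
class FieldValue:
    """One class's state on one run: values, provenance, validation status."""

    values: list[str] = field(default_factory=list)
    source: str = "none"  # api | rule | lexicon_propagation | llm | none
    status: str = "missing"  # validated | flagged | missing
    confidence: Optional[object] = None
    term_id: Optional[str] = None
    note: Optional[str] = None
    alt: Optional[str] = None  # losing value retained at resolution time


@dataclass
class AnnotationRow:
    """Per-run, per-class annotation state flowing through the pipeline."""

    run_accession: str
    fields: dict[str, FieldValue] = field(default_factory=dict)
    ambiguity_notes: list[str] = field(default_factory=list)

    @classmethod
    def empty(cls, run_accession: str, registry: Optional[schema.ClassRegistry] = None):
        registry = registry or schema.registry()
        return cls(run_accession, {c.name: FieldValue() for c in registry})

    def is_missing(self, name: str) -> bool:
        return not self.fields[name].values

    def set_values(self, name: str, values: Sequence[str], source: str,
                   status: str = "validated") -> None:
        fv = self.fields[name]
        fv.values = list(values)
        fv.source = source
        fv.status = status


# --------------------------------------------------------------------------
# keyword heuristics

def _kw(phrase: str, prefix: bool = False) -> re.Pattern:
    from .lexicons import _elastic_pattern

    return re.compile(_elastic_pattern(phrase, prefix=prefix), re.IGNORECASE)


#: Library-selection keyword groups, tried in precedence order.  Keywords
#: are matched case-insensitively with elastic separators (".", "-", "_",
#: space).  A few stems (marked prefix) match word beginnings, e.g.
#: "ribodep" also hits "ribodepletion".
LIBRARY_SELECTION_KEYWORDS: list[tuple[str, list[re.Pattern]]] = [
    (
        "polyA",
        [
            _kw("polyA"), _kw("poly.A"), _kw("oligo.dT"), _kw("oligodT"),
            _kw("truseq.mrna"), _kw("truseq.stranded.mrna"),
            _kw("truseq.standard.mrna"), _kw("smarter.mRNA"), _kw("stranded.mRNA"),
        ],
    ),
    (
        "inverse rRNA",
        [
            _kw("ribominus"), _kw("ribodep", prefix=True), _kw("ribozero"),
            _kw("ribo.zero"), _kw("riboerase"), _kw("ribogone"), _kw("ribocop"),
            _kw("ribo-dep", prefix=True), _kw("ribo-mi", prefix=True),
            _kw("ribo minus"), _kw("depleted ribosom", prefix=True),
            _kw("remove ribosom", prefix=True), _kw("TruSeq.Stranded.Total"),
            _kw("TruSeq.Total"), _kw("SMARTer.Stranded.Total"), _kw("SMARTer.Total"),
        ],
    ),
    (
        "hybrid selection",
        [
            _kw("Hybrid.Selection"), _kw("Exon.capture"), _kw("Exome.capture"),
            _kw("RNA.Exome"), _kw("geoMX"),
        ],
    ),
    (
        "small RNA",
        [_kw("TruSeq.Small"), _kw("size.fraction", prefix=True)],
    ),
]

SEQUENCING_SOURCE_KEYWORDS: list[tuple[str, list[re.Pattern]]] = [
    (
        "single cell",
        [_kw("single cell"), _kw("single-cell"), _kw("scRNA", prefix=True),
         _kw("snRNA", prefix=True), _kw("10x Chromium"), _kw("Smart-seq")],
    ),
    (
        "spatial",
        [_kw("spatial"), _kw("Visium"), _kw("in-tissue localization"), _kw("GeoMx")],
    ),
    ("bulk", [_kw("bulk")]),
]

_METASTASIS_RE = re.compile(r"\bmetasta", re.IGNORECASE)
_BLOOD_RE = re.compile(
    r"\b(blood|pbmc|plasma|serum|leukocyte|leukapheresis|buffy coat)", re.IGNORECASE
)
_CANCER_RE = re.compile(
    r"\b(cancer|carcinoma|tumou?r|melanoma|leuka?emia|lymphoma|glioma|glioblastoma"
    r"|sarcoma|adenocarcinoma|neoplasm|malignan|myeloma|neuroblastoma|metasta)",
    re.IGNORECASE,
)


def heuristic_library_selection(text: str) -> Optional[str]:
    """Infer library selection from the printed keyword groups.

    Returns the label of the first group with a hit (polyA, then inverse
    rRNA, hybrid selection, small RNA).  With no keyword hit the rule stage
    abstains — the "other" default belongs to the LLM prompt, so genuinely
    undecided cases reach the model.
    """
    for label, patterns in LIBRARY_SELECTION_KEYWORDS:
        if any(p.search(text) for p in patterns):
            return label
    return None


def heuristic_sequencing_source(text: str) -> Optional[str]:
    """Infer sampling granularity (single cell / spatial / bulk) from
    explicit keywords and common protocol synonyms; abstain otherwise."""
    for label, patterns in SEQUENCING_SOURCE_KEYWORDS:
        if any(p.search(text) for p in patterns):
            return label
    return None


def looks_cancerous(text: str, lexicons: Optional[LexiconSet] = None) -> bool:
    """Whether the text establishes a cancer context (keywords plus any
    disease-lexicon entry flagged as cancer)."""
    if _CANCER_RE.search(text):
        return True
    if lexicons is not None:
        for _, preferred, _ in lexicons.disease_map.entries:
            if preferred.casefold() in text.casefold():
                if lexicons.disease_map.is_cancer(preferred):
                    return True
    return False


def heuristic_biopsy_type(text: str, is_cancer_hint: Optional[bool] = None) -> Optional[str]:
    """Three-way clinical-context rule.

    "metastasis" only with an established cancer context and an explicit
    metastasis keyword; else "blood" on a blood keyword without metastasis;
    else "primary" once a cancer context is established; abstain when no
    cancer context can be established at the rule stage.
    """
    cancer = is_cancer_hint if is_cancer_hint is not None else looks_cancerous(text)
    has_met = bool(_METASTASIS_RE.search(text))
    has_blood = bool(_BLOOD_RE.search(text))
    if cancer and has_met:
        return "metastasis"
    if has_blood and not has_met:
        return "blood"
    if cancer:
        return "primary"
    return None


# --------------------------------------------------------------------------
# cross-source consistency


def cross_source_check(
    candidates: list[tuple[str, str]]
) -> tuple[list[str], list[str]]:
    """Reconcile one class's candidate values across sources.

    Values agreeing after normalization collapse to one accepted value;
    conflicting values are all retained and a flag note is returned so the
    disagreement reaches the LLM stage as an ambiguity note.
    """
    if not candidates:
        return [], []
    groups: dict[str, str] = {}
    for value, _ in candidates:
        key = re.sub(r"\s+", " ", value).strip().casefold()
        groups.setdefault(key, value)
    if len(groups) == 1:
        return [next(iter(groups.values()))], []
    note = "; ".join(f"{source} says {value!r}" for value, source in candidates)
    return list(groups.values()), [note]


# --------------------------------------------------------------------------
# alias tables

#: Default per-class aliases matched against XML tags and BioSample
#: attribute keys (lowercased, whitespace-collapsed).  Configurable.
DEFAULT_ALIASES: dict[str, tuple[str, ...]] = {
    "library_selection": ("library_selection", "library selection"),
    "sequencing_source": ("sequencing_source", "sequencing source"),
    "biopsy_site": ("biopsy_site", "biopsy site", "tissue", "organ part",
                    "body site", "source_name", "source name", "tissue source"),
    "biopsy_type": ("biopsy_type", "biopsy type", "sample type"),
    "cell_line": ("cell_line", "cell line"),
    "cell_type": ("cell_type", "cell type"),
    "organ": ("organ", "organism part", "organ site"),
    "disease": ("disease", "disease state", "diagnosis", "condition", "health state"),
    "treatment": ("treatment", "drug", "compound", "agent", "intervention"),
    "treatment_time": ("treatment_time", "treatment time", "time point", "timepoint"),
    "response": ("response", "clinical response", "outcome", "treatment response"),
    "age": ("age", "donor age", "age_years", "age years"),
    "sex": ("sex", "gender", "donor sex"),
    "ethnicity": ("ethnicity", "race", "ancestry"),
    "is_cancer": ("is_cancer", "is cancer"),
}

#: API column aliases for the four submission-mandatory classes.
API_FIELD_ALIASES: dict[str, tuple[str, ...]] = {
    "study_accession": ("study_accession", "study"),
    "instrument_platform": ("instrument_platform", "platform"),
    "number_of_base_pairs": ("number_of_base_pairs", "bases", "total_bases"),
    "library_strategy": ("library_strategy",),
}

_SOURCE_GROUPS = (
    ("biosample_attributes", "biosample"),
    ("sample_fields", "sra_xml"),
    ("experiment_fields", "sra_xml"),
    ("run_fields", "sra_xml"),
    ("study_fields", "sra_xml"),
    ("user_notes", "user"),
)


def _alias_candidates(record: RunRecord, cls_name: str,
                      aliases: dict[str, tuple[str, ...]]) -> list[tuple[str, str]]:
    wanted = {a.casefold().replace("_", " ") for a in aliases.get(cls_name, (cls_name,))}
    out: list[tuple[str, str]] = []
    for group, source in _SOURCE_GROUPS:
        for key, value in getattr(record, group).items():
            if key.casefold().replace("_", " ") in wanted and value.strip():
                out.append((value, source))
    return out


def run_rule_stage(
    record: RunRecord,
    bundle: ContextBundle,
    lexicons: LexiconSet,
    registry: Optional[schema.ClassRegistry] = None,
    aliases: Optional[dict[str, tuple[str, ...]]] = None,
) -> AnnotationRow:
    """Apply the full deterministic extraction stage to one run.

    Per-class failures degrade to missing; every accepted value has passed
    :func:`srameta.schema.validate_value` and the cross-source check.
    Flagged disagreements are appended to the bundle's ambiguity notes so
    the LLM prompt sees them.
    """
    registry = registry or schema.registry()
    aliases = aliases or DEFAULT_ALIASES
    row = AnnotationRow.empty(record.run_accession, registry)
    text = strip_markers(bundle.text)

    # (1) submission-mandatory classes straight from the API record
    for cls in registry.api_direct:
        for column in API_FIELD_ALIASES.get(cls.name, (cls.name,)):
            value = record.api_fields.get(column, "")
            if value.strip():
                row.set_values(cls.name, [value.strip()], source="api")
                break

    # (2) alias-tagged extraction + validation + cross-source consistency
    for cls in registry.llm_routed:
        candidates = []
        for raw, source in _alias_candidates(record, cls.name, aliases):
            for part in schema.parse_multi_value(raw):
                outcome = schema.validate_value(cls, part)
                if outcome.accepted and outcome.normalized_value != schema.UNKNOWN:
                    candidates.append((outcome.normalized_value, source))
        if not candidates:
            continue
        values, flags = cross_source_check(candidates)
        if flags:
            row.set_values(cls.name, values, source="rule", status="flagged")
            for flag in flags:
                note = f"{cls.name}: {flag}"
                row.ambiguity_notes.append(note)
                bundle.ambiguity_notes.append(note)
        else:
            row.set_values(cls.name, values, source="rule")

    # (3) gazetteer cell-line matching over the cleaned context text
    cell_fv = row.fields["cell_line"]
    if cell_fv.values:
        entry = lexicons.cell_line_entry(cell_fv.values[0])
        if entry is not None:
            cell_fv.values[0] = entry.canonical
    else:
        hits = find_phrases(text, lexicons.gazetteer)
        if hits:
            row.set_values("cell_line", [hits[0][1]], source="rule")

    # (4) keyword heuristics for the three protocol classes
    if row.is_missing("library_selection"):
        label = heuristic_library_selection(text)
        if label:
            row.set_values("library_selection", [label], source="rule")
    if row.is_missing("sequencing_source"):
        label = heuristic_sequencing_source(text)
        if label:
            row.set_values("sequencing_source", [label], source="rule")
    if row.is_missing("biopsy_type"):
        hint: Optional[bool] = None
        if row.fields["is_cancer"].values:
            hint = row.fields["is_cancer"].values[0] == "True"
        elif row.fields["disease"].values:
            hint = lexicons.disease_map.is_cancer(row.fields["disease"].values[0]) or None
        label = heuristic_biopsy_type(text, is_cancer_hint=hint)
        if label:
            row.set_values("biopsy_type", [label], source="rule")

    # (5) cell-line attribute propagation (fills only missing fields)
    if row.fields["cell_line"].values:
        entry = lexicons.cell_line_entry(row.fields["cell_line"].values[0])
        if entry is not None:
            propagate_from_cell_line(entry, row)

    # (6) ontology normalization for disease and anatomy classes
    normalize_annotations(row, lexicons)
    return row


def normalize_annotations(row: AnnotationRow, lexicons: LexiconSet) -> AnnotationRow:
    """Map disease/organ/biopsy-site values to preferred names + stable ids."""
    for name, term_map in (
        ("disease", lexicons.disease_map),
        ("organ", lexicons.anatomy_map),
        ("biopsy_site", lexicons.anatomy_map),
    ):
        fv = row.fields.get(name)
        if not fv or not fv.values:
            continue
        normalized = []
        ids = []
        for value in fv.values:
            hit = normalize_term(value, term_map)
            if hit:
                preferred, term_id = hit
                normalized.append(preferred)
                ids.append(term_id)
            else:
                normalized.append(value)
        # dedupe after normalization, preserving order
        fv.values = schema.parse_multi_value(", ".join(normalized))
        if ids:
            fv.term_id = ";".join(dict.fromkeys(ids))
    return row
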