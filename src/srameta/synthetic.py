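"""Synthetic labeled contexts, SRA-like fixtures, and proximity splits.

Well-annotated SRA records are scarce, so benchmarking relies on generated
contexts that mimic the pipeline's own run summaries.  Each sample carries
a ground-truth label per class, realized in one of three phrasing modes:
*explicit* (the value stated next to its class keyword), *paraphrase* (a
synonym or indirect protocol cue from the lexicons), or *absent* (truth is
"unknown" and no cue appears).  Labels are balanced per class — including
the "unknown" option — to within one count.

A 2000-sample evaluation pool is split into ID/MID/OOD partitions of
400/1200/400 by proximity to a training-reference set: every sample is
scored by its maximum similarity to the reference, and the closest become
ID, the farthest OOD, the middle MID.  Similarity defaults to token-set
Jaccard over lowercased words (an embedding similarity can be plugged in;
Jaccard preserves the rank structure the split needs without downloads).
Open-vocabulary value pools are partitioned across the reference and the
three strata at generation time, so labels never leak between splits; a
leakage check counts near-duplicate texts across splits and verifies that
pool disjointness.

Samples also render to four-block run XML + BioSample XML + an API row, so
the same fixtures exercise the parsing and rule stages end to end.  Each
context embeds a hidden machine-readable truth marker for the mock
inference backend; all similarity and rule logic strips it first.
"""

from __future__ import annotations

import random
import re
import xml.etree.ElementTree as ET
import zlib
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Callable, Optional, Sequence

from . import schema
from ._markers import format_markers, strip_markers
from .lexicons import LexiconSet, load_default_lexicons
from .sra_io import ConfigError

# --------------------------------------------------------------------------
# value pools

OPEN_VOCAB_CLASSES = (
    "biopsy_site", "cell_line", "cell_type", "organ", "disease",
    "treatment", "treatment_time", "ethnicity",
)

_CELL_TYPES = (
    "fibroblast", "neuron", "hepatocyte", "melanocyte", "CD8 T cell",
    "B cell", "NK cell", "monocyte", "macrophage", "epithelial cell",
    "endothelial cell", "keratinocyte", "astrocyte", "cardiomyocyte",
    "dendritic cell", "megakaryocyte",
)

_TREATMENTS = (
    "cisplatin", "paclitaxel", "doxorubicin", "vemurafenib", "nivolumab",
    "pembrolizumab", "radiotherapy", "surgery", "tamoxifen", "imatinib",
    "gemcitabine", "5-fluorouracil", "dexamethasone", "erlotinib",
    "carboplatin", "trastuzumab",
)

_TREATMENT_TIMES = (
    "pre-treatment", "post-treatment", "on-treatment", "baseline",
    "day 3", "day 7", "week 2", "week 6", "24 hours", "48 hours",
    "month 1", "month 6",
)

_ETHNICITIES = (
    "caucasian", "asian", "black", "hispanic", "african american",
    "east asian", "south asian", "middle eastern",
)

_AGES = ("7", "15", "23", "34", "42", "51", "63", "77", "adult", "senior")


def default_value_pools(lexicons: Optional[LexiconSet] = None) -> dict[str, list[str]]:
    """Per-class label pools assembled from the packaged lexicons."""
    lexicons = lexicons or load_default_lexicons()
    anatomy = lexicons.anatomy_map.preferred_names
    return {
        "biopsy_site": list(anatomy),
        "organ": list(anatomy),
        "disease": list(lexicons.disease_map.preferred_names),
        "cell_line": [e.canonical for e in lexicons.cell_lines],
        "cell_type": list(_CELL_TYPES),
        "treatment": list(_TREATMENTS),
        "treatment_time": list(_TREATMENT_TIMES),
        "ethnicity": list(_ETHNICITIES),
        "age": list(_AGES),
    }


# --------------------------------------------------------------------------
# templates (two phrasing families, used to control split distance)

#: Two boilerplate "phrasing families".  A sample's family composition is
#: what positions it relative to the reference set under text similarity:
#: the reference and the ID stratum are pure family A, the OOD stratum is
#: pure family B, and the MID stratum mixes both.
_STYLE_SENTENCES = {
    "A": (
        "This study profiles transcriptomes from clinical specimens collected "
        "at a university hospital.",
        "Libraries were sequenced to standard depth and deposited with the archive.",
        "Annotations below were transcribed from the submitting laboratory records.",
        "Quality control relied on alignment statistics reviewed by curators.",
        "Consent paperwork and ethics approvals are filed alongside the project.",
        "Frozen aliquots were tracked through the institutional biobank inventory.",
    ),
    "B": (
        "Archived material underwent nucleic acid workup before machine readout.",
        "Entries originate from a public repository deposit curated retrospectively.",
        "Accompanying descriptors were recovered from heterogeneous submitter documents.",
        "Custody metadata follow a bespoke retrospective digitization workflow.",
        "Scanned ledgers supplied provenance hints during reconstruction.",
        "Index cards bearing catalogue numbers anchor every recovered entry.",
    ),
}

_EXPLICIT_TEMPLATES = {
    "A": "The {label} recorded for this sample is {value}.",
    "B": "Submitter notes list {value} under the {label} field.",
}

_PARAPHRASE_TEMPLATES = {
    "A": "{cue}.",
    "B": "According to the deposit description, {cue}.",
}

#: Neutral sentences emitted for absent-mode classes.  They carry no class
#: cue; they keep context length comparable across samples so that text
#: similarity reflects phrasing family rather than how many fields a
#: submitter happened to leave empty.
_FILLER_SENTENCES = {
    "A": (
        "Routine archival fields were left at their default entries.",
        "Laboratory paperwork accompanied the shipment without further detail.",
        "Standard handling applied throughout specimen intake and storage.",
        "Remaining annotations follow the usual submission conventions.",
    ),
    "B": (
        "Several descriptor slots remained unfilled in the original deposit.",
        "Portions of the registry form carry no usable content.",
        "Certain catalogue positions were skipped by the depositing party.",
        "Unpopulated template rows persist across the recovered documents.",
    ),
}

#: Indirect protocol cues for closed-class labels (paraphrase mode).
_DISCRETE_CUES: dict[str, dict[str, str]] = {
    "sequencing_source": {
        "single cell": "droplet-based scRNA-seq libraries were prepared from dissociated cells",
        "spatial": "Visium slides preserved the in-tissue localization of transcripts",
        "bulk": "RNA was extracted from homogenized bulk tissue lysate",
    },
    "library_selection": {
        "polyA": "messenger RNA was enriched with oligo-dT beads",
        "inverse rRNA": "ribosomal RNA was depleted with a Ribo-Zero kit",
        "hybrid selection": "transcripts were captured with an RNA exome panel",
        "small RNA": "small RNAs were size fractionated before TruSeq small library preparation",
        "other": "library enrichment followed a custom in-house protocol",
    },
    "biopsy_type": {
        "primary": "the resected primary tumor was sampled directly",
        "metastasis": "tissue was taken from a distant metastasis of the carcinoma",
        "blood": "peripheral blood was drawn into collection tubes",
    },
    "response": {
        "no treatment": "the donors received no therapeutic intervention",
        "stable": "the disease remained stable under therapy",
        "progressive": "imaging showed progressive disease despite therapy",
        "success": "the intervention achieved a complete clinical success",
    },
    "is_cancer": {
        "True": "the pathology report confirmed a malignant tumor",
        "False": "the donors were volunteers with no malignancy on record",
    },
    "sex": {
        "male": "all donors enrolled in this arm were men",
        "female": "all donors enrolled in this arm were women",
    },
    "age": {},
}

_CLASS_LABELS = {
    "library_selection": "library selection",
    "sequencing_source": "sequencing source",
    "biopsy_site": "biopsy site",
    "biopsy_type": "biopsy type",
    "cell_line": "cell line",
    "cell_type": "cell type",
    "treatment_time": "treatment time",
    "is_cancer": "is cancer",
}


@dataclass
class SyntheticSample:
    """One generated context with per-class truth and phrasing modes."""

    sample_id: str
    context_text: str
    truth: dict[str, tuple[str, ...]]
    mode: dict[str, str]
    split: Optional[str] = None
    proximity: Optional[float] = None
    hidden_marker: str = ""


def _synonym_for(value: str, class_name: str, lexicons: LexiconSet,
                 rng: random.Random) -> str:
    if class_name in ("organ", "biopsy_site"):
        term_map = lexicons.anatomy_map
    elif class_name == "disease":
        term_map = lexicons.disease_map
    elif class_name == "cell_line":
        entry = lexicons.cell_line_entry(value)
        if entry and entry.synonyms:
            return rng.choice(sorted(entry.synonyms))
        return value
    else:
        return value
    for term_id, preferred, synonyms in term_map.entries:
        if preferred == value and synonyms:
            return rng.choice(list(synonyms))
    return value


def _class_sentence(class_name: str, value: str, mode: str, family: str,
                    lexicons: LexiconSet, rng: random.Random) -> str:
    label = _CLASS_LABELS.get(class_name, class_name.replace("_", " "))
    if mode == "explicit":
        return _EXPLICIT_TEMPLATES[family].format(label=label, value=value)
    cues = _DISCRETE_CUES.get(class_name)
    if cues is not None and value in cues:
        cue = cues[value]
    elif class_name == "age":
        cue = f"the donor was {value} years old at collection"
    elif class_name in ("organ", "biopsy_site", "disease", "cell_line"):
        syn = _synonym_for(value, class_name, lexicons, rng)
        noun = {"organ": "the material originated from the {}",
                "biopsy_site": "specimens were excised from the {}",
                "disease": "donors presented with {}",
                "cell_line": "cultures of {} were expanded before extraction"}
        cue = noun[class_name].format(syn)
    elif class_name == "cell_type":
        cue = f"staining showed the preparations to consist mainly of {value}s"
    elif class_name == "treatment":
        cue = f"participants had received {value} before sampling"
    elif class_name == "treatment_time":
        cue = f"material was collected at the {value} visit"
    elif class_name == "ethnicity":
        cue = f"the enrolled donors self-reported {value} ancestry"
    else:
        cue = f"the {label} was noted as {value}"
    return _PARAPHRASE_TEMPLATES[family].format(cue=cue)


def _balanced_labels(label_set: Sequence[str], n: int, rng: random.Random) -> list[str]:
    labels = [label_set[i % len(label_set)] for i in range(n)]
    rng.shuffle(labels)
    return labels


def generate_pool(
    n: int,
    classes: Optional[Sequence[str]] = None,
    seed: int = 0,
    config: Optional[dict] = None,
) -> list[SyntheticSample]:
    """Generate *n* labeled synthetic contexts.

    Per class, the label assignment cycles through the class's label set
    plus "unknown", so counts are balanced within one.  Samples with truth
    "unknown" for a class use the absent mode (no cue in the text); other
    samples draw explicit vs paraphrase from the configured proportions.
    Deterministic given *seed*.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    config = dict(config or {})
    registry = schema.registry()
    lexicons: LexiconSet = config.get("lexicons") or load_default_lexicons()
    pools = dict(default_value_pools(lexicons))
    pools.update(config.get("value_pools") or {})
    class_names = list(classes or [c.name for c in registry.llm_routed])
    mode_props = config.get("mode_props") or {"explicit": 0.5, "paraphrase": 0.5}
    style = config.get("style", "A")
    prefix = config.get("id_prefix", "SYN")
    start = int(config.get("start_index", 0))

    rng = random.Random(seed)
    assignments: dict[str, list[str]] = {}
    for name in class_names:
        cls = registry.get(name)
        if cls.is_closed:
            label_set = list(cls.allowed_values)
            if schema.UNKNOWN not in [v.casefold() for v in label_set]:
                label_set.append(schema.UNKNOWN)
        else:
            pool = pools.get(name) or []
            if not pool:
                raise ConfigError(f"empty value pool for open-vocabulary class {name!r}")
            label_set = list(pool) + [schema.UNKNOWN]
        assignments[name] = _balanced_labels(label_set, n, rng)

    p_explicit = mode_props.get("explicit", 0.5)
    samples = []
    for i in range(n):
        sample_id = f"{prefix}{start + i:06d}"
        truth: dict[str, tuple[str, ...]] = {}
        modes: dict[str, str] = {}
        sentences: list[str] = []
        if style == "AB":
            for off in range(3):
                sentences.append(_STYLE_SENTENCES["A"][(i + off) % 6])
            for off in range(2):
                sentences.append(_STYLE_SENTENCES["B"][(i + off) % 6])
            sentences.append("Additional context sentences accompany this record "
                             "for completeness.")
        else:
            sentences.extend(_STYLE_SENTENCES[style])
        for idx, name in enumerate(class_names):
            label = assignments[name][i]
            truth[name] = (label,)
            # mixed style alternates families deterministically: half the
            # class sentences look like each family, keeping the mixed
            # stratum's distance to the reference tightly between the pure
            # families'
            family = style if style in ("A", "B") else ("A" if idx % 2 == 0 else "B")
            if label == schema.UNKNOWN:
                modes[name] = "absent"
                sentences.append(_FILLER_SENTENCES[family][idx % 4])
                continue
            mode = "explicit" if rng.random() < p_explicit else "paraphrase"
            modes[name] = mode
            sentences.append(_class_sentence(name, label, mode, family, lexicons, rng))
        marker = format_markers(truth)
        samples.append(
            SyntheticSample(
                sample_id=sample_id,
                context_text=" ".join(sentences) + " " + marker,
                truth=truth,
                mode=modes,
                hidden_marker=marker,
            )
        )
    return samples


# --------------------------------------------------------------------------
# fixture rendering


def _ids_for(sample: SyntheticSample) -> dict[str, str]:
    digits = re.sub(r"\D", "", sample.sample_id) or "0"
    n = int(digits) % 10**6
    return {
        "run": f"SRR9{n:06d}",
        "experiment": f"SRX9{n:06d}",
        "sample": f"SRS9{n:06d}",
        "study": f"SRP9{n:06d}",
        "biosample": f"SAMN8{n:07d}",
    }


def render_fixture_xml(sample: SyntheticSample) -> tuple[str, str, dict[str, str]]:
    """Render a sample as (run XML, BioSample XML, API row).

    The context (with its hidden marker) goes into the study abstract;
    explicit-mode class values additionally become BioSample attributes so
    the alias-extraction path sees them.  The result parses back through
    the I/O layer with every planted value intact.
    """
    ids = _ids_for(sample)
    pkg = ET.Element("EXPERIMENT_PACKAGE")
    study = ET.SubElement(pkg, "STUDY", accession=ids["study"])
    desc = ET.SubElement(study, "DESCRIPTOR")
    ET.SubElement(desc, "STUDY_TITLE").text = f"Synthetic benchmark study {sample.sample_id}"
    ET.SubElement(desc, "STUDY_ABSTRACT").text = sample.context_text
    sample_el = ET.SubElement(pkg, "SAMPLE", accession=ids["sample"])
    ET.SubElement(sample_el, "TITLE").text = f"Synthetic sample {sample.sample_id}"
    links = ET.SubElement(sample_el, "SAMPLE_LINKS")
    xref = ET.SubElement(links, "XREF_LINK")
    ET.SubElement(xref, "DB").text = "biosample"
    ET.SubElement(xref, "ID").text = ids["biosample"]
    ET.SubElement(pkg, "EXPERIMENT", accession=ids["experiment"])
    ET.SubElement(pkg, "RUN", accession=ids["run"])
    run_xml = ET.tostring(pkg, encoding="unicode")

    bio = ET.Element("BioSample", accession=ids["biosample"])
    attrs = ET.SubElement(bio, "Attributes")
    for name, mode in sample.mode.items():
        if mode != "explicit":
            continue
        attr = ET.SubElement(attrs, "Attribute", attribute_name=name)
        attr.text = "; ".join(sample.truth[name])
    biosample_xml = ET.tostring(bio, encoding="unicode")

    digits = int(re.sub(r"\D", "", sample.sample_id) or 0)
    api_row = {
        "run_accession": ids["run"],
        "study_accession": ids["study"],
        "instrument_platform": "ILLUMINA",
        "number_of_base_pairs": str(1_000_000 + digits),
        "library_strategy": "RNA-Seq",
    }
    return run_xml, biosample_xml, api_row


# --------------------------------------------------------------------------
# similarity, splitting, leakage


@lru_cache(maxsize=200_000)
def _wordset(text: str) -> frozenset[str]:
    return frozenset(re.findall(r"[a-z0-9]+", strip_markers(text).casefold()))


def jaccard_similarity(a: str, b: str) -> float:
    """Token-set Jaccard over lowercased words, ignoring truth markers."""
    sa, sb = _wordset(a), _wordset(b)
    if not sa and not sb:
        return 1.0
    union = len(sa | sb)
    return len(sa & sb) / union if union else 0.0


Similarity = Callable[[str, str], float]


def split_by_proximity(
    pool: Sequence[SyntheticSample],
    reference: Sequence[SyntheticSample],
    sim: Similarity = jaccard_similarity,
    sizes: tuple[int, int, int] = (400, 1200, 400),
) -> tuple[list[SyntheticSample], list[SyntheticSample], list[SyntheticSample]]:
    """Partition *pool* into ID/MID/OOD by max similarity to *reference*.

    Samples are sorted by descending score (ties broken by sample id); the
    top block becomes ID, the bottom block OOD, the remainder MID.
    """
    if len(pool) != sum(sizes):
        raise ValueError(f"pool size {len(pool)} != sum of split sizes {sizes}")
    if not reference:
        raise ValueError("reference set must be non-empty")
    ref_texts = [r.context_text for r in reference]
    scored = []
    for s in pool:
        score = max(sim(s.context_text, rt) for rt in ref_texts)
        s.proximity = score
        scored.append((-score, s.sample_id, s))
    scored.sort()
    ordered = [s for _, _, s in scored]
    id_part = ordered[: sizes[0]]
    mid_part = ordered[sizes[0]: sizes[0] + sizes[1]]
    ood_part = ordered[sizes[0] + sizes[1]:]
    for part, name in ((id_part, "ID"), (mid_part, "MID"), (ood_part, "OOD")):
        for s in part:
            s.split = name
    return id_part, mid_part, ood_part


def mean_reference_similarity(part: Sequence[SyntheticSample]) -> float:
    scores = [s.proximity for s in part if s.proximity is not None]
    return sum(scores) / len(scores) if scores else float("nan")


def leakage_check(
    splits: dict[str, Sequence[SyntheticSample]],
    sim: Similarity = jaccard_similarity,
    threshold: float = 0.9,
) -> dict[str, object]:
    """Diagnose leakage across splits.

    Counts cross-split text pairs with similarity >= *threshold* and
    open-vocabulary label values shared between any two splits.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    names = list(splits)
    near_dupes = 0
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            for s1 in splits[a]:
                for s2 in splits[b]:
                    if sim(s1.context_text, s2.context_text) >= threshold:
                        near_dupes += 1
    violations: dict[str, list[str]] = {}
    for cls_name in OPEN_VOCAB_CLASSES:
        pools = {}
        for name in names:
            values = set()
            for s in splits[name]:
                for v in s.truth.get(cls_name, ()):
                    if v != schema.UNKNOWN:
                        values.add(v.casefold())
            pools[name] = values
        shared = set()
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                shared |= pools[a] & pools[b]
        if shared:
            violations[cls_name] = sorted(shared)
    return {
        "near_duplicates": near_dupes,
        "label_pool_violations": sum(len(v) for v in violations.values()),
        "violating_values": violations,
        "threshold": threshold,
    }


# --------------------------------------------------------------------------
# benchmark assembly


def _partition_pool(values: Sequence[str], seed: int, class_name: str) -> list[list[str]]:
    rng = random.Random(zlib.crc32(f"{seed}:{class_name}".encode()))
    shuffled = list(values)
    rng.shuffle(shuffled)
    k, extra = divmod(len(shuffled), 4)
    parts = []
    pos = 0
    for i in range(4):
        size = k + (1 if i < extra else 0)
        parts.append(shuffled[pos: pos + size])
        pos += size
    return parts


def generate_benchmark(
    seed: int = 0,
    sizes: tuple[int, int, int] = (400, 1200, 400),
    n_reference: int = 150,
    classes: Optional[Sequence[str]] = None,
    lexicons: Optional[LexiconSet] = None,
) -> tuple[list[SyntheticSample], list[SyntheticSample]]:
    """Build a training-reference set and an evaluation pool.

    Open-vocabulary pools are partitioned four ways (reference and the
    three strata) so values never repeat across splits.  The ID stratum
    shares the reference's phrasing family, the OOD stratum uses a fully
    different family, and the MID stratum mixes both — giving the proximity
    split its monotone distance structure by construction.
    """
    lexicons = lexicons or load_default_lexicons()
    base_pools = default_value_pools(lexicons)
    chunked = {
        name: _partition_pool(values, seed, name)
        for name, values in base_pools.items()
        if name in OPEN_VOCAB_CLASSES
    }

    def _pools(part: int) -> dict[str, list[str]]:
        return {name: parts[part] for name, parts in chunked.items()}

    common = {"lexicons": lexicons}
    reference = generate_pool(
        n_reference, classes, seed=seed + 1,
        config={**common, "value_pools": _pools(0), "style": "A", "id_prefix": "REF"},
    )
    id_stratum = generate_pool(
        sizes[0], classes, seed=seed + 2,
        config={**common, "value_pools": _pools(1), "style": "A",
                "id_prefix": "SYN", "start_index": 0},
    )
    mid_stratum = generate_pool(
        sizes[1], classes, seed=seed + 3,
        config={**common, "value_pools": _pools(2), "style": "AB",
                "id_prefix": "SYN", "start_index": sizes[0]},
    )
    ood_stratum = generate_pool(
        sizes[2], classes, seed=seed + 4,
        config={**common, "value_pools": _pools(3), "style": "B",
                "id_prefix": "SYN", "start_index": sizes[0] + sizes[1]},
    )
    pool = id_stratum + mid_stratum + ood_stratum
    return reference, pool
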