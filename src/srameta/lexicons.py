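"""Flat-file lexicons: cell-line registry, disease and anatomy term maps.

Cultured cell lines are a rich source of indirect metadata: once a line is
recognized in free text, its registry entry supplies the sampling site,
cell type, organ, disease and donor demographics.  This module loads the
lexicon TSVs, compiles a phrase gazetteer for in-text matching (exact
token-boundary matches plus a regex fallback for alphanumeric variants such
as ``MCF7`` vs ``MCF-7``), normalizes free-text terms to preferred
ontology-style names and stable identifiers, and propagates cell-line
attributes into missing annotation fields.

The packaged lexicons are small curated fixtures (about 20 cell lines and
30 terms per ontology) with illustrative ``DIS:``/``ANAT:`` identifiers, so
the full pipeline runs offline; full-size Cellosaurus or OBO releases can
be converted into the same TSV layout and dropped in.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Sequence

from . import schema
from .sra_io import ConfigError

#: Cell-line attributes that may be propagated into an annotation row.
PROPAGATABLE_FIELDS = (
    "biopsy_site",
    "cell_type",
    "organ",
    "disease",
    "age",
    "sex",
    "ethnicity",
)

#: Generic words never indexed as phrases: common English plus generic
#: biology terms that collide with real cell-line synonyms.
DEFAULT_STOPLIST = frozenset(
    {
        "cell", "cells", "line", "lines", "tissue", "human", "mouse", "sample",
        "samples", "culture", "cultured", "primary", "normal", "control", "wild",
        "type", "clone", "stock", "the", "and", "with", "from", "this", "that",
    }
)

_WS_RE = re.compile(r"\s+")


def _norm_key(text: str) -> str:
    return _WS_RE.sub(" ", text).strip().casefold()


@dataclass(frozen=True)
class CellLineEntry:
    canonical: str
    synonyms: frozenset[str] = frozenset()
    attributes: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if not self.canonical:
            raise ValueError("cell line entry needs a canonical name")
        if self.canonical in self.synonyms:
            object.__setattr__(self, "synonyms", self.synonyms - {self.canonical})


@dataclass
class TermMap:
    """A name/synonym -> (preferred name, stable id) lookup for one ontology."""

    ontology_name: str
    entries: list[tuple[str, str, tuple[str, ...]]]
    cancer_ids: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        self._by_name: dict[str, tuple[str, str]] = {}
        self._by_syn: dict[str, tuple[str, str]] = {}
        seen_ids = set()
        for term_id, preferred, synonyms in self.entries:
            if not preferred:
                raise ValueError(f"term {term_id} has no preferred name")
            if term_id in seen_ids:
                raise ValueError(f"duplicate term id {term_id}")
            seen_ids.add(term_id)
            self._by_name.setdefault(_norm_key(preferred), (preferred, term_id))
            for syn in synonyms:
                self._by_syn.setdefault(_norm_key(syn), (preferred, term_id))

    def lookup(self, term: str) -> Optional[tuple[str, str]]:
        key = _norm_key(term)
        return self._by_name.get(key) or self._by_syn.get(key)

    def is_cancer(self, term: str) -> bool:
        hit = self.lookup(term)
        return bool(hit and hit[1] in self.cancer_ids)

    @property
    def preferred_names(self) -> list[str]:
        return [preferred for _, preferred, _ in self.entries]


def normalize_term(term: str, term_map: TermMap) -> Optional[tuple[str, str]]:
    """Map a free-text term to ``(preferred_name, term_id)``, or ``None``.

    Preferred names take priority over synonyms; matching is
    case-insensitive with collapsed whitespace.  Fixed point: normalizing a
    preferred name returns itself.
    """
    if not term:
        return None
    return term_map.lookup(term)


_CHUNK_RE = re.compile(r"[A-Za-z]+|\d+")
_SEP_ELASTIC = r"[\s.\-_]?"


def _elastic_pattern(phrase: str, prefix: bool = False) -> str:
    """Separator-elastic regex for a phrase: hyphens, dots, spaces and
    underscores between letter/digit chunks become optional/interchangeable."""
    chunks = _CHUNK_RE.findall(phrase)
    if not chunks:
        return re.escape(phrase)
    body = _SEP_ELASTIC.join(re.escape(c) for c in chunks)
    tail = "" if prefix else r"(?![A-Za-z0-9])"
    return r"(?<![A-Za-z0-9])" + body + tail


class Gazetteer:
    """Compiled phrase index over lowercased names and synonyms.

    One pass of a combined regex returns exact token-boundary matches
    (longest alternative first); a second, fallback pass catches
    alphanumeric variants of entries the exact pass missed.
    """

    def __init__(self, index: dict[str, str], stoplist: frozenset[str], min_len: int):
        self.index = index
        self.stoplist = stoplist
        self.min_len = min_len
        keys = sorted(index, key=len, reverse=True)
        if keys:
            pattern = "|".join(
                r"(?<![A-Za-z0-9])" + re.escape(k) + r"(?![A-Za-z0-9])" for k in keys
            )
            self._exact_re: Optional[re.Pattern] = re.compile(pattern, re.IGNORECASE)
        else:
            self._exact_re = None
        self._variants: list[tuple[re.Pattern, str]] = []
        for key in keys:
            if len(_CHUNK_RE.findall(key)) > 1:
                self._variants.append(
                    (re.compile(_elastic_pattern(key), re.IGNORECASE), index[key])
                )

    def lookup(self, phrase: str) -> Optional[str]:
        return self.index.get(_norm_key(phrase))

    def __len__(self) -> int:
        return len(self.index)


def compile_gazetteer(
    entries: Sequence[CellLineEntry],
    stoplist: Iterable[str] = DEFAULT_STOPLIST,
    min_len: int = 3,
) -> Gazetteer:
    """Build the phrase index from a cell-line registry.

    Every name and synonym is lowercased; generic (stoplisted) terms and
    phrases shorter than *min_len* characters are purged before indexing.
    """
    if not entries:
        raise ConfigError("cannot compile a gazetteer from an empty registry")
    stop = frozenset(_norm_key(s) for s in stoplist)
    index: dict[str, str] = {}
    for entry in entries:
        for name in (entry.canonical, *sorted(entry.synonyms)):
            key = _norm_key(name)
            if len(key) < min_len or key in stop:
                continue
            index.setdefault(key, entry.canonical)
    return Gazetteer(index, stop, min_len)


def find_phrases(text: str, gazetteer: Gazetteer) -> list[tuple[tuple[int, int], str]]:
    """Locate lexicon phrases in *text* in document order.

    Exact case-insensitive token-boundary matches come from a single regex
    pass; entries missed exactly get a fallback pass with separator-elastic
    variants.  Overlapping spans keep the longest match (then the earliest),
    and duplicate canonicals keep their first occurrence.
    """
    hits: list[tuple[int, int, str]] = []
    if gazetteer._exact_re is not None:
        for m in gazetteer._exact_re.finditer(text):
            canonical = gazetteer.index[_norm_key(m.group(0))]
            hits.append((m.start(), m.end(), canonical))
    found = {c for _, _, c in hits}
    for pattern, canonical in gazetteer._variants:
        if canonical in found:
            continue
        m = pattern.search(text)
        if m:
            hits.append((m.start(), m.end(), canonical))
            found.add(canonical)
    hits.sort(key=lambda h: (h[0], -(h[1] - h[0])))
    out: list[tuple[tuple[int, int], str]] = []
    seen: set[str] = set()
    last_end = -1
    for start, end, canonical in hits:
        if start < last_end or canonical in seen:
            continue
        out.append(((start, end), canonical))
        seen.add(canonical)
        last_end = end
    return out


def propagate_from_cell_line(entry: CellLineEntry, row) -> "AnnotationRow":  # noqa: F821
    """Fill still-missing dependent fields of *row* from a cell-line entry.

    Only missing fields are touched; validated values are never overwritten,
    and filled values are tagged ``lexicon_propagation``.  Idempotent.
    """
    reg = schema.registry()
    for name in PROPAGATABLE_FIELDS:
        if name not in reg:
            continue
        value = entry.attributes.get(name)
        if not value or value.casefold() == schema.UNKNOWN:
            continue
        fv = row.fields[name]
        if fv.values:
            continue
        outcome = schema.validate_value(reg.get(name), value)
        if outcome.accepted:
            fv.values = [outcome.normalized_value]
            fv.source = "lexicon_propagation"
            fv.status = "validated"
    if "cell_line" in row.fields and not row.fields["cell_line"].values:
        row.fields["cell_line"].values = [entry.canonical]
        row.fields["cell_line"].source = "lexicon_propagation"
        row.fields["cell_line"].status = "validated"
    return row


def _data_path(name: str):
    return resources.as_file(resources.files("srameta.data") / name)


def load_cell_lines(path: Optional[str | Path] = None) -> list[CellLineEntry]:
    """Load the cell-line registry TSV (packaged fixture by default)."""
    import csv

    def _load(p) -> list[CellLineEntry]:
        entries = []
        with open(p, newline="", encoding="utf-8") as fh:
            for row in csv.DictReader(fh, delimiter="\t"):
                synonyms = frozenset(s for s in (row.get("synonyms") or "").split("|") if s)
                attributes = {
                    f: row[f].strip()
                    for f in PROPAGATABLE_FIELDS
                    if row.get(f) and row[f].strip()
                }
                entries.append(CellLineEntry(row["canonical"].strip(), synonyms, attributes))
        return entries

    if path is not None:
        return _load(path)
    with _data_path("cell_lines.tsv") as p:
        return _load(p)


def load_term_map(
    path: Optional[str | Path] = None,
    ontology_name: str = "disease",
) -> TermMap:
    """Load a term map TSV: ``term_id``, ``preferred_name``, ``synonyms``
    (pipe-separated) and an optional ``is_cancer`` flag column."""
    import csv

    def _load(p) -> TermMap:
        entries = []
        cancer_ids = set()
        with open(p, newline="", encoding="utf-8") as fh:
            for row in csv.DictReader(fh, delimiter="\t"):
                synonyms = tuple(s for s in (row.get("synonyms") or "").split("|") if s)
                entries.append((row["term_id"].strip(), row["preferred_name"].strip(), synonyms))
                if (row.get("is_cancer") or "").strip() in ("1", "true", "True"):
                    cancer_ids.add(row["term_id"].strip())
        return TermMap(ontology_name, entries, frozenset(cancer_ids))

    if path is not None:
        return _load(path)
    default = "disease_terms.tsv" if ontology_name == "disease" else "anatomy_terms.tsv"
    with _data_path(default) as p:
        return _load(p)


@dataclass
class LexiconSet:
    """Everything the rule and resolution stages need in one place."""

    cell_lines: list[CellLineEntry]
    gazetteer: Gazetteer
    disease_map: TermMap
    anatomy_map: TermMap

    def __post_init__(self) -> None:
        self._entry_by_name: dict[str, CellLineEntry] = {}
        for entry in self.cell_lines:
            self._entry_by_name.setdefault(_norm_key(entry.canonical), entry)
            for syn in entry.synonyms:
                self._entry_by_name.setdefault(_norm_key(syn), entry)

    def cell_line_entry(self, name: str) -> Optional[CellLineEntry]:
        return self._entry_by_name.get(_norm_key(name))


def load_default_lexicons(
    stoplist: Iterable[str] = DEFAULT_STOPLIST, min_len: int = 3
) -> LexiconSet:
    cell_lines = load_cell_lines()
    return LexiconSet(
        cell_lines=cell_lines,
        gazetteer=compile_gazetteer(cell_lines, stoplist, min_len),
        disease_map=load_term_map(ontology_name="disease"),
        anatomy_map=load_term_map(ontology_name="anatomy"),
    )
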