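"""Parsing and merging of SRA run XML, BioSample XML, API rows and user notes.

An SRA run record is structured into four blocks — STUDY, SAMPLE,
EXPERIMENT and RUN — describing the project, the biological sample, the
library setup and the sequencing run.  This module flattens each block into
a label->text mapping, resolves the BioSample accession (cross-reference
elements first, then a regex scan of the raw XML), parses BioSample
attributes, and merges everything with API fields and an optional
user-supplied supplement into one :class:`RunRecord` per run.

Merging is lossless: sources never overwrite each other; conflicts are kept
side by side and resolved later by cross-source checking.
"""

from __future__ import annotations

import logging
import re
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Optional, Protocol

import pandas as pd

log = logging.getLogger(__name__)

_WS_RE = re.compile(r"\s+")
_SAMN_RE = re.compile(r"\bSAMN\d+\b")
_RUN_ACC_RE = re.compile(r"\b[SED]RR\d+\b")

#: Source tag attached (per field group) to every stored value.
SOURCE_OF_GROUP = {
    "study_fields": "sra_xml",
    "sample_fields": "sra_xml",
    "experiment_fields": "sra_xml",
    "run_fields": "sra_xml",
    "biosample_attributes": "biosample",
    "api_fields": "api",
    "user_notes": "user",
}

#: Default list of per-run API fields carried through the pipeline.  The
#: four submission-mandatory classes are read from these columns; the list
#: is configurable at fetch time.
DEFAULT_API_FIELDS = (
    "study_accession",
    "instrument_platform",
    "number_of_base_pairs",
    "library_strategy",
)


class SraXmlError(ValueError):
    """Raised on malformed SRA or BioSample XML."""


class ConfigError(ValueError):
    """Raised on unusable configuration or input tables."""


def _norm(text: str) -> str:
    return _WS_RE.sub(" ", text).strip()


@dataclass
class RunRecord:
    """Merged per-run view of all metadata sources."""

    run_accession: str = ""
    study_fields: dict[str, str] = field(default_factory=dict)
    sample_fields: dict[str, str] = field(default_factory=dict)
    experiment_fields: dict[str, str] = field(default_factory=dict)
    run_fields: dict[str, str] = field(default_factory=dict)
    biosample_accession: Optional[str] = None
    biosample_attributes: dict[str, str] = field(default_factory=dict)
    api_fields: dict[str, str] = field(default_factory=dict)
    user_notes: dict[str, str] = field(default_factory=dict)

    def iter_values(self) -> Iterator[tuple[str, str, str, str]]:
        """Yield ``(group, label, value, source_tag)`` for every stored value."""
        for group, source in SOURCE_OF_GROUP.items():
            for label, value in getattr(self, group).items():
                yield group, label, value, source

    def n_values(self) -> int:
        return sum(1 for _ in self.iter_values())


def _guess_accession(xml_text: str) -> str:
    m = _RUN_ACC_RE.search(xml_text)
    return m.group(0) if m else "<unknown run>"


_BLOCKS = (
    ("STUDY", "study_fields"),
    ("SAMPLE", "sample_fields"),
    ("EXPERIMENT", "experiment_fields"),
    ("RUN", "run_fields"),
)


def _flatten_block(elem: ET.Element, block: str) -> dict[str, str]:
    """Flatten one record block into a label->text mapping.

    Leaf elements become entries keyed by their lowercased tag (with the
    redundant block prefix stripped, so STUDY_TITLE -> ``title``).
    TAG/VALUE attribute pairs become entries keyed by the TAG text.
    Duplicate labels keep the first occurrence.
    """
    out: dict[str, str] = {}
    skip: set[int] = set()
    for attr_el in elem.iter():
        if attr_el.tag.upper().endswith("_ATTRIBUTE"):
            tag = attr_el.findtext("TAG")
            value = attr_el.findtext("VALUE")
            for child in attr_el:
                skip.add(id(child))
            if tag and value and _norm(value):
                out.setdefault(_norm(tag).lower(), _norm(value))
    prefix = block.lower() + "_"
    for child in elem.iter():
        if child is elem or id(child) in skip or len(child):
            continue
        text = child.text or ""
        if not _norm(text):
            continue
        key = child.tag.lower()
        if key.startswith(prefix):
            key = key[len(prefix):]
        out.setdefault(key, _norm(text))
    for name in ("accession", "alias"):
        if elem.get(name):
            out.setdefault(name, elem.get(name))
    return out


def parse_run_xml(xml_text: str) -> RunRecord:
    """Parse one SRA run document into a partial :class:`RunRecord`.

    Both a bare four-block record and an E-utilities package wrapper are
    accepted; absent blocks simply yield empty field groups.
    """
    try:
        root = ET.fromstring(xml_text)
    except ET.ParseError as exc:
        raise SraXmlError(
            f"malformed run XML for {_guess_accession(xml_text)}: {exc}"
        ) from exc
    record = RunRecord()
    for block, attr in _BLOCKS:
        elem = root if root.tag.upper() == block else root.find(f".//{block}")
        if elem is not None:
            setattr(record, attr, _flatten_block(elem, block))
    run_el = root if root.tag.upper() == "RUN" else root.find(".//RUN")
    if run_el is not None and run_el.get("accession"):
        record.run_accession = run_el.get("accession", "")
    if not record.run_accession:
        record.run_accession = record.run_fields.get("primary_id", "")
    if not record.run_accession:
        m = _RUN_ACC_RE.search(xml_text)
        record.run_accession = m.group(0) if m else ""
    return record


def iter_run_xml(xml_text: str) -> Iterator[RunRecord]:
    """Yield one record per run element of a package-of-runs document."""
    try:
        root = ET.fromstring(xml_text)
    except ET.ParseError as exc:
        raise SraXmlError(f"malformed run package XML: {exc}") from exc
    packages = root.findall("./EXPERIMENT_PACKAGE") or [root]
    for pkg in packages:
        yield parse_run_xml(ET.tostring(pkg, encoding="unicode"))


def resolve_biosample_accession(record: RunRecord, xml_text: str) -> Optional[str]:
    """Find the BioSample accession for a run.

    Cross-reference elements (EXTERNAL_ID with a BioSample namespace, or an
    XREF_LINK to the biosample DB) are consulted first; failing that, the
    first ``SAMN<digits>`` token anywhere in the raw XML text is used.
    """
    try:
        root = ET.fromstring(xml_text)
    except ET.ParseError:
        root = None
    if root is not None:
        for ext in root.iter("EXTERNAL_ID"):
            ns = (ext.get("namespace") or "").lower()
            text = _norm(ext.text or "")
            if _SAMN_RE.fullmatch(text) and (not ns or "biosample" in ns):
                return text
        for xref in root.iter("XREF_LINK"):
            db = _norm(xref.findtext("DB") or "").lower()
            ident = _norm(xref.findtext("ID") or "")
            if "biosample" in db and ident:
                return ident
    m = _SAMN_RE.search(xml_text)
    return m.group(0) if m else None


def parse_biosample_xml(xml_text: str) -> dict[str, str]:
    """Parse BioSample attributes into a lowercased label->text mapping.

    Duplicate attribute names keep the first occurrence; the collision is
    logged because it usually signals a submitter error worth inspecting.
    """
    try:
        root = ET.fromstring(xml_text)
    except ET.ParseError as exc:
        raise SraXmlError(f"malformed BioSample XML: {exc}") from exc
    out: dict[str, str] = {}
    for attr in root.iter("Attribute"):
        name = _norm(attr.get("attribute_name") or "").lower()
        value = _norm(attr.text or "")
        if not name or not value:
            continue
        if name in out:
            log.warning("duplicate BioSample attribute %r; keeping first value", name)
            continue
        out[name] = value
    return out


def merge_sources(
    run_part: RunRecord,
    biosample: Mapping[str, str],
    api_row: Mapping[str, str],
    user_row: Optional[Mapping[str, str]] = None,
    biosample_accession: Optional[str] = None,
) -> RunRecord:
    """Attach BioSample, API and user values to a parsed run record.

    Nothing is overwritten: each source lives in its own tagged group and
    conflicting values are reconciled later by the rule stage.
    """
    if not run_part.run_accession:
        raise ConfigError("cannot merge sources without a run accession")
    return RunRecord(
        run_accession=run_part.run_accession,
        study_fields=dict(run_part.study_fields),
        sample_fields=dict(run_part.sample_fields),
        experiment_fields=dict(run_part.experiment_fields),
        run_fields=dict(run_part.run_fields),
        biosample_accession=biosample_accession or run_part.biosample_accession,
        biosample_attributes={k.lower(): _norm(v) for k, v in biosample.items()},
        api_fields={str(k): _norm(str(v)) for k, v in api_row.items()},
        user_notes={str(k): _norm(str(v)) for k, v in (user_row or {}).items()},
    )


def _read_table(path: str | Path) -> pd.DataFrame:
    sep = "\t" if str(path).endswith((".tsv", ".tab", ".txt")) else ","
    return pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)


def read_user_supplement(table_path: str | Path) -> dict[str, dict[str, str]]:
    """Read the optional user table keyed by a required run accession column.

    Additional text columns are preserved verbatim as user notes.  Rows
    sharing an accession are concatenated with ``" | "`` and a warning.
    """
    frame = _read_table(table_path)
    acc_col = next(
        (c for c in frame.columns if c.strip().lower().replace(" ", "_") == "run_accession"),
        None,
    )
    if acc_col is None:
        raise ConfigError(
            "user supplement is missing the required 'run_accession' column; "
            f"found columns: {list(frame.columns)}"
        )
    out: dict[str, dict[str, str]] = {}
    for _, row in frame.iterrows():
        accession = _norm(row[acc_col])
        if not accession:
            continue
        notes = {c: _norm(str(row[c])) for c in frame.columns if c != acc_col and _norm(str(row[c]))}
        if accession in out:
            log.warning("duplicate run accession %s in user supplement; concatenating", accession)
            for key, value in notes.items():
                prior = out[accession].get(key)
                out[accession][key] = f"{prior} | {value}" if prior else value
        else:
            out[accession] = notes
    return out


class Fetcher(Protocol):
    """Contract for anything that can resolve per-run inputs."""

    def fetch_run_xml(self, accession: str) -> str: ...

    def fetch_biosample_xml(self, accession: str) -> str: ...

    def fetch_api_row(self, accession: str) -> Mapping[str, str]: ...


class FixtureFetcher:
    """Resolves run inputs entirely from a local fixture directory.

    Layout: ``<acc>.run.xml`` and ``<samn>.biosample.xml`` files plus an
    ``api.tsv`` table with a ``run_accession`` column.  Used by all tests
    and by offline pipeline runs.
    """

    def __init__(self, directory: str | Path):
        self.directory = Path(directory)
        self._api: Optional[dict[str, dict[str, str]]] = None

    def run_accessions(self) -> list[str]:
        return sorted(p.name[: -len(".run.xml")] for p in self.directory.glob("*.run.xml"))

    def fetch_run_xml(self, accession: str) -> str:
        path = self.directory / f"{accession}.run.xml"
        if not path.exists():
            raise FileNotFoundError(f"no fixture run XML for {accession} in {self.directory}")
        return path.read_text(encoding="utf-8")

    def fetch_biosample_xml(self, accession: str) -> str:
        path = self.directory / f"{accession}.biosample.xml"
        if not path.exists():
            raise FileNotFoundError(f"no fixture BioSample XML for {accession}")
        return path.read_text(encoding="utf-8")

    def fetch_api_row(self, accession: str) -> dict[str, str]:
        if self._api is None:
            api_path = self.directory / "api.tsv"
            self._api = read_user_supplement(api_path) if api_path.exists() else {}
        return dict(self._api.get(accession, {}))


class LiveFetcher:
    """Thin NCBI E-utilities adapter with retry and a polite rate limit.

    Network access is opt-in; the whole test suite and all documented
    examples run on :class:`FixtureFetcher`.
    """

    EFETCH = "https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi"

    def __init__(self, delay: float = 0.4, retries: int = 3):
        self.delay = delay
        self.retries = retries

    def _get(self, url: str) -> str:
        import time
        import urllib.request

        last: Exception | None = None
        for _ in range(self.retries):
            try:
                with urllib.request.urlopen(url, timeout=30) as resp:
                    return resp.read().decode("utf-8", "replace")
            except Exception as exc:  # pragma: no cover - network only
                last = exc
                time.sleep(self.delay * 2)
            finally:
                time.sleep(self.delay)
        raise RuntimeError(f"fetch failed for {url}: {last}")  # pragma: no cover

    def fetch_run_xml(self, accession: str) -> str:  # pragma: no cover - network only
        return self._get(f"{self.EFETCH}?db=sra&id={accession}&rettype=xml")

    def fetch_biosample_xml(self, accession: str) -> str:  # pragma: no cover - network only
        return self._get(f"{self.EFETCH}?db=biosample&id={accession}&rettype=xml")

    def fetch_api_row(self, accession: str) -> dict[str, str]:  # pragma: no cover
        return {}


def fetch_record(fetcher: Fetcher, accession: str,
                 user_rows: Optional[Mapping[str, Mapping[str, str]]] = None) -> RunRecord:
    """Resolve, parse and merge every source for one run accession."""
    xml_text = fetcher.fetch_run_xml(accession)
    part = parse_run_xml(xml_text)
    if not part.run_accession:
        part.run_accession = accession
    samn = resolve_biosample_accession(part, xml_text)
    biosample: dict[str, str] = {}
    if samn:
        try:
            biosample = parse_biosample_xml(fetcher.fetch_biosample_xml(samn))
        except (FileNotFoundError, SraXmlError) as exc:
            log.warning("BioSample %s unavailable for %s: %s", samn, accession, exc)
    api_row = fetcher.fetch_api_row(accession)
    user_row = (user_rows or {}).get(accession)
    return merge_sources(part, biosample, api_row, user_row, biosample_accession=samn)
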