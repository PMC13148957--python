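"""Rule/LLM value resolution, post-hoc propagation and table export.

Two resolution policies are provided.  ``locked`` (default): values the
rule stage validated are final and the LLM only fills missing or flagged
fields.  ``per_class_preference``: each class declares whether the rule or
the LLM value wins when both exist — rules win for library selection and
treatment, the LLM elsewhere — and the losing value is retained in an
``*_alt`` provenance column so it can be inspected or overridden.

After resolution, cell lines newly introduced by the LLM are normalized
against the lexicon and their attributes propagated into still-missing
fields; disease/organ/biopsy-site terms are mapped to preferred names and
stable identifiers.  Final tables export to CSV/TSV/JSON always, and to
Parquet/Feather/XLSX when the optional writers are importable; every
format reloads to the same logical content.
"""

from __future__ import annotations

import copy
import json
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from . import schema
from .lexicons import LexiconSet, propagate_from_cell_line
from .llm import Prediction
from .rules import AnnotationRow, normalize_annotations

RESOLUTION_POLICIES = ("locked", "per_class_preference")

ALWAYS_FORMATS = ("csv", "tsv", "json")
OPTIONAL_FORMATS = {"parquet": "pyarrow", "feather": "pyarrow", "xlsx": "openpyxl"}


class CapabilityError(RuntimeError):
    """Requested an export format whose optional writer is unavailable."""


def _validated_llm_values(cls: schema.MetadataClass, pred: Prediction) -> list[str]:
    out = []
    for value in pred.values:
        if value == schema.UNKNOWN:
            continue
        outcome = schema.validate_value(cls, value)
        if outcome.accepted and outcome.normalized_value != schema.UNKNOWN:
            out.append(outcome.normalized_value)
    return out


def resolve_row(
    curated: AnnotationRow,
    predictions: Sequence[Prediction],
    policy: str = "locked",
    registry: Optional[schema.ClassRegistry] = None,
) -> AnnotationRow:
    """Merge the curated rule-stage row with the LLM predictions.

    Deterministic and per-run independent.  Losing values are kept in the
    field's ``alt`` slot regardless of policy.
    """
    if policy not in RESOLUTION_POLICIES:
        raise ValueError(f"unknown policy {policy!r}; choose from {RESOLUTION_POLICIES}")
    registry = registry or schema.registry()
    row = copy.deepcopy(curated)
    for pred in predictions:
        if pred.class_name not in row.fields:
            continue
        cls = registry.get(pred.class_name)
        if cls.is_api_direct:
            continue
        fv = row.fields[cls.name]
        llm_values = _validated_llm_values(cls, pred)
        rule_locked = fv.status == "validated" and bool(fv.values)
        if policy == "locked":
            take_llm = bool(llm_values) and not rule_locked
        else:
            rule_present = bool(fv.values) and fv.source in (
                "api", "rule", "lexicon_propagation"
            )
            if cls.resolution_preference == "rule":
                take_llm = bool(llm_values) and not rule_present
            else:
                take_llm = bool(llm_values)
        if take_llm:
            if fv.values and fv.values != llm_values:
                fv.alt = f"{fv.source}: " + ", ".join(fv.values)
            fv.values = llm_values
            fv.source = "llm"
            fv.status = "validated"
            fv.confidence = pred.confidence
        elif fv.values and llm_values and llm_values != fv.values:
            fv.alt = "llm: " + ", ".join(llm_values)
    return row


def post_propagate(row: AnnotationRow, lexicons: LexiconSet) -> AnnotationRow:
    """Normalize LLM-introduced cell lines and fill their dependents, then
    map disease/anatomy values to preferred names and ids.  Idempotent."""
    cell_fv = row.fields.get("cell_line")
    if cell_fv and cell_fv.values:
        entry = lexicons.cell_line_entry(cell_fv.values[0])
        if entry is not None:
            cell_fv.values[0] = entry.canonical
            propagate_from_cell_line(entry, row)
    return normalize_annotations(row, lexicons)


def rows_to_frame(
    rows: Iterable[AnnotationRow],
    registry: Optional[schema.ClassRegistry] = None,
) -> pd.DataFrame:
    """One row per run; per class: value, source, status, ppl, id and alt
    columns.  All cells are strings so exports round-trip exactly."""
    registry = registry or schema.registry()
    records = []
    for row in rows:
        record: dict[str, str] = {"run_accession": row.run_accession}
        for cls in registry:
            fv = row.fields[cls.name]
            record[cls.name] = ", ".join(fv.values)
            record[f"{cls.name}_source"] = fv.source if fv.values else "none"
            record[f"{cls.name}_status"] = fv.status
            ppl = getattr(fv.confidence, "ppl", None)
            record[f"{cls.name}_ppl"] = f"{ppl:.6g}" if ppl is not None else ""
            record[f"{cls.name}_id"] = fv.term_id or ""
            record[f"{cls.name}_alt"] = fv.alt or ""
        records.append(record)
    if not records:
        raise ValueError("no annotation rows to export")
    return pd.DataFrame.from_records(records).astype(str)


def _check_capability(fmt: str) -> None:
    module = OPTIONAL_FORMATS[fmt]
    try:
        __import__(module)
    except ImportError:
        available = list(ALWAYS_FORMATS) + [
            f for f, m in OPTIONAL_FORMATS.items()
            if _importable(m)
        ]
        raise CapabilityError(
            f"format {fmt!r} needs the optional {module!r} writer; "
            f"available formats: {available}"
        ) from None


def _importable(module: str) -> bool:
    try:
        __import__(module)
        return True
    except ImportError:
        return False


def export_table(
    rows: Sequence[AnnotationRow],
    formats: Iterable[str] = ("tsv",),
    out_dir: str | Path = ".",
    stem: str = "metadata",
    registry: Optional[schema.ClassRegistry] = None,
) -> dict[str, Path]:
    """Export the final annotation table in the requested formats."""
    frame = rows_to_frame(rows, registry)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    for fmt in formats:
        path = out_dir / f"{stem}.{fmt}"
        if fmt == "csv":
            frame.to_csv(path, index=False)
        elif fmt == "tsv":
            frame.to_csv(path, sep="\t", index=False)
        elif fmt == "json":
            path.write_text(
                json.dumps(frame.to_dict(orient="records"), indent=1),
                encoding="utf-8",
            )
        elif fmt in OPTIONAL_FORMATS:
            _check_capability(fmt)
            if fmt == "parquet":
                frame.to_parquet(path, index=False)
            elif fmt == "feather":
                frame.to_feather(path)
            else:
                frame.to_excel(path, index=False)
        else:
            raise CapabilityError(
                f"unknown format {fmt!r}; available: "
                f"{list(ALWAYS_FORMATS) + list(OPTIONAL_FORMATS)}"
            )
        written[fmt] = path
    return written


def read_exported(path: str | Path) -> pd.DataFrame:
    """Reload an exported table to compare logical content across formats."""
    path = Path(path)
    if path.suffix == ".csv":
        frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    elif path.suffix == ".tsv":
        frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    elif path.suffix == ".json":
        frame = pd.DataFrame(json.loads(path.read_text(encoding="utf-8")))
    elif path.suffix == ".parquet":
        frame = pd.read_parquet(path)
    elif path.suffix == ".feather":
        frame = pd.read_feather(path)
    elif path.suffix == ".xlsx":
        frame = pd.read_excel(path, dtype=str, keep_default_na=False)
    else:
        raise ValueError(f"unrecognized table format: {path.suffix}")
    return frame.fillna("").astype(str)


def summarize_table(
    rows: Sequence[AnnotationRow],
    registry: Optional[schema.ClassRegistry] = None,
    top_values: int = 5,
) -> pd.DataFrame:
    """Plain tabular quality summary.

    Per class: fill rate (fraction of runs with a non-missing, non-unknown
    value), the most frequent values, and quartiles of the perplexity
    confidence where predictions carry one.
    """
    registry = registry or schema.registry()
    if not rows:
        raise ValueError("no rows to summarize")
    records = []
    for cls in registry:
        values = []
        ppls = []
        filled = 0
        for row in rows:
            fv = row.fields[cls.name]
            known = [v for v in fv.values if v.casefold() != schema.UNKNOWN]
            if known:
                filled += 1
                values.extend(known)
            ppl = getattr(fv.confidence, "ppl", None)
            if ppl is not None:
                ppls.append(ppl)
        counts = pd.Series(values).value_counts() if values else pd.Series(dtype=int)
        top = "; ".join(f"{v} ({c})" for v, c in counts.head(top_values).items())
        quartiles = (
            np.quantile(ppls, [0.25, 0.5, 0.75]) if ppls else (np.nan, np.nan, np.nan)
        )
        records.append(
            {
                "class": cls.name,
                "fill_rate": filled / len(rows),
                "n_values": len(values),
                "top_values": top,
                "ppl_q25": quartiles[0],
                "ppl_median": quartiles[1],
                "ppl_q75": quartiles[2],
            }
        )
    return pd.DataFrame.from_records(records)
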