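"""The 19-field metadata schema used throughout the pipeline.

Each run in the Sequence Read Archive is annotated with 19 metadata
*classes* (organ, disease, cell line, donor age, ...).  Four of them are
submission-mandatory and always present in the NCBI API record
(``api_direct`` classes); the remaining 15 are reconstructed by the
rule-based and LLM stages.  Classes are either *discrete* (a closed label
set), *boolean*, *open vocabulary* (free text, normalized downstream), or
*numeric-or-qualitative* (donor age).

The default registry is shipped as a TSV data file so that users can add or
edit classes without touching code; :func:`load_registry` reads any file in
the same five-column layout.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional

#: Out-of-band abstention token.  It is a *member* of the label set only for
#: the ``response`` class; everywhere else it marks "no value recoverable".
UNKNOWN = "unknown"

VALUE_KINDS = frozenset(
    {"api_direct", "discrete", "open_vocab", "boolean", "numeric_or_qualitative"}
)

#: Qualitative donor-age terms accepted alongside numeric ages.
AGE_QUALITATIVE = frozenset({"child", "teen", "adult", "senior"})

#: Plausible human donor age bounds (years).
AGE_BOUNDS = (0.0, 120.0)

#: Alias folding for donor sex before membership checking.
SEX_ALIASES = {"m": "male", "f": "female", "male": "male", "female": "female"}

_WS_RE = re.compile(r"\s+")


def _collapse(text: str) -> str:
    return _WS_RE.sub(" ", text).strip()


@dataclass(frozen=True)
class MetadataClass:
    """One metadata class: its value kind, label set and prompt definition."""

    name: str
    kind: str
    allowed_values: tuple[str, ...] = ()
    definition_text: str = ""
    resolution_preference: str = "llm"

    def __post_init__(self) -> None:
        if self.kind not in VALUE_KINDS:
            raise ValueError(f"unknown value kind {self.kind!r} for class {self.name!r}")
        if self.kind in ("discrete", "boolean") and not self.allowed_values:
            raise ValueError(f"class {self.name!r} is {self.kind} but has no allowed values")
        if self.kind != "api_direct" and not self.definition_text:
            raise ValueError(f"non-api class {self.name!r} needs a definition text")
        if self.resolution_preference not in ("rule", "llm"):
            raise ValueError(f"bad resolution preference for {self.name!r}")

    @property
    def is_api_direct(self) -> bool:
        return self.kind == "api_direct"

    @property
    def is_closed(self) -> bool:
        return self.kind in ("discrete", "boolean")

    def canonical_label(self, raw: str) -> Optional[str]:
        """Case-insensitive lookup of *raw* in the allowed label set."""
        folded = _collapse(raw).casefold()
        for label in self.allowed_values:
            if label.casefold() == folded:
                return label
        return None


@dataclass(frozen=True)
class ValidationOutcome:
    accepted: bool
    normalized_value: Optional[str] = None
    reason: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.accepted and not self.reason:
            raise ValueError("rejections must carry a reason")


@dataclass(frozen=True)
class ClassRegistry:
    """Ordered, immutable collection of the pipeline's metadata classes."""

    classes: tuple[MetadataClass, ...]
    _by_name: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "_by_name", {c.name: c for c in self.classes})
        if len(self._by_name) != len(self.classes):
            raise ValueError("duplicate class names in registry")

    def __iter__(self):
        return iter(self.classes)

    def __len__(self) -> int:
        return len(self.classes)

    def get(self, name: str) -> MetadataClass:
        try:
            return self._by_name[name]
        except KeyError:
            raise KeyError(f"no metadata class named {name!r}") from None

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(c.name for c in self.classes)

    @property
    def api_direct(self) -> tuple[MetadataClass, ...]:
        return tuple(c for c in self.classes if c.is_api_direct)

    @property
    def llm_routed(self) -> tuple[MetadataClass, ...]:
        """Classes completed by the LLM stage (everything not API-direct)."""
        return tuple(c for c in self.classes if not c.is_api_direct)


def load_registry(path: str | Path) -> ClassRegistry:
    """Read a class registry from a five-column TSV file.

    Columns: ``name``, ``kind``, ``allowed_values`` (pipe-separated),
    ``definition_text``, ``resolution_preference``.
    """
    classes = []
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            allowed = tuple(v for v in (row.get("allowed_values") or "").split("|") if v)
            classes.append(
                MetadataClass(
                    name=row["name"].strip(),
                    kind=row["kind"].strip(),
                    allowed_values=allowed,
                    definition_text=(row.get("definition_text") or "").strip(),
                    resolution_preference=(row.get("resolution_preference") or "llm").strip(),
                )
            )
    return ClassRegistry(tuple(classes))


_REGISTRY: Optional[ClassRegistry] = None


def registry() -> ClassRegistry:
    """The fixed default 19-class registry (cached; immutable)."""
    global _REGISTRY
    if _REGISTRY is None:
        with resources.as_file(resources.files("srameta.data") / "classes.tsv") as p:
            _REGISTRY = load_registry(p)
    return _REGISTRY


_NUMERIC_RE = re.compile(r"^\d+(?:\.\d+)?$")
_AGE_RANGE_RE = re.compile(r"^(\d+(?:\.\d+)?)\s*[-–]\s*(\d+(?:\.\d+)?)$")


def _validate_age(raw: str) -> ValidationOutcome:
    folded = raw.casefold()
    if folded in AGE_QUALITATIVE:
        return ValidationOutcome(True, folded)
    lo, hi = AGE_BOUNDS
    m = _AGE_RANGE_RE.match(raw)
    if m:
        a, b = float(m.group(1)), float(m.group(2))
        if lo <= a <= b <= hi:
            return ValidationOutcome(True, raw)
        return ValidationOutcome(False, reason="out_of_range")
    if _NUMERIC_RE.match(raw):
        if lo <= float(raw) <= hi:
            return ValidationOutcome(True, raw)
        return ValidationOutcome(False, reason="out_of_range")
    if re.match(r"^-\d+(?:\.\d+)?$", raw):
        return ValidationOutcome(False, reason="out_of_range")
    return ValidationOutcome(False, reason="not_numeric_or_qualitative")


def validate_value(cls: MetadataClass, raw: str) -> ValidationOutcome:
    """Type-and-range check for one raw value of one class.

    Rejection is an outcome, not an error: rejected values simply never
    enter the curated table.  Closed classes are matched case-insensitively
    against their allowed labels and normalized to the canonical casing.
    Donor age must be numeric (or a numeric range) within plausible human
    bounds, or one of the qualitative terms; donor sex is alias-folded
    (``m``/``f``) and accepted only as male/female/unknown.
    """
    value = _collapse(raw)
    if not value:
        return ValidationOutcome(False, reason="empty")
    if cls.name == "age":
        return _validate_age(value)
    if cls.name == "sex":
        folded = SEX_ALIASES.get(value.casefold(), value.casefold())
        if folded in ("male", "female", UNKNOWN):
            return ValidationOutcome(True, folded)
        return ValidationOutcome(False, reason="not_in_allowed_values")
    if cls.is_closed:
        canonical = cls.canonical_label(value)
        if canonical is not None:
            return ValidationOutcome(True, canonical)
        return ValidationOutcome(False, reason="not_in_allowed_values")
    return ValidationOutcome(True, value)


def parse_multi_value(raw: str) -> list[str]:
    """Split a possibly multi-valued answer on ``,``/``;`` into clean parts.

    Whitespace is trimmed, empties dropped, and duplicates removed
    (case-insensitively) while preserving first-occurrence order, so the
    result is stable under re-rendering with ``", ".join``.
    """
    seen: set[str] = set()
    out: list[str] = []
    for part in re.split(r"[,;]", raw):
        value = _collapse(part)
        key = value.casefold()
        if value and key not in seen:
            seen.add(key)
            out.append(value)
    return out
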