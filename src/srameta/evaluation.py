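"""Hybrid scoring, per-class accuracy, trivial baselines, error taxonomy.

Closed classes are scored by exact (case-insensitive) label-set equality;
open-vocabulary classes tolerate context: a prediction is correct when any
predicted value matches any reference value by normalized string equality,
by mapping to the same lexicon/ontology identifier, or by being a listed
synonym pair ("oral cavity" vs "mouth" counts).  Two trivial baselines per
class — always the modal label, always "unknown" — expose majority bias
and over-abstention.  Errors split into abstentions (predicted "unknown"
when the reference is known) and substitutions (a wrong non-unknown
value), with substitution patterns tallied as ``class=value`` frequencies.
"""

from __future__ import annotations

import re
from collections import Counter
from typing import Optional, Sequence

from . import schema
from .lexicons import LexiconSet

ValueSet = Sequence[str]

_WS_RE = re.compile(r"\s+")


def _norm(value: str) -> str:
    return _WS_RE.sub(" ", value).strip().casefold()


def _is_unknown_ref(ref: ValueSet) -> bool:
    keys = {_norm(v) for v in ref}
    return keys <= {schema.UNKNOWN, "not applicable", "na", "n/a"}


def _open_values_match(a: str, b: str, cls: schema.MetadataClass,
                       lexicons: Optional[LexiconSet]) -> bool:
    na, nb = _norm(a), _norm(b)
    if na == nb:
        return True
    if lexicons is None:
        return False
    if cls.name == "cell_line":
        ea = lexicons.cell_line_entry(a)
        eb = lexicons.cell_line_entry(b)
        return ea is not None and ea is eb
    maps = []
    if cls.name == "disease":
        maps.append(lexicons.disease_map)
    elif cls.name in ("organ", "biopsy_site"):
        maps.append(lexicons.anatomy_map)
    else:
        maps.extend([lexicons.disease_map, lexicons.anatomy_map])
    for term_map in maps:
        ha, hb = term_map.lookup(a), term_map.lookup(b)
        if ha is not None and hb is not None and ha[1] == hb[1]:
            return True
    return False


def hybrid_match(pred: ValueSet, ref: ValueSet, cls: schema.MetadataClass,
                 lexicons: Optional[LexiconSet] = None) -> bool:
    """Whether a prediction counts as correct for one run and class.

    Closed/boolean classes (and donor sex): exact case-insensitive equality
    of the full label sets.  Open-vocabulary classes: any-overlap between
    predicted and reference values under string/identifier/synonym
    matching.  Symmetric in its two value sets.
    """
    if not pred or not ref:
        raise ValueError("prediction and reference value sets must be non-empty")
    if cls.is_closed or cls.name == "sex":
        return {_norm(v) for v in pred} == {_norm(v) for v in ref}
    return any(
        _open_values_match(p, r, cls, lexicons) for p in pred for r in ref
    )


def class_accuracy(
    preds: Sequence[ValueSet],
    refs: Sequence[ValueSet],
    cls: schema.MetadataClass,
    lexicons: Optional[LexiconSet] = None,
    exclude_unknown_refs: bool = True,
) -> Optional[float]:
    """Fraction of hybrid-match successes over aligned pairs.

    With *exclude_unknown_refs*, pairs whose reference is "unknown" (or
    "not applicable") are dropped first — accuracy then measures recovery
    of actually-known values.  Returns ``None`` when no pair survives the
    exclusion (the undefined case is signaled, not silently zero).
    """
    if len(preds) != len(refs):
        raise ValueError("predictions and references must align")
    pairs = list(zip(preds, refs))
    if exclude_unknown_refs:
        pairs = [(p, r) for p, r in pairs if not _is_unknown_ref(r)]
    if not pairs:
        return None
    hits = sum(hybrid_match(p, r, cls, lexicons) for p, r in pairs)
    return hits / len(pairs)


def _ref_key(ref: ValueSet) -> tuple[str, ...]:
    return tuple(sorted(_norm(v) for v in ref))


def baselines(refs: Sequence[ValueSet], cls: Optional[schema.MetadataClass] = None
              ) -> tuple[float, float]:
    """Trivial-classifier accuracies: (majority label, always-"unknown").

    Majority accuracy is the frequency of the modal reference value (ties
    broken lexicographically for determinism); unknown accuracy is the
    frequency of "unknown" references.
    """
    if not refs:
        raise ValueError("reference collection must be non-empty")
    counts = Counter(_ref_key(r) for r in refs)
    top = max(counts.items(), key=lambda kv: (kv[1], kv[0]))
    majority = top[1] / len(refs)
    unknown = counts.get((schema.UNKNOWN,), 0) / len(refs)
    return majority, unknown


def error_taxonomy(
    preds: Sequence[ValueSet],
    refs: Sequence[ValueSet],
    cls: schema.MetadataClass,
    lexicons: Optional[LexiconSet] = None,
) -> dict[str, object]:
    """Partition errors into abstentions and substitutions.

    Computed over pairs with a known reference.  Abstention: the model
    answered "unknown" although a value exists.  Substitution: a wrong
    non-unknown value; these are tallied as ``class=value`` patterns.
    The two fractions sum to one over the errors.
    """
    if len(preds) != len(refs):
        raise ValueError("predictions and references must align")
    abstentions = 0
    n_sub_events = 0
    substitutions: Counter[str] = Counter()
    for pred, ref in zip(preds, refs):
        if _is_unknown_ref(ref):
            continue
        if hybrid_match(pred, ref, cls, lexicons):
            continue
        if {_norm(v) for v in pred} == {schema.UNKNOWN}:
            abstentions += 1
        else:
            n_sub_events += 1
            for value in pred:
                substitutions[f"{cls.name}={_norm(value)}"] += 1
    n_errors = abstentions + n_sub_events
    if n_errors == 0:
        return {"n_errors": 0, "abstention_fraction": None,
                "substitution_fraction": None, "substitution_patterns": {}}
    return {
        "n_errors": n_errors,
        "abstention_fraction": abstentions / n_errors,
        "substitution_fraction": n_sub_events / n_errors,
        "substitution_patterns": dict(substitutions.most_common()),
    }


def evaluation_report(
    preds_by_class: dict[str, Sequence[ValueSet]],
    refs_by_class: dict[str, Sequence[ValueSet]],
    registry: Optional[schema.ClassRegistry] = None,
    lexicons: Optional[LexiconSet] = None,
):
    """Per-class TSV-ready report: n, accuracy, baselines, abstention share
    and the top substitution patterns."""
    import pandas as pd

    registry = registry or schema.registry()
    records = []
    for name, refs in refs_by_class.items():
        if name not in registry or name not in preds_by_class:
            continue
        cls = registry.get(name)
        preds = preds_by_class[name]
        known = [r for r in refs if not _is_unknown_ref(r)]
        accuracy = class_accuracy(preds, refs, cls, lexicons)
        majority, unknown = baselines(refs)
        taxonomy = error_taxonomy(preds, refs, cls, lexicons)
        top = "; ".join(
            f"{k} ({v})" for k, v in list(taxonomy["substitution_patterns"].items())[:3]
        )
        records.append(
            {
                "class": name,
                "n": len(refs),
                "n_known_ref": len(known),
                "accuracy": accuracy,
                "majority_baseline": majority,
                "unknown_baseline": unknown,
                "abstention_fraction": taxonomy["abstention_fraction"],
                "top_substitutions": top,
            }
        )
    return pd.DataFrame.from_records(records)
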