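"""Per-class prompt assembly, pluggable backends and confidence scoring.

Each of the 15 non-mandatory classes is predicted by its own prompt — one
class definition per prompt, since asking for a single class at a time is
far more reliable than asking for all of them at once.  A prompt has four
blocks in fixed order: (a) the run accession, (b) the context summary plus
any ambiguity notes from preprocessing, (c) the class's definition line
from the registry, and (d) a shared instruction block (extract if possible,
answer "unknown" otherwise, disambiguate the current run, list multiple
answers with ","/";" separators).

Backends implement a two-method contract (``generate`` returning text plus
per-token log-probabilities, plus identity metadata).  The package ships a
deterministic mock backend that answers from the hidden truth markers the
synthetic fixtures plant in their contexts, with seeded substitution and
abstention noise — so end-to-end and evaluation behavior can be exercised
without any model weights.  Real local-model runners plug in behind the
same contract.  Confidence per prediction is the mean negative
log-likelihood of the generated answer tokens (nats/token) and its
exponential, the perplexity.
"""

from __future__ import annotations

import json
import logging
import math
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Protocol, Sequence

from . import schema
from ._markers import parse_markers
from .context import ContextBundle

log = logging.getLogger(__name__)

#: Shared instruction block (prompt block (d)).
INSTRUCTION_BLOCK = (
    "Extract information from the summary if possible. "
    'If one value is impossible to extract, even by deducing it, return "unknown." '
    "Be careful: sometimes the information concerns several samples from the same "
    "study. Distinguish what applies to the current run so everything remains "
    "consistent. For each class, several answers can be possible; cite them all "
    'with a "," or ";" separator.'
)


@dataclass(frozen=True)
class Confidence:
    """Answer-token confidence: mean NLL (nats/token) and perplexity."""

    mean_nll: float
    ppl: float

    def __post_init__(self) -> None:
        if self.mean_nll < 0:
            raise ValueError("mean NLL must be non-negative")
        if abs(self.ppl - math.exp(self.mean_nll)) > 1e-9 * max(1.0, self.ppl):
            raise ValueError("perplexity must equal exp(mean NLL)")


def confidence_from_logprobs(logprobs: Sequence[float]) -> Confidence:
    """Mean negative log-likelihood and perplexity of the answer tokens."""
    if not logprobs:
        raise ValueError("cannot score an empty log-probability list")
    mean_nll = -sum(logprobs) / len(logprobs)
    return Confidence(mean_nll=mean_nll, ppl=math.exp(mean_nll))


@dataclass(frozen=True)
class Prompt:
    """One per-run, per-class prompt with its four ordered blocks."""

    run_accession: str
    summary_text: str
    ambiguity_text: str
    class_name: str
    class_definition_line: str
    instruction_block: str = INSTRUCTION_BLOCK

    def render(self) -> str:
        parts = [
            f"(a) Run accession: {self.run_accession}",
            f"(b) Context summary: {self.summary_text}",
        ]
        if self.ambiguity_text:
            parts.append(f"Ambiguity notes: {self.ambiguity_text}")
        parts.append(f"(c) Class definition line: - {self.class_name}: "
                     f"{self.class_definition_line}")
        parts.append(f"(d) {self.instruction_block}")
        return "\n".join(parts)


def build_prompt(run_accession: str, bundle: ContextBundle,
                 cls: schema.MetadataClass) -> Prompt:
    """Assemble the four-block prompt for one class of one run."""
    if cls.is_api_direct:
        raise ValueError(
            f"{cls.name} is API-mandatory and is never routed to the LLM stage"
        )
    return Prompt(
        run_accession=run_accession,
        summary_text=bundle.text,
        ambiguity_text="; ".join(bundle.ambiguity_notes),
        class_name=cls.name,
        class_definition_line=cls.definition_text,
    )


def route_adapter(cls: schema.MetadataClass, config: Mapping) -> str:
    """Pure lookup of the adapter id serving one class.

    One low-rank adapter per class keeps the deployment modular; unmapped
    classes fall back to the base model id, and the mock backend routes
    everything to ``"mock"``.
    """
    if cls.is_api_direct:
        raise ValueError(f"{cls.name} is not routed to the LLM stage")
    if config.get("backend") == "mock":
        return "mock"
    adapter_map = config.get("adapter_map") or {}
    return adapter_map.get(cls.name, config.get("base_model", "base"))


class Backend(Protocol):
    """Contract every inference backend implements."""

    model_name: str

    def generate(self, prompt: Prompt) -> tuple[str, list[float]]: ...


#: Decoy values used by the mock backend when it substitutes a wrong
#: answer for an open-vocabulary class.
_OPEN_DECOYS = ("basalt", "quasar", "meridian", "obelisk", "zephyr", "cobalt")


class MockBackend:
    """Deterministic test backend answering from planted truth markers.

    Reads the hidden ``@@class=value@@`` truth block the synthetic module
    embeds in fixture contexts and returns the truth, corrupted at seeded
    per-call rates: with probability *abstention_rate* it answers
    "unknown", with probability *substitution_rate* it answers a wrong
    label (another allowed label for closed classes, a decoy token for open
    ones).  Output and log-probabilities are fully determined by
    ``(prompt, seed)``.
    """

    model_name = "mock"
    adapter_id = "mock"

    def __init__(
        self,
        substitution_rate: float = 0.0,
        abstention_rate: float = 0.0,
        seed: int = 0,
        registry: Optional[schema.ClassRegistry] = None,
    ):
        if substitution_rate + abstention_rate > 1.0:
            raise ValueError("noise rates must sum to at most 1")
        self.substitution_rate = substitution_rate
        self.abstention_rate = abstention_rate
        self.seed = seed
        self.registry = registry or schema.registry()

    def _rng(self, prompt: Prompt):
        import random

        key = f"{self.seed}:{prompt.run_accession}:{prompt.class_name}"
        return random.Random(zlib.crc32(key.encode()))

    def _decoy(self, cls: schema.MetadataClass, truth: str, rng) -> str:
        if cls.is_closed:
            options = [v for v in cls.allowed_values
                       if v.casefold() != truth.casefold() and v != schema.UNKNOWN]
            if options:
                return rng.choice(options)
        options = [d for d in _OPEN_DECOYS if d.casefold() != truth.casefold()]
        return rng.choice(options)

    def generate(self, prompt: Prompt) -> tuple[str, list[float]]:
        truth_map = parse_markers(prompt.summary_text)
        values = truth_map.get(prompt.class_name, (schema.UNKNOWN,))
        rng = self._rng(prompt)
        draw = rng.random()
        correct = True
        if draw < self.abstention_rate:
            answer_values: tuple[str, ...] = (schema.UNKNOWN,)
            correct = False
        elif draw < self.abstention_rate + self.substitution_rate:
            cls = self.registry.get(prompt.class_name)
            answer_values = (self._decoy(cls, values[0], rng),)
            correct = False
        else:
            answer_values = values
        answer = ", ".join(answer_values)
        n_tokens = max(1, len(answer.split()))
        if correct:
            logprobs = [-rng.uniform(0.01, 0.2) for _ in range(n_tokens)]
        else:
            logprobs = [-rng.uniform(0.5, 2.5) for _ in range(n_tokens)]
        return answer, logprobs


@dataclass(frozen=True)
class Prediction:
    """Parsed model output for one class of one run."""

    class_name: str
    values: tuple[str, ...]
    confidence: Optional[Confidence]
    raw_text: str = ""
    failed: bool = False

    def __post_init__(self) -> None:
        if schema.UNKNOWN in self.values and len(self.values) > 1:
            raise ValueError('"unknown" cannot co-occur with other values')

    @property
    def is_unknown(self) -> bool:
        return self.values == (schema.UNKNOWN,)


def infer_class(backend: Backend, prompt: Prompt,
                cls: schema.MetadataClass) -> Prediction:
    """Run one prompt through a backend and parse the prediction.

    Output is whitespace/quote-stripped and split on ","/";".  Closed-class
    outputs snap to the canonical label by case-insensitive exact match;
    anything else becomes "unknown" with a warning (no fuzzy snapping — a
    silent wrong label is worse than an abstention).  Backend failures
    yield an "unknown" prediction flagged as failed.
    """
    try:
        text, logprobs = backend.generate(prompt)
    except Exception as exc:
        log.warning("backend failure for %s/%s: %s", prompt.run_accession, cls.name, exc)
        return Prediction(cls.name, (schema.UNKNOWN,), None, raw_text="", failed=True)
    stripped = text.strip().strip("\"'").strip()
    values = schema.parse_multi_value(stripped)
    if not values:
        values = [schema.UNKNOWN]
    if cls.is_closed or cls.name == "sex":
        snapped = []
        for value in values:
            if value.casefold() == schema.UNKNOWN:
                snapped.append(schema.UNKNOWN)
                continue
            outcome = schema.validate_value(cls, value)
            if outcome.accepted:
                snapped.append(outcome.normalized_value)
            else:
                log.warning("unparseable %s output %r; treating as unknown",
                            cls.name, value)
                snapped.append(schema.UNKNOWN)
        values = list(dict.fromkeys(snapped))
    if len(values) > 1:
        values = [v for v in values if v != schema.UNKNOWN]
    conf = confidence_from_logprobs(logprobs) if logprobs else None
    return Prediction(cls.name, tuple(values), conf, raw_text=text)


def infer_run(backend: Backend, bundle: ContextBundle,
              registry: Optional[schema.ClassRegistry] = None) -> list[Prediction]:
    """Predict every LLM-routed class for one run."""
    registry = registry or schema.registry()
    out = []
    for cls in registry.llm_routed:
        prompt = build_prompt(bundle.run_accession, bundle, cls)
        out.append(infer_class(backend, prompt, cls))
    return out


def write_prediction_file(run_accession: str, predictions: Sequence[Prediction],
                          path: str | Path,
                          registry: Optional[schema.ClassRegistry] = None) -> Path:
    """Write the per-run JSON prediction file (one entry per routed class)."""
    registry = registry or schema.registry()
    expected = {c.name for c in registry.llm_routed}
    got = {p.class_name for p in predictions}
    if got != expected:
        missing = sorted(expected - got)
        extra = sorted(got - expected)
        raise ValueError(f"prediction set mismatch: missing={missing} extra={extra}")
    payload = {
        "run_accession": run_accession,
        "predictions": {
            p.class_name: {
                "values": list(p.values),
                "mean_nll": p.confidence.mean_nll if p.confidence else None,
                "ppl": p.confidence.ppl if p.confidence else None,
                "raw_text": p.raw_text,
                "failed": p.failed,
            }
            for p in predictions
        },
    }
    path = Path(path)
    path.write_text(json.dumps(payload, indent=1), encoding="utf-8")
    return path


def load_prediction_file(path: str | Path) -> tuple[str, list[Prediction]]:
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    predictions = []
    for name, entry in payload["predictions"].items():
        conf = None
        if entry.get("mean_nll") is not None:
            conf = Confidence(entry["mean_nll"], entry["ppl"])
        predictions.append(
            Prediction(name, tuple(entry["values"]), conf,
                       raw_text=entry.get("raw_text", ""),
                       failed=bool(entry.get("failed", False)))
        )
    return payload["run_accession"], predictions
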