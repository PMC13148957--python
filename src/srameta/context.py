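"""Paragraph-style context building and budgeted extractive summarization.

Long prompts degrade LLM extraction, so each run's merged record is turned
into labeled paragraph text and, only when it exceeds the token budget
(default 2000 tokens), condensed: accession-like identifiers and
boilerplate are removed, exact duplicate sentences deleted, and the
remaining sentences are kept greedily by rare-term content (sum of inverse
within-bundle term frequencies) in document order until the budget fits.
Summarization never rewrites text (extractive only) and is idempotent.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from typing import Callable, Optional

from .sra_io import RunRecord

log = logging.getLogger(__name__)

#: Submitter placeholder values carrying no information.
PLACEHOLDER_VALUES = frozenset(
    {"", "unknown", "missing", "not collected", "na", "n/a", "none",
     "not applicable", "not provided", "not available", "--", "-"}
)

#: Boilerplate cues; sentences containing one are dropped during
#: summarization.  Configurable via the ``boilerplate`` argument.
DEFAULT_BOILERPLATE = (
    "keywords:",
    "none provided",
    "please cite",
    "this submission",
    "for more information",
)

#: Accession-like identifiers removed during summarization.
ACCESSION_RE = re.compile(
    r"\b(?:[SED]R[RXSPAZ]\d+|SAMN\d+|SAMEA\d+|PRJ[EDN][A-Z]\d+|GS[ME]\d+)\b"
)

_TOKEN_RE = re.compile(r"\w+|[^\w\s]")
_WORD_RE = re.compile(r"\w+")
_SENT_SPLIT_RE = re.compile(r"(?<=[.!?])\s+")

Tokenizer = Callable[[str], list[str]]


def default_tokenizer(text: str) -> list[str]:
    """Whitespace/punctuation word tokenizer (pluggable default)."""
    return _TOKEN_RE.findall(text)


def count_tokens(text: str, tokenizer: Optional[Tokenizer] = None) -> int:
    """Deterministic token count under the configured tokenizer."""
    return len((tokenizer or default_tokenizer)(text))


@dataclass
class ContextBundle:
    """Cleaned paragraph text plus its token count and ambiguity notes."""

    paragraphs: list[tuple[str, str]] = field(default_factory=list)
    token_count: int = 0
    ambiguity_notes: list[str] = field(default_factory=list)
    run_accession: str = ""

    @property
    def text(self) -> str:
        return "\n".join(p for p, _ in self.paragraphs)

    def recount(self, tokenizer: Optional[Tokenizer] = None) -> "ContextBundle":
        self.token_count = count_tokens(self.text, tokenizer)
        return self


_GROUP_ORDER = (
    ("Study", "study_fields", "sra_xml"),
    ("Sample", "sample_fields", "sra_xml"),
    ("Experiment", "experiment_fields", "sra_xml"),
    ("Run", "run_fields", "sra_xml"),
    ("Biosample", "biosample_attributes", "biosample"),
    ("Record", "api_fields", "api"),
    ("User note", "user_notes", "user"),
)


def is_placeholder(value: str) -> bool:
    return value.strip().casefold() in PLACEHOLDER_VALUES


def build_context(record: RunRecord, tokenizer: Optional[Tokenizer] = None) -> ContextBundle:
    """Render a merged run record as labeled paragraph text.

    Field groups appear in a stable order (study, sample, experiment, run,
    BioSample, API record, user notes last) and placeholder values are
    dropped.
    """
    bundle = ContextBundle(run_accession=record.run_accession)
    for label, group, source in _GROUP_ORDER:
        sentences = []
        for key, value in getattr(record, group).items():
            if is_placeholder(value):
                continue
            pretty_key = key.replace("_", " ")
            sentences.append(f"{label} {pretty_key}: {value}.")
        if sentences:
            bundle.paragraphs.append((" ".join(sentences), source))
    return bundle.recount(tokenizer)


def _split_sentences(text: str) -> list[str]:
    return [s for s in _SENT_SPLIT_RE.split(text) if s.strip()]


def _clean_sentence(sentence: str, boilerplate: tuple[str, ...]) -> Optional[str]:
    low = sentence.casefold()
    if any(b in low for b in boilerplate):
        return None
    cleaned = ACCESSION_RE.sub("", sentence)
    cleaned = re.sub(r"\s+", " ", cleaned).strip()
    return cleaned or None


def summarize(
    bundle: ContextBundle,
    budget: int = 2000,
    tokenizer: Optional[Tokenizer] = None,
    boilerplate: tuple[str, ...] = DEFAULT_BOILERPLATE,
) -> ContextBundle:
    """Enforce the token budget by extractive selection.

    Bundles at or below the budget are returned unchanged.  Otherwise
    identifiers/boilerplate are removed and duplicates deleted first; if the
    text still exceeds the budget, sentences are scored by the sum of
    inverse within-bundle term frequencies (rare phrases score high, ties
    broken by earlier position) and kept greedily; the survivors are emitted
    in document order.  A single over-budget sentence is truncated at a
    token boundary with a warning.
    """
    if budget <= 0:
        raise ValueError("budget must be positive")
    if bundle.token_count <= budget:
        return bundle
    tok = tokenizer or default_tokenizer

    # sentence list with (position, text, source); cleaned, exact-deduped
    sentences: list[tuple[int, str, str]] = []
    seen: set[str] = set()
    pos = 0
    for para, source in bundle.paragraphs:
        for raw in _split_sentences(para):
            pos += 1
            cleaned = _clean_sentence(raw, boilerplate)
            if cleaned is None:
                continue
            key = cleaned.casefold()
            if key in seen:
                continue
            seen.add(key)
            sentences.append((pos, cleaned, source))

    counts = [count_tokens(s, tok) for _, s, _ in sentences]
    if sum(counts) > budget:
        freq: dict[str, int] = {}
        for _, sentence, _ in sentences:
            for word in _WORD_RE.findall(sentence.casefold()):
                freq[word] = freq.get(word, 0) + 1
        scored = []
        for idx, (position, sentence, source) in enumerate(sentences):
            words = _WORD_RE.findall(sentence.casefold())
            score = sum(1.0 / freq[w] for w in words)
            scored.append((-score, position, idx))
        scored.sort()
        kept: set[int] = set()
        used = 0
        for _, _, idx in scored:
            if used + counts[idx] <= budget:
                kept.add(idx)
                used += counts[idx]
        if not kept and sentences:
            # degenerate: one giant sentence — truncate at a token boundary
            log.warning("single sentence exceeds the %d-token budget; truncating", budget)
            _, sentence, source = sentences[0]
            tokens = tok(sentence)[:budget]
            sentences = [(0, " ".join(tokens), source)]
            kept = {0}
        sentences = [s for i, s in enumerate(sentences) if i in kept]

    # regroup consecutive kept sentences by source, preserving order
    paragraphs: list[tuple[str, str]] = []
    for _, sentence, source in sentences:
        if paragraphs and paragraphs[-1][1] == source:
            paragraphs[-1] = (paragraphs[-1][0] + " " + sentence, source)
        else:
            paragraphs.append((sentence, source))
    out = ContextBundle(
        paragraphs=paragraphs,
        ambiguity_notes=list(bundle.ambiguity_notes),
        run_accession=bundle.run_accession,
    ).recount(tok)
    if out.token_count > budget:  # pragma: no cover - defensive
        log.warning("summary still over budget (%d > %d)", out.token_count, budget)
    return out
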