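"""Hidden ground-truth markers used by the synthetic fixtures.

Synthetic contexts carry a machine-readable truth block of the form
``@@class=value1;value2@@`` so that the mock inference backend can answer
from the planted truth without any model weights.  The rule stage and the
similarity functions strip these markers first: they are test plumbing, not
metadata.
"""

from __future__ import annotations

import re

MARKER_RE = re.compile(r"@@([A-Za-z_]+)=([^@]*)@@")


def format_markers(truth: dict[str, tuple[str, ...] | list[str]]) -> str:
    return " ".join(f"@@{name}={';'.join(values)}@@" for name, values in truth.items())


def parse_markers(text: str) -> dict[str, tuple[str, ...]]:
    out: dict[str, tuple[str, ...]] = {}
    for m in MARKER_RE.finditer(text):
        values = tuple(v.strip() for v in m.group(2).split(";") if v.strip())
        out.setdefault(m.group(1), values)
    return out


def strip_markers(text: str) -> str:
    return MARKER_RE.sub(" ", text)
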