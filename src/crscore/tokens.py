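"""Whitespace/punctuation tokenization with recorded character offsets.

Offset fidelity matters: spans are scored by character overlap, so the
tagger must be able to map token-level decisions back to exact offsets.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

_TOKEN_RE = re.compile(r"\w+|[^\w\s]", re.UNICODE)


@dataclass(frozen=True)
class Token:
    start: int
    end: int
    text: str


def tokenize(text: str) -> list[Token]:
    """Split into word/punctuation tokens, each with [start, end) offsets."""
    return [
        Token(m.start(), m.end(), m.group()) for m in _TOKEN_RE.finditer(text)
    ]
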