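"""Truncate a full admission note to its assessment section.

The models only ever see the portion of the note where the differential
diagnosis for the primary presenting problem is argued. Institutions
differ in note-writing style, so the header/plan-marker vocabulary is a
per-site "dialect" table; the output is always a contiguous substring of
the input, and a note with no recognizable header falls back to the
whole text with a logged warning.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Dialect:
    """Site-specific header and plan-marker vocabularies."""

    name: str
    headers: tuple[str, ...]
    plan_markers: tuple[str, ...] = ("plan",)


DEFAULT_DIALECT = Dialect(
    name="default",
    headers=("assessment and plan", "assessment & plan", "assessment", "a/p", "impression"),
)

DIALECTS: dict[str, Dialect] = {
    "default": DEFAULT_DIALECT,
    "nyu": Dialect(
        name="nyu",
        headers=("assessment and plan", "assessment", "a/p"),
    ),
    "uc": Dialect(
        name="uc",
        headers=("impression and plan", "impression", "assessment"),
    ),
}


@dataclass(frozen=True)
class TruncationResult:
    """The extracted assessment span and the heuristic that produced it."""

    text: str
    start: int
    end: int
    matched_rule: str


def _header_regex(dialect: Dialect) -> re.Pattern[str]:
    alts = "|".join(re.escape(h) for h in sorted(dialect.headers, key=len, reverse=True))
    return re.compile(rf"^[ \t]*({alts})[ \t]*:?[ \t]*", re.IGNORECASE | re.MULTILINE)


def _plan_regex(dialect: Dialect) -> re.Pattern[str]:
    alts = "|".join(re.escape(p) for p in dialect.plan_markers)
    return re.compile(
        rf"^[ \t]*(?:(?:{alts})[ \t]*:|\d+[.)][ \t])", re.IGNORECASE | re.MULTILINE
    )


def truncate_assessment(
    text: str, dialect: Dialect | str = DEFAULT_DIALECT
) -> TruncationResult:
    """Extract the span from the first assessment header to the first
    plan-enumeration marker.

    Returns the whole text with ``matched_rule="fallback_whole_note"``
    when no header matches. Raises ``ValueError`` on empty input.
    """
    if not text:
        raise ValueError("cannot truncate empty note text")
    if isinstance(dialect, str):
        try:
            dialect = DIALECTS[dialect]
        except KeyError:
            raise ValueError(f"unknown dialect {dialect!r}") from None

    header_match = _header_regex(dialect).search(text)
    if header_match is None:
        logger.warning("no assessment header matched; returning whole note")
        return TruncationResult(
            text=text, start=0, end=len(text), matched_rule="fallback_whole_note"
        )

    start = header_match.end()
    plan_match = _plan_regex(dialect).search(text, start)
    end = plan_match.start() if plan_match else len(text)
    # trim surrounding whitespace while keeping offsets into the original
    while start < end and text[start].isspace():
        start += 1
    while end > start and text[end - 1].isspace():
        end -= 1
    rule = f"header:{header_match.group(1).lower()}" + (
        "|plan_marker" if plan_match else "|eof"
    )
    return TruncationResult(text=text[start:end], start=start, end=end, matched_rule=rule)
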