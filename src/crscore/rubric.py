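"""Deterministic mappings from entities and model decisions to Revised-IDEA scores.

The differential-diagnosis (D) score is derived from recognized
entities: a note scores D0 when it names fewer than two unique specific
diagnoses, D2 when it names at least two unique diagnoses *and* contains
explicit prioritization language, and D1 otherwise. Diagnostic-category
words ("cardiac", "infectious", ...) never count as diagnoses.

Two further rules compose classifier decisions back to scores: the
ordered stepwise rule for the D scale built from one-vs-rest D0/D2
models, and the binarization of the explanation-of-reasoning (EA) scale
into EA2 vs not-EA2.
"""

from __future__ import annotations

import re
import unicodedata
from dataclasses import dataclass
from typing import Iterable

from .corpus import EntitySpan

_WS_RE = re.compile(r"\s+")


def _is_punct(char: str) -> bool:
    return unicodedata.category(char).startswith("P")


def normalize_dx(surface: str) -> str:
    """Normalized surface form used for diagnosis uniqueness.

    Unicode casefold, strip leading/trailing punctuation, collapse
    internal whitespace. No synonym or ontology merging: "CHF" and
    "congestive heart failure" remain two distinct diagnoses.
    """
    text = surface.casefold()
    start, end = 0, len(text)
    while start < end and (_is_punct(text[start]) or text[start].isspace()):
        start += 1
    while end > start and (_is_punct(text[end - 1]) or text[end - 1].isspace()):
        end -= 1
    return _WS_RE.sub(" ", text[start:end])


@dataclass(frozen=True)
class DScoreBreakdown:
    """Entity counts behind a D score, for auditability."""

    unique_dx_count: int
    prior_count: int
    dc_count: int
    d_score: int
    normalized_dx_forms: tuple[str, ...]


def count_unique_dx(spans: Iterable[EntitySpan]) -> tuple[int, list[str]]:
    """Count distinct normalized diagnosis surfaces among Dx spans.

    Spans of the other four types never contribute. Forms are returned
    in order of first occurrence.
    """
    forms: list[str] = []
    seen: set[str] = set()
    for span in spans:
        if span.etype != "Dx":
            continue
        form = normalize_dx(span.surface)
        if form and form not in seen:
            seen.add(form)
            forms.append(form)
    return len(forms), forms


def d_score_from_entities(spans: Iterable[EntitySpan]) -> DScoreBreakdown:
    """Apply the entity→D logic rule.

    D0: fewer than 2 unique diagnoses. D2: >=2 unique diagnoses and at
    least one prioritization span. D1: everything else.
    """
    spans = list(spans)
    unique_dx, forms = count_unique_dx(spans)
    prior_count = sum(1 for s in spans if s.etype == "Prior")
    dc_count = sum(1 for s in spans if s.etype == "DC")
    if unique_dx < 2:
        score = 0
    elif prior_count >= 1:
        score = 2
    else:
        score = 1
    return DScoreBreakdown(
        unique_dx_count=unique_dx,
        prior_count=prior_count,
        dc_count=dc_count,
        d_score=score,
        normalized_dx_forms=tuple(forms),
    )


def stepwise_d(d0_positive: bool, d2_positive: bool) -> int:
    """Compose thresholded one-vs-rest D0/D2 decisions into a D score.

    Ordered rule: if the D0 model fires, D=0; else if the D2 model
    fires, D=2; else D=1.
    """
    if d0_positive:
        return 0
    if d2_positive:
        return 2
    return 1


def ea2_binarize(ea_score: int) -> str:
    """Collapse the 0-2 EA scale to the binary EA2 vs not-EA2 target."""
    if ea_score not in (0, 1, 2):
        raise ValueError(f"EA score must be 0, 1 or 2; got {ea_score!r}")
    return "EA2" if ea_score == 2 else "not_EA2"
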