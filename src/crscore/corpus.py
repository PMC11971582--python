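"""Domain types and JSONL readers/writers for annotated note corpora.

A corpus is one JSON object per line with fields ``note_id``, ``text``,
``site``, ``d_gold``, ``ea_gold``, ``meta`` and ``spans``; spans use
0-based, half-open character offsets into ``text``, the convention of
common standoff-annotation exports. Unknown extra fields are preserved
on round trip.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable

#: The five rubric entity types: specific diagnosis, diagnostic
#: category, prioritization language, clinical data, linkage term.
ENTITY_TYPES: tuple[str, ...] = ("Dx", "DC", "Prior", "Data", "Link")

_SCORES = (0, 1, 2)

_NOTE_FIELDS = {"note_id", "text", "site", "d_gold", "ea_gold", "meta", "spans"}
_SPAN_FIELDS = {"start", "end", "etype", "surface"}


class CorpusError(ValueError):
    """Base class for corpus reading/validation failures."""


class CorpusParseError(CorpusError):
    """A line of a JSONL file is not valid JSON."""


class CorpusValidationError(CorpusError):
    """A record violates a domain-type invariant."""


@dataclass(frozen=True)
class EntitySpan:
    """A character-offset span tagged with one of the five entity types.

    ``start`` is 0-based inclusive, ``end`` exclusive; ``surface`` must
    equal the slice ``text[start:end]`` of the owning note.
    """

    start: int
    end: int
    etype: str
    surface: str

    def validate(self, text: str, note_id: str = "?") -> None:
        if self.etype not in ENTITY_TYPES:
            raise CorpusValidationError(
                f"note {note_id!r}: unknown entity type {self.etype!r}"
            )
        if not (0 <= self.start < self.end <= len(text)):
            raise CorpusValidationError(
                f"note {note_id!r}: span [{self.start},{self.end}) outside "
                f"text of length {len(text)}"
            )
        if text[self.start : self.end] != self.surface:
            raise CorpusValidationError(
                f"note {note_id!r}: span surface {self.surface!r} does not "
                f"equal text slice {text[self.start:self.end]!r}"
            )

    def overlaps(self, other: "EntitySpan") -> bool:
        return self.start < other.end and other.start < self.end


@dataclass
class Note:
    """One admission-note assessment text with optional gold labels.

    ``d_gold`` is the differential-diagnosis score and ``ea_gold`` the
    explanation-of-reasoning score, each on the 0-2 Revised-IDEA scale.
    """

    note_id: str
    text: str
    site: str | None = None
    d_gold: int | None = None
    ea_gold: int | None = None
    meta: dict[str, str] | None = None
    extra: dict[str, Any] = field(default_factory=dict)

    def validate(self) -> None:
        if not isinstance(self.note_id, str) or not self.note_id:
            raise CorpusValidationError(f"invalid note_id {self.note_id!r}")
        if not isinstance(self.text, str):
            raise CorpusValidationError(f"note {self.note_id!r}: text not a string")
        for name, value in (("d_gold", self.d_gold), ("ea_gold", self.ea_gold)):
            if value is not None and value not in _SCORES:
                raise CorpusValidationError(
                    f"note {self.note_id!r}: {name}={value!r} not in {{0,1,2}}"
                )


@dataclass
class AnnotatedNote:
    """A note plus its gold entity spans; the unit of NER training."""

    note: Note
    spans: list[EntitySpan] = field(default_factory=list)

    def validate(self) -> None:
        self.note.validate()
        for span in self.spans:
            span.validate(self.note.text, self.note.note_id)
        starts = [s.start for s in self.spans]
        if starts != sorted(starts):
            raise CorpusValidationError(
                f"note {self.note.note_id!r}: spans not sorted by start"
            )


def _span_from_dict(raw: dict[str, Any], note_id: str) -> EntitySpan:
    try:
        return EntitySpan(
            start=raw["start"],
            end=raw["end"],
            etype=raw["etype"],
            surface=raw["surface"],
        )
    except KeyError as exc:
        raise CorpusValidationError(
            f"note {note_id!r}: span missing field {exc.args[0]!r}"
        ) from None


def note_from_dict(raw: dict[str, Any], with_annotations: bool = True) -> AnnotatedNote:
    """Build a validated :class:`AnnotatedNote` from a decoded JSON record."""
    if "note_id" not in raw or "text" not in raw:
        raise CorpusValidationError(
            f"record missing required field(s): {sorted({'note_id', 'text'} - raw.keys())}"
        )
    extra = {k: v for k, v in raw.items() if k not in _NOTE_FIELDS}
    note = Note(
        note_id=raw["note_id"],
        text=raw["text"],
        site=raw.get("site"),
        d_gold=raw.get("d_gold"),
        ea_gold=raw.get("ea_gold"),
        meta=raw.get("meta"),
        extra=extra,
    )
    spans: list[EntitySpan] = []
    if with_annotations:
        spans = [_span_from_dict(s, note.note_id) for s in raw.get("spans", [])]
        spans.sort(key=lambda s: (s.start, s.end))
    annotated = AnnotatedNote(note=note, spans=spans)
    annotated.validate()
    return annotated


def note_to_dict(annotated: AnnotatedNote) -> dict[str, Any]:
    note = annotated.note
    record: dict[str, Any] = {"note_id": note.note_id, "text": note.text}
    if note.site is not None:
        record["site"] = note.site
    if note.d_gold is not None:
        record["d_gold"] = note.d_gold
    if note.ea_gold is not None:
        record["ea_gold"] = note.ea_gold
    if note.meta is not None:
        record["meta"] = note.meta
    record["spans"] = [
        {"start": s.start, "end": s.end, "etype": s.etype, "surface": s.surface}
        for s in annotated.spans
    ]
    for key in sorted(note.extra):
        record[key] = note.extra[key]
    return record


def read_corpus(path: str | Path, with_annotations: bool = True) -> list[AnnotatedNote]:
    """Read a JSONL corpus, validating every record.

    File order is preserved. A malformed JSON line raises
    :class:`CorpusParseError` naming the line number; an invariant
    violation raises :class:`CorpusValidationError` naming the note.
    """
    path = Path(path)
    corpus: list[AnnotatedNote] = []
    seen_ids: set[str] = set()
    with path.open("r", encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            if not line.strip():
                continue
            try:
                raw = json.loads(line)
            except json.JSONDecodeError as exc:
                raise CorpusParseError(
                    f"{path}:{lineno}: malformed JSON ({exc.msg})"
                ) from exc
            annotated = note_from_dict(raw, with_annotations=with_annotations)
            if annotated.note.note_id in seen_ids:
                raise CorpusValidationError(
                    f"{path}:{lineno}: duplicate note_id {annotated.note.note_id!r}"
                )
            seen_ids.add(annotated.note.note_id)
            corpus.append(annotated)
    return corpus


def write_corpus(corpus: Iterable[AnnotatedNote], path: str | Path) -> None:
    """Write a corpus as JSONL; byte-identical for repeated writes."""
    path = Path(path)
    lines = []
    for annotated in corpus:
        annotated.validate()
        lines.append(
            json.dumps(note_to_dict(annotated), ensure_ascii=False, sort_keys=False)
        )
    path.write_text("".join(line + "\n" for line in lines), encoding="utf-8")
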