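"""Synthetic assessment-section notes with gold entity spans and scores.

Real admission-note corpora for this task are private EHR data, so this
module generates stand-ins that preserve the statistical structure the
models care about: a controllable number of distinct specific-diagnosis
mentions, diagnostic-category words, prioritization phrases, supporting
clinical data, and linkage terms, with gold D/EA labels derived from the
same deterministic logic the scorer applies.

Gold D labels are produced by :func:`crscore.rubric.d_score_from_entities`
applied to the gold spans, so generator and scorer share one logic by
construction — this is asserted for every emitted note.

EA gold convention (a generator convention, not a clinical claim): the
EA score counts the *distinct* diagnoses that carry both at least one
Data span and at least one Link span within a shared sentence — 0 such
diagnoses is EA0, exactly 1 is EA1, 2 or more is EA2. This mirrors the
"explanation of lead/alternative diagnoses" semantics of the rubric and
gives classifiers a learnable signal. Under it a note with fewer than
two unique diagnoses (D0) can reach at most EA1, so the corpus sampler
draws (D, EA) pairs from a coupled joint distribution that still honors
both configured marginals.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field, replace

import numpy as np

from .corpus import AnnotatedNote, EntitySpan, Note
from .lexicons import DISTRACTORS, default_lexicons
from .rubric import d_score_from_entities

#: Class proportions default to the retrospective development set:
#: D 109/154/437 of 700 and EA 73/255/372 of 700.
DEFAULT_D_PROPORTIONS: tuple[float, float, float] = (109 / 700, 154 / 700, 437 / 700)
DEFAULT_EA_PROPORTIONS: tuple[float, float, float] = (73 / 700, 255 / 700, 372 / 700)


class ConfigError(ValueError):
    """The generator configuration is invalid or unsatisfiable."""


@dataclass
class GeneratorConfig:
    """Knobs controlling corpus size, class mix and difficulty.

    ``noise`` is a per-character misspelling/casing rate applied to the
    connective prose between entities; with ``noise_in_spans`` it also
    corrupts entity surfaces (the "hard" regime). Diagnosis surfaces are
    corrupted consistently within a note so uniqueness counting — and
    hence the gold D label — is unaffected.
    """

    n_notes: int = 100
    d_proportions: tuple[float, float, float] = DEFAULT_D_PROPORTIONS
    ea_proportions: tuple[float, float, float] = DEFAULT_EA_PROPORTIONS
    lexicons: dict[str, tuple[str, ...]] = field(default_factory=default_lexicons)
    distractor_vocabulary: tuple[str, ...] = DISTRACTORS
    noise: float = 0.0
    noise_in_spans: bool = False
    seed: int = 0
    site: str = "synthetic"

    def validate(self) -> None:
        if self.n_notes < 0:
            raise ConfigError("n_notes must be nonnegative")
        for name, props in (
            ("d_proportions", self.d_proportions),
            ("ea_proportions", self.ea_proportions),
        ):
            if len(props) != 3 or any(p < 0 for p in props):
                raise ConfigError(f"{name} must be 3 nonnegative values")
            if abs(sum(props) - 1.0) > 1e-9:
                raise ConfigError(f"{name} must sum to 1, got {sum(props)}")
        if not 0.0 <= self.noise <= 1.0:
            raise ConfigError("noise must lie in [0, 1]")
        missing = {"Dx", "DC", "Prior", "Data", "Link"} - set(self.lexicons)
        if missing:
            raise ConfigError(f"lexicons missing entity types: {sorted(missing)}")
        for etype, phrases in self.lexicons.items():
            if not phrases:
                raise ConfigError(f"lexicon for {etype} is empty")
        if sum(self.d_proportions[1:]) > 0 and len(self.lexicons["Dx"]) < 2:
            raise ConfigError(
                "D1/D2 notes need >=2 distinct diagnoses in the Dx lexicon"
            )
        if not self.distractor_vocabulary:
            raise ConfigError("distractor vocabulary is empty")


class _NoteBuilder:
    """Accumulates text fragments while recording entity span offsets."""

    def __init__(self) -> None:
        self._parts: list[str] = []
        self._length = 0
        self.spans: list[EntitySpan] = []

    def glue(self, fragment: str) -> None:
        self._parts.append(fragment)
        self._length += len(fragment)

    def entity(self, phrase: str, etype: str) -> None:
        start = self._length
        self.glue(phrase)
        self.spans.append(
            EntitySpan(start=start, end=start + len(phrase), etype=etype, surface=phrase)
        )

    @property
    def text(self) -> str:
        return "".join(self._parts)


def _corrupt(text: str, rate: float, rng: np.random.Generator) -> str:
    """Character-level misspelling plus random casing flips."""
    if rate <= 0 or not text:
        return text
    out: list[str] = []
    for char in text:
        if char.isalpha() and rng.random() < rate:
            action = rng.integers(0, 4)
            if action == 0:
                continue  # deletion
            if action == 1:
                out.append(char + char)  # duplication
                continue
            if action == 2:
                out.append(str(rng.choice(list(string.ascii_lowercase))))
                continue
            out.append(char.swapcase())
        else:
            out.append(char)
    return "".join(out)


def _pick(rng: np.random.Generator, items: tuple[str, ...] | list[str]) -> str:
    return items[int(rng.integers(0, len(items)))]


def sample_note(
    d_target: int,
    ea_target: int,
    config: GeneratorConfig,
    rng: np.random.Generator,
    note_id: str = "syn-0",
) -> AnnotatedNote:
    """Generate one note whose gold spans realize the requested scores.

    D2 notes contain >=2 distinct diagnoses plus prioritization
    language; D1 notes >=2 diagnoses and no prioritization; D0 notes at
    most one unique diagnosis (possibly alongside diagnostic-category
    words, which never count). The EA target is realized via the
    supported-diagnosis convention in the module docstring; a D0 note
    cannot reach EA2 (that needs two distinct supported diagnoses), so
    the pair (0, 2) is rejected as unsatisfiable.
    """
    if d_target not in (0, 1, 2) or ea_target not in (0, 1, 2):
        raise ConfigError("score targets must be 0, 1 or 2")
    if d_target == 0 and ea_target == 2:
        raise ConfigError(
            "unsatisfiable targets: EA2 needs >=2 distinct supported "
            "diagnoses, while D0 allows at most 1 unique diagnosis"
        )
    lex = config.lexicons
    noise = config.noise

    # Per-note corruption memo keeps repeated diagnosis surfaces identical.
    dx_memo: dict[str, str] = {}

    def span_surface(phrase: str, etype: str) -> str:
        if not config.noise_in_spans or noise <= 0:
            return phrase
        if etype == "Dx":
            if phrase not in dx_memo:
                dx_memo[phrase] = _corrupt(phrase, noise, rng) or phrase
            return dx_memo[phrase]
        return _corrupt(phrase, noise, rng) or phrase

    # --- plan the mention structure -----------------------------------
    # mentions: list of (dx phrase, supported?) — one sentence each.
    if d_target == 0:
        n_unique = 1 if ea_target > 0 or rng.random() < 0.6 else 0
        dx_forms = (
            [str(x) for x in rng.choice(lex["Dx"], size=1, replace=False)]
            if n_unique
            else []
        )
        if ea_target == 0:
            mentions = [(dx_forms[0], False)] if dx_forms else []
        else:  # EA1: the single diagnosis is explained
            mentions = [(dx_forms[0], True)]
        want_prior = bool(dx_forms) and rng.random() < 0.3
    else:
        n_unique = int(rng.integers(2, 5))
        if len(lex["Dx"]) < n_unique:
            n_unique = 2
        dx_forms = [
            str(x) for x in rng.choice(lex["Dx"], size=n_unique, replace=False)
        ]
        supported = set(range(min(ea_target, n_unique)))
        mentions = [(dx, i in supported) for i, dx in enumerate(dx_forms)]
        want_prior = d_target == 2

    builder = _NoteBuilder()

    def glue(fragment: str) -> None:
        builder.glue(_corrupt(fragment, noise, rng))

    # intro sentence of pure filler
    glue("The patient ")
    glue(_pick(rng, config.distractor_vocabulary))
    glue(" ")
    glue(_pick(rng, config.distractor_vocabulary))
    glue(". ")

    prior_used = False
    sentences = list(mentions)
    for idx, (dx, is_supported) in enumerate(sentences):
        attach_prior = want_prior and not prior_used
        if is_supported:
            if attach_prior:
                builder.entity(span_surface(dx, "Dx"), "Dx")
                glue(" is ")
                builder.entity(span_surface(_pick(rng, lex["Prior"]), "Prior"), "Prior")
                glue(", ")
                builder.entity(span_surface(_pick(rng, lex["Link"]), "Link"), "Link")
                glue(" ")
                builder.entity(span_surface(_pick(rng, lex["Data"]), "Data"), "Data")
                glue(". ")
                prior_used = True
            else:
                glue("There is ")
                builder.entity(span_surface(_pick(rng, lex["Data"]), "Data"), "Data")
                glue(" ")
                builder.entity(span_surface(_pick(rng, lex["Link"]), "Link"), "Link")
                glue(" ")
                builder.entity(span_surface(dx, "Dx"), "Dx")
                glue(". ")
        else:
            if attach_prior:
                builder.entity(span_surface(dx, "Dx"), "Dx")
                glue(" is ")
                builder.entity(span_surface(_pick(rng, lex["Prior"]), "Prior"), "Prior")
                glue(". ")
                prior_used = True
            elif rng.random() < 0.5:
                # data without a linkage term: mention stays unsupported
                glue("We also consider ")
                builder.entity(span_surface(dx, "Dx"), "Dx")
                glue("; noted ")
                builder.entity(span_surface(_pick(rng, lex["Data"]), "Data"), "Data")
                glue(". ")
            else:
                glue("We also consider ")
                builder.entity(span_surface(dx, "Dx"), "Dx")
                glue(". ")

    if want_prior and not prior_used:
        # D0 note with prioritization language but <2 diagnoses
        glue("It is ")
        builder.entity(span_surface(_pick(rng, lex["Prior"]), "Prior"), "Prior")
        glue(" that this will declare itself. ")

    if rng.random() < 0.4:
        glue("A ")
        builder.entity(span_surface(_pick(rng, lex["DC"]), "DC"), "DC")
        glue(" process is considered. ")

    glue("Will continue to ")
    glue(_pick(rng, config.distractor_vocabulary))
    glue(" and reassess.")

    note = Note(
        note_id=note_id,
        text=builder.text,
        site=config.site,
        d_gold=d_target,
        ea_gold=ea_target,
    )
    annotated = AnnotatedNote(note=note, spans=builder.spans)
    annotated.validate()

    breakdown = d_score_from_entities(annotated.spans)
    if breakdown.d_score != d_target:
        raise AssertionError(
            f"generator/logic mismatch for {note_id}: built for D{d_target} "
            f"but logic says D{breakdown.d_score}"
        )
    if ea_score_from_spans(annotated) != ea_target:
        raise AssertionError(f"generator EA convention violated for {note_id}")
    return annotated


def ea_score_from_spans(annotated: AnnotatedNote) -> int:
    """Recompute the EA gold convention from spans.

    Sentences are the maximal inter-period segments of the text; a
    diagnosis is "supported" when one of its mentions shares a sentence
    with at least one Data span and at least one Link span. The EA
    score is the count of distinct supported diagnoses capped at 2.
    """
    from .rubric import normalize_dx

    text = annotated.note.text
    boundaries = [i for i, ch in enumerate(text) if ch == "."] + [len(text)]
    supported: set[str] = set()
    start = 0
    for stop in boundaries:
        in_sentence = [s for s in annotated.spans if start <= s.start < stop]
        has_data = any(s.etype == "Data" for s in in_sentence)
        has_link = any(s.etype == "Link" for s in in_sentence)
        if has_data and has_link:
            supported.update(
                normalize_dx(s.surface) for s in in_sentence if s.etype == "Dx"
            )
        start = stop + 1
    return min(len(supported), 2)


def joint_score_distribution(
    d_proportions: tuple[float, float, float],
    ea_proportions: tuple[float, float, float],
) -> np.ndarray:
    """Couple the D and EA marginals into a feasible 3x3 joint.

    Starts from the independent product and moves the infeasible
    (D0, EA2) mass to (D0, EA1), compensating by shifting equal mass
    from (D>=1, EA1) to (D>=1, EA2), so both configured marginals are
    preserved exactly. Raises :class:`ConfigError` when no such joint
    exists (the D>=1/EA1 cell cannot donate enough mass).
    """
    joint = np.outer(np.asarray(d_proportions), np.asarray(ea_proportions))
    excess = joint[0, 2]
    if excess > 0:
        donors = joint[1, 1] + joint[2, 1]
        if donors + 1e-12 < excess:
            raise ConfigError(
                "infeasible D/EA marginals: EA2 requires D>=1, and the "
                "configured proportions leave too little D>=1/EA1 mass "
                "to rebalance"
            )
        joint[0, 1] += excess
        joint[0, 2] = 0.0
        for row in (1, 2):
            shift = excess * joint[row, 1] / donors
            joint[row, 1] -= shift
            joint[row, 2] += shift
    return joint


def generate_corpus(config: GeneratorConfig) -> list[AnnotatedNote]:
    """Generate a corpus of annotated notes under the configured mix.

    (D, EA) targets are drawn from the coupled joint of the configured
    marginals; every note's gold labels are re-derived from its spans,
    so label/logic consistency holds corpus-wide. Same config and seed
    give a byte-identical corpus.
    """
    config.validate()
    joint = joint_score_distribution(config.d_proportions, config.ea_proportions)
    flat = joint.reshape(-1)
    flat = flat / flat.sum()
    rng = np.random.default_rng(config.seed)
    width = max(4, len(str(max(config.n_notes - 1, 0))))
    corpus: list[AnnotatedNote] = []
    for i in range(config.n_notes):
        cell = int(rng.choice(9, p=flat))
        d_target, ea_target = divmod(cell, 3)
        corpus.append(
            sample_note(
                d_target,
                ea_target,
                config,
                rng,
                note_id=f"{config.site}-{i:0{width}d}",
            )
        )
    return corpus


def easy_config(n_notes: int, seed: int = 0, **overrides) -> GeneratorConfig:
    """The clean benchmark regime: disjoint lexicons, zero noise."""
    return replace(GeneratorConfig(n_notes=n_notes, seed=seed), **overrides)


def hard_config(n_notes: int, seed: int = 0, noise: float = 0.08) -> GeneratorConfig:
    """Noisy regime: misspellings inside and outside entity surfaces."""
    return GeneratorConfig(
        n_notes=n_notes, seed=seed, noise=noise, noise_in_spans=True
    )
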