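import numpy as np
import pytest

from crscore.corpus import AnnotatedNote, EntitySpan, Note
from crscore.synthetic import easy_config, generate_corpus


@pytest.fixture(scope="session")
def easy_corpus():
    """A small clean synthetic corpus shared across read-only tests."""
    return generate_corpus(easy_config(120, seed=11))


@pytest.fixture(scope="session")
def benchmark_corpus():
    """The clean benchmark regime: n=600, zero noise, fixed seed."""
    return generate_corpus(easy_config(600, seed=0))


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def make_note(text, spans=(), note_id="n1", d_gold=None, ea_gold=None):
    return AnnotatedNote(
        note=Note(note_id=note_id, text=text, d_gold=d_gold, ea_gold=ea_gold),
        spans=sorted(spans, key=lambda s: s.start),
    )


def dx(start, end, text):
    return EntitySpan(start, end, "Dx", text[start:end])


def span_at(text, phrase, etype, occurrence=0):
    """Build a span for the nth occurrence of ``phrase`` in ``text``."""
    pos = -1
    for _ in range(occurrence + 1):
        pos = text.index(phrase, pos + 1)
    return EntitySpan(pos, pos + len(phrase), etype, phrase)
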