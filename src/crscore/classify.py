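"""One-vs-rest note classifiers for the D0, D2 and EA2 targets.

The multi-class D scale is decomposed into per-class binary models whose
thresholded decisions are recomposed by the ordered stepwise rule
(:func:`crscore.rubric.stepwise_d`); the EA scale is handled by a single
binary EA2-vs-rest model. Backends are registered by name behind one
contract — score each note in [0, 1] — so a transformer backend can be
slotted in without touching the surrounding machinery; the packaged
reference backend is a bag-of-words logistic regression.

Training supports the two imbalance counter-measures used with small
note sets: runtime text augmentation (synonym replacement, random
insertion, random swap, then random deletion) and random minority
oversampling with inverse-class-frequency draw weights.
"""

from __future__ import annotations

import json
import logging
import pickle
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Callable, Iterable, Sequence

import numpy as np
from sklearn.feature_extraction.text import CountVectorizer
from sklearn.linear_model import LogisticRegression

from .corpus import Note
from .lexicons import SYNONYMS

logger = logging.getLogger(__name__)

TARGETS = ("D0", "D2", "EA2")


@dataclass(frozen=True)
class AugmentParams:
    """Intensities of the four augmentation operations.

    Defaults follow the small-corpus training recipe: 15 words each of
    synonym replacement, random insertion and random swap, then random
    word deletion with 15% per-word probability. Counts are capped at
    the number of eligible words in the example.
    """

    n_synonym: int = 15
    n_insert: int = 15
    n_swap: int = 15
    p_delete: float = 0.15

    def __post_init__(self) -> None:
        if min(self.n_synonym, self.n_insert, self.n_swap) < 0:
            raise ValueError("augmentation counts must be nonnegative")
        if not 0.0 <= self.p_delete <= 1.0:
            raise ValueError("p_delete must lie in [0, 1]")

    @property
    def is_identity(self) -> bool:
        return (
            self.n_synonym == 0
            and self.n_insert == 0
            and self.n_swap == 0
            and self.p_delete == 0.0
        )


OFF = AugmentParams(0, 0, 0, 0.0)


@dataclass(frozen=True)
class Prediction:
    note_id: str
    score: float
    label: bool


def augment_text(
    text: str,
    params: AugmentParams,
    rng: np.random.Generator,
    synonyms: dict[str, tuple[str, ...]] | None = None,
) -> str:
    """Perturb one training example.

    Operations apply in a fixed order — synonym replacement, random
    insertion, random swap, per-word deletion — on whitespace tokens.
    Zero-intensity parameters return the input unchanged.
    """
    if params.is_identity or not text:
        return text
    synonyms = SYNONYMS if synonyms is None else synonyms
    words = text.split()
    if not words:
        return text

    # synonym replacement: n_synonym distinct positions with a known synonym
    eligible = [i for i, w in enumerate(words) if w.lower() in synonyms]
    n_rep = min(params.n_synonym, len(eligible))
    if n_rep:
        for i in rng.choice(len(eligible), size=n_rep, replace=False):
            pos = eligible[int(i)]
            options = synonyms[words[pos].lower()]
            words[pos] = str(options[int(rng.integers(0, len(options)))])

    # random insertion of synonym-vocabulary words
    insert_pool = [s for opts in synonyms.values() for s in opts]
    for _ in range(params.n_insert):
        where = int(rng.integers(0, len(words) + 1))
        words.insert(where, str(insert_pool[int(rng.integers(0, len(insert_pool)))]))

    # random swaps
    for _ in range(params.n_swap):
        if len(words) < 2:
            break
        i, j = rng.choice(len(words), size=2, replace=False)
        words[int(i)], words[int(j)] = words[int(j)], words[int(i)]

    # per-word deletion
    if params.p_delete > 0:
        keep = rng.random(len(words)) >= params.p_delete
        words = [w for w, k in zip(words, keep) if k]

    return " ".join(words)


def oversample_indices(
    labels: Sequence[Any], n_draws: int, seed: int | np.random.Generator = 0
) -> np.ndarray:
    """Draw indices with inverse-class-frequency weights.

    Each example's weight is proportional to 1/(count of its class), so
    expected per-class totals are equal — random minority oversampling.
    """
    labels = list(labels)
    if not labels:
        raise ValueError("labels must be non-empty")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    counts: dict[Any, int] = {}
    for lab in labels:
        counts[lab] = counts.get(lab, 0) + 1
    weights = np.array([1.0 / counts[lab] for lab in labels])
    weights /= weights.sum()
    return rng.choice(len(labels), size=n_draws, replace=True, p=weights)


def _f1_at(scores: np.ndarray, labels: np.ndarray, threshold: float) -> float:
    pred = scores >= threshold
    tp = int(np.sum(pred & labels))
    fp = int(np.sum(pred & ~labels))
    fn = int(np.sum(~pred & labels))
    denom = 2 * tp + fp + fn
    return 2 * tp / denom if denom else 0.0


def _youden_at(scores: np.ndarray, labels: np.ndarray, threshold: float) -> float:
    pred = scores >= threshold
    pos, neg = labels.sum(), (~labels).sum()
    sens = np.sum(pred & labels) / pos
    spec = np.sum(~pred & ~labels) / neg
    return float(sens + spec - 1.0)

_CRITERIA: dict[str, Callable[[np.ndarray, np.ndarray, float], float]] = {
    "f1": _f1_at,
    "youden": _youden_at,
}


def select_threshold(
    scores: Sequence[float], labels: Sequence[bool], criterion: str = "f1"
) -> float:
    """Pick the operating point maximizing ``criterion`` on validation data.

    Candidates are the unique observed scores; ties break toward the
    higher threshold. Raises ``ValueError`` when only one class is
    present (the criterion would be degenerate).
    """
    scores_arr = np.asarray(scores, dtype=float)
    labels_arr = np.asarray(labels, dtype=bool)
    if scores_arr.size == 0 or labels_arr.all() or (~labels_arr).all():
        raise ValueError("threshold selection needs both classes present")
    try:
        crit = _CRITERIA[criterion]
    except KeyError:
        raise ValueError(f"unknown criterion {criterion!r}") from None
    best_t, best_v = None, -np.inf
    for t in np.unique(scores_arr):
        v = crit(scores_arr, labels_arr, float(t))
        if v > best_v or (v == best_v):  # candidates ascend: ties -> higher t
            best_t, best_v = float(t), v
    assert best_t is not None
    return best_t


# --------------------------------------------------------------------------
# Backends


def _build_bow_logreg(hyper: dict[str, Any], seed: int):
    vectorizer = CountVectorizer(
        lowercase=True,
        ngram_range=tuple(hyper.get("ngram_range", (1, 2))),
        min_df=int(hyper.get("min_df", 1)),
    )
    estimator = LogisticRegression(
        C=float(hyper.get("C", 1.0)),
        max_iter=int(hyper.get("max_iter", 500)),
        random_state=seed,
    )
    return vectorizer, estimator


BACKENDS: dict[str, Callable[[dict[str, Any], int], tuple[Any, Any]]] = {
    "bow_logreg": _build_bow_logreg,
}


@dataclass
class ClassifierModel:
    """A trained one-vs-rest model plus its stored operating point."""

    target: str
    backend: str
    vectorizer: Any
    estimator: Any
    threshold: float = 0.5
    training_meta: dict[str, Any] = field(default_factory=dict)

    def scores(self, texts: Iterable[str]) -> np.ndarray:
        X = self.vectorizer.transform(list(texts))
        return self.estimator.predict_proba(X)[:, 1]


def _target_label(note: Note, target: str) -> bool:
    if target == "D0":
        gold = note.d_gold
        wanted = 0
    elif target == "D2":
        gold = note.d_gold
        wanted = 2
    elif target == "EA2":
        gold = note.ea_gold
        wanted = 2
    else:
        raise ValueError(f"unknown target {target!r}; expected one of {TARGETS}")
    if gold is None:
        raise ValueError(f"note {note.note_id!r} lacks the gold label for {target}")
    return gold == wanted


def train_ovr(
    corpus: Sequence[Note],
    target: str,
    hyper: dict[str, Any] | None = None,
    augment: AugmentParams | None = None,
    oversample: bool = False,
    seed: int = 0,
    backend: str = "bow_logreg",
) -> ClassifierModel:
    """Train a one-vs-rest classifier for D0, D2 or EA2.

    For EA2 the negative class aggregates EA0 and EA1. With
    ``oversample`` training draws use inverse-class-frequency weights;
    with ``augment`` each drawn example is perturbed at runtime. Fully
    deterministic given ``seed``.
    """
    hyper = hyper or {}
    labels = [_target_label(a.note if hasattr(a, "note") else a, target) for a in corpus]
    texts = [(a.note if hasattr(a, "note") else a).text for a in corpus]
    if all(labels) or not any(labels):
        raise ValueError(
            f"training corpus for {target} contains a single class; need both"
        )
    rng = np.random.default_rng(seed)

    if oversample:
        idx = oversample_indices(labels, n_draws=len(labels), seed=rng)
        texts = [texts[i] for i in idx]
        labels = [labels[i] for i in idx]

    if augment is not None and not augment.is_identity:
        texts = [augment_text(t, augment, rng) for t in texts]

    build = BACKENDS[backend]
    vectorizer, estimator = build(hyper, seed)
    X = vectorizer.fit_transform(texts)
    estimator.fit(X, np.asarray(labels))
    meta = {
        "seed": seed,
        "hyper": hyper,
        "augment": None if augment is None else vars(augment).copy(),
        "oversample": oversample,
        "n_train": len(texts),
    }
    return ClassifierModel(
        target=target,
        backend=backend,
        vectorizer=vectorizer,
        estimator=estimator,
        training_meta=meta,
    )


def predict(model: ClassifierModel, notes: Sequence[Note]) -> list[Prediction]:
    """Score notes and threshold with the model's stored operating point."""
    notes = [a.note if hasattr(a, "note") else a for a in notes]
    if not notes:
        return []
    scores = model.scores(n.text for n in notes)
    return [
        Prediction(note_id=n.note_id, score=float(s), label=bool(s >= model.threshold))
        for n, s in zip(notes, scores)
    ]


def stepwise_predict(
    d0_model: ClassifierModel, d2_model: ClassifierModel, notes: Sequence[Note]
) -> list[int]:
    """Full D pipeline: thresholded D0/D2 models composed stepwise."""
    from .rubric import stepwise_d

    p0 = predict(d0_model, notes)
    p2 = predict(d2_model, notes)
    return [stepwise_d(a.label, b.label) for a, b in zip(p0, p2)]


def save_classifier(model: ClassifierModel, path: str | Path) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    meta = {
        "target": model.target,
        "backend": model.backend,
        "threshold": model.threshold,
        "training_meta": model.training_meta,
    }
    (path / "meta.json").write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")
    (path / "params.pkl").write_bytes(
        pickle.dumps({"vectorizer": model.vectorizer, "estimator": model.estimator}, 4)
    )


def load_classifier(path: str | Path) -> ClassifierModel:
    path = Path(path)
    meta = json.loads((path / "meta.json").read_text())
    payload = pickle.loads((path / "params.pkl").read_bytes())
    return ClassifierModel(
        target=meta["target"],
        backend=meta["backend"],
        vectorizer=payload["vectorizer"],
        estimator=payload["estimator"],
        threshold=float(meta["threshold"]),
        training_meta=meta.get("training_meta", {}),
    )
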