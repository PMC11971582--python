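"""Metric suite: Type-match NER scoring, ranking metrics, CV, ICC.

NER predictions are scored in "Type" mode: a predicted span is credited
when its entity type equals a gold span's type and their character
intervals overlap by at least one character, with a one-to-one
assignment between gold and predicted spans. The assignment maximizes
the number of matched pairs (ties resolved toward larger total overlap,
then earlier gold start), so the reported correct/spurious/missing
counts agree with an exhaustive maximum-matching oracle.

Ranking metrics (AUROC, AUPRC) delegate to scikit-learn, with explicit
errors for the degenerate single-class cases; the intraclass
correlation is the two-way mixed-effects, consistency, single-rater
form computed from the two-way ANOVA decomposition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.model_selection import KFold, StratifiedKFold

from .corpus import ENTITY_TYPES, AnnotatedNote, EntitySpan

import logging

logger = logging.getLogger(__name__)


class UndefinedMetricError(ValueError):
    """The requested metric is undefined for the given inputs."""


# --------------------------------------------------------------------------
# Type-mode span matching


@dataclass
class MatchResult:
    """Per-type correct/spurious/missing counts plus the matched pairs."""

    correct: dict[str, int]
    spurious: dict[str, int]
    missing: dict[str, int]
    pairs: list[tuple[EntitySpan, EntitySpan]] = field(default_factory=list)

    def __add__(self, other: "MatchResult") -> "MatchResult":
        def merge(a: dict[str, int], b: dict[str, int]) -> dict[str, int]:
            return {t: a.get(t, 0) + b.get(t, 0) for t in set(a) | set(b)}

        return MatchResult(
            correct=merge(self.correct, other.correct),
            spurious=merge(self.spurious, other.spurious),
            missing=merge(self.missing, other.missing),
            pairs=self.pairs + other.pairs,
        )


def _overlap(a: EntitySpan, b: EntitySpan) -> int:
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def match_type(
    gold: Sequence[EntitySpan], pred: Sequence[EntitySpan]
) -> MatchResult:
    """One-to-one Type matching between gold and predicted spans.

    A pair is matchable iff entity types are equal and the spans overlap
    by >=1 character. The assignment maximizes the matched-pair count,
    breaking ties toward larger total character overlap and then toward
    pairs earlier in gold order.
    """
    gold = sorted(gold, key=lambda s: (s.start, s.end))
    pred = sorted(pred, key=lambda s: (s.start, s.end))
    correct = {t: 0 for t in ENTITY_TYPES}
    spurious = dict.fromkeys(ENTITY_TYPES, 0)
    missing = dict.fromkeys(ENTITY_TYPES, 0)
    pairs: list[tuple[EntitySpan, EntitySpan]] = []

    if gold and pred:
        # Assignment profit: a large constant per admissible pair makes the
        # solver maximize match count first, overlap second, early-gold third.
        big = 10 ** 6
        eps = 1e-3
        profit = np.zeros((len(gold), len(pred)))
        for i, g in enumerate(gold):
            for j, p in enumerate(pred):
                if g.etype == p.etype:
                    ov = _overlap(g, p)
                    if ov > 0:
                        profit[i, j] = big + ov + eps * (len(gold) - i)
        rows, cols = optimize.linear_sum_assignment(profit, maximize=True)
        for i, j in zip(rows, cols):
            if profit[i, j] > 0:
                correct[gold[i].etype] += 1
                pairs.append((gold[i], pred[j]))

    matched_gold = {id(g) for g, _ in pairs}
    matched_pred = {id(p) for _, p in pairs}
    for g in gold:
        if id(g) not in matched_gold:
            missing[g.etype] = missing.get(g.etype, 0) + 1
    for p in pred:
        if id(p) not in matched_pred:
            spurious[p.etype] = spurious.get(p.etype, 0) + 1
    return MatchResult(correct=correct, spurious=spurious, missing=missing, pairs=pairs)


def ner_f1(results: Iterable[MatchResult]) -> pd.DataFrame:
    """Aggregate match counts to per-type and micro P/R/F1.

    Convention for a type with no gold and no predicted spans:
    P = R = F1 = 1.0 (vacuously perfect); the ``support`` column makes
    such types visible.
    """
    results = list(results)
    if not results:
        raise ValueError("ner_f1 needs at least one match result")
    total = results[0]
    for r in results[1:]:
        total = total + r

    rows = []
    types = sorted(set(total.correct) | set(total.spurious) | set(total.missing))
    sums = {"correct": 0, "spurious": 0, "missing": 0}
    for etype in types + ["micro"]:
        if etype == "micro":
            c, s, m = sums["correct"], sums["spurious"], sums["missing"]
        else:
            c = total.correct.get(etype, 0)
            s = total.spurious.get(etype, 0)
            m = total.missing.get(etype, 0)
            sums["correct"] += c
            sums["spurious"] += s
            sums["missing"] += m
        if c + s + m == 0:
            p = r = f1 = 1.0
        else:
            p = c / (c + s) if c + s else 0.0
            r = c / (c + m) if c + m else 0.0
            f1 = 2 * p * r / (p + r) if p + r else 0.0
        rows.append(
            {
                "etype": etype,
                "precision": p,
                "recall": r,
                "f1": f1,
                "support": c + m,
                "correct": c,
                "spurious": s,
                "missing": m,
            }
        )
    return pd.DataFrame(rows).set_index("etype")


def per_class_f1(gold: Sequence[int], pred: Sequence[int], classes=(0, 1, 2)) -> dict[int, float]:
    """One-vs-rest F1 for each class of an ordinal scale."""
    gold_arr = np.asarray(gold)
    pred_arr = np.asarray(pred)
    out: dict[int, float] = {}
    for c in classes:
        tp = int(np.sum((gold_arr == c) & (pred_arr == c)))
        fp = int(np.sum((gold_arr != c) & (pred_arr == c)))
        fn = int(np.sum((gold_arr == c) & (pred_arr != c)))
        denom = 2 * tp + fp + fn
        out[c] = 2 * tp / denom if denom else 1.0
    return out


# --------------------------------------------------------------------------
# Ranking metrics


def _check_binary(labels: np.ndarray) -> None:
    if labels.size == 0:
        raise UndefinedMetricError("empty label vector")


def auroc(scores: Sequence[float], labels: Sequence[bool]) -> float:
    """Area under the ROC curve.

    Equals the probability that a random positive outscores a random
    negative, with ties counted 1/2. Undefined for single-class labels.
    """
    labels_arr = np.asarray(labels, dtype=bool)
    _check_binary(labels_arr)
    if labels_arr.all() or not labels_arr.any():
        raise UndefinedMetricError("AUROC needs both classes present")
    return float(roc_auc_score(labels_arr, np.asarray(scores, dtype=float)))


def auprc(scores: Sequence[float], labels: Sequence[bool]) -> float:
    """Area under the precision-recall curve.

    Step-wise (average-precision) summation — precision at each recall
    step, no linear interpolation. Undefined with no positives.
    """
    labels_arr = np.asarray(labels, dtype=bool)
    _check_binary(labels_arr)
    if not labels_arr.any():
        raise UndefinedMetricError("AUPRC needs at least one positive")
    return float(average_precision_score(labels_arr, np.asarray(scores, dtype=float)))


def bootstrap_ci(
    metric: Callable[[np.ndarray, np.ndarray], float],
    scores: Sequence[float],
    labels: Sequence[bool],
    n_resamples: int = 2000,
    seed: int = 0,
    alpha: float = 0.05,
) -> tuple[float, float]:
    """Seeded percentile bootstrap CI for a score/label metric.

    Resamples in which the metric is undefined (single-class draws) are
    redrawn implicitly by being skipped.
    """
    scores_arr = np.asarray(scores, dtype=float)
    labels_arr = np.asarray(labels, dtype=bool)
    rng = np.random.default_rng(seed)
    values = []
    n = scores_arr.size
    for _ in range(n_resamples):
        idx = rng.integers(0, n, size=n)
        try:
            values.append(metric(scores_arr[idx], labels_arr[idx]))
        except UndefinedMetricError:
            continue
    if not values:
        raise UndefinedMetricError("metric undefined on every bootstrap resample")
    lo, hi = np.quantile(values, [alpha / 2, 1 - alpha / 2])
    return float(lo), float(hi)


# --------------------------------------------------------------------------
# Cross-validation


@dataclass(frozen=True)
class FoldAssignment:
    """A stratified k-fold partition, note_id -> fold index."""

    k: int
    assignment: dict[str, int]
    seed: int

    def fold_ids(self, fold: int) -> list[str]:
        return [nid for nid, f in self.assignment.items() if f == fold]


def stratified_kfold(
    labels: Mapping[str, Any], k: int, seed: int = 0
) -> FoldAssignment:
    """Stratified partition of note ids into k folds.

    Per-fold class counts differ from perfect stratification by at most
    one; deterministic given the seed. When k exceeds the smallest class
    count (e.g. leave-one-out), stratification is impossible and the
    split degrades to a plain shuffled k-fold with a warning.
    """
    ids = list(labels.keys())
    y = [labels[i] for i in ids]
    if k > len(ids):
        raise ValueError(f"k={k} exceeds corpus size {len(ids)}")
    if k < 2:
        raise ValueError("k must be at least 2")
    min_class = min(y.count(c) for c in set(y))
    if k > min_class:
        logger.warning(
            "k=%d exceeds smallest class count %d; using unstratified folds",
            k,
            min_class,
        )
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
    else:
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    assignment: dict[str, int] = {}
    for fold, (_, test_idx) in enumerate(splitter.split(np.zeros(len(ids)), y)):
        for i in test_idx:
            assignment[ids[int(i)]] = fold
    return FoldAssignment(k=k, assignment=assignment, seed=seed)


@dataclass
class EvalReport:
    """Per-fold metric values, their mean and a 95% CI across folds."""

    per_fold: pd.DataFrame
    mean: dict[str, float]
    ci: dict[str, tuple[float, float]]
    folds: FoldAssignment


def _fold_ci(values: np.ndarray) -> tuple[float, float]:
    k = values.size
    m = float(values.mean())
    if k < 2 or np.allclose(values, m):
        return m, m
    half = float(stats.t.ppf(0.975, k - 1) * values.std(ddof=1) / np.sqrt(k))
    return m - half, m + half


def cross_validate(
    corpus: Sequence[AnnotatedNote],
    k: int,
    trainer: Callable[[list[AnnotatedNote]], Any],
    metrics: Mapping[str, Callable[[Any, list[AnnotatedNote]], float]],
    seed: int = 0,
    stratify_by: str = "d_gold",
) -> EvalReport:
    """Leak-free stratified k-fold cross-validation.

    The trainer callable receives only the training folds; each metric
    callable receives the trained model and the held-out fold. Values
    are aggregated as mean with a t-interval across folds.
    """
    labels = {
        a.note.note_id: getattr(a.note, stratify_by, None) for a in corpus
    }
    folds = stratified_kfold(labels, k=k, seed=seed)
    by_id = {a.note.note_id: a for a in corpus}
    rows = []
    for fold in range(k):
        test_ids = set(folds.fold_ids(fold))
        train = [a for a in corpus if a.note.note_id not in test_ids]
        test = [by_id[nid] for nid in folds.fold_ids(fold)]
        model = trainer(train)
        row: dict[str, Any] = {"fold": fold, "n_test": len(test)}
        for name, fn in metrics.items():
            row[name] = fn(model, test)
        rows.append(row)
    per_fold = pd.DataFrame(rows).set_index("fold")
    metric_cols = [c for c in per_fold.columns if c != "n_test"]
    mean = {c: float(per_fold[c].mean()) for c in metric_cols}
    ci = {c: _fold_ci(per_fold[c].to_numpy(dtype=float)) for c in metric_cols}
    return EvalReport(per_fold=per_fold, mean=mean, ci=ci, folds=folds)


# --------------------------------------------------------------------------
# Inter-rater reliability


def icc_consistency(
    matrix: Sequence[Sequence[float]] | np.ndarray,
    absolute: bool = False,
    alpha: float = 0.05,
) -> tuple[float, float, float]:
    """Intraclass correlation from a complete subjects x raters matrix.

    Default is the two-way mixed-effects, consistency, single-rater
    form: (MS_subjects - MS_error) / (MS_subjects + (k-1) MS_error),
    with the CI from F-distribution bounds. ``absolute=True`` switches
    to the absolute-agreement single-rater variant. Raises
    :class:`UndefinedMetricError` when between-subject variance is zero.
    """
    data = np.asarray(matrix, dtype=float)
    if data.ndim != 2 or data.shape[0] < 2 or data.shape[1] < 2:
        raise ValueError("rating matrix must be at least 2 subjects x 2 raters")
    if np.isnan(data).any():
        raise ValueError("rating matrix must be complete (no missing cells)")
    n, k = data.shape
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_rows = k * float(((row_means - grand) ** 2).sum())
    ss_cols = n * float(((col_means - grand) ** 2).sum())
    ss_total = float(((data - grand) ** 2).sum())
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    if msr <= 0 or np.isclose(ss_rows, 0.0):
        raise UndefinedMetricError("zero between-subject variance; ICC undefined")

    if not absolute:
        est = (msr - mse) / (msr + (k - 1) * mse) if msr + (k - 1) * mse > 0 else 1.0
        if mse == 0:
            return 1.0, 1.0, 1.0
        f_obs = msr / mse
        df1, df2 = n - 1, (n - 1) * (k - 1)
        f_low = f_obs / stats.f.ppf(1 - alpha / 2, df1, df2)
        f_up = f_obs * stats.f.ppf(1 - alpha / 2, df2, df1)
        lo = (f_low - 1) / (f_low + k - 1)
        hi = (f_up - 1) / (f_up + k - 1)
        return float(est), float(lo), float(hi)

    # absolute agreement, single rater (two-way random ANOVA decomposition)
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    est = (msr - mse) / denom if denom > 0 else 1.0
    if mse == 0 and msc == mse:
        return 1.0, 1.0, 1.0
    a = k * est / (n * (1 - est)) if est < 1 else np.inf
    b = 1 + k * est * (n - 1) / (n * (1 - est)) if est < 1 else np.inf
    if not np.isfinite(a):
        return 1.0, 1.0, 1.0
    v = (a * msc + b * mse) ** 2 / (
        (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
    )
    f_star = stats.f.ppf(1 - alpha / 2, n - 1, v)
    f_star2 = stats.f.ppf(1 - alpha / 2, v, n - 1)
    lo = n * (msr - f_star * mse) / (
        f_star * (k * msc + (k * n - k - n) * mse) + n * msr
    )
    hi_num = n * (f_star2 * msr - mse)
    hi = hi_num / (k * msc + (k * n - k - n) * mse + n * f_star2 * msr)
    return float(est), float(lo), float(hi)


def rating_matrix(frame: pd.DataFrame) -> np.ndarray:
    """Pivot a long (subject_id, rater_id, score) table to a complete matrix."""
    wide = frame.pivot(index="subject_id", columns="rater_id", values="score")
    if wide.isna().any().any():
        raise ValueError("ratings are incomplete: every rater must score every subject")
    return wide.to_numpy(dtype=float)
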