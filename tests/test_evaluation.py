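"""Metric suite: Type matching vs an exhaustive oracle, ranking metrics
vs closed-form oracles, CV leakage guarantees, and ICC against a
hand-computed ANOVA decomposition (cross-checked with pingouin)."""

import numpy as np
import pandas as pd
import pytest

from crscore.classify import train_ovr, predict
from crscore.corpus import EntitySpan, Note, AnnotatedNote
from crscore.evaluation import (
    UndefinedMetricError,
    auprc,
    auroc,
    bootstrap_ci,
    cross_validate,
    icc_consistency,
    match_type,
    ner_f1,
    per_class_f1,
    rating_matrix,
    stratified_kfold,
)
from crscore.ner import oracle_recognizer, predict_entities
from crscore.rubric import d_score_from_entities


def _span(start, end, etype):
    return EntitySpan(start, end, etype, "x" * (end - start))


# --------------------------------------------------------------------------
# Type matching


def _oracle_max_matching(gold, pred):
    """Exhaustive per-type maximum bipartite matching size (recursion)."""

    def best(gs, used):
        if not gs:
            return 0
        g, rest = gs[0], gs[1:]
        out = best(rest, used)
        for j, p in enumerate(pred):
            if (
                j not in used
                and p.etype == g.etype
                and min(g.end, p.end) > max(g.start, p.start)
            ):
                out = max(out, 1 + best(rest, used | {j}))
        return out

    sizes = {}
    for etype in {s.etype for s in gold} | {s.etype for s in pred}:
        gs = [g for g in gold if g.etype == etype]
        sizes[etype] = best(gs, frozenset())
    return sizes


class TestMatchType:
    def test_identical_spans_all_correct(self):
        spans = [_span(0, 5, "Dx"), _span(10, 14, "Data")]
        result = match_type(spans, spans)
        assert result.correct["Dx"] == 1 and result.correct["Data"] == 1
        assert sum(result.spurious.values()) == sum(result.missing.values()) == 0

    def test_partial_overlap_same_type_matches(self):
        assert match_type([_span(15, 30, "Dx")], [_span(10, 20, "Dx")]).correct["Dx"] == 1

    def test_type_mismatch_is_spurious_plus_missing(self):
        result = match_type([_span(10, 20, "Dx")], [_span(10, 20, "DC")])
        assert result.correct["Dx"] == 0
        assert result.missing["Dx"] == 1
        assert result.spurious["DC"] == 1

    def test_adjacent_spans_do_not_match(self):
        result = match_type([_span(0, 5, "Dx")], [_span(5, 9, "Dx")])
        assert result.correct["Dx"] == 0

    def test_matching_is_one_to_one(self):
        # two predictions overlap one gold: only one may match
        result = match_type([_span(0, 10, "Dx")], [_span(0, 4, "Dx"), _span(5, 10, "Dx")])
        assert result.correct["Dx"] == 1
        assert result.spurious["Dx"] == 1

    def test_crossing_overlaps_resolved_to_maximum(self):
        # greedy largest-overlap-first would strand the second gold span
        gold = [_span(0, 10, "Dx"), _span(5, 6, "Dx")]
        pred = [_span(0, 10, "Dx"), _span(9, 11, "Dx")]
        result = match_type(gold, pred)
        assert result.correct["Dx"] == 2

    def test_counts_agree_with_exhaustive_oracle_on_random_sets(self):
        rng = np.random.default_rng(5)
        types = ["Dx", "DC", "Prior", "Data", "Link"]
        for _ in range(200):
            def random_spans():
                spans = []
                for _ in range(int(rng.integers(0, 7))):
                    start = int(rng.integers(0, 40))
                    end = start + int(rng.integers(1, 8))
                    spans.append(_span(start, end, types[int(rng.integers(0, 5))]))
                return spans

            gold, pred = random_spans(), random_spans()
            result = match_type(gold, pred)
            oracle = _oracle_max_matching(gold, pred)
            for etype, size in oracle.items():
                assert result.correct.get(etype, 0) == size
                n_gold = sum(1 for g in gold if g.etype == etype)
                n_pred = sum(1 for p in pred if p.etype == etype)
                assert result.missing.get(etype, 0) == n_gold - size
                assert result.spurious.get(etype, 0) == n_pred - size


class TestNerF1:
    def test_hand_computed_counts(self):
        result = match_type(
            [_span(0, 5, "Dx"), _span(10, 15, "Dx")],
            [_span(0, 5, "Dx"), _span(10, 15, "Dx"), _span(20, 25, "Dx")],
        )
        frame = ner_f1([result])
        row = frame.loc["Dx"]
        assert row["precision"] == pytest.approx(2 / 3)
        assert row["recall"] == pytest.approx(1.0)
        assert row["f1"] == pytest.approx(0.8)

    def test_vacuous_type_scores_one_with_zero_support(self):
        frame = ner_f1([match_type([], [])])
        assert (frame["f1"] == 1.0).all()
        assert (frame["support"] == 0).all()

    def test_no_predictions_gives_zero_recall(self):
        frame = ner_f1([match_type([_span(0, 3, "Dx")], [])])
        assert frame.loc["Dx", "recall"] == 0.0
        assert frame.loc["Dx", "f1"] == 0.0

    def test_f1_bounded_by_max_of_p_and_r(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            gold = [_span(int(s), int(s) + 3, "Dx") for s in rng.integers(0, 30, 4)]
            pred = [_span(int(s), int(s) + 3, "Dx") for s in rng.integers(0, 30, 4)]
            frame = ner_f1([match_type(gold, pred)])
            row = frame.loc["Dx"]
            assert row["f1"] <= max(row["precision"], row["recall"]) + 1e-12


# --------------------------------------------------------------------------
# Ranking metrics


def _pairs_auroc(scores, labels):
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestAuroc:
    def test_perfect_separation(self):
        assert auroc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0

    def test_all_ties_give_half(self):
        assert auroc([0.5] * 6, [0, 1, 0, 1, 0, 1]) == 0.5

    def test_matches_all_pairs_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            n = int(rng.integers(4, 50))
            scores = rng.random(n)
            labels = rng.random(n) < 0.4
            if labels.all() or not labels.any():
                labels[0] = not labels[0]
            assert auroc(scores, labels) == pytest.approx(
                _pairs_auroc(scores, labels), abs=1e-9
            )

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(4)
        scores = rng.random(40)
        labels = rng.random(40) < 0.5
        labels[0], labels[1] = True, False
        base = auroc(scores, labels)
        assert auroc(np.exp(5 * scores), labels) == pytest.approx(base, abs=1e-12)
        assert auroc(np.log(scores + 1e-9), labels) == pytest.approx(base, abs=1e-12)

    def test_single_class_undefined(self):
        with pytest.raises(UndefinedMetricError):
            auroc([0.1, 0.9], [1, 1])


class TestAuprc:
    def test_perfect_separation(self):
        assert auprc([0.1, 0.9], [0, 1]) == 1.0

    def test_single_positive_ranked_first(self):
        assert auprc([0.9, 0.2, 0.1], [1, 0, 0]) == 1.0

    def test_label_independent_scores_approach_positive_rate(self):
        rng = np.random.default_rng(6)
        n, rate = 10_000, 0.3
        scores = rng.random(n)
        labels = rng.random(n) < rate
        assert auprc(scores, labels) == pytest.approx(rate, abs=0.03)

    def test_no_positives_undefined(self):
        with pytest.raises(UndefinedMetricError):
            auprc([0.4, 0.6], [0, 0])


def test_bootstrap_ci_brackets_point_estimate():
    rng = np.random.default_rng(8)
    scores = rng.random(120)
    labels = scores + rng.normal(0, 0.3, 120) > 0.5
    point = auroc(scores, labels)
    lo, hi = bootstrap_ci(auroc, scores, labels, n_resamples=500, seed=1)
    assert lo <= point <= hi


# --------------------------------------------------------------------------
# Cross-validation


class TestStratifiedKfold:
    def test_balanced_two_class_split_is_exact(self):
        labels = {f"n{i}": i % 2 for i in range(100)}
        folds = stratified_kfold(labels, k=10, seed=0)
        for fold in range(10):
            ids = folds.fold_ids(fold)
            assert len(ids) == 10
            assert sum(labels[i] for i in ids) == 5

    def test_folds_partition_the_corpus(self):
        labels = {f"n{i}": i % 3 for i in range(47)}
        folds = stratified_kfold(labels, k=5, seed=2)
        all_ids = [i for f in range(5) for i in folds.fold_ids(f)]
        assert sorted(all_ids) == sorted(labels)

    def test_deterministic_given_seed(self):
        labels = {f"n{i}": i % 2 for i in range(30)}
        a = stratified_kfold(labels, k=3, seed=7)
        b = stratified_kfold(labels, k=3, seed=7)
        assert a.assignment == b.assignment

    def test_k_larger_than_corpus_rejected(self):
        with pytest.raises(ValueError):
            stratified_kfold({"a": 0, "b": 1}, k=3)


def _tiny_corpus(n=40, seed=0):
    from crscore.synthetic import easy_config, generate_corpus

    return generate_corpus(easy_config(n, seed=seed))


class TestCrossValidate:
    def test_oracle_pipeline_hits_the_ceiling(self):
        corpus = _tiny_corpus(40)

        def trainer(train):
            return oracle_recognizer(corpus)  # replay oracle: perfect by design

        def accuracy(model, test):
            pred = [
                d_score_from_entities(predict_entities(model, a.note.text)).d_score
                for a in test
            ]
            return float(np.mean([p == a.note.d_gold for p, a in zip(pred, test)]))

        report = cross_validate(corpus, k=4, trainer=trainer, metrics={"acc": accuracy})
        assert report.mean["acc"] == 1.0
        assert report.ci["acc"] == (1.0, 1.0)

    def test_trainer_never_sees_test_fold(self):
        corpus = _tiny_corpus(30)
        seen: list[set] = []

        def trainer(train):
            seen.append({a.note.note_id for a in train})
            return None

        def nil(model, test):
            return 0.0

        report = cross_validate(corpus, k=3, trainer=trainer, metrics={"m": nil})
        for fold in range(3):
            test_ids = set(report.folds.fold_ids(fold))
            assert seen[fold].isdisjoint(test_ids)
            assert seen[fold] | test_ids == {a.note.note_id for a in corpus}

    def test_blanking_test_fold_leaves_training_identical(self):
        corpus = _tiny_corpus(30)
        captured: list[list[str]] = []

        def trainer(train):
            captured.append([a.note.text for a in train])
            return None

        report = cross_validate(
            corpus, k=3, trainer=trainer, metrics={"m": lambda m, t: 0.0}
        )
        first = [list(x) for x in captured]
        # replacing each fold's held-out notes by blanks must leave the
        # training material untouched — i.e. no test-fold leakage
        for fold in range(3):
            test_ids = set(report.folds.fold_ids(fold))
            mutated = [
                (
                    AnnotatedNote(
                        note=Note(note_id=a.note.note_id, text="", d_gold=a.note.d_gold),
                        spans=[],
                    )
                    if a.note.note_id in test_ids
                    else a
                )
                for a in corpus
            ]
            train_texts = [
                a.note.text for a in mutated if a.note.note_id not in test_ids
            ]
            assert train_texts == first[fold]

    def test_leave_one_out_runs_on_tiny_corpus(self):
        corpus = _tiny_corpus(8)
        report = cross_validate(
            corpus,
            k=8,
            trainer=lambda train: None,
            metrics={"m": lambda model, test: float(len(test))},
        )
        assert report.mean["m"] == 1.0

    def test_shuffled_labels_give_null_auroc(self):
        corpus = _tiny_corpus(200, seed=3)
        rng = np.random.default_rng(0)
        shuffled = rng.permutation([a.note.d_gold for a in corpus])
        notes = [
            Note(note_id=a.note.note_id, text=a.note.text, d_gold=int(s))
            for a, s in zip(corpus, shuffled)
        ]
        corpus_shuffled = [AnnotatedNote(note=n, spans=[]) for n in notes]

        def trainer(train):
            return train_ovr([a.note for a in train], target="D0", seed=0)

        def fold_auroc(model, test):
            preds = predict(model, [a.note for a in test])
            return auroc([p.score for p in preds], [a.note.d_gold == 0 for a in test])

        report = cross_validate(
            corpus_shuffled, k=5, trainer=trainer, metrics={"auroc": fold_auroc}
        )
        values = report.per_fold["auroc"].to_numpy()
        se = values.std(ddof=1) / np.sqrt(len(values))
        assert abs(values.mean() - 0.5) <= max(3 * se, 0.1)


def test_per_class_f1_hand_case():
    gold = [0, 0, 1, 2, 2, 2]
    pred = [0, 1, 1, 2, 2, 0]
    scores = per_class_f1(gold, pred)
    assert scores[0] == pytest.approx(2 * 1 / (2 * 1 + 1 + 1))
    assert scores[1] == pytest.approx(2 * 1 / (2 * 1 + 1 + 0))
    assert scores[2] == pytest.approx(2 * 2 / (2 * 2 + 0 + 1))


# --------------------------------------------------------------------------
# ICC


TOY_MATRIX = [[1, 2], [2, 1], [3, 4], [4, 4]]
# Hand-derived two-way ANOVA for TOY_MATRIX: MS_subjects = 83/24,
# MS_error = 11/24, ICC(consistency, single) = 3 / (47/12) = 36/47.
TOY_ICC = 36 / 47


class TestIcc:
    def test_identical_raters_give_exactly_one(self):
        est, lo, hi = icc_consistency([[1, 1], [2, 2], [3, 3], [4, 4]])
        assert (est, lo, hi) == (1.0, 1.0, 1.0)

    def test_toy_matrix_matches_hand_computed_anova(self):
        est, lo, hi = icc_consistency(TOY_MATRIX)
        assert est == pytest.approx(TOY_ICC, abs=1e-9)
        assert lo <= est <= hi

    def test_constant_matrix_undefined(self):
        with pytest.raises(UndefinedMetricError):
            icc_consistency([[2, 2], [2, 2], [2, 2]])

    def test_matches_pingouin_consistency_and_agreement(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(12)
        subjects = rng.normal(0, 2, 12)
        data = np.column_stack(
            [subjects + rng.normal(0, 0.5, 12) for _ in range(3)]
        )
        long = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(12), 3),
                "rater": np.tile(np.arange(3), 12),
                "score": data.ravel(),
            }
        )
        table = pingouin.intraclass_corr(
            long, targets="subject", raters="rater", ratings="score"
        ).set_index("Type")
        ci_col = "CI95" if "CI95" in table.columns else "CI95%"
        est_c, lo_c, hi_c = icc_consistency(data)
        assert est_c == pytest.approx(table.loc["ICC(C,1)", "ICC"], abs=1e-9)
        assert (lo_c, hi_c) == pytest.approx(
            tuple(table.loc["ICC(C,1)", ci_col]), abs=0.006  # pingouin rounds to 2 dp
        )
        est_a, lo_a, hi_a = icc_consistency(data, absolute=True)
        assert est_a == pytest.approx(table.loc["ICC(A,1)", "ICC"], abs=1e-9)
        assert (lo_a, hi_a) == pytest.approx(
            tuple(table.loc["ICC(A,1)", ci_col]), abs=0.006
        )

    def test_rating_matrix_pivots_long_table(self):
        frame = pd.DataFrame(
            {
                "subject_id": ["a", "a", "b", "b"],
                "rater_id": ["r1", "r2", "r1", "r2"],
                "score": [1, 2, 3, 4],
            }
        )
        assert rating_matrix(frame).tolist() == [[1.0, 2.0], [3.0, 4.0]]

    def test_incomplete_ratings_rejected(self):
        frame = pd.DataFrame(
            {
                "subject_id": ["a", "b", "b"],
                "rater_id": ["r1", "r1", "r2"],
                "score": [1, 3, 4],
            }
        )
        with pytest.raises(ValueError, match="incomplete"):
            rating_matrix(frame)
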