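"""NNA, jackknife evaluation, metrics, IFS sweep and ROC/AUC."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import matthews_corrcoef, roc_auc_score

from pupsite import ifs_eval, mrmr
from pupsite.ifs_eval import ConfusionCounts


class TestNnaPredict:
    def test_exact_match_returns_its_label(self):
        X = np.array([[0.0, 0.0], [5.0, 5.0]])
        assert ifs_eval.nna_predict(X, [0, 1], [5.0, 5.0]) == 1

    def test_equidistant_tie_goes_to_lower_index(self):
        X = np.array([[1.0, 0.0], [-1.0, 0.0]])
        assert ifs_eval.nna_predict(X, [1, 0], [0.0, 0.0]) == 1
        assert ifs_eval.nna_predict(X, [0, 1], [0.0, 0.0]) == 0

    def test_matches_exhaustive_scan(self, rng):
        X = rng.normal(size=(10, 4))
        y = rng.integers(0, 2, 10)
        for _ in range(20):
            q = rng.normal(size=4)
            d = [np.sum((x - q) ** 2) for x in X]
            assert ifs_eval.nna_predict(X, y, q) == y[int(np.argmin(d))]

    def test_empty_training_set(self):
        with pytest.raises(ValueError):
            ifs_eval.nna_predict(np.zeros((0, 3)), [], np.zeros(3))

    def test_cosine_metric(self):
        X = np.array([[1.0, 0.0], [0.0, 1.0]])
        assert ifs_eval.nna_predict(X, [0, 1], [0.1, 2.0], metric="cosine") == 1


class TestJackknife:
    def test_separable_duplicates(self):
        X = np.array([[0.0], [0.0], [10.0], [10.0]])
        y = np.array([1, 1, 0, 0])
        counts = ifs_eval.jackknife_evaluate(X, y)
        assert (counts.tp, counts.tn, counts.fp, counts.fn) == (2, 2, 0, 0)

    def test_prediction_count_conservation(self, rng):
        X = rng.normal(size=(9, 3))
        y = np.array([1, 0, 1, 0, 1, 0, 0, 0, 1])
        counts = ifs_eval.jackknife_evaluate(X, y)
        assert counts.total == 9
        assert counts.tp + counts.fn == int(y.sum())
        assert counts.tn + counts.fp == int((1 - y).sum())

    def test_matches_explicit_loop(self, rng):
        X = rng.normal(size=(12, 5))
        y = rng.permutation([1] * 5 + [0] * 7)
        counts = ifs_eval.jackknife_evaluate(X, y)
        tp = fp = tn = fn = 0
        for i in range(12):
            others = [j for j in range(12) if j != i]
            d = [np.sum((X[j] - X[i]) ** 2) for j in others]
            pred = y[others[int(np.argmin(d))]]
            if y[i] == 1 and pred == 1:
                tp += 1
            elif y[i] == 1:
                fn += 1
            elif pred == 1:
                fp += 1
            else:
                tn += 1
        assert (counts.tp, counts.fp, counts.tn, counts.fn) == (tp, fp, tn, fn)

    def test_grouped_jackknife_leaves_out_whole_group(self):
        # two groups of duplicated points: per-sample jackknife is perfect,
        # group-level jackknife cannot lean on the within-group twin
        X = np.array([[0.0], [0.0], [10.0], [10.0], [5.0], [4.0]])
        y = np.array([1, 1, 0, 0, 1, 0])
        groups = np.array(["a", "a", "b", "b", "c", "d"])
        per_sample = ifs_eval.jackknife_evaluate(X, y)
        grouped = ifs_eval.jackknife_evaluate(X, y, groups=groups)
        assert per_sample.total == grouped.total == 6
        assert grouped != per_sample

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            ifs_eval.jackknife_evaluate(np.zeros((3, 1)), np.ones(3, int))


class TestMetrics:
    def test_perfect_counts(self):
        m = ifs_eval.metrics(ConfusionCounts(tp=3, fp=0, tn=5, fn=0))
        assert (m.sn, m.sp, m.ac, m.mcc) == (1.0, 1.0, 1.0, 1.0)

    def test_all_positive_predictions_mcc_zero(self):
        m = ifs_eval.metrics(ConfusionCounts(tp=5, fp=5, tn=0, fn=0))
        assert m.mcc == 0.0 and m.sn == 1.0 and m.sp == 0.0

    def test_hand_formula(self):
        c = ConfusionCounts(tp=99, fp=114, tn=435, fn=84)
        m = ifs_eval.metrics(c)
        assert m.sn == pytest.approx(99 / 183)
        assert m.sp == pytest.approx(435 / 549)
        assert m.ac == pytest.approx(534 / 732)
        denom = np.sqrt((99 + 114) * (99 + 84) * (435 + 114) * (435 + 84))
        assert m.mcc == pytest.approx((99 * 435 - 114 * 84) / denom)

    def test_agrees_with_sklearn_mcc(self, rng):
        for _ in range(25):
            y = rng.integers(0, 2, 30)
            p = rng.integers(0, 2, 30)
            m = ifs_eval.metrics(ifs_eval.confusion(y, p))
            assert m.mcc == pytest.approx(matthews_corrcoef(y, p), abs=1e-12)

    @given(st.tuples(*[st.integers(0, 20)] * 4))
    @settings(max_examples=100, deadline=None)
    def test_mcc_invariant_under_class_swap(self, counts):
        tp, fp, tn, fn = counts
        if tp + fp + tn + fn == 0:
            return
        m = ifs_eval.metrics(ConfusionCounts(tp, fp, tn, fn))
        swapped = ifs_eval.metrics(ConfusionCounts(tp=tn, fp=fn, tn=tp, fn=fp))
        assert m.mcc == pytest.approx(swapped.mcc)

    def test_empty_class_reported_missing(self):
        m = ifs_eval.metrics(ConfusionCounts(tp=0, fp=1, tn=3, fn=0))
        assert m.sn is None and m.sp is not None


class TestRunIfs:
    def test_full_prefix_matches_plain_jackknife(self, rng):
        X = rng.normal(size=(15, 6))
        y = rng.permutation([1] * 6 + [0] * 9)
        ranked = mrmr.RankedList(np.arange(1, 7), np.zeros(6), "MaxRel")
        curve = ifs_eval.run_ifs(X, y, ranked)
        assert len(curve) == 6
        full = ifs_eval.metrics(ifs_eval.jackknife_evaluate(X, y))
        last = curve.metric_sets[-1]
        assert (last.sn, last.sp, last.ac, last.mcc) == (full.sn, full.sp, full.ac, full.mcc)

    def test_every_prefix_matches_truncated_manual_evaluation(self, rng):
        X = rng.normal(size=(14, 5))
        y = rng.permutation([1] * 5 + [0] * 9)
        order = rng.permutation(5) + 1
        ranked = mrmr.RankedList(order, np.zeros(5), "mRMR-MID")
        curve = ifs_eval.run_ifs(X, y, ranked)
        for k in range(1, 6):
            manual = ifs_eval.metrics(
                ifs_eval.jackknife_evaluate(X[:, ranked.positions(k)], y)
            )
            got = curve.metric_sets[k - 1]
            assert (got.sn, got.sp, got.ac, got.mcc) == (
                manual.sn, manual.sp, manual.ac, manual.mcc,
            )

    def test_planted_signal_curve(self):
        # only the first 3 ranked features separate the classes
        rng = np.random.default_rng(5)
        n = 60
        y = rng.permutation([1] * 20 + [0] * 40)
        signal = y[:, None] * 4.0 + rng.normal(size=(n, 3)) * 0.3
        noise = rng.normal(size=(n, 12))
        X = np.hstack([signal, noise])
        ranked = mrmr.RankedList(np.arange(1, 16), np.zeros(15), "MaxRel")
        curve = ifs_eval.run_ifs(X, y, ranked)
        mccs = [m.mcc for m in curve.metric_sets]
        assert min(mccs[:3]) > 0.9  # non-degrading over the signal prefix
        k_opt, _ = ifs_eval.find_optimum(curve)
        assert k_opt <= 9  # optimum within a small multiple of the signal size


class TestFindOptimum:
    def test_increasing_curve_picks_last(self):
        sets = [ifs_eval.MetricSet(1, 1, 1, m) for m in (0.1, 0.2, 0.3)]
        curve = ifs_eval.IFSCurve(np.arange(1, 4), sets)
        assert ifs_eval.find_optimum(curve)[0] == 3

    def test_plateau_picks_smallest(self):
        sets = [ifs_eval.MetricSet(1, 1, 1, m) for m in (0.1, 0.5, 0.5, 0.2)]
        curve = ifs_eval.IFSCurve(np.arange(1, 5), sets)
        assert ifs_eval.find_optimum(curve)[0] == 2

    def test_matches_naive_scan(self, rng):
        mccs = rng.uniform(-1, 1, 30)
        sets = [ifs_eval.MetricSet(1, 1, 1, m) for m in mccs]
        curve = ifs_eval.IFSCurve(np.arange(1, 31), sets)
        k, best = ifs_eval.find_optimum(curve)
        assert best.mcc == max(mccs) and k == int(np.argmax(mccs)) + 1


class TestRocAuc:
    def test_perfect_separation(self):
        assert ifs_eval.roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_null_scores_near_half(self):
        rng = np.random.default_rng(3)
        y = rng.integers(0, 2, 4000)
        s = rng.normal(size=4000)
        assert abs(ifs_eval.roc_auc(s, y) - 0.5) < 0.05

    def test_pair_counting_oracle(self):
        scores = [0.1, 0.4, 0.35, 0.8, 0.65, 0.35, 0.9, 0.5]
        y = [0, 0, 1, 1, 0, 0, 1, 1]
        pos = [s for s, lab in zip(scores, y) if lab == 1]
        neg = [s for s, lab in zip(scores, y) if lab == 0]
        conc = sum(
            1.0 if p > q else (0.5 if p == q else 0.0) for p in pos for q in neg
        )
        expected = conc / (len(pos) * len(neg))
        assert ifs_eval.roc_auc(scores, y) == pytest.approx(expected)
        assert ifs_eval.roc_auc(scores, y) == pytest.approx(roc_auc_score(y, scores))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            ifs_eval.roc_auc([0.1, 0.2], [1, 1])


def test_nna_margin_scores_rank_separable_data(rng):
    X = np.vstack([rng.normal(5, 0.3, size=(6, 2)), rng.normal(0, 0.3, size=(10, 2))])
    y = np.array([1] * 6 + [0] * 10)
    scores = ifs_eval.nna_margin_scores(X, y)
    assert ifs_eval.roc_auc(scores, y) == 1.0
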