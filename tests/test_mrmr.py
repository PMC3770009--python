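"""Discretization, mutual information, MaxRel and mRMR ranking.

Brute-force oracles use sklearn's contingency-based MI estimator (converted
to bits) and plain greedy loops, independent of the vectorized implementation.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp
from sklearn.metrics import mutual_info_score

from pupsite import mrmr

LN2 = np.log(2.0)


def sk_mi(a, b) -> float:
    return mutual_info_score(a, b) / LN2


class TestDiscretize:
    def test_constant_column(self):
        X = np.ones((5, 1))
        assert np.all(mrmr.discretize(X).states == 1)

    def test_hand_computed_thresholds(self):
        # column (-10, 0, 10): mu=0, sigma=sqrt(200/3)~8.16 -> states 0,1,2
        X = np.array([[-10.0], [0.0], [10.0]])
        np.testing.assert_array_equal(mrmr.discretize(X).states.ravel(), [0, 1, 2])

    def test_unbalanced_onehot_two_states(self):
        # p=0.25: mu-sigma < 0 and mu+sigma < 1, so 0 -> 1 and 1 -> 2
        X = np.array([[0.0], [0.0], [0.0], [1.0]])
        states = mrmr.discretize(X).states.ravel()
        assert set(states) == {1, 2}

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            mrmr.discretize(np.array([[1.0], [np.nan]]))

    @given(
        hnp.arrays(
            float,
            st.tuples(st.integers(2, 12), st.integers(1, 5)),
            elements=st.floats(-50, 50),
        )
    )
    @settings(max_examples=60, deadline=None)
    def test_states_in_range(self, X):
        states = mrmr.discretize(X).states
        assert states.shape == X.shape
        assert set(np.unique(states)) <= {0, 1, 2}


class TestMutualInformation:
    def test_identical_two_equiprobable_states(self):
        a = np.array([0, 1, 0, 1])
        assert mrmr.mutual_information(a, a) == pytest.approx(1.0)

    def test_constant_gives_zero(self):
        assert mrmr.mutual_information([1, 1, 1], [0, 1, 2]) == pytest.approx(0.0)

    def test_hand_computed_joint(self):
        # joint table ((2,1),(1,2)) over 6 samples
        a = [0, 0, 0, 1, 1, 1]
        b = [0, 0, 1, 0, 1, 1]
        # two cells of count 2 and two of count 1; all marginals are 1/2
        expected = 2 * (2 / 6) * np.log2((2 / 6) / (0.5 * 0.5)) + 2 * (1 / 6) * np.log2(
            (1 / 6) / (0.5 * 0.5)
        )
        assert mrmr.mutual_information(a, b) == pytest.approx(expected)
        assert mrmr.mutual_information(a, b) == pytest.approx(sk_mi(a, b))

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            mrmr.mutual_information([0, 1], [0, 1, 2])

    @given(
        st.integers(2, 40).flatmap(
            lambda n: st.tuples(
                hnp.arrays(int, n, elements=st.integers(0, 2)),
                hnp.arrays(int, n, elements=st.integers(0, 2)),
            )
        )
    )
    @settings(max_examples=80, deadline=None)
    def test_symmetric_and_nonnegative(self, ab):
        a, b = ab
        mab = mrmr.mutual_information(a, b)
        assert mab >= -1e-12
        assert abs(mab - mrmr.mutual_information(b, a)) < 1e-12
        assert mab == pytest.approx(sk_mi(a, b), abs=1e-10)


def brute_maxrel(states, y):
    mis = [sk_mi(states[:, j], y) for j in range(states.shape[1])]
    order = sorted(range(len(mis)), key=lambda j: (-mis[j], j))
    return [j + 1 for j in order]


def brute_mrmr(states, y):
    f = states.shape[1]
    rel = [sk_mi(states[:, j], y) for j in range(f)]
    selected = []
    remaining = list(range(f))
    while remaining:
        best_j, best_c = None, -np.inf
        for j in remaining:
            red = (
                np.mean([sk_mi(states[:, j], states[:, s]) for s in selected])
                if selected
                else 0.0
            )
            c = rel[j] - red
            if c > best_c + 1e-12:
                best_j, best_c = j, c
        selected.append(best_j)
        remaining.remove(best_j)
    return [j + 1 for j in selected]


class TestMaxRel:
    def test_label_copy_ranks_first(self, rng):
        y = rng.integers(0, 2, 40)
        X = np.column_stack([rng.integers(0, 3, 40), y, rng.integers(0, 3, 40)])
        ranked = mrmr.maxrel_rank(mrmr.DiscretizedMatrix(X), y)
        assert ranked.order[0] == 2
        assert np.all(np.diff(ranked.scores) <= 1e-12)  # non-increasing scores

    def test_column_permutation_equivariance(self, rng):
        y = rng.integers(0, 2, 30)
        X = rng.integers(0, 3, (30, 6))
        ranked = mrmr.maxrel_rank(mrmr.DiscretizedMatrix(X), y)
        perm = np.array([3, 0, 5, 1, 4, 2])
        ranked_p = mrmr.maxrel_rank(mrmr.DiscretizedMatrix(X[:, perm]), y)
        # feature originally at column perm[j] is now column j
        relabel = {int(old) + 1: j + 1 for j, old in enumerate(perm)}
        assert [relabel[int(i)] for i in ranked.order] == [int(i) for i in ranked_p.order]

    def test_brute_force_order(self, rng):
        y = rng.integers(0, 2, 35)
        X = rng.integers(0, 3, (35, 6))
        ranked = mrmr.maxrel_rank(mrmr.DiscretizedMatrix(X), y)
        assert list(ranked.order) == brute_maxrel(X, y)

    def test_degenerate_labels_rejected(self):
        with pytest.raises(ValueError):
            mrmr.maxrel_rank(mrmr.DiscretizedMatrix(np.zeros((4, 2), int)), np.ones(4, int))


class TestMrmr:
    def test_single_feature_equals_maxrel(self, rng):
        y = rng.integers(0, 2, 20)
        X = rng.integers(0, 3, (20, 1))
        a = mrmr.mrmr_rank(mrmr.DiscretizedMatrix(X), y)
        b = mrmr.maxrel_rank(mrmr.DiscretizedMatrix(X), y)
        assert list(a.order) == list(b.order)

    def test_duplicate_column_deferred(self, rng):
        y = rng.integers(0, 2, 60)
        informative = (y + rng.integers(0, 2, 60) * (rng.random(60) < 0.2)).clip(0, 2)
        weak = (y * (rng.random(60) < 0.6)).astype(int)
        X = np.column_stack([informative, informative, weak])
        ranked = mrmr.mrmr_rank(mrmr.DiscretizedMatrix(X), y)
        # the exact duplicate of the first pick is maximally redundant and
        # must not be chosen second while a non-redundant feature remains
        assert ranked.order[0] in (1, 2)
        assert ranked.order[1] == 3

    def test_first_element_matches_maxrel(self, rng):
        y = rng.integers(0, 2, 40)
        X = rng.integers(0, 3, (40, 8))
        assert (
            mrmr.mrmr_rank(mrmr.DiscretizedMatrix(X), y).order[0]
            == mrmr.maxrel_rank(mrmr.DiscretizedMatrix(X), y).order[0]
        )

    def test_brute_force_full_order(self, rng):
        y = rng.integers(0, 2, 30)
        X = rng.integers(0, 3, (30, 8))
        ranked = mrmr.mrmr_rank(mrmr.DiscretizedMatrix(X), y)
        assert list(ranked.order) == brute_mrmr(X, y)

    def test_null_top_score_concentrates_near_zero(self):
        # independent features: best MaxRel MI shrinks as n grows
        rng = np.random.default_rng(7)
        tops = []
        for n in (50, 2000):
            y = rng.integers(0, 2, n)
            X = rng.integers(0, 3, (n, 20))
            tops.append(mrmr.maxrel_rank(mrmr.DiscretizedMatrix(X), y).scores[0])
        assert tops[1] < tops[0]
        assert tops[1] < 0.01


def test_ranked_list_tsv_round_trip(tmp_path, rng):
    ranked = mrmr.RankedList(
        order=np.array([3, 1, 2]), scores=np.array([0.5, 0.25, 0.1]), criterion="mRMR-MID"
    )
    p = tmp_path / "ranked.tsv"
    mrmr.write_ranked(ranked, p)
    back = mrmr.read_ranked(p)
    np.testing.assert_array_equal(back.order, ranked.order)
    np.testing.assert_allclose(back.scores, ranked.scores)
    assert back.criterion == "mRMR-MID"
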