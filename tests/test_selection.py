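"""Discretization, mutual information, MaxRel/mRMR and the IFS sweep."""

import collections
import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from triadnet.classify import KNNConfig, cross_validate, metrics
from triadnet.selection import (DiscretizationRule, discretize, discretize_matrix,
                                ifs, maxrel_rank, mrmr_rank, mutual_information)

from conftest import make_feature_matrix


def mi_oracle(x, y):
    """Plug-in MI in bits from explicit cell counts (independent coding)."""
    n = len(x)
    joint = collections.Counter(zip(x, y))
    px = collections.Counter(x)
    py = collections.Counter(y)
    total = 0.0
    for (a, b), c in joint.items():
        p_ab = c / n
        total += p_ab * math.log2(p_ab / (px[a] / n * py[b] / n))
    return total


def mrmr_oracle(dX, y, n_select):
    """Independent greedy-MID ordering; quadratic and unoptimized."""
    n_features = dX.shape[1]
    rel = [mi_oracle(dX[:, j], y) for j in range(n_features)]
    selected = []
    for _ in range(n_select):
        best, best_score = None, -math.inf
        for j in range(n_features):
            if j in selected:
                continue
            if selected:
                red = sum(mi_oracle(dX[:, j], dX[:, s]) for s in selected) / len(selected)
            else:
                red = 0.0
            score = rel[j] - red
            if score > best_score + 1e-12:
                best, best_score = j, score
        selected.append(best)
    return selected


class TestDiscretize:
    def test_constant_vector_all_zero(self):
        np.testing.assert_array_equal(discretize(np.full(5, 3.3)), 0)

    def test_three_levels(self):
        out = discretize(np.array([-10.0, 0.0, 10.0]), DiscretizationRule(t=0.5))
        np.testing.assert_array_equal(out, [-1, 0, 1])

    def test_idempotent_mapping(self):
        rng = np.random.default_rng(0)
        v = rng.normal(size=100)
        np.testing.assert_array_equal(discretize(v), discretize(v))

    def test_monotone(self):
        rng = np.random.default_rng(1)
        v = np.sort(rng.normal(size=50))
        assert np.all(np.diff(discretize(v)) >= 0)


class TestMutualInformation:
    def test_independent_is_zero(self):
        assert mutual_information([0, 0, 1, 1], [0, 1, 0, 1]) == pytest.approx(0.0)

    def test_identical_balanced_binary_is_one_bit(self):
        assert mutual_information([0, 0, 1, 1], [0, 0, 1, 1]) == pytest.approx(1.0)

    def test_worked_joint_table(self):
        # joint counts {(0,0):2, (0,1):1, (1,0):1, (1,1):4}
        x = [0, 0, 0, 1, 1, 1, 1, 1]
        y = [0, 0, 1, 0, 1, 1, 1, 1]
        assert mutual_information(x, y) == pytest.approx(mi_oracle(x, y))
        assert mutual_information(x, y) == pytest.approx(0.1588684, abs=1e-6)

    def test_length_mismatch_error(self):
        with pytest.raises(ValueError):
            mutual_information([0, 1], [0, 1, 2])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.integers(2, 40), st.integers(0, 10_000))
    def test_properties_on_random_vectors(self, n, seed):
        rng = np.random.default_rng(seed)
        x = rng.integers(0, 3, size=n)
        y = rng.integers(0, 3, size=n)
        mi = mutual_information(x, y)
        assert mi >= -1e-12
        assert mi == pytest.approx(mutual_information(y, x))
        # MI with itself is the empirical entropy
        _, counts = np.unique(x, return_counts=True)
        p = counts / n
        assert mutual_information(x, x) == pytest.approx(-(p * np.log2(p)).sum())


class TestMaxRel:
    def test_label_copy_ranked_first(self):
        rng = np.random.default_rng(0)
        y = np.tile([0, 1], 50)
        X = rng.normal(size=(100, 5))
        X[:, 3] = y + rng.normal(0, 0.01, 100)
        m = make_feature_matrix(X, y)
        assert maxrel_rank(m).ordering[0] == "f3"

    def test_identical_informative_features_precede_noise(self):
        rng = np.random.default_rng(1)
        y = np.tile([0, 1], 50)
        X = rng.normal(size=(100, 4))
        X[:, 0] = y
        X[:, 1] = y
        order = maxrel_rank(make_feature_matrix(X, y)).ordering
        assert set(order[:2]) == {"f0", "f1"}

    def test_matches_per_feature_mi_oracle(self):
        rng = np.random.default_rng(2)
        y = rng.integers(0, 2, size=60)
        X = rng.normal(size=(60, 5)) + 0.5 * y[:, None] * rng.normal(size=5)
        m = make_feature_matrix(X, y)
        table = maxrel_rank(m)
        dX = discretize_matrix(X)
        expect = sorted(range(5), key=lambda j: (-mi_oracle(dX[:, j], y), j))
        assert table.ordering == [f"f{j}" for j in expect]
        assert np.all(np.diff(table.scores) <= 1e-12)  # nonincreasing


class TestMrmr:
    def test_first_pick_equals_maxrel_top(self):
        rng = np.random.default_rng(3)
        for seed in range(5):
            rng = np.random.default_rng(seed)
            y = rng.integers(0, 2, size=80)
            X = rng.normal(size=(80, 6)) + y[:, None] * rng.normal(size=6)
            m = make_feature_matrix(X, y)
            assert mrmr_rank(m).ordering[0] == maxrel_rank(m).ordering[0]

    def test_redundant_copy_demoted(self):
        # f0 near-copy of the label, f1 = copy of f0, f2 weakly informative
        # and independent; the oracle puts f2 ahead of the redundant f1
        rng = np.random.default_rng(4)
        y = np.tile([0, 1], 60)
        f0 = y.astype(float).copy()
        f0[0] = 1.0 - f0[0]  # one flipped sample
        f2 = y + rng.normal(0, 2.0, len(y))
        X = np.column_stack([f0, f0.copy(), f2])
        m = make_feature_matrix(X, y)
        got = mrmr_rank(m).ordering
        dX = discretize_matrix(X)
        expect = [f"f{j}" for j in mrmr_oracle(dX, y, 3)]
        assert got == expect == ["f0", "f2", "f1"]

    def test_full_selection_is_permutation(self):
        rng = np.random.default_rng(5)
        y = rng.integers(0, 2, size=40)
        X = rng.normal(size=(40, 7))
        order = mrmr_rank(make_feature_matrix(X, y)).ordering
        assert sorted(order) == sorted(f"f{j}" for j in range(7))

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_independent_greedy_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n, p = 60, int(rng.integers(3, 9))
        y = rng.integers(0, 2, size=n)
        X = rng.normal(size=(n, p)) + 0.8 * y[:, None] * rng.normal(size=p)
        X[:, 0] = X[:, 1] + rng.normal(0, 0.1, n)  # inject redundancy
        m = make_feature_matrix(X, y)
        got = mrmr_rank(m).ordering
        expect = [f"f{j}" for j in mrmr_oracle(discretize_matrix(X), y, p)]
        assert got == expect

    def test_constant_features_deferred_to_end(self):
        rng = np.random.default_rng(9)
        y = rng.integers(0, 2, size=50)
        X = rng.normal(size=(50, 4))
        X[:, 2] = 5.0  # constant
        order = mrmr_rank(make_feature_matrix(X, y)).ordering
        assert order[-1] == "f2"


class TestIFS:
    @staticmethod
    def _separable_matrix(seed=0, n=60, p=6):
        rng = np.random.default_rng(seed)
        y = np.tile([0, 1], n // 2)
        X = rng.normal(size=(n, p))
        X[:, 0] = 10 * y + rng.normal(0, 0.1, n)  # single separating feature
        return make_feature_matrix(X, y)

    def test_single_informative_feature_selected_alone(self):
        m = self._separable_matrix()
        table = maxrel_rank(m)
        assert table.ordering[0] == "f0"
        curve = ifs(m, table, KNNConfig(k=1), folds=5, seed=0)
        assert curve.selected_size == 1
        assert curve.points.loc[0, "MCC"] >= curve.points["MCC"].max() - 1e-12

    def test_curve_covers_every_prefix(self):
        m = self._separable_matrix(seed=1)
        curve = ifs(m, maxrel_rank(m), KNNConfig(k=1), folds=5, seed=0)
        assert list(curve.points["size"]) == list(range(1, 7))
        assert curve.selected_features == ["f0"]

    @pytest.mark.parametrize("prefix", [1, 3, 6])
    def test_agrees_with_standalone_cross_validation(self, prefix):
        # the incremental-distance fast path must reproduce plain CV
        # on every prefix
        m = self._separable_matrix(seed=2)
        table = maxrel_rank(m)
        curve = ifs(m, table, KNNConfig(k=3), folds=5, seed=4)
        sub = m.X[table.ordering[:prefix]].to_numpy()
        rep = metrics(cross_validate((sub, m.y), KNNConfig(k=3), folds=5, seed=4))
        row = curve.points.iloc[prefix - 1]
        assert row["MCC"] == pytest.approx(rep.mcc)
        assert row["ACC"] == pytest.approx(rep.acc)
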