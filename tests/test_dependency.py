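"""Rank pixelation, entropy, and the generalized-correlation test."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from openqct import (
    build_matrices,
    mesh_side,
    pair_dependency,
    rank_pixelate,
    shannon_entropy,
)
from openqct.dependency import MatrixPair, null_threshold, rank_bins
from openqct.exceptions import (
    DegenerateVariableError,
    InsufficientSamplesError,
    InvalidInputError,
    InvalidMatrixError,
)


class TestMeshSide:
    @pytest.mark.parametrize("m,b", [(100, 10), (4, 2), (101, 10), (99, 9), (10000, 100)])
    def test_floor_sqrt_rule(self, m, b):
        assert mesh_side(m) == b

    def test_too_few_samples(self):
        with pytest.raises(InsufficientSamplesError):
            mesh_side(3)


class TestShannonEntropy:
    def test_closed_forms(self):
        assert shannon_entropy([0.25] * 4) == pytest.approx(2.0, abs=1e-12)
        assert shannon_entropy([0.5, 0.5]) == pytest.approx(1.0, abs=1e-12)
        assert shannon_entropy([1.0]) == 0.0
        assert shannon_entropy([0.5, 0.5, 0.0]) == pytest.approx(1.0, abs=1e-12)

    def test_against_direct_summation(self):
        # independent oracle: plain loop over an enumerated distribution
        p = np.array([0.1, 0.2, 0.3, 0.15, 0.25])
        direct = -sum(pi * np.log2(pi) for pi in p)
        assert shannon_entropy(p) == pytest.approx(direct, abs=1e-12)

    def test_negative_probability_rejected(self):
        with pytest.raises(InvalidInputError):
            shannon_entropy([0.5, -0.1])

    @given(st.lists(st.floats(0.001, 1.0), min_size=1, max_size=20))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_bounded_by_log_support(self, weights):
        p = np.array(weights) / np.sum(weights)
        h = shannon_entropy(p)
        assert -1e-12 <= h <= np.log2(len(p)) + 1e-12


class TestRankPixelate:
    def test_identity_fills_diagonal(self):
        img = rank_pixelate(np.arange(1, 101), np.arange(1, 101))
        assert img.b == 10
        assert np.array_equal(np.diag(img.counts), np.full(10, 10))
        assert img.counts.sum() == 100
        assert np.array_equal(img.counts, np.diag(np.diag(img.counts)))

    def test_density_sums_to_one(self):
        rng = np.random.default_rng(0)
        img = rank_pixelate(rng.normal(size=60), rng.normal(size=60))
        assert img.density.sum() == pytest.approx(1.0, abs=1e-12)
        assert (img.density >= 0).all()

    @pytest.mark.parametrize("transform", [np.exp, lambda v: v ** 3,
                                           lambda v: 5 * v - 2, np.arctan])
    def test_monotone_transform_invariance(self, transform):
        rng = np.random.default_rng(3)
        x, y = rng.normal(size=100), rng.normal(size=100)
        base = rank_pixelate(x, y)
        moved = rank_pixelate(transform(x), y)
        assert np.array_equal(base.counts, moved.counts)

    def test_constant_axis_degenerate(self):
        with pytest.raises(DegenerateVariableError):
            rank_bins(np.ones(50), 7)

    def test_gap_rejected(self):
        x = np.arange(10.0)
        x[3] = np.nan
        with pytest.raises(InvalidInputError):
            rank_pixelate(x, np.arange(10.0))


class TestPairDependency:
    def test_identity_dependence(self):
        r = pair_dependency(np.arange(100.0), np.arange(100.0), rng_seed=0)
        assert r.mi == pytest.approx(np.log2(10), abs=1e-9)
        assert r.structured
        assert r.h_ij == pytest.approx(np.log2(10), abs=1e-9)
        assert r.h_i == pytest.approx(np.log2(10), abs=1e-9)

    def test_symmetry_bit_identical(self):
        rng = np.random.default_rng(11)
        x = rng.normal(size=100)
        y = 0.5 * x + rng.normal(size=100)
        a = pair_dependency(x, y, rng_seed=5)
        b = pair_dependency(y, x, rng_seed=5)
        assert a == b

    def test_constant_variable_unstructured(self):
        r = pair_dependency(np.arange(100.0), np.full(100, 3.14), rng_seed=0)
        assert not r.structured
        assert r.mi == 0.0 and r.h_j == 0.0

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=144)
        y = rng.normal(size=144) + 0.8 * x
        a = pair_dependency(x, y, rng_seed=9)
        b = pair_dependency(np.exp(x), y, rng_seed=9)
        assert a == b

    @given(st.integers(0, 10_000))
    @settings(deadline=None, max_examples=25, derandomize=True)
    def test_mi_non_negative_and_bounded(self, seed):
        rng = np.random.default_rng(seed)
        x, y = rng.normal(size=36), rng.normal(size=36)
        r = pair_dependency(x, y, n_surrogates=30, rng_seed=seed)
        assert r.mi >= -1e-9
        assert 0.0 <= r.h_ij <= 2 * np.log2(r.b) + 1e-9
        assert r.mi == pytest.approx(r.h_i + r.h_j - r.h_ij, abs=1e-12)

    def test_threshold_order_statistic(self):
        nulls = np.arange(200.0)  # 0..199
        # k = floor(0.05 * 201) = 10 -> 10th largest = 190
        assert null_threshold(nulls, 0.05) == 190.0
        with pytest.raises(InvalidInputError):
            null_threshold(np.arange(5.0), 0.05)


class TestBuildMatrices:
    def test_constructed_structure(self):
        rng = np.random.default_rng(21)
        x = rng.normal(size=100)
        z = rng.normal(size=100)
        data = np.column_stack([x, x.copy(), z])
        mp = build_matrices(data, variable_names=("a", "b", "c"), seed=3)
        assert mp.S[0, 1] == 1  # y = x pair
        assert mp.S[0, 2] == 0 and mp.S[1, 2] == 0
        assert np.array_equal(np.diag(mp.S), np.ones(3))

    def test_independent_columns_mostly_identity(self):
        rng = np.random.default_rng(8)
        data = rng.normal(size=(100, 2))
        mp = build_matrices(data, alpha=0.01, seed=2)
        assert np.array_equal(mp.S, np.eye(2))

    def test_identical_pair_all_ones(self):
        x = np.random.default_rng(5).normal(size=100)
        mp = build_matrices(np.column_stack([x, x]), seed=1)
        assert np.array_equal(mp.S, np.ones((2, 2)))

    def test_symmetry_and_diagonal_semantics(self):
        rng = np.random.default_rng(13)
        data = rng.normal(size=(120, 4))
        mp = build_matrices(data, seed=7)
        assert np.array_equal(mp.S, mp.S.T)
        np.testing.assert_allclose(mp.E, mp.E.T)
        # rank binning pins marginals at ~log2(b)
        b = mesh_side(120)
        np.testing.assert_allclose(np.diag(mp.E), np.log2(b), atol=0.05)

    def test_gapped_pair_uses_pairwise_complete_rows(self):
        rng = np.random.default_rng(17)
        x = rng.normal(size=100)
        data = np.column_stack([x, x + 0.1 * rng.normal(size=100),
                                rng.normal(size=100)])
        data[:20, 1] = np.nan  # 20% gap in column 1
        mp = build_matrices(data, variable_names=("a", "b", "c"), seed=5)
        assert mp.S[0, 1] == 1  # still detected on the 80 complete rows

    def test_fully_masked_variable_isolated(self):
        rng = np.random.default_rng(19)
        data = rng.normal(size=(100, 3))
        data[:, 2] = np.nan
        mp = build_matrices(data, variable_names=("a", "b", "c"), seed=5)
        assert mp.dropped == ("c",)
        assert mp.E[2, 2] == 0.0
        assert mp.S[2, :2].sum() == 0 and mp.S[2, 2] == 1

    def test_matrix_pair_validation(self):
        with pytest.raises(InvalidMatrixError):
            MatrixPair(S=np.array([[1.0, 2.0], [2.0, 1.0]]),
                       E=np.zeros((2, 2)), variable_names=("a", "b"))
        with pytest.raises(InvalidMatrixError):
            MatrixPair(S=np.eye(2), E=np.array([[np.nan, 0], [0, 0.0]]),
                       variable_names=("a", "b"))
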