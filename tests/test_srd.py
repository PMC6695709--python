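import itertools
import math

import numpy as np
import pytest

from dockfuse import (
    ScoreMatrix,
    build_reference,
    fuse_matrix,
    null_distribution,
    rank_transform,
    srd_analysis,
    srd_max,
    srd_value,
)
from dockfuse.srd import _null_dp, _null_enumeration

from conftest import random_negative_matrix


# --- rank transform ---------------------------------------------------------

def test_rank_transform_examples():
    np.testing.assert_array_equal(rank_transform([-10, -4, -7]), [1, 3, 2])
    np.testing.assert_array_equal(rank_transform([-5, -5, -1]), [1.5, 1.5, 3])
    np.testing.assert_array_equal(
        rank_transform([-5, -1], direction="higher_better"), [2, 1]
    )


def test_rank_transform_is_bijection_on_distinct_values(rng):
    for _ in range(20):
        v = rng.permutation(np.arange(10.0)) - 20
        ranks = rank_transform(v)
        assert sorted(ranks) == list(range(1, 11))
        assert ranks.sum() == 55


# --- minimax reference ------------------------------------------------------

def test_build_reference_minimax_rule():
    # column ranks: S1 -> B=1, X=2, A=3, Y=4 ; S2 -> A=1, Y=2, X=3, B=4
    m = ScoreMatrix(
        compound_ids=["A", "B", "X", "Y"],
        labels=[1, 0, 0, 1],
        structure_ids=["S1", "S2"],
        scores=[[-8.0, -12.0], [-11.0, -6.0], [-9.0, -8.0], [-7.0, -10.0]],
    )
    ref = build_reference(m)
    # active A: min(3, 1) = 1 ; inactive B: max(1, 4) = 4
    # inactive X: max(2, 3) = 3 ; active Y: min(4, 2) = 2
    np.testing.assert_array_equal(ref.values, [1, 4, 3, 2])
    assert ref.construction == "minimax"


def test_build_reference_identical_columns_degenerate(rng):
    col = -rng.uniform(2, 12, size=8)
    m = ScoreMatrix(
        compound_ids=[f"C{i}" for i in range(8)],
        labels=[1, 1, 0, 0, 0, 0, 0, 1],
        structure_ids=["S1", "S2", "S3"],
        scores=np.column_stack([col, col, col]),
    )
    np.testing.assert_array_equal(build_reference(m).values, rank_transform(col))


def test_build_reference_matches_loop_oracle(rng):
    m = random_negative_matrix(rng, n=20, k=4, n_act=6)
    ranks = np.column_stack(
        [rank_transform(m.scores[:, j]) for j in range(4)]
    )
    expected = [
        ranks[i].min() if m.labels[i] == 1 else ranks[i].max() for i in range(20)
    ]
    np.testing.assert_array_equal(build_reference(m).values, expected)


# --- SRD values and normalization -------------------------------------------

def test_srd_value_hand_cases():
    ref = np.array([1.0, 2.0, 3.0, 4.0])
    assert srd_value([1, 2, 3, 4], ref) == 0.0
    assert srd_value([4, 3, 2, 1], ref) == 8.0  # |3|+|1|+|1|+|3|
    assert srd_value([2, 1, 3, 4], ref) == 2.0
    assert 100 * srd_value([2, 1, 3, 4], ref) / srd_max(4) == pytest.approx(25.0)


def test_srd_value_length_mismatch():
    with pytest.raises(ValueError, match="mismatch"):
        srd_value([1, 2, 3], np.array([1.0, 2.0]))


@pytest.mark.parametrize("n, expected", [(2, 2), (4, 8), (5, 12)])
def test_srd_max_matches_exhaustive_enumeration(n, expected):
    ref = np.arange(1, n + 1)
    brute = max(
        int(np.abs(np.array(p) - ref).sum())
        for p in itertools.permutations(range(1, n + 1))
    )
    assert srd_max(n) == brute == expected


def test_srd_max_rejects_small_n():
    with pytest.raises(ValueError):
        srd_max(1)


def test_srd_value_even_integer_without_ties(rng):
    for _ in range(50):
        n = int(rng.integers(3, 15))
        method = rng.permutation(np.arange(1.0, n + 1))
        ref = rng.permutation(np.arange(1.0, n + 1))
        v = srd_value(method, ref)
        assert v == int(v) and int(v) % 2 == 0


def test_srd_invariant_under_standardization_and_monotone_maps(rng):
    for _ in range(20):
        method = -rng.uniform(0, 15, size=30)
        ref = -rng.uniform(0, 15, size=30)
        base = srd_value(method, ref)
        z = (method - method.mean()) / method.std()
        assert srd_value(z, ref) == base
        assert srd_value(np.exp(method / 5) * 3 - 1, ref) == base


# --- random-ranking null ----------------------------------------------------

def test_null_n3_exact():
    null = null_distribution(3, mode="exact")
    assert null.as_dict() == {0.0: pytest.approx(1 / 6), 2.0: pytest.approx(2 / 6), 4.0: pytest.approx(3 / 6)}


def test_null_exact_matches_enumeration_for_n4():
    null = null_distribution(4, mode="exact")
    ref = np.arange(1, 5)
    counts = {}
    for p in itertools.permutations(range(1, 5)):
        d = int(np.abs(np.array(p) - ref).sum())
        counts[d] = counts.get(d, 0) + 1
    assert set(null.values) <= set(range(0, 9, 2))
    for v, prob in null.as_dict().items():
        assert prob == pytest.approx(counts[int(v)] / 24)


@pytest.mark.parametrize("n", [4, 5, 6, 7, 8])
def test_null_dp_equals_enumeration(n):
    ev, ep = _null_enumeration(n)
    dv, dp = _null_dp(n)
    np.testing.assert_array_equal(ev, dv)
    np.testing.assert_allclose(ep, dp, atol=1e-15)


@pytest.mark.parametrize("n", [3, 6, 10, 12])
def test_null_probabilities_sum_to_one_and_mean_formula(n):
    null = null_distribution(n, mode="exact")
    assert null.probs.sum() == pytest.approx(1.0, abs=1e-9)
    # E sum|pi(i)-i| for a uniform permutation is (n^2 - 1) / 3
    assert null.mean == pytest.approx((n * n - 1) / 3)


def test_null_monte_carlo_close_to_exact_at_n8():
    exact = null_distribution(8, mode="exact")
    mc = null_distribution(8, mode="monte_carlo", n_samples=100_000, seed=5)
    grid = exact.values
    exact_cdf = exact.cdf()
    mc_cdf = np.array(
        [mc.probs[mc.values <= v].sum() for v in grid]
    )
    assert np.max(np.abs(exact_cdf - mc_cdf)) < 0.01


def test_null_mode_errors():
    with pytest.raises(ValueError, match="monte_carlo"):
        null_distribution(13, mode="exact")
    with pytest.raises(ValueError):
        null_distribution(1)


def test_null_percentile_is_smallest_value_reaching_mass():
    null = null_distribution(3, mode="exact")
    assert null.percentile(10) == 0.0   # CDF(0) = 1/6 >= 0.10
    assert null.percentile(50) == 2.0   # CDF(2) = 1/2 >= 0.50
    assert null.percentile(99) == 4.0


# --- full SRD analysis ------------------------------------------------------

def test_srd_analysis_identical_columns_gives_zero_everywhere(rng):
    """Every rule ranks like the common column, which is the reference."""
    col = -rng.uniform(2, 12, size=21)
    m = ScoreMatrix(
        compound_ids=[f"C{i}" for i in range(21)],
        labels=np.r_[np.ones(7, int), np.zeros(14, int)],
        structure_ids=["S1", "S2", "S3"],
        scores=np.column_stack([col, col, col]),
    )
    res = srd_analysis(fuse_matrix(m), m, k_folds=7, seed=3)
    np.testing.assert_allclose(res.srd_norm, 0.0, atol=1e-12)
    np.testing.assert_allclose(res.cv_values, 0.0, atol=1e-12)


def test_srd_reversed_reference_is_100():
    ref = np.arange(1.0, 11.0)
    assert 100 * srd_value(ref[::-1], ref) / srd_max(10) == pytest.approx(100.0)


def test_srd_analysis_structure_and_determinism(rng):
    m = random_negative_matrix(rng, n=40, k=4, n_act=12)
    fused = fuse_matrix(m)
    res1 = srd_analysis(fused, m, k_folds=5, seed=11, include_single_structures=True)
    res2 = srd_analysis(fused, m, k_folds=5, seed=11, include_single_structures=True)
    assert res1.method_names == list(fused.rules) + [f"struct:S{j}" for j in range(4)]
    assert res1.cv_values.shape == (11, 5)
    np.testing.assert_array_equal(res1.cv_values, res2.cv_values)
    np.testing.assert_array_equal(res1.srd_norm, res2.srd_norm)
    assert ((res1.srd_norm >= 0) & (res1.srd_norm <= 100)).all()
    assert ((res1.cv_values >= 0) & (res1.cv_values <= 100)).all()
    np.testing.assert_allclose(
        res1.srd_norm, 100 * res1.srd_raw / srd_max(40), rtol=1e-12
    )


def test_srd_analysis_validates_inputs(toy_matrix):
    fused = fuse_matrix(toy_matrix)
    with pytest.raises(ValueError, match="k_folds"):
        srd_analysis(fused, toy_matrix, k_folds=1)
    other = ScoreMatrix(
        compound_ids=["Z1", "Z2", "Z3", "Z4"],
        labels=toy_matrix.labels,
        structure_ids=toy_matrix.structure_ids,
        scores=toy_matrix.scores,
    )
    with pytest.raises(ValueError, match="aligned"):
        srd_analysis(fused, other)
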