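"""Sparse/low-rank Binomial surrogate: windows, blocks, fast mat-vec."""

import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, strategies as st

from fastwf import (
    MutationSelectionModel,
    RowProbabilities,
    assign_blocks,
    binomial_pmf_window,
    build_approx_matrix,
    exact_transpose_matvec,
    fast_transpose_matvec,
    hoeffding_halfwidth,
    moment_match_representatives,
    random_probability_vector,
    row_success_probabilities,
    sparsify_row,
)


def exact_binomial_pmf(N: int, p: Fraction):
    """Exact rational Binomial PMF, the independent small-N oracle."""
    return [
        Fraction(math.comb(N, k)) * p**k * (1 - p) ** (N - k) for k in range(N + 1)
    ]


class TestHoeffdingHalfwidth:
    def test_vacuous_tolerance(self):
        assert hoeffding_halfwidth(123, 2.0) == 0

    def test_numerical_precision_radius(self):
        # sqrt((10000/2) ln(2e16)) = 433.2 -> 434, i.e. about 4.33 sqrt(N)
        assert hoeffding_halfwidth(10_000, 1e-16) == 434

    def test_tiny_population(self):
        assert hoeffding_halfwidth(1, 0.5) == 1  # ceil(sqrt(0.5 ln 4)) = ceil(0.833)

    def test_tail_mass_outside_radius_is_bounded(self):
        from scipy import stats

        N, tol = 2000, 1e-6
        r = hoeffding_halfwidth(N, tol)
        for p in (0.05, 0.37, 0.5, 0.91):
            mean = N * p
            pmf = stats.binom.pmf(np.arange(N + 1), N, p)
            outside = pmf[np.abs(np.arange(N + 1) - mean) > r].sum()
            assert outside <= tol


class TestPmfWindow:
    def test_small_symmetric(self):
        np.testing.assert_allclose(binomial_pmf_window(2, 0.5, 0, 2), [0.25, 0.5, 0.25])

    def test_degenerate_p(self):
        np.testing.assert_array_equal(binomial_pmf_window(5, 0.0, 0, 5), [1, 0, 0, 0, 0, 0])

    @pytest.mark.parametrize("N,p", [(10, Fraction(3, 10)), (40, Fraction(1, 7))])
    def test_matches_exact_rational_oracle(self, N, p):
        window = binomial_pmf_window(N, float(p), 0, N)
        oracle = [float(x) for x in exact_binomial_pmf(N, p)]
        np.testing.assert_allclose(window, oracle, rtol=1e-12)

    def test_large_N_window_against_high_precision_spots(self):
        window = binomial_pmf_window(1000, 0.3, 250, 350)
        oracle = exact_binomial_pmf(1000, Fraction(3, 10))[250:351]
        np.testing.assert_allclose(window, [float(x) for x in oracle], rtol=1e-10)


class TestSparsifyRow:
    def test_radius_exceeding_population_keeps_everything(self):
        row = sparsify_row(2, 0.5, 1e-8)
        assert row.offset == 0
        np.testing.assert_allclose(row.mass, [0.25, 0.5, 0.25])

    def test_point_mass(self):
        row = sparsify_row(100, 0.0)
        assert row.offset == 0 and list(row.mass) == [1.0]

    def test_support_and_gap_at_N_1000(self):
        # r = ceil(sqrt(500 ln(2e8))) = 98 around mean 500
        row = sparsify_row(1000, 0.5, 1e-8)
        assert row.offset == 402 and len(row.mass) == 197
        from scipy import stats

        full = stats.binom.pmf(np.arange(1001), 1000, 0.5)
        gap = np.abs(row.expand(1000) - full).sum()
        assert gap <= 2e-8

    @given(
        N=st.integers(min_value=1, max_value=300),
        p=st.one_of(
            st.just(0.0), st.just(1.0), st.floats(min_value=1e-9, max_value=1 - 1e-9)
        ),
        tol=st.floats(min_value=1e-10, max_value=0.5),
    )
    def test_row_contract(self, N, p, tol):
        from scipy import stats

        row = sparsify_row(N, p, tol)
        assert row.offset >= 0 and row.offset + len(row.mass) - 1 <= N
        assert np.all(row.mass >= 0.0)
        assert abs(row.mass.sum() - 1.0) <= 1e-12
        full = stats.binom.pmf(np.arange(N + 1), N, p)
        assert np.abs(row.expand(N) - full).sum() <= 2 * tol / (1 - tol) + 1e-12


class TestBlockAssignment:
    def test_boundary_rows_are_singletons(self):
        part = assign_blocks(RowProbabilities(1, np.array([0.0, 1.0])), 1)
        assert part.n_blocks == 2

    def test_wide_spacing_gives_singletons(self):
        # spacing at p=0.2 is 0.1*sqrt(0.16/100) = 0.004 < 0.05 steps
        rows = RowProbabilities(3, np.array([0.2, 0.25, 0.3, 0.9]))
        part = assign_blocks(rows, 100, c_eps=0.1)
        assert part.n_blocks == 4

    def test_neutral_large_population_block_structure(self):
        N = 10_000
        rows = row_success_probabilities(N, MutationSelectionModel())
        part = assign_blocks(rows, N, c_eps=0.1)
        assert math.sqrt(N) < part.n_blocks < N + 1
        sizes = part.sizes
        interior = sizes[len(sizes) // 2]
        assert interior > sizes[1]  # blocks near p=0.5 are wider than near 0

    def test_block_count_scales_like_sqrt_N(self):
        counts = {}
        for N in (10_000, 40_000):
            rows = row_success_probabilities(N, MutationSelectionModel())
            counts[N] = assign_blocks(rows, N, c_eps=0.1).n_blocks
        ratio = counts[40_000] / counts[10_000]
        assert 1.7 <= ratio <= 2.3

    def test_block_count_bound(self):
        for N in (100, 1000, 10_000):
            rows = row_success_probabilities(N, MutationSelectionModel())
            assert assign_blocks(rows, N).n_blocks <= 40 * math.sqrt(N) + 2

    def test_within_block_spacing_invariant(self):
        N = 2000
        rows = row_success_probabilities(N, MutationSelectionModel(mu_fwd=1e-8))
        part = assign_blocks(rows, N, c_eps=0.1)
        for (first, last), anchor in zip(part.boundaries, part.anchor_ps):
            width = rows.ps[last] - anchor
            assert width <= 0.1 * math.sqrt(anchor * (1 - anchor) / N) + 1e-15


class TestMomentMatching:
    def test_weighted_mean(self):
        rows = RowProbabilities(1, np.array([0.1, 0.2]))
        part = assign_blocks(rows, 10, c_eps=10.0)  # huge spacing: one block
        assert part.n_blocks == 1
        rep = moment_match_representatives(part, rows, np.array([1.0, 3.0]))
        assert rep[0] == pytest.approx(0.175)

    def test_zero_weight_falls_back_to_anchor(self):
        rows = RowProbabilities(1, np.array([0.4, 0.5]))
        part = assign_blocks(rows, 10, c_eps=10.0)
        rep = moment_match_representatives(part, rows, np.array([0.0, 0.0]))
        assert rep[0] == 0.4

    def test_singleton_block_keeps_own_probability(self):
        rows = RowProbabilities(0, np.array([0.7]))
        part = assign_blocks(rows, 100)
        rep = moment_match_representatives(part, rows, np.array([5.0]))
        assert rep[0] == 0.7

    @given(v=st.lists(st.floats(min_value=0.0, max_value=10.0), min_size=4, max_size=4))
    def test_representative_stays_in_block_range(self, v):
        rows = RowProbabilities(3, np.array([0.30, 0.31, 0.32, 0.33]))
        part = assign_blocks(rows, 50, c_eps=1.0)
        rep = moment_match_representatives(part, rows, np.array(v))
        for (first, last), r in zip(part.boundaries, rep):
            assert rows.ps[first] <= r <= rows.ps[last]


class TestFastMatvec:
    def test_identity_rows(self):
        rows = RowProbabilities(1, np.array([0.0, 1.0]))
        matrix = build_approx_matrix(rows, 1, np.array([0.3, 0.7]))
        np.testing.assert_allclose(fast_transpose_matvec(matrix, np.array([0.3, 0.7])), [0.3, 0.7])

    def test_single_binomial_row(self):
        rows = row_success_probabilities(2, MutationSelectionModel())
        v = np.array([0.0, 1.0, 0.0])
        matrix = build_approx_matrix(rows, 2, v)
        np.testing.assert_allclose(fast_transpose_matvec(matrix, v), [0.25, 0.5, 0.25], atol=1e-15)

    def test_tiny_population_surrogate_is_exact(self):
        rows = row_success_probabilities(2, MutationSelectionModel())
        v = np.array([0.2, 0.5, 0.3])
        matrix = build_approx_matrix(rows, 2, v)
        assert matrix.partition.n_blocks == 3
        np.testing.assert_allclose(
            fast_transpose_matvec(matrix, v), exact_transpose_matvec(rows, 2, v), atol=1e-14
        )

    def test_rectangular_growth_supports_stay_in_range(self):
        rows = row_success_probabilities(100, MutationSelectionModel(mu_fwd=1e-8))
        matrix = build_approx_matrix(rows, 300, np.full(101, 1 / 101))
        for row in matrix.rep_rows:
            assert row.offset >= 0
            assert row.offset + len(row.mass) - 1 <= 300

    def test_max_row_l1_error_within_budget(self):
        from scipy import stats

        N = 200
        rows = row_success_probabilities(N, MutationSelectionModel(mu_fwd=1.25e-8))
        matrix = build_approx_matrix(rows, N, np.full(N + 1, 1 / (N + 1)))
        block_of = matrix.partition.state_to_block()
        worst = 0.0
        reps = matrix.rep_rows
        for i in range(N + 1):
            surrogate = reps[block_of[i]].expand(N)
            exact_row = stats.binom.pmf(np.arange(N + 1), N, rows.ps[i])
            worst = max(worst, np.abs(surrogate - exact_row).sum())
        assert worst <= 0.05

    def test_seeded_vector_close_to_dense_oracle(self):
        N = 500
        rows = row_success_probabilities(N, MutationSelectionModel(mu_fwd=1.25e-8))
        v = random_probability_vector(N, 7).mass
        matrix = build_approx_matrix(rows, N, v)
        gap = np.abs(fast_transpose_matvec(matrix, v) - exact_transpose_matvec(rows, N, v)).sum()
        assert gap < 1e-4

    def test_conservation(self):
        N = 400
        rows = row_success_probabilities(N, MutationSelectionModel(mu_fwd=1e-7, mu_back=1e-7))
        for seed in range(5):
            v = random_probability_vector(N, seed).mass
            out = fast_transpose_matvec(build_approx_matrix(rows, N, v), v)
            assert out.sum() == pytest.approx(1.0, abs=1e-10)
            assert np.all(out >= 0.0)

    def test_mean_preservation_with_unsparsified_rows(self):
        # the moment-matching guarantee: expected next-generation count is
        # matched exactly when sparsification is disabled
        N = 300
        model = MutationSelectionModel(mu_fwd=1e-8, mode="haploid_genic", s_het=0.02)
        rows = row_success_probabilities(N, model)
        v = random_probability_vector(N, 11).mass
        matrix = build_approx_matrix(rows, N, v, sparsity_tol=None)
        out = fast_transpose_matvec(matrix, v)
        expected_mean = float(v @ (N * rows.ps))
        assert out @ np.arange(N + 1) == pytest.approx(expected_mean, rel=1e-12)

    def test_degenerate_rows_reproduced_exactly(self):
        N = 150
        rows = row_success_probabilities(N, MutationSelectionModel())  # p_0=0, p_N=1
        v = np.zeros(N + 1)
        v[0] = 0.5
        v[N] = 0.5
        out = fast_transpose_matvec(build_approx_matrix(rows, N, v), v)
        assert out[0] == pytest.approx(0.5, abs=1e-15)
        assert out[N] == pytest.approx(0.5, abs=1e-15)

    def test_length_mismatch_raises(self):
        rows = row_success_probabilities(10, MutationSelectionModel())
        matrix = build_approx_matrix(rows, 10, np.full(11, 1 / 11))
        with pytest.raises(ValueError):
            fast_transpose_matvec(matrix, np.full(5, 0.2))


class TestExactOracle:
    def test_point_mass_returns_row(self):
        from scipy import stats

        rows = row_success_probabilities(30, MutationSelectionModel(mu_fwd=1e-3))
        v = np.zeros(31)
        v[7] = 1.0
        np.testing.assert_allclose(
            exact_transpose_matvec(rows, 30, v),
            stats.binom.pmf(np.arange(31), 30, rows.ps[7]),
            rtol=1e-12,
        )

    def test_stochastic_output(self):
        rows = row_success_probabilities(80, MutationSelectionModel(mu_fwd=1e-4, mu_back=1e-4))
        v = random_probability_vector(80, 3).mass
        assert exact_transpose_matvec(rows, 80, v).sum() == pytest.approx(1.0, abs=1e-10)

    def test_size_guard(self):
        rows = RowProbabilities(1, np.array([0.0, 1.0]))
        big = RowProbabilities.__new__(RowProbabilities)
        object.__setattr__(big, "N_in", 50_000)
        object.__setattr__(big, "ps", np.linspace(0, 1, 50_001))
        with pytest.raises(ValueError, match="approximation"):
            exact_transpose_matvec(big, 50_000, np.full(50_001, 1 / 50_001))
        del rows
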