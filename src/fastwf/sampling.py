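"""Sparse, low-rank surrogate of the Hypergeometric sampling matrix.

Sampling ``n`` haploids uniformly without replacement from a population of
``N`` carrying ``K`` copies of the focal allele yields a
``Hypergeometric(N, n, K)`` number of copies in the sample.  The
``(N+1) x (n+1)`` matrix ``S`` of these PMFs maps population likelihoods to
sample likelihoods via ``v_sample = S^T v``.

The same two properties that make Binomial transition matrices compressible
hold for Hypergeometric rows (Hoeffding's inequality covers sampling
without replacement): rows concentrate within ``O(sqrt n)`` of their mean,
and rows whose means differ by a small fraction of a standard deviation are
nearly identical.  Because the row parameter ``K`` is an integer, exact
mean-matching of a block under weights ``v`` needs a *mixture of two*
Hypergeometric rows: the integer counts ``K1 = floor(Kbar)`` and
``K2 = ceil(Kbar)`` bracketing the v-weighted mean count ``Kbar``, mixed
with weight ``w = K2 - Kbar`` on ``K1``.  When no block merges more than
two rows, this mixture reproduces the dense product exactly (up to the
sparsification budget).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats

from .binomial import (
    DEFAULT_SPARSITY_TOL,
    EXACT_SIZE_GUARD,
    BlockPartition,
    build_approx_matrix,
    fast_transpose_matvec,
    hoeffding_halfwidth,
)
from .model import MutationSelectionModel, RowProbabilities, expected_offspring_frequency

logger = logging.getLogger("fastwf")

DEFAULT_C_EPS_SAMPLING = 0.05

__all__ = [
    "ApproxSamplingMatrix",
    "hypergeometric_pmf_window",
    "sampling_halfwidth",
    "assign_sampling_blocks",
    "mixture_representative",
    "build_approx_sampling_matrix",
    "fast_sample_matvec",
    "exact_sample_matvec",
    "with_replacement_sample",
]


def hypergeometric_pmf_window(N: int, n: int, K: int, lo: int, hi: int) -> np.ndarray:
    """PMF of Hypergeometric(N, n, K) on sample counts lo..hi inclusive."""
    support_lo, support_hi = max(0, n + K - N), min(n, K)
    if not support_lo <= lo <= hi <= support_hi:
        raise ValueError(
            f"window [{lo}, {hi}] outside support [{support_lo}, {support_hi}]"
        )
    return stats.hypergeom.pmf(np.arange(lo, hi + 1), N, K, n)


def sampling_halfwidth(n: int, tol: float) -> int:
    """Hoeffding count radius for a sample of size n (see hoeffding_halfwidth)."""
    return hoeffding_halfwidth(n, tol)


def _sd_sample_count(N: int, n: int, K) -> np.ndarray:
    """Standard deviation of the Hypergeometric(N, n, K) sample count."""
    frac = np.asarray(K, dtype=float) / N
    fpc = (N - n) / (N - 1.0)
    return np.sqrt(n * frac * (1.0 - frac) * fpc)


def assign_sampling_blocks(N: int, n: int, c_eps_s: float = DEFAULT_C_EPS_SAMPLING) -> BlockPartition:
    """Greedy partition of population counts K = 0..N into blocks.

    A new block starts at K when the mean sample count has moved more than
    ``c_eps_s`` standard deviations from the anchor row:
    ``(K - K_anchor) n / N > c_eps_s * sd(K_anchor)``.  K = 0 and K = N are
    forced singletons (point-mass rows).  When n = N the sd is zero and
    every K is a singleton: S is the identity.
    """
    if not 1 <= n <= N:
        raise ValueError("need 1 <= n <= N")
    starts = [0]
    anchor = 0
    anchor_is_boundary = True
    sd_anchor = 0.0
    for K in range(1, N + 1):
        boundary = K == N
        if boundary or anchor_is_boundary or (K - anchor) * n / N > c_eps_s * sd_anchor:
            starts.append(K)
            anchor = K
            sd_anchor = float(_sd_sample_count(N, n, K))
            anchor_is_boundary = boundary
    starts_arr = np.asarray(starts, dtype=np.int64)
    ends = np.append(starts_arr[1:] - 1, N)
    anchor_ps = starts_arr / N  # anchor "success fraction" K/N, for inspection
    return BlockPartition(np.stack([starts_arr, ends], axis=1), anchor_ps)


def mixture_representative(block_Ks: np.ndarray, v_block: np.ndarray):
    """Two-point mixture (K1, K2, w) matching the v-weighted mean count.

    ``Kbar = sum(K v) / sum(v)``; ``K1 = floor(Kbar)``, ``K2 = ceil(Kbar)``,
    ``w = K2 - Kbar`` is the weight on K1 (w = 1 when Kbar is integral).
    Zero total weight falls back to the anchor (first) K with w = 1.
    """
    block_Ks = np.asarray(block_Ks, dtype=np.int64)
    v_block = np.asarray(v_block, dtype=float)
    if np.any(v_block < 0.0):
        raise ValueError("weights must be nonnegative")
    total = v_block.sum()
    if total <= 0.0:
        K = int(block_Ks[0])
        return K, K, 1.0
    kbar = float(block_Ks @ v_block / total)
    k1 = math.floor(kbar)
    k2 = math.ceil(kbar)
    if k1 == k2:
        return k1, k2, 1.0
    return k1, k2, k2 - kbar


def _hypergeom_windows(N: int, n: int, Ks: np.ndarray, sparsity_tol: Optional[float]):
    """Windowed, renormalized Hypergeometric PMF rows for many K values."""
    Ks = np.asarray(Ks, dtype=np.int64)
    support_lo = np.maximum(0, n + Ks - N)
    support_hi = np.minimum(n, Ks)
    if sparsity_tol is None:
        lo = support_lo
        hi = support_hi
    else:
        radius = sampling_halfwidth(n, sparsity_tol)
        centers = n * Ks / N
        lo = np.maximum(support_lo, np.ceil(centers - radius).astype(np.int64))
        hi = np.minimum(support_hi, np.floor(centers + radius).astype(np.int64))
        mid = np.clip(np.rint(centers).astype(np.int64), support_lo, support_hi)
        lo = np.minimum(lo, mid)
        hi = np.maximum(hi, mid)
    width = int((hi - lo).max()) + 1
    ks = lo[:, None] + np.arange(width)
    valid = ks <= hi[:, None]
    mass = stats.hypergeom.pmf(np.minimum(ks, n), N, Ks[:, None], n)
    mass[~valid] = 0.0
    totals = mass.sum(axis=1, keepdims=True)
    mass /= totals
    return ks, mass


@dataclass(frozen=True)
class ApproxSamplingMatrix:
    """Sparse, low-rank surrogate S~ of the Hypergeometric sampling matrix."""

    N: int
    n: int
    partition: BlockPartition
    K1: np.ndarray  # (B,) lower mixture count per block
    K2: np.ndarray  # (B,) upper mixture count per block
    w: np.ndarray  # (B,) mixture weight on K1
    sparsity_tol: Optional[float]
    _ks1: np.ndarray
    _mass1: np.ndarray
    _ks2: np.ndarray
    _mass2: np.ndarray


def build_approx_sampling_matrix(
    N: int,
    n: int,
    v: np.ndarray,
    c_eps_s: float = DEFAULT_C_EPS_SAMPLING,
    sparsity_tol: Optional[float] = DEFAULT_SPARSITY_TOL,
    partition: Optional[BlockPartition] = None,
) -> ApproxSamplingMatrix:
    """Assemble S~ for weights v: block K = 0..N, pick two-point mixtures."""
    v = np.asarray(v, dtype=float)
    if v.shape != (N + 1,):
        raise ValueError(f"expected weight vector of length {N + 1}, got {v.shape}")
    if partition is None:
        partition = assign_sampling_blocks(N, n, c_eps_s)
    starts = partition.starts
    Kvals = np.arange(N + 1)
    totals = np.add.reduceat(v, starts)
    weighted = np.add.reduceat(v * Kvals, starts)
    anchors = partition.boundaries[:, 0].astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        kbar = np.where(totals > 0.0, weighted / np.where(totals > 0.0, totals, 1.0), anchors)
    K1 = np.floor(kbar).astype(np.int64)
    K2 = np.ceil(kbar).astype(np.int64)
    w = np.where(K2 > K1, K2 - kbar, 1.0)
    ks1, mass1 = _hypergeom_windows(N, n, K1, sparsity_tol)
    ks2, mass2 = _hypergeom_windows(N, n, K2, sparsity_tol)
    return ApproxSamplingMatrix(N, n, partition, K1, K2, w, sparsity_tol, ks1, mass1, ks2, mass2)


def fast_sample_matvec(matrix: ApproxSamplingMatrix, v_pop: np.ndarray) -> np.ndarray:
    """Compute S~^T v: per block add (group sum) * [w row(K1) + (1-w) row(K2)]."""
    v_pop = np.asarray(v_pop, dtype=float)
    if v_pop.shape != (matrix.N + 1,):
        raise ValueError(f"expected vector of length {matrix.N + 1}, got {v_pop.shape}")
    group = np.add.reduceat(v_pop, matrix.partition.starts)
    out = np.zeros(matrix.n + 1)
    c1 = (group * matrix.w)[:, None] * matrix._mass1
    c2 = (group * (1.0 - matrix.w))[:, None] * matrix._mass2
    np.add.at(out, np.minimum(matrix._ks1, matrix.n).ravel(), c1.ravel())
    np.add.at(out, np.minimum(matrix._ks2, matrix.n).ravel(), c2.ravel())
    return out


def exact_sample_matvec(N: int, n: int, v_pop: np.ndarray) -> np.ndarray:
    """Dense O(nN) oracle for S^T v, chunked over nonzero entries of v."""
    if N > EXACT_SIZE_GUARD:
        raise ValueError(
            f"exact sampling mat-vec guarded at N <= {EXACT_SIZE_GUARD}; "
            "use the sparse low-rank approximation for larger populations"
        )
    v_pop = np.asarray(v_pop, dtype=float)
    if v_pop.shape != (N + 1,):
        raise ValueError(f"expected vector of length {N + 1}, got {v_pop.shape}")
    out = np.zeros(n + 1)
    ks = np.arange(n + 1)
    nz = np.nonzero(v_pop)[0]
    for chunk_start in range(0, len(nz), 256):
        idx = nz[chunk_start : chunk_start + 256]
        pmf = stats.hypergeom.pmf(ks[None, :], N, idx[:, None], n)
        out += v_pop[idx] @ pmf
    return out


def with_replacement_sample(
    v_pop: np.ndarray,
    n: int,
    bias_model: Optional[MutationSelectionModel] = None,
) -> np.ndarray:
    """Sample n haploids *with* replacement: one extra DTWF generation.

    Unbiased sampling corresponds to a mutation-free neutral generation with
    offspring size n; allele-biased sampling to the same generation with the
    bias model's selection map.  Mutation rates of the bias model should be
    zero (sampling does not mutate); they are used as given.
    """
    v_pop = np.asarray(v_pop, dtype=float)
    if n < 1:
        raise ValueError("sample size must be >= 1")
    N = len(v_pop) - 1
    model = bias_model if bias_model is not None else MutationSelectionModel()
    f = np.arange(N + 1, dtype=float) / N
    rows = RowProbabilities(N, expected_offspring_frequency(f, model))
    matrix = build_approx_matrix(rows, n, v_pop)
    return fast_transpose_matvec(matrix, v_pop)
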