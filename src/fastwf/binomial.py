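"""Sparse, low-rank surrogates of Binomial transition matrices.

A DTWF transition matrix has row ``i`` equal to the PMF of
``Binomial(N_out, p_i)``.  Two structural facts make an O(N) surrogate
possible:

* **Sparsity** — by Hoeffding's inequality a Binomial variate lies within
  ``r = ceil(sqrt((N/2) ln(2/tol)))`` of its mean except with probability
  ``tol``, so each row can be windowed to ``O(sqrt N)`` entries around its
  mean and renormalized.
* **Low rank** — Binomials whose success probabilities differ by less than
  about ``c_eps * sqrt(p (1-p) / N)`` (a ``c_eps`` fraction of a standard
  deviation in frequency space) are nearly identical in total variation, so
  consecutive rows can share a single representative row.  With the default
  ``c_eps = 0.1`` this yields ``O(sqrt N)`` distinct rows.

Representative success probabilities are moment-matched: within each block
the representative is the average of the member probabilities weighted by
the vector being multiplied, which preserves the expected next-generation
frequency exactly.  The transpose mat-vec then groups the input vector by
block, scales one sparse representative row per block, and scatters —
``O(blocks * window)`` work instead of ``O(N^2)``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import List, Optional

import numpy as np
from scipy import stats

from .model import RowProbabilities

logger = logging.getLogger("fastwf")

DEFAULT_C_EPS = 0.1
DEFAULT_SPARSITY_TOL = 1e-8
EXACT_SIZE_GUARD = 20_000

__all__ = [
    "SparseRow",
    "BlockPartition",
    "ApproxBinomialMatrix",
    "hoeffding_halfwidth",
    "binomial_pmf_window",
    "sparsify_row",
    "assign_blocks",
    "moment_match_representatives",
    "build_approx_matrix",
    "fast_transpose_matvec",
    "exact_transpose_matvec",
]


def hoeffding_halfwidth(N_out: int, tol: float) -> int:
    """Count radius r such that P(|X - E X| > r) <= tol for Binomial(N_out, p).

    ``r = ceil(sqrt((N/2) * ln(2/tol)))``, independent of p.  ``tol >= 2``
    makes the bound vacuous; 0 is returned with a warning.
    """
    if N_out < 1:
        raise ValueError("N_out must be >= 1")
    if not 0.0 < tol < 2.0:
        if tol >= 2.0:
            logger.warning("hoeffding_halfwidth: tol >= 2 makes the bound vacuous")
            return 0
        raise ValueError("tol must be in (0, 2)")
    return int(math.ceil(math.sqrt(0.5 * N_out * math.log(2.0 / tol))))


def binomial_pmf_window(N_out: int, p: float, lo: int, hi: int) -> np.ndarray:
    """PMF of Binomial(N_out, p) on counts lo..hi inclusive (not normalized)."""
    if not 0 <= lo <= hi <= N_out:
        raise ValueError(f"invalid window [{lo}, {hi}] for N_out={N_out}")
    return stats.binom.pmf(np.arange(lo, hi + 1), N_out, p)


def _window_bounds(N_out: int, ps: np.ndarray, radius: int):
    """Per-row [lo, hi] window around the mean N_out*p, clipped to [0, N_out]."""
    centers = N_out * ps
    lo = np.ceil(centers - radius).astype(np.int64)
    hi = np.floor(centers + radius).astype(np.int64)
    mid = np.rint(centers).astype(np.int64)
    lo = np.clip(np.minimum(lo, mid), 0, N_out)
    hi = np.clip(np.maximum(hi, mid), 0, N_out)
    return lo, hi


def _pmf_windows(
    N_out: int,
    ps: np.ndarray,
    sparsity_tol: Optional[float],
    drop_index: Optional[int] = None,
):
    """Windowed, renormalized Binomial PMF rows for many success probabilities.

    Returns ``(ks, mass)`` of shape (len(ps), W): ``ks`` are count indices,
    ``mass`` the renormalized PMF values (zero on padding).  With
    ``sparsity_tol=None`` the full rows 0..N_out are produced.  Entries at
    ``drop_index`` (the fixation column of a non-fixation-conditioned
    chain) are zeroed *after* renormalization, leaving sub-stochastic rows
    whose deficit is the one-step fixation probability.
    """
    ps = np.asarray(ps, dtype=float)
    # scipy's Boost backend overflows on subnormal success probabilities;
    # a Binomial with p below ~1e-250 is a point mass at 0 in float anyway
    ps = np.where(np.abs(ps) < 1e-250, 0.0, np.clip(ps, 0.0, 1.0))
    if sparsity_tol is None:
        ks = np.broadcast_to(np.arange(N_out + 1), (len(ps), N_out + 1)).copy()
        mass = stats.binom.pmf(ks, N_out, ps[:, None])
    else:
        radius = hoeffding_halfwidth(N_out, sparsity_tol)
        lo, hi = _window_bounds(N_out, ps, radius)
        width = int((hi - lo).max()) + 1
        ks = lo[:, None] + np.arange(width)
        valid = ks <= hi[:, None]
        mass = stats.binom.pmf(np.minimum(ks, N_out), N_out, ps[:, None])
        mass[~valid] = 0.0
    totals = mass.sum(axis=1, keepdims=True)
    if np.any(totals <= 0.0):
        raise ValueError("a PMF window retained zero mass")
    mass /= totals
    if drop_index is not None:
        mass[ks == drop_index] = 0.0
    return ks, mass


@dataclass(frozen=True)
class SparseRow:
    """A windowed, renormalized PMF row: values for counts offset..offset+len-1."""

    offset: int
    mass: np.ndarray

    def expand(self, N_out: int) -> np.ndarray:
        out = np.zeros(N_out + 1)
        out[self.offset : self.offset + len(self.mass)] = self.mass
        return out


def sparsify_row(N_out: int, p: float, tol: float = DEFAULT_SPARSITY_TOL) -> SparseRow:
    """Window the Binomial(N_out, p) PMF to mean +- Hoeffding radius, renormalize.

    The l1 distance between the returned row and the full PMF is at most
    ``2 tol / (1 - tol)``.  ``p`` of 0 or 1 yields an exact point mass.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError("p outside [0, 1]")
    if p == 0.0:
        return SparseRow(0, np.array([1.0]))
    if p == 1.0:
        return SparseRow(N_out, np.array([1.0]))
    ks, mass = _pmf_windows(N_out, np.array([p]), tol)
    keep = mass[0] > 0.0
    if not keep.any():  # degenerate tol: keep the modal entry
        keep[np.argmax(mass[0])] = True
    first = int(np.argmax(keep))
    last = len(keep) - int(np.argmax(keep[::-1]))
    return SparseRow(int(ks[0, first]), mass[0, first:last].copy())


@dataclass(frozen=True)
class BlockPartition:
    """Contiguous partition of rows 0..N_in into blocks of similar rows.

    ``boundaries[k] = (first_row, last_row)`` inclusive; ``anchor_ps[k]`` is
    the success probability of the block's first row, which anchors the
    greedy spacing rule.
    """

    boundaries: np.ndarray  # (B, 2) int
    anchor_ps: np.ndarray  # (B,)

    @property
    def n_blocks(self) -> int:
        return len(self.anchor_ps)

    @property
    def starts(self) -> np.ndarray:
        return self.boundaries[:, 0]

    @property
    def sizes(self) -> np.ndarray:
        return self.boundaries[:, 1] - self.boundaries[:, 0] + 1

    def state_to_block(self) -> np.ndarray:
        return np.repeat(np.arange(self.n_blocks), self.sizes)


def assign_blocks(rows: RowProbabilities, N_out: int, c_eps: float = DEFAULT_C_EPS) -> BlockPartition:
    """Greedy left-to-right assignment of ordered success probabilities to blocks.

    A new block starts at row i when
    ``p_i > anchor_p + c_eps * sqrt(anchor_p (1 - anchor_p) / N_out)``,
    where ``anchor_p`` is the current block's first probability.  Rows with
    p exactly 0 or 1 (absorbing states) are forced singletons.  Linear in
    the number of rows.
    """
    ps = rows.ps
    starts: List[int] = []
    anchor = math.inf
    threshold = -math.inf
    anchor_is_boundary = False
    for i, p in enumerate(ps):
        boundary = p == 0.0 or p == 1.0
        if i == 0 or boundary or anchor_is_boundary or p > threshold:
            starts.append(i)
            anchor = p
            threshold = p + c_eps * math.sqrt(p * (1.0 - p) / N_out)
            anchor_is_boundary = boundary
    starts_arr = np.asarray(starts, dtype=np.int64)
    ends = np.append(starts_arr[1:] - 1, len(ps) - 1)
    return BlockPartition(np.stack([starts_arr, ends], axis=1), ps[starts_arr])


def moment_match_representatives(
    partition: BlockPartition, rows: RowProbabilities, v: np.ndarray
) -> np.ndarray:
    """Per-block representative p~ = sum(p_l v_l) / sum(v_l) over the block.

    Preserves the v-weighted expected next-generation frequency exactly.
    Blocks where v has zero total mass fall back to the anchor probability
    (any in-block value is admissible there).
    """
    v = np.asarray(v, dtype=float)
    if np.any(v < 0.0):
        raise ValueError("weights must be nonnegative")
    if v.shape != rows.ps.shape:
        raise ValueError("weight vector length must equal number of rows")
    starts = partition.starts
    totals = np.add.reduceat(v, starts)
    weighted = np.add.reduceat(v * rows.ps, starts)
    with np.errstate(invalid="ignore", divide="ignore"):
        rep = np.where(totals > 0.0, weighted / np.where(totals > 0.0, totals, 1.0), partition.anchor_ps)
    lo = rows.ps[partition.boundaries[:, 0]]
    hi = rows.ps[partition.boundaries[:, 1]]
    return np.clip(rep, lo, hi)


@dataclass(frozen=True)
class ApproxBinomialMatrix:
    """Sparse, low-rank surrogate M~ of one generation's DTWF transition matrix."""

    N_in: int
    N_out: int
    partition: BlockPartition
    rep_ps: np.ndarray
    sparsity_tol: Optional[float]
    _ks: np.ndarray  # (B, W) count indices of each representative row window
    _mass: np.ndarray  # (B, W) renormalized PMF values (0 on padding)

    @property
    def rep_rows(self) -> List[SparseRow]:
        rows = []
        for k_row, m_row in zip(self._ks, self._mass):
            keep = m_row > 0.0
            first = int(np.argmax(keep))
            last = len(keep) - int(np.argmax(keep[::-1]))
            rows.append(SparseRow(int(k_row[first]), m_row[first:last].copy()))
        return rows


def build_approx_matrix(
    rows: RowProbabilities,
    N_out: int,
    v: np.ndarray,
    c_eps: float = DEFAULT_C_EPS,
    sparsity_tol: Optional[float] = DEFAULT_SPARSITY_TOL,
    partition: Optional[BlockPartition] = None,
    drop_index: Optional[int] = None,
) -> ApproxBinomialMatrix:
    """Assemble the surrogate: block the rows, moment-match representatives
    against ``v``, and window/renormalize one Binomial PMF row per block.

    ``sparsity_tol=None`` keeps full rows (used to isolate the low-rank step
    from the sparsification step).  A precomputed ``partition`` may be
    passed; blocks depend only on the row probabilities and ``N_out``, so
    they are reusable across vectors and generations.
    """
    if partition is None:
        partition = assign_blocks(rows, N_out, c_eps)
    rep_ps = moment_match_representatives(partition, rows, v)
    ks, mass = _pmf_windows(N_out, rep_ps, sparsity_tol, drop_index=drop_index)
    return ApproxBinomialMatrix(rows.N_in, N_out, partition, rep_ps, sparsity_tol, ks, mass)


def fast_transpose_matvec(matrix: ApproxBinomialMatrix, v: np.ndarray) -> np.ndarray:
    """Compute M~^T v by grouping v per block and scattering scaled rows.

    Cost is proportional to (number of blocks) x (window width).
    """
    v = np.asarray(v, dtype=float)
    if v.shape != (matrix.N_in + 1,):
        raise ValueError(f"expected vector of length {matrix.N_in + 1}, got {v.shape}")
    group = np.add.reduceat(v, matrix.partition.starts)
    out = np.zeros(matrix.N_out + 1)
    contrib = group[:, None] * matrix._mass
    flat_k = np.minimum(matrix._ks, matrix.N_out).ravel()
    np.add.at(out, flat_k, contrib.ravel())
    return out


def exact_transpose_matvec(rows: RowProbabilities, N_out: int, v: np.ndarray) -> np.ndarray:
    """Dense O(N^2) oracle for M^T v, chunked to bound memory.

    Guarded at N_in <= 20000; beyond that use the approximation.
    """
    if rows.N_in > EXACT_SIZE_GUARD:
        raise ValueError(
            f"exact transpose mat-vec guarded at N_in <= {EXACT_SIZE_GUARD}; "
            "use the sparse low-rank approximation for larger populations"
        )
    v = np.asarray(v, dtype=float)
    if v.shape != (rows.N_in + 1,):
        raise ValueError(f"expected vector of length {rows.N_in + 1}, got {v.shape}")
    out = np.zeros(N_out + 1)
    ks = np.arange(N_out + 1)
    nz = np.nonzero(v)[0]
    for chunk_start in range(0, len(nz), 256):
        idx = nz[chunk_start : chunk_start + 256]
        pmf = stats.binom.pmf(ks[None, :], N_out, rows.ps[idx, None])
        out += v[idx] @ pmf
    return out
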