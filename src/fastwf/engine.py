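"""Likelihood engine: evolve allele-count distributions, solve equilibria,
project to samples, and assemble site-frequency spectra.

The engine composes the building blocks of :mod:`fastwf.model`,
:mod:`fastwf.binomial` and :mod:`fastwf.sampling`:

* ``evolve`` applies one transpose mat-vec per generation,
  ``v_t = M_{t-1}^T v_{t-1}``, with representative rows re-moment-matched
  against the current vector every generation (blocks are reused while the
  population size and model are unchanged).
* ``equilibrium`` solves ``M^T v = v``.  The exact path solves the dense
  stationary system; the fast path condenses the chain onto meta-states
  (one per block of similar rows), solves the small meta-state chain, and
  expands the meta-state masses through the representative PMF rows.
  Because the representatives are moment-matched against the equilibrium
  itself, the construction is iterated to a fixed point.
* ``equilibrium_conditional_nonfixed`` conditions the chain on not (yet)
  having fixed: the state space is restricted to counts 0..N-1, the
  fixation column is deleted (leaving sub-stochastic rows), and the
  conditioned law at each generation is the propagated vector renormalized.
  The long-run conditioned equilibrium is the quasi-stationary distribution
  — the left Perron eigenvector of the sub-stochastic matrix — computed by
  shift-regularized inverse iteration.  With recurrent forward mutation
  feeding state 0 this equilibrium is non-trivial and grounds the
  single-site site-frequency spectrum with a well-defined
  ancestral/derived labeling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np
from scipy import stats

from . import binomial, sampling
from .binomial import (
    DEFAULT_C_EPS,
    DEFAULT_SPARSITY_TOL,
    EXACT_SIZE_GUARD,
    BlockPartition,
    _pmf_windows,
    assign_blocks,
    moment_match_representatives,
)
from .model import Demography, MutationSelectionModel, RowProbabilities, row_success_probabilities
from .sampling import DEFAULT_C_EPS_SAMPLING

logger = logging.getLogger("fastwf")

__all__ = [
    "ProbabilityVector",
    "CondensedChain",
    "point_mass",
    "evolve",
    "transition_mass_function",
    "equilibrium",
    "equilibrium_conditional_nonfixed",
    "sample_likelihood",
    "probability_segregating",
    "normalized_sfs",
    "sample_count_likelihoods",
    "likelihood_of_sample_count",
]


class ProbabilityVector:
    """Nonnegative mass over allele counts 0..size_bound, summing to one.

    Construction renormalizes when the sum is within 1e-8 of one and raises
    otherwise.
    """

    __slots__ = ("mass",)

    def __init__(self, mass, *, tol: float = 1e-8):
        mass = np.asarray(mass, dtype=float)
        if mass.ndim != 1 or len(mass) == 0:
            raise ValueError("mass must be a nonempty 1-d array")
        if np.any(mass < 0.0):
            if np.min(mass) < -tol:
                raise ValueError(f"negative mass {np.min(mass)}")
            mass = np.clip(mass, 0.0, None)
        total = mass.sum()
        if abs(total - 1.0) > tol:
            raise ValueError(f"mass sums to {total}, not 1 within {tol}")
        self.mass = mass / total

    @property
    def size_bound(self) -> int:
        return len(self.mass) - 1

    def __len__(self) -> int:
        return len(self.mass)

    def __getitem__(self, i):
        return self.mass[i]

    def __array__(self, dtype=None, copy=None):
        return np.asarray(self.mass, dtype=dtype)


def point_mass(count: int, size_bound: int) -> ProbabilityVector:
    if not 0 <= count <= size_bound:
        raise ValueError("count outside 0..size_bound")
    mass = np.zeros(size_bound + 1)
    mass[count] = 1.0
    return ProbabilityVector(mass)


@dataclass(frozen=True)
class CondensedChain:
    """Meta-state (block-level) Markov chain used to solve equilibria.

    Rows sum to one for the full chain; for the non-fixation-conditioned
    chain they are sub-stochastic, the deficit being the one-step fixation
    probability out of the meta-state.
    """

    blocks: BlockPartition
    transition: np.ndarray  # (B, B) meta-state transition probabilities
    rep_ps: np.ndarray  # (B,) representative success probability per block

    def __post_init__(self) -> None:
        rowsum = self.transition.sum(axis=1)
        if np.any(rowsum > 1.0 + 1e-10) or np.any(rowsum < -1e-10):
            raise ValueError("condensed transition rows must sum to at most 1 within 1e-10")


def _as_mass(v) -> np.ndarray:
    return np.asarray(v.mass if isinstance(v, ProbabilityVector) else v, dtype=float)


# ---------------------------------------------------------------------------
# single-generation steps
# ---------------------------------------------------------------------------

def _approx_step(
    rows: RowProbabilities,
    N_out: int,
    v: np.ndarray,
    partition: BlockPartition,
    c_eps: float,
    sparsity_tol: float,
    conditioned: bool,
) -> np.ndarray:
    drop = N_out if conditioned else None
    matrix = binomial.build_approx_matrix(
        rows, N_out, v, c_eps, sparsity_tol, partition=partition, drop_index=drop
    )
    out = binomial.fast_transpose_matvec(matrix, v)
    return out[:N_out] if conditioned else out


def _dense_matrix(rows: RowProbabilities, N_out: int, conditioned: bool) -> np.ndarray:
    """Dense transition matrix; conditioned matrices drop the fixation
    column and stay sub-stochastic (the conditioned law renormalizes the
    propagated vector, not the rows)."""
    ks = np.arange(N_out + 1)
    M = stats.binom.pmf(ks[None, :], N_out, rows.ps[:, None])
    if conditioned:
        M = M[:, :N_out]
    return M


def _exact_step(rows: RowProbabilities, N_out: int, v: np.ndarray, conditioned: bool) -> np.ndarray:
    if rows.N_in > EXACT_SIZE_GUARD:
        raise ValueError(f"exact path guarded at N <= {EXACT_SIZE_GUARD}")
    if not conditioned:
        return binomial.exact_transpose_matvec(rows, N_out, v)
    out = np.zeros(N_out)
    ks = np.arange(N_out + 1)
    nz = np.nonzero(v)[0]
    for chunk_start in range(0, len(nz), 256):
        idx = nz[chunk_start : chunk_start + 256]
        pmf = stats.binom.pmf(ks[None, :], N_out, rows.ps[idx, None])[:, :N_out]
        out += v[idx] @ pmf
    return out


def _size_sequence(demography: Demography, generations: Optional[int]) -> np.ndarray:
    sched = demography.size_schedule()
    if generations is None:
        return sched
    if generations < 0:
        raise ValueError("generations must be >= 0")
    if len(sched) >= generations:
        return sched[:generations]
    pad_size = sched[-1] if len(sched) else demography.ancient_N
    return np.concatenate([sched, np.full(generations - len(sched), pad_size, dtype=np.int64)])


def evolve(
    v: ProbabilityVector,
    demography: Demography,
    model: MutationSelectionModel,
    generations: Optional[int] = None,
    method: str = "approx",
    *,
    conditioned: bool = False,
    c_eps: float = DEFAULT_C_EPS,
    sparsity_tol: float = DEFAULT_SPARSITY_TOL,
) -> ProbabilityVector:
    """Integrate v forward through the demography's epoch schedule.

    ``generations=None`` runs the full (finite) schedule; an explicit count
    truncates or extends it at the final size (required for a constant
    demography, whose schedule is empty).  ``conditioned=True`` evolves the
    non-fixation-conditioned chain: the state space is 0..N-1 and the
    fixation column is deleted and rows renormalized each generation.
    """
    if method not in ("approx", "exact"):
        raise ValueError("method must be 'approx' or 'exact'")
    sizes = _size_sequence(demography, generations)
    mass = _as_mass(v)
    state_size = len(mass) - 1  # == N for the full chain, N-1 conditioned
    N_cur = state_size + 1 if conditioned else state_size
    expected = demography.ancient_N - 1 if conditioned else demography.ancient_N
    if state_size != expected:
        raise ValueError(
            f"vector sized for N={N_cur}, demography starts at N={demography.ancient_N}"
        )
    rows_cache: dict[int, RowProbabilities] = {}
    part_cache: dict[tuple[int, int], BlockPartition] = {}
    dense_cache: dict[tuple[int, int], np.ndarray] = {}
    for N_out in sizes:
        N_out = int(N_out)
        if N_cur not in rows_cache:
            rows_cache[N_cur] = row_success_probabilities(N_cur, model)
        rows_full = rows_cache[N_cur]
        if conditioned:
            rows = RowProbabilities(N_cur - 1, rows_full.ps[:-1])
        else:
            rows = rows_full
        if method == "exact":
            key = (N_cur, N_out)
            if key not in dense_cache:
                dense_cache.clear()  # keep at most one dense matrix alive
                dense_cache[key] = _dense_matrix(rows, N_out, conditioned)
            mass = mass @ dense_cache[key]
        else:
            key = (N_cur, N_out)
            if key not in part_cache:
                part_cache[key] = assign_blocks(rows, N_out, c_eps)
            mass = _approx_step(rows, N_out, mass, part_cache[key], c_eps, sparsity_tol, conditioned)
        mass = mass / mass.sum()
        N_cur = N_out
    return ProbabilityVector(mass)


def transition_mass_function(
    initial_count: int,
    generations: int,
    N: int,
    model: MutationSelectionModel,
    method: str = "approx",
    **kwargs,
) -> ProbabilityVector:
    """Distribution of the allele count ``generations`` ahead of a point mass."""
    v0 = point_mass(initial_count, N)
    demography = Demography(ancient_N=N)
    return evolve(v0, demography, model, generations, method, **kwargs)


# ---------------------------------------------------------------------------
# equilibria
# ---------------------------------------------------------------------------

def _stationary(T: np.ndarray) -> np.ndarray:
    """Stationary distribution of a row-stochastic matrix by dense solve.

    Uses the rank-one-shifted system (T^T - I + 11^T) pi = 1, which encodes
    the normalization without singling out one state (so structural
    symmetries of the chain survive floating-point) and is nonsingular for
    any irreducible chain.
    """
    B = T.shape[0]
    A = T.T - np.eye(B) + 1.0
    b = np.ones(B)
    try:
        pi = np.linalg.solve(A, b)
    except np.linalg.LinAlgError:
        pi, *_ = np.linalg.lstsq(A, b, rcond=None)
    pi = np.clip(pi, 0.0, None)
    return pi / pi.sum()


def _perron_left(Q: np.ndarray, delta: float = 1e-8, tol: float = 1e-14, max_iter: int = 200) -> np.ndarray:
    """Left Perron eigenvector of a sub-stochastic matrix (the
    quasi-stationary distribution), by inverse iteration with shift 1+delta.

    The Perron eigenvalue of the killed chain lies just below one while the
    subdominant spectrum is well separated, so the shifted solve converges
    in a handful of iterations; the small positive shift keeps the linear
    system comfortably nonsingular even when the kill rate underflows.
    """
    import scipy.linalg as sla

    B = Q.shape[0]
    A = (1.0 + delta) * np.eye(B) - Q.T
    lu = sla.lu_factor(A)
    v = np.full(B, 1.0 / B)
    for _ in range(max_iter):
        w = sla.lu_solve(lu, v)
        w = np.clip(w, 0.0, None)
        w /= w.sum()
        if 0.5 * np.abs(w - v).sum() < tol:
            return w
        v = w
    logger.warning("Perron inverse iteration hit max_iter; returning last iterate")
    return v


def _condensed_equilibrium(
    ps: np.ndarray,
    N_out: int,
    conditioned: bool,
    c_eps: float,
    sparsity_tol: float,
    tol: float = 1e-10,
    max_iter: int = 100,
):
    """Meta-state equilibrium with moment-matching weights iterated to a
    fixed point (weights start uniform within blocks)."""
    S = len(ps)  # number of states: N_out + 1, or N_out when conditioned
    rows = RowProbabilities(S - 1, ps)
    partition = assign_blocks(rows, N_out, c_eps)
    B = partition.n_blocks
    state_block = partition.state_to_block()
    sizes = partition.sizes.astype(float)
    # uniform within-block weights for the first pass
    rep = np.add.reduceat(ps, partition.starts) / sizes
    lo = ps[partition.boundaries[:, 0]]
    hi = ps[partition.boundaries[:, 1]]
    rep = np.clip(rep, lo, hi)
    drop = N_out if conditioned else None
    row_idx = None
    v_prev = None
    trace = []
    for iteration in range(max_iter):
        ks, mass = _pmf_windows(N_out, rep, sparsity_tol, drop_index=drop)
        if row_idx is None or row_idx.shape != ks.shape:
            row_idx = np.broadcast_to(np.arange(B)[:, None], ks.shape)
        k_state = np.minimum(ks, S - 1)
        T = np.zeros((B, B))
        np.add.at(T, (row_idx.ravel(), state_block[k_state].ravel()), mass.ravel())
        if conditioned:
            pi = _perron_left(T)
        else:
            T /= T.sum(axis=1, keepdims=True)
            pi = _stationary(T)
        v = np.zeros(S)
        np.add.at(v, k_state.ravel(), (pi[:, None] * mass).ravel())
        v /= v.sum()
        if v_prev is not None:
            step = 0.5 * np.abs(v - v_prev).sum()
            trace.append(step)
            if step < tol:
                chain = CondensedChain(partition, T, rep)
                logger.debug(
                    "condensed equilibrium converged in %d iterations (TV step %.3g)",
                    iteration + 1,
                    step,
                )
                return v, chain
        v_prev = v
        rep = moment_match_representatives(partition, rows, v)
    raise RuntimeError(
        f"meta-state equilibrium did not converge in {max_iter} iterations; "
        f"TV trace tail: {trace[-5:]}"
    )


def equilibrium(
    N: int,
    model: MutationSelectionModel,
    method: str = "approx",
    *,
    c_eps: float = DEFAULT_C_EPS,
    sparsity_tol: float = DEFAULT_SPARSITY_TOL,
    return_chain: bool = False,
):
    """Stationary distribution of the full chain on counts 0..N.

    Requires recurrent mutation in both directions; otherwise the boundary
    states are absorbing and the stationary law is degenerate (use
    :func:`equilibrium_conditional_nonfixed` for the one-way case).
    """
    if model.mu_fwd <= 0.0 or model.mu_back <= 0.0:
        raise ValueError(
            "equilibrium requires mu_fwd > 0 and mu_back > 0; with one-way "
            "mutation use equilibrium_conditional_nonfixed"
        )
    rows = row_success_probabilities(N, model)
    if method == "exact":
        if N > EXACT_SIZE_GUARD:
            raise ValueError(f"exact equilibrium guarded at N <= {EXACT_SIZE_GUARD}")
        M = _dense_matrix(rows, N, conditioned=False)
        v = _stationary(M)
        return (ProbabilityVector(v), None) if return_chain else ProbabilityVector(v)
    v, chain = _condensed_equilibrium(rows.ps, N, False, c_eps, sparsity_tol)
    pv = ProbabilityVector(v)
    return (pv, chain) if return_chain else pv


def equilibrium_conditional_nonfixed(
    N: int,
    model: MutationSelectionModel,
    method: str = "approx",
    *,
    c_eps: float = DEFAULT_C_EPS,
    sparsity_tol: float = DEFAULT_SPARSITY_TOL,
    return_chain: bool = False,
):
    """Quasi-stationary distribution of the chain conditioned on non-fixation.

    States are counts 0..N-1; transition rows are the Binomial(N, p_i) PMFs
    with the fixation column deleted (sub-stochastic), and the equilibrium
    is the left Perron eigenvector of that killed chain — the long-run law
    of the allele count given that fixation has not occurred.  Forward
    mutation must be positive so state 0 keeps injecting new alleles.
    """
    if model.mu_fwd <= 0.0:
        raise ValueError("conditioned equilibrium requires mu_fwd > 0 (mutational influx)")
    rows_full = row_success_probabilities(N, model)
    ps = rows_full.ps[:-1]
    if method == "exact":
        if N > EXACT_SIZE_GUARD:
            raise ValueError(f"exact equilibrium guarded at N <= {EXACT_SIZE_GUARD}")
        rows = RowProbabilities(N - 1, ps)
        M = _dense_matrix(rows, N, conditioned=True)
        v = _perron_left(M)
        return (ProbabilityVector(v), None) if return_chain else ProbabilityVector(v)
    v, chain = _condensed_equilibrium(ps, N, True, c_eps, sparsity_tol)
    pv = ProbabilityVector(v)
    return (pv, chain) if return_chain else pv


# ---------------------------------------------------------------------------
# sampling and spectra
# ---------------------------------------------------------------------------

def sample_likelihood(
    v_pop,
    n: int,
    method: str = "approx",
    *,
    c_eps_s: float = DEFAULT_C_EPS_SAMPLING,
    sparsity_tol: float = DEFAULT_SPARSITY_TOL,
) -> ProbabilityVector:
    """Project population likelihoods to a sample of n haploids drawn
    without replacement (a diploid sample of n individuals is 2n draws;
    pass 2n)."""
    mass = _as_mass(v_pop)
    N = len(mass) - 1
    if not 1 <= n <= N:
        raise ValueError("need 1 <= n <= N")
    if method == "exact":
        out = sampling.exact_sample_matvec(N, n, mass)
    else:
        matrix = sampling.build_approx_sampling_matrix(N, n, mass, c_eps_s, sparsity_tol)
        out = sampling.fast_sample_matvec(matrix, mass)
    return ProbabilityVector(out)


def probability_segregating(v_sample) -> float:
    """Probability the site is segregating in the sample: 1 - P(0) - P(n)."""
    mass = _as_mass(v_sample)
    return float(1.0 - mass[0] - mass[-1])


def normalized_sfs(
    N: int,
    model: MutationSelectionModel,
    n: int,
    method: str = "approx",
    **kwargs,
) -> np.ndarray:
    """Normalized site-frequency spectrum over sample counts 1..n-1.

    The conditioned (non-fixed) equilibrium is projected to the sample and
    renormalized over segregating counts: the distribution of the derived
    allele count at a randomly chosen segregating site.
    """
    if n < 2:
        raise ValueError("sample size must be >= 2")
    veq = equilibrium_conditional_nonfixed(N, model, method, **kwargs)
    v_pop = np.append(veq.mass, 0.0)  # fixation state carries zero mass
    vs = sample_likelihood(v_pop, n, method)
    inner = vs.mass[1:n]
    total = inner.sum()
    if total <= 0.0:
        raise ValueError("zero segregating mass; cannot normalize the SFS")
    return inner / total


def sample_count_likelihoods(
    n_diploid: int,
    demography: Demography,
    model: MutationSelectionModel,
    method: str = "approx",
    generations: Optional[int] = None,
) -> ProbabilityVector:
    """P(k alleles among 2*n_diploid sampled haploids) for k = 0..2n.

    Conditioned equilibrium at the ancient size, evolved (still conditioned
    on non-fixation) through the epochs, then hypergeometric sampling of
    2*n_diploid haploid draws.
    """
    veq = equilibrium_conditional_nonfixed(demography.ancient_N, model, method)
    v = evolve(veq, demography, model, generations, method, conditioned=True)
    v_pop = np.append(v.mass, 0.0)
    return sample_likelihood(v_pop, 2 * n_diploid, method)


def likelihood_of_sample_count(
    k: int,
    n_diploid: int,
    demography: Demography,
    model: MutationSelectionModel,
    method: str = "approx",
) -> float:
    """Likelihood of observing exactly k copies in a diploid sample."""
    if not 0 <= k <= 2 * n_diploid:
        raise ValueError("k outside 0..2*n_diploid")
    return float(sample_count_likelihoods(n_diploid, demography, model, method)[k])
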