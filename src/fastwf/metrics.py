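"""Distances between distributions and Fisher information for selection.

Total variation (half the l1 distance) is the package's accuracy currency:
it is directly bounded by the 1-operator norm of the matrix perturbation
introduced by the transition-matrix surrogate.  The symmetrized
Kullback-Leibler divergence supplements it with an information-theoretic
view that is far more sensitive to relative errors in small entries.

Fisher information for the selection coefficient is computed in the
log10(s_het) parameterization,

    I(s) = sum_k P(k | s) * (d/dt log P(k | 10^t) at t = log10 s)^2,

with the score obtained by central differences of the sample-count
log-likelihood curves (default step 0.05 log10 units).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Callable, Optional, Sequence

import numpy as np

from .engine import Demography, ProbabilityVector, sample_count_likelihoods
from .model import MutationSelectionModel

DEFAULT_LOG10_STEP = 0.05

__all__ = [
    "LikelihoodGrid",
    "tv_distance",
    "kl_symmetrized",
    "one_operator_distance",
    "fisher_information",
    "fisher_information_for_selection",
    "selection_likelihood_grid",
]


def _as_array(p) -> np.ndarray:
    return np.asarray(p.mass if isinstance(p, ProbabilityVector) else p, dtype=float)


def tv_distance(p, q) -> float:
    """Total variation distance, half the l1 distance between PMFs."""
    p, q = _as_array(p), _as_array(q)
    if p.shape != q.shape:
        raise ValueError("distributions must have equal length")
    return float(0.5 * np.abs(p - q).sum())


def kl_symmetrized(p, q) -> float:
    """D(p||q) + D(q||p) with natural logarithms.

    Entries where both masses vanish are skipped; one-sided zeros make the
    divergence infinite and +inf is returned explicitly (callers comparing
    reports fall back to TV in that case).
    """
    p, q = _as_array(p), _as_array(q)
    if p.shape != q.shape:
        raise ValueError("distributions must have equal length")
    both_zero = (p == 0.0) & (q == 0.0)
    p, q = p[~both_zero], q[~both_zero]
    if np.any((p == 0.0) != (q == 0.0)):
        return math.inf
    keep = p > 0.0
    p, q = p[keep], q[keep]
    ratio = np.log(p) - np.log(q)
    return float((p - q) @ ratio)


def one_operator_distance(A: np.ndarray) -> float:
    """1-operator norm of a (small, dense) matrix: max column-wise l1 sum."""
    A = np.asarray(A, dtype=float)
    if A.ndim != 2:
        raise ValueError("expected a matrix")
    return float(np.abs(A).sum(axis=0).max())


def fisher_information(
    likelihood_fn: Callable[[float], np.ndarray],
    s0: float,
    step: float = DEFAULT_LOG10_STEP,
) -> float:
    """Fisher information for log10(s) at s0 by central differences.

    ``likelihood_fn(s)`` must return the full outcome distribution
    P(k | s).  Outcomes with zero probability at s0 contribute nothing;
    outcomes whose probability vanishes at a perturbed point (infinite
    score) are excluded the same way.
    """
    if s0 <= 0.0:
        raise ValueError("s0 must be > 0")
    if step <= 0.0:
        raise ValueError("step must be > 0")
    t0 = math.log10(s0)
    s_plus, s_minus = 10.0 ** (t0 + step), 10.0 ** (t0 - step)
    if s_plus == s0 or s_minus == s0:
        raise ValueError("step underflows the log10 grid")
    p0 = _as_array(likelihood_fn(s0))
    pp = _as_array(likelihood_fn(s_plus))
    pm = _as_array(likelihood_fn(s_minus))
    keep = (p0 > 0.0) & (pp > 0.0) & (pm > 0.0)
    score = (np.log(pp[keep]) - np.log(pm[keep])) / (2.0 * step)
    return float(p0[keep] @ score**2)


@dataclass(frozen=True)
class LikelihoodGrid:
    """Sample-count log-likelihood curves over a grid of log10(s_het)."""

    s_grid: np.ndarray  # log10(s_het) grid values, ordered
    loglik: np.ndarray  # (2n + 1, len(s_grid)) log P(k | s)

    def __post_init__(self) -> None:
        col_mass = np.exp(self.loglik).sum(axis=0)
        if np.any(np.abs(col_mass - 1.0) > 1e-6):
            raise ValueError("each log-likelihood column must exponentiate to a distribution")


def _engine_likelihood_fn(
    n_diploid: int,
    demography: Demography,
    model: MutationSelectionModel,
    method: str,
) -> Callable[[float], np.ndarray]:
    def fn(s: float) -> np.ndarray:
        m = replace(model, s_het=s, s_hom=None)
        return sample_count_likelihoods(n_diploid, demography, m, method).mass

    return fn


def fisher_information_for_selection(
    n_diploid: int,
    demography: Demography,
    model: MutationSelectionModel,
    s0: float,
    step: float = DEFAULT_LOG10_STEP,
    method: str = "approx",
) -> float:
    """Fisher information for log10(s_het) under the full likelihood engine."""
    return fisher_information(_engine_likelihood_fn(n_diploid, demography, model, method), s0, step)


def selection_likelihood_grid(
    n_diploid: int,
    demography: Demography,
    model: MutationSelectionModel,
    s_values: Sequence[float],
    method: str = "approx",
) -> LikelihoodGrid:
    """Log-likelihood curves log P(k | s_het) over an ordered grid of s_het."""
    fn = _engine_likelihood_fn(n_diploid, demography, model, method)
    s_values = np.asarray(sorted(s_values), dtype=float)
    with np.errstate(divide="ignore"):
        cols = [np.log(fn(float(s))) for s in s_values]
    return LikelihoodGrid(np.log10(s_values), np.stack(cols, axis=1))
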