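"""Wright-Fisher diffusion equilibrium SFS, the comparison baseline.

In the large-N diffusion limit with genic selection, the equilibrium
frequency spectrum of a derived allele (Poisson-Random-Field form) has
density

    f(x)  proportional to  (1 - exp(-2 gamma (1 - x)))
                           / ((1 - exp(-2 gamma)) x (1 - x)),

where ``gamma`` is the scaled selective *advantage* of the derived allele.
Here ``s`` is a fitness reduction, as in the DTWF parameterization, so
``gamma = -sigma`` with ``sigma = N * s`` (N haploid — like-for-like with
the DTWF chain).  Deleterious alleles (sigma > 0) are suppressed at high
frequency and enriched for singletons.  The neutral limit ``sigma -> 0``
recovers the classical 1/x law.  The expected sample
spectrum at size n mixes Binomial sampling over the density,

    E[xi_i]  proportional to  integral_0^1 f(x) C(n,i) x^i (1-x)^(n-i) dx,

normalized over i = 1..n-1.  For sigma = 0 this yields exactly 1/i.

The diffusion is only trustworthy for weak selection (s <~ 1/N) and small
samples (n << N); the DTWF surrogate has no such restriction, which is
precisely what the baseline is here to demonstrate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln
from scipy.special import roots_legendre

__all__ = ["DiffusionParams", "diffusion_sfs_density", "diffusion_sample_sfs"]


@dataclass(frozen=True)
class DiffusionParams:
    """Scaled parameters of the equilibrium diffusion.

    ``sigma = N * s`` is derived; ``mu`` only scales the spectrum and drops
    out of the normalized SFS.
    """

    N: int
    s: float = 0.0
    mu: float = 0.0
    sigma: float = field(init=False)

    def __post_init__(self) -> None:
        if self.N < 2:
            raise ValueError("N must be >= 2")
        if self.mu < 0.0:
            raise ValueError("mu must be >= 0")
        object.__setattr__(self, "sigma", self.N * self.s)


def _shape(x: np.ndarray, sigma: float) -> np.ndarray:
    """(1 - e^{2 sigma (1-x)}) / (1 - e^{2 sigma}), the selection factor
    with gamma = -sigma (sigma > 0 means selection *against* the allele).

    Evaluated through expm1 ratios, which stay accurate down to the
    sigma -> 0 limit (1 - x); sigma exactly 0 uses the limit directly.
    """
    if sigma == 0.0:
        return 1.0 - x
    return np.expm1(2.0 * sigma * (1.0 - x)) / np.expm1(2.0 * sigma)


def diffusion_sfs_density(x, params: DiffusionParams):
    """Unnormalized equilibrium SFS density f(x) on 0 < x < 1."""
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0.0) or np.any(x >= 1.0):
        raise ValueError("x must lie strictly inside (0, 1)")
    out = _shape(x, params.sigma) / (x * (1.0 - x))
    return out if out.ndim else float(out)


def diffusion_sample_sfs(params: DiffusionParams, n: int, rtol: float = 1e-8) -> np.ndarray:
    """Normalized expected sample SFS over counts 1..n-1.

    The Binomial-mixture integrals are evaluated by Gauss-Legendre
    quadrature with the node count doubled until the normalized spectrum is
    stable to ``rtol`` in l1 (the integrand is a degree <= n polynomial
    times an entire function, so convergence is fast and certifiable).
    """
    if n < 2:
        raise ValueError("sample size must be >= 2")
    i = np.arange(1, n, dtype=float)
    log_binom = gammaln(n + 1) - gammaln(i + 1) - gammaln(n - i + 1)

    def spectrum(m: int) -> np.ndarray:
        nodes, weights = roots_legendre(m)
        x = 0.5 * (nodes + 1.0)
        w = 0.5 * weights
        # integrand_i(x) = shape(x) * C(n,i) x^(i-1) (1-x)^(n-i-1)
        logx = np.log(x)
        log1mx = np.log1p(-x)
        log_pm = log_binom[:, None] + (i[:, None] - 1.0) * logx[None, :] + (
            n - i[:, None] - 1.0
        ) * log1mx[None, :]
        vals = np.exp(log_pm) * (_shape(x, params.sigma) * w)[None, :]
        out = vals.sum(axis=1)
        return out / out.sum()

    m = max(64, n // 2 + 32)
    prev = spectrum(m)
    for _ in range(6):
        m *= 2
        cur = spectrum(m)
        if np.abs(cur - prev).sum() < rtol:
            return cur
        prev = cur
    raise RuntimeError(f"sample-SFS quadrature failed to converge at {m} nodes")
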