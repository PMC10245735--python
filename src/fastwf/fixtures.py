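"""Seeded synthetic inputs: every experiment runs from generated data.

The random test vectors copy the benchmark design used throughout the
accuracy experiments — iid Uniform(0, 1) entries normalized to sum to one —
so measured mat-vec errors are comparable in spirit across scales.  The toy
demographies are scaled-down stand-ins for human-like histories: a
constant-size population, and a bottleneck followed by smooth exponential
regrowth discretized per generation.
"""

from __future__ import annotations

import numpy as np

from .engine import ProbabilityVector
from .model import Demography

__all__ = ["random_probability_vector", "toy_demography"]


def random_probability_vector(N: int, seed: int) -> ProbabilityVector:
    """N+1 iid Uniform(0,1) entries normalized to sum to one; seed-reproducible."""
    if N < 0:
        raise ValueError("N must be >= 0")
    rng = np.random.default_rng(seed)
    u = rng.uniform(size=N + 1)
    return ProbabilityVector(u / u.sum())


def toy_demography(kind: str = "constant", N: int = 2000) -> Demography:
    """Small synthetic demographies for end-to-end runs.

    ``constant``
        A single effectively infinite epoch at size ``N`` (the population
        sits at its ancient equilibrium).
    ``bottleneck_growth``
        Ancient size 2000, a bottleneck at 400 haploids for 100
        generations, then exponential growth to 4000 over 200 generations
        (one epoch per generation).
    """
    if kind == "constant":
        return Demography(ancient_N=N)
    if kind == "bottleneck_growth":
        epochs = [(100, 400)]
        growth = np.rint(400.0 * (4000.0 / 400.0) ** (np.arange(1, 201) / 200.0))
        epochs.extend((1, int(n)) for n in growth)
        return Demography(ancient_N=2000, epochs=tuple(epochs))
    raise ValueError(f"unknown demography kind {kind!r}")
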