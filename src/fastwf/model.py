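"""Parameterization of the discrete-time Wright-Fisher (DTWF) process.

The DTWF model tracks the count of a focal allele A in a haploid population
of size ``N``.  Each generation, every one of the ``N_out`` offspring draws
its allele independently with success probability ``p(f)``, where ``f`` is
the current frequency of A among the parents and ``p`` folds in mutation
(applied first, yielding the post-mutation frequency ``f~``) and viability
selection.  A row of the transition matrix is therefore the PMF of
``Binomial(N_out, p(i / N_in))``.

Two selection modes are provided:

``diploid_additive``
    Random mating with Hardy-Weinberg genotype frequencies.  A heterozygote
    suffers a fitness reduction ``s_het`` and a homozygote ``s_hom``
    (defaulting to ``min(1, 2*s_het)``, i.e. additive with fitness floored
    at zero):

        p(f~) = [(1-s_het) f~ (1-f~) + (1-s_hom) f~^2]
                / [(1-f~)^2 + 2 (1-s_het) f~ (1-f~) + (1-s_hom) f~^2]

``haploid_genic``
    Classical genic selection with a single coefficient ``s`` (stored in
    ``s_het``):  p(f~) = (1-s) f~ / (1 - s f~).

Mutation is two-way:  f~ = f (1 - mu_back) + mu_fwd (1 - f), which reduces
to the one-way form f~ = f + mu (1 - f) when ``mu_back`` is zero.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence, Tuple

import numpy as np
import pandas as pd

logger = logging.getLogger("fastwf")

MODES = ("neutral", "haploid_genic", "diploid_additive")

__all__ = [
    "MutationSelectionModel",
    "Demography",
    "RowProbabilities",
    "frequency_after_mutation",
    "expected_offspring_frequency",
    "row_success_probabilities",
    "read_demography",
]


@dataclass(frozen=True)
class MutationSelectionModel:
    """Per-generation mutation rates and selection parameters.

    Parameters
    ----------
    mu_fwd
        Probability per generation of an a -> A mutation.
    mu_back
        Probability per generation of an A -> a mutation (may be 0).
    mode
        One of ``neutral``, ``haploid_genic``, ``diploid_additive``.
    s_het
        Fitness reduction per heterozygous copy (or the genic coefficient
        ``s`` in ``haploid_genic`` mode).  Dimensionless, in [0, 1].
    s_hom
        Fitness reduction of the A/A homozygote.  When omitted in
        ``diploid_additive`` mode it defaults to ``min(1, 2 * s_het)``,
        the additive value with fitness bounded below by zero.
    """

    mu_fwd: float = 0.0
    mu_back: float = 0.0
    mode: str = "neutral"
    s_het: float = 0.0
    s_hom: float | None = None

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode!r}; expected one of {MODES}")
        for name in ("mu_fwd", "mu_back", "s_het"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name}={value} outside [0, 1]")
        if self.s_hom is None:
            object.__setattr__(self, "s_hom", min(1.0, 2.0 * self.s_het))
        if not 0.0 <= self.s_hom <= 1.0:
            raise ValueError(f"s_hom={self.s_hom} outside [0, 1]")

    def with_selection(self, s_het: float, s_hom: float | None = None) -> "MutationSelectionModel":
        """Copy of this model with the selection coefficient(s) replaced."""
        return replace(self, s_het=s_het, s_hom=s_hom)


def frequency_after_mutation(f, model: MutationSelectionModel):
    """Post-mutation frequency f~ = f (1 - mu_back) + mu_fwd (1 - f).

    Accepts scalars or numpy arrays; the result lies in [0, 1] and equals
    ``f`` when both mutation rates are zero.
    """
    f = np.asarray(f, dtype=float)
    out = f * (1.0 - model.mu_back) + model.mu_fwd * (1.0 - f)
    return out if out.ndim else float(out)


def expected_offspring_frequency(f, model: MutationSelectionModel):
    """Expected offspring-allele frequency p(f): mutation, then selection.

    Neutral mode returns f~ unchanged.  The degenerate case of fully
    inviable carriers (zero denominator) is defined as 0 and logged.
    """
    ft = np.atleast_1d(np.asarray(frequency_after_mutation(f, model), dtype=float))
    if model.mode == "neutral":
        out = ft
    elif model.mode == "haploid_genic":
        s = model.s_het
        den = 1.0 - s * ft
        out = np.where(den > 0.0, (1.0 - s) * ft / np.where(den > 0.0, den, 1.0), 0.0)
        if np.any(den <= 0.0):
            logger.warning("degenerate haploid selection denominator (s=1, f~=1); p set to 0")
    else:  # diploid_additive
        sh, sH = model.s_het, model.s_hom
        num = (1.0 - sh) * ft * (1.0 - ft) + (1.0 - sH) * ft * ft
        den = (1.0 - ft) ** 2 + 2.0 * (1.0 - sh) * ft * (1.0 - ft) + (1.0 - sH) * ft * ft
        out = np.where(den > 0.0, num / np.where(den > 0.0, den, 1.0), 0.0)
        degenerate = den <= 0.0  # only at ft = 1 with s_hom = 1
        if np.any(degenerate):
            if sh < 1.0:
                # homozygotes inviable but heterozygotes not: in the ft -> 1
                # limit only Aa parents reproduce, transmitting A half the
                # time, so the map extends continuously (and monotonically)
                # to 1/2
                out = np.where(degenerate, 0.5, out)
            else:
                # all carriers inviable: no A allele can be transmitted
                out = np.where(degenerate, 0.0, out)
                logger.warning("fully inviable carriers (s_het=s_hom=1) at f~=1; p set to 0")
    out = np.clip(out, 0.0, 1.0)
    return out if np.asarray(f).ndim else float(out[0])


@dataclass(frozen=True)
class RowProbabilities:
    """Per-row Binomial success probabilities of one DTWF transition matrix.

    Entry ``i`` of ``ps`` is the expected offspring frequency given ``i``
    copies among ``N_in`` parents.  Entries must be non-decreasing in ``i``
    (the expected frequency next generation is non-decreasing in the current
    frequency for all standard mutation/selection models); violations raise.
    """

    N_in: int
    ps: np.ndarray

    def __post_init__(self) -> None:
        ps = np.asarray(self.ps, dtype=float)
        if ps.shape != (self.N_in + 1,):
            raise ValueError(f"expected {self.N_in + 1} probabilities, got {ps.shape}")
        if np.any(ps < 0.0) or np.any(ps > 1.0):
            raise ValueError("success probabilities outside [0, 1]")
        diffs = np.diff(ps)
        bad = np.nonzero(diffs < -1e-14)[0]
        if bad.size:
            i = int(bad[0])
            raise ValueError(
                f"success probabilities not non-decreasing: ps[{i + 1}]={ps[i + 1]!r} "
                f"< ps[{i}]={ps[i]!r}"
            )
        # absorb float dust so downstream code sees a genuinely sorted array
        object.__setattr__(self, "ps", np.maximum.accumulate(ps))


def row_success_probabilities(N_in: int, model: MutationSelectionModel) -> RowProbabilities:
    """Assemble p_i = expected_offspring_frequency(i / N_in) for i = 0..N_in."""
    if N_in < 2:
        raise ValueError("population size must be at least 2")
    f = np.arange(N_in + 1, dtype=float) / N_in
    return RowProbabilities(N_in, expected_offspring_frequency(f, model))


@dataclass(frozen=True)
class Demography:
    """Piecewise-constant population-size history.

    ``epochs`` is an ordered (oldest -> newest) sequence of
    ``(duration_in_generations, haploid_size)`` pairs; ``ancient_N`` is the
    haploid size assumed to hold at equilibrium before the first epoch.
    """

    ancient_N: int
    epochs: Tuple[Tuple[int, int], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.ancient_N < 2:
            raise ValueError("ancient_N must be >= 2")
        epochs = tuple((int(d), int(n)) for d, n in self.epochs)
        for d, n in epochs:
            if d < 0:
                raise ValueError("epoch durations must be >= 0")
            if n < 2:
                raise ValueError("all population sizes must be >= 2")
        object.__setattr__(self, "epochs", epochs)

    @property
    def total_generations(self) -> int:
        return sum(d for d, _ in self.epochs)

    def size_schedule(self) -> np.ndarray:
        """Offspring population size for each post-equilibrium generation."""
        if not self.epochs:
            return np.empty(0, dtype=np.int64)
        return np.concatenate([np.full(d, n, dtype=np.int64) for d, n in self.epochs])


def read_demography(path) -> Demography:
    """Read a two-column TSV ``duration_generations <TAB> N``.

    Epochs are ordered oldest -> newest.  A duration of ``inf`` is permitted
    only in the first row and denotes the ancient equilibrium size; if
    absent, the first (finite) epoch's size doubles as the ancient size.
    """
    table = pd.read_csv(path, sep="\t", dtype={"duration_generations": str})
    if list(table.columns) != ["duration_generations", "N"]:
        raise ValueError(
            "demography file must have header 'duration_generations\\tN', "
            f"got columns {list(table.columns)}"
        )
    durations = [d.strip() for d in table["duration_generations"]]
    sizes = [int(n) for n in table["N"]]
    if any(d == "inf" for d in durations[1:]):
        raise ValueError("a duration of 'inf' is only permitted in the first row")
    if durations and durations[0] == "inf":
        ancient = sizes[0]
        epochs = list(zip((int(float(d)) for d in durations[1:]), sizes[1:]))
    else:
        if not durations:
            raise ValueError("demography file has no epochs")
        ancient = sizes[0]
        epochs = list(zip((int(float(d)) for d in durations), sizes))
    return Demography(ancient_N=ancient, epochs=tuple(epochs))
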