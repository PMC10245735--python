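# Methods

## Model

`fastwf` works with the single-locus, biallelic, panmictic haploid DTWF
chain.  The state is the count `i ∈ {0, …, N}` of the focal allele A; one
generation maps `i` to `Binomial(N_out, p(i/N_in))`, with `N_in` the
parental and `N_out` the offspring haploid size (sizes may change between
epochs; no interpolation of the state vector is performed — the
rectangular Binomial transition is the natural DTWF reading of a size
change).

The expected offspring frequency applies mutation first,

    f~ = f (1 − mu_back) + mu_fwd (1 − f),

then selection:

* `neutral`: `p = f~`;
* `haploid_genic`: `p = (1 − s) f~ / (1 − s f~)`, `s = s_het`;
* `diploid_additive` (Hardy–Weinberg genotype frequencies, fitnesses
  `1, 1 − s_het, 1 − s_hom`):

      p = [(1−s_het) f~ (1−f~) + (1−s_hom) f~²]
          / [(1−f~)² + 2(1−s_het) f~ (1−f~) + (1−s_hom) f~²].

  When constructed from `s_het` alone, `s_hom = min(1, 2·s_het)` —
  additive with fitness floored at zero.  Degenerate corner: at `f~ = 1`
  with `s_hom = 1` the ratio is 0/0; if `s_het < 1` only heterozygotes
  reproduce and the map extends continuously (and monotonically) to 1/2,
  while with `s_het = s_hom = 1` no carrier can reproduce and `p = 0`.

All implemented maps make `p(f)` non-decreasing in `f`; the row container
validates this (it is the assumption that lets the linear-time block
assignment work) and raises on the first violating index rather than
silently reordering.

## The surrogate transition matrix

**Sparsification.**  Each retained row is windowed to
`mean ± ⌈√((N_out/2)·ln(2/tol))⌉` (Hoeffding's bound, valid for every
success probability, hence a constructive guarantee) and the window is
renormalized.  The `ℓ1` distance between a windowed row and the exact PMF
is at most `2·tol/(1 − tol)`; in practice the Hoeffding bound is loose
and realized gaps are orders of magnitude below `tol`.  Default
`tol = 10⁻⁸`.  Rows with `p ∈ {0, 1}` are exact point masses and are
never altered: they are the absorbing boundary and approximating them
would corrupt fixation probabilities.

**Blocking.**  Rows are grouped by a single greedy left-to-right pass:
a block anchored at probability `p_a` accepts row `i` while
`p_i ≤ p_a + c_ε·√(p_a(1−p_a)/N_out)`; boundary rows `p ∈ {0, 1}` are
forced singletons.  The anchor-based threshold makes the pass one-shot,
deterministic, and `O(N)`.  With `c_ε = 0.1`, block counts grow like
`√N` (≈ 31·√N for a neutral chain, confirmed empirically by the ratio of
counts at N and 4N).

**Moment matching.**  Given the vector `v` being multiplied, the
representative probability of a block is the `v`-weighted mean of its
member probabilities (anchor probability when the block carries no
weight), so the surrogate preserves `Σ_i v_i · N_out · p_i` — the
expected next-generation count — exactly.  Blocks depend only on the row
probabilities and `N_out` and are cached; representatives are recomputed
from the current vector every generation (they are cheap).

**Sampling matrix.**  The Hypergeometric population→sample matrix is
treated identically, with two differences: the block rule standardizes
the *mean sample count* shift by the Hypergeometric standard deviation
`√(n·(K/N)(1−K/N)·(N−n)/(N−1))` with `c_ε = 0.05`, and the representative
is a two-point mixture of the integer counts bracketing the v-weighted
mean `K̄` (`K1 = ⌊K̄⌋`, `K2 = ⌈K̄⌉`, weight `K2 − K̄` on `K1`), because the
Hypergeometric "success parameter" is an integer and exact mean matching
needs the mixture.  When no block merges more than two rows the mixture
weights reproduce the member weights identically and the product is
exact up to sparsification; at `N = 2000, n = 1000` this regime holds
and the measured gap is at float precision.  The Hoeffding radius is
applied unchanged (Hoeffding's inequality covers sampling without
replacement); finite-population corrections to the radius would only
shrink windows and were not pursued.

## Equilibria

The full chain (both mutation rates positive) has a stationary law
solved either densely — via the rank-one-shifted system
`(M^T − I + 𝟙𝟙^T) v = 𝟙`, which encodes normalization without singling
out a state, so structural symmetries of the chain survive floating
point — or through the condensed **meta-state chain**: each block is one
meta-state, the transition probability between meta-states is the mass
of the representative row landing in the target block, the small chain
is solved densely, and the meta-state masses are expanded through the
representative PMF rows.  Because representatives are moment-matched
against the (unknown) equilibrium, the construction iterates from
uniform within-block weights to a fixed point (TV change `< 10⁻¹⁰`, cap
100 iterations; convergence is typically reached in well under ten
because the representative can only move within its narrow block range).
At the fixed point the expanded vector is exactly stationary for the
surrogate operator, so one further generation of evolution moves it by
less than the fixed-point tolerance.

**Conditioning on non-fixation.**  With one-way mutation the only true
equilibrium is fixation, so the derived-allele SFS is grounded in the
chain *conditioned on not having fixed*: the fixation column is deleted
(rows become sub-stochastic; the deficit is the one-step fixation
probability) and the conditioned law at each generation is the
propagated vector renormalized.  The long-run conditioned equilibrium is
the quasi-stationary distribution — the left Perron eigenvector of the
killed chain — computed by inverse iteration with shift `1 + 10⁻⁸`.  The
small shift keeps the system comfortably nonsingular even when the
per-generation fixation flux underflows (under strong selection the
Perron eigenvalue is within `10⁻²⁰` of one), while the wide gap to the
subdominant spectrum makes the iteration converge in a few steps.  The
condensed path uses the same construction on the sub-stochastic
meta-state chain.  Row-by-row renormalization of the killed chain — the
other defensible reading of "ignoring fixation" — yields a different
equilibrium that substantially over-weights high frequencies; the
quasi-stationary reading is the standard probabilistic meaning of
conditioning on survival and is the one whose neutral SFS agrees with
the diffusion limit, so it is the one implemented.

## Diffusion baseline

The comparison baseline is the Poisson-Random-Field equilibrium density
for genic selection,

    f(x) ∝ (1 − e^{2σ(1−x)}) / ((1 − e^{2σ}) · x (1 − x)),   σ = N·s,

with `s` a fitness *reduction* (the deleterious classical form; the
neutral `σ → 0` limit is `1/x`).  The factor is evaluated through
`expm1` ratios, which are accurate uniformly in `σ` down to the limit,
so no small-`σ` series switch is needed; `σ = 0` uses the `1/x` limit
directly.  The expected sample SFS mixes Binomial sampling over the
density and is normalized over counts `1..n−1`; the integrals use
Gauss–Legendre quadrature with the node count doubled until the
normalized spectrum is `ℓ1`-stable to `10⁻⁸` (the integrand is a
polynomial of degree `≤ n` times an entire function, so convergence is
certifiable).  For `σ = 0` the quadrature is exact and returns `1/i` to
float precision.

The diffusion is trusted only for `s ≲ 1/N` and `n ≪ N`.  In that regime
it agrees with the exact DTWF spectrum to TV ≈ 2×10⁻⁴ (N = 2000,
n = 20); under `s = 0.01` at `n = 200`, or neutrally at `n = N = 2000`,
it is hundreds to thousands of times less accurate than the surrogate —
which is the point of the comparison.

## Fisher information

Sample-count likelihood curves `P(k | s_het)` come from the conditioned
equilibrium at the ancient size, conditioned evolution through the
epochs, and Hypergeometric sampling of `2n` haploid draws for `n`
diploids.  Fisher information is computed in the `log₁₀ s_het`
parameterization by central differences of the log-likelihoods, default
step 0.05 log₁₀ units — small enough that truncation error is below the
`~10⁻⁸` accuracy of the likelihoods, large enough that float noise does
not dominate the quotient.  Outcomes with zero probability at any of the
three grid points are excluded (they carry no mass at `s₀` or have an
undefined score).  Infinite symmetrized KL between spectra with
mismatched support is reported as `+inf` rather than clipped; reports
fall back to TV in that case.

## Synthetic data

The generator produces (i) seeded random probability vectors — iid
Uniform(0,1) entries normalized to sum to one, the same design used for
all mat-vec error benchmarks, so measured errors are comparable across
scales — and (ii) toy demographies: a constant population of 2000
haploids, and a bottleneck–growth history (ancient 2000; 100 generations
at 400; exponential regrowth to 4000 over 200 single-generation epochs).
These emulate the *shapes* of human-like histories at desk scale; they do
not reproduce any published demography's parameter values, so tests
passing on them demonstrate correctness of the machinery, not agreement
with any particular empirical population.  Uniform random vectors are an
average-case probe: worst-case error over adversarial vectors is bounded
by the theory but not measured here.

## Problem sizes and defaults

All validation runs use populations up to `N = 2000` (where the dense
`O(N²)` oracle and dense stationary solves are comfortable), 20-seed
vector batteries at `N ∈ {50, 200, 1000}`, 1000-generation transition
mass functions, and block-count scaling probes at `N ∈ {10⁴, 4·10⁴}`.
The dense oracle paths are guarded at `N ≤ 20000` and raise beyond it,
directing callers to the linear-time path, which has no such limit.

## Known limitations

* Single locus, two alleles, one panmictic population; no
  time-series/HMM machinery and no gradients of likelihoods.
* Biased sampling is supported only *with* replacement (one extra
  selection-like DTWF generation); biased sampling without replacement is
  out of scope.
* The quasi-stationary conditioning and the diffusion sign convention are
  the package's resolutions of genuinely underdetermined construction
  details; both are documented above and isolated behind their module
  surfaces.
* The meta-state equilibrium's fixed-point iteration is a heuristic
  self-consistency device; it has always converged well inside the
  100-iteration cap in testing, but no global convergence proof is
  claimed, and non-convergence raises with the TV trace.
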