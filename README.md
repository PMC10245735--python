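# fastwf

Linear-time allele-frequency likelihoods under the discrete-time
Wright–Fisher (DTWF) model.

## The problem

The DTWF model is the canonical forward-in-time description of how the
frequency of an allele evolves in a finite population under genetic drift,
mutation, and selection: given `i` copies among `N` haploid parents, the
number of copies among the `N'` offspring is `Binomial(N', p(i/N))`, where
`p(f)` folds mutation and selection into the expected offspring frequency.
Computing the likelihood of observing a given allele count — the key
ingredient of site-frequency-spectrum (SFS) inference of demography and
selection — reduces to repeated transpose matrix–vector products
`v_t = M_{t-1}^T v_{t-1}` with the `(N+1)×(N+1)` transition matrix, an
`O(N²)` operation that does not scale to modern effective population
sizes.  The usual escape hatch, the Wright–Fisher diffusion, breaks down
exactly where modern data live: large samples (`n ≳ √N`) and strong
selection (`s ≫ 1/N`), the regime of loss-of-function (LoF) variants in
biobank-scale exomes.

## The method

`fastwf` replaces each transition matrix `M` by a surrogate `M̃` that is
provably close in the 1-operator norm (so `‖M^T v − M̃^T v‖₁` is bounded)
and admits mat-vecs in time linear in `N`, using two structural facts
about Binomial rows:

* **approximate sparsity** — by Hoeffding's inequality, all but
  `O(√N)` entries around the row mean (radius
  `⌈√((N/2)·ln(2/ε))⌉`, ≈ `4.33√N` at `ε = 10⁻¹⁶`) carry negligible mass;
  each row is windowed and renormalized;
* **approximate low rank** — Binomials whose success probabilities differ
  by less than `c_ε·√(p(1−p)/N)` are nearly identical in total variation,
  so a greedy pass groups the (sorted) rows into `O(√N)` blocks sharing a
  single representative row.  Representatives are **moment-matched**:
  `p̃ = Σ p_ℓ v_ℓ / Σ v_ℓ` over the block, which preserves the expected
  next-generation frequency exactly and prevents drift-like bias over long
  time scales.

The same construction applies to the Hypergeometric population→sample
matrix `S` (`v_sample = S^T v`), with a two-point mixture of integer-count
rows as the block representative; when no block merges more than two rows
the fast product is exact up to the sparsification budget.

On top of the fast mat-vec the package provides: transition mass
functions, equilibria via a condensed meta-state chain (with the
equilibrium recovered by expanding meta-state masses through the
representative rows and iterating the moment-matching weights to a fixed
point), equilibria conditioned on non-fixation (quasi-stationary
distributions, giving a well-defined derived-allele SFS under recurrent
one-way mutation), sample-count likelihood curves over selection
coefficients, Fisher information for `log₁₀ s_het`, and a closed-form
Wright–Fisher diffusion equilibrium SFS as the comparison baseline.
Dense `O(N²)` oracle paths back every fast path for validation.

Default hyperparameters: `c_ε = 0.1` (transition), `c_ε = 0.05`
(sampling), row sparsification tolerance `10⁻⁸`.

## Worked example

Selection against a LoF variant (`s_het = 0.01`, additive diploid model,
CpG-scale mutation rate `1.25×10⁻⁷`) in a constant population of 2000
haploids, sampled as 100 diploids:

```python
import numpy as np
import fastwf as fw

model = fw.MutationSelectionModel(mu_fwd=1.25e-7, mode="diploid_additive", s_het=0.01)
veq = fw.equilibrium_conditional_nonfixed(2000, model, "approx")
v_pop = np.append(veq.mass, 0.0)          # fixation state carries no mass
v_sample = fw.sample_likelihood(v_pop, 200, "approx")   # 2n = 200 haploid draws
print(fw.probability_segregating(v_sample))
print(v_sample.mass[:5])
```

prints

```
0.0009069960973097091
[9.990930e-01 4.223250e-04 1.746384e-04 9.731949e-05 6.097277e-05]
```

i.e. a site with this mutation rate and selection coefficient is
segregating in the sample with probability ≈ 9.1×10⁻⁴, is monomorphic
ancestral with probability 0.9991, a singleton with probability
4.2×10⁻⁴, and so on — the raw ingredients of LoF selection inference.
The neutral normalized SFS reproduces the classical `1/i` shape:

```python
fw.normalized_sfs(2000, fw.MutationSelectionModel(mu_fwd=1.25e-8), 20, "approx")[:5]
# array([0.2819, 0.1409, 0.094 , 0.0705, 0.0564])
```

A thin CLI mirrors the library (`fastwf likelihood`, `fastwf sfs`,
`fastwf tmf`, `fastwf fisher`, `fastwf compare-sfs`, `fastwf fixtures`);
run `fastwf --help`.

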