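# Methods

## Model and estimator

The estimator targets the correlation structure of log absolute abundances
(`log x_i`) of `D` community components observed only through compositional
counts. Its identity is the decomposition of the log-ratio variance

    t_ij = Var[log(x_i/x_j)] = w_i² + w_j² − 2 ρ_ij w_i w_j

with `w_i² = Var[log x_i]`. `t_ij` is estimated from fractions with the
unbiased (S−1) sample variance across samples; it is subcompositionally
coherent (dropping or adding other components does not move it) and
invariant to per-sample rescaling of counts, which is what makes it usable
on closed data.

**Assumptions.** (1) Sparsity: the *average* correlation involving each
component is small — individual pairs may be strongly correlated. (2) All
components are present in every sample; zeros are treated as detection
limits and handled by the Dirichlet prior (structural zeros are out of
scope, and very rare components should be filtered out before analysis
because their correlations are not estimable anyway). (3) The correlation
recovered is linear dependence of *log* abundances; no distributional
assumption is made beyond the existence of log-variances.

**Variance solve.** Neglecting correlation terms in the component
variation `t_i = Σ_{j≠i} t_ij` gives the linear system
`(D−2) w_i² + Σ_j w_j² = t_i`. With excluded pairs, the coefficient of
`w_i²` is the number of `i`'s included pairs and only included partners
contribute their variances; this form follows from dropping the excluded
terms of the decomposition symmetrically, and every solve is verified by a
residual check (tolerance 1e-8 relative to the right-hand side). The system
needs `D ≥ 4`: for `D ≤ 3` the pairwise equations can always be satisfied
exactly by an independent basis, so dependence is undetectable.

**Degenerate outcomes.** The approximation can produce nonpositive
variance solutions; these are clamped to 1e-10 with a logged warning.
Recovered correlations outside [−1, 1] (a symptom of excluding too many
pairs) are clipped to the boundary and the affected pairs are reported.
An exclusion pattern can make the variance system exactly singular at small
`D` (e.g. two disjoint excluded pairs at `D = 4`); the iterative loop then
rolls back the offending round and stops refining rather than failing the
whole run, since that state already signals the sparsity assumption has
collapsed.

**Iterative exclusion.** Default threshold 0.1 and at most 10 exclusion
rounds. Ties for the strongest pair are broken by the lexicographically
smallest index pair, making runs reproducible. A component whose every
pair is excluded is removed outright: its correlations are reported as NaN,
never fabricated, and the remaining fractions are renormalized over the
surviving subset (the current posterior draw is renormalized, not redrawn).
If fewer than four components survive, refinement stops.

**Resampling.** Fractions come from each sample's Dirichlet posterior
under a uniform prior, `Dir(n+1)`; the point-estimate alternative is the
posterior mean `(n_i+1)/(N+D)`. The full estimator aggregates 100 posterior
draws by the per-pair median, ignoring draws where a pair was undefined; a
pair undefined in more than half the draws stays undefined. The per-pair
inter-quartile range across draws is returned as a robustness diagnostic.
All draws derive from one seeded generator via spawned substreams.

## Significance

Null tables are built by resampling each component's counts across samples
with replacement, which preserves per-component marginals and destroys all
cross-component dependence. The same estimator configuration is run on each
null table and two-sided pseudo p-values are computed on magnitude with the
add-one correction `p = (1 + k)/(n_null + 1)`, so the attainable minimum is
`1/(n_null+1)` and p-values are never zero.

## Synthetic communities

The generator draws per-sample log abundances from a multivariate normal
with covariance `σ²·C`, `σ² = 1` by default. `C` starts as the identity,
each pair is independently planted at ±1 (equal signs) with probability
`density_p`, and the matrix is projected to the Frobenius-nearest
positive-definite correlation matrix (eigenvalue floor 1e-6; the
projection softens planted pairs to magnitudes around 0.3–0.9, and the
*post-projection* matrix is the ground truth estimators are scored
against). Community dominance is controlled by raising component 1's mean
log abundance until the mean Shannon effective number of species (ENS,
`exp H`) of the exact fractions matches a target within 2%, via bisection
on a fixed set of 400 tuning draws. Counts are a multinomial draw of
`depth` reads per sample from the exact fractions — the canonical
closure-inducing observation model, and the one that makes the Dirichlet
posterior well-posed.

Defaults are 50 components, 500 samples, depth 2000 reads/sample, unit log
variance. With `σ² = 1` and `D = 50` the attainable mean ENS tops out near
32 (log-normal spread alone creates dominance), so feasible diversity
targets are roughly 1–30 and the benchmark grid uses ENS {2, 5, 10, 25};
infeasible targets raise an error rather than silently undershooting.

What the generator does *not* emulate: structural zeros and
presence/absence patterns, taxon-specific read biases, variable library
sizes, overdispersion beyond multinomial, and phylogenetic correlation of
abundances. Passing benchmarks therefore demonstrate correct recovery under
the stated generative model, not performance guarantees on real surveys.

## Diversity estimators

Natural logarithms throughout. The plug-in estimator is `−Σ p_i log p_i`
on normalized abundances; Chao-Shen adjusts count data for unseen species
via Good-Turing coverage `C = 1 − f₁/n` and a Horvitz-Thompson correction
`H = −Σ C p̂_i log(C p̂_i) / (1 − (1 − C p̂_i)^n)`. Chao-Shen requires
integer counts and is undefined when every individual is a singleton
(estimated coverage zero) — that case raises.

## Benchmark and evaluation

Accuracy is RMSE over unordered pairs, excluding undefined entries
pairwise. Spearman estimates are scored against the true basis *Spearman*
correlations, obtained from the planted Pearson matrix through the normal
rank relation `ρ_s = (6/π)·asin(ρ/2)`. Network agreement uses edge sets at
a magnitude cutoff (0.3 by default, the value used for all exported edge
lists). The sweep derives one seed per repeat from a root seed, simulates a
fresh community, and scores all methods on the same table; failed repeats
are logged and excluded with counts reported.

## Problem sizes

The test suite and benchmark defaults run at 100 samples, 10–20 repeats
per cell and 20 posterior resamples, which reproduces the method's
qualitative behavior in minutes on one core; 500 samples, 50 repeats and
100 resamples are the full-scale settings, reachable through the same
flags. One scale effect is worth knowing: the null distribution of a
sample correlation has spread ~1/√S, so the *maximum* |ρ| over all pairs of
a 50-component independent dataset sits near 0.3 at S = 100 but near 0.1 at
S = 500 — shuffled-data network claims at the 0.3 cutoff are clear-cut only
at survey-scale sample counts.

## Known limitations

- Correlations of fully excluded components are undefined, not estimated;
  dense correlation structures (high planted density, a shared dominant
  factor) violate sparsity and degrade the approximation for everyone.
- The estimator measures linear log-abundance dependence only.
- p-values are not corrected for multiple testing; downstream FDR control
  is the caller's choice.
- Absolute-scale variances `w²` are identified only through the sparsity
  approximation; treat them as diagnostics, not measurements.
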