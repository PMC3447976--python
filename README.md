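# sparcc

Inference of correlations between the *absolute* (basis) abundances of
community members from relative-abundance survey data, such as 16S rRNA OTU
count tables.

## The problem

Sequencing surveys are compositional: a sample's counts carry only relative
information, because the library size is an artifact of the instrument, not
of the community. Normalizing counts to fractions forces them to sum to one,
which induces spurious dependence — in a two-species community the fractions
are *always* perfectly anti-correlated regardless of how the species
actually covary, and in low-diversity communities standard Pearson or
Spearman correlations between fractions are dominated by this closure
artifact rather than by real interactions.

## The method

Let `x_i` denote the (unobserved) absolute abundance of component `i`,
`w_i² = Var[log x_i]` and `ρ_ij` the correlation of the log abundances. The
log-ratio variance between two components,

```
t_ij = Var[ log(x_i / x_j) ] = w_i² + w_j² − 2 ρ_ij w_i w_j,
```

is observable from fractions alone (the library size cancels inside the
ratio) and is invariant to which other components are in the table. The
pairwise system is underdetermined, but if most pairs are *sparsely*
correlated, the correlation terms in the per-component variation
`t_i = Σ_j t_ij` are negligible, leaving a linear system

```
(D − 2) w_i² + Σ_j w_j² = t_i ,   i = 1..D
```

for the basis variances, which are then plugged back in to recover every
`ρ_ij = (w_i² + w_j² − t_ij) / (2 w_i w_j)`. At least four components are
required — with three or fewer, any pairwise variation pattern is exactly
explained by independent components. Two refinements complete the
estimator:

- **Iterative exclusion** — the single most strongly correlated pair is
  repeatedly removed from the variance estimation (not from the output)
  until no remaining pair exceeds a threshold (default 0.1, max 10 rounds),
  protecting the sparsity approximation from a few strong true correlations.
- **Posterior resampling** — fractions are not point estimates but random
  draws from each sample's Dirichlet posterior `Dir(n + 1)` given its
  counts; the procedure is repeated (default 100 draws) and each pair's
  median correlation is reported, which propagates sequencing-depth noise
  and avoids spurious correlations among rare taxa.

The package also provides bootstrap pseudo p-values against a
column-shuffled null, plug-in and Chao-Shen effective-diversity estimators,
baseline estimators (Pearson, Spearman, CLR) for comparison, a synthetic
community simulator with a planted correlation network, and an accuracy
benchmark crossing network density with community diversity.

## Worked example

```python
import numpy as np
from sparcc import (SimulationSpec, simulate_dataset, sparcc_estimate,
                    posterior_mean_fractions, baseline_correlations, rmse,
                    mean_effective_diversity)

spec = SimulationSpec(n_components=50, n_samples=100, density_p=0.1,
                      target_ens=5.0, depth=2000, seed=7)
table, truth = simulate_dataset(spec)
print("mean ENS:", round(mean_effective_diversity(table), 2))

res = sparcc_estimate(table, n_resamples=100, rng=7)
pear = baseline_correlations(posterior_mean_fractions(table), "pearson")
print("SparCC RMSE :", round(rmse(truth, res.correlations), 3))
print("Pearson RMSE:", round(rmse(truth, pear), 3))
```

prints

```
mean ENS: 4.59
SparCC RMSE : 0.113
Pearson RMSE: 0.227
```

i.e. for a 50-taxon community dominated enough to have an effective number
of species of about 5 — the regime typical of real body-site surveys, and
the one where closure artifacts are worst — SparCC halves the
root-mean-squared error of the recovered correlation network relative to
Pearson correlations computed on the fractions. At the 0.3 edge cutoff this
run yields 57 SparCC edges versus 228 Pearson edges against 142 true ones:
the Pearson network is swamped by closure-induced false edges.

The same pipeline is available from the shell:

```
sparcc simulate --components 50 --samples 100 --density 0.1 --ens 5 --seed 7 --out-prefix sim
sparcc corr --input sim.counts.tsv --method sparcc --seed 7 --out-prefix run
sparcc pvals --input sim.counts.tsv --nulls 100 --seed 7 --out-prefix run
```

writing the correlation matrix, an edge list thresholded at `|ρ| > 0.3`, a
GraphML network and a reproducibility manifest beside each output.

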