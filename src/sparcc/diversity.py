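"""Shannon entropy and the effective number of species (ENS).

ENS = exp(H) is the number of equally abundant components that would give
the same Shannon entropy H; it captures both richness and dominance.
Natural logarithms are used throughout — the exponential in the effective
number requires a consistent base.

Two entropy estimators are provided: the plug-in estimator on normalized
abundances, and the Chao-Shen coverage-adjusted estimator for count data,
which corrects the plug-in's downward bias under incomplete sampling by
combining a Good-Turing coverage estimate (C = 1 - singletons/total) with a
Horvitz-Thompson correction for unseen species.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .tables import CountTable, FractionTable

__all__ = ["DiversityResult", "effective_diversity", "mean_effective_diversity"]


@dataclass
class DiversityResult:
    entropy: float  # nats
    effective_n: float  # exp(entropy)


def _plugin_entropy(x: np.ndarray) -> float:
    p = x / x.sum()
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def _chao_shen_entropy(x: np.ndarray) -> float:
    if not np.allclose(x, np.rint(x)):
        raise ValueError("chao_shen requires integer counts")
    counts = np.rint(x).astype(np.int64)
    counts = counts[counts > 0]
    n = int(counts.sum())
    f1 = int((counts == 1).sum())
    if f1 == n:
        raise ValueError(
            "chao_shen undefined when every individual is a singleton "
            "(estimated coverage is zero)"
        )
    coverage = 1.0 - f1 / n
    p_adj = coverage * counts / n
    h_terms = -p_adj * np.log(p_adj) / (1.0 - (1.0 - p_adj) ** n)
    return float(h_terms.sum())


def effective_diversity(abundances, estimator: str = "plugin") -> DiversityResult:
    """Entropy and effective number of components of one abundance vector.

    ``plugin`` accepts any nonnegative abundances (invariant to rescaling);
    ``chao_shen`` requires integer counts and adjusts for unsampled species.
    """
    x = np.asarray(abundances, dtype=float).ravel()
    if x.size == 0 or (x < 0).any() or not (x > 0).any():
        raise ValueError("need a vector with at least one positive entry")
    if estimator == "plugin":
        h = _plugin_entropy(x)
    elif estimator == "chao_shen":
        h = _chao_shen_entropy(x)
    else:
        raise ValueError(f"unknown estimator: {estimator!r}")
    return DiversityResult(entropy=h, effective_n=float(np.exp(h)))


def mean_effective_diversity(table, estimator: str = "plugin") -> float:
    """Arithmetic mean of per-sample effective diversities.

    Accepts a CountTable, FractionTable or a plain samples x components
    array.
    """
    if isinstance(table, CountTable):
        mat = table.counts
    elif isinstance(table, FractionTable):
        mat = table.fractions
    else:
        mat = np.asarray(table, dtype=float)
    if mat.ndim != 2:
        raise ValueError("expected a samples x components matrix")
    ens = [effective_diversity(row, estimator).effective_n for row in mat]
    return float(np.mean(ens))
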