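"""Shuffled-null generation and bootstrap pseudo p-values.

The null model destroys cross-component dependence while preserving each
component's marginal count distribution: every cell for component ``j`` is
redrawn uniformly, with replacement, from component ``j``'s observed counts
across samples. Running the *same* estimator on many such null tables gives
an empirical null distribution for every pairwise correlation.
"""

from __future__ import annotations

import numpy as np

from .core import CorrelationMatrix, EstimatorConfig, estimate_correlations
from .tables import CountTable

__all__ = ["PValueMatrix", "shuffle_counts", "pseudo_pvalues"]


class PValueMatrix:
    """Symmetric matrix of pseudo p-values in (0, 1]; NaN diagonal."""

    def __init__(self, p: np.ndarray):
        p = np.asarray(p, dtype=float)
        if p.ndim != 2 or p.shape[0] != p.shape[1]:
            raise ValueError("p-value matrix must be square")
        off = p[~np.eye(p.shape[0], dtype=bool)]
        finite = off[np.isfinite(off)]
        if finite.size and ((finite <= 0).any() or (finite > 1).any()):
            raise ValueError("p-values must lie in (0, 1]")
        self.p = p

    @property
    def n_components(self) -> int:
        return self.p.shape[0]


def shuffle_counts(table: CountTable, rng: np.random.Generator) -> CountTable:
    """Bootstrap-shuffle each component's counts across samples.

    For each component independently, every sample's count is drawn with
    replacement from that component's observed column, so per-component
    marginals are preserved in expectation and all cross-component
    dependence is destroyed.
    """
    if table.n_samples < 2:
        raise ValueError("shuffling needs at least 2 samples")
    counts = table.counts
    S = counts.shape[0]
    shuffled = np.empty_like(counts)
    for j in range(counts.shape[1]):
        shuffled[:, j] = rng.choice(counts[:, j], size=S, replace=True)
    return CountTable(
        shuffled,
        sample_ids=list(table.sample_ids),
        component_ids=list(table.component_ids),
        taxonomy=table.taxonomy,
    )


def pseudo_pvalues(
    observed: CorrelationMatrix,
    table: CountTable,
    n_null: int = 100,
    estimator_config: EstimatorConfig | None = None,
    rng: np.random.Generator | int | None = None,
) -> PValueMatrix:
    """Two-sided bootstrap pseudo p-values for observed correlations.

    Generates ``n_null`` shuffled tables, reruns the estimator that produced
    ``observed`` on each, and sets

        p_ij = (1 + #{null sets with |rho_null| >= |rho_obs|}) / (n_null + 1).

    The add-one correction keeps p-values strictly positive (the attainable
    minimum is ``1/(n_null + 1)``). Undefined null entries never count as
    exceedances. A null set on which the estimator fails is redrawn once;
    a second failure propagates.
    """
    if n_null < 1:
        raise ValueError("n_null must be >= 1")
    rng = np.random.default_rng(rng)
    estimator_config = estimator_config or EstimatorConfig()
    obs = np.abs(observed.rho)
    D = obs.shape[0]
    if D != table.n_components:
        raise ValueError("observed matrix does not match the count table")
    exceed = np.zeros((D, D), dtype=int)
    for _ in range(n_null):
        for attempt in range(2):
            null_table = shuffle_counts(table, rng)
            try:
                null_corr = estimate_correlations(null_table, estimator_config, rng)
                break
            except Exception:
                if attempt == 1:
                    raise
        with np.errstate(invalid="ignore"):
            exceed += np.abs(null_corr.rho) >= obs
    p = (1.0 + exceed) / (n_null + 1.0)
    p = 0.5 * (p + p.T)
    np.fill_diagonal(p, np.nan)
    p[~np.isfinite(obs)] = np.nan
    np.fill_diagonal(p, np.nan)
    return PValueMatrix(p)
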