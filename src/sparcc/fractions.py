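"""Dirichlet posterior estimation of component fractions from counts.

Observed counts are a multinomial draw from the sample's true fractions.
With a uniform Dirichlet prior the posterior over fractions given counts
``(n_1, ..., n_D)`` is Dirichlet with concentration ``(n_1 + 1, ..., n_D + 1)``.
The posterior mean is the classical add-one pseudocount estimate
``(n_i + 1) / (N + D)``; random posterior draws are used for resampling, which
both removes zeros and propagates sequencing-depth noise into downstream
correlation estimates.
"""

from __future__ import annotations

import numpy as np

from .tables import CountTable, FractionTable

__all__ = ["posterior_mean_fractions", "sample_posterior_fractions"]


def posterior_mean_fractions(table: CountTable) -> FractionTable:
    """Posterior-mean (add-one pseudocount) fraction estimates.

    Every entry is strictly positive even for zero counts; an all-zero
    sample gets the uniform prior mean ``1/D``.
    """
    counts = table.counts
    if counts.size == 0:
        raise ValueError("empty count table")
    D = counts.shape[1]
    pseudo = counts + 1.0
    frac = pseudo / pseudo.sum(axis=1, keepdims=True)
    frac = frac / frac.sum(axis=1, keepdims=True)
    return FractionTable(frac, list(table.sample_ids), list(table.component_ids))


def sample_posterior_fractions(
    table: CountTable, rng: np.random.Generator
) -> FractionTable:
    """One random draw of each sample's fractions from its Dirichlet posterior.

    Rows are drawn independently from ``Dirichlet(n + 1)``; the result is
    strictly positive and deterministic for a given generator state.
    """
    counts = table.counts
    if counts.size == 0:
        raise ValueError("empty count table")
    alpha = counts + 1.0
    frac = np.empty(counts.shape, dtype=float)
    for i in range(counts.shape[0]):
        frac[i] = rng.dirichlet(alpha[i])
    # Guard against zero underflow in extreme draws so logs stay finite.
    tiny = np.finfo(float).tiny
    np.clip(frac, tiny, None, out=frac)
    frac /= frac.sum(axis=1, keepdims=True)
    return FractionTable(frac, list(table.sample_ids), list(table.component_ids))
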