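"""Estimator accuracy metrics and the density x diversity benchmark.

Accuracy against a known truth is the root-mean-squared error over
unordered component pairs; network-level agreement between two thresholded
correlation networks is summarized by a confusion table over pairs. The
benchmark sweep crosses correlation-network density with community
diversity, simulating fresh communities per cell and scoring each
configured estimator against the planted truth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import (
    CorrelationMatrix,
    baseline_correlations,
    sparcc_estimate,
)
from .fractions import posterior_mean_fractions
from .simulate import SimulationSpec, simulate_dataset, with_seed

__all__ = [
    "ConfusionCounts",
    "rmse",
    "network_confusion",
    "spearman_from_pearson",
    "benchmark_sweep",
]

logger = logging.getLogger(__name__)


@dataclass
class ConfusionCounts:
    """Pairwise edge confusion between a reference and a test network."""

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def false_discovery_fraction(self) -> float:
        return self.fp / (self.tp + self.fp) if (self.tp + self.fp) else float("nan")

    @property
    def miss_fraction(self) -> float:
        return self.fn / (self.tp + self.fn) if (self.tp + self.fn) else float("nan")

    @property
    def total_pairs(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def _rho(m) -> np.ndarray:
    return np.asarray(getattr(m, "rho", m), dtype=float)


def rmse(true_corr, est_corr) -> float:
    """Root-mean-squared error over unordered pairs i < j.

    Pairs undefined (NaN) in either matrix are excluded pairwise; it is an
    error if no comparable pair remains.
    """
    t, e = _rho(true_corr), _rho(est_corr)
    if t.shape != e.shape:
        raise ValueError("correlation matrices must have the same shape")
    iu = np.triu_indices(t.shape[0], k=1)
    dt, de = t[iu], e[iu]
    ok = np.isfinite(dt) & np.isfinite(de)
    if not ok.any():
        raise ValueError("no comparable pairs (all entries undefined)")
    return float(np.sqrt(np.mean((dt[ok] - de[ok]) ** 2)))


def network_confusion(reference, test, cutoff: float = 0.3) -> ConfusionCounts:
    """Edge confusion counts between two thresholded networks.

    A pair is an edge iff its correlation magnitude exceeds ``cutoff``;
    undefined entries never form edges.
    """
    r, t = _rho(reference), _rho(test)
    if r.shape != t.shape:
        raise ValueError("correlation matrices must have the same shape")
    iu = np.triu_indices(r.shape[0], k=1)
    with np.errstate(invalid="ignore"):
        ref_edge = np.abs(r[iu]) > cutoff
        test_edge = np.abs(t[iu]) > cutoff
    ref_edge &= np.isfinite(r[iu])
    test_edge &= np.isfinite(t[iu])
    return ConfusionCounts(
        tp=int((ref_edge & test_edge).sum()),
        fp=int((~ref_edge & test_edge).sum()),
        tn=int((~ref_edge & ~test_edge).sum()),
        fn=int((ref_edge & ~test_edge).sum()),
    )


def spearman_from_pearson(rho: np.ndarray) -> np.ndarray:
    """Population Spearman correlation of a bivariate normal from Pearson rho.

    For jointly normal variables rank correlation relates to linear
    correlation by ``rho_s = (6 / pi) * arcsin(rho / 2)``; used to score
    Spearman estimates against the planted (normal log-basis) truth.
    """
    return (6.0 / np.pi) * np.arcsin(np.asarray(rho, dtype=float) / 2.0)


def _estimate_for_method(table, method, n_resamples, exclusion_threshold,
                         max_iterations, rng) -> CorrelationMatrix:
    if method == "sparcc":
        return sparcc_estimate(
            table,
            n_resamples=n_resamples,
            exclusion_threshold=exclusion_threshold,
            max_iterations=max_iterations,
            rng=rng,
        ).correlations
    return baseline_correlations(posterior_mean_fractions(table), method)


def benchmark_sweep(
    densities,
    ens_targets,
    n_repeats: int = 10,
    methods=("sparcc", "pearson"),
    base_spec: SimulationSpec | None = None,
    n_resamples: int = 20,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean RMSE of each estimator across a density x diversity grid.

    For every (density, ens) cell, ``n_repeats`` communities are simulated
    with independently derived seeds and every method is scored on the same
    tables. Spearman estimates are compared to the true basis *Spearman*
    correlations (Pearson truth mapped through the normal rank relation).
    Returns a long-format frame with columns density, ens, method,
    mean_rmse, sd_rmse, n; failed repeats are logged and excluded.
    """
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    base = base_spec or SimulationSpec()
    root = np.random.SeedSequence(seed)
    rows = []
    for density in densities:
        for ens in ens_targets:
            errors: dict[str, list[float]] = {m: [] for m in methods}
            n_failed = 0
            for _rep in range(n_repeats):
                child = root.spawn(1)[0]
                sim_seed = int(child.generate_state(1)[0] % (2**31))
                spec = with_seed(
                    SimulationSpec(
                        n_components=base.n_components,
                        n_samples=base.n_samples,
                        density_p=float(density),
                        target_ens=float(ens),
                        basis_log_variance=base.basis_log_variance,
                        depth=base.depth,
                    ),
                    sim_seed,
                )
                try:
                    table, truth = simulate_dataset(spec)
                except Exception as err:
                    n_failed += 1
                    logger.warning(
                        "simulation failed (density=%s, ens=%s): %s",
                        density, ens, err,
                    )
                    continue
                for method in methods:
                    est_rng = np.random.default_rng(
                        int(child.generate_state(2)[1] % (2**31))
                    )
                    try:
                        est = _estimate_for_method(
                            table, method, n_resamples,
                            0.1, 10, est_rng,
                        )
                        ref = (
                            CorrelationMatrix(spearman_from_pearson(truth.rho))
                            if method == "spearman"
                            else truth
                        )
                        errors[method].append(rmse(ref, est))
                    except Exception as err:
                        logger.warning(
                            "%s failed (density=%s, ens=%s): %s",
                            method, density, ens, err,
                        )
            for method in methods:
                vals = np.asarray(errors[method], dtype=float)
                rows.append(
                    {
                        "density": float(density),
                        "ens": float(ens),
                        "method": method,
                        "mean_rmse": float(vals.mean()) if vals.size else float("nan"),
                        "sd_rmse": float(vals.std(ddof=1)) if vals.size > 1 else float("nan"),
                        "n": int(vals.size),
                        "n_failed": n_failed,
                    }
                )
    return pd.DataFrame(rows)
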