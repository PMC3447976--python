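"""Synthetic communities with known basis correlation structure.

The generator emulates an idealized sequencing survey of a community whose
log basis abundances are multivariate normal. A sparse "true" correlation
network is planted by setting a random subset of pairs to perfect (+/-1)
correlation and projecting to the nearest positive-definite correlation
matrix; community dominance (and hence effective diversity) is controlled
by raising the mean log-abundance of component 1 until the mean Shannon
effective number of components of the exact fractions hits a target; the
observed table is a fixed-depth multinomial read-out of each sample's exact
fractions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import brentq
from statsmodels.stats.correlation_tools import corr_nearest

from .core import CorrelationMatrix
from .tables import CountTable, FractionTable

__all__ = ["SimulationSpec", "random_correlation_structure", "simulate_dataset"]

_EIG_FLOOR = 1e-6
_ENS_TOL = 0.02  # relative tolerance on the realized mean effective diversity
_N_TUNE = 400  # common-random-number draws used while tuning dominance
_MU_MAX = 20.0


@dataclass
class SimulationSpec:
    """Parameters of one synthetic community.

    Defaults follow the benchmark conditions: 50 components, 500 samples,
    unit log-abundance variance, and a multinomial read depth of 2000 per
    sample (a typical 16S library size). ``density_p`` is the probability
    that a pair is planted as perfectly correlated; ``target_ens`` is the
    desired mean Shannon effective number of components.
    """

    n_components: int = 50
    n_samples: int = 500
    density_p: float = 0.1
    target_ens: float = 10.0
    basis_log_variance: float = 1.0
    depth: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_components < 2:
            raise ValueError("need at least 2 components")
        if not (0.0 <= self.density_p <= 1.0):
            raise ValueError("density_p must be in [0, 1]")
        if not (1.0 <= self.target_ens <= self.n_components):
            raise ValueError("target_ens must be in [1, n_components]")
        if self.basis_log_variance <= 0:
            raise ValueError("basis_log_variance must be positive")
        if self.depth < 1 or self.n_samples < 1:
            raise ValueError("depth and n_samples must be positive")


def _planted_sign_matrix(
    D: int, density_p: float, rng: np.random.Generator
) -> np.ndarray:
    """Pre-projection matrix: identity plus random +/-1 planted pairs."""
    C = np.eye(D)
    iu = np.triu_indices(D, k=1)
    planted = rng.random(len(iu[0])) < density_p
    signs = rng.choice([-1.0, 1.0], size=len(iu[0]))
    vals = np.where(planted, signs, 0.0)
    C[iu] = vals
    C.T[iu] = vals
    np.fill_diagonal(C, 1.0)
    return C


def random_correlation_structure(
    D: int, density_p: float, rng: np.random.Generator
) -> CorrelationMatrix:
    """Random sparse correlation structure with planted perfect pairs.

    Each off-diagonal pair is independently set to +1 or -1 (equal
    probability) with probability ``density_p``; the resulting symmetric
    matrix is then projected to the nearest positive-definite correlation
    matrix (Frobenius-nearest with a small eigenvalue floor), which softens
    the planted +/-1 entries just enough to make the matrix valid.
    """
    if D < 2:
        raise ValueError("need at least 2 components")
    raw = _planted_sign_matrix(D, density_p, rng)
    if np.array_equal(raw, np.eye(D)):
        return CorrelationMatrix(np.eye(D))
    with warnings.catch_warnings():
        # Planted +/-1 entries sit on the boundary of the correlation
        # cone; the alternating projection converges slowly there and its
        # iteration-limit warning is expected. Positive definiteness is
        # enforced explicitly below.
        warnings.simplefilter("ignore")
        C = corr_nearest(raw, threshold=_EIG_FLOOR, n_fact=20)
    C = 0.5 * (C + C.T)
    np.fill_diagonal(C, 1.0)
    C = np.clip(C, -1.0, 1.0)
    if np.linalg.eigvalsh(C).min() <= 0:
        # Nudge onto the PD cone if the projection landed on its boundary.
        w, V = np.linalg.eigh(C)
        C = (V * np.clip(w, _EIG_FLOOR, None)) @ V.T
        d = np.sqrt(np.diag(C))
        C = C / np.outer(d, d)
        np.fill_diagonal(C, 1.0)
    return CorrelationMatrix(C)


def _mean_ens(log_abund: np.ndarray) -> float:
    """Mean exp(Shannon entropy) of the exact fractions of each row."""
    x = log_abund - log_abund.max(axis=1, keepdims=True)
    a = np.exp(x)
    f = a / a.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(f > 0, f * np.log(f), 0.0)
    return float(np.exp(-plogp.sum(axis=1)).mean())


def _tune_dominance(
    L: np.ndarray, target_ens: float, rng: np.random.Generator
) -> float:
    """Log-mean offset of component 1 achieving the target mean diversity.

    Uses a fixed set of tuning draws (common random numbers) so the mean
    diversity is a smooth, monotone-decreasing function of the offset, then
    bisects. Raises if the target exceeds the diversity attainable with
    equal means (the log-normal spread alone caps it below D).
    """
    D = L.shape[0]
    Z = rng.standard_normal((_N_TUNE, D)) @ L.T

    def g(mu1: float) -> float:
        shifted = Z.copy()
        shifted[:, 0] += mu1
        return _mean_ens(shifted) - target_ens

    g0 = g(0.0)
    if abs(g0) <= _ENS_TOL * target_ens:
        return 0.0
    if g0 < 0:
        raise ValueError(
            f"target_ens={target_ens} infeasible: maximum attainable mean "
            f"effective diversity at these settings is about {g0 + target_ens:.2f}"
        )
    if g(_MU_MAX) > 0:
        raise ValueError(
            f"target_ens={target_ens} not reachable within the dominance "
            f"search range"
        )
    return brentq(g, 0.0, _MU_MAX, xtol=1e-6)


def simulate_dataset(
    spec: SimulationSpec, return_fractions: bool = False
) -> tuple[CountTable, CorrelationMatrix] | tuple[
    CountTable, CorrelationMatrix, FractionTable
]:
    """Simulate one community and its sequencing read-out.

    Per-sample log abundances are drawn from a multivariate normal with
    covariance ``basis_log_variance * C`` (``C`` the planted correlation
    structure); abundances are exponentials of these; counts are a
    multinomial draw of ``depth`` reads from each sample's exact fractions.
    Returns the count table and the post-projection true correlation matrix
    (exactly the identity when ``density_p == 0``); with
    ``return_fractions=True`` also the exact fractions. Deterministic given
    ``spec.seed``.
    """
    D, S = spec.n_components, spec.n_samples
    seq = np.random.SeedSequence(spec.seed)
    rng_struct, rng_tune, rng_samp = (np.random.default_rng(s) for s in seq.spawn(3))

    truth = random_correlation_structure(D, spec.density_p, rng_struct)
    cov = spec.basis_log_variance * truth.rho
    L = np.linalg.cholesky(cov)
    mu1 = _tune_dominance(L, spec.target_ens, rng_tune)

    mu = np.zeros(D)
    mu[0] = mu1
    log_abund = rng_samp.standard_normal((S, D)) @ L.T + mu
    shifted = log_abund - log_abund.max(axis=1, keepdims=True)
    abund = np.exp(shifted)
    frac = abund / abund.sum(axis=1, keepdims=True)
    counts = np.empty((S, D), dtype=np.int64)
    for i in range(S):
        counts[i] = rng_samp.multinomial(spec.depth, frac[i])

    sample_ids = [f"s{i:04d}" for i in range(S)]
    component_ids = [f"otu{j:03d}" for j in range(D)]
    table = CountTable(counts, sample_ids, component_ids)
    if return_fractions:
        tiny = np.finfo(float).tiny
        f = FractionTable(
            np.clip(frac, tiny, None)
            / np.clip(frac, tiny, None).sum(axis=1, keepdims=True),
            sample_ids,
            component_ids,
        )
        return table, truth, f
    return table, truth


def with_seed(spec: SimulationSpec, seed: int) -> SimulationSpec:
    """Copy of ``spec`` with a different seed."""
    return replace(spec, seed=int(seed))
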