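"""SparCC: inference of basis correlations from compositional data.

Sequencing surveys observe only relative abundances (fractions), so sample
correlations between fractions confound true co-variation with closure
artifacts. SparCC instead works with the log-ratio variation

    t_ij = Var[ log(x_i / x_j) ]

which for log-basis variances ``w_i^2 = Var[log a_i]`` and basis
correlations ``rho_ij`` satisfies

    t_ij = w_i^2 + w_j^2 - 2 rho_ij w_i w_j.

Under the sparsity assumption (average correlations are small) the
correlation terms in the per-component variation ``t_i = sum_j t_ij`` can be
neglected, giving a linear system for the ``w_i^2`` alone; the estimated
variances are then plugged back in to recover every pairwise correlation:

    rho_ij = (w_i^2 + w_j^2 - t_ij) / (2 w_i w_j).

An iterative refinement repeatedly excludes the single most strongly
correlated pair from the variance estimation, which protects the sparsity
assumption from a few strong true correlations. The full estimator repeats
the whole procedure on many Dirichlet posterior draws of the fractions and
reports the per-pair median.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .fractions import sample_posterior_fractions
from .tables import CountTable, FractionTable

__all__ = [
    "VariationMatrix",
    "BasisVariances",
    "CorrelationMatrix",
    "SparccResult",
    "EstimatorConfig",
    "variation_matrix",
    "component_variation",
    "solve_basis_variances",
    "basis_correlations",
    "sparcc_iterative",
    "sparcc_estimate",
    "baseline_correlations",
    "estimate_correlations",
]

logger = logging.getLogger(__name__)

VARIANCE_FLOOR = 1e-10
MIN_COMPONENTS = 4


@dataclass
class VariationMatrix:
    """Symmetric matrix of log-ratio variances t_ij with zero diagonal."""

    t: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        if t.ndim != 2 or t.shape[0] != t.shape[1]:
            raise ValueError("variation matrix must be square")
        if not np.allclose(t, t.T):
            raise ValueError("variation matrix must be symmetric")
        if (np.diag(t) != 0).any():
            raise ValueError("variation matrix diagonal must be zero")
        if (t < 0).any():
            raise ValueError("variation matrix entries are variances, must be >= 0")
        self.t = t

    @property
    def n_components(self) -> int:
        return self.t.shape[0]


@dataclass
class BasisVariances:
    """Estimated variances of the log-transformed basis abundances."""

    omega_sq: np.ndarray

    def __post_init__(self) -> None:
        self.omega_sq = np.asarray(self.omega_sq, dtype=float)


@dataclass
class CorrelationMatrix:
    """Symmetric correlation matrix with unit diagonal.

    ``clipped`` records unordered pairs whose raw estimate fell outside
    [-1, 1] before clipping; undefined entries (excluded components,
    zero-variance columns) are NaN.
    """

    rho: np.ndarray
    clipped: frozenset[tuple[int, int]] = frozenset()

    def __post_init__(self) -> None:
        rho = np.asarray(self.rho, dtype=float)
        if rho.ndim != 2 or rho.shape[0] != rho.shape[1]:
            raise ValueError("correlation matrix must be square")
        self.rho = rho
        self.clipped = frozenset(tuple(sorted(p)) for p in self.clipped)

    @property
    def n_components(self) -> int:
        return self.rho.shape[0]


@dataclass
class SparccResult:
    """Output of a SparCC run.

    ``excluded_pairs`` are pairs removed from the variance estimation;
    ``excluded_components`` are components whose every pair was excluded and
    whose correlations are therefore undefined (NaN rows/columns).
    ``spread`` (resampling runs only) is the per-pair inter-quartile range of
    the correlation across posterior draws.
    """

    correlations: CorrelationMatrix
    variances: BasisVariances
    excluded_pairs: frozenset[tuple[int, int]] = frozenset()
    excluded_components: frozenset[int] = frozenset()
    iterations_run: int = 1
    spread: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.excluded_pairs = frozenset(
            tuple(sorted(p)) for p in self.excluded_pairs
        )
        self.excluded_components = frozenset(self.excluded_components)


def variation_matrix(f: FractionTable | np.ndarray) -> VariationMatrix:
    """Aitchison variation matrix: t_ij = Var[log(f_i / f_j)] across samples.

    Uses the unbiased (S - 1) sample variance. Requires at least two samples
    and strictly positive fractions.
    """
    x = f.fractions if isinstance(f, FractionTable) else np.asarray(f, dtype=float)
    if x.shape[0] < 2:
        raise ValueError("variation matrix needs at least 2 samples")
    if (x <= 0).any():
        raise ValueError("fractions must be strictly positive")
    logx = np.log(x)
    cov = np.cov(logx, rowvar=False, ddof=1)
    v = np.diag(cov)
    t = v[:, None] + v[None, :] - 2.0 * cov
    t = 0.5 * (t + t.T)
    np.fill_diagonal(t, 0.0)
    np.clip(t, 0.0, None, out=t)
    return VariationMatrix(t)


def _inclusion_mask(D: int, excluded_pairs) -> np.ndarray:
    """Boolean (D, D) mask of included off-diagonal pairs."""
    mask = ~np.eye(D, dtype=bool)
    for i, j in excluded_pairs:
        mask[i, j] = mask[j, i] = False
    return mask


def component_variation(
    T: VariationMatrix, excluded_pairs=frozenset()
) -> tuple[np.ndarray, np.ndarray]:
    """Per-component variation t_i = sum over included pairs of t_ij.

    Returns ``(t_vec, included_counts)``; a component with zero included
    pairs has ``included_counts == 0`` and is flagged for exclusion by the
    iterative procedure, not an error here.
    """
    D = T.n_components
    mask = _inclusion_mask(D, excluded_pairs)
    t_vec = (T.t * mask).sum(axis=1)
    return t_vec, mask.sum(axis=1)


def solve_basis_variances(
    t_vec: np.ndarray,
    included_counts: np.ndarray,
    D: int,
    excluded_pairs=frozenset(),
) -> BasisVariances:
    """Solve the sparsity-approximation linear system for basis variances.

    With no exclusions the system reads ``(D - 2) w_i^2 + sum_j w_j^2 = t_i``
    for every component; with exclusions the coefficient of ``w_i^2`` is the
    number of included pairs of ``i`` and only included partners contribute
    their variances. At least four components are required: with three or
    fewer the pairwise system can be satisfied exactly by independent
    components, so deviations from independence are undetectable.

    Nonpositive solutions (a degenerate outcome of the approximation) are
    clamped to a small positive floor with a logged warning.
    """
    t_vec = np.asarray(t_vec, dtype=float)
    if D < MIN_COMPONENTS:
        raise ValueError(
            f"at least {MIN_COMPONENTS} components are required to detect "
            f"deviations from independence; got {D}"
        )
    mask = _inclusion_mask(D, excluded_pairs)
    A = mask.astype(float)
    np.fill_diagonal(A, np.asarray(included_counts, dtype=float))
    try:
        omega_sq = np.linalg.solve(A, t_vec)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            f"singular variance system (exclusions leave the system rank "
            f"deficient): {err}"
        ) from err
    resid = np.abs(A @ omega_sq - t_vec).max()
    scale = max(1.0, np.abs(t_vec).max())
    if resid > 1e-8 * scale:
        raise np.linalg.LinAlgError(
            f"variance system residual {resid:.3e} exceeds tolerance"
        )
    if (omega_sq <= 0).any():
        n_bad = int((omega_sq <= 0).sum())
        logger.warning(
            "%d nonpositive basis variance(s) clamped to %.0e", n_bad, VARIANCE_FLOOR
        )
        omega_sq = np.clip(omega_sq, VARIANCE_FLOOR, None)
    return BasisVariances(omega_sq)


def basis_correlations(T: VariationMatrix, v: BasisVariances) -> CorrelationMatrix:
    """Recover pairwise correlations from the variation matrix and variances.

    ``rho_ij = (w_i^2 + w_j^2 - t_ij) / (2 w_i w_j)``; raw values outside
    [-1, 1] — a symptom of over-aggressive pair exclusion — are clipped to
    the boundary and recorded.
    """
    w2 = v.omega_sq
    if (w2 <= 0).any():
        raise ValueError("basis variances must be strictly positive")
    w = np.sqrt(w2)
    raw = (w2[:, None] + w2[None, :] - T.t) / (2.0 * np.outer(w, w))
    np.fill_diagonal(raw, 1.0)
    over = np.abs(raw) > 1.0
    iu = np.triu_indices_from(raw, k=1)
    clipped = frozenset(
        (int(i), int(j)) for i, j in zip(*iu) if over[i, j]
    )
    rho = np.clip(raw, -1.0, 1.0)
    rho = 0.5 * (rho + rho.T)
    return CorrelationMatrix(rho, clipped)


def _basic_estimate(frac: np.ndarray, excluded_pairs=frozenset()):
    """One basic SparCC pass on a fraction matrix with pair exclusions."""
    T = variation_matrix(frac)
    t_vec, counts = component_variation(T, excluded_pairs)
    v = solve_basis_variances(t_vec, counts, T.n_components, excluded_pairs)
    corr = basis_correlations(T, v)
    return corr, v


def sparcc_iterative(
    f: FractionTable,
    exclusion_threshold: float = 0.1,
    max_iterations: int = 10,
) -> SparccResult:
    """Iterative SparCC on a single fraction table.

    Starting from the basic estimate, repeatedly: find the most strongly
    correlated not-yet-excluded pair (ties broken by lowest ``(i, j)``); if
    its magnitude exceeds ``exclusion_threshold``, exclude it and re-solve
    with the exclusion, otherwise stop. Components whose every pair is
    excluded are removed entirely (their correlations are undefined and
    reported as NaN) and the remaining fractions are renormalized over the
    surviving subset. The loop also stops when fewer than four components
    remain (the sparsity assumption is violated system-wide) or after
    ``max_iterations`` exclusion rounds.
    """
    if not (0.0 < exclusion_threshold <= 1.0):
        raise ValueError("exclusion_threshold must be in (0, 1]")
    if max_iterations < 0:
        raise ValueError("max_iterations must be >= 0")
    fr = f.fractions
    D = fr.shape[1]
    if D < MIN_COMPONENTS:
        raise ValueError(
            f"at least {MIN_COMPONENTS} components are required; got {D}"
        )

    active: list[int] = list(range(D))
    excluded_pairs: set[tuple[int, int]] = set()
    excluded_components: set[int] = set()
    sub = fr
    corr, v = _basic_estimate(sub)
    est_active = list(active)  # component indices the current estimate covers
    iterations = 1

    for _round in range(max_iterations):
        pos = {c: k for k, c in enumerate(est_active)}
        mag = np.abs(corr.rho).copy()
        mag[np.tril_indices_from(mag)] = -np.inf
        for i, j in excluded_pairs:
            if i in pos and j in pos:
                mag[pos[i], pos[j]] = -np.inf
        a, b = np.unravel_index(int(np.argmax(mag)), mag.shape)
        if not mag[a, b] > exclusion_threshold:
            break
        saved = (list(active), set(excluded_pairs), set(excluded_components), sub)
        excluded_pairs.add((est_active[a], est_active[b]))

        pos = {c: k for k, c in enumerate(active)}
        local_excl = {
            (pos[i], pos[j])
            for i, j in excluded_pairs
            if i in pos and j in pos
        }
        n_act = len(active)
        excl_count = np.zeros(n_act, dtype=int)
        for x, y in local_excl:
            excl_count[x] += 1
            excl_count[y] += 1
        dead = {active[k] for k in range(n_act) if excl_count[k] >= n_act - 1}
        if dead:
            excluded_components |= dead
            active = [c for c in active if c not in dead]
            if len(active) < MIN_COMPONENTS:
                break
            sub = fr[:, active]
            sub = sub / sub.sum(axis=1, keepdims=True)
            pos = {c: k for k, c in enumerate(active)}
            local_excl = {
                (pos[i], pos[j])
                for i, j in excluded_pairs
                if i in pos and j in pos
            }
        try:
            corr, v = _basic_estimate(sub, local_excl)
        except np.linalg.LinAlgError:
            # The exclusion pattern made the variance system rank deficient
            # (possible at small D): the sparsity assumption has broken
            # down, so stop refining and keep the last valid estimate.
            logger.warning(
                "exclusion round made the variance system singular; "
                "terminating refinement early"
            )
            active, excluded_pairs, excluded_components, sub = saved
            break
        est_active = list(active)
        iterations += 1

    rho_full = np.full((D, D), np.nan)
    w2_full = np.full(D, np.nan)
    idx = np.asarray(est_active)
    rho_full[np.ix_(idx, idx)] = corr.rho
    w2_full[idx] = v.omega_sq
    # Components excluded after the last estimate still have undefined rows.
    for c in excluded_components:
        rho_full[c, :] = np.nan
        rho_full[:, c] = np.nan
        w2_full[c] = np.nan
    clipped_full = frozenset(
        (est_active[i], est_active[j])
        for i, j in corr.clipped
        if est_active[i] not in excluded_components
        and est_active[j] not in excluded_components
    )
    kept_pairs = frozenset(
        (i, j)
        for i, j in excluded_pairs
        if i not in excluded_components and j not in excluded_components
    )
    return SparccResult(
        correlations=CorrelationMatrix(rho_full, clipped_full),
        variances=BasisVariances(w2_full),
        excluded_pairs=kept_pairs,
        excluded_components=frozenset(excluded_components),
        iterations_run=iterations,
    )


def sparcc_estimate(
    table: CountTable,
    n_resamples: int = 100,
    exclusion_threshold: float = 0.1,
    max_iterations: int = 10,
    rng: np.random.Generator | int | None = None,
) -> SparccResult:
    """Full SparCC estimator on a count table.

    Runs the iterative procedure on ``n_resamples`` Dirichlet posterior
    draws of the fractions and aggregates per-pair correlations by the
    median, ignoring draws in which a pair was undefined; a pair undefined
    in more than half of the draws is reported as NaN. ``spread`` holds the
    per-pair inter-quartile range across draws. Deterministic given a seed;
    per-draw substreams are derived from the single generator.
    """
    if n_resamples < 1:
        raise ValueError("n_resamples must be >= 1")
    rng = np.random.default_rng(rng)
    D = table.n_components
    streams = rng.spawn(n_resamples)
    rho_stack = np.empty((n_resamples, D, D))
    w2_stack = np.empty((n_resamples, D))
    pair_excl = np.zeros((D, D), dtype=int)
    comp_excl = np.zeros(D, dtype=int)
    clip_count = np.zeros((D, D), dtype=int)
    max_iter_run = 0
    for k, stream in enumerate(streams):
        f = sample_posterior_fractions(table, stream)
        res = sparcc_iterative(f, exclusion_threshold, max_iterations)
        rho_stack[k] = res.correlations.rho
        w2_stack[k] = res.variances.omega_sq
        for i, j in res.excluded_pairs:
            pair_excl[i, j] += 1
        for c in res.excluded_components:
            comp_excl[c] += 1
        for i, j in res.correlations.clipped:
            clip_count[i, j] += 1
        max_iter_run = max(max_iter_run, res.iterations_run)

    defined = np.isfinite(rho_stack).sum(axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        median = np.nanmedian(rho_stack, axis=0)
        q75 = np.nanpercentile(rho_stack, 75, axis=0)
        q25 = np.nanpercentile(rho_stack, 25, axis=0)
        w2 = np.nanmedian(w2_stack, axis=0)
    undefined = defined <= n_resamples / 2.0
    median[undefined] = np.nan
    spread = q75 - q25
    spread[undefined] = np.nan

    half = n_resamples / 2.0
    iu = np.triu_indices(D, k=1)
    maj_pairs = frozenset(
        (int(i), int(j)) for i, j in zip(*iu) if pair_excl[i, j] > half
    )
    maj_comps = frozenset(int(c) for c in np.flatnonzero(comp_excl > half))
    clipped = frozenset(
        (int(i), int(j)) for i, j in zip(*iu) if clip_count[i, j] > half
    )
    return SparccResult(
        correlations=CorrelationMatrix(median, clipped),
        variances=BasisVariances(w2),
        excluded_pairs=maj_pairs,
        excluded_components=maj_comps,
        iterations_run=max_iter_run,
        spread=spread,
    )


def clr_transform(fractions: np.ndarray) -> np.ndarray:
    """Centered log-ratio transform: log f_i minus the per-sample mean log f."""
    logf = np.log(fractions)
    return logf - logf.mean(axis=1, keepdims=True)


def baseline_correlations(f: FractionTable, method: str = "pearson") -> CorrelationMatrix:
    """Conventional correlation estimators applied directly to fractions.

    These serve as comparison baselines: Pearson and Spearman on the raw
    fraction columns are both distorted by closure (two-component
    compositions always appear perfectly anti-correlated), while ``clr``
    (Pearson on centered-log-ratio-transformed columns) partially corrects
    for it. Zero-variance columns yield NaN entries.
    """
    x = f.fractions
    # Columns that are constant up to float noise have no defined correlation.
    col_sd = x.std(axis=0)
    degenerate = col_sd <= 1e-12 * np.abs(x).mean(axis=0)
    if method == "pearson":
        with np.errstate(invalid="ignore", divide="ignore"):
            rho = np.corrcoef(x, rowvar=False)
    elif method == "spearman":
        res = stats.spearmanr(x)
        rho = np.atleast_2d(res.statistic)
        if rho.shape == (1, 1):  # spearmanr collapses D=2 to a scalar
            r = float(res.statistic)
            rho = np.array([[1.0, r], [r, 1.0]])
    elif method == "clr":
        z = clr_transform(x)
        col_sd = z.std(axis=0)
        degenerate = col_sd <= 1e-12 * (np.abs(z).mean(axis=0) + 1.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            rho = np.corrcoef(z, rowvar=False)
    else:
        raise ValueError(f"unknown method: {method!r}")
    rho = np.asarray(rho, dtype=float)
    rho = np.clip(rho, -1.0, 1.0)
    if degenerate.any():
        rho[degenerate, :] = np.nan
        rho[:, degenerate] = np.nan
    np.fill_diagonal(rho, 1.0)
    return CorrelationMatrix(rho)


@dataclass
class EstimatorConfig:
    """Configuration shared between an observed run and its null replicates."""

    method: str = "sparcc"
    n_resamples: int = 100
    exclusion_threshold: float = 0.1
    max_iterations: int = 10


def estimate_correlations(
    table: CountTable,
    config: EstimatorConfig | None = None,
    rng: np.random.Generator | int | None = None,
) -> CorrelationMatrix:
    """Run the configured estimator on a count table.

    ``sparcc`` uses the full resampling estimator; the baselines operate on
    posterior-mean (pseudocount) fractions.
    """
    from .fractions import posterior_mean_fractions

    config = config or EstimatorConfig()
    if config.method == "sparcc":
        return sparcc_estimate(
            table,
            n_resamples=config.n_resamples,
            exclusion_threshold=config.exclusion_threshold,
            max_iterations=config.max_iterations,
            rng=rng,
        ).correlations
    return baseline_correlations(posterior_mean_fractions(table), config.method)
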