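"""Ensemble selection from the optimization archive.

Four stages turn the archive of evaluated parameter vectors into an ensemble:

1. *Acceptance interval*: a chi-square approximation of the nominal
   log-likelihood defines an admissible band of objective values; the lower
   bound sits one likelihood-ratio offset (Pr(chi2_1) < 0.05, i.e. 3.841)
   below it, the upper bound is widened by the value obtained when the
   standard deviations are inflated by the per-output maximum sigma.
2. *Percentile thinning*: per parameter, vectors are grouped by the nearest of
   the 21 percentile values P0, P5, ..., P100 and only vectors in even-
   numbered groups (1-based) for every parameter are kept, discarding both
   extremes while retaining off-center diversity.
3. *Distance pruning*: near-duplicate vectors (squared relative Euclidean
   distance below a cutoff, coordinates rescaled by the best fit) are removed,
   better-fitting vectors winning ties.
4. *Subsampling* to the target ensemble size (default 1000) uniformly at
   random.

All stages operate on negative-log-likelihood values as stored in the archive;
the interval endpoints are converted from the log-likelihood scale by negation
in exactly one place (:meth:`AcceptanceInterval.nll_bounds`).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import chi2

from .data import Dataset
from .estimation import PENALTY, ParameterArchive

__all__ = [
    "AcceptanceInterval",
    "Ensemble",
    "chi2_quantile",
    "approx_nominal_loglik",
    "acceptance_interval",
    "filter_archive",
    "percentile_thin",
    "distance_prune",
    "subsample",
    "build_ensemble",
]

DELTA_ALPHA = 3.841  # chi2(1) 95% quantile, the likelihood-ratio offset


def chi2_quantile(alpha: float, dof: int) -> float:
    """Quantile of the chi-square distribution with ``dof`` degrees of freedom."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    if dof < 1:
        raise ValueError("dof must be >= 1")
    return float(chi2.ppf(alpha, dof))


def approx_nominal_loglik(
    dataset: Dataset,
    sigma_abs_star: float,
    sigma_rel_star: float,
    n_theta: int,
    best_fit_outputs: np.ndarray,
    chi2_term: float | None = None,
) -> float:
    """Chi-square approximation of log L at the (unknown) nominal parameters.

    With Gaussian errors the summed squared residuals follow a chi-square law
    with t_f*n_y - n_theta degrees of freedom; replacing that term by its
    expectation and the sigma by sigma_rel*y + sigma_abs evaluated on the best
    fit gives

        log L(theta_nominal) ~ -1/2 [ sum_ij log(sigma_ij^2 * 2*pi) + (t_f*n_y - n_theta) ].

    ``chi2_term`` overrides the expectation (e.g. with a quantile).
    """
    y = np.atleast_2d(np.asarray(best_fit_outputs, dtype=float))
    n_data = y.size
    if n_data <= n_theta:
        raise ValueError("need more data points than parameters (t_f*n_y > n_theta)")
    sigma = sigma_rel_star * y + sigma_abs_star
    if np.any(sigma <= 0):
        raise ValueError("non-positive sigma in the nominal log-likelihood approximation")
    if chi2_term is None:
        chi2_term = float(n_data - n_theta)
    return float(-0.5 * (np.sum(np.log(sigma**2 * 2.0 * math.pi)) + chi2_term))


@dataclass(frozen=True)
class AcceptanceInterval:
    """Admissible band of log-likelihood values around the nominal estimate."""

    loglik_nominal_approx: float
    delta_upper: float
    delta_alpha: float = DELTA_ALPHA

    @property
    def lower(self) -> float:
        return self.loglik_nominal_approx - self.delta_alpha

    @property
    def upper(self) -> float:
        return self.loglik_nominal_approx + self.delta_upper + self.delta_alpha

    def nll_bounds(self) -> tuple[float, float]:
        """The interval on the negative-log-likelihood scale (the archive's)."""
        return (-self.upper, -self.lower)

    def contains_nll(self, values: np.ndarray) -> np.ndarray:
        lo, hi = self.nll_bounds()
        v = np.asarray(values, dtype=float)
        return (v >= lo) & (v <= hi)


def residual_sigma_scale(dataset: Dataset, best_fit_outputs: np.ndarray, n_free: int) -> float:
    """Estimated noise-scale factor from the best-fit weighted residuals.

    The interval construction needs *estimated* noise levels sigma*.  Using
    the generating values directly makes the chi-square-expectation
    approximation fragile: the realized minimum sum of squares fluctuates
    around its mean with SD sqrt(2*dof), which exceeds the likelihood-ratio
    offset for datasets beyond ~8 points.  Rescaling sigma* by the classical
    residual standard deviation s = sqrt(SSR_min/(N - n_free)) calibrates the
    approximation to the realized noise level, which is what estimating
    sigma_abs*, sigma_rel* from the fit achieves.
    """
    y = np.atleast_2d(np.asarray(best_fit_outputs, dtype=float))
    r = (dataset.y - y) / dataset.sigma
    dof = dataset.y.size - n_free
    if dof <= 0:
        return 1.0
    return float(np.sqrt(max(np.sum(r * r) / dof, 1e-12)))


def acceptance_interval(
    dataset: Dataset,
    sigma_abs_star: float,
    sigma_rel_star: float,
    n_theta: int,
    best_fit_outputs: np.ndarray,
) -> AcceptanceInterval:
    """Likelihood-ratio acceptance interval (lower offset 3.841; upper widened).

    The upper widening Delta log L comes from re-evaluating the approximation
    with inflated deviations sigma~_ij = sigma_rel*y_ij*max_i(sigma_ij) +
    sigma_abs, where the maximum is over time points of output j.  A negative
    widening (possible when max sigma < 1) is floored at zero with a warning.
    """
    base = approx_nominal_loglik(dataset, sigma_abs_star, sigma_rel_star, n_theta, best_fit_outputs)
    y = np.atleast_2d(np.asarray(best_fit_outputs, dtype=float))
    sigma = sigma_rel_star * y + sigma_abs_star
    sigma_max = np.max(sigma, axis=0)  # per output j
    sigma_tilde = sigma_rel_star * y * sigma_max[None, :] + sigma_abs_star
    if np.any(sigma_tilde <= 0):
        raise ValueError("non-positive inflated sigma in acceptance interval")
    n_data = y.size
    tilde = float(-0.5 * (np.sum(np.log(sigma_tilde**2 * 2.0 * math.pi)) + (n_data - n_theta)))
    delta = tilde - base
    if delta < 0:
        warnings.warn("negative interval widening floored at zero", RuntimeWarning)
        delta = 0.0
    return AcceptanceInterval(loglik_nominal_approx=base, delta_upper=delta)


def filter_archive(
    archive: ParameterArchive, interval: AcceptanceInterval, value_transform=None
) -> tuple[np.ndarray, np.ndarray]:
    """Vectors whose objective value falls inside the acceptance interval.

    Penalty-flagged (failed) evaluations are excluded.  ``value_transform``
    optionally maps archived objective values onto the noise scale the
    interval was built with (see :func:`build_ensemble`).  An empty result
    raises: it indicates a failed optimization or wrong noise estimates.
    """
    if len(archive) == 0:
        raise ValueError("empty archive")
    X, v, bad = archive.as_arrays()
    if value_transform is not None:
        ok = ~bad & (v < PENALTY)
        v = np.where(ok, value_transform(v), v)
    mask = interval.contains_nll(v) & ~bad & (v < PENALTY)
    if not np.any(mask):
        lo, hi = interval.nll_bounds()
        raise ValueError(
            f"no archived vector falls in the acceptance interval [{lo:.4g}, {hi:.4g}]; "
            f"archive NLL range is [{v.min():.4g}, {v.max():.4g}]"
        )
    return X[mask], v[mask]


def percentile_thin(
    candidates: np.ndarray, values: np.ndarray | None = None, mode: str = "all"
) -> np.ndarray:
    """Discard vectors sitting in odd-numbered percentile groups.

    Per parameter, the percentile values P0, P5, ..., P100 define 21 groups;
    each vector joins the group of its nearest percentile value (ties to the
    lower group).  Groups are numbered 1..21, so both extremes land in odd
    groups and are discarded.  With ``mode="all"`` a vector survives only when
    it sits in an even group for *every* parameter; with ``mode="majority"``
    it survives when it does so for more than half of its parameters.  The two
    rules coincide in one dimension; the conjunction's survival probability
    decays like ~0.5^d with the decision dimension d, so the majority variant
    is what the selection pipeline uses by default on multi-parameter models.
    Returns indices into ``candidates`` preserving input order.  Degenerate
    (constant) parameters are skipped with a warning.
    """
    if mode not in ("all", "majority"):
        raise ValueError(f"unknown thinning mode {mode!r}")
    X = np.atleast_2d(np.asarray(candidates, dtype=float))
    if X.shape[0] == 0:
        raise ValueError("empty candidate set")
    grid = np.arange(0, 101, 5)
    even = []
    for k in range(X.shape[1]):
        col = X[:, k]
        if np.ptp(col) == 0:
            warnings.warn(f"parameter {k} constant across candidates; skipped in thinning")
            continue
        pct = np.percentile(col, grid)
        dist = np.abs(col[:, None] - pct[None, :])
        group = np.argmin(dist, axis=1) + 1  # 1-based; argmin ties -> lower group
        even.append(group % 2 == 0)
    if not even:
        return np.arange(X.shape[0])
    even = np.column_stack(even)
    if mode == "all":
        keep = np.all(even, axis=1)
    else:
        keep = np.sum(even, axis=1) > even.shape[1] / 2.0
    return np.flatnonzero(keep)


def distance_prune(
    candidates: np.ndarray,
    values: np.ndarray,
    theta_star: np.ndarray,
    epsilon: float = 1e-4,
) -> np.ndarray:
    """Remove near-duplicates by relative Euclidean distance to kept vectors.

    Candidates are visited in ascending objective order (better fits win
    ties); a vector is dropped when its squared relative distance — each
    coordinate rescaled by the best fit theta* — to an already-kept vector is
    below ``epsilon``.  Zero coordinates of theta* are excluded from the
    distance with a warning.  The best-fit vector itself is always kept.
    Returns kept indices into ``candidates``.
    """
    X = np.atleast_2d(np.asarray(candidates, dtype=float))
    v = np.asarray(values, dtype=float)
    theta_star = np.asarray(theta_star, dtype=float)
    nz = theta_star != 0
    if not np.all(nz):
        warnings.warn("zero components in theta*; excluded from the distance")
    if not np.any(nz):
        raise ValueError("theta* has no non-zero components")
    S = X[:, nz] / theta_star[nz]
    star = np.flatnonzero(np.all(X == theta_star, axis=1))
    order = np.argsort(v, kind="stable")
    if star.size:
        first = star[0]
        order = np.concatenate(([first], order[order != first]))
    kept: list[int] = []
    kept_S: list[np.ndarray] = []
    for i in order:
        si = S[i]
        if kept_S:
            d2 = np.sum((np.array(kept_S) - si) ** 2, axis=1)
            if np.any(d2 < epsilon):
                continue
        kept.append(int(i))
        kept_S.append(si)
    return np.array(sorted(kept), dtype=int)


@dataclass(frozen=True)
class Ensemble:
    """Selected parameter vectors with their objective values and provenance."""

    vectors: np.ndarray  # (m, n_dim)
    values: np.ndarray  # (m,)
    decision_names: tuple[str, ...]
    interval: AcceptanceInterval
    provenance: dict = field(default_factory=dict)  # counts per stage
    target_size: int = 1000
    seed: int = 0

    @property
    def size(self) -> int:
        return self.vectors.shape[0]

    def to_frame(self):
        import pandas as pd

        df = pd.DataFrame(self.vectors, columns=list(self.decision_names))
        df.insert(0, "value", self.values)
        return df


def subsample(
    candidates: np.ndarray,
    values: np.ndarray,
    target_size: int,
    seed: int,
) -> np.ndarray:
    """Uniform random subset without replacement; identity when small enough."""
    n = candidates.shape[0]
    if n == 0:
        raise ValueError("empty candidate set")
    if n <= target_size:
        return np.arange(n)
    rng = np.random.default_rng(seed)
    return np.sort(rng.choice(n, size=target_size, replace=False))


def build_ensemble(
    archive: ParameterArchive,
    dataset: Dataset,
    sigma_abs_star: float,
    sigma_rel_star: float,
    n_theta: int,
    best_fit_outputs: np.ndarray,
    decision_names=(),
    target_size: int = 1000,
    epsilon: float = 1e-4,
    seed: int = 0,
    thin: str | bool = "majority",
    calibrate_sigma: bool = True,
) -> Ensemble:
    """Full selection pipeline: interval -> thinning -> pruning -> subsampling.

    ``thin`` selects the thinning rule ("majority", "all") or disables the
    stage (False).  With ``calibrate_sigma`` the supplied noise levels are
    rescaled by the best-fit residual standard deviation s, turning them into
    estimated sigma* as the interval construction assumes, and the archived
    objective values are mapped onto the same noise scale
    (v -> const + N*log(s) + (v - const)/s^2, the exact NLL identity under
    sigma -> s*sigma), so interval and archive stay commensurable.
    """
    value_transform = None
    if calibrate_sigma:
        s = residual_sigma_scale(dataset, best_fit_outputs, n_theta)
        sigma_abs_star = np.asarray(sigma_abs_star) * s
        sigma_rel_star = sigma_rel_star * s
        const = float(np.sum(np.log(dataset.sigma * math.sqrt(2.0 * math.pi))))
        n_data = dataset.y.size

        def value_transform(v, s=s, const=const, n_data=n_data):
            return const + n_data * math.log(s) + (v - const) / (s * s)

        # widening term from the sigma~ variant at the calibrated sigma*; the
        # base term is anchored on the rescaled dataset sigma so that the
        # transformed best fit sits exactly at the approximation centre
        widening = acceptance_interval(
            dataset, sigma_abs_star, sigma_rel_star, n_theta, best_fit_outputs
        ).delta_upper
        base = float(
            -0.5 * (np.sum(np.log((s * dataset.sigma) ** 2 * 2.0 * math.pi))
                    + (n_data - n_theta))
        )
        interval = AcceptanceInterval(loglik_nominal_approx=base, delta_upper=widening)
    else:
        interval = acceptance_interval(
            dataset, sigma_abs_star, sigma_rel_star, n_theta, best_fit_outputs
        )
    X, v = filter_archive(archive, interval, value_transform=value_transform)
    counts = {"archive": len(archive), "interval": X.shape[0]}
    if thin:
        idx = percentile_thin(X, mode="all" if thin is True else thin)
        if idx.size == 0:
            warnings.warn("percentile thinning removed every candidate; stage skipped")
        else:
            X, v = X[idx], v[idx]
    counts["thinned"] = X.shape[0]
    theta_star = X[np.argmin(v)]
    idx = distance_prune(X, v, theta_star, epsilon=epsilon)
    X, v = X[idx], v[idx]
    counts["pruned"] = X.shape[0]
    idx = subsample(X, v, target_size, seed)
    X, v = X[idx], v[idx]
    counts["sampled"] = X.shape[0]
    return Ensemble(
        vectors=X,
        values=v,
        decision_names=tuple(decision_names),
        interval=interval,
        provenance=counts,
        target_size=target_size,
        seed=seed,
    )
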