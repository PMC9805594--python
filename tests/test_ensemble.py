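"""Acceptance interval, thinning, pruning and subsampling."""

import math

import numpy as np
import pytest
from scipy.stats import chi2 as chi2_dist

from obsens.data import Dataset
from obsens.ensemble import (
    DELTA_ALPHA,
    AcceptanceInterval,
    acceptance_interval,
    approx_nominal_loglik,
    build_ensemble,
    chi2_quantile,
    distance_prune,
    filter_archive,
    percentile_thin,
    subsample,
)
from obsens.estimation import ParameterArchive


def _dataset(n=10, n_y=1, sigma=1.0):
    times = np.linspace(0.0, 1.0, n)
    y = np.ones((n, n_y))
    return Dataset(times=times, y=y, sigma=np.full((n, n_y), sigma))


class TestChi2Quantile:
    def test_delta_alpha(self):
        assert chi2_quantile(0.95, 1) == pytest.approx(3.841, abs=5e-4)

    def test_chi2_2_median_closed_form(self):
        assert chi2_quantile(0.5, 2) == pytest.approx(2 * math.log(2), rel=1e-10)

    def test_roundtrip_with_independent_cdf(self):
        for a in (0.05, 0.25, 0.5, 0.9, 0.99):
            for k in (1, 2, 5, 20):
                q = chi2_quantile(a, k)
                assert chi2_dist.cdf(q, k) == pytest.approx(a, abs=1e-10)

    def test_invalid_rejected(self):
        with pytest.raises(ValueError):
            chi2_quantile(1.5, 1)
        with pytest.raises(ValueError):
            chi2_quantile(0.5, 0)


class TestNominalLoglikApprox:
    def test_unit_sigma_direct_substitution(self):
        # sigma_ij = 1, t_f*n_y = 10, n_theta = 2 -> -0.5*(10*log(2*pi) + 8)
        y = np.zeros((10, 1))
        val = approx_nominal_loglik(_dataset(), 0.0 + 1.0, 0.0, 2, y)
        assert val == pytest.approx(-0.5 * (10 * math.log(2 * math.pi) + 8), rel=1e-12)

    def test_doubling_sigma_shifts_by_log2(self):
        y = np.ones((10, 1))
        v1 = approx_nominal_loglik(_dataset(), 0.5, 0.5, 2, y)  # sigma = 1
        v2 = approx_nominal_loglik(_dataset(), 1.0, 1.0, 2, y)  # sigma = 2
        assert v2 - v1 == pytest.approx(-10 * math.log(2), rel=1e-12)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="more data"):
            approx_nominal_loglik(_dataset(n=3), 1.0, 0.0, 5, np.zeros((3, 1)))


class TestAcceptanceInterval:
    def test_degenerate_variant_symmetric(self):
        """When the inflated sigma equals sigma (max sigma == 1) the interval
        is symmetric with half-width 3.841."""
        y = np.ones((10, 1))
        iv = acceptance_interval(_dataset(), 0.5, 0.5, 2, y)  # sigma = 1 = max
        assert iv.delta_upper == 0.0
        assert iv.upper - iv.lower == pytest.approx(2 * DELTA_ALPHA)

    def test_lower_bound_is_always_approx_minus_delta(self):
        y = np.full((10, 1), 3.0)
        iv = acceptance_interval(_dataset(), 0.2, 0.1, 2, y)
        base = approx_nominal_loglik(_dataset(), 0.2, 0.1, 2, y)
        assert iv.lower == pytest.approx(base - 3.841, abs=1e-9)

    def test_interval_invariants(self):
        y = np.full((8, 1), 2.0)
        ds = _dataset(n=8)
        iv = acceptance_interval(ds, 0.3, 0.2, 3, y)
        assert iv.lower == pytest.approx(iv.loglik_nominal_approx - iv.delta_alpha)
        assert iv.upper - iv.lower == pytest.approx(iv.delta_upper + 2 * iv.delta_alpha)

    def test_endpoints_match_direct_recomputation(self):
        """Independent recomputation from the two chi-square-style evaluations
        on a 3-point toy dataset."""
        times = np.array([0.0, 1.0, 2.0])
        y = np.array([[0.5], [1.0], [1.5]])
        ds = Dataset(times=times, y=y, sigma=np.ones((3, 1)))
        sa, sr, ntheta = 0.1, 0.2, 1
        iv = acceptance_interval(ds, sa, sr, ntheta, y)
        sigma = sr * y + sa
        base = -0.5 * (np.sum(np.log(sigma**2 * 2 * np.pi)) + (3 - 1))
        smax = sigma.max()
        sigma_t = sr * y * smax + sa
        tilde = -0.5 * (np.sum(np.log(sigma_t**2 * 2 * np.pi)) + (3 - 1))
        assert iv.lower == pytest.approx(base - 3.841, abs=1e-12)
        assert iv.upper == pytest.approx(base + (tilde - base) + 3.841, abs=1e-12)

    def test_negative_widening_floored(self):
        # max sigma > 1 inflates sigma~ beyond sigma, making the raw widening
        # negative; it must be floored at zero with a warning
        y = np.full((10, 1), 10.0)
        with pytest.warns(RuntimeWarning, match="floored"):
            iv = acceptance_interval(_dataset(), 1.0, 0.2, 2, y)
        assert iv.delta_upper == 0.0


def _archive_from(values, dim=3, seed=0):
    rng = np.random.default_rng(seed)
    arch = ParameterArchive()
    for v in values:
        arch.record(rng.uniform(0.5, 2.0, dim), v)
    return arch


class TestFilterArchive:
    def _interval(self, nll_lo, nll_hi):
        # nll bounds are [-upper, -lower] on the log-likelihood scale
        approx = -nll_hi + DELTA_ALPHA
        delta = -nll_lo - approx - DELTA_ALPHA
        iv = AcceptanceInterval(loglik_nominal_approx=approx, delta_upper=delta)
        assert iv.nll_bounds() == (pytest.approx(nll_lo), pytest.approx(nll_hi))
        return iv

    def test_hand_counted_survivors(self):
        arch = _archive_from([-10.0, -5.0, 0.0, 5.0, 10.0])
        X, v = filter_archive(arch, self._interval(-6.0, 6.0))
        assert X.shape[0] == 3
        assert sorted(v) == [-5.0, 0.0, 5.0]

    def test_interval_covering_everything(self):
        arch = _archive_from([1.0, 2.0, 3.0])
        X, _ = filter_archive(arch, self._interval(-100.0, 100.0))
        assert X.shape[0] == 3

    def test_penalties_excluded(self):
        arch = _archive_from([1.0, 2.0])
        arch.record(np.ones(3), 1e10, failed=True)
        X, _ = filter_archive(arch, self._interval(-1e12, 1e12))
        assert X.shape[0] == 2

    def test_matches_linear_scan_oracle(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(0, 20, 1000)
        arch = _archive_from(vals, seed=2)
        iv = self._interval(-7.0, 13.0)
        X, v = filter_archive(arch, iv)
        keep = [i for i, val in enumerate(vals) if -7.0 <= val <= 13.0]
        assert X.shape[0] == len(keep)
        np.testing.assert_allclose(np.sort(v), np.sort(vals[keep]))

    def test_empty_result_is_hard_error(self):
        arch = _archive_from([100.0, 200.0])
        with pytest.raises(ValueError, match="acceptance interval"):
            filter_archive(arch, self._interval(-1.0, 1.0))


def _thin_oracle(X):
    """Independent reimplementation of the grouping rule."""
    keep = np.ones(X.shape[0], bool)
    for k in range(X.shape[1]):
        col = X[:, k]
        if np.ptp(col) == 0:
            continue
        pct = np.percentile(col, np.arange(0, 101, 5))
        for i, v in enumerate(col):
            dists = np.abs(v - pct)
            g = int(np.flatnonzero(dists == dists.min())[0]) + 1
            if g % 2 == 1:
                keep[i] = False
    return np.flatnonzero(keep)


class TestPercentileThin:
    def test_extreme_vectors_always_discarded(self):
        rng = np.random.default_rng(3)
        X = rng.uniform(0, 1, (200, 2))
        idx = percentile_thin(X)
        for k in range(2):
            assert np.argmin(X[:, k]) not in idx
            assert np.argmax(X[:, k]) not in idx

    def test_median_group_tie_rule(self):
        """A value equidistant between two percentile values joins the lower
        group; the exact-median vector sits in group 11 (odd) and is removed."""
        col = np.arange(21, dtype=float)  # percentiles land on the integers
        X = col[:, None]
        idx = percentile_thin(X)
        assert 10 not in idx  # the median (group 11)
        kept_groups = {int(v) + 1 for v in X[idx, 0]}
        assert all(g % 2 == 0 for g in kept_groups)

    def test_matches_independent_grouping_oracle(self):
        rng = np.random.default_rng(4)
        X = rng.uniform(-3, 7, (800, 4))
        np.testing.assert_array_equal(percentile_thin(X), _thin_oracle(X))

    def test_degenerate_parameter_skipped_with_warning(self):
        rng = np.random.default_rng(5)
        X = np.column_stack([rng.uniform(0, 1, 100), np.full(100, 2.0)])
        with pytest.warns(UserWarning, match="constant"):
            idx = percentile_thin(X)
        assert idx.size > 0


class TestDistancePrune:
    def test_duplicates_collapse_to_one(self):
        X = np.array([[1.0, 2.0], [1.0, 2.0]])
        idx = distance_prune(X, np.array([0.0, 1.0]), X[0], epsilon=1e-6)
        assert idx.size == 1

    def test_epsilon_zero_keeps_everything(self):
        X = np.array([[1.0, 2.0], [1.0, 2.0], [3.0, 4.0]])
        idx = distance_prune(X, np.arange(3.0), X[0], epsilon=0.0)
        assert idx.size == 3  # strict inequality: identical vectors survive

    def test_best_fit_always_kept(self):
        rng = np.random.default_rng(6)
        X = rng.uniform(0.9, 1.1, (50, 3))
        v = rng.uniform(0, 1, 50)
        star = X[np.argmin(v)]
        idx = distance_prune(X, v, star, epsilon=10.0)  # aggressive cutoff
        assert np.argmin(v) in idx

    def test_matches_pairwise_scan_oracle(self):
        rng = np.random.default_rng(7)
        X = rng.uniform(0.5, 1.5, (500, 3))
        v = rng.uniform(0, 1, 500)
        star = X[np.argmin(v)]
        eps = 0.01
        idx = distance_prune(X, v, star, epsilon=eps)
        # oracle: greedy scan in ascending objective order
        order = np.argsort(v, kind="stable")
        first = np.argmin(v)
        order = np.concatenate(([first], order[order != first]))
        kept = []
        for i in order:
            si = X[i] / star
            if all(np.sum((si - X[j] / star) ** 2) >= eps for j in kept):
                kept.append(i)
        assert sorted(kept) == list(idx)

    def test_zero_component_excluded_with_warning(self):
        X = np.array([[1.0, 5.0], [1.0, 9.0], [2.0, 5.0]])
        star = np.array([1.0, 0.0])
        with pytest.warns(UserWarning, match="zero components"):
            idx = distance_prune(X, np.arange(3.0), star, epsilon=0.5)
        # second column ignored: rows 0 and 1 coincide in the first coordinate
        assert idx.size == 2


class TestSubsample:
    def test_identity_when_small(self):
        X = np.ones((5, 2))
        idx = subsample(X, np.arange(5.0), 10, seed=0)
        np.testing.assert_array_equal(idx, np.arange(5))

    def test_deterministic(self):
        rng = np.random.default_rng(8)
        X = rng.uniform(0, 1, (500, 2))
        a = subsample(X, np.zeros(500), 100, seed=9)
        b = subsample(X, np.zeros(500), 100, seed=9)
        np.testing.assert_array_equal(a, b)

    def test_marginal_quantiles_preserved(self):
        rng = np.random.default_rng(10)
        X = rng.lognormal(0.0, 0.5, (5000, 3))
        qs = np.arange(5, 100, 5)
        ref = np.percentile(X, qs, axis=0)
        err = []
        for seed in range(20):
            idx = subsample(X, np.zeros(5000), 1000, seed=seed)
            samp = np.percentile(X[idx], qs, axis=0)
            err.append(np.abs(samp - ref) / ref)
        assert np.mean(err) < 0.05


class TestBuildEnsemble:
    def test_pipeline_monotone_and_interval_invariant(self):
        rng = np.random.default_rng(11)
        arch = ParameterArchive()
        # synthetic archive around a quadratic basin, NLL-like values
        # NLL-like values compatible with the unit-sigma interval below
        center = np.array([1.0, 2.0, 0.5])
        for _ in range(4000):
            x = center * rng.lognormal(0.0, 0.4, 3)
            arch.record(x, 38.0 + 5.0 * float(np.sum(((x - center) / center) ** 2)))
        ds = _dataset(n=30)
        ens = build_ensemble(
            arch, ds, sigma_abs_star=0.5, sigma_rel_star=0.5, n_theta=3,
            best_fit_outputs=np.ones((30, 1)), decision_names=("a", "b", "c"),
            target_size=50, epsilon=1e-6, seed=1, calibrate_sigma=False,
        )
        c = ens.provenance
        assert c["archive"] >= c["interval"] >= c["thinned"] >= c["pruned"] >= c["sampled"]
        assert ens.size == c["sampled"] <= 50
        lo, hi = ens.interval.nll_bounds()
        assert np.all((ens.values >= lo) & (ens.values <= hi))
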