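"""Background-model fitting: spline basis, knots, NB GLM, two-step fit."""

import json

import numpy as np
import pandas as pd
import pytest

from hicnb import simulate
from hicnb.background import (
    BackgroundFit,
    SplineSpec,
    bspline_basis,
    choose_knots,
    estimate_distance_dispersion,
    fit_nb_glm,
    full_bspline_basis,
    predict_table,
    two_step_fit,
)
from hicnb.calling import call_interactions


# ---------------------------------------------------------------------------
# B-spline basis
# ---------------------------------------------------------------------------

def deboor(x, t, k, i):
    """Independent Cox-de Boor recursion for basis function B_{i,k}."""
    if k == 0:
        return 1.0 if (t[i] <= x < t[i + 1]) else 0.0
    left = 0.0
    if t[i + k] != t[i]:
        left = (x - t[i]) / (t[i + k] - t[i]) * deboor(x, t, k - 1, i)
    right = 0.0
    if t[i + k + 1] != t[i + 1]:
        right = (t[i + k + 1] - x) / (t[i + k + 1] - t[i + 1]) * deboor(x, t, k - 1, i + 1)
    return left + right


class TestSpline:
    spec = SplineSpec(inner_knots=(2.5e5, 5e5, 7.5e5), boundary=(1e4, 1e6))

    def test_six_columns_and_partition_of_unity(self):
        x = np.linspace(1e4, 1e6, 101)
        B6 = bspline_basis(x, self.spec)
        assert B6.shape == (101, 6)
        full = full_bspline_basis(x, self.spec)
        assert full.shape[1] == 7
        np.testing.assert_allclose(full.sum(axis=1), 1.0, atol=1e-12)
        # the design basis is the full basis minus its first function
        np.testing.assert_allclose(B6, full[:, 1:], atol=0)

    def test_matches_de_boor_recursion(self):
        t = self.spec.knot_vector()
        xs = np.linspace(1.2e4, 9.9e5, 50)
        full = full_bspline_basis(xs, self.spec)
        for xi, row in zip(xs, full):
            oracle = [deboor(float(xi), t, 3, i) for i in range(7)]
            np.testing.assert_allclose(row, oracle, atol=1e-10)

    def test_out_of_range_clamped(self):
        inside = bspline_basis(np.array([1e4, 1e6 * 0.9999999]), self.spec)
        outside = bspline_basis(np.array([1.0, 2e6]), self.spec)
        np.testing.assert_allclose(outside[0], inside[0], atol=1e-9)
        assert np.isfinite(outside).all()

    def test_single_point_evaluation(self):
        # prediction for one pair must work: no minimum-size requirement
        b = bspline_basis(np.array([5e5]), self.spec)
        assert b.shape == (1, 6) and np.isfinite(b).all()


class TestChooseKnots:
    def test_quantile_oracle_uniform(self):
        d = np.arange(1.0, 100.0)  # {1..99}
        spec = choose_knots(d)
        # independent oracle: linear interpolation between order statistics
        srt = np.sort(d)
        expected = []
        for q in (0.25, 0.5, 0.75):
            pos = q * (len(srt) - 1)
            lo = int(np.floor(pos))
            expected.append(srt[lo] + (pos - lo) * (srt[min(lo + 1, len(srt) - 1)] - srt[lo]))
        np.testing.assert_allclose(spec.inner_knots, expected)
        assert spec.boundary == (1.0, 99.0)

    def test_symmetric_middle_knot_is_median(self):
        d = np.array([10.0, 20, 30, 40, 50, 60, 70])
        spec = choose_knots(d)
        assert spec.inner_knots[1] == 40.0

    def test_ties_yield_distinct_valid_knots(self):
        d = np.r_[np.full(50, 10.0), np.full(50, 10.0), [20.0, 30.0, 40.0, 1000.0]]
        spec = choose_knots(d)
        assert len(set(spec.inner_knots)) == 3
        lo, hi = spec.boundary
        assert all(lo < k < hi for k in spec.inner_knots)
        ks = list(spec.inner_knots)
        assert ks == sorted(ks)

    def test_all_equal_raises(self):
        with pytest.raises(ValueError):
            choose_knots(np.full(10, 5.0))


# ---------------------------------------------------------------------------
# NB GLM
# ---------------------------------------------------------------------------

class TestFitNbGlm:
    def test_recovers_generating_parameters(self):
        y, X, beta, alpha = simulate.simulate_glm_dataset(50_000, seed=42)
        fit = fit_nb_glm(y, X)
        z = np.abs(fit.beta - beta) / fit.bse
        assert np.max(z) < 3.0
        assert abs(fit.alpha - alpha) / alpha < 0.15
        assert fit.converged

    def test_all_zero_response_raises(self):
        X = np.column_stack([np.ones(100), np.linspace(-1, 1, 100)])
        with pytest.raises(ValueError, match="all-zero"):
            fit_nb_glm(np.zeros(100), X)

    def test_poisson_fallback_on_equidispersed_data(self):
        rng = np.random.default_rng(5)
        X = np.column_stack([np.ones(5000), rng.normal(size=5000)])
        mu = np.exp(1.0 + 0.5 * X[:, 1])
        y = rng.poisson(mu)
        fit = fit_nb_glm(y, X)
        assert fit.poisson_fallback and fit.alpha == 0.0

    def test_rank_deficient_design_raises(self):
        X = np.ones((100, 2))
        with pytest.raises(ValueError, match="rank"):
            fit_nb_glm(np.ones(100), X)

    def test_too_few_observations_raises(self):
        X = np.column_stack([np.ones(15), np.linspace(0, 1, 15)])
        with pytest.raises(ValueError, match="observations"):
            fit_nb_glm(np.ones(15), X)


# ---------------------------------------------------------------------------
# two-step fit
# ---------------------------------------------------------------------------

class TestTwoStep:
    def test_same_seed_bit_identical(self, small_world):
        table, truth = small_world
        f1 = two_step_fit(table, truth.features, seed=9, min_subsample=20_000)
        f2 = two_step_fit(table, truth.features, seed=9, min_subsample=20_000)
        np.testing.assert_array_equal(f1.fits["chrSim"].beta, f2.fits["chrSim"].beta)
        assert f1.fits["chrSim"].alpha == f2.fits["chrSim"].alpha

    def test_planted_enriched_pairs_trimmed(self):
        table, truth = simulate.simulate_contacts(
            seed=33, n_bins=400, d_max=400_000, n_loops=60, loop_fold=10.0)
        fit = two_step_fit(table, truth.features, seed=33, min_subsample=20_000)
        # recompute the trim mask from the recorded diagnostics path:
        # planted pairs must essentially all be above their null quantile
        calls = call_interactions(table, fit, truth.features)
        merged = calls.merge(truth.planted, on=["chrom", "bin_i", "bin_j"])
        from scipy.stats import nbinom
        cf = fit.fits["chrSim"]
        r = 1 / cf.alpha
        thr = nbinom.ppf(0.975, r, r / (r + merged["mu"]))
        assert (merged["count"] > thr).mean() > 0.99

    def test_trimmed_fraction_matches_quantile_property(self, small_world_fit):
        """Observed trim fraction agrees with the analytic expectation
        E[P(Y > q975)] computed from the generating parameters (the discrete
        quantile property makes this strictly below 2.5%)."""
        table, truth, fit = small_world_fit
        from scipy.stats import nbinom
        r = 1 / truth.alpha
        p = r / (r + truth.mu_baseline)
        q = nbinom.ppf(0.975, r, p)
        expected = float(nbinom.sf(q, r, p).mean())
        observed = fit.fits["chrSim"].diagnostics["trimmed_fraction"]
        sd = np.sqrt(expected * (1 - expected) / len(table))
        assert abs(observed - expected) < 5 * sd + 0.002

    def test_refit_deviance_not_worse_on_retained(self, small_world):
        """Plain-refit contract: step 2 maximizes the NB likelihood on the
        retained pairs, so its deviance there cannot exceed step 1's."""
        table, truth = small_world
        from hicnb.background import (
            CovariateScaler, _nb_threshold, _stratified_subsample, build_design,
            nb_deviance, pair_covariates)
        cov = pair_covariates(table, truth.features)
        d = table["distance"].to_numpy(float)
        y = table["count"].to_numpy(float)
        spline = choose_knots(d)
        scaler = CovariateScaler.fit(cov)
        X = build_design(d, cov, spline, scaler, "spline")
        rng = np.random.default_rng(4)
        take = _stratified_subsample(d, 0.25, 20_000, rng)
        fit1 = fit_nb_glm(y[take], X[take])
        thr = _nb_threshold(np.exp(X @ fit1.beta), fit1.alpha, 0.975)
        keep = take[y[take] <= thr[take]]
        fit2 = fit_nb_glm(y[keep], X[keep], init=fit1)
        dev1 = nb_deviance(y[keep], np.exp(X[keep] @ fit1.beta), fit2.alpha)
        dev2 = nb_deviance(y[keep], np.exp(X[keep] @ fit2.beta), fit2.alpha)
        assert dev2 <= dev1 + 1e-6 * abs(dev1)

    def test_row_order_invariance(self, small_world):
        table, truth = small_world
        fit_a = two_step_fit(table, truth.features, seed=3, min_subsample=20_000)
        shuffled = table.sample(frac=1.0, random_state=1).reset_index(drop=True)
        fit_b = two_step_fit(shuffled, truth.features, seed=3, min_subsample=20_000)
        np.testing.assert_allclose(fit_a.fits["chrSim"].beta, fit_b.fits["chrSim"].beta,
                                   rtol=1e-6)

    def test_mu_total_matches_observed_total(self, small_world_fit):
        table, truth, fit = small_world_fit
        pred = predict_table(fit, table, truth.features)
        assert pred["mu"].sum() == pytest.approx(table["count"].sum(), rel=0.02)


# ---------------------------------------------------------------------------
# prediction
# ---------------------------------------------------------------------------

class TestPredict:
    def test_centered_covariates_give_intercept(self, small_world_fit):
        table, truth, fit = small_world_fit
        cf = fit.fits["chrSim"]
        # a pair whose scaled covariates are exactly zero and whose distance
        # basis is zeroed contributes only the intercept
        import pandas as pd
        cov = pd.DataFrame({
            "gc": [cf.scaler.mean["gc"]],
            "mappability": [cf.scaler.mean["mappability"]],
            "effective_size": [cf.scaler.mean["effective_size"]],
        })
        X = cf.design(np.array([cf.spline.boundary[0]]), cov)
        manual = np.exp(X @ cf.beta)
        only_int = np.exp(cf.beta[0] + X[0, 1:7] @ cf.beta[1:7])
        assert manual[0] == pytest.approx(only_int)

    def test_permutation_equivariance(self, small_world_fit):
        table, truth, fit = small_world_fit
        sub = table.head(500)
        mu1 = predict_table(fit, sub, truth.features)["mu"].to_numpy()
        perm = sub.sample(frac=1.0, random_state=7)
        mu2 = predict_table(fit, perm, truth.features)["mu"].to_numpy()
        np.testing.assert_allclose(mu2, mu1[perm.index.to_numpy() - sub.index[0]])

    def test_serialization_roundtrip_bit_exact(self, small_world_fit, tmp_path):
        table, truth, fit = small_world_fit
        path = tmp_path / "fit.json"
        fit.to_json(path)
        fit2 = BackgroundFit.from_json(path)
        sub = table.head(1000)
        mu1 = predict_table(fit, sub, truth.features)["mu"].to_numpy()
        mu2 = predict_table(fit2, sub, truth.features)["mu"].to_numpy()
        np.testing.assert_array_equal(mu1, mu2)


# ---------------------------------------------------------------------------
# dispersion models
# ---------------------------------------------------------------------------

class TestDispersion:
    def test_constant_alpha_recovered_per_stratum(self, small_world):
        table, truth = small_world
        y = table["count"].to_numpy(float)
        d = table["distance"].to_numpy(float)
        lookup = estimate_distance_dispersion(y, truth.mu_baseline, d, n_strata=8)
        probe = lookup(np.quantile(d, [0.1, 0.5, 0.9]))
        assert np.all(np.abs(probe - truth.alpha) / truth.alpha < 0.2)

    def test_increasing_dispersion_trend_detected(self):
        rng = np.random.default_rng(8)
        n = 60_000
        d = rng.uniform(1e4, 1e6, n)
        mu = np.full(n, 30.0)
        alpha_d = 0.05 * (1 + d / 1e6)  # doubles across the range
        r = 1 / alpha_d
        y = rng.poisson(rng.gamma(shape=r, scale=mu / r))
        lookup = estimate_distance_dispersion(y, mu, d, n_strata=8)
        lo, hi = lookup(np.array([2e4, 9.5e5]))
        assert hi > lo

    def test_single_stratum_reduces_to_constant(self, small_world):
        table, truth = small_world
        y = table["count"].to_numpy(float)
        d = table["distance"].to_numpy(float)
        one = estimate_distance_dispersion(y, truth.mu_baseline, d, n_strata=1)
        from hicnb.background import _ml_alpha
        const = _ml_alpha(y, truth.mu_baseline)
        assert one(np.array([5e5]))[0] == pytest.approx(const, rel=1e-6)


# ---------------------------------------------------------------------------
# hurdle / zero-truncated families
# ---------------------------------------------------------------------------

class TestHurdle:
    @pytest.fixture(scope="class")
    def zero_free_world(self):
        table, truth = simulate.simulate_contacts(
            seed=2, n_bins=300, d_max=300_000, peak_mean=500, decay_exponent=0.3)
        assert (table["count"] > 0).all()
        return table, truth

    def test_hurdle_matches_ztnb_when_no_zeros(self, zero_free_world):
        table, truth = zero_free_world
        fz = two_step_fit(table, truth.features, family="ztnb", seed=2,
                          min_subsample=20_000)
        fh = two_step_fit(table, truth.features, family="hurdle", seed=2,
                          min_subsample=20_000)
        pz = call_interactions(table, fz, truth.features)["pvalue"]
        ph = call_interactions(table, fh, truth.features)["pvalue"]
        pred = predict_table(fh, table, truth.features)
        assert pred["pi"].min() > 0.999
        assert np.nanmax(np.abs(pz - ph)) < 1e-6

    def test_hurdle_survival_at_zero_equals_pi(self, zero_free_world):
        from hicnb.calling import pvalue_survival
        pi = np.array([0.7, 0.95])
        p = pvalue_survival(np.array([0, 0]), np.array([5.0, 5.0]), 0.1,
                            family="hurdle", pi=pi)
        np.testing.assert_allclose(p, pi)

    def test_all_zero_raises(self):
        feats = simulate.simulate_features(50, seed=1)
        table = pd.DataFrame({
            "chrom": "chrSim", "bin_i": np.repeat(np.arange(40), 5),
            "bin_j": np.repeat(np.arange(40), 5) + np.tile(np.arange(1, 6), 40),
            "count": 0})
        table["distance"] = (table.bin_j - table.bin_i) * 5000
        with pytest.raises(ValueError):
            two_step_fit(table, feats, family="ztnb", seed=0)
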