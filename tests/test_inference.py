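import numpy as np
import pandas as pd
import pytest

from divstab.inference import (
    CollinearityError,
    DegenerateFitError,
    GroupingError,
    MixedSlopeModel,
    PairingError,
    RangedMajorAxis,
    aic_all_subsets,
    climate_residualize,
    fit_mixed,
    heterogeneity_interaction,
    rma_fit,
    treatment_effects,
)


def _ma_slope_oracle(x, y):
    """Closed-form major-axis slope on ranged variables (independent of the
    eigen-decomposition route used by the implementation)."""
    xr = x / np.ptp(x)
    yr = y / np.ptp(y)
    sxx = np.var(xr, ddof=1)
    syy = np.var(yr, ddof=1)
    sxy = np.cov(xr, yr, ddof=1)[0, 1]
    b = (syy - sxx + np.sqrt((syy - sxx) ** 2 + 4 * sxy**2)) / (2 * sxy)
    return b * np.ptp(y) / np.ptp(x)


class TestRangedMajorAxis:
    def test_exact_line(self):
        x = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
        r = rma_fit(x, 2 * x + 1)
        assert r.slope == pytest.approx(2.0, abs=1e-10)
        assert r.intercept == pytest.approx(1.0, abs=1e-10)

    def test_axis_swap_gives_reciprocal_slope(self):
        x = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
        y = 2 * x + 1
        assert rma_fit(y, x).slope == pytest.approx(1 / rma_fit(x, y).slope, abs=1e-10)

    def test_scale_equivariance(self, rng):
        x = rng.normal(size=60)
        y = 0.8 * x + rng.normal(scale=0.4, size=60)
        assert rma_fit(3.0 * x, y).slope == pytest.approx(rma_fit(x, y).slope / 3.0, rel=1e-10)

    def test_matches_closed_form_oracle(self, rng):
        for _ in range(50):
            x = rng.normal(size=40)
            y = 1.4 * x + rng.normal(scale=0.7, size=40)
            assert rma_fit(x, y).slope == pytest.approx(_ma_slope_oracle(x, y), abs=1e-8)

    def test_ci_brackets_slope_and_estimator_api(self, rng):
        x = rng.normal(size=80)
        y = -0.9 * x + rng.normal(scale=0.5, size=80)
        est = RangedMajorAxis().fit(x, y)
        lo, hi = est.ci95_
        assert lo <= est.slope_ <= hi
        np.testing.assert_allclose(est.predict([0.0]), [est.intercept_])

    def test_zero_range_errors(self):
        with pytest.raises(DegenerateFitError):
            rma_fit([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


def _grouped_xy(rng, n_sites=12, n_blocks=3, slope=-0.5, site_sd=0.4, noise=0.3):
    sites = np.repeat([f"s{i}" for i in range(n_sites)], n_blocks)
    x = rng.uniform(0, 10, size=n_sites * n_blocks)
    site_eff = np.repeat(rng.normal(0, site_sd, n_sites), n_blocks)
    y = 2.0 + slope * x + site_eff + rng.normal(0, noise, n_sites * n_blocks)
    return x, y, sites


class TestMixedSlope:
    def test_identity_predictor(self, rng):
        x, y, sites = _grouped_xy(rng)
        r = fit_mixed(y, y, sites)
        assert r.slope == pytest.approx(1.0, abs=1e-6)
        assert r.chi2 > 50 and r.p < 1e-10

    def test_recovers_generating_slope(self, rng):
        x, y, sites = _grouped_xy(rng, n_sites=30)
        r = fit_mixed(y, x, sites)
        assert r.ci95[0] <= -0.5 <= r.ci95[1]
        assert r.ci95[0] <= r.slope <= r.ci95[1]

    def test_zero_variance_response_errors(self):
        with pytest.raises(DegenerateFitError):
            fit_mixed([1.0] * 6, [1, 2, 3, 4, 5, 6], ["a", "a", "a", "b", "b", "b"])

    def test_single_site_errors(self):
        with pytest.raises(GroupingError):
            fit_mixed([1.0, 2.0, 3.0], [1, 2, 3], ["a", "a", "a"])

    def test_no_group_variance_matches_ols(self, rng):
        # with no among-site variance the random effect collapses and the
        # fixed slope approaches the pooled OLS slope
        x, y, sites = _grouped_xy(rng, n_sites=20, site_sd=0.0, noise=0.5)
        r = fit_mixed(y, x, sites)
        ols = np.polyfit(x, y, 1)[0]
        assert r.slope == pytest.approx(ols, rel=0.05)

    def test_wald_agrees_with_lrt_in_verdict(self, rng):
        x, y, sites = _grouped_xy(rng, n_sites=25)
        lrt = fit_mixed(y, x, sites, test="lrt")
        wald = fit_mixed(y, x, sites, test="wald")
        # the two chi-squares differ numerically for strong effects but
        # share the estimate and the qualitative verdict
        assert wald.slope == pytest.approx(lrt.slope, rel=1e-6)
        assert wald.chi2 > 10 and lrt.chi2 > 10
        assert wald.p < 0.01 and lrt.p < 0.01

    def test_sklearn_param_interface(self):
        est = MixedSlopeModel(test="wald")
        assert est.get_params()["test"] == "wald"
        est.set_params(test="lrt")
        assert est.test == "lrt"


class TestClimateResidualize:
    def _climate(self, rng, n=30):
        return pd.DataFrame(
            {
                "MAT": rng.uniform(-5, 25, n),
                "MAP": rng.uniform(200, 2500, n),
                "temp_range": rng.uniform(10, 40, n),
                "temp_sd": rng.uniform(2, 10, n),
                "precip_cv": rng.uniform(10, 60, n),
                "temp_wettest4": rng.uniform(0, 30, n),
            },
            index=[f"s{i}" for i in range(n)],
        )

    def test_exact_linear_gives_zero_residuals(self, rng):
        clim = self._climate(rng)
        y = pd.Series(3.0 + 0.2 * clim["MAT"], index=clim.index)
        resid = climate_residualize(y, clim)
        np.testing.assert_allclose(resid, 0.0, atol=1e-10)

    def test_constant_covariates_give_centered_response(self, rng):
        clim = self._climate(rng)
        for c in clim.columns:
            clim[c] = 0.0
        y = pd.Series(rng.normal(size=30), index=clim.index)
        with pytest.warns(UserWarning):
            resid = climate_residualize(y, clim)
        np.testing.assert_allclose(resid, y - y.mean(), atol=1e-12)

    def test_residuals_orthogonal_to_covariates(self, rng):
        clim = self._climate(rng)
        y = pd.Series(rng.normal(size=30), index=clim.index)
        resid = climate_residualize(y, clim)
        for c in clim.columns:
            centered = clim[c] - clim[c].mean()
            assert abs(np.dot(resid, centered)) / max(1.0, np.abs(centered).sum()) < 1e-10

    def test_collinear_columns_named(self, rng):
        clim = self._climate(rng)
        clim["temp_sd"] = 2.0 * clim["MAT"]
        y = pd.Series(rng.normal(size=30), index=clim.index)
        with pytest.raises(CollinearityError, match="temp_sd"):
            climate_residualize(y, clim)


class TestAicAllSubsets:
    def test_main_effect_enumeration(self, rng):
        x = pd.DataFrame(rng.normal(size=(40, 3)), columns=list("abc"))
        y = rng.normal(size=40)
        table = aic_all_subsets(y, x)
        assert len(table) == 8

    def test_interaction_requires_mains(self, rng):
        x = pd.DataFrame(rng.normal(size=(40, 2)), columns=list("ab"))
        y = rng.normal(size=40)
        table = aic_all_subsets(y, x, interactions=[("a", "b")])
        # {}, {a}, {b}, {a,b}, {a,b,a:b}
        assert len(table) == 5
        assert set(table["terms"]) == {"1", "a", "b", "a+b", "a+b+a:b"}

    def test_strong_effect_ranks_first(self, rng):
        x = pd.DataFrame(rng.normal(size=(60, 3)), columns=list("abc"))
        y = 2.5 * x["a"].to_numpy() + rng.normal(scale=0.5, size=60)
        table = aic_all_subsets(y, x)
        assert "a" in table.loc[0, "terms"].split("+")

    def test_noise_prefers_intercept_majority(self):
        wins = 0
        for seed in range(21):
            r = np.random.default_rng(seed)
            x = pd.DataFrame(r.normal(size=(35, 1)), columns=["a"])
            table = aic_all_subsets(r.normal(size=35), x)
            wins += table.loc[0, "terms"] == "1"
        assert wins > 10

    def test_refuses_more_than_12_terms(self, rng):
        x = pd.DataFrame(rng.normal(size=(30, 13)), columns=[f"v{i}" for i in range(13)])
        with pytest.raises(ValueError, match="12"):
            aic_all_subsets(rng.normal(size=30), x)


def _metric_frames(rng, n_sites=10, slope_pre=-0.4, slope_post=-0.4):
    rows_pre, rows_post = [], []
    for i in range(n_sites):
        site = f"s{i}"
        eff = rng.normal(0, 0.3)
        for b in range(3):
            x = rng.uniform(0, 10)
            rows_pre.append(
                {"site_id": site, "block_id": f"b{b}", "alpha": x,
                 "log_cv": 1 + slope_pre * x + eff + rng.normal(0, 0.25)}
            )
            x2 = rng.uniform(0, 10)
            rows_post.append(
                {"site_id": site, "block_id": f"b{b}", "alpha": x2,
                 "log_cv": 1 + slope_post * x2 + eff + rng.normal(0, 0.25)}
            )
    return pd.DataFrame(rows_pre), pd.DataFrame(rows_post)


class TestPhaseModels:
    def test_identical_phases_zero_interaction(self, rng):
        pre, _ = _metric_frames(rng)
        r = heterogeneity_interaction(pre, pre.copy(), "alpha", response="log_cv")
        assert r.slope == pytest.approx(0.0, abs=1e-6)
        assert r.chi2 == pytest.approx(0.0, abs=1e-4)

    def test_phase_swap_negates_interaction(self, rng):
        pre, post = _metric_frames(rng, slope_pre=-0.5, slope_post=-0.1)
        fwd = heterogeneity_interaction(pre, post, "alpha", response="log_cv")
        rev = heterogeneity_interaction(post, pre, "alpha", response="log_cv")
        assert rev.slope == pytest.approx(-fwd.slope, rel=1e-4, abs=1e-8)

    def test_attenuation_detected(self, rng):
        pre, post = _metric_frames(rng, n_sites=25, slope_pre=-0.5, slope_post=-0.05)
        r = heterogeneity_interaction(pre, post, "alpha", response="log_cv")
        assert r.slope > 0 and r.p < 0.05

    def test_unmatched_blocks_error(self, rng):
        pre, post = _metric_frames(rng)
        with pytest.raises(PairingError, match="s0"):
            heterogeneity_interaction(pre, post[post["site_id"] != "s0"], "alpha")

    def test_identical_phase_effect_zero(self, rng):
        pre, _ = _metric_frames(rng)
        r = treatment_effects(pre, pre.copy(), "log_cv")
        assert r.slope == pytest.approx(0.0, abs=1e-8) and r.chi2 == pytest.approx(0.0, abs=1e-6)

    def test_shifted_phase_effect_detected(self, rng):
        pre, post = _metric_frames(rng, n_sites=15)
        post = post.copy()
        post["log_cv"] = post["log_cv"] + 1.0
        r = treatment_effects(pre, post, "log_cv")
        assert r.slope > 0.5 and r.p < 0.01
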