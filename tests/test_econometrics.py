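"""Regression estimators: exact identities, recovery, and calibration."""

import warnings

import numpy as np
import pandas as pd
import pytest

from ecoeff.econometrics import (
    TobitSpec,
    iv_2sls,
    lagged_regressor_fit,
    marginal_effect,
    moderation_fit,
    ols,
    pooled_ols,
    subsample_fit,
    threshold_fit,
    tobit_fit,
    winsorize,
)
from ecoeff.exceptions import EstimationError, SingularityError, ValidationError
from ecoeff.synthetic import SyntheticConfig, generate_regression_panel


def _panel(**kw):
    return generate_regression_panel(SyntheticConfig(**kw)).data


class TestPooledOLS:
    def test_regressing_a_variable_on_itself(self, default_panel):
        fit = ols(default_panel.data, "ndi", ["ndi"])
        assert fit.params["ndi"] == pytest.approx(1.0, abs=1e-10)
        assert fit.params["const"] == pytest.approx(0.0, abs=1e-10)
        assert np.max(np.abs(fit.resid)) < 1e-10

    def test_stochastic_estimate_within_two_se_of_truth(self):
        fit = pooled_ols(_panel(seed=11), winsor=0.0)
        assert abs(fit.params["ndi"] - 1.0) <= 2 * fit.se["ndi"]

    def test_winsorization_idempotent(self):
        rng = np.random.default_rng(0)
        x = rng.standard_cauchy(500)
        once = winsorize(x, 0.01)
        np.testing.assert_array_equal(winsorize(once, 0.01), once)

    def test_t_values_equal_coef_over_se(self, default_panel):
        fit = pooled_ols(default_panel.data)
        np.testing.assert_allclose(fit.tvalues, fit.params / fit.se, rtol=1e-12)

    def test_robust_se_available(self, default_panel):
        fit = pooled_ols(default_panel.data)
        assert fit.robust_se is not None and (fit.robust_se > 0).all()

    def test_rank_deficient_design_names_columns(self, default_panel):
        df = default_panel.data.assign(dup=lambda d: 2.0 * d["ndi"])
        with pytest.raises(SingularityError):
            ols(df, "aee_vrs", ["ndi", "dup"])

    def test_winsor_fraction_bounds_enforced(self, default_panel):
        with pytest.raises(ValidationError):
            pooled_ols(default_panel.data, winsor=0.2)

    def test_subdimension_regressors_accepted(self, default_panel):
        for reg in ("infi", "ci", "inni"):
            fit = pooled_ols(default_panel.data, regressor=reg)
            assert reg in fit.params.index


class TestThreshold:
    def test_noise_free_regime_coefficients_exact(self):
        df = _panel(seed=2, sigma_eps=0.0, beta_low=15.0, beta_high=-4.0,
                    theta_true=0.28, beta_ndi=0.0)
        tf = threshold_fit(df, seed=0)
        assert tf.regime_coefs[0] == pytest.approx(15.0, abs=1e-6)
        assert tf.regime_coefs[1] == pytest.approx(-4.0, abs=1e-6)
        # estimated split reproduces the true regime assignment
        v = df["inni"]
        assert ((v <= tf.theta_hat) == (v <= 0.28)).all()

    def test_threshold_estimate_in_grid(self):
        df = _panel(seed=5, beta_low=15.0, beta_high=-4.0, sigma_eps=0.5)
        tf = threshold_fit(df, seed=1)
        assert tf.theta_hat in tf.grid
        assert tf.n_boot == 300
        assert 0.0 <= tf.boot_p <= 1.0

    def test_no_threshold_null_is_rarely_rejected(self):
        """With equal regime slopes the bootstrap p-value should exceed 0.10
        in the large majority of replications (test size calibration)."""
        clear = 0
        for s in range(50):
            # beta_ndi = 0 keeps the null clean: with it on, the persistent
            # omitted NDI components violate the bootstrap's iid assumption
            df = _panel(seed=s, beta_ndi=0.0, beta_low=0.5, beta_high=0.5,
                        sigma_eps=0.5)
            tf = threshold_fit(df, seed=s, max_thresholds=1)
            clear += tf.boot_p > 0.10
        assert clear >= 0.85 * 50

    def test_strong_single_threshold_usually_classified_single(self):
        """The sequential test should detect the threshold every time and
        stop at one threshold in most replications (second stage tests at 5%,
        so occasional spurious doubles are expected)."""
        detected = singles = 0
        for s in range(10):
            df = _panel(seed=200 + s, beta_low=15.0, beta_high=-4.0, sigma_eps=0.5)
            tf = threshold_fit(df, seed=s)
            detected += tf.boot_p <= 0.05
            singles += tf.n_thresholds == 1
        assert detected == 10
        assert singles >= 8

    def test_small_bootstrap_rejected(self, default_panel):
        with pytest.raises(ValidationError):
            threshold_fit(default_panel.data, n_boot=50)


class TestModeration:
    def test_noise_free_interaction_exact(self):
        df = _panel(seed=2, sigma_eps=0.0, gamma_interact=0.15)
        fit = moderation_fit(df, time_fe=False)
        assert fit.params["ndi_lu"] == pytest.approx(0.15, abs=1e-10)

    def test_stochastic_interaction_within_two_se(self):
        fit = moderation_fit(_panel(seed=3, gamma_interact=0.15), time_fe=False)
        assert abs(fit.params["ndi_lu"] - 0.15) <= 2 * fit.se["ndi_lu"]

    def test_time_fixed_effects_add_year_dummies(self, default_panel):
        fit = moderation_fit(default_panel.data, time_fe=True)
        assert sum(c.startswith("year_") for c in fit.params.index) == 9

    def test_constant_moderator_is_collinear(self, default_panel):
        df = default_panel.data.assign(lu=55.0)
        with pytest.raises(SingularityError):
            moderation_fit(df, time_fe=False)

    def test_marginal_effect_linear_in_lu(self):
        fit = moderation_fit(_panel(seed=4, gamma_interact=0.1), time_fe=False)
        a1, a3 = fit.params["ndi"], fit.params["ndi_lu"]
        assert marginal_effect(fit, 50.0) == pytest.approx(a1 + 50 * a3)


class TestLagged:
    def test_first_year_drops_out(self, default_panel):
        fit = lagged_regressor_fit(default_panel.data)
        assert fit.n_obs == 270  # 30 units x 9 remaining years

    def test_static_regressor_matches_pooled_on_truncated_sample(self, default_panel):
        df = default_panel.data.copy()
        first = df.groupby("unit")["ndi"].transform("first")
        df["ndi"] = first  # time-invariant regressor: lag == level
        lagged = lagged_regressor_fit(df)
        trunc = df[df["year"] > df["year"].min()]
        direct = pooled_ols(trunc, winsor=0.0)
        assert lagged.params["ndi_lag"] == pytest.approx(direct.params["ndi"], rel=1e-10)

    def test_single_year_panel_rejected(self, default_panel):
        df = default_panel.data[default_panel.data["year"] == 2011]
        with pytest.raises(ValidationError):
            lagged_regressor_fit(df)


class TestTobit:
    def test_equals_ols_without_censoring(self, default_panel):
        f_ols = pooled_ols(default_panel.data, winsor=0.0)
        f_tob = tobit_fit(default_panel.data, TobitSpec(lower_bound=-1e6))
        np.testing.assert_allclose(f_tob.params, f_ols.params, atol=1e-4)
        assert f_tob.extra["n_censored"] == 0

    def test_all_censored_is_unidentified(self, default_panel):
        with pytest.raises(EstimationError):
            tobit_fit(default_panel.data, TobitSpec(lower_bound=1e6))

    def test_censored_slope_within_two_se(self):
        sp = generate_regression_panel(SyntheticConfig(seed=6, censor_frac=0.2))
        fit = tobit_fit(sp.data, TobitSpec(lower_bound=sp.censor_bound))
        assert fit.extra["n_censored"] > 0
        assert abs(fit.params["ndi"] - 1.0) <= 2 * fit.se["ndi"]

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ValidationError):
            TobitSpec(lower_bound=1.0, upper_bound=0.0)


class TestIV:
    def test_perfect_instrument_reproduces_ols_exactly(self, default_panel):
        df = default_panel.data.assign(iv=lambda d: d["ndi"])
        _, second = iv_2sls(df, "iv")
        f_ols = pooled_ols(df, winsor=0.0)
        np.testing.assert_allclose(second.params, f_ols.params, atol=1e-10)

    def test_irrelevant_instrument_warns_weak(self, default_panel):
        rng = np.random.default_rng(0)
        df = default_panel.data.assign(iv=rng.normal(size=300))
        with pytest.warns(UserWarning, match="weak instrument"):
            iv_2sls(df, "iv")

    def test_first_stage_reports_excluded_f(self, default_panel):
        df = default_panel.data.assign(
            iv=lambda d: d["ndi"] + 0.05 * np.random.default_rng(1).normal(size=300))
        first, _ = iv_2sls(df, "iv")
        assert first.extra["f_excluded"] > 10

    def test_constant_instrument_rejected(self, default_panel):
        df = default_panel.data.assign(iv=1.0)
        with pytest.raises(ValidationError):
            iv_2sls(df, "iv")

    def test_iv_less_biased_than_ols_under_endogeneity(self):
        """Shared confounder in regressor and outcome: 2SLS with a valid
        instrument shrinks the bias OLS incurs."""
        b_ols, b_iv = [], []
        for s in range(40):
            rng = np.random.default_rng(s)
            df = _panel(seed=s, sigma_eps=0.0)
            n = len(df)
            u = rng.normal(0, 1, n)      # confounder
            z = rng.normal(0, 1, n)      # instrument
            df["ndi"] = df["ndi"] + 0.08 * z + 0.08 * u
            df["aee_vrs"] = (df["aee_vrs"] + 1.0 * (0.08 * z + 0.08 * u)
                             + 0.5 * u + rng.normal(0, 0.3, n))
            df["iv"] = z
            b_ols.append(pooled_ols(df, winsor=0.0).params["ndi"])
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                b_iv.append(iv_2sls(df, "iv")[1].params["ndi"])
        assert np.mean(np.abs(np.array(b_iv) - 1.0)) < np.mean(np.abs(np.array(b_ols) - 1.0))


class TestSubsample:
    def test_year_split_sizes(self, default_panel):
        early, late = subsample_fit(
            default_panel.data, lambda d: d["year"] <= 2016, winsor=0.0)
        assert (early.n_obs, late.n_obs) == (180, 120)

    def test_identical_dgp_sides_agree_within_joint_ci(self):
        df = _panel(seed=13)
        a, b = subsample_fit(df, lambda d: d["year"] <= 2016, winsor=0.0)
        diff = abs(a.params["ndi"] - b.params["ndi"])
        joint = np.hypot(a.se["ndi"], b.se["ndi"])
        assert diff <= 2 * joint

    def test_degenerate_split_rejected(self, default_panel):
        with pytest.raises(ValidationError):
            subsample_fit(default_panel.data, lambda d: d["year"] > 0)
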