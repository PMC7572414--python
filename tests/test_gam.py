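import numpy as np
import pandas as pd
import pytest

from pelagidiet.gam import (choose_family, collinearity_diagnostics,
                            fit_additive_model, stepwise_select)


def linear_frame(n=300, slope=2.0, noise=0.3, seed=0):
    rng = np.random.default_rng(seed)
    x1 = rng.uniform(0, 1, n)
    x2 = rng.uniform(0, 1, n)
    y = slope * x1 + rng.normal(0, noise, n)
    return pd.DataFrame({"y": y, "x1": x1, "x2": x2})


class TestCollinearity:
    def test_orthogonal_predictors_unflagged(self, rng):
        df = pd.DataFrame({"a": rng.normal(size=300), "b": rng.normal(size=300)})
        rep = collinearity_diagnostics(df)
        assert rep.gvif.max() < 1.1
        assert rep.passed

    def test_constructed_collinearity_flagged(self, rng):
        x = rng.uniform(0, 1, 200)
        df = pd.DataFrame({"x1": x, "x2": x + rng.normal(0, 0.01, 200)})
        rep = collinearity_diagnostics(df)
        assert any(abs(r) >= 0.70 for _, _, r in rep.corr_flags)
        assert all(v >= 3 for _, v in rep.gvif_flags) and rep.gvif_flags

    def test_single_predictor_gvif_is_one(self, rng):
        rep = collinearity_diagnostics(pd.DataFrame({"x": rng.normal(size=50)}))
        assert rep.gvif["x"] == 1.0

    def test_factor_term_grouped(self, rng):
        df = pd.DataFrame({"x": rng.normal(size=120),
                           "f": rng.choice(list("abc"), 120)})
        rep = collinearity_diagnostics(df)
        assert set(rep.gvif.index) == {"x", "f"}

    def test_constant_predictor_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            collinearity_diagnostics(pd.DataFrame({"x": [1.0] * 10,
                                                   "y": [1, 2] * 5}))


class TestFamilyChoice:
    def test_normal_sample_takes_identity(self, rng):
        dec = choose_family(rng.normal(0, 1, 200))
        assert dec.family == "gaussian-identity"
        assert dec.path[0][0] == "shapiro_raw"

    def test_skewed_positive_sample_takes_log_or_gamma(self, rng):
        dec = choose_family(rng.lognormal(0, 1.5, 200))
        assert dec.family in {"gaussian-log", "gamma-log"}
        assert len(dec.path) == 2

    def test_zeros_on_log_path_name_offending_rows(self, rng):
        y = rng.lognormal(0, 2, 100)
        y[[3, 17]] = 0.0
        with pytest.raises(ValueError, match=r"\[3, 17\]"):
            choose_family(y)


class TestAdditiveFit:
    def test_linear_truth_recovery(self):
        df = linear_frame()
        fit = fit_additive_model(df, "y", smooth_terms=["x1"])
        assert fit.edf["x1"] == pytest.approx(1.0, abs=0.2)
        # deviance explained matches the R^2 of a straight-line fit
        r = np.corrcoef(df.x1, df.y)[0, 1]
        assert fit.deviance_explained == pytest.approx(100 * r**2, abs=2.0)

    def test_pure_noise_explains_little(self, rng):
        df = pd.DataFrame({"y": rng.normal(size=300),
                           "x1": rng.uniform(size=300)})
        fit = fit_additive_model(df, "y", smooth_terms=["x1"])
        assert fit.deviance_explained < 5.0

    def test_unpenalized_limit_matches_ols_oracle(self):
        import statsmodels.api as sm
        df = linear_frame(noise=0.5, seed=3)
        fit = fit_additive_model(df, "y", smooth_terms=["x1"],
                                 lambdas={"x1": 1e9})
        X = sm.add_constant(df["x1"].to_numpy())
        ols = sm.OLS(df["y"].to_numpy(), X).fit()
        np.testing.assert_allclose(fit.fitted_values, ols.fittedvalues,
                                   atol=1e-4)

    def test_edf_limits_in_lambda(self):
        df = linear_frame(seed=4)
        lo = fit_additive_model(df, "y", smooth_terms=["x1"],
                                lambdas={"x1": 1e-9})
        hi = fit_additive_model(df, "y", smooth_terms=["x1"],
                                lambdas={"x1": 1e9})
        assert lo.edf["x1"] == pytest.approx(3.0, abs=0.05)  # k - 1 with k=4
        assert hi.edf["x1"] == pytest.approx(1.0, abs=0.05)
        assert 1.0 - 0.06 <= hi.edf["x1"] <= lo.edf["x1"] <= 4.0

    def test_deviance_invariant_to_predictor_rescaling(self):
        df = linear_frame(seed=5)
        base = fit_additive_model(df, "y", smooth_terms=["x1"])
        df2 = df.assign(x1=df.x1 * 1000 - 37.5)
        scaled = fit_additive_model(df2, "y", smooth_terms=["x1"])
        assert scaled.deviance_explained == pytest.approx(
            base.deviance_explained, abs=0.1)

    def test_gamma_log_on_positive_response(self, rng):
        x = rng.uniform(0, 1, 300)
        mu = np.exp(0.5 + 1.5 * x)
        df = pd.DataFrame({"y": rng.gamma(5, mu / 5), "x": x})
        fit = fit_additive_model(df, "y", smooth_terms=["x"], family="gamma-log")
        assert (fit.fitted_values > 0).all()
        assert fit.deviance_explained > 10.0

    def test_nonpositive_response_rejected_for_gamma(self):
        df = pd.DataFrame({"y": [1.0, 0.0, 2.0, 3.0, 1.0, 2.0],
                           "x": [0.0, 0.2, 0.4, 0.6, 0.8, 1.0]})
        with pytest.raises(ValueError, match="rows"):
            fit_additive_model(df, "y", smooth_terms=["x"], family="gamma-log")

    def test_factor_coefficients_reported_with_se(self, rng):
        n = 200
        f = rng.choice(["lo", "hi"], n)
        y = (f == "hi") * 1.5 + rng.normal(0, 0.5, n)
        df = pd.DataFrame({"y": y, "f": f})
        fit = fit_additive_model(df, "y", factor_terms=["f"])
        coef = fit.coefficients
        assert "Intercept" in coef.index
        assert (coef["se"] > 0).all()
        effect = coef.loc[[i for i in coef.index if i.startswith("f[")],
                          "estimate"].iloc[0]
        assert abs(abs(effect) - 1.5) < 0.3


class TestStepwise:
    def test_single_candidate_returned(self):
        df = linear_frame()
        fit, trace = stepwise_select(df, "y", candidate_smooths=["x1"])
        assert fit.smooth_terms == ["x1"]
        assert trace[-1][0] == "final"

    def test_noise_covariate_excluded(self):
        df = linear_frame(seed=11)
        fit, _ = stepwise_select(df, "y", candidate_smooths=["x1", "x2"])
        assert "x1" in fit.smooth_terms
        assert "x2" not in fit.smooth_terms

    def test_selected_aic_not_worse_than_full(self):
        df = linear_frame(seed=12)
        best, _ = stepwise_select(df, "y", candidate_smooths=["x1", "x2"])
        full = fit_additive_model(df, "y", smooth_terms=["x1", "x2"])
        assert best.aic <= full.aic + 2.0

    def test_no_candidates_rejected(self):
        with pytest.raises(ValueError):
            stepwise_select(linear_frame(), "y")
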