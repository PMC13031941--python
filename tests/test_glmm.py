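"""NB mixed model: likelihood reductions, marginal means, contrasts, diagnostics."""

import numpy as np
import pandas as pd
import pytest

import finpulse as fp
from finpulse.glmm import NegativeBinomialGLMM


class TestReductions:
    def test_zero_variance_matches_plain_nb_regression(self, no_re_count_table):
        """With both random-effect SDs fixed at 0 the Laplace model collapses
        to an ordinary NB regression; cross-check against statsmodels."""
        import statsmodels.api as sm

        fit = NegativeBinomialGLMM(
            fix_sigma_instrument=0.0, fix_sigma_day=0.0
        ).fit(no_re_count_table)
        y = no_re_count_table["count"].to_numpy()
        X = pd.get_dummies(no_re_count_table["period"], dtype=float)[fit.period_names_]
        sm_fit = sm.NegativeBinomial(y, X.to_numpy()).fit(disp=0)
        assert np.allclose(fit.beta_.to_numpy(), sm_fit.params[:-1], atol=1e-3)
        # statsmodels parametrises overdispersion as alpha = 1/theta
        assert fit.theta_ == pytest.approx(1.0 / sm_fit.params[-1], rel=2e-3)

    def test_intercept_only_recovers_sample_mean(self):
        rng = np.random.default_rng(0)
        mu, theta = 40.0, 5.0
        y = rng.negative_binomial(theta, theta / (theta + mu), size=3000)
        data = pd.DataFrame(
            {"count": y, "period": "all", "instrument": "I0", "jd": np.arange(y.size) % 50}
        )
        fit = NegativeBinomialGLMM(fix_sigma_instrument=0.0, fix_sigma_day=0.0).fit(data)
        assert np.exp(fit.beta_.iloc[0]) == pytest.approx(y.mean(), rel=1e-4)

    def test_treatment_and_means_codings_agree_on_emms(self, no_re_count_table):
        m1 = NegativeBinomialGLMM(fix_sigma_instrument=0.0, fix_sigma_day=0.0).fit(
            no_re_count_table
        )
        m2 = NegativeBinomialGLMM(
            coding="treatment", fix_sigma_instrument=0.0, fix_sigma_day=0.0
        ).fit(no_re_count_table)
        e1 = m1.emmeans().set_index("period")["emm"]
        e2 = m2.emmeans().set_index("period")["emm"]
        assert np.allclose(e1, e2[e1.index], rtol=1e-4)


class TestFit:
    @pytest.fixture(scope="class")
    def fit(self, small_count_table):
        return fp.fit_nb_glmm(small_count_table)

    def test_recovers_simulation_settings(self, fit):
        from finpulse.counts import DEFAULT_BETA

        for name in fit.period_names_:
            assert abs(fit.beta_[name] - DEFAULT_BETA[name]) < 4 * fit.se_beta_[name]
        assert 3.0 < fit.theta_ < 12.0
        assert 0.2 < fit.sigma_day_ < 0.7

    def test_emm_is_exponentiated_linear_predictor(self, fit):
        emm = fit.emmeans().set_index("period")
        for name in fit.period_names_:
            assert emm.loc[name, "emm"] == pytest.approx(np.exp(fit.beta_[name]))

    def test_emm_ordering_matches_beta_ordering(self, fit):
        emm = fit.emmeans()
        assert (
            emm.sort_values("log_emm")["period"].tolist()
            == emm.sort_values("emm")["period"].tolist()
        )

    def test_emms_close_to_cell_means_without_random_effects(self, no_re_count_table):
        fit = NegativeBinomialGLMM(fix_sigma_instrument=0.0, fix_sigma_day=0.0).fit(
            no_re_count_table
        )
        emm = fit.emmeans().set_index("period")["emm"]
        cell = no_re_count_table.groupby("period")["count"].mean()
        assert np.allclose(emm, cell[emm.index], rtol=1e-3)

    def test_rank_deficient_design_rejected(self):
        data = pd.DataFrame(
            {"count": [1, 2, 3, 4], "period": "only", "instrument": ["A", "A", "B", "B"],
             "jd": [1, 2, 1, 2]}
        )
        fit = NegativeBinomialGLMM(coding="treatment", reference="missing")
        with pytest.raises(ValueError):
            fit.fit(data)


class TestContrasts:
    @pytest.fixture(scope="class")
    def contrasts(self, small_count_table):
        fit = fp.fit_nb_glmm(small_count_table)
        return fit.pairwise_contrasts(seed=0, n_mc=20_000)

    def test_all_pairs_present(self, contrasts):
        assert len(contrasts) == 6  # 4 periods choose 2

    def test_adjusted_never_below_unadjusted(self, contrasts):
        assert (contrasts["p_adjusted"] >= contrasts["p_unadjusted"] - 1e-12).all()

    def test_quiet_vs_shooting_significant(self, contrasts):
        c = contrasts.set_index("contrast")
        assert c.loc["Shooting 1 / Quiet 1", "p_adjusted"] < 0.05
        assert c.loc["Quiet 1 / Shooting 2", "p_adjusted"] < 0.05

    def test_null_contrast_large_p(self):
        beta = {p.name: float(np.log(30.0)) for p in fp.DEFAULT_PERIODS}
        data = fp.simulate_counts(
            fp.CountSimConfig(beta=beta, sigma_instrument=0.0, sigma_day=0.05, seed=3)
        )
        fit = fp.fit_nb_glmm(data)
        c = fit.pairwise_contrasts(seed=0, n_mc=20_000)
        assert (c["p_adjusted"] > 0.05).all()

    def test_rate_ratio_consistent_with_log(self, contrasts):
        assert np.allclose(contrasts["rate_ratio"], np.exp(contrasts["log_ratio"]))


class TestDiagnostics:
    def test_self_consistent_model_residuals_uniform(self, small_count_table):
        fit = fp.fit_nb_glmm(small_count_table)
        report = fit.diagnostics(n_sim=100, seed=0)
        assert report["ks_pvalue"] > 0.01
        assert 0.7 < report["dispersion_ratio"] < 1.3

    def test_zero_inflated_data_flagged(self):
        data = fp.simulate_counts(fp.CountSimConfig(seed=4))
        rng = np.random.default_rng(1)
        zeroed = data.copy()
        zeroed.loc[rng.random(len(zeroed)) < 0.3, "count"] = 0
        fit = fp.fit_nb_glmm(zeroed)
        report = fit.diagnostics(n_sim=100, seed=0)
        assert report["zeros_observed"] > report["zeros_expected"]
        assert report["zero_inflation_pvalue"] < 0.05
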