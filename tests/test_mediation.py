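"""Model fits, counterfactual decomposition, oracle agreement, bootstrap."""

import numpy as np
import pytest

from medgwg.errors import FitError, InferenceError
from medgwg.mediation import (Contrast, MediatorModelFit,
                              OutcomeModelFit, _logistic_irls,
                              bootstrap_decomposition, decompose_effects,
                              fit_mediator_model, fit_outcome_model,
                              mc_counterfactual_oracle, proportion_mediated)


class TestLogisticFit:
    def test_matches_statsmodels_mle(self, analysis_rows):
        import statsmodels.api as sm

        from medgwg.mediation import covariate_design
        mfit = fit_mediator_model(analysis_rows)
        C, _ = covariate_design(analysis_rows)
        X = np.column_stack([np.ones(len(analysis_rows)),
                             analysis_rows.bmi.to_numpy(float), C])
        ref = sm.Logit(analysis_rows.excessive_gwg.to_numpy(float), X).fit(disp=0)
        np.testing.assert_allclose(mfit.params, ref.params, atol=1e-6)
        np.testing.assert_allclose(mfit.vcov, ref.cov_params(), rtol=1e-4)

    def test_balanced_toy_data_zero_slope(self):
        # M balanced within each exposure level -> exact symmetry
        A = np.repeat([0.0, 1.0], 10)
        M = np.tile([0.0, 1.0], 10)
        X = np.column_stack([np.ones(20), A])
        beta, _, converged = _logistic_irls(X, M)
        assert converged
        assert beta[1] == pytest.approx(0.0, abs=1e-8)

    def test_null_exposure_effect(self):
        """With beta1 = 0 the fitted exposure slope is a centred
        z-statistic: across seeds nearly all lie within 3 SE and their
        mean is near zero (a single seed can legitimately exceed 3 SE)."""
        from medgwg.synthetic import GeneratorConfig, generate_cohort
        zs = []
        for s in range(10):
            cfg = GeneratorConfig(n_pairs=5_000, seed=s, beta_bmi=0.0)
            mfit = fit_mediator_model(generate_cohort(cfg).latent)
            zs.append(mfit.beta1 / np.sqrt(mfit.vcov[1, 1]))
        zs = np.asarray(zs)
        assert (np.abs(zs) < 3).sum() >= 9
        assert abs(zs.mean()) < 1.5

    def test_constant_mediator_rejected(self, analysis_rows):
        rows = analysis_rows.copy()
        rows["excessive_gwg"] = 1
        with pytest.raises(FitError, match="constant"):
            fit_mediator_model(rows)

    def test_separation_detected(self):
        x = np.linspace(-2, 2, 40)
        y = (x > 0).astype(float)
        with pytest.raises(FitError, match="separat|singular|diverg"):
            _logistic_irls(np.column_stack([np.ones(40), x]), y)


class TestOutcomeFit:
    def test_constant_outcome(self, analysis_rows):
        rows = analysis_rows.copy()
        rows["child_z"] = 1.25
        ofit = fit_outcome_model(rows)
        assert ofit.theta0 == pytest.approx(1.25, abs=1e-10)
        np.testing.assert_allclose(ofit.params[1:], 0.0, atol=1e-10)
        assert ofit.sigma == pytest.approx(0.0, abs=1e-10)

    def test_exact_linear_structure(self, analysis_rows):
        rows = analysis_rows.copy()
        rows["child_z"] = 1.0 + 0.5 * rows.bmi
        ofit = fit_outcome_model(rows)
        assert ofit.theta0 == pytest.approx(1.0, abs=1e-8)
        assert ofit.theta1 == pytest.approx(0.5, abs=1e-10)

    def test_matches_normal_equations(self, analysis_rows):
        from medgwg.mediation import covariate_design
        ofit = fit_outcome_model(analysis_rows)
        C, _ = covariate_design(analysis_rows)
        a = analysis_rows.bmi.to_numpy(float)
        m = analysis_rows.excessive_gwg.to_numpy(float)
        X = np.column_stack([np.ones(len(a)), a, m, a * m, C])
        y = analysis_rows.child_z.to_numpy(float)
        ref = np.linalg.solve(X.T @ X, X.T @ y)
        np.testing.assert_allclose(ofit.params, ref, atol=1e-10)

    def test_collinear_design_rejected(self, analysis_rows):
        rows = analysis_rows.copy()
        rows["cohort_period"] = 1.0     # duplicates the intercept
        with pytest.raises(FitError, match="collinear|rank"):
            fit_outcome_model(rows)


def _toy_fits(theta=(0.1, 0.04, 0.8, -0.02), beta=(-1.0, 0.06), cbar=()):
    """Hand-assembled fit objects for formula-level tests."""
    nc = len(cbar)
    ofit = OutcomeModelFit(
        params=np.array([theta[0], theta[1], theta[2], theta[3]] + [0.0] * nc),
        names=[], vcov=np.eye(4 + nc), sigma=0.5, n=100, interaction=True)
    mfit = MediatorModelFit(
        params=np.array([beta[0], beta[1]] + [0.0] * nc), names=[],
        vcov=np.eye(2 + nc), n=100, converged=True,
        cbar=np.array(cbar, dtype=float))
    return ofit, mfit


class TestDecomposition:
    def test_null_contrast(self):
        ofit, mfit = _toy_fits()
        dec = decompose_effects(ofit, mfit, Contrast(a=25.0, a_star=25.0))
        assert dec.cde == dec.nde == dec.nie == dec.te == 0.0

    def test_no_interaction_identity(self):
        ofit, mfit = _toy_fits(theta=(0.1, 0.04, 0.8, 0.0))
        from scipy.special import expit
        for m_cde in (0.0, 0.5, 1.0):
            dec = decompose_effects(ofit, mfit, Contrast(m_cde=m_cde))
            assert dec.cde == pytest.approx(dec.nde)
        dec = decompose_effects(ofit, mfit)
        p30 = expit(-1.0 + 0.06 * 30)
        p22 = expit(-1.0 + 0.06 * 22)
        assert dec.nie == pytest.approx(0.8 * (p30 - p22))

    def test_cross_world_consistency(self):
        # CDE at m = p(a*) equals the NDE
        ofit, mfit = _toy_fits()
        p_astar = mfit.p_mediator(22.0, np.empty((1, 0))).item()
        dec = decompose_effects(ofit, mfit, Contrast(m_cde=p_astar))
        assert dec.cde == pytest.approx(dec.nde, abs=1e-12)

    def test_additivity(self, analysis_rows):
        dec = decompose_effects(fit_outcome_model(analysis_rows),
                                fit_mediator_model(analysis_rows))
        assert dec.te == dec.nde + dec.nie

    def test_printed_proportion_mediated_arithmetic(self):
        assert 100 * proportion_mediated(0.020, 0.246) == pytest.approx(8.13, abs=0.005)

    def test_te_zero_pm_undefined(self):
        assert np.isnan(proportion_mediated(0.0, 0.0))

    def test_marginal_vs_mean_conditioning_close(self, analysis_rows):
        from medgwg.mediation import covariate_design
        ofit = fit_outcome_model(analysis_rows)
        mfit = fit_mediator_model(analysis_rows)
        C, _ = covariate_design(analysis_rows)
        mean_dec = decompose_effects(ofit, mfit)
        marg_dec = decompose_effects(ofit, mfit,
                                     Contrast(conditioning="marginal"),
                                     covariate_rows=C)
        # expit is nearly linear over the covariate spread; the two
        # conditioning conventions should agree closely but not exactly
        assert marg_dec.nie == pytest.approx(mean_dec.nie, rel=0.15)
        assert marg_dec.te == marg_dec.nde + marg_dec.nie


class TestOracle:
    def test_oracle_deterministic(self):
        ofit, mfit = _toy_fits()
        a = mc_counterfactual_oracle(ofit, mfit, n_mc=10_000, seed=3)
        b = mc_counterfactual_oracle(ofit, mfit, n_mc=10_000, seed=3)
        assert (a.nde, a.nie) == (b.nde, b.nie)

    def test_no_mediator_effect_zero_nie(self):
        ofit, mfit = _toy_fits(theta=(0.1, 0.04, 0.0, 0.0))
        orc = mc_counterfactual_oracle(ofit, mfit, n_mc=10_000, seed=4)
        assert orc.nie == 0.0

    def test_closed_form_within_mc_error(self):
        rng = np.random.default_rng(12)
        for _ in range(5):
            theta = (rng.normal(0, 0.5), rng.normal(0, 0.05),
                     rng.normal(0, 0.5), rng.normal(0, 0.02))
            beta = (rng.normal(-1, 0.5), rng.normal(0.05, 0.03))
            ofit, mfit = _toy_fits(theta=theta, beta=beta)
            dec = decompose_effects(ofit, mfit)
            orc = mc_counterfactual_oracle(ofit, mfit, n_mc=400_000,
                                           seed=int(rng.integers(2**31)))
            assert abs(dec.nde - orc.nde) <= 3 * orc.se_nde + 1e-12
            assert abs(dec.nie - orc.nie) <= 3 * orc.se_nie + 1e-12

    def test_noise_cancels_in_expectation(self):
        ofit, mfit = _toy_fits()
        noisy = mc_counterfactual_oracle(ofit, mfit, n_mc=400_000, seed=6,
                                         include_noise=True)
        clean = mc_counterfactual_oracle(ofit, mfit, n_mc=400_000, seed=6)
        assert noisy.nde == pytest.approx(clean.nde, abs=3 * noisy.se_nde)
        assert noisy.nie == pytest.approx(clean.nie, abs=3 * noisy.se_nie)


class TestBootstrap:
    def test_deterministic_given_seed(self, analysis_rows):
        a = bootstrap_decomposition(analysis_rows, B=50, seed=21)
        b = bootstrap_decomposition(analysis_rows, B=50, seed=21)
        assert a.ci_nie == b.ci_nie and a.ci_te == b.ci_te

    def test_zero_outcome_variance_zero_width_intervals(self, analysis_rows):
        rows = analysis_rows.copy()
        rows["child_z"] = 0.7
        dec = bootstrap_decomposition(rows, B=50, seed=1)
        for ci in (dec.ci_cde, dec.ci_nde, dec.ci_nie, dec.ci_te):
            assert ci[1] - ci[0] == pytest.approx(0.0, abs=1e-10)

    def test_additivity_on_every_replicate(self, analysis_rows):
        dec = bootstrap_decomposition(analysis_rows, B=100, seed=2,
                                      keep_replicates=True)
        np.testing.assert_allclose(
            dec.replicates["te"],
            dec.replicates["nde"] + dec.replicates["nie"], atol=1e-12)

    def test_interval_brackets_point(self, analysis_rows):
        dec = bootstrap_decomposition(analysis_rows, B=200, seed=3)
        for point, ci in ((dec.cde, dec.ci_cde), (dec.nde, dec.ci_nde),
                          (dec.nie, dec.ci_nie), (dec.te, dec.ci_te)):
            assert ci[0] <= point <= ci[1]

    def test_too_many_failures_raise(self, analysis_rows):
        # 12 rows with a rare mediator: most resamples are constant in M
        rows = analysis_rows.head(12).copy()
        rows["excessive_gwg"] = [1] + [0] * 11
        with pytest.raises((InferenceError, FitError)):
            bootstrap_decomposition(rows, B=100, seed=4)
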