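"""Synthetic-cohort generator: determinism, truth, calibration, corruption."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from medgwg.anthropometry import derive_analysis_rows
from medgwg.cleaning import GrowthSeries, flag_nonmonotone
from medgwg.errors import ConfigError
from medgwg.mediation import fit_mediator_model, fit_outcome_model
from medgwg.synthetic import (GeneratorConfig, generate_cohort,
                              generate_growth_series, inject_errors,
                              true_effects)


class TestDeterminism:
    def test_identical_seed_identical_cohort(self):
        cfg = GeneratorConfig(n_pairs=100, seed=7)
        a, b = generate_cohort(cfg), generate_cohort(cfg)
        pd.testing.assert_frame_equal(a.mothers, b.mothers)
        pd.testing.assert_frame_equal(a.growth, b.growth)
        assert a.truth == b.truth

    def test_injection_deterministic(self):
        cfg = GeneratorConfig(n_pairs=100, seed=7, glitch_rate=0.2)
        a = inject_errors(generate_cohort(cfg), cfg)
        b = inject_errors(generate_cohort(cfg), cfg)
        pd.testing.assert_frame_equal(a.growth, b.growth)
        pd.testing.assert_frame_equal(a.mothers, b.mothers)


class TestTruth:
    def test_null_model_has_null_effects(self):
        cfg = GeneratorConfig(theta_bmi=0.0, theta_m=0.0, theta_am=0.0)
        t = true_effects(cfg)
        assert t["cde"] == t["nde"] == t["nie"] == t["te"] == 0.0

    def test_additivity_exact(self, default_config):
        t = true_effects(default_config)
        assert t["te"] == t["nde"] + t["nie"]

    def test_default_truth_magnitudes(self, default_config):
        # the shipped defaults are calibrated to a positive, partially
        # mediated effect of maternal BMI on child z-score
        t = true_effects(default_config)
        assert t["nie"] > 0 and t["nde"] > 0
        assert 0 < t["proportion_mediated"] < 0.2


class TestConsistency:
    def test_large_n_recovers_coefficients(self):
        cfg = GeneratorConfig(n_pairs=50_000, seed=42, beta_bmi=0.1,
                              theta_bmi=0.03, theta_m=0.2, theta_am=0.0)
        cohort = generate_cohort(cfg)
        mfit = fit_mediator_model(cohort.latent)
        ofit = fit_outcome_model(cohort.latent)
        true_beta = np.concatenate([[cfg.beta0, cfg.beta_bmi], cfg.beta_vector()])
        se_beta = np.sqrt(np.diag(mfit.vcov))
        np.testing.assert_array_less(np.abs(mfit.params - true_beta), 3 * se_beta)
        true_theta = np.concatenate([[cfg.theta0, cfg.theta_bmi, cfg.theta_m,
                                      cfg.theta_am], cfg.theta_vector()])
        se_theta = np.sqrt(np.diag(ofit.vcov))
        np.testing.assert_array_less(np.abs(ofit.params - true_theta), 3 * se_theta)


class TestMarginalCalibration:
    def test_table1_like_prevalences(self):
        """Under the shipped defaults the cohort mimics the published
        composition: child overweight/obese in [0.18, 0.30] and excessive
        GWG in [0.45, 0.65] on average across seeds."""
        from scipy.special import ndtri
        q85 = ndtri(0.85)
        child, gwg = [], []
        for s in range(100):
            lat = generate_cohort(
                dataclasses.replace(GeneratorConfig(), seed=s)).latent
            child.append((lat.child_z >= q85).mean())
            gwg.append(lat.excessive_gwg.mean())
        assert 0.18 <= np.mean(child) <= 0.30
        assert 0.45 <= np.mean(gwg) <= 0.65


class TestGrowthSeries:
    def test_target_z_zero_hits_interpolated_median(self, lms):
        recs = generate_growth_series(0.0, "male", [48.0, 54.0], lms, seed=1)
        sel = recs[recs.age_months == 54.0].iloc[0]
        bmi = sel.weight_kg / (sel.height_cm / 100) ** 2
        _, M, _ = lms.lookup("male", 54.0)
        assert bmi == pytest.approx(M, abs=1e-9)

    def test_single_visit_schedule(self, lms):
        recs = generate_growth_series(0.5, "female", [50.0], lms, seed=2)
        assert len(recs) == 1 and recs.iloc[0].height_cm > 0

    def test_analytic_lms_inversion(self, lms):
        recs = generate_growth_series(1.0, "male", [45.0, 53.0], lms, seed=3)
        sel = recs[recs.age_months == 53.0].iloc[0]
        bmi = sel.weight_kg / (sel.height_cm / 100) ** 2
        L, M, S = lms.lookup("male", 53.0)
        assert bmi == pytest.approx(M * (1 + L * S) ** (1 / L), abs=1e-6)

    def test_heights_strictly_increasing(self, lms):
        recs = generate_growth_series(0.3, "male",
                                      [30, 36, 42, 48, 54, 60], lms, seed=4)
        assert np.all(np.diff(recs.height_cm) > 0)

    def test_schedule_outside_reference_range(self, lms):
        from medgwg.errors import AgeRangeError
        with pytest.raises(AgeRangeError):
            generate_growth_series(0.0, "male", [10.0, 54.0], lms, seed=5)

    def test_derived_outcome_equals_generated(self, cohort, lms):
        """Deriving the pristine cohort recovers the latent z exactly."""
        rows, exclusions = derive_analysis_rows(cohort.mothers, cohort.growth, lms)
        assert sum(exclusions.values()) == 0
        lat = cohort.latent.set_index("mother_id").loc[rows.mother_id]
        np.testing.assert_allclose(rows.child_z.to_numpy(),
                                   lat.child_z.to_numpy(), atol=1e-9)
        np.testing.assert_array_equal(rows.excessive_gwg.to_numpy(),
                                      lat.excessive_gwg.to_numpy())


class TestInjectErrors:
    def test_zero_rates_identity(self, small_config):
        cohort = generate_cohort(small_config)
        out = inject_errors(cohort, small_config)
        pd.testing.assert_frame_equal(out.growth, cohort.growth)
        pd.testing.assert_frame_equal(out.mothers, cohort.mothers)
        assert len(out.corruptions) == 0 and len(out.missing_log) == 0

    def test_forced_corruption_is_flagged(self):
        cfg = GeneratorConfig(n_pairs=5, seed=9, glitch_rate=1.0,
                              missing_rate={},
                              growth_schedule=(46.0, 52.0, 58.0),
                              schedule_jitter=0.0)
        out = inject_errors(generate_cohort(cfg), cfg)
        for _, grp in out.growth.groupby("child_id"):
            grp = grp.sort_values("age_months")
            flags = flag_nonmonotone(GrowthSeries(
                "c", grp.age_months.to_numpy(), grp.height_cm.to_numpy())).flags
            assert flags.any()

    def test_corruption_fraction_within_binomial_bounds(self):
        cfg = GeneratorConfig(n_pairs=1000, seed=13, glitch_rate=0.1,
                              missing_rate={},
                              growth_schedule=(36.0, 42.0, 48.0, 54.0, 60.0),
                              schedule_jitter=1.0)
        out = inject_errors(generate_cohort(cfg), cfg)
        n_eligible = 1000 * 4          # first visit per child is exempt
        frac = len(out.corruptions) / n_eligible
        half = 2.576 * np.sqrt(0.1 * 0.9 / n_eligible)   # binomial 99% bound
        assert abs(frac - 0.1) < half

    def test_missingness_logged_and_mar(self):
        cfg = GeneratorConfig(n_pairs=2000, seed=3,
                              glitch_rate=0.0,
                              missing_rate={"education": 0.2})
        out = inject_errors(generate_cohort(cfg), cfg)
        miss = out.mothers.education.isna()
        assert len(out.missing_log) == miss.sum() > 0
        # MAR mechanism: missingness depends on the observed cohort period
        late = out.mothers.cohort_period == 1
        assert miss[late].mean() > miss[~late].mean()


class TestConfigValidation:
    @pytest.mark.parametrize("kwargs,fragment", [
        (dict(n_pairs=0), "n_pairs"),
        (dict(sigma_y=0.0), "sigma_y"),
        (dict(glitch_rate=1.5), "glitch_rate"),
        (dict(growth_schedule=(30.0, 36.0)), "window"),
        (dict(missing_rate={"education": 2.0}), "missing_rate"),
        (dict(beta_cov={"nonexistent": 1.0}), "beta_cov"),
    ])
    def test_invalid_config_names_field(self, kwargs, fragment):
        with pytest.raises(ConfigError, match=fragment):
            GeneratorConfig(**kwargs).validate()

    def test_mixture_weights_must_sum_to_one(self):
        from medgwg.synthetic import BMIMixture
        with pytest.raises(ConfigError, match="weights"):
            cfg = GeneratorConfig(bmi_mixture=BMIMixture(weights=(0.5, 0.4, 0.3)))
            cfg.validate()
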