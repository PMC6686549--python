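"""Synthetic mother-child cohorts with known causal structure.

The study data behind this pipeline are not publicly deposited, so the
package generates cohorts that follow exactly the model pair the
analysis fits:

* mediator (excessive gestational weight gain, binary):
  ``M ~ Bernoulli(expit(beta0 + beta1 * A + beta_cov' C))``
* outcome (child age-4 BMI z-score):
  ``Y ~ Normal(theta0 + theta1 A + theta2 M + theta3 A M + theta_cov' C,
  sigma_y)``

with the exposure ``A`` (maternal pre-pregnancy BMI) drawn from a
3-component normal mixture truncated at 18.5 (normal / overweight /
obese components; the analysis excludes underweight mothers, so the
excluded group is not modelled).  The outcome is realised as a
longitudinal growth series along a constant-z LMS trajectory so that the
derived age-4 z-score equals the generating one; downstream cleaning and
outcome selection are therefore exercised on the same records.

Default parameters are calibrated so a generated cohort mimics the
published cohort's composition: n = 766 pairs, ~24% of children
overweight or obese, maternal BMI classes ~44/25/31% normal /
overweight / obese, ~55-60% excessive GWG, and true effects at the
BMI 30 vs 22 contrast near CDE 0.32, NDE 0.235, NIE 0.020.

Corruption (non-monotone height glitches) and arbitrary-pattern MAR
missingness are injected by :func:`inject_errors` as a separate step so
tests can compare against the pristine cohort.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .anthropometry import AGE4_WINDOW, IOM_RANGES_LBS
from .errors import ConfigError
from .lms import LMSTable, synthetic_lms_table

RACE_LEVELS = ("black", "white", "hispanic", "other")
EDU_LEVELS = ("less_hs", "hs", "some_college", "college")

#: Covariate design-column order shared with :mod:`medgwg.mediation`.
MINIMAL_COV_NAMES = (
    "race_white", "race_hispanic", "race_other",
    "edu_hs", "edu_some_college", "edu_college",
    "smoking", "gdm", "cohort_period",
)


@dataclass
class BMIMixture:
    """Truncated 3-component normal mixture for pre-pregnancy BMI."""

    weights: tuple = (0.45, 0.21, 0.34)
    means: tuple = (21.9, 27.2, 34.6)
    sds: tuple = (1.7, 1.35, 4.2)
    truncate_at: float = 18.5

    def validate(self):
        if len(self.weights) != len(self.means) or len(self.means) != len(self.sds):
            raise ConfigError("bmi_mixture: weights/means/sds length mismatch")
        if abs(sum(self.weights) - 1.0) > 1e-9:
            raise ConfigError("bmi_mixture: weights must sum to 1")
        if any(w < 0 for w in self.weights) or any(s <= 0 for s in self.sds):
            raise ConfigError("bmi_mixture: weights must be >= 0 and sds > 0")


@dataclass
class CovariateDist:
    """Category probabilities for the baseline covariates."""

    race_probs: tuple = (0.47, 0.32, 0.17, 0.04)
    edu_probs: tuple = (0.22, 0.21, 0.23, 0.34)
    smoking: float = 0.21
    gdm: float = 0.06
    cohort_period: float = 0.5
    parity_probs: tuple = (0.29, 0.37, 0.20, 0.14)
    male_prob: float = 0.53
    cesarean: float = 0.37

    def validate(self):
        for name in ("race_probs", "edu_probs", "parity_probs"):
            probs = getattr(self, name)
            if abs(sum(probs) - 1.0) > 1e-9 or any(p < 0 for p in probs):
                raise ConfigError(f"covariate_dist.{name} must be a probability vector")
        for name in ("smoking", "gdm", "cohort_period", "male_prob", "cesarean"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"covariate_dist.{name} must be in [0, 1]")

    def dummy_means(self) -> dict:
        """Expected value of each minimal-model design column."""
        out = {f"race_{lev}": p for lev, p in zip(RACE_LEVELS[1:], self.race_probs[1:])}
        out.update({f"edu_{lev}": p for lev, p in zip(EDU_LEVELS[1:], self.edu_probs[1:])})
        out.update(smoking=self.smoking, gdm=self.gdm,
                   cohort_period=self.cohort_period)
        return out


# Defaults calibrated against the published cohort's Table-1 composition
# and Table-2 effect sizes (see docs/methods.md).
_DEFAULT_BETA_COV = {
    "race_white": -0.15, "race_hispanic": 0.10, "race_other": 0.0,
    "edu_hs": -0.05, "edu_some_college": -0.05, "edu_college": -0.25,
    "smoking": 0.10, "gdm": -0.30, "cohort_period": 0.0,
}
_DEFAULT_THETA_COV = {
    "race_white": -0.10, "race_hispanic": 0.12, "race_other": -0.05,
    "edu_hs": -0.02, "edu_some_college": -0.04, "edu_college": -0.10,
    "smoking": 0.05, "gdm": 0.10, "cohort_period": 0.0,
}


@dataclass
class GeneratorConfig:
    """True model coefficients, marginals and corruption rates.

    ``beta*`` are the mediator-model coefficients on the log-odds scale,
    ``theta*`` the outcome-model coefficients on the BMI-z scale.
    """

    n_pairs: int = 766
    beta0: float = -1.15
    beta_bmi: float = 0.06
    beta_cov: dict = field(default_factory=lambda: dict(_DEFAULT_BETA_COV))
    theta0: float = -0.78
    theta_bmi: float = 0.04025
    theta_m: float = 0.8118853789029210
    theta_am: float = -0.0213759589018010
    theta_cov: dict = field(default_factory=lambda: dict(_DEFAULT_THETA_COV))
    sigma_y: float = 0.85
    bmi_mixture: BMIMixture = field(default_factory=BMIMixture)
    covariate_dist: CovariateDist = field(default_factory=CovariateDist)
    growth_schedule: tuple = (24.0, 30.0, 36.0, 42.0, 48.0, 54.0, 60.0, 66.0)
    schedule_jitter: float = 1.5
    z_visit_jitter: float = 0.12
    height_offset_sd: float = 3.0
    maternal_height: tuple = (163.0, 6.5)
    age_delivery: tuple = (28.7, 6.2)
    gestational_age_days: tuple = (270.0, 16.0)
    birth_weight_g: tuple = (3180.0, 650.0)
    glitch_rate: float = 0.02
    missing_rate: dict = field(default_factory=lambda: {
        "education": 0.06, "smoking": 0.04, "gdm": 0.04})
    confounded: bool = False
    seed: int | None = None

    def validate(self):
        if self.n_pairs < 1:
            raise ConfigError("n_pairs must be >= 1")
        if self.sigma_y <= 0:
            raise ConfigError("sigma_y must be > 0")
        self.bmi_mixture.validate()
        self.covariate_dist.validate()
        sched = np.asarray(self.growth_schedule, dtype=float)
        if sched.size == 0 or (sched.size > 1 and not np.all(np.diff(sched) > 0)):
            raise ConfigError("growth_schedule must be non-empty and ascending")
        if self.schedule_jitter < 0:
            raise ConfigError("schedule_jitter must be >= 0")
        if sched.size > 1 and 2 * self.schedule_jitter >= np.min(np.diff(sched)):
            raise ConfigError("schedule_jitter too large for the visit spacing")
        lo, hi = AGE4_WINDOW
        if not np.any((sched - self.schedule_jitter >= lo)
                      & (sched + self.schedule_jitter <= hi)):
            raise ConfigError(
                "growth_schedule must contain a visit that always falls in "
                f"the {lo:g}-{hi:g} month outcome window")
        if not 0.0 <= self.glitch_rate <= 1.0:
            raise ConfigError("glitch_rate must be in [0, 1]")
        for key, rate in self.missing_rate.items():
            if not 0.0 <= rate <= 1.0:
                raise ConfigError(f"missing_rate[{key!r}] must be in [0, 1]")
        for key in self.beta_cov:
            if key not in MINIMAL_COV_NAMES:
                raise ConfigError(f"beta_cov has unknown design column {key!r}")
        for key in self.theta_cov:
            if key not in MINIMAL_COV_NAMES:
                raise ConfigError(f"theta_cov has unknown design column {key!r}")

    def beta_vector(self) -> np.ndarray:
        return np.array([self.beta_cov.get(k, 0.0) for k in MINIMAL_COV_NAMES])

    def theta_vector(self) -> np.ndarray:
        return np.array([self.theta_cov.get(k, 0.0) for k in MINIMAL_COV_NAMES])


@dataclass
class SyntheticCohort:
    """Generated cohort tables plus the generating truth.

    ``corruptions`` and ``missing_log`` record exactly which cells
    :func:`inject_errors` altered, for test assertions; both are empty
    on a pristine cohort.
    """

    mothers: pd.DataFrame
    growth: pd.DataFrame
    truth: dict
    latent: pd.DataFrame = None
    corruptions: pd.DataFrame = None
    missing_log: pd.DataFrame = None

    def __post_init__(self):
        if self.corruptions is None:
            self.corruptions = pd.DataFrame(
                columns=["child_id", "age_months", "original_height_cm",
                         "corrupted_height_cm"])
        if self.missing_log is None:
            self.missing_log = pd.DataFrame(columns=["mother_id", "variable"])

    def write(self, out_dir):
        import pathlib
        out = pathlib.Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.mothers.to_csv(out / "mothers.csv", index=False)
        self.growth.to_csv(out / "growth.csv", index=False)
        with open(out / "truth.json", "w") as fh:
            json.dump(self.truth, fh, indent=2)


def true_effects(config: GeneratorConfig, a: float = 30.0, a_star: float = 22.0,
                 m_cde: float = 0.0) -> dict:
    """Closed-form CDE/NDE/NIE/TE implied by the generating coefficients.

    Conditional on the covariate vector at its population expectation
    (dummy-coded categoricals at their category probabilities).
    """
    cbar = config.covariate_dist.dummy_means()
    cvec = np.array([cbar[k] for k in MINIMAL_COV_NAMES])
    lin = config.beta0 + config.beta_vector() @ cvec
    p_a = expit(lin + config.beta_bmi * a)
    p_astar = expit(lin + config.beta_bmi * a_star)
    gap = a - a_star
    cde = (config.theta_bmi + config.theta_am * m_cde) * gap
    nde = (config.theta_bmi + config.theta_am * p_astar) * gap
    nie = (config.theta_m + config.theta_am * a) * (p_a - p_astar)
    te = nde + nie
    return {
        "a": a, "a_star": a_star, "m_cde": m_cde,
        "cde": cde, "nde": nde, "nie": nie, "te": te,
        "proportion_mediated": nie / te if te != 0 else float("nan"),
        "p_mediator_a": float(p_a), "p_mediator_a_star": float(p_astar),
    }


def _height_curve(age_months, sex_is_female, offset):
    """Smooth stature-for-age curve (cm), strictly increasing in age."""
    t = np.asarray(age_months, dtype=float) - 24.0
    base = 87.0 + 0.75 * t - 0.002 * t ** 2
    return base - 1.0 * np.asarray(sex_is_female, dtype=float) + offset


def generate_growth_series(target_age4_z: float, sex: str, schedule,
                           lms: LMSTable, seed=None, child_id="child",
                           height_offset: float = 0.0,
                           z_visit_jitter: float = 0.12) -> pd.DataFrame:
    """Longitudinal growth records realising a target age-4 z-score.

    Visits follow ``schedule`` (months, ascending).  BMI at each visit
    sits on the constant-z LMS trajectory at ``target_age4_z`` plus a
    small per-visit jitter, except at the last visit inside the 48-59
    month outcome window, where the z-score is exact so that deriving
    the outcome recovers the generating value.  Heights come from a
    smooth stature curve and are strictly increasing.
    """
    ages = np.asarray(schedule, dtype=float)
    if ages.size == 0:
        raise ConfigError("schedule must be non-empty")
    if ages.size > 1 and not np.all(np.diff(ages) > 0):
        raise ConfigError("schedule ages must be strictly ascending")
    rng = np.random.default_rng(seed)
    z = target_age4_z + rng.normal(0.0, z_visit_jitter, size=ages.size)
    lo, hi = AGE4_WINDOW
    in_window = (ages >= lo) & (ages <= hi)
    if in_window.any():
        z[np.flatnonzero(in_window)[-1]] = target_age4_z
    female = str(sex).lower().startswith("f")
    heights = _height_curve(ages, female, height_offset)
    bmi = lms.inverse(z, sex, ages)
    weights = np.asarray(bmi) * (heights / 100.0) ** 2
    return pd.DataFrame({
        "child_id": child_id, "sex": "female" if female else "male",
        "age_months": ages, "height_cm": heights, "weight_kg": weights,
    })


def _draw_truncated_mixture(rng, mix: BMIMixture, n: int) -> np.ndarray:
    comp = rng.choice(len(mix.weights), size=n, p=np.asarray(mix.weights))
    means = np.asarray(mix.means)[comp]
    sds = np.asarray(mix.sds)[comp]
    x = rng.normal(means, sds)
    while True:
        bad = x < mix.truncate_at
        if not bad.any():
            return x
        x[bad] = rng.normal(means[bad], sds[bad])


def _draw_gwg(rng, maternal_category: np.ndarray, mediator: np.ndarray) -> np.ndarray:
    """GWG (lbs) consistent with the drawn mediator and IOM category.

    Excessive gains sit above the category's upper bound by a gamma
    offset (mean ~8 lbs); non-excessive gains are uniform from 8 lbs
    below the lower bound up to the upper bound, covering both the
    inadequate and adequate ranges in roughly the published proportions.
    """
    lo = np.array([IOM_RANGES_LBS[c][0] for c in maternal_category])
    hi = np.array([IOM_RANGES_LBS[c][1] for c in maternal_category])
    n = mediator.size
    excessive = hi + 0.5 + rng.gamma(2.0, 4.0, size=n)
    not_excessive = rng.uniform(lo - 8.0, hi)
    return np.where(mediator == 1, excessive, not_excessive)


def generate_cohort(config: GeneratorConfig,
                    lms: LMSTable | None = None) -> SyntheticCohort:
    """Draw a pristine cohort from the generating model.

    Fully reproducible given ``config.seed``.  Corruption and
    missingness are *not* applied here; pass the result through
    :func:`inject_errors` for that.
    """
    config.validate()
    lms = lms or synthetic_lms_table()
    rng = np.random.default_rng(config.seed)
    n = config.n_pairs
    cd = config.covariate_dist

    race = rng.choice(RACE_LEVELS, size=n, p=np.asarray(cd.race_probs))
    education = rng.choice(EDU_LEVELS, size=n, p=np.asarray(cd.edu_probs))
    smoking = rng.binomial(1, cd.smoking, size=n)
    gdm = rng.binomial(1, cd.gdm, size=n)
    cohort_period = rng.binomial(1, cd.cohort_period, size=n)
    parity = rng.choice(len(cd.parity_probs), size=n, p=np.asarray(cd.parity_probs))
    child_sex = np.where(rng.random(n) < cd.male_prob, "male", "female")

    A = _draw_truncated_mixture(rng, config.bmi_mixture, n)
    if config.confounded:
        # optional confounding: education shifts the exposure distribution
        A = A + np.select([education == "less_hs", education == "college"],
                          [1.5, -1.2], 0.0)
        A = np.maximum(A, config.bmi_mixture.truncate_at)

    # design columns in MINIMAL_COV_NAMES order
    C = np.column_stack(
        [(race == lev).astype(float) for lev in RACE_LEVELS[1:]]
        + [(education == lev).astype(float) for lev in EDU_LEVELS[1:]]
        + [smoking.astype(float), gdm.astype(float), cohort_period.astype(float)])

    p_m = expit(config.beta0 + config.beta_bmi * A + C @ config.beta_vector())
    M = rng.binomial(1, p_m)
    mu_y = (config.theta0 + config.theta_bmi * A + config.theta_m * M
            + config.theta_am * A * M + C @ config.theta_vector())
    Y = rng.normal(mu_y, config.sigma_y)

    maternal_cat = np.select([A < 25.0, A < 30.0], ["normal", "overweight"], "obese")
    gwg_lbs = _draw_gwg(rng, maternal_cat, M)

    height_cm = rng.normal(*config.maternal_height, size=n)
    weight_prepreg = A * (height_cm / 100.0) ** 2
    weight_lmp = weight_prepreg + rng.normal(0.0, 0.4, size=n)
    from .anthropometry import KG_PER_LB
    weight_delivery = weight_lmp + gwg_lbs * KG_PER_LB
    delivery_gap = rng.integers(0, 4, size=n)

    mother_id = np.array([f"P{i:05d}" for i in range(1, n + 1)])
    mothers = pd.DataFrame({
        "mother_id": mother_id,
        "race": race, "education": education,
        "smoking": smoking, "gdm": gdm, "cohort_period": cohort_period,
        "parity": parity,
        "age_delivery": rng.normal(*config.age_delivery, size=n),
        "cesarean": rng.binomial(1, cd.cesarean, size=n),
        "gestational_age_days": rng.normal(*config.gestational_age_days, size=n),
        "birth_weight_g": rng.normal(*config.birth_weight_g, size=n),
        "child_sex": child_sex,
        "height_cm": height_cm,
        "weight_prepreg_kg": weight_prepreg,
        "weight_lmp_kg": weight_lmp,
        "weight_delivery_kg": weight_delivery,
        "delivery_gap_days": delivery_gap,
    })

    # growth series, vectorised over the cohort
    sched = np.asarray(config.growth_schedule, dtype=float)
    k = sched.size
    ages = sched[None, :] + rng.uniform(-config.schedule_jitter,
                                        config.schedule_jitter, size=(n, k))
    z = Y[:, None] + rng.normal(0.0, config.z_visit_jitter, size=(n, k))
    lo, hi = AGE4_WINDOW
    in_window = (ages >= lo) & (ages <= hi)
    last_in_window = k - 1 - np.argmax(in_window[:, ::-1], axis=1)
    z[np.arange(n), last_in_window] = Y
    offsets = rng.normal(0.0, config.height_offset_sd, size=n)
    female = (child_sex == "female")
    heights = _height_curve(ages, female[:, None], offsets[:, None])
    bmi = np.empty_like(z)
    for sex in ("male", "female"):
        mask = female if sex == "female" else ~female
        if mask.any():
            bmi[mask] = lms.inverse(z[mask].ravel(), sex,
                                    ages[mask].ravel()).reshape(-1, k)
    weight = bmi * (heights / 100.0) ** 2
    growth = pd.DataFrame({
        "child_id": np.repeat(mother_id, k),
        "sex": np.repeat(child_sex, k),
        "age_months": ages.ravel(),
        "height_cm": heights.ravel(),
        "weight_kg": weight.ravel(),
    })

    # latent analysis frame: the generated (A, M, Y) before realisation as
    # growth records; deriving the pristine cohort recovers child_z exactly
    latent = pd.DataFrame({
        "mother_id": mother_id, "bmi": A,
        "maternal_category": maternal_cat,
        "gwg_lbs": gwg_lbs, "excessive_gwg": M, "child_z": Y,
        "race": race, "education": education, "smoking": smoking,
        "gdm": gdm, "cohort_period": cohort_period,
        "age_delivery": mothers["age_delivery"],
        "cesarean": mothers["cesarean"],
        "gestational_age_days": mothers["gestational_age_days"],
        "child_sex": child_sex, "birth_weight_g": mothers["birth_weight_g"],
        "parity": parity,
    })

    truth = true_effects(config)
    truth.update(
        theta={"theta0": config.theta0, "theta1": config.theta_bmi,
               "theta2": config.theta_m, "theta3": config.theta_am,
               "theta_cov": dict(config.theta_cov)},
        beta={"beta0": config.beta0, "beta1": config.beta_bmi,
              "beta_cov": dict(config.beta_cov)},
        sigma_y=config.sigma_y,
    )
    return SyntheticCohort(mothers=mothers, growth=growth, truth=truth,
                           latent=latent)


def inject_errors(cohort: SyntheticCohort,
                  config: GeneratorConfig) -> SyntheticCohort:
    """Corrupt heights downward and set covariate cells missing (MAR).

    Each height record after a child's first visit is independently
    corrupted with probability ``glitch_rate`` by pulling it below the
    previous visit's height, which guarantees a departure from
    monotonicity.  Each variable in ``missing_rate`` is set missing with
    a probability that depends on the always-observed cohort-period
    indicator (rate x1.5 in the later period, x0.5 in the earlier), so
    missingness is MAR given observed data.  Rates of zero return the
    cohort unchanged.  Altered cells are logged in ``corruptions`` /
    ``missing_log``.
    """
    config.validate()
    rng = np.random.default_rng(
        None if config.seed is None else [config.seed, 0x9E3779B9])
    growth = cohort.growth.copy()
    corruptions = []
    if config.glitch_rate > 0:
        grouped = growth.groupby("child_id", sort=False)
        heights = growth["height_cm"].to_numpy(copy=True)
        for _, grp in grouped:
            idx = grp.sort_values("age_months").index.to_numpy()
            hit = rng.random(idx.size - 1) < config.glitch_rate if idx.size > 1 \
                else np.array([], dtype=bool)
            for j in np.flatnonzero(hit):
                pos = growth.index.get_loc(idx[j + 1])
                prev_pos = growth.index.get_loc(idx[j])
                original = heights[pos]
                corrupted = heights[prev_pos] - rng.uniform(0.5, 4.0)
                heights[pos] = corrupted
                corruptions.append({
                    "child_id": grp["child_id"].iloc[0],
                    "age_months": growth.loc[idx[j + 1], "age_months"],
                    "original_height_cm": original,
                    "corrupted_height_cm": corrupted,
                })
        growth["height_cm"] = heights

    mothers = cohort.mothers.copy()
    missing = []
    for var, rate in config.missing_rate.items():
        if rate <= 0:
            continue
        if var not in mothers.columns:
            raise ConfigError(f"missing_rate names unknown variable {var!r}")
        prob = rate * np.where(mothers["cohort_period"].to_numpy() == 1, 1.5, 0.5)
        prob = np.clip(prob, 0.0, 1.0)
        hit = rng.random(len(mothers)) < prob
        if hit.any():
            col = mothers[var].astype(object) if mothers[var].dtype.kind in "iub" \
                else mothers[var]
            col = col.copy()
            col[hit] = np.nan
            mothers[var] = col
            missing.extend({"mother_id": mid, "variable": var}
                           for mid in mothers.loc[hit, "mother_id"])

    return SyntheticCohort(
        mothers=mothers, growth=growth, truth=dict(cohort.truth),
        latent=cohort.latent,
        corruptions=pd.DataFrame(
            corruptions, columns=["child_id", "age_months",
                                  "original_height_cm", "corrupted_height_cm"]),
        missing_log=pd.DataFrame(missing, columns=["mother_id", "variable"]),
    )
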