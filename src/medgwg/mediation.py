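"""Counterfactual mediation analysis for a continuous exposure, binary
mediator and continuous outcome.

Two regression models are fit on the analysis rows:

* mediator:  logit P(M=1 | A, C) = beta0 + beta1 A + beta2' C
* outcome:   E[Y | A, M, C] = theta0 + theta1 A + theta2 M
             + theta3 A M + theta4' C

and combined into the closed-form effect decomposition at an exposure
contrast ``a`` vs ``a*`` (default BMI 30 vs 22), conditional on a
covariate vector ``c``; with ``p(a) = expit(beta0 + beta1 a + beta2'c)``:

    CDE = (theta1 + theta3 * m) * (a - a*)
    NDE = (theta1 + theta3 * p(a*)) * (a - a*)
    NIE = (theta2 + theta3 * a) * (p(a) - p(a*))
    TE  = NDE + NIE                (exact, by construction)
    PM  = NIE / TE

Inference is by nonparametric bootstrap with percentile intervals.  A
Monte-Carlo oracle that simulates the potential outcomes directly is
provided as an independent cross-check of the closed form.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg as sla
from scipy.special import expit

from .errors import ConfigError, FitError, InferenceError, SchemaError

logger = logging.getLogger(__name__)

RACE_LEVELS = ("black", "white", "hispanic", "other")
EDU_LEVELS = ("less_hs", "hs", "some_college", "college")

MINIMAL_COLUMNS = ("race", "education", "smoking", "gdm", "cohort_period")
EXTENDED_COLUMNS = MINIMAL_COLUMNS + (
    "age_delivery", "cesarean", "gestational_age_days", "child_sex",
    "birth_weight_g", "parity")

_MAX_IRLS_ITER = 50
_IRLS_TOL = 1e-10


@dataclass
class ModelSpec:
    """Which covariate set to adjust for, and whether to include the
    exposure-by-mediator interaction in the outcome model (default on)."""

    covariate_set: str = "minimal"
    interaction: bool = True

    def __post_init__(self):
        if self.covariate_set not in ("minimal", "extended"):
            raise ConfigError("covariate_set must be 'minimal' or 'extended'")


def covariate_design(rows: pd.DataFrame, covariate_set: str = "minimal"
                     ) -> tuple[np.ndarray, list[str]]:
    """Dummy-coded covariate matrix in a fixed column order.

    Reference categories: race=black, education=less than high school,
    parity=0.  The extended set adds parturition variables (birth weight
    in kg, gestational age in weeks to keep columns on comparable
    scales).
    """
    needed = MINIMAL_COLUMNS if covariate_set == "minimal" else EXTENDED_COLUMNS
    missing = [c for c in needed if c not in rows.columns]
    if missing:
        raise SchemaError(f"analysis rows missing covariate columns: {missing}")
    with_na = [c for c in needed if rows[c].isna().any()]
    if with_na:
        raise SchemaError("covariates contain missing values (impute or drop "
                          f"incomplete rows first): {with_na}")
    cols: dict[str, np.ndarray] = {}
    race = rows["race"].astype(object)
    for lev in RACE_LEVELS[1:]:
        cols[f"race_{lev}"] = (race == lev).to_numpy(float)
    edu = rows["education"].astype(object)
    for lev in EDU_LEVELS[1:]:
        cols[f"edu_{lev}"] = (edu == lev).to_numpy(float)
    for c in ("smoking", "gdm", "cohort_period"):
        cols[c] = rows[c].to_numpy(float)
    if covariate_set == "extended":
        cols["age_delivery"] = rows["age_delivery"].to_numpy(float)
        cols["cesarean"] = rows["cesarean"].to_numpy(float)
        cols["gestational_age_wk"] = rows["gestational_age_days"].to_numpy(float) / 7.0
        cols["child_male"] = (rows["child_sex"].astype(object) == "male").to_numpy(float)
        cols["birth_weight_kg"] = rows["birth_weight_g"].to_numpy(float) / 1000.0
        parity = rows["parity"].to_numpy(float)
        cols["parity_1"] = (parity == 1).astype(float)
        cols["parity_2"] = (parity == 2).astype(float)
        cols["parity_3plus"] = (parity >= 3).astype(float)
    names = list(cols)
    X = np.column_stack([cols[c] for c in names])
    if not np.all(np.isfinite(X)):
        raise SchemaError("covariate design contains missing values; "
                          "impute or drop incomplete rows before fitting")
    return X, names


@dataclass
class MediatorModelFit:
    """Logistic mediator model: coefficients on the log-odds scale."""

    params: np.ndarray
    names: list[str]
    vcov: np.ndarray
    n: int
    converged: bool
    cbar: np.ndarray = None       # mean of the covariate design columns
    cov_names: list[str] = None

    @property
    def beta0(self) -> float:
        return float(self.params[0])

    @property
    def beta1(self) -> float:
        return float(self.params[1])

    @property
    def beta_cov(self) -> np.ndarray:
        return self.params[2:]

    def p_mediator(self, a, c) -> np.ndarray:
        """P(M=1 | A=a, C=c); c may be a vector or a matrix of rows."""
        c = np.atleast_2d(np.asarray(c, dtype=float))
        return expit(self.beta0 + self.beta1 * a + c @ self.beta_cov)


@dataclass
class OutcomeModelFit:
    """Linear outcome model on the BMI z-score scale."""

    params: np.ndarray
    names: list[str]
    vcov: np.ndarray
    sigma: float
    n: int
    interaction: bool

    @property
    def theta0(self) -> float:
        return float(self.params[0])

    @property
    def theta1(self) -> float:
        return float(self.params[1])

    @property
    def theta2(self) -> float:
        return float(self.params[2])

    @property
    def theta3(self) -> float:
        return float(self.params[3]) if self.interaction else 0.0

    @property
    def theta_cov(self) -> np.ndarray:
        return self.params[4:] if self.interaction else self.params[3:]


@dataclass
class Contrast:
    """Exposure contrast and evaluation point of the decomposition.

    ``c`` is an optional covariate vector (aligned with the mediator
    model's covariate columns); when None the sample means stored on the
    fit are used.  ``conditioning='marginal'`` instead averages the
    decomposition over the empirical covariate rows.
    """

    a: float = 30.0
    a_star: float = 22.0
    m_cde: float = 0.0
    c: np.ndarray | None = None
    conditioning: str = "mean"

    def __post_init__(self):
        if self.conditioning not in ("mean", "marginal"):
            raise ConfigError("conditioning must be 'mean' or 'marginal'")


@dataclass
class EffectDecomposition:
    cde: float
    nde: float
    nie: float
    te: float
    proportion_mediated: float
    ci_cde: tuple | None = None
    ci_nde: tuple | None = None
    ci_nie: tuple | None = None
    ci_te: tuple | None = None
    ci_pm: tuple | None = None
    b: int = 0
    n_failed: int = 0
    n_pm_dropped: int = 0
    replicates: dict = field(default=None, repr=False)

    def to_dict(self) -> dict:
        out = {"cde": self.cde, "nde": self.nde, "nie": self.nie,
               "te": self.te, "proportion_mediated": self.proportion_mediated,
               "b": self.b, "n_failed": self.n_failed,
               "n_pm_dropped": self.n_pm_dropped}
        for k in ("ci_cde", "ci_nde", "ci_nie", "ci_te", "ci_pm"):
            v = getattr(self, k)
            out[k] = None if v is None else [float(v[0]), float(v[1])]
        return out


def _logistic_irls(X: np.ndarray, y: np.ndarray,
                   max_iter: int = _MAX_IRLS_ITER,
                   tol: float = _IRLS_TOL,
                   ridge: float = 0.0) -> tuple[np.ndarray, np.ndarray, bool]:
    """Iteratively-reweighted maximum-likelihood logistic fit.

    Newton-Raphson on the log-likelihood with a capped iteration budget;
    the covariance is the inverse observed information at the optimum.
    Raises :class:`FitError` on a constant response or (quasi-)complete
    separation, detected as diverging coefficients.  ``ridge`` adds a
    small diagonal to the information matrix; leave it at 0 for exact
    maximum likelihood (imputation conditionals use a tiny value for
    stability on sparse cells).
    """
    y = np.asarray(y, dtype=float)
    if np.all(y == y[0]):
        raise FitError("mediator is constant; logistic model cannot be fit")
    n, p = X.shape
    beta = np.zeros(p)
    converged = False
    eye = np.eye(p)
    for _ in range(max_iter):
        eta = X @ beta
        mu = expit(eta)
        w = mu * (1.0 - mu)
        grad = X.T @ (y - mu) - ridge * beta
        info = X.T @ (X * w[:, None]) + ridge * eye
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError as exc:
            raise FitError(f"singular information matrix in logistic fit: {exc}")
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            converged = True
            break
        if np.max(np.abs(beta)) > 1e3:
            raise FitError("logistic coefficients diverging; data are likely "
                           "completely separated")
    eta = X @ beta
    if np.max(np.abs(eta)) > 30 and np.all((eta > 0) == (y == 1)):
        raise FitError("complete separation detected in logistic fit")
    mu = expit(eta)
    w = np.clip(mu * (1.0 - mu), 1e-12, None)
    info = X.T @ (X * w[:, None]) + ridge * eye
    vcov = np.linalg.inv(info)
    return beta, vcov, converged


def fit_mediator_model(rows: pd.DataFrame, spec: ModelSpec | None = None
                       ) -> MediatorModelFit:
    """Maximum-likelihood logistic regression of excessive GWG on
    pre-pregnancy BMI and the covariate set."""
    spec = spec or ModelSpec()
    C, cov_names = covariate_design(rows, spec.covariate_set)
    a = rows["bmi"].to_numpy(float)
    m = rows["excessive_gwg"].to_numpy(float)
    if np.isnan(a).any() or np.isnan(m).any():
        raise SchemaError("exposure/mediator contain missing values")
    X = np.column_stack([np.ones(len(a)), a, C])
    beta, vcov, converged = _logistic_irls(X, m)
    if not converged:
        raise FitError("logistic fit did not converge within the iteration budget")
    return MediatorModelFit(params=beta, names=["intercept", "bmi", *cov_names],
                            vcov=vcov, n=len(a), converged=converged,
                            cbar=C.mean(axis=0), cov_names=cov_names)


def _collinear_columns(X: np.ndarray, names: list[str]) -> list[str]:
    _, r, piv = sla.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    bad = diag < max(X.shape) * np.finfo(float).eps * (diag[0] if diag.size else 1.0)
    return [names[piv[i]] for i in np.flatnonzero(bad)]


def fit_outcome_model(rows: pd.DataFrame, spec: ModelSpec | None = None
                      ) -> OutcomeModelFit:
    """Ordinary least squares of the child z-score on exposure, mediator,
    their interaction (if specified) and the covariate set."""
    spec = spec or ModelSpec()
    C, cov_names = covariate_design(rows, spec.covariate_set)
    a = rows["bmi"].to_numpy(float)
    m = rows["excessive_gwg"].to_numpy(float)
    y = rows["child_z"].to_numpy(float)
    if np.isnan(a).any() or np.isnan(m).any() or np.isnan(y).any():
        raise SchemaError("exposure/mediator/outcome contain missing values")
    parts = [np.ones(len(a)), a, m]
    names = ["intercept", "bmi", "excessive_gwg"]
    if spec.interaction:
        parts.append(a * m)
        names.append("bmi_x_gwg")
    X = np.column_stack(parts + [C])
    names = names + cov_names
    coef, rss, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        raise FitError("rank-deficient outcome design; collinear columns: "
                       f"{_collinear_columns(X, names)}")
    resid = y - X @ coef
    dof = len(y) - X.shape[1]
    sigma2 = float(resid @ resid) / dof if dof > 0 else 0.0
    xtx_inv = np.linalg.inv(X.T @ X)
    return OutcomeModelFit(params=coef, names=names, vcov=sigma2 * xtx_inv,
                           sigma=float(np.sqrt(sigma2)), n=len(y),
                           interaction=spec.interaction)


def proportion_mediated(nie: float, te: float) -> float:
    """NIE / TE, the share of the total effect carried by the mediator.

    Undefined (NaN) when the total effect is zero.
    """
    return nie / te if te != 0 else float("nan")


def _decompose_point(theta1, theta2, theta3, p_a, p_astar, a, a_star, m_cde):
    """Point decomposition from scalars / averaged mediator probabilities."""
    gap = a - a_star
    cde = (theta1 + theta3 * m_cde) * gap
    nde = (theta1 + theta3 * np.mean(p_astar)) * gap
    nie = (theta2 + theta3 * a) * (np.mean(p_a) - np.mean(p_astar))
    te = nde + nie
    pm = nie / te if te != 0 else float("nan")
    return float(cde), float(nde), float(nie), float(te), float(pm)


def decompose_effects(ofit: OutcomeModelFit, mfit: MediatorModelFit,
                      contrast: Contrast | None = None,
                      covariate_rows: np.ndarray | None = None
                      ) -> EffectDecomposition:
    """Closed-form CDE/NDE/NIE/TE/PM at the contrast.

    By default the decomposition is conditional on the covariate vector
    ``contrast.c`` (falling back to the sample means stored on the
    mediator fit).  With ``contrast.conditioning == 'marginal'`` the
    mediator probabilities are averaged over ``covariate_rows``.
    """
    contrast = contrast or Contrast()
    if contrast.conditioning == "marginal":
        if covariate_rows is None:
            raise ConfigError("marginal conditioning requires covariate_rows")
        c = np.asarray(covariate_rows, dtype=float)
    else:
        c = contrast.c if contrast.c is not None else mfit.cbar
    p_a = mfit.p_mediator(contrast.a, c)
    p_astar = mfit.p_mediator(contrast.a_star, c)
    cde, nde, nie, te, pm = _decompose_point(
        ofit.theta1, ofit.theta2, ofit.theta3, p_a, p_astar,
        contrast.a, contrast.a_star, contrast.m_cde)
    return EffectDecomposition(cde=cde, nde=nde, nie=nie, te=te,
                               proportion_mediated=pm)


@dataclass
class OracleEstimates:
    """Monte-Carlo potential-outcome estimates with standard errors."""

    cde: float
    nde: float
    nie: float
    te: float
    se_cde: float
    se_nde: float
    se_nie: float
    n_mc: int


def mc_counterfactual_oracle(ofit: OutcomeModelFit, mfit: MediatorModelFit,
                             contrast: Contrast | None = None,
                             covariate_sample: np.ndarray | None = None,
                             n_mc: int = 1_000_000, seed=None,
                             include_noise: bool = False) -> OracleEstimates:
    """Simulate the counterfactual definitions directly.

    Draws M(a) ~ Bernoulli(p(a | c)) and evaluates Y(a, m) from the
    fitted outcome mean; the residual noise cancels in expectation and
    is omitted unless ``include_noise`` is set (useful for testing that
    it does cancel).  NDE = E[Y(a, M(a*)) - Y(a*, M(a*))] and
    NIE = E[Y(a, M(a)) - Y(a, M(a*))], each with an MC standard error.
    """
    if n_mc < 1:
        raise ConfigError("n_mc must be >= 1")
    contrast = contrast or Contrast()
    rng = np.random.default_rng(seed)
    if covariate_sample is not None:
        sample = np.asarray(covariate_sample, dtype=float)
        c = sample[rng.integers(0, sample.shape[0], size=n_mc)]
    else:
        cvec = contrast.c if contrast.c is not None else mfit.cbar
        c = np.broadcast_to(np.asarray(cvec, dtype=float), (n_mc, len(cvec)))
    p_a = mfit.p_mediator(contrast.a, c).ravel()
    p_astar = mfit.p_mediator(contrast.a_star, c).ravel()
    m_a = (rng.random(n_mc) < p_a).astype(float)
    m_astar = (rng.random(n_mc) < p_astar).astype(float)

    cov_term = c @ ofit.theta_cov

    def y(a, m):
        out = (ofit.theta0 + ofit.theta1 * a + ofit.theta2 * m
               + ofit.theta3 * a * m + cov_term)
        if include_noise:
            out = out + rng.normal(0.0, ofit.sigma, size=n_mc)
        return out

    a, a_star = contrast.a, contrast.a_star
    nde_i = y(a, m_astar) - y(a_star, m_astar)
    nie_i = y(a, m_a) - y(a, m_astar)
    cde_i = y(a, contrast.m_cde) - y(a_star, contrast.m_cde)
    sem = lambda v: float(np.std(v, ddof=1) / np.sqrt(n_mc)) if n_mc > 1 else 0.0
    return OracleEstimates(
        cde=float(np.mean(cde_i)), nde=float(np.mean(nde_i)),
        nie=float(np.mean(nie_i)),
        te=float(np.mean(nde_i) + np.mean(nie_i)),
        se_cde=sem(cde_i), se_nde=sem(nde_i), se_nie=sem(nie_i), n_mc=n_mc)


def _decompose_arrays(Xo, y, Xm, m, contrast: Contrast, interaction: bool,
                      n_cov: int):
    """Fit both models from prebuilt design matrices and decompose.

    Fast path used inside the bootstrap loop; mirrors
    fit_mediator_model / fit_outcome_model / decompose_effects.
    """
    beta, _, converged = _logistic_irls(Xm, m, max_iter=25, tol=1e-8)
    if not converged:
        raise FitError("bootstrap logistic fit did not converge")
    coef, _, rank, _ = np.linalg.lstsq(Xo, y, rcond=None)
    if rank < Xo.shape[1]:
        raise FitError("rank-deficient bootstrap outcome design")
    theta1 = coef[1]
    theta2 = coef[2]
    theta3 = coef[3] if interaction else 0.0
    if contrast.conditioning == "marginal":
        c = Xm[:, 2:]
    elif contrast.c is not None:
        c = np.atleast_2d(np.asarray(contrast.c, dtype=float))
    else:
        c = Xm[:, 2:].mean(axis=0, keepdims=True)
    lin = beta[0] + c @ beta[2:]
    p_a = expit(lin + beta[1] * contrast.a)
    p_astar = expit(lin + beta[1] * contrast.a_star)
    return _decompose_point(theta1, theta2, theta3, p_a, p_astar,
                            contrast.a, contrast.a_star, contrast.m_cde)


def bootstrap_decomposition(rows: pd.DataFrame, spec: ModelSpec | None = None,
                            contrast: Contrast | None = None, B: int = 1000,
                            seed=None, keep_replicates: bool = False
                            ) -> EffectDecomposition:
    """Nonparametric bootstrap of the full decomposition.

    ``B`` resamples of the analysis rows with replacement at the
    original n; both models are refit and the effects recomputed on each
    resample; 95% percentile intervals.  Point estimates come from the
    full data.  Resamples whose fits fail are dropped and counted; more
    than 10% failures aborts with an inference error.  The PM interval
    uses the bootstrap distribution of NIE/TE with replicates whose TE
    changes sign relative to the point estimate dropped and counted.
    """
    if B < 1:
        raise ConfigError("B must be >= 1")
    spec = spec or ModelSpec()
    contrast = contrast or Contrast()
    rng = np.random.default_rng(seed)

    mfit = fit_mediator_model(rows, spec)
    ofit = fit_outcome_model(rows, spec)
    C, _ = covariate_design(rows, spec.covariate_set)
    point = decompose_effects(ofit, mfit, contrast,
                              covariate_rows=C if contrast.conditioning == "marginal"
                              else None)

    a = rows["bmi"].to_numpy(float)
    m = rows["excessive_gwg"].to_numpy(float)
    y = rows["child_z"].to_numpy(float)
    n = len(a)
    ones = np.ones(n)
    Xm = np.column_stack([ones, a, C])
    parts = [ones, a, m] + ([a * m] if spec.interaction else [])
    Xo = np.column_stack(parts + [C])

    reps = {k: np.empty(B) for k in ("cde", "nde", "nie", "te", "pm")}
    ok = np.zeros(B, dtype=bool)
    for b in range(B):
        idx = rng.integers(0, n, size=n)
        try:
            cde, nde, nie, te, pm = _decompose_arrays(
                Xo[idx], y[idx], Xm[idx], m[idx], contrast,
                spec.interaction, C.shape[1])
        except FitError:
            continue
        reps["cde"][b], reps["nde"][b] = cde, nde
        reps["nie"][b], reps["te"][b], reps["pm"][b] = nie, te, pm
        ok[b] = True
    n_failed = int(B - ok.sum())
    if n_failed > 0.1 * B:
        raise InferenceError(
            f"{n_failed}/{B} bootstrap resamples failed to fit; the sample "
            "is too small or too unbalanced for reliable intervals")

    def ci(vals):
        return (float(np.percentile(vals, 2.5)), float(np.percentile(vals, 97.5)))

    cde_r, nde_r = reps["cde"][ok], reps["nde"][ok]
    nie_r, te_r, pm_r = reps["nie"][ok], reps["te"][ok], reps["pm"][ok]
    sign = np.sign(point.te) if point.te != 0 else 1.0
    pm_keep = (np.sign(te_r) == sign) & np.isfinite(pm_r)
    n_pm_dropped = int((~pm_keep).sum())
    result = EffectDecomposition(
        cde=point.cde, nde=point.nde, nie=point.nie, te=point.te,
        proportion_mediated=point.proportion_mediated,
        ci_cde=ci(cde_r), ci_nde=ci(nde_r), ci_nie=ci(nie_r), ci_te=ci(te_r),
        ci_pm=ci(pm_r[pm_keep]) if pm_keep.any() else None,
        b=B, n_failed=n_failed, n_pm_dropped=n_pm_dropped)
    if keep_replicates:
        result.replicates = {"cde": cde_r, "nde": nde_r, "nie": nie_r,
                             "te": te_r, "pm": pm_r}
    return result
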