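"""Fully-conditional-specification multiple imputation and Rubin pooling.

Missing covariate cells are filled by cycling through per-variable
conditional models given all other analysis variables at their current
values: linear regression with Gaussian noise for continuous variables,
binary logistic draws for two-level variables, and multinomial logistic
draws for multi-level categoricals (a discriminant-equivalent conditional
under the conditional-model view of FCS).  Linear and binary conditionals
draw their parameters from the approximate posterior (normal on the
coefficients, scaled inverse chi-square on the residual variance) so
between-imputation variance is propagated; the multinomial conditional
uses plug-in parameters, a documented approximation.

Per-imputation effect estimates are combined by Rubin's rules:
``point = mean``, ``T = W + (1 + 1/m) B`` with a normal-reference
interval; bootstrap percentile bounds are pooled across completed
datasets by averaging.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from .errors import ConfigError, FitError, ImputationError
from .mediation import (Contrast, EffectDecomposition, ModelSpec,
                        _logistic_irls, bootstrap_decomposition,
                        decompose_effects, fit_mediator_model,
                        fit_outcome_model)

logger = logging.getLogger(__name__)

#: Analysis variables used as predictors in every conditional model.
DEFAULT_PREDICTORS = ("bmi", "excessive_gwg", "child_z", "race", "education",
                      "smoking", "gdm", "cohort_period")


@dataclass
class ImputationConfig:
    m: int = 20
    cycles: int = 10
    seed: int | None = None
    variables: tuple | None = None   # None -> every predictor column with NaN
    predictors: tuple = DEFAULT_PREDICTORS

    def __post_init__(self):
        if self.m < 2:
            raise ConfigError("imputation m must be >= 2")
        if self.cycles < 1:
            raise ConfigError("imputation cycles must be >= 1")


@dataclass
class PooledEstimate:
    point: float
    within: float
    between: float
    total: float
    ci: tuple
    m: int


def pool_rubin(estimates, variances) -> PooledEstimate:
    """Rubin's rules: T = W + (1 + 1/m) B, 95% normal-reference interval."""
    est = np.asarray(estimates, dtype=float)
    var = np.asarray(variances, dtype=float)
    if est.size != var.size or est.size < 2:
        raise ImputationError("pooling needs >= 2 estimates with matching variances")
    if np.any(var < 0):
        raise ImputationError("variances must be non-negative")
    m = est.size
    point = float(est.mean())
    within = float(var.mean())
    between = float(est.var(ddof=1))
    total = within + (1.0 + 1.0 / m) * between
    half = 1.96 * np.sqrt(total)
    return PooledEstimate(point=point, within=within, between=between,
                          total=total, ci=(point - half, point + half), m=m)


def _encode(table: pd.DataFrame, columns, exclude: str) -> np.ndarray:
    """Predictor matrix from the current table (dummy-coded categoricals)."""
    parts = [np.ones(len(table))]
    for col in columns:
        if col == exclude:
            continue
        s = table[col]
        if s.dtype.kind in "OUS" or isinstance(s.dtype, pd.CategoricalDtype):
            levels = sorted(x for x in s.dropna().unique())
            for lev in levels[1:]:
                parts.append((s == lev).to_numpy(float))
        else:
            parts.append(s.to_numpy(float))
    return np.column_stack(parts)


def _variable_kind(s: pd.Series) -> str:
    obs = s.dropna()
    if s.dtype.kind in "OUS" or isinstance(s.dtype, pd.CategoricalDtype):
        return "binary_cat" if obs.nunique() <= 2 else "multinomial"
    return "logistic" if set(obs.unique()) <= {0, 1, 0.0, 1.0} else "linear"


def _draw_linear(rng, X_obs, y_obs, X_mis):
    coef, _, rank, _ = np.linalg.lstsq(X_obs, y_obs, rcond=None)
    if rank < X_obs.shape[1]:
        raise FitError("rank-deficient conditional linear model")
    resid = y_obs - X_obs @ coef
    dof = max(len(y_obs) - X_obs.shape[1], 1)
    sigma2 = float(resid @ resid) / dof
    sigma2_draw = float(resid @ resid) / rng.chisquare(dof)
    xtx_inv = np.linalg.inv(X_obs.T @ X_obs)
    coef_draw = rng.multivariate_normal(coef, sigma2_draw * xtx_inv,
                                        method="cholesky")
    return X_mis @ coef_draw + rng.normal(0.0, np.sqrt(sigma2_draw),
                                          size=X_mis.shape[0])


def _draw_logistic(rng, X_obs, y_obs, X_mis):
    # small ridge + loose tolerance: draws need a stable conditional, not
    # an exact MLE, and sparse cells can be quasi-separated
    beta, vcov, converged = _logistic_irls(X_obs, y_obs, max_iter=50,
                                           tol=1e-6, ridge=1e-4)
    if not converged:
        raise FitError("conditional logistic fit did not converge")
    beta_draw = rng.multivariate_normal(beta, vcov, method="cholesky")
    p = expit(X_mis @ beta_draw)
    return (rng.random(X_mis.shape[0]) < p).astype(float)


def _softmax_probs(X, B):
    """Class probabilities under baseline-category logits B (p x K-1)."""
    eta = np.hstack([np.zeros((X.shape[0], 1)), X @ B])
    eta -= eta.max(axis=1, keepdims=True)
    e = np.exp(eta)
    return e / e.sum(axis=1, keepdims=True)


def _multinomial_newton(X, codes, n_classes, ridge=1e-4, max_iter=30, tol=1e-6):
    """Ridged Newton fit of baseline-category multinomial logits.

    Small problems only (a dozen predictors, a handful of classes); the
    full (K-1)p Newton system is solved directly each iteration.
    """
    n, p = X.shape
    K = n_classes
    Y = np.zeros((n, K))
    Y[np.arange(n), codes] = 1.0
    B = np.zeros((p, K - 1))
    for _ in range(max_iter):
        P = _softmax_probs(X, B)
        grad = (X.T @ (Y[:, 1:] - P[:, 1:]) - ridge * B).ravel(order="F")
        H = np.empty((p * (K - 1), p * (K - 1)))
        for k in range(1, K):
            for l in range(1, K):
                w = P[:, k] * ((k == l) - P[:, l])
                block = X.T @ (X * w[:, None])
                if k == l:
                    block = block + ridge * np.eye(p)
                H[(k - 1) * p:k * p, (l - 1) * p:l * p] = block
        step = np.linalg.solve(H, grad)
        B = B + step.reshape((p, K - 1), order="F")
        if np.max(np.abs(step)) < tol:
            break
        if np.max(np.abs(B)) > 1e3:
            raise FitError("multinomial conditional diverging")
    return B


def _draw_multinomial(rng, X_obs, y_obs_codes, X_mis, levels):
    B = _multinomial_newton(X_obs, y_obs_codes, n_classes=len(levels))
    probs = _softmax_probs(X_mis, B)
    cum = probs.cumsum(axis=1)
    u = rng.random((X_mis.shape[0], 1))
    picks = (u > cum).sum(axis=1)
    return np.array([levels[k] for k in picks], dtype=object)


def fcs_impute(table: pd.DataFrame, config: ImputationConfig | None = None
               ) -> list[pd.DataFrame]:
    """Produce ``m`` completed copies of ``table``.

    Missing cells are initialised by sampling observed values of the
    same variable, then updated over ``cycles`` FCS sweeps in order of
    increasing missingness.  A conditional fit that fails falls back to
    a marginal draw for that sweep (logged).  Deterministic given
    ``config.seed``; with no missing cells the result is ``m`` identical
    copies of the input.
    """
    config = config or ImputationConfig()
    predictors = [c for c in config.predictors if c in table.columns]
    if config.variables is None:
        targets = [c for c in predictors if table[c].isna().any()]
    else:
        targets = list(config.variables)
        for v in targets:
            if v not in table.columns:
                raise ImputationError(f"imputation target {v!r} not in table")
    if not targets:
        return [table.copy() for _ in range(config.m)]
    for v in targets:
        if table[v].isna().all():
            raise ImputationError(f"variable {v!r} is 100% missing")
    if not any(table[c].notna().all() for c in predictors):
        raise ImputationError("FCS needs at least one fully observed predictor")
    targets = sorted(targets, key=lambda v: table[v].isna().sum())
    kinds = {v: _variable_kind(table[v]) for v in targets}
    miss_masks = {v: table[v].isna().to_numpy() for v in targets}

    completed = []
    for d in range(config.m):
        rng = np.random.default_rng(
            [0 if config.seed is None else config.seed, 0xFC5, d])
        cur = table.copy()
        for v in targets:
            mask = miss_masks[v]
            obs = cur.loc[~mask, v].to_numpy()
            fill = obs[rng.integers(0, obs.size, size=int(mask.sum()))]
            cur.loc[mask, v] = fill
        for _ in range(config.cycles):
            for v in targets:
                mask = miss_masks[v]
                X = _encode(cur, predictors, exclude=v)
                X_obs, X_mis = X[~mask], X[mask]
                kind = kinds[v]
                try:
                    if kind == "linear":
                        draws = _draw_linear(rng, X_obs,
                                             table.loc[~mask, v].to_numpy(float),
                                             X_mis)
                    elif kind in ("logistic", "binary_cat"):
                        obs_vals = table.loc[~mask, v]
                        levels = sorted(obs_vals.unique())
                        y01 = (obs_vals == levels[-1]).to_numpy(float)
                        z = _draw_logistic(rng, X_obs, y01, X_mis)
                        if kind == "binary_cat":
                            draws = np.where(z == 1.0, levels[-1], levels[0])
                        else:
                            draws = z
                    else:
                        obs_vals = table.loc[~mask, v]
                        levels = sorted(obs_vals.unique())
                        codes = obs_vals.map({l: i for i, l in enumerate(levels)})
                        draws = _draw_multinomial(rng, X_obs,
                                                  codes.to_numpy(int), X_mis,
                                                  levels)
                except (FitError, np.linalg.LinAlgError) as exc:
                    logger.warning("conditional fit for %s failed (%s); "
                                   "marginal draw this sweep", v, exc)
                    obs_vals = table.loc[~mask, v].to_numpy()
                    draws = obs_vals[rng.integers(0, obs_vals.size,
                                                  size=int(mask.sum()))]
                cur.loc[mask, v] = draws
        for v in targets:   # restore integer dtypes where possible
            if table[v].dtype.kind in "iu":
                cur[v] = cur[v].astype(table[v].dtype)
        completed.append(cur)
    return completed


def pooled_decomposition(tables: list[pd.DataFrame],
                         spec: ModelSpec | None = None,
                         contrast: Contrast | None = None,
                         B: int = 1000, seed: int | None = None
                         ) -> EffectDecomposition:
    """Decomposition pooled over completed datasets.

    Point estimates are Rubin means of the per-imputation points (which
    preserves TE = NDE + NIE exactly); PM is recomputed as pooled
    NIE / pooled TE.  With ``B >= 1`` each dataset is bootstrapped and
    the 95% percentile bounds are averaged across imputations; with
    ``B = 0`` only points are returned.
    """
    spec = spec or ModelSpec()
    contrast = contrast or Contrast()
    per = []
    for d, tab in enumerate(tables):
        if B >= 1:
            dec = bootstrap_decomposition(
                tab, spec, contrast, B=B,
                seed=[0 if seed is None else seed, 0xB007, d])
        else:
            mfit = fit_mediator_model(tab, spec)
            ofit = fit_outcome_model(tab, spec)
            dec = decompose_effects(ofit, mfit, contrast)
        per.append(dec)

    def mean_of(attr):
        return float(np.mean([getattr(p, attr) for p in per]))

    nde, nie = mean_of("nde"), mean_of("nie")
    te = nde + nie
    result = EffectDecomposition(
        cde=mean_of("cde"), nde=nde, nie=nie, te=te,
        proportion_mediated=nie / te if te != 0 else float("nan"),
        b=B, n_failed=sum(p.n_failed for p in per),
        n_pm_dropped=sum(p.n_pm_dropped for p in per))
    if B >= 1:
        for name in ("ci_cde", "ci_nde", "ci_nie", "ci_te", "ci_pm"):
            bounds = [getattr(p, name) for p in per]
            if any(b is None for b in bounds):
                continue
            lo = float(np.mean([b[0] for b in bounds]))
            hi = float(np.mean([b[1] for b in bounds]))
            setattr(result, name, (lo, hi))
    return result
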