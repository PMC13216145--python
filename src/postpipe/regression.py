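"""Multivariable logistic regression with Wald odds-ratio tables.

Maximum likelihood by Newton-Raphson/IRLS with step-halving; standard errors
from the inverse observed information; Wald 95% intervals exp(beta +/- 1.96 se).
Complete-case analysis: rows with any missing covariate are dropped and the
used sample size is reported.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm

from .cohort_model import PatientRecord, Sex
from .errors import ConvergenceError, SchemaError, SeparationError

Z_95 = 1.96
MAX_ITER = 50
SCORE_TOL = 1e-10
LL_REL_TOL = 1e-13

#: Covariates available to model specifications, with their design-matrix
#: coding. Booleans are 0/1; sex is male=1 vs female=0; anterior=1 vs
#: posterior=0; continuous covariates enter unscaled (years, mm, months).
_COVARIATE_CODERS = {
    "age": lambda r: r.age,
    "sex": lambda r: 1.0 if r.sex is Sex.MALE else 0.0,
    "dome_mm": lambda r: r.dome_mm,
    "anterior_circulation": lambda r: 1.0 if r.anterior_circulation else 0.0,
    "neck_mm": lambda r: r.neck_mm,
    "dapt_months": lambda r: r.dapt_months,
    "mapt_months": lambda r: r.mapt_months,
    "partial_thrombosis": lambda r: (
        None if r.partial_thrombosis is None else (1.0 if r.partial_thrombosis else 0.0)
    ),
    "coils_used": lambda r: (
        None if r.coils_used is None else (1.0 if r.coils_used else 0.0)
    ),
    "steroids_postop": lambda r: (
        None if r.steroids_postop is None else (1.0 if r.steroids_postop else 0.0)
    ),
}

MODEL_SPECS = {
    # baseline model restricted to demographics
    "model0": ("age", "sex"),
    # full odds-ratio table specification
    "full": (
        "age",
        "sex",
        "dome_mm",
        "anterior_circulation",
        "neck_mm",
        "dapt_months",
        "mapt_months",
        "partial_thrombosis",
    ),
}


@dataclass(frozen=True)
class CovariateEffect:
    name: str
    beta: float
    se: float
    odds_ratio: float
    ci95_low: float
    ci95_high: float
    p_wald: float


@dataclass(frozen=True)
class ORTable:
    effects: tuple[CovariateEffect, ...]
    intercept: CovariateEffect
    n_used: int
    converged: bool
    n_iterations: int
    log_likelihood: float

    @property
    def covariates(self) -> tuple[str, ...]:
        return tuple(e.name for e in self.effects)

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "covariate": e.name,
                "beta": round(e.beta, 3),
                "se": round(e.se, 3),
                "odds_ratio": round(e.odds_ratio, 3),
                "ci95_low": round(e.ci95_low, 3),
                "ci95_high": round(e.ci95_high, 3),
                "p_value": round(e.p_wald, 3),
            }
            for e in self.effects
        ]
        return pd.DataFrame(rows)


def build_design(
    records: Iterable[PatientRecord], covariates: Sequence[str]
) -> pd.DataFrame:
    """Covariate matrix with named columns (no intercept column; the fit adds
    it). Missing optional values become NaN; complete-case filtering happens
    at fit time."""
    unknown = [c for c in covariates if c not in _COVARIATE_CODERS]
    if unknown:
        raise SchemaError(f"unknown covariate(s): {', '.join(unknown)}")
    records = list(records)
    data = {}
    for name in covariates:
        coder = _COVARIATE_CODERS[name]
        col = [coder(r) for r in records]
        col = [np.nan if v is None else float(v) for v in col]
        data[name] = col
    df = pd.DataFrame(data, index=[r.patient_id for r in records])
    for name in covariates:
        if df[name].isna().all():
            raise SchemaError(f"covariate {name!r} is missing for every record")
    return df


def _check_separation(X: np.ndarray, y: np.ndarray, names: Sequence[str]) -> None:
    for j, name in enumerate(names):
        x = X[:, j]
        x1, x0 = x[y == 1], x[y == 0]
        if x1.size == 0 or x0.size == 0:
            continue
        if x1.min() > x0.max() or x0.min() > x1.max():
            raise SeparationError(name)


def _log_likelihood(beta, X1, y):
    eta = X1 @ beta
    # numerically stable: sum y*eta - log(1+exp(eta))
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def fit_logistic(
    outcome: Sequence, design: pd.DataFrame, add_intercept: bool = True
) -> ORTable:
    """Maximum-likelihood logistic regression.

    Parameters
    ----------
    outcome:
        Binary outcome aligned with the design rows (bools or 0/1).
    design:
        Named covariate matrix from :func:`build_design` (or any DataFrame).

    Raises
    ------
    SeparationError
        If a single covariate perfectly separates the outcome.
    ConvergenceError
        If IRLS does not converge within 50 iterations (trace attached).
    """
    y_all = np.asarray([1.0 if v else 0.0 for v in outcome], dtype=float)
    if y_all.size != len(design):
        raise ValueError("outcome and design have different lengths")
    mask = ~design.isna().any(axis=1).to_numpy()
    X = design.to_numpy(dtype=float)[mask]
    y = y_all[mask]
    names = list(design.columns)
    n_used = int(mask.sum())
    if n_used == 0:
        raise ValueError("no complete cases")
    if y.min() == y.max():
        raise ValueError("outcome is constant on complete cases")
    for j, name in enumerate(names):
        if np.ptp(X[:, j]) == 0:
            raise ValueError(f"covariate {name!r} is constant on complete cases")
    _check_separation(X, y, names)

    X1 = np.column_stack([np.ones(n_used), X]) if add_intercept else X
    p = X1.shape[1]
    beta = np.zeros(p)
    ll = _log_likelihood(beta, X1, y)
    trace = [ll]
    converged = False
    it = 0
    for it in range(1, MAX_ITER + 1):
        mu = expit(X1 @ beta)
        score = X1.T @ (y - mu)
        w = mu * (1.0 - mu)
        info = X1.T @ (X1 * w[:, None])
        if np.max(np.abs(score)) < SCORE_TOL:
            converged = True
            break
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError(
                f"singular information matrix at iteration {it}", trace
            ) from exc
        # step-halving keeps the log-likelihood monotone (up to float noise)
        ll_noise = 1e-12 * (abs(ll) + 1.0)
        factor = 1.0
        new_ll = _log_likelihood(beta + step, X1, y)
        while new_ll < ll - ll_noise and factor > 1e-10:
            factor /= 2.0
            new_ll = _log_likelihood(beta + factor * step, X1, y)
        beta = beta + factor * step
        if abs(new_ll - ll) <= LL_REL_TOL * (abs(ll) + 1e-12):
            ll = new_ll
            trace.append(ll)
            # a likelihood plateau only counts as convergence when the
            # gradient has actually vanished
            mu = expit(X1 @ beta)
            if np.max(np.abs(X1.T @ (y - mu))) < 1e-6:
                converged = True
                break
        ll = new_ll
        trace.append(ll)
        if np.max(np.abs(beta)) > 1e3:
            raise ConvergenceError(
                "coefficients diverging (quasi-separation suspected)", trace
            )
    if not converged:
        raise ConvergenceError(f"IRLS did not converge in {MAX_ITER} iterations", trace)

    mu = expit(X1 @ beta)
    w = mu * (1.0 - mu)
    info = X1.T @ (X1 * w[:, None])
    cov = np.linalg.inv(info)
    se = np.sqrt(np.diag(cov))

    def effect(name, b, s):
        return CovariateEffect(
            name=name,
            beta=float(b),
            se=float(s),
            odds_ratio=float(np.exp(b)),
            ci95_low=float(np.exp(b - Z_95 * s)),
            ci95_high=float(np.exp(b + Z_95 * s)),
            p_wald=float(2.0 * norm.sf(abs(b / s))),
        )

    offset = 1 if add_intercept else 0
    effects = tuple(
        effect(name, beta[j + offset], se[j + offset]) for j, name in enumerate(names)
    )
    intercept = (
        effect("intercept", beta[0], se[0])
        if add_intercept
        else CovariateEffect("intercept", 0.0, float("nan"), 1.0, float("nan"), float("nan"), float("nan"))
    )
    return ORTable(
        effects=effects,
        intercept=intercept,
        n_used=n_used,
        converged=converged,
        n_iterations=it,
        log_likelihood=float(_log_likelihood(beta, X1, y)),
    )


def fit_model(
    records: Iterable[PatientRecord],
    outcome_by_id: Mapping[str, bool],
    model: str = "full",
) -> ORTable:
    """Fit a named model specification against a per-patient binary outcome."""
    if model not in MODEL_SPECS:
        raise SchemaError(f"unknown model {model!r}; choose from {sorted(MODEL_SPECS)}")
    records = list(records)
    design = build_design(records, MODEL_SPECS[model])
    outcome = [outcome_by_id[r.patient_id] for r in records]
    return fit_logistic(outcome, design)
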