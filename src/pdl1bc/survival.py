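"""Survival analysis: Kaplan-Meier estimation, log-rank comparison, Cox
proportional-hazards regression (Efron ties) and subtype-by-expression
interaction testing.

Endpoints are metastasis-free survival (MFS, time to distant relapse) and
overall specific survival (OSS, time to breast-cancer death), both in months
from diagnosis.  Model fitting is delegated to lifelines; this module fixes
the conventions (Efron tie handling, Wald p-values, 5-year = 60 months with
right-continuous carry-forward) and the result contracts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from lifelines.utils import ConvergenceError


@dataclass
class KMEstimate:
    """Product-limit survival curve with Greenwood-based confidence band."""

    timeline: np.ndarray
    survival: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    n: int
    n_events: int

    def rate_at(self, t: float) -> float:
        """S(t) by right-continuous step convention (last value carried
        forward); ``rate_at(60)`` is the 5-year survival rate."""
        idx = np.searchsorted(self.timeline, t, side="right") - 1
        if idx < 0:
            return 1.0
        return float(self.survival[idx])


@dataclass
class CoxResult:
    """One row per covariate: coefficient, HR = exp(coef), Wald CI and p."""

    summary: pd.DataFrame  # columns: coef, hr, ci_low, ci_high, se, p
    n: int
    n_events: int
    converged: bool
    tie_method: str = "efron"
    note: str = ""

    def hr(self, term: str) -> float:
        return float(self.summary.loc[term, "hr"])

    def p(self, term: str) -> float:
        return float(self.summary.loc[term, "p"])

    def ci(self, term: str) -> tuple[float, float]:
        row = self.summary.loc[term]
        return float(row["ci_low"]), float(row["ci_high"])


def _check_endpoints(time, event) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=float)
    if t.size == 0:
        raise ValueError("no subjects")
    if np.any(~np.isfinite(t)) or np.any(t < 0):
        raise ValueError("times must be finite and non-negative")
    if not set(np.unique(e)).issubset({0.0, 1.0}):
        raise ValueError("events must be 0/1")
    return t, e


def km_estimate(time, event) -> KMEstimate:
    """Kaplan-Meier product-limit estimate with Greenwood 95% CI."""
    t, e = _check_endpoints(time, event)
    if np.all(t == 0):
        raise ValueError("all subjects censored or failing at t=0")
    kmf = KaplanMeierFitter()
    kmf.fit(t, e)
    ci = kmf.confidence_interval_survival_function_
    return KMEstimate(
        timeline=kmf.survival_function_.index.to_numpy(dtype=float),
        survival=kmf.survival_function_["KM_estimate"].to_numpy(),
        ci_low=ci.iloc[:, 0].to_numpy(),
        ci_high=ci.iloc[:, 1].to_numpy(),
        n=int(t.size),
        n_events=int(e.sum()),
    )


def logrank_test(time, event, group) -> tuple[float, float]:
    """Log-rank chi-square and p comparing survival across groups.

    Standard (O-E)^2/V statistic; one degree of freedom for two groups.
    """
    t, e = _check_endpoints(time, event)
    g = np.asarray(group)
    labels, counts = np.unique(g, return_counts=True)
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    if np.any(counts == 0):
        raise ValueError("empty group")
    res = multivariate_logrank_test(t, g, e)
    return float(res.test_statistic), float(res.p_value)


def cox_fit(df: pd.DataFrame, duration_col: str, event_col: str,
            formula_terms: list[str] | None = None) -> CoxResult:
    """Cox proportional-hazards fit (partial likelihood, Efron ties).

    ``formula_terms`` selects covariate columns; categorical columns are
    dummy-coded against their first (sorted) level.  Non-convergence or
    separation is reported on the result, never raised silently.
    """
    terms = formula_terms or [c for c in df.columns
                              if c not in (duration_col, event_col)]
    data = df[[duration_col, event_col] + terms].dropna().copy()
    X = pd.get_dummies(data[terms], drop_first=True, dtype=float)
    for col in X.columns:
        if X[col].nunique() <= 1:
            raise ValueError(f"covariate {col!r} is constant")
    n_events = int(data[event_col].sum())
    if n_events < X.shape[1]:
        raise ValueError("fewer events than model terms")
    fit_df = pd.concat([data[[duration_col, event_col]], X], axis=1)
    cph = CoxPHFitter()
    converged, note = True, ""
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(fit_df, duration_col=duration_col, event_col=event_col)
    except ConvergenceError as exc:  # separation or flat likelihood
        return CoxResult(summary=pd.DataFrame(), n=len(fit_df),
                         n_events=n_events, converged=False, note=str(exc))
    s = cph.summary
    summary = pd.DataFrame({
        "coef": s["coef"],
        "hr": np.exp(s["coef"]),
        "ci_low": np.exp(s["coef"] - 1.96 * s["se(coef)"]),
        "ci_high": np.exp(s["coef"] + 1.96 * s["se(coef)"]),
        "se": s["se(coef)"],
        "p": s["p"],
    })
    summary.index = s.index
    return CoxResult(summary=summary, n=len(fit_df), n_events=n_events,
                     converged=converged, note=note)


def interaction_test(df: pd.DataFrame, duration_col: str, event_col: str,
                     expression_col: str, subtype_col: str) -> tuple[float, float]:
    """Wald p for the expression-by-subtype product term.

    Both factors must be binary 0/1 (e.g. PDL1 up vs no-up; basal vs
    non-basal).  Fits main effects plus the product and returns the product
    coefficient and its Wald p-value.
    """
    data = df[[duration_col, event_col, expression_col, subtype_col]].dropna().copy()
    for col in (expression_col, subtype_col):
        if not set(data[col].unique()).issubset({0, 1}):
            raise ValueError(f"{col!r} must be coded 0/1")
    cross = pd.crosstab(data[expression_col], data[subtype_col])
    if cross.shape != (2, 2) or (cross.to_numpy() == 0).any():
        raise ValueError("empty cell in the expression-by-subtype cross")
    inter = f"{expression_col}:{subtype_col}"
    data[inter] = data[expression_col] * data[subtype_col]
    res = cox_fit(data, duration_col, event_col,
                  [expression_col, subtype_col, inter])
    if not res.converged:
        return np.nan, np.nan
    return float(res.summary.loc[inter, "coef"]), res.p(inter)


def build_multivariate(univariate: dict[str, float], alpha: float = 0.05) -> list[str]:
    """Covariates carried into multivariate analysis: univariate Wald p < alpha."""
    return [term for term, p in univariate.items() if p < alpha]
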