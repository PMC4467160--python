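"""Contingency-table statistics: exact 2x2 inference and clinicopathological
association tables.

The 2x2 machinery follows the exact-test convention throughout: the two-sided
Fisher p-value orders tables by hypergeometric probability mass, and the odds
ratio is the *conditional* maximum-likelihood estimate under the noncentral
hypergeometric distribution (the estimate R's ``fisher.test`` prints), not the
sample cross-product ratio.  With both margins fixed, the count in the (1,1)
cell is sufficient for the odds ratio, and its conditional likelihood is

    P(X = k | psi) = C(r1, k) C(r2, c1 - k) psi^k / sum_j C(r1, j) C(r2, c1 - j) psi^j

where r1, r2 are the row totals, c1 the first column total and psi the odds
ratio.  The CMLE solves E[X | psi] = a (monotone in psi), and the exact 95% CI
inverts the one-sided tail tests at 2.5% each side.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import gammaln


@dataclass
class ContingencyResult:
    """Exact analysis of a 2x2 table (rows = group, cols = outcome)."""

    table: np.ndarray
    p_value: float
    odds_ratio: float
    ci_low: float
    ci_high: float
    estimable: bool = True
    note: str = ""

    @property
    def counts(self) -> list[list[int]]:
        return self.table.astype(int).tolist()


def _check_2x2(table) -> np.ndarray:
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {t.shape}")
    if np.any(t < 0) or np.any(t != np.round(t)):
        raise ValueError("2x2 table must contain non-negative integers")
    return t.astype(np.int64)


def _support(table: np.ndarray) -> tuple[int, int, int, int, np.ndarray]:
    """Margins and the support of the (1,1) cell given fixed margins."""
    r1, r2 = int(table[0].sum()), int(table[1].sum())
    c1 = int(table[:, 0].sum())
    n = r1 + r2
    lo = max(0, c1 - r2)
    hi = min(c1, r1)
    return r1, r2, c1, n, np.arange(lo, hi + 1)


def _log_central_weights(r1: int, r2: int, c1: int, support: np.ndarray) -> np.ndarray:
    """log C(r1, k) + log C(r2, c1-k) over the support."""
    k = support
    return (
        gammaln(r1 + 1) - gammaln(k + 1) - gammaln(r1 - k + 1)
        + gammaln(r2 + 1) - gammaln(c1 - k + 1) - gammaln(r2 - c1 + k + 1)
    )


def fisher_exact(table) -> float:
    """Two-sided Fisher exact p for a 2x2 table.

    Sums hypergeometric probabilities of every table with the observed margins
    whose probability does not exceed the observed table's (probability-mass
    ordering), with a 1e-12 relative slack on the comparison so that ties at
    machine precision are included.
    """
    t = _check_2x2(table)
    r1, r2, c1, n, support = _support(t)
    if min(r1, r2) == 0 or min(c1, n - c1) == 0:
        # A degenerate margin: only one table is possible.
        return 1.0
    logw = _log_central_weights(r1, r2, c1, support)
    logpmf = logw - (gammaln(n + 1) - gammaln(c1 + 1) - gammaln(n - c1 + 1))
    pmf = np.exp(logpmf)
    a = int(t[0, 0])
    p_obs = pmf[support.searchsorted(a)]
    return float(min(1.0, pmf[pmf <= p_obs * (1 + 1e-12)].sum()))


def _cond_mean(log_psi: float, logw: np.ndarray, support: np.ndarray) -> float:
    logterms = logw + support * log_psi
    logterms -= logterms.max()
    w = np.exp(logterms)
    return float((support * w).sum() / w.sum())


def _tail_prob(log_psi: float, logw: np.ndarray, support: np.ndarray,
               a: int, upper: bool) -> float:
    logterms = logw + support * log_psi
    logterms -= logterms.max()
    w = np.exp(logterms)
    w /= w.sum()
    mask = support >= a if upper else support <= a
    return float(w[mask].sum())


def _solve_monotone(f, target: float, increasing: bool) -> float:
    """Root of f(x) = target over log-psi, expanding the bracket as needed."""
    g = (lambda x: f(x) - target) if increasing else (lambda x: target - f(x))
    lo, hi = -1.0, 1.0
    for _ in range(200):
        if g(lo) < 0:
            break
        lo *= 2
    for _ in range(200):
        if g(hi) > 0:
            break
        hi *= 2
    return optimize.brentq(g, lo, hi, xtol=1e-12, rtol=1e-12)


def conditional_mle_or(table, alpha: float = 0.05) -> ContingencyResult:
    """Conditional-MLE odds ratio of a 2x2 table with exact CI.

    The point estimate solves ``E[X | psi] = a`` (the conditional score
    equation) by monotone root-finding; the CI endpoints invert the exact
    one-sided tail tests at ``alpha/2`` each side.  When the observed cell
    sits at an end of its support the corresponding estimate/endpoint is 0 or
    infinity, mirroring the one-sided nature of the information in the table.
    """
    t = _check_2x2(table)
    r1, r2, c1, n, support = _support(t)
    if min(r1, r2) == 0 or min(c1, n - c1) == 0:
        raise ValueError("degenerate margin: odds ratio not estimable")
    a = int(t[0, 0])
    logw = _log_central_weights(r1, r2, c1, support)
    p = fisher_exact(t)

    lo_s, hi_s = int(support[0]), int(support[-1])
    if a == lo_s:
        psi = 0.0
    elif a == hi_s:
        psi = math.inf
    else:
        root = _solve_monotone(lambda x: _cond_mean(x, logw, support), float(a),
                               increasing=True)
        psi = math.exp(root)

    # Exact tail-inversion CI.
    if a == lo_s:
        ci_low = 0.0
    else:
        # smallest psi with P(X >= a | psi) = alpha/2
        root = _solve_monotone(
            lambda x: _tail_prob(x, logw, support, a, upper=True),
            alpha / 2, increasing=True)
        ci_low = math.exp(root)
    if a == hi_s:
        ci_high = math.inf
    else:
        root = _solve_monotone(
            lambda x: _tail_prob(x, logw, support, a, upper=False),
            alpha / 2, increasing=False)
        ci_high = math.exp(root)

    return ContingencyResult(table=t, p_value=p, odds_ratio=psi,
                             ci_low=ci_low, ci_high=ci_high)


# ---------------------------------------------------------------------------
# Report-style tables
# ---------------------------------------------------------------------------

CATEGORICAL_DEFAULTS = ("pt", "pn", "grade", "histotype", "er", "pr",
                        "erbb2", "ki67", "subtype")
CONTINUOUS_DEFAULTS = ("age",)


def association_table(clinical: pd.DataFrame, group_column: str,
                      categorical: tuple[str, ...] = CATEGORICAL_DEFAULTS,
                      continuous: tuple[str, ...] = CONTINUOUS_DEFAULTS,
                      ) -> pd.DataFrame:
    """Per-variable association of clinical covariates with a binary group.

    Categorical variables are cross-tabulated (counts and column percentages)
    and tested with Fisher's exact test (2 levels) or a chi-square test
    (>2 levels); continuous variables get a two-sided t-test.  Variables with
    a single observed level are skipped with a warning.
    """
    groups = clinical[group_column].dropna().unique()
    if len(groups) != 2:
        raise ValueError(f"group column {group_column!r} must be binary, "
                         f"found {len(groups)} levels")
    g0, g1 = sorted(map(str, groups))
    rows = []
    for var in categorical:
        if var not in clinical.columns:
            continue
        sub = clinical[[var, group_column]].dropna()
        levels = sorted(sub[var].astype(str).unique())
        if len(levels) < 2:
            warnings.warn(f"variable {var!r} has a single level; skipped")
            continue
        ct = pd.crosstab(sub[var].astype(str), sub[group_column].astype(str))
        ct = ct.reindex(index=levels, columns=[g0, g1], fill_value=0)
        if len(levels) == 2:
            pval = fisher_exact(ct.to_numpy())
        else:
            pval = float(stats.chi2_contingency(ct.to_numpy())[1])
        colsum = ct.sum(axis=0)
        for i, lev in enumerate(levels):
            rows.append({
                "variable": var, "level": lev,
                f"n_{g0}": int(ct.loc[lev, g0]),
                f"pct_{g0}": round(100 * ct.loc[lev, g0] / max(colsum[g0], 1), 1),
                f"n_{g1}": int(ct.loc[lev, g1]),
                f"pct_{g1}": round(100 * ct.loc[lev, g1] / max(colsum[g1], 1), 1),
                "p_value": pval if i == 0 else np.nan,
            })
    for var in continuous:
        if var not in clinical.columns:
            continue
        sub = clinical[[var, group_column]].dropna()
        x0 = sub.loc[sub[group_column].astype(str) == g0, var].astype(float)
        x1 = sub.loc[sub[group_column].astype(str) == g1, var].astype(float)
        if x0.std() == 0 and x1.std() == 0:
            warnings.warn(f"variable {var!r} is constant; skipped")
            continue
        tt = stats.ttest_ind(x0, x1)
        rows.append({
            "variable": var, "level": "mean",
            f"n_{g0}": len(x0), f"pct_{g0}": round(float(x0.mean()), 2),
            f"n_{g1}": len(x1), f"pct_{g1}": round(float(x1.mean()), 2),
            "p_value": float(tt.pvalue),
        })
    return pd.DataFrame(rows)


def pcr_analysis(clinical: pd.DataFrame, group_column: str = "pdl1",
                 pcr_column: str = "pcr", subtype_column: str = "subtype",
                 up_label: str = "up", no_up_label: str = "no_up",
                 ) -> pd.DataFrame:
    """Pathological-complete-response analysis by PDL1 group.

    Builds the whole-cohort 2x2 table (rows up/no-up, columns residual
    disease / pCR) and one per subtype; each row reports counts, pCR rates
    per group, the exact p and the conditional-MLE OR with exact CI.  Samples
    with missing pCR are excluded and counted.  A stratum whose table has an
    empty margin is flagged "not estimable".
    """
    if pcr_column not in clinical.columns:
        raise ValueError(f"column {pcr_column!r} missing from clinical table")
    usable = clinical.dropna(subset=[pcr_column, group_column])
    n_excluded = len(clinical) - len(usable)

    def one(stratum: str, sub: pd.DataFrame) -> dict:
        up = sub[sub[group_column] == up_label]
        nu = sub[sub[group_column] == no_up_label]
        # rows: no-up, up; cols: residual disease (pcr=0), pCR (pcr=1)
        tab = np.array([
            [(nu[pcr_column] == 0).sum(), (nu[pcr_column] == 1).sum()],
            [(up[pcr_column] == 0).sum(), (up[pcr_column] == 1).sum()],
        ], dtype=np.int64)
        rec = {
            "stratum": stratum,
            "n": int(tab.sum()), "n_excluded": n_excluded if stratum == "all" else np.nan,
            "no_up_rd": int(tab[0, 0]), "no_up_pcr": int(tab[0, 1]),
            "up_rd": int(tab[1, 0]), "up_pcr": int(tab[1, 1]),
            "pcr_rate_no_up": tab[0, 1] / tab[0].sum() if tab[0].sum() else np.nan,
            "pcr_rate_up": tab[1, 1] / tab[1].sum() if tab[1].sum() else np.nan,
        }
        r1, r2 = tab.sum(axis=1)
        c1, c2 = tab.sum(axis=0)
        if min(r1, r2) == 0 or min(c1, c2) == 0:
            rec.update(p_value=np.nan, odds_ratio=np.nan,
                       ci_low=np.nan, ci_high=np.nan, estimable="not_estimable")
            return rec
        # OR for pCR in up vs no-up: condition on the up/pCR cell.
        res = conditional_mle_or(np.array([[tab[1, 1], tab[1, 0]],
                                           [tab[0, 1], tab[0, 0]]]))
        rec.update(p_value=res.p_value, odds_ratio=res.odds_ratio,
                   ci_low=res.ci_low, ci_high=res.ci_high, estimable="yes")
        return rec

    rows = [one("all", usable)]
    if subtype_column in usable.columns:
        for st in sorted(usable[subtype_column].dropna().unique()):
            rows.append(one(str(st), usable[usable[subtype_column] == st]))
    return pd.DataFrame(rows)
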