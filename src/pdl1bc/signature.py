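"""Supervised differential expression and the "metagene PDL1 up" classifier.

The differential test is an empirical-Bayes moderated two-sample t-test:
per-gene pooled variances s2_g (d_g = n1 + n2 - 2 df) are shrunk toward an
ensemble prior,

    s2_tilde_g = (d0 * s0^2 + d_g * s2_g) / (d0 + d_g),

with the prior (d0, s0^2) estimated by moment matching on log s2_g — the mean
and variance of log s2_g determine d0 through a trigamma inversion and s0^2
through a digamma correction.  The moderated statistic is referred to a t
distribution with d0 + d_g degrees of freedom and adjusted for multiplicity
by Benjamini-Hochberg.

Signature genes must clear three thresholds simultaneously: raw p < 0.05,
BH q < 0.05 and |fold change| >= 2 on the linear scale (|log2 FC| >= 1).
The metagene score of a sample is the arithmetic mean of its up-gene
expressions; its cutoff is placed on the learning-set ROC curve at maximum
Youden J.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .tables import fisher_exact


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton, as in variance-shrinkage
    estimators).  Large y -> small x; y -> 0 gives x -> infinity."""
    if y <= 0:
        return math.inf
    if y > 1e7:
        return 1.0 / math.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(100):
        tri = special.polygamma(1, x)
        dif = tri * (1 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-14 * x:
            break
    return float(x)


def estimate_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-matching estimate of the variance prior (d0, s0^2).

    Uses the exact moments of log s2_g under the scaled-chi-square model:
    E[log s2] = log s0^2 + digamma(d/2) - log(d/2) + ... ; the excess variance
    of log s2 over trigamma(d/2) identifies trigamma(d0/2).
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if not np.any(ok):
        raise ValueError("all per-gene variances are zero")
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2) + math.log(df / 2)
    evar = float(np.var(e, ddof=1)) - float(special.polygamma(1, df / 2))
    if evar > 0:
        d0 = 2 * _trigamma_inverse(evar)
        s02 = math.exp(float(np.mean(e)) + special.digamma(d0 / 2)
                       - math.log(d0 / 2))
    else:
        # no excess spread in the sample variances: the prior is a point
        # mass; take the geometric mean so identical s2 stay untouched
        d0 = math.inf
        s02 = math.exp(float(np.mean(z)))
    return d0, s02


def moderated_t(matrix: pd.DataFrame, group_labels, group_up="up",
                prior_df: float | None = None) -> pd.DataFrame:
    """Moderated t-test per gene (rows) between two sample groups (columns).

    Returns a DataFrame indexed by gene with columns log2_fc (up minus other
    group means), t, p, q, df_total, and the fitted prior in attrs.
    ``prior_df`` overrides the estimated d0 (0 recovers the ordinary pooled
    two-sample t exactly).
    """
    labels = np.asarray(group_labels)
    if matrix.shape[1] != labels.size:
        raise ValueError("one label per sample column required")
    up = labels == group_up
    n1, n2 = int(up.sum()), int((~up).sum())
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least 2 samples per group")
    if matrix.shape[0] < 10:
        raise ValueError("need >= 10 genes to estimate the variance prior")
    X = matrix.to_numpy(dtype=float)
    x1, x2 = X[:, up], X[:, ~up]
    m1, m2 = x1.mean(axis=1), x2.mean(axis=1)
    ss = ((x1 - m1[:, None]) ** 2).sum(axis=1) + ((x2 - m2[:, None]) ** 2).sum(axis=1)
    df_g = n1 + n2 - 2
    s2 = ss / df_g
    if np.all(s2 == 0):
        raise ValueError("zero within-group variance for every gene")
    if prior_df is None:
        d0, s02 = estimate_variance_prior(s2, df_g)
    else:
        d0 = float(prior_df)
        s02 = estimate_variance_prior(s2, df_g)[1] if d0 > 0 else 0.0
    if math.isinf(d0):
        s2_tilde = np.full_like(s2, s02)
        df_total = np.inf
    else:
        s2_tilde = (d0 * s02 + df_g * s2) / (d0 + df_g)
        df_total = d0 + df_g
    delta = m1 - m2
    se = np.sqrt(s2_tilde * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = delta / se
    if math.isinf(df_total):
        p = 2 * stats.norm.sf(np.abs(t))
    else:
        p = 2 * stats.t.sf(np.abs(t), df_total)
    q = multipletests(p, method="fdr_bh")[1]
    out = pd.DataFrame({"log2_fc": delta, "t": t, "p": p, "q": q},
                       index=matrix.index)
    out.attrs["d0"] = d0
    out.attrs["s02"] = s02
    out.attrs["df_total"] = df_total
    return out


def select_signature(de: pd.DataFrame, p_max: float = 0.05, q_max: float = 0.05,
                     min_abs_log2_fc: float = 1.0) -> pd.DataFrame:
    """Apply the three signature thresholds and split genes by direction.

    Keeps genes with p < p_max, q < q_max and |log2 FC| >= min_abs_log2_fc
    (fold change of at least 2x either way), ordered by decreasing |t|, with
    a ``direction`` column (up = higher in the up group).
    """
    keep = (de["p"] < p_max) & (de["q"] < q_max) & \
        (de["log2_fc"].abs() >= min_abs_log2_fc)
    sel = de[keep].copy()
    sel["direction"] = np.where(sel["log2_fc"] > 0, "up", "down")
    sel = sel.iloc[np.argsort(-sel["t"].abs().to_numpy(), kind="stable")]
    return sel


@dataclass
class MetageneModel:
    """Mean-expression score over the up-gene list plus its ROC threshold."""

    up_genes: list[str]
    threshold: float
    auc: float
    youden_j: float
    training_accuracy: float

    def score(self, matrix: pd.DataFrame, min_coverage: float = 0.8) -> pd.Series:
        present = [g for g in self.up_genes if g in matrix.index]
        if not present:
            raise ValueError("no signature genes present in matrix")
        if len(present) < min_coverage * len(self.up_genes):
            warnings.warn(
                f"only {len(present)}/{len(self.up_genes)} signature genes "
                "present; scores use the intersection")
        return matrix.loc[present].mean(axis=0)

    def predict(self, matrix: pd.DataFrame) -> pd.Series:
        return (self.score(matrix) >= self.threshold).map(
            {True: "up", False: "no_up"})


def _youden_threshold(scores: np.ndarray, truth: np.ndarray) -> tuple[float, float]:
    """Threshold at maximum Youden J, placed midway between adjacent distinct
    scores; ties in J resolved toward the lower threshold."""
    distinct = np.unique(scores)
    if distinct.size < 2:
        raise ValueError("all scores identical; no threshold exists")
    mids = (distinct[:-1] + distinct[1:]) / 2
    n_pos, n_neg = truth.sum(), (~truth).sum()
    best_j, best_thr = -np.inf, mids[0]
    for thr in mids:
        pred = scores >= thr
        sens = (pred & truth).sum() / n_pos if n_pos else 0.0
        spec = (~pred & ~truth).sum() / n_neg if n_neg else 0.0
        j = sens + spec - 1
        if j > best_j + 1e-12:
            best_j, best_thr = j, thr
    return float(best_thr), float(best_j)


def fit_metagene(learning_matrix: pd.DataFrame, up_genes, labels,
                 up_label: str = "up") -> MetageneModel:
    """Fit the metagene classifier on a learning cohort.

    Score = mean expression of the up genes; threshold chosen on the
    learning-set ROC curve at maximum Youden J (sensitivity + specificity - 1).
    """
    up_genes = [g for g in up_genes]
    if not up_genes:
        raise ValueError("empty up-gene list")
    missing = [g for g in up_genes if g not in learning_matrix.index]
    if missing:
        raise ValueError(f"signature genes missing from learning matrix: "
                         f"{missing[:5]}")
    scores = learning_matrix.loc[up_genes].mean(axis=0).to_numpy()
    truth = np.asarray(labels) == up_label
    thr, j = _youden_threshold(scores, truth)
    # rank-based AUC (Mann-Whitney)
    order = stats.rankdata(scores)
    n1, n0 = truth.sum(), (~truth).sum()
    auc = (order[truth].sum() - n1 * (n1 + 1) / 2) / (n1 * n0) if n1 and n0 else np.nan
    acc = float(((scores >= thr) == truth).mean())
    return MetageneModel(up_genes=up_genes, threshold=thr, auc=float(auc),
                         youden_j=j, training_accuracy=acc)


def validate_metagene(model: MetageneModel, matrix: pd.DataFrame,
                      observed_labels, up_label: str = "up") -> dict:
    """Apply a fitted metagene to a validation cohort.

    Returns accuracy, the Fisher exact p of the 2x2 confusion table
    (predicted x observed status) and the table itself.
    """
    pred = model.predict(matrix).to_numpy() == "up"
    truth = np.asarray(observed_labels) == up_label
    confusion = np.array([
        [(pred & truth).sum(), (pred & ~truth).sum()],
        [(~pred & truth).sum(), (~pred & ~truth).sum()],
    ], dtype=np.int64)
    accuracy = float((pred == truth).mean())
    p = fisher_exact(confusion)
    return {"accuracy": accuracy, "fisher_p": p, "confusion": confusion,
            "n": int(truth.size)}
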