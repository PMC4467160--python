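"""Marker dichotomization from mRNA.

Hormone/growth-factor receptor and proliferation markers (ESR1, PGR, ERBB2,
MKI67) are called positive/negative by exploiting the bimodal shape of their
log2 expression: a two-component Gaussian mixture is fitted per dataset and
the cutoff is the point between the two means where posterior membership is
0.5.  PDL1 (CD274) is called up/no-up by the tumor-to-normal-breast ratio:
"up" means T/NB >= 2 on the linear scale, i.e. a difference >= 1 in log2
space against the mean of the pooled normal-breast samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.mixture import GaussianMixture

MARKER_GENES = {"er": "ESR1", "pr": "PGR", "erbb2": "ERBB2", "ki67": "MKI67"}
PDL1_GENE = "CD274"
LOG2_RATIO_CUTOFF = 1.0  # T/NB ratio >= 2


@dataclass
class MarkerCall:
    sample_id: str
    marker: str
    status: str  # positive | negative | up | no_up
    cutoff_used: float
    method: str  # mixture | ratio


@dataclass
class BimodalFit:
    cutoff: float
    means: tuple[float, float]
    sds: tuple[float, float]
    weights: tuple[float, float]
    bimodal: bool
    note: str = ""


def bimodal_cutoff(values, min_n: int = 20) -> BimodalFit:
    """Cutoff separating the two modes of a bimodal log2 expression vector.

    Fits a 2-component equal-variance Gaussian mixture by EM (10
    deterministic restarts) and returns the point between the component means
    where the posterior membership probability equals 0.5.  A fit whose mode
    separation is below twice the component SD (Ashman D < 1, the point where
    a two-component normal mixture stops being bimodal) is flagged not
    bimodal, and the median is used instead.
    """
    x = np.asarray(values, dtype=float)
    if x.size < min_n:
        raise ValueError(f"need at least {min_n} values, got {x.size}")
    if np.ptp(x) == 0:
        raise ValueError("constant vector: no cutoff exists")
    gm = GaussianMixture(n_components=2, n_init=10, random_state=0,
                         covariance_type="tied", reg_covar=1e-6)
    gm.fit(x[:, None])
    order = np.argsort(gm.means_.ravel())
    m1, m2 = gm.means_.ravel()[order]
    s1 = s2 = float(np.sqrt(gm.covariances_.ravel()[0]))
    w1, w2 = gm.weights_[order]
    pooled_sd = np.sqrt(w1 * s1 ** 2 + w2 * s2 ** 2)
    if (m2 - m1) < 2.0 * pooled_sd:
        return BimodalFit(cutoff=float(np.median(x)), means=(m1, m2),
                          sds=(s1, s2), weights=(w1, w2), bimodal=False,
                          note="mode separation below 2 component SDs; "
                               "median used")

    def logratio(v: float) -> float:
        return (np.log(w2) + stats.norm.logpdf(v, m2, s2)
                - np.log(w1) - stats.norm.logpdf(v, m1, s1))

    try:
        cut = optimize.brentq(logratio, m1, m2, xtol=1e-10)
    except ValueError:  # no sign change between the means (heavy overlap)
        cut = float(np.median(x))
        return BimodalFit(cutoff=cut, means=(m1, m2), sds=(s1, s2),
                          weights=(w1, w2), bimodal=False,
                          note="no posterior crossing between means")
    return BimodalFit(cutoff=float(cut), means=(m1, m2), sds=(s1, s2),
                      weights=(w1, w2), bimodal=True)


def call_pdl1_up(tumor_log2: float, nb_mean_log2: float) -> str:
    """'up' iff tumor minus normal-breast mean >= 1 log2 unit (T/NB >= 2);
    the boundary itself is 'up'."""
    return "up" if tumor_log2 - nb_mean_log2 >= LOG2_RATIO_CUTOFF else "no_up"


def call_all_markers(pooled: pd.DataFrame, clinical: pd.DataFrame,
                     dataset_col: str = "dataset_id", role_col: str = "role",
                     marker_genes: dict[str, str] | None = None,
                     pdl1_gene: str = PDL1_GENE) -> pd.DataFrame:
    """Dichotomize every marker for every tumor sample.

    ``pooled`` is genes x samples (standardized scale); ``clinical`` maps
    sample_id (index) to dataset and role.  Receptor/proliferation markers are
    cut by a per-dataset bimodal mixture; PDL1 by the ratio to the pooled
    normal-breast mean.  Returns the clinical table with status columns
    (er, pr, erbb2, ki67 as positive/negative; pdl1 as up/no_up) added.
    """
    marker_genes = marker_genes or MARKER_GENES
    for gene in list(marker_genes.values()) + [pdl1_gene]:
        if gene not in pooled.index:
            raise ValueError(f"marker gene {gene!r} missing from matrix")
    out = clinical.copy()
    nb_samples = out.index[out[role_col] == "normal_breast"]
    nb_samples = [s for s in nb_samples if s in pooled.columns]
    if not nb_samples:
        raise ValueError("no normal-breast samples available for the "
                         "T/NB reference")
    nb_mean = float(pooled.loc[pdl1_gene, nb_samples].mean())

    tumors = out.index[out[role_col] == "tumor"]
    for col, gene in marker_genes.items():
        status = pd.Series(index=out.index, dtype=object)
        for ds, grp in out.loc[tumors].groupby(dataset_col):
            cols = [s for s in grp.index if s in pooled.columns]
            vals = pooled.loc[gene, cols]
            fit = bimodal_cutoff(vals.to_numpy())
            status.loc[cols] = np.where(vals >= fit.cutoff,
                                        "positive", "negative")
        out[col] = status
    pdl1_vals = pooled.loc[pdl1_gene, [s for s in tumors if s in pooled.columns]]
    pdl1 = pd.Series(index=out.index, dtype=object)
    pdl1.loc[pdl1_vals.index] = np.where(
        pdl1_vals - nb_mean >= LOG2_RATIO_CUTOFF, "up", "no_up")
    out["pdl1"] = pdl1
    out.attrs["nb_mean_log2"] = nb_mean
    return out
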