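"""Nearest-centroid molecular subtyping of breast tumors.

Each sample is assigned to the intrinsic subtype (luminal A, luminal B,
basal, ERBB2-enriched, normal-like) whose centroid profile over a fixed gene
panel it correlates with best.  Correlation is Spearman by default, making
the assignment invariant to any monotone transform of the sample vector.
Centroids are supplied from file; no published centroid set is bundled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

SUBTYPE_ORDER = ("LumA", "LumB", "Basal", "ERBB2", "Normal-like")
UNCLASSIFIED = "unclassified"


@dataclass
class CentroidSet:
    """Per-subtype centroid vectors over a common gene panel."""

    centroids: pd.DataFrame  # genes x subtypes

    def __post_init__(self) -> None:
        missing = set(SUBTYPE_ORDER) - set(self.centroids.columns)
        if missing:
            raise ValueError(f"centroid file missing subtypes: {sorted(missing)}")
        if self.centroids.index.duplicated().any():
            raise ValueError("duplicate genes in centroid panel")
        self.centroids = self.centroids[list(SUBTYPE_ORDER)]

    @property
    def panel(self) -> list[str]:
        return list(self.centroids.index)

    @classmethod
    def from_tsv(cls, path) -> "CentroidSet":
        return cls(pd.read_csv(path, sep="\t", index_col=0))

    def to_tsv(self, path) -> None:
        self.centroids.to_csv(path, sep="\t", float_format="%.6f")


def assign_subtype(sample: pd.Series, centroids: CentroidSet,
                   method: str = "spearman") -> tuple[str, dict[str, float]]:
    """Assign one sample to its nearest centroid.

    Requires at least 50% of the panel genes measured.  Returns the label
    plus the per-subtype correlations; if every correlation is <= 0 the
    sample is 'unclassified'.  Ties break by the fixed subtype order.
    """
    common = [g for g in centroids.panel if g in sample.index
              and np.isfinite(sample[g])]
    if len(common) < 0.5 * len(centroids.panel):
        raise ValueError(
            f"only {len(common)}/{len(centroids.panel)} panel genes measured")
    x = sample[common].to_numpy(dtype=float)
    corrs: dict[str, float] = {}
    for st in SUBTYPE_ORDER:
        c = centroids.centroids.loc[common, st].to_numpy(dtype=float)
        if method == "spearman":
            r = stats.spearmanr(x, c).statistic
        elif method == "pearson":
            r = stats.pearsonr(x, c).statistic
        else:
            raise ValueError(f"unknown correlation method {method!r}")
        corrs[st] = float(r) if np.isfinite(r) else 0.0
    best = max(SUBTYPE_ORDER, key=lambda s: (corrs[s], -SUBTYPE_ORDER.index(s)))
    if corrs[best] <= 0:
        return UNCLASSIFIED, corrs
    return best, corrs


def assign_subtypes(matrix: pd.DataFrame, centroids: CentroidSet,
                    method: str = "spearman") -> pd.Series:
    """Vectorized assignment for a genes x samples matrix (Spearman only).

    Rank-transforms the panel sub-matrix once per call; equivalent to calling
    :func:`assign_subtype` per column.
    """
    if method != "spearman":
        return pd.Series(
            {s: assign_subtype(matrix[s], centroids, method)[0]
             for s in matrix.columns}, name="subtype")
    common = [g for g in centroids.panel if g in matrix.index]
    if len(common) < 0.5 * len(centroids.panel):
        raise ValueError("fewer than half of the panel genes measured")
    sub = matrix.loc[common].to_numpy(dtype=float)
    ranks = np.apply_along_axis(stats.rankdata, 0, sub)
    cent = centroids.centroids.loc[common].to_numpy(dtype=float)
    cent_ranks = np.apply_along_axis(stats.rankdata, 0, cent)
    rsd = np.where(ranks.std(axis=0) == 0, 1.0, ranks.std(axis=0))
    csd = np.where(cent_ranks.std(axis=0) == 0, 1.0, cent_ranks.std(axis=0))
    rz = (ranks - ranks.mean(axis=0)) / rsd
    cz = (cent_ranks - cent_ranks.mean(axis=0)) / csd
    corr = rz.T @ cz / len(common)  # samples x subtypes
    best = corr.argmax(axis=1)
    labels = np.array(SUBTYPE_ORDER)[best]
    labels[corr.max(axis=1) <= 0] = UNCLASSIFIED
    return pd.Series(labels, index=matrix.columns, name="subtype")
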