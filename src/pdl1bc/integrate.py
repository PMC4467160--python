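"""Multi-cohort expression integration.

Each cohort (one microarray dataset) is processed separately — quantile
normalization, probe-to-gene collapse by highest within-dataset variance,
per-dataset subtyping — and then standardized against its own luminal-A
subpopulation (per-gene z-score using the luminal-A mean and SD) before
pooling.  Anchoring every dataset to the same biological reference removes
laboratory- and platform-specific location/scale effects while preserving
within-dataset sample ranks per gene.  A PCA-plus-silhouette report
quantifies how much dataset-of-origin structure remains before and after.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score


@dataclass
class ExpressionCohort:
    """One dataset: log2 matrix (probes or genes x samples) plus annotations."""

    dataset_id: str
    platform: str
    matrix: pd.DataFrame
    probe_map: dict[str, str] | None = None  # probe_id -> gene_id
    sample_roles: pd.Series | None = None  # tumor | normal_breast

    def __post_init__(self) -> None:
        if self.matrix.columns.duplicated().any():
            raise ValueError(f"duplicate sample ids in {self.dataset_id}")
        if self.sample_roles is None:
            self.sample_roles = pd.Series("tumor", index=self.matrix.columns)


@dataclass
class PooledMatrix:
    """Standardized genes x samples matrix pooled across datasets."""

    matrix: pd.DataFrame
    provenance: pd.Series  # sample -> dataset_id

    def dataset(self, dataset_id: str) -> pd.DataFrame:
        return self.matrix.loc[:, self.provenance == dataset_id]


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Force every column onto the common reference distribution.

    The reference is the vector of row means of the column-sorted matrix;
    each column's values are replaced by the reference value at their rank,
    tied values receiving the mean of the reference values at the rank
    positions they occupy.  Idempotent; preserves row/column labels.
    """
    if matrix.isna().to_numpy().any():
        raise ValueError("missing values not allowed in quantile normalization")
    if matrix.shape[1] < 2:
        warnings.warn("single-column matrix: quantile normalization is the "
                      "identity")
        return matrix.copy()
    X = matrix.to_numpy(dtype=float)
    n, m = X.shape
    ref = np.sort(X, axis=0).mean(axis=1)
    out = np.empty_like(X)
    for j in range(m):
        col = X[:, j]
        order = np.argsort(col, kind="stable")
        mapped = np.empty(n)
        mapped[order] = ref
        # average reference values over runs of tied input values
        sorted_col = col[order]
        start = 0
        for end in range(1, n + 1):
            if end == n or sorted_col[end] != sorted_col[start]:
                if end - start > 1:
                    mapped[order[start:end]] = ref[start:end].mean()
                start = end
        out[:, j] = mapped
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def collapse_probes(cohort: ExpressionCohort) -> ExpressionCohort:
    """Collapse probe rows to one row per gene.

    Keeps, per gene, the probe with the highest within-dataset variance
    (sample variance, ddof=1); exact ties resolve to the lexicographically
    smallest probe id.  Unmapped probes are dropped.
    """
    if not cohort.probe_map:
        raise ValueError("empty probe map")
    mapped = [p for p in cohort.matrix.index if p in cohort.probe_map]
    sub = cohort.matrix.loc[mapped]
    variances = sub.var(axis=1, ddof=1)
    choice = (
        pd.DataFrame({
            "probe": sub.index,
            "gene": [cohort.probe_map[p] for p in sub.index],
            "var": variances.to_numpy(),
        })
        .sort_values(["gene", "var", "probe"], ascending=[True, False, True],
                     kind="stable")
        .drop_duplicates("gene")
    )
    out = sub.loc[choice["probe"]]
    out.index = choice["gene"].to_numpy()
    out = out.sort_index()
    return ExpressionCohort(dataset_id=cohort.dataset_id,
                            platform=cohort.platform, matrix=out,
                            probe_map=None, sample_roles=cohort.sample_roles)


def standardize_to_reference(cohort: ExpressionCohort,
                             subtype_labels: pd.Series,
                             reference_subtype: str = "LumA",
                             sd_floor: float = 1e-6) -> ExpressionCohort:
    """Per-gene z-score against the reference subpopulation of this dataset.

    Subtracts the reference-subtype mean and divides by its SD (floored at
    ``sd_floor``).  If fewer than two reference samples exist the whole
    dataset's mean/SD is used instead, with a warning.  Normal-breast samples
    are transformed with the same per-gene affine map but never contribute to
    the reference statistics.
    """
    if reference_subtype not in set(subtype_labels.dropna().unique()):
        ref_cols: list = []
    else:
        ref_cols = [s for s in cohort.matrix.columns
                    if subtype_labels.get(s) == reference_subtype]
    tumor_cols = [s for s in cohort.matrix.columns
                  if cohort.sample_roles.get(s, "tumor") == "tumor"]
    if len(ref_cols) < 2:
        warnings.warn(f"{cohort.dataset_id}: reference subtype "
                      f"{reference_subtype!r} has n={len(ref_cols)} < 2; "
                      "falling back to whole-dataset mean/SD")
        ref_cols = tumor_cols
    ref = cohort.matrix[ref_cols]
    mean = ref.mean(axis=1)
    sd = ref.std(axis=1, ddof=1).clip(lower=sd_floor)
    out = cohort.matrix.sub(mean, axis=0).div(sd, axis=0)
    res = ExpressionCohort(dataset_id=cohort.dataset_id,
                           platform=cohort.platform, matrix=out,
                           probe_map=None, sample_roles=cohort.sample_roles)
    res.matrix.attrs["n_reference"] = len(ref_cols)
    res.matrix.attrs["floored_genes"] = int((ref.std(axis=1, ddof=1)
                                             <= sd_floor).sum())
    return res


def pool(cohorts: list[ExpressionCohort]) -> PooledMatrix:
    """Concatenate standardized cohorts on their common gene set."""
    common = cohorts[0].matrix.index
    for c in cohorts[1:]:
        common = common.intersection(c.matrix.index)
    mats = [c.matrix.loc[common] for c in cohorts]
    prov = pd.concat([
        pd.Series(c.dataset_id, index=c.matrix.columns) for c in cohorts])
    return PooledMatrix(matrix=pd.concat(mats, axis=1), provenance=prov)


@dataclass
class BatchCheckReport:
    variance_explained: np.ndarray
    silhouette_by_dataset: float
    silhouette_by_subtype: float | None


def pca_batch_check(pooled: PooledMatrix, gene_panel=None,
                    subtype_labels: pd.Series | None = None,
                    n_components: int = 5) -> BatchCheckReport:
    """PCA over a gene panel plus silhouette scores of the embedding.

    Silhouette-by-dataset measures residual batch structure; on standardized
    data it should be near zero (and lower than before standardization),
    while silhouette-by-subtype should dominate when biology drives the map.
    """
    genes = [g for g in (gene_panel if gene_panel is not None
                         else pooled.matrix.index) if g in pooled.matrix.index]
    X = pooled.matrix.loc[genes].to_numpy(dtype=float).T  # samples x genes
    if X.shape[0] < 3:
        raise ValueError("need at least 3 samples")
    k = min(n_components, X.shape[0] - 1, X.shape[1])
    pca = PCA(n_components=k, random_state=0)
    emb = pca.fit_transform(X)

    def safe_sil(labels) -> float:
        lab = np.asarray(labels)
        if len(np.unique(lab)) < 2:
            return 0.0
        return float(silhouette_score(emb, lab))

    sil_ds = safe_sil(pooled.provenance.loc[pooled.matrix.columns])
    sil_st = None
    if subtype_labels is not None:
        st = subtype_labels.reindex(pooled.matrix.columns)
        mask = st.notna().to_numpy()
        if mask.sum() >= 3 and len(st[mask].unique()) >= 2:
            sil_st = float(silhouette_score(emb[mask], st[mask].to_numpy()))
    return BatchCheckReport(variance_explained=pca.explained_variance_ratio_,
                            silhouette_by_dataset=sil_ds,
                            silhouette_by_subtype=sil_st)
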