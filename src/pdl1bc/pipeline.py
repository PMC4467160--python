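"""End-to-end orchestration: from raw per-dataset cohorts (or the synthetic
generator) to the report tables.

Stages: per-dataset quantile normalization -> probe collapse -> centroid
subtyping -> luminal-A-referenced standardization -> pooling -> marker and
PDL1 calls -> clinicopathological association table -> Cox/KM prognostic
analysis (whole cohort, basal stratum, interaction) -> exact pCR analysis ->
copy-number association -> supervised signature with metagene validation.
Stage failures after input loading are recorded in the run summary and do
not abort independent stages.
"""

from __future__ import annotations

import json
import platform
import traceback
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cna import call_cna_vector, cna_expression_association, GAINED_STATES
from .integrate import (ExpressionCohort, collapse_probes, pca_batch_check,
                        pool, quantile_normalize, standardize_to_reference,
                        PooledMatrix)
from .markers import call_all_markers, PDL1_GENE
from .signature import (fit_metagene, moderated_t, select_signature,
                        validate_metagene)
from .subtype import CentroidSet, assign_subtypes
from .survival import (build_multivariate, cox_fit, interaction_test,
                       km_estimate, logrank_test)
from .synth import SimConfig, generate_cna, generate_cohorts, write_simulation
from .tables import association_table, pcr_analysis


class PipelineError(RuntimeError):
    """Configuration or input error that prevents the run from starting."""


UNIVARIATE_TERMS = ("age_gt50", "pt_2_4", "pn_pos", "grade_2_3", "pdl1_up")


def load_config(config_path) -> dict:
    path = Path(config_path)
    if not path.exists():
        raise PipelineError(f"config file not found: {path}")
    try:
        cfg = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise PipelineError(f"config does not parse: {exc}") from exc
    if not isinstance(cfg, dict) or "mode" not in cfg:
        raise PipelineError("config must be a mapping with a 'mode' key "
                            "('synth' or 'files')")
    return cfg


def _load_file_inputs(cfg: dict):
    inputs = cfg.get("inputs") or {}
    for key in ("expression", "clinical", "centroids"):
        if key not in inputs:
            raise PipelineError(f"config missing inputs.{key}")
    clin_path = Path(inputs["clinical"])
    if not clin_path.exists():
        raise PipelineError(f"clinical file not found: {clin_path}")
    clinical = pd.read_csv(clin_path, index_col=0)
    cohorts = []
    for item in inputs["expression"]:
        expr_path = Path(item["path"])
        if not expr_path.exists():
            raise PipelineError(f"expression file not found: {expr_path}")
        matrix = pd.read_csv(expr_path, sep="\t", index_col=0)
        probe_map = None
        if item.get("probe_map"):
            pm = pd.read_csv(item["probe_map"], sep="\t", index_col=0)
            probe_map = pm.iloc[:, 0].to_dict()
        ds = item.get("dataset_id", expr_path.stem)
        roles = None
        if "role" in clinical.columns:
            roles = clinical.loc[clinical["dataset_id"] == ds, "role"]
        cohorts.append(ExpressionCohort(
            dataset_id=ds, platform=item.get("platform", "unknown"),
            matrix=matrix, probe_map=probe_map, sample_roles=roles))
    centroids = CentroidSet.from_tsv(inputs["centroids"])
    cna = None
    if inputs.get("cna"):
        cna = pd.read_csv(inputs["cna"], sep="\t", index_col=0)
    return cohorts, clinical, centroids, cna


def _binary_codings(clinical: pd.DataFrame) -> pd.DataFrame:
    """Code covariates the way the survival analysis contrasts them:
    age <=50 vs >50, pT1 vs pT2-4, pN negative vs positive, grade 1 vs 2-3,
    PDL1 no-up vs up."""
    df = clinical.copy()
    df["age_gt50"] = (df["age"] > 50).astype(float)
    df["pt_2_4"] = (df["pt"].astype(str) != "pT1").astype(float)
    df["pn_pos"] = (df["pn"].astype(str) == "positive").astype(float)
    df["grade_2_3"] = df["grade"].astype(str).isin(["2", "3"]).astype(float)
    df["pdl1_up"] = (df["pdl1"] == "up").astype(float)
    return df


def _cox_table(df: pd.DataFrame, endpoint: str,
               terms=UNIVARIATE_TERMS) -> tuple[pd.DataFrame, dict[str, float]]:
    """Univariate Cox rows (one fit per term) for one endpoint."""
    rows, pvals = [], {}
    for term in terms:
        try:
            res = cox_fit(df, f"{endpoint}_time", f"{endpoint}_event", [term])
        except ValueError as exc:
            rows.append({"endpoint": endpoint, "term": term, "n": 0,
                         "hr": np.nan, "ci_low": np.nan, "ci_high": np.nan,
                         "p": np.nan, "note": str(exc)})
            continue
        if not res.converged:
            rows.append({"endpoint": endpoint, "term": term, "n": res.n,
                         "hr": np.nan, "ci_low": np.nan, "ci_high": np.nan,
                         "p": np.nan, "note": "non-convergence"})
            continue
        lo, hi = res.ci(term)
        rows.append({"endpoint": endpoint, "term": term, "n": res.n,
                     "hr": res.hr(term), "ci_low": lo, "ci_high": hi,
                     "p": res.p(term), "note": ""})
        pvals[term] = res.p(term)
    return pd.DataFrame(rows), pvals


def _multivariate_table(df: pd.DataFrame, endpoint: str,
                        univariate_p: dict[str, float],
                        alpha: float = 0.05) -> pd.DataFrame:
    selected = build_multivariate(univariate_p, alpha)
    if len(selected) < 2:
        return pd.DataFrame()
    res = cox_fit(df, f"{endpoint}_time", f"{endpoint}_event", selected)
    if not res.converged:
        return pd.DataFrame([{"endpoint": endpoint, "term": t, "n": res.n,
                              "hr": np.nan, "ci_low": np.nan,
                              "ci_high": np.nan, "p": np.nan,
                              "note": "non-convergence"} for t in selected])
    rows = []
    for term in res.summary.index:
        lo, hi = res.ci(term)
        rows.append({"endpoint": endpoint, "term": term, "n": res.n,
                     "hr": res.hr(term), "ci_low": lo, "ci_high": hi,
                     "p": res.p(term), "note": "multivariate"})
    return pd.DataFrame(rows)


def _km_export(df: pd.DataFrame, endpoint: str, group_col: str = "pdl1"
               ) -> tuple[pd.DataFrame, dict]:
    """KM step-function data per group plus log-rank and 5-year rates."""
    curves, summary = [], {}
    sub = df.dropna(subset=[f"{endpoint}_time", f"{endpoint}_event", group_col])
    chi2, p = logrank_test(sub[f"{endpoint}_time"], sub[f"{endpoint}_event"],
                           sub[group_col])
    summary["logrank_chi2"] = chi2
    summary["logrank_p"] = p
    for label, grp in sub.groupby(group_col):
        km = km_estimate(grp[f"{endpoint}_time"], grp[f"{endpoint}_event"])
        summary[f"five_year_{label}"] = km.rate_at(60)
        curves.append(pd.DataFrame({
            "endpoint": endpoint, "group": label, "time": km.timeline,
            "survival": km.survival, "ci_low": km.ci_low,
            "ci_high": km.ci_high}))
    return pd.concat(curves, ignore_index=True), summary


def integrate_cohorts(cohorts: list[ExpressionCohort], centroids: CentroidSet
                      ) -> tuple[PooledMatrix, PooledMatrix, pd.Series]:
    """Normalize, collapse, subtype and standardize each dataset; pool.

    Returns the standardized pool, the pre-standardization pool (for the
    batch check) and the per-sample subtype labels assigned per dataset.
    """
    std_cohorts, raw_cohorts = [], []
    labels: dict[str, str] = {}
    for c in cohorts:
        qn = quantile_normalize(c.matrix)
        qc = ExpressionCohort(c.dataset_id, c.platform, qn, c.probe_map,
                              c.sample_roles)
        collapsed = collapse_probes(qc) if c.probe_map else qc
        st = assign_subtypes(collapsed.matrix, centroids)
        labels.update(st.to_dict())
        raw_cohorts.append(collapsed)
        std_cohorts.append(standardize_to_reference(collapsed, st))
    return pool(std_cohorts), pool(raw_cohorts), pd.Series(labels, name="subtype")


def run_pipeline(config_path, outdir, seed: int | None = None) -> dict:
    """Run the full analysis and write report tables under ``outdir``.

    Returns the run summary (also written as run_summary.json).  Input or
    configuration errors raise :class:`PipelineError` before any output is
    written; failures of individual analysis stages afterwards are recorded
    in the summary under ``stage_errors``.
    """
    cfg = load_config(config_path)
    mode = cfg.get("mode")
    summary: dict = {"package_version": __version__,
                     "python": platform.python_version(),
                     "mode": mode, "stage_errors": {}}
    cna_table = None
    if mode == "synth":
        sim_kwargs = dict(cfg.get("synth") or {})
        if seed is not None:
            sim_kwargs["seed"] = seed
        sim = SimConfig(**sim_kwargs)
        summary["seed"] = sim.seed
        cohorts, clinical, truth = generate_cohorts(sim)
        centroids = truth.centroids
        cna_table = generate_cna(sim, truth)
    elif mode == "files":
        cohorts, clinical, centroids, cna_table = _load_file_inputs(cfg)
        summary["seed"] = seed
    else:
        raise PipelineError(f"unknown mode {mode!r}")

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pooled, raw_pooled, subtypes = integrate_cohorts(cohorts, centroids)
        clinical = clinical.copy()
        clinical["subtype"] = subtypes.reindex(clinical.index)
        clinical = call_all_markers(pooled.matrix, clinical)
    tumors = clinical[clinical["role"] == "tumor"].copy()
    summary["n_samples"] = int(len(clinical))
    summary["n_tumors"] = int(len(tumors))
    summary["n_normal_breast"] = int((clinical["role"] == "normal_breast").sum())
    summary["pdl1_up_fraction"] = float((tumors["pdl1"] == "up").mean())
    basal_mask = tumors["subtype"] == "Basal"
    if basal_mask.any():
        summary["pdl1_up_fraction_basal"] = float(
            (tumors.loc[basal_mask, "pdl1"] == "up").mean())
    summary["subtype_counts"] = {
        k: int(v) for k, v in tumors["subtype"].value_counts().items()}

    # batch check on the centroid panel
    try:
        st_series = tumors["subtype"]
        before = pca_batch_check(raw_pooled, centroids.panel, st_series)
        after = pca_batch_check(pooled, centroids.panel, st_series)
        summary["batch_check"] = {
            "silhouette_by_dataset_before": before.silhouette_by_dataset,
            "silhouette_by_dataset_after": after.silhouette_by_dataset,
            "silhouette_by_subtype_after": after.silhouette_by_subtype,
        }
    except Exception:
        summary["stage_errors"]["batch_check"] = traceback.format_exc(limit=1)

    # Table 1: clinicopathological associations with PDL1 group
    try:
        t1 = association_table(tumors, "pdl1")
        t1.to_csv(out / "table1_associations.tsv", sep="\t", index=False,
                  float_format="%.6g")
    except Exception:
        summary["stage_errors"]["table1"] = traceback.format_exc(limit=1)

    # Tables 2-3 + KM exports: prognostic analyses
    try:
        coded = _binary_codings(tumors)
        t2_parts, km_parts = [], []
        for endpoint in ("mfs", "oss"):
            uni, pvals = _cox_table(coded, endpoint)
            t2_parts.append(uni)
            km_curves, km_summary = _km_export(coded, endpoint)
            km_parts.append(km_curves)
            summary[f"km_{endpoint}"] = km_summary
            coef, p_int = interaction_test(
                coded.assign(basal=(coded["subtype"] == "Basal").astype(float)),
                f"{endpoint}_time", f"{endpoint}_event", "pdl1_up", "basal")
            summary[f"interaction_{endpoint}"] = {"coef": coef, "p": p_int}
        pd.concat(t2_parts, ignore_index=True).to_csv(
            out / "table2_univariate_cox.tsv", sep="\t", index=False,
            float_format="%.6g")
        pd.concat(km_parts, ignore_index=True).to_csv(
            out / "km_curves.tsv", sep="\t", index=False, float_format="%.6g")

        basal = coded[coded["subtype"] == "Basal"]
        t3_parts = []
        for endpoint in ("mfs", "oss"):
            uni, pvals = _cox_table(basal, endpoint)
            uni["note"] = uni["note"].where(uni["note"] != "", "univariate")
            t3_parts.append(uni)
            t3_parts.append(_multivariate_table(basal, endpoint, pvals))
            km_curves, km_summary = _km_export(basal, endpoint)
            summary[f"km_{endpoint}_basal"] = km_summary
        pd.concat(t3_parts, ignore_index=True).to_csv(
            out / "table3_subtype_cox.tsv", sep="\t", index=False,
            float_format="%.6g")
    except Exception:
        summary["stage_errors"]["survival"] = traceback.format_exc(limit=1)

    # Table 5: exact pCR analysis
    try:
        t5 = pcr_analysis(tumors)
        t5.to_csv(out / "table5_pcr.tsv", sep="\t", index=False,
                  float_format="%.6g")
    except Exception:
        summary["stage_errors"]["pcr"] = traceback.format_exc(limit=1)

    # copy-number association
    if cna_table is not None:
        try:
            shared = [s for s in tumors.index if s in cna_table.index
                      and s in pooled.matrix.columns]
            states = call_cna_vector(cna_table.loc[shared, "log2_ratio"])
            tstat, p = cna_expression_association(
                states, pooled.matrix.loc[PDL1_GENE, shared])
            frac = {k: float((states == k).sum()) / len(states)
                    for k in np.unique(states)}
            summary["cna"] = {"t": tstat, "p": p, "state_fractions": frac,
                              "n": len(shared)}
        except Exception:
            summary["stage_errors"]["cna"] = traceback.format_exc(limit=1)

    # signature: learning set = first dataset, validation = the rest
    try:
        ds_ids = [c.dataset_id for c in cohorts]
        learn_ds, val_ds = ds_ids[0], ds_ids[1:3]
        learn_cols = [s for s in tumors.index
                      if tumors.loc[s, "dataset_id"] == learn_ds
                      and s in pooled.matrix.columns]
        learn_mat = pooled.matrix[learn_cols]
        labels = tumors.loc[learn_cols, "pdl1"].to_numpy()
        de = moderated_t(learn_mat, labels, group_up="up")
        sig = select_signature(de)
        sig.to_csv(out / "signature_genes.tsv", sep="\t",
                   float_format="%.6g")
        summary["signature"] = {
            "n_genes": int(len(sig)),
            "n_up": int((sig["direction"] == "up").sum()),
            "n_down": int((sig["direction"] == "down").sum()),
        }
        up_genes = sig.index[sig["direction"] == "up"].tolist()
        val_rows = []
        if up_genes and val_ds:
            model = fit_metagene(learn_mat, up_genes, labels)
            summary["signature"]["threshold"] = model.threshold
            summary["signature"]["learning_auc"] = model.auc
            for ds in val_ds:
                cols = [s for s in tumors.index
                        if tumors.loc[s, "dataset_id"] == ds
                        and s in pooled.matrix.columns]
                res = validate_metagene(model, pooled.matrix[cols],
                                        tumors.loc[cols, "pdl1"].to_numpy())
                val_rows.append({
                    "dataset_id": ds, "n": res["n"],
                    "accuracy": res["accuracy"], "fisher_p": res["fisher_p"],
                    "tp": int(res["confusion"][0, 0]),
                    "fp": int(res["confusion"][0, 1]),
                    "fn": int(res["confusion"][1, 0]),
                    "tn": int(res["confusion"][1, 1])})
        pd.DataFrame(val_rows).to_csv(out / "metagene_validation.tsv",
                                      sep="\t", index=False,
                                      float_format="%.6g")
    except Exception:
        summary["stage_errors"]["signature"] = traceback.format_exc(limit=1)

    (out / "run_summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True, default=float) + "\n")
    return summary


def simulate_to_dir(config_path, outdir, seed: int | None = None) -> SimConfig:
    """Generate a synthetic compendium and write it as plain-text tables."""
    cfg = load_config(config_path)
    if cfg.get("mode") != "synth":
        raise PipelineError("simulate requires mode: synth")
    sim_kwargs = dict(cfg.get("synth") or {})
    if seed is not None:
        sim_kwargs["seed"] = seed
    sim = SimConfig(**sim_kwargs)
    cohorts, clinical, truth = generate_cohorts(sim)
    cna = generate_cna(sim, truth)
    write_simulation(outdir, cohorts, clinical, truth, cna, sim)
    return sim
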