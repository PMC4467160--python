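"""Multi-cohort synthetic data generator.

Emulates the statistical structure of a pooled breast-cancer expression
compendium: several microarray datasets with dataset-specific location/scale
batch effects, five intrinsic subtypes at fixed proportions, bimodally
expressed receptor/proliferation markers, a PDL1-upregulated subpopulation
concentrated in basal tumors, exponential survival with subtype- and
group-specific hazards, a per-subtype logistic model for pathological
complete response, and basal-enriched copy-number gains at the PDL1 locus
that boost its expression.

The generator is fully deterministic given ``SimConfig.seed``: regenerating
with the same configuration reproduces byte-identical tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import optimize
from scipy.special import expit, logit

from .integrate import ExpressionCohort
from .subtype import SUBTYPE_ORDER, CentroidSet

SUBTYPES = list(SUBTYPE_ORDER)

# Marker genes and the subtypes in which their high mode sits.
MARKER_HIGH_MODE = {
    "ESR1": ("LumA", "LumB"),
    "PGR": ("LumA", "LumB"),
    "ERBB2": ("ERBB2",),
    "MKI67": ("LumB", "Basal", "ERBB2"),
}
PDL1_GENE = "CD274"


def _subtype_map(default: float, **overrides: float) -> dict[str, float]:
    d = {s: default for s in SUBTYPES}
    d.update(overrides)
    return d


@dataclass
class SimConfig:
    """Study-condition parameters of the simulated compendium.

    Defaults encode the cohort structure the analysis targets: five subtypes
    at 28/23/22/15/12%, PDL1 upregulation in 38% of basal and ~15% of other
    tumors (≈20% overall), a protective basal-specific hazard ratio of 0.55
    (MFS) / 0.52 (OSS) for up vs no-up, pCR odds ratios of 4.3 (basal) and
    6.5 (ERBB2-enriched), and copy-number gains in 17% of basal vs 2% of
    other tumors.
    """

    n_datasets: int = 5
    samples_per_dataset: int = 300
    n_genes: int = 2000
    n_normal_per_dataset: int = 10
    subtype_proportions: dict[str, float] = field(default_factory=lambda: {
        "LumA": 0.28, "LumB": 0.23, "Basal": 0.22,
        "ERBB2": 0.15, "Normal-like": 0.12})
    pdl1_up_prevalence: dict[str, float] = field(
        default_factory=lambda: _subtype_map(0.15, Basal=0.38))
    batch_location_sd: float = 0.8  # log2 units, per dataset per gene
    batch_scale_range: tuple[float, float] = (0.8, 1.25)
    marker_mode_separation: float = 3.0  # log2 units between bimodal modes
    marker_label_noise: float = 0.05
    hr_mfs: dict[str, float] = field(
        default_factory=lambda: _subtype_map(1.0, Basal=0.55))
    hr_oss: dict[str, float] = field(
        default_factory=lambda: _subtype_map(1.0, Basal=0.52))
    baseline_hazard_mfs: dict[str, float] = field(
        default_factory=lambda: _subtype_map(0.007, Basal=0.0137))
    baseline_hazard_oss: dict[str, float] = field(
        default_factory=lambda: _subtype_map(0.0027, Basal=0.0064))
    pcr_or: dict[str, float] = field(
        default_factory=lambda: _subtype_map(1.0, Basal=4.3, ERBB2=6.5))
    baseline_pcr_rate: float = 0.21
    censoring_rate: float = 0.30
    n_signature_genes: int = 300
    signature_effect: float = 1.5  # log2 FC of true up-vs-no-up DE genes
    signature_up_fraction: float = 0.8
    cna_gain_prob: dict[str, float] = field(
        default_factory=lambda: _subtype_map(0.02, Basal=0.17))
    n_panel_genes: int = 50  # subtype-informative genes beyond the markers
    centroid_sd: float = 2.0
    noise_sd: float = 0.5
    pdl1_up_shift: float = 2.5
    pdl1_noise_sd: float = 0.25
    two_probe_fraction: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_datasets", "samples_per_dataset", "n_genes",
                     "n_signature_genes", "n_panel_genes"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_normal_per_dataset < 0:
            raise ValueError("n_normal_per_dataset must be non-negative")
        if abs(sum(self.subtype_proportions.values()) - 1.0) > 1e-9:
            raise ValueError("subtype_proportions must sum to 1")
        for mp in (self.subtype_proportions, self.pdl1_up_prevalence,
                   self.cna_gain_prob):
            for k, v in mp.items():
                if not 0.0 <= v <= 1.0:
                    raise ValueError(f"fraction {k}={v} outside [0,1]")
        for mp in (self.hr_mfs, self.hr_oss, self.pcr_or,
                   self.baseline_hazard_mfs, self.baseline_hazard_oss):
            for k, v in mp.items():
                if v <= 0:
                    raise ValueError(f"rate/ratio {k}={v} must be positive")
        if not 0.0 <= self.censoring_rate < 1.0:
            raise ValueError("censoring_rate must be in [0,1)")
        min_genes = (len(MARKER_HIGH_MODE) + 1 + self.n_panel_genes
                     + self.n_signature_genes)
        if self.n_genes < min_genes:
            raise ValueError(f"n_genes must be >= {min_genes} to hold the "
                             "marker, panel and signature genes")

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["batch_scale_range"] = list(self.batch_scale_range)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        d = yaml.safe_load(Path(path).read_text())
        if "batch_scale_range" in d:
            d["batch_scale_range"] = tuple(d["batch_scale_range"])
        return cls(**d)


@dataclass
class SimTruth:
    """Ground truth of a simulated compendium."""

    samples: pd.DataFrame  # per-sample truth (subtype, PDL1 group, CNA, ...)
    genes: pd.DataFrame  # per-gene truth (signature membership, effect)
    centroids: CentroidSet  # the generating centroids over the panel


def _gene_universe(config: SimConfig, rng: np.random.Generator):
    markers = list(MARKER_HIGH_MODE) + [PDL1_GENE]
    panel_extra = [f"PANEL{i:04d}" for i in range(1, config.n_panel_genes + 1)]
    signature = [f"SIG{i:04d}" for i in range(1, config.n_signature_genes + 1)]
    n_bg = config.n_genes - len(markers) - len(panel_extra) - len(signature)
    background = [f"G{i:05d}" for i in range(1, n_bg + 1)]
    genes = markers + panel_extra + signature + background
    base = pd.Series(rng.normal(7.0, 1.0, len(genes)), index=genes)
    base[PDL1_GENE] = 6.0
    # subtype centroid deviations over the informative panel
    dev = pd.DataFrame(0.0, index=panel_extra, columns=SUBTYPES)
    for st in SUBTYPES:
        dev[st] = rng.normal(0.0, config.centroid_sd, len(panel_extra))
    half = config.marker_mode_separation / 2
    marker_dev = pd.DataFrame(-half, index=list(MARKER_HIGH_MODE),
                              columns=SUBTYPES)
    for g, highs in MARKER_HIGH_MODE.items():
        marker_dev.loc[g, list(highs)] = half
    # direction of the true DE effect for signature genes
    n_up = int(round(config.signature_up_fraction * len(signature)))
    direction = np.where(np.arange(len(signature)) < n_up, 1.0, -1.0)
    gene_truth = pd.DataFrame({
        "gene_id": genes,
        "is_marker": [g in markers for g in genes],
        "is_panel": [g in set(panel_extra) for g in genes],
        "is_signature": [g in set(signature) for g in genes],
        "effect": 0.0,
    }).set_index("gene_id")
    gene_truth.loc[signature, "effect"] = direction * config.signature_effect
    centroid_values = pd.concat([
        marker_dev.add(base[list(MARKER_HIGH_MODE)], axis=0),
        dev.add(base[panel_extra], axis=0),
    ])
    return genes, base, dev, marker_dev, gene_truth, CentroidSet(centroid_values)


def _censoring_horizon(lam_mean: float, rate: float) -> float:
    """T_max such that uniform-[0, T_max] censoring yields the configured
    expected censored fraction at the cohort-average hazard."""
    if rate <= 0:
        return math.inf

    def f(T: float) -> float:
        return (1 - math.exp(-lam_mean * T)) / (lam_mean * T) - rate

    return optimize.brentq(f, 1e-6, 1e7)


def generate_clinical(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-sample clinical covariates, endpoints, and truth labels.

    The clinical table indexes samples and carries dataset, role, covariates,
    MFS/OSS endpoints and pCR; the truth table carries the generating labels
    (true subtype, true PDL1 group, CNA gain, per-endpoint hazards).
    Expression is generated separately (:func:`generate_cohorts`) from the
    same seed, so both views describe the same virtual patients.
    """
    ss = np.random.SeedSequence(config.seed)
    rng = np.random.default_rng(ss.spawn(3)[0])
    props = np.array([config.subtype_proportions[s] for s in SUBTYPES])
    rows, truth_rows = [], []
    for d in range(1, config.n_datasets + 1):
        ds = f"D{d:02d}"
        for i in range(1, config.samples_per_dataset + 1):
            sid = f"{ds}_S{i:04d}"
            st = SUBTYPES[rng.choice(len(SUBTYPES), p=props)]
            up = rng.random() < config.pdl1_up_prevalence[st]
            gain = rng.random() < config.cna_gain_prob[st]
            rows.append({"sample_id": sid, "dataset_id": ds, "role": "tumor"})
            truth_rows.append({"sample_id": sid, "dataset_id": ds,
                               "role": "tumor", "subtype_true": st,
                               "pdl1_up_true": up, "cna_gain_true": gain})
        for i in range(1, config.n_normal_per_dataset + 1):
            sid = f"{ds}_NB{i:02d}"
            rows.append({"sample_id": sid, "dataset_id": ds,
                         "role": "normal_breast"})
            truth_rows.append({"sample_id": sid, "dataset_id": ds,
                               "role": "normal_breast",
                               "subtype_true": "Normal-like",
                               "pdl1_up_true": False, "cna_gain_true": False})
    clinical = pd.DataFrame(rows).set_index("sample_id")
    truth = pd.DataFrame(truth_rows).set_index("sample_id")
    tumor = truth["role"] == "tumor"
    n_t = int(tumor.sum())

    # covariates: age independent; grade mildly subtype-linked
    clinical["age"] = np.nan
    clinical.loc[tumor, "age"] = np.clip(
        np.round(rng.normal(55, 12, n_t)), 25, 90)
    clinical.loc[tumor, "pt"] = rng.choice(
        ["pT1", "pT2", "pT3"], size=n_t, p=[0.40, 0.45, 0.15])
    clinical.loc[tumor, "pn"] = rng.choice(
        ["negative", "positive"], size=n_t, p=[0.55, 0.45])
    grade_probs = {"LumA": [0.30, 0.50, 0.20], "Normal-like": [0.30, 0.50, 0.20],
                   "LumB": [0.10, 0.50, 0.40], "Basal": [0.05, 0.25, 0.70],
                   "ERBB2": [0.05, 0.25, 0.70]}
    grades = np.empty(n_t, dtype=object)
    st_arr = truth.loc[tumor, "subtype_true"].to_numpy()
    for st in SUBTYPES:
        m = st_arr == st
        grades[m] = rng.choice(["1", "2", "3"], size=int(m.sum()),
                               p=grade_probs[st])
    clinical.loc[tumor, "grade"] = grades
    clinical.loc[tumor, "histotype"] = rng.choice(
        ["DUC", "LOB", "other"], size=n_t, p=[0.85, 0.10, 0.05])

    up_arr = truth.loc[tumor, "pdl1_up_true"].to_numpy()
    for endpoint, hr_map, base_map in (
            ("mfs", config.hr_mfs, config.baseline_hazard_mfs),
            ("oss", config.hr_oss, config.baseline_hazard_oss)):
        lam = np.array([base_map[s] for s in st_arr])
        lam = lam * np.where(up_arr,
                             np.array([hr_map[s] for s in st_arr]), 1.0)
        t_event = rng.exponential(1.0 / lam)
        tmax = _censoring_horizon(float(lam.mean()), config.censoring_rate)
        c = rng.uniform(0, tmax, n_t) if math.isfinite(tmax) else \
            np.full(n_t, np.inf)
        event = (t_event <= c).astype(int)
        time = np.ceil(np.minimum(t_event, c)).clip(min=1.0)
        clinical.loc[tumor, f"{endpoint}_time"] = time
        clinical.loc[tumor, f"{endpoint}_event"] = event
        truth.loc[tumor, f"lambda_{endpoint}"] = lam

    p_pcr = expit(logit(config.baseline_pcr_rate)
                  + np.log(np.array([config.pcr_or[s] for s in st_arr]))
                  * up_arr)
    clinical.loc[tumor, "pcr"] = (rng.random(n_t) < p_pcr).astype(float)
    truth.loc[tumor, "p_pcr_true"] = p_pcr
    return clinical, truth


def generate_cohorts(config: SimConfig
                     ) -> tuple[list[ExpressionCohort], pd.DataFrame, SimTruth]:
    """Generate the full simulated compendium.

    Returns per-dataset probe-level expression cohorts (log2 scale, with
    probe maps), the clinical table and the ground truth.  Expression =
    gene base level + subtype centroid deviation + marker mode + PDL1 group
    shift + signature effect + CNA boost, scaled by a per-dataset factor and
    shifted by a per-dataset per-gene batch offset, plus Gaussian noise.
    """
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(4)
    rng_genes = np.random.default_rng(children[1])
    dataset_seqs = children[3].spawn(config.n_datasets)
    clinical, truth = generate_clinical(config)
    genes, base, panel_dev, marker_dev, gene_truth, centroids = \
        _gene_universe(config, rng_genes)
    marker_names = list(MARKER_HIGH_MODE)
    panel_extra = list(panel_dev.index)
    sig_genes = gene_truth.index[gene_truth["is_signature"]].tolist()
    half = config.marker_mode_separation / 2

    cohorts: list[ExpressionCohort] = []
    marker_truth_cols = {f"{g.lower()}_high_true": [] for g in marker_names}
    sample_order: list[str] = []
    for d in range(1, config.n_datasets + 1):
        ds = f"D{d:02d}"
        rng = np.random.default_rng(dataset_seqs[d - 1])
        cols = clinical.index[clinical["dataset_id"] == ds].tolist()
        n = len(cols)
        st_arr = truth.loc[cols, "subtype_true"].to_numpy()
        up_arr = truth.loc[cols, "pdl1_up_true"].to_numpy()
        gain_arr = truth.loc[cols, "cna_gain_true"].to_numpy()
        is_nb = (truth.loc[cols, "role"] == "normal_breast").to_numpy()

        dev = pd.DataFrame(0.0, index=genes, columns=cols)
        # subtype-informative panel
        for st in SUBTYPES:
            m = st_arr == st
            if m.any():
                dev.loc[panel_extra, np.array(cols)[m]] = \
                    np.tile(panel_dev[st].to_numpy()[:, None], (1, int(m.sum())))
        # bimodal markers with label noise (flips define the truth mode)
        for g in marker_names:
            high = np.isin(st_arr, MARKER_HIGH_MODE[g])
            flip = (~is_nb) & (rng.random(n) < config.marker_label_noise)
            high = high ^ flip
            dev.loc[g, :] = np.where(high, half, -half)
            marker_truth_cols[f"{g.lower()}_high_true"].extend(
                zip(cols, high))
        # PDL1 group shift and CNA expression boost
        pdl1_dev = np.where(up_arr, config.pdl1_up_shift, 0.0)
        pdl1_dev = pdl1_dev + np.where(gain_arr,
                                       config.signature_effect / 2, 0.0)
        dev.loc[PDL1_GENE, :] = pdl1_dev
        # signature genes differ between PDL1 groups (tumors only)
        eff = gene_truth.loc[sig_genes, "effect"].to_numpy()
        up_t = up_arr & ~is_nb
        if up_t.any():
            dev.loc[sig_genes, np.array(cols)[up_t]] += eff[:, None]

        noise = rng.normal(0.0, config.noise_sd, (len(genes), n))
        noise[genes.index(PDL1_GENE)] = rng.normal(
            0.0, config.pdl1_noise_sd, n)
        scale = rng.uniform(*config.batch_scale_range)
        shift = rng.normal(0.0, config.batch_location_sd, len(genes))
        values = (base.to_numpy()[:, None]
                  + scale * (dev.to_numpy() + noise)
                  + shift[:, None])
        gene_mat = pd.DataFrame(values, index=genes, columns=cols)

        # expand to probe level: a fraction of genes carry two probes
        two_probe = rng.random(len(genes)) < config.two_probe_fraction
        probe_rows, probe_ids, probe_map = [], [], {}
        for gi, g in enumerate(genes):
            pid = f"{g}_p1"
            probe_ids.append(pid)
            probe_map[pid] = g
            probe_rows.append(gene_mat.iloc[gi].to_numpy()
                              + rng.normal(0, 0.1, n))
            if two_probe[gi]:
                pid2 = f"{g}_p2"
                probe_ids.append(pid2)
                probe_map[pid2] = g
                probe_rows.append(gene_mat.iloc[gi].to_numpy() * 0.6
                                  + rng.normal(0, 0.1, n)
                                  + base[g] * 0.4)
        probe_mat = pd.DataFrame(np.vstack(probe_rows), index=probe_ids,
                                 columns=cols)
        roles = pd.Series(np.where(is_nb, "normal_breast", "tumor"),
                          index=cols)
        cohorts.append(ExpressionCohort(
            dataset_id=ds, platform=f"synth_array_{(d - 1) % 3 + 1}",
            matrix=probe_mat, probe_map=probe_map, sample_roles=roles))
        sample_order.extend(cols)

    for col, pairs in marker_truth_cols.items():
        s = pd.Series(dict(pairs))
        truth[col] = s.reindex(truth.index)
    sim_truth = SimTruth(samples=truth, genes=gene_truth, centroids=centroids)
    return cohorts, clinical, sim_truth


def generate_cna(config: SimConfig, truth: SimTruth) -> pd.DataFrame:
    """Single-locus DNA log2 copy ratios at the PDL1 locus.

    Gained samples draw ratios at or above log2(1.5) (a tail of them reaches
    the 2x amplification threshold); all other samples stay in the neutral
    band.
    """
    ss = np.random.SeedSequence(config.seed)
    rng = np.random.default_rng(ss.spawn(3)[2])
    samples = truth.samples
    gained = samples["cna_gain_true"].to_numpy(dtype=bool)
    n = len(samples)
    neutral = np.clip(rng.normal(0.0, 0.08, n), -0.30, 0.30)
    gain_ratio = math.log2(1.5) + np.abs(rng.normal(0.0, 0.25, n))
    ratio = np.where(gained, gain_ratio, neutral)
    return pd.DataFrame({"sample_id": samples.index,
                         "log2_ratio": ratio}).set_index("sample_id")


def write_simulation(outdir, cohorts: list[ExpressionCohort],
                     clinical: pd.DataFrame, truth: SimTruth,
                     cna: pd.DataFrame | None, config: SimConfig) -> None:
    """Write the simulated compendium as plain-text tables.

    One expression TSV per dataset (probes x samples, log2), a probe-map TSV,
    the clinical CSV, the truth TSVs, the centroid TSV, optionally the CNA
    TSV, and the config as YAML.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for c in cohorts:
        c.matrix.to_csv(out / f"expression_{c.dataset_id}.tsv", sep="\t",
                        float_format="%.6f")
        pd.Series(c.probe_map, name="gene_id").rename_axis("probe_id") \
            .to_csv(out / f"probe_map_{c.dataset_id}.tsv", sep="\t")
    clinical.to_csv(out / "clinical.csv")
    truth.samples.to_csv(out / "truth_samples.tsv", sep="\t")
    truth.genes.to_csv(out / "truth_genes.tsv", sep="\t")
    truth.centroids.to_tsv(out / "centroids.tsv")
    if cna is not None:
        cna.to_csv(out / "cna.tsv", sep="\t", float_format="%.6f")
    config.to_yaml(out / "config.yaml")
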