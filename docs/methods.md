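# Methods

## Integration model

Each dataset is treated as an independently assayed cohort with its own
location/scale distortions. The pipeline order is: quantile normalization →
probe→gene collapse → per-dataset centroid subtyping → luminal-A-referenced
standardization → pooling. Subtyping runs *before* standardization because
the centroid correlation (Spearman) is invariant to monotone per-sample
transforms and therefore tolerates raw per-dataset scales, whereas the
standardization needs the subtype labels to locate its reference
subpopulation.

*Quantile normalization* maps every column onto the row-means of the
column-sorted matrix; tied values receive the mean of the reference values
at the rank positions they occupy. With this tie rule one pass is a fixed
point on tie-free (continuous) data; ties can shift a column's value
multiset, so exact idempotence is only guaranteed without ties.

*Probe collapse* keeps, per gene, the probe with the largest within-dataset
sample variance (ddof = 1); exact ties resolve to the lexicographically
smallest probe id so builds are reproducible.

*Standardization* z-scores each gene against the mean and SD of the
dataset's luminal-A samples (SD floored at 1e-6; fewer than two reference
samples triggers a whole-dataset fallback with a warning). Because the
simulated batch distortions are per-gene affine within a dataset (per-gene
additive shift plus a global scale), this removes them exactly up to the
sampling noise of the reference estimates, while preserving within-dataset
ranks per gene. The PCA batch check quantifies residual dataset structure
as the silhouette of dataset labels in a 5-component PCA embedding over the
centroid gene panel, against the silhouette of subtype labels.

## Marker dichotomization

Receptor/proliferation markers are cut per dataset by a two-component
Gaussian mixture with tied (equal) variances, EM with 10 deterministic
restarts; the cutoff is the point between the component means where the
posterior membership is 0.5 (closed form for equal variances, located by
root-finding on the posterior log-ratio). A fit whose mean separation is
below twice the component SD is flagged *not bimodal* and falls back to the
median: two-component fits to genuinely unimodal data always split their
means by roughly one component SD, so a useful bimodality gate has to sit
above that — separation of two component SDs (Ashman D = 1) is exactly the
point where a balanced normal mixture stops having two modes.

PDL1 upregulation is a ratio call against the pooled normal-breast
reference: up ⇔ tumor − mean(NB) ≥ 1 in log2 units (T/NB ≥ 2 linear), with
the boundary inclusive. The reference is the mean over *all* pooled
normal-breast samples in standardized space; a per-dataset reference is a
config-level variant.

## Survival analysis

Kaplan-Meier estimation, Greenwood-based confidence bands, log-rank tests
and Cox models are delegated to lifelines; the module fixes the
conventions: Efron tie handling (simulated times are rounded up to whole
months, so ties are heavy), Wald p-values and Wald CIs
(`exp(β ± 1.96·SE)`), 5-year rates read at 60 months with the
right-continuous step convention. The interaction analysis fits main
effects plus the product of two binary factors (up/no-up ×
basal/non-basal) and reports the product coefficient and its Wald p.
Univariate screening into the multivariate model uses Wald p < 0.05.
Non-convergence or separation is reported on the result object, never
silently swallowed.

## Exact 2×2 inference

The two-sided Fisher p sums the hypergeometric probabilities of all tables
with the observed margins whose probability does not exceed the observed
one (probability-mass ordering, with 1e-12 relative slack for ties at
machine precision). The odds ratio is the conditional MLE under the
noncentral hypergeometric likelihood: ψ solves `E[X | ψ] = a` by Brent
root-finding on log ψ (the conditional mean is strictly increasing in ψ);
the 95% CI inverts the one-sided exact tail tests at 2.5% per side. When
the observed cell sits at the end of its support, the corresponding
estimate/limit is 0 or ∞. The conditional MLE, not the sample
cross-product ratio, is what published exact-test odds ratios report; the
two differ visibly in small strata.

Exact tests are conservative and discrete: their null p-values are only
asymptotically uniform as the margins grow. The null-calibration check for
Fisher therefore uses 2,000-subject tables per replicate; at a few hundred
subjects the discreteness itself fails a KS comparison against uniform for
any correct implementation.

## Moderated t and the metagene

Per-gene pooled variances `s²_g` (d_g = n₁+n₂−2 df) are shrunk to
`s̃²_g = (d₀s₀² + d_g s²_g)/(d₀+d_g)`. The prior (d₀, s₀²) is estimated by
moment matching on log s²_g: the excess of `var(log s²_g)` over
trigamma(d_g/2) identifies trigamma(d₀/2) (inverted by Newton iteration),
and s₀² follows from the mean with a digamma bias correction. The
moderated statistic is referred to t with d₀+d_g df; multiplicity is
Benjamini-Hochberg. In the degenerate case where the sample variances show
no excess spread (var of log s² at or below its chi-square expectation),
the prior is a point mass: d₀ = ∞ and s₀² is set to the geometric mean of
the sample variances without the bias correction, so that identical sample
variances are left untouched.

Signature genes must clear all three thresholds (p < 0.05, q < 0.05,
|log2FC| ≥ 1, fold changes computed on group means in log2 space). The
metagene score is the unweighted mean of the up-gene rows; its cutoff is
placed midway between adjacent distinct learning-set scores at maximum
Youden J (ties toward the lower threshold). Validation on a disjoint
cohort reports accuracy and the Fisher exact p of the 2×2 confusion table;
missing signature genes are tolerated down to 80% coverage with a warning.

## Copy number

Input is a per-sample log2 DNA ratio at the PDL1 locus (segmentation is
upstream). States use symmetric fold-change thresholds with boundaries
assigned to the altered state: |ratio| ≥ 1 (2× FC) is
amplification/homozygous deletion, |ratio| ≥ log2 1.5 is gain/loss,
otherwise neutral. Association with expression is a two-sided pooled
(Student) t of gained+amplified vs the rest; Welch is available by flag.

## The synthetic compendium

The generator emulates the statistical structure the analysis assumes, not
any real dataset:

| parameter | default | role |
| --- | --- | --- |
| n_datasets × samples_per_dataset | 5 × 300 (+10 normal breast each) | pooled multi-cohort design |
| subtype_proportions | LumA .28, LumB .23, Basal .22, ERBB2 .15, Normal-like .12 | intrinsic subtype mix |
| pdl1_up_prevalence | Basal .38, others .15 (≈ .20 overall) | biomarker prevalence |
| marker_mode_separation | 3.0 log2 | bimodal marker modes (noise SD 0.5) |
| pdl1_up_shift / pdl1_noise_sd | 2.5 / 0.25 log2 | up-group shift over the normal-breast level |
| hr_mfs / hr_oss (up vs no-up) | Basal 0.55 / 0.52, others 1.0 | subtype-specific protective effect |
| baseline_hazard_mfs / oss | Basal .0137/.0064, others .007/.0027 per month | ≈ 44%/68% basal no-up 5-year rates, ≈ 66%/85% elsewhere |
| pcr_or | Basal 4.3, ERBB2 6.5, others 1.0 (baseline rate .21) | per-subtype logistic response model |
| cna_gain_prob | Basal .17, others .02 | basal-enriched gains; gained samples get a +signature_effect/2 expression boost |
| n_signature_genes / signature_effect | 300 (80% up) / 1.5 log2 | true differential genes between PDL1 groups |
| batch_location_sd / batch_scale_range | 0.8 / (0.8, 1.25) | per-dataset per-gene shift + global scale |

Survival times are exponential with subtype- and group-specific hazards
(the simplest law consistent with proportional hazards); censoring is
uniform on [0, T_max], where T_max is solved so the expected censored
fraction equals `censoring_rate` at the cohort-average hazard. Times are
rounded up to whole months, deliberately creating ties. Expression is
`gene base + scale·(structure + noise) + per-gene dataset shift`, expanded
to probe level (a configurable fraction of genes carries a second,
attenuated probe so the collapse step has real work to do). Normal-breast
samples sit on the normal-like centroid with PDL1 at the no-up level, so
the up-group's +2.5 log2 shift clears the 2× ratio threshold by
construction. The PDL1 within-group noise (0.25 log2) is deliberately
small relative to the 1-log2 threshold so that the configured prevalences,
not the dichotomization noise, are the operative study condition. All
randomness flows from a single seed through spawned child streams;
regeneration is byte-identical.

What the generator does *not* emulate: probe-level CEL intensities,
count-based noise, correlated gene-gene structure beyond the subtype
centroids, non-proportional hazards, informative censoring, missing data
patterns, or platform-specific probe annotation errors. Passing tests
therefore demonstrate that the analysis machinery recovers known structure
under its own assumptions — not that those assumptions hold in any real
compendium.

A faithful *null* configuration (for type-I-error checks) must flatten
`pdl1_up_prevalence` across subtypes in addition to setting all HRs/ORs to
1: the default basal-enriched prevalence makes the up group a subtype
marker, and subtypes carry different baseline hazards — a real
association, not a calibration failure.

## Problem sizes

Defaults (5 × 300 × 2,000 genes) run the full pipeline in a few seconds.
The test suite's simulation studies use 100-seed batches at n = 600
(coverage), n = 3,000 (interaction power) and 200 replicates for null
calibration; these sizes give binomial 3-SD bands of a few percent around
the tested rates while keeping the whole suite under a couple of minutes.

## Known limitations

- The centroid classifier is file-driven; no published centroid set is
  bundled, so real-data use requires supplying centroids on the intended
  scale.
- The conditional-MLE CI uses exact tail inversion (central CI); mid-p
  variants are not implemented.
- Cox models assume proportional hazards; no diagnostic (e.g. Schoenfeld
  residuals) is exposed.
- The metagene threshold is learned on called (not true) labels, so label
  noise propagates into the validation confusion table, as it would on
  real data.
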