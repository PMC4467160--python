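"""Per-dataset normalization, probe collapse, reference standardization and
the PCA batch check."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra.numpy import arrays

from pdl1bc.integrate import (ExpressionCohort, collapse_probes,
                              pca_batch_check, pool, quantile_normalize,
                              standardize_to_reference)
from pdl1bc.pipeline import integrate_cohorts
from pdl1bc.subtype import assign_subtypes
from pdl1bc.synth import SimConfig, generate_cohorts


class TestQuantileNormalize:
    def test_hand_computed_two_column_example(self):
        m = pd.DataFrame([[1.0, 4.0], [3.0, 2.0]], index=["a", "b"],
                         columns=["s1", "s2"])
        out = quantile_normalize(m)
        expected = pd.DataFrame([[1.5, 3.5], [3.5, 1.5]], index=["a", "b"],
                                columns=["s1", "s2"])
        pd.testing.assert_frame_equal(out, expected)

    def test_constant_matrix_unchanged(self):
        m = pd.DataFrame(np.full((4, 3), 2.5))
        pd.testing.assert_frame_equal(quantile_normalize(m), m)

    def test_columns_share_sorted_values_and_sums(self):
        rng = np.random.default_rng(81)
        m = pd.DataFrame(rng.normal(5, 2, (50, 6)))
        out = quantile_normalize(m)
        ref = np.sort(out.iloc[:, 0].to_numpy())
        for j in range(1, 6):
            np.testing.assert_allclose(np.sort(out.iloc[:, j]), ref,
                                       atol=1e-12)
        np.testing.assert_allclose(out.sum(axis=0), out.sum(axis=0).iloc[0])

    @given(arrays(float, (12, 4), elements=st.floats(-50, 50, width=32),
                  unique=True))
    @settings(max_examples=25, deadline=None)
    def test_idempotent_on_tie_free_data(self, x):
        # continuous (tie-free) data: one pass reaches the fixed point
        m = pd.DataFrame(np.asarray(x, dtype=float))
        once = quantile_normalize(m)
        twice = quantile_normalize(once)
        np.testing.assert_allclose(twice.to_numpy(), once.to_numpy(),
                                   atol=1e-12)

    def test_ties_get_mean_of_reference_values(self):
        m = pd.DataFrame({"s1": [1.0, 1.0, 5.0], "s2": [2.0, 4.0, 6.0]})
        out = quantile_normalize(m)
        # reference = [1.5, 2.5, 5.5]; tied pair in s1 -> mean(1.5, 2.5)
        assert out.loc[0, "s1"] == out.loc[1, "s1"] == pytest.approx(2.0)

    def test_nan_rejected(self):
        m = pd.DataFrame([[1.0, np.nan], [2.0, 3.0]])
        with pytest.raises(ValueError):
            quantile_normalize(m)

    def test_single_column_warns_and_returns_identity(self):
        m = pd.DataFrame({"s1": [3.0, 1.0]})
        with pytest.warns(UserWarning):
            out = quantile_normalize(m)
        pd.testing.assert_frame_equal(out, m)


class TestCollapseProbes:
    @staticmethod
    def _cohort(matrix, probe_map):
        return ExpressionCohort("D01", "test", matrix, probe_map)

    def test_highest_variance_probe_kept(self):
        m = pd.DataFrame({"s1": [0.0, 0.0], "s2": [2.0, 1.0]},
                         index=["pA", "pB"])
        out = collapse_probes(self._cohort(m, {"pA": "G1", "pB": "G1"}))
        assert list(out.matrix.index) == ["G1"]
        np.testing.assert_allclose(out.matrix.loc["G1"], [0.0, 2.0])

    def test_variance_tie_resolved_lexicographically(self):
        m = pd.DataFrame({"s1": [0.0, 1.0], "s2": [2.0, 3.0]},
                         index=["pB", "pA"])
        out = collapse_probes(self._cohort(m, {"pA": "G1", "pB": "G1"}))
        np.testing.assert_allclose(out.matrix.loc["G1"], [1.0, 3.0])  # pA

    def test_single_probe_genes_pass_through(self):
        m = pd.DataFrame({"s1": [1.0, 2.0], "s2": [3.0, 4.0]},
                         index=["pA", "pB"])
        out = collapse_probes(self._cohort(m, {"pA": "G1", "pB": "G2"}))
        assert sorted(out.matrix.index) == ["G1", "G2"]

    def test_unmapped_probes_dropped_and_gene_count_correct(self):
        m = pd.DataFrame(np.arange(12.0).reshape(4, 3),
                         index=["p1", "p2", "p3", "p4"])
        out = collapse_probes(self._cohort(
            m, {"p1": "G1", "p2": "G1", "p3": "G2"}))
        assert len(out.matrix) == 2

    def test_empty_map_rejected(self):
        m = pd.DataFrame(np.zeros((2, 2)), index=["p1", "p2"])
        with pytest.raises(ValueError):
            collapse_probes(self._cohort(m, {}))


class TestStandardize:
    @staticmethod
    def _cohort_with_labels(seed=83, n=60, n_ref=20):
        rng = np.random.default_rng(seed)
        cols = [f"s{i}" for i in range(n)]
        m = pd.DataFrame(rng.normal(6, 2, (30, n)),
                         index=[f"g{i}" for i in range(30)], columns=cols)
        labels = pd.Series(["LumA"] * n_ref + ["Basal"] * (n - n_ref),
                           index=cols)
        return ExpressionCohort("D01", "test", m), labels

    def test_reference_population_centered_and_scaled(self):
        cohort, labels = self._cohort_with_labels()
        out = standardize_to_reference(cohort, labels)
        ref = out.matrix.loc[:, labels == "LumA"]
        np.testing.assert_allclose(ref.mean(axis=1), 0.0, atol=1e-9)
        np.testing.assert_allclose(ref.std(axis=1, ddof=1), 1.0, atol=1e-9)

    def test_ranks_preserved_per_gene(self):
        cohort, labels = self._cohort_with_labels(seed=89)
        out = standardize_to_reference(cohort, labels)
        for g in cohort.matrix.index[:5]:
            before = cohort.matrix.loc[g].rank()
            after = out.matrix.loc[g].rank()
            pd.testing.assert_series_equal(before, after)

    def test_constant_reference_gene_floored_and_flagged(self):
        cohort, labels = self._cohort_with_labels()
        cohort.matrix.iloc[0, :20] = 5.0  # constant within reference
        out = standardize_to_reference(cohort, labels)
        assert out.matrix.attrs["floored_genes"] >= 1
        assert np.isfinite(out.matrix.iloc[0]).all()

    def test_small_reference_falls_back_with_warning(self):
        cohort, labels = self._cohort_with_labels(n_ref=1)
        with pytest.warns(UserWarning, match="falling back"):
            out = standardize_to_reference(cohort, labels)
        np.testing.assert_allclose(out.matrix.mean(axis=1), 0.0, atol=1e-9)

    def test_known_batch_shifts_removed_after_standardization(self):
        """Two cohorts of the same tumors offset by +/-2 log2 units align to
        < 0.05 mean difference once each is referenced to its luminal-A
        samples (the shifts are per-gene affine, so standardization removes
        them exactly up to reference-estimate noise)."""
        rng = np.random.default_rng(97)
        base = rng.normal(6, 1, (40, 80))
        cols_a = [f"a{i}" for i in range(80)]
        cols_b = [f"b{i}" for i in range(80)]
        genes = [f"g{i}" for i in range(40)]
        ca = ExpressionCohort("DA", "t", pd.DataFrame(base + 2.0,
                              index=genes, columns=cols_a))
        cb = ExpressionCohort("DB", "t", pd.DataFrame(base - 2.0,
                              index=genes, columns=cols_b))
        lab_a = pd.Series(["LumA"] * 30 + ["Basal"] * 50, index=cols_a)
        lab_b = pd.Series(["LumA"] * 30 + ["Basal"] * 50, index=cols_b)
        pooled = pool([standardize_to_reference(ca, lab_a),
                       standardize_to_reference(cb, lab_b)])
        mean_a = pooled.matrix[cols_a].mean(axis=1)
        mean_b = pooled.matrix[cols_b].mean(axis=1)
        assert (mean_a - mean_b).abs().max() < 0.05


class TestBatchCheck:
    def test_strong_batch_effect_silhouette_decreases(self):
        cfg = SimConfig(seed=12, n_datasets=3, samples_per_dataset=120,
                        n_genes=400, n_signature_genes=40,
                        batch_location_sd=2.0)
        cohorts, clinical, truth = generate_cohorts(cfg)
        pooled, raw_pooled, subtypes = integrate_cohorts(cohorts,
                                                         truth.centroids)
        before = pca_batch_check(raw_pooled, truth.centroids.panel, subtypes)
        after = pca_batch_check(pooled, truth.centroids.panel, subtypes)
        assert after.silhouette_by_dataset < before.silhouette_by_dataset

    def test_subtype_structure_dominates_after_standardization(self, compendium):
        """Under the default batch conditions, samples group by molecular
        subtype, not by dataset of origin, once standardized."""
        labels = compendium.clinical["subtype"]
        after = pca_batch_check(compendium.pooled,
                                compendium.truth.centroids.panel, labels)
        assert after.silhouette_by_subtype > 0.5
        assert after.silhouette_by_subtype > after.silhouette_by_dataset

    def test_no_batch_effect_silhouette_near_zero(self):
        cfg = SimConfig(seed=14, n_datasets=3, samples_per_dataset=100,
                        n_genes=300, n_signature_genes=30,
                        batch_location_sd=0.0, batch_scale_range=(1.0, 1.0))
        cohorts, clinical, truth = generate_cohorts(cfg)
        pooled, raw_pooled, subtypes = integrate_cohorts(cohorts,
                                                         truth.centroids)
        before = pca_batch_check(raw_pooled, truth.centroids.panel, subtypes)
        after = pca_batch_check(pooled, truth.centroids.panel, subtypes)
        assert abs(before.silhouette_by_dataset) < 0.1
        assert abs(after.silhouette_by_dataset) < 0.1

    def test_too_few_samples_rejected(self):
        from pdl1bc.integrate import PooledMatrix
        m = pd.DataFrame(np.zeros((5, 2)), columns=["s1", "s2"])
        pm = PooledMatrix(m, pd.Series(["D1", "D2"], index=["s1", "s2"]))
        with pytest.raises(ValueError):
            pca_batch_check(pm)
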