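"""Moderated t differential expression and the metagene classifier."""

import math

import numpy as np
import pandas as pd
import pytest
import scipy.stats
from scipy import special
from statsmodels.stats.multitest import multipletests

from pdl1bc.signature import (fit_metagene, moderated_t, select_signature,
                              validate_metagene)


def oracle_moderated_t(X, up_mask):
    """Independently coded moderated-t oracle: explicit per-gene loops over
    the shrinkage and test formulas."""
    n1, n2 = up_mask.sum(), (~up_mask).sum()
    dg = n1 + n2 - 2
    s2, delta = [], []
    for row in X:
        x1, x2 = row[up_mask], row[~up_mask]
        v = (np.sum((x1 - x1.mean()) ** 2) + np.sum((x2 - x2.mean()) ** 2)) / dg
        s2.append(v)
        delta.append(x1.mean() - x2.mean())
    s2, delta = np.array(s2), np.array(delta)
    z = np.log(s2)
    e = z - special.digamma(dg / 2) + math.log(dg / 2)
    evar = np.var(e, ddof=1) - special.polygamma(1, dg / 2)
    if evar > 0:
        # invert trigamma by bisection (deliberately different root-finder)
        lo, hi = 1e-6, 1e8
        for _ in range(200):
            mid = math.sqrt(lo * hi)
            if special.polygamma(1, mid) > evar:
                lo = mid
            else:
                hi = mid
        d0 = 2 * lo
        s02 = math.exp(np.mean(e) + special.digamma(d0 / 2)
                       - math.log(d0 / 2))
        s2_tilde = (d0 * s02 + dg * s2) / (d0 + dg)
        t = delta / np.sqrt(s2_tilde * (1 / n1 + 1 / n2))
        p = 2 * scipy.stats.t.sf(np.abs(t), d0 + dg)
    else:
        # point-mass prior: geometric-mean variance, normal reference
        s2_tilde = np.full_like(s2, math.exp(np.mean(z)))
        t = delta / np.sqrt(s2_tilde * (1 / n1 + 1 / n2))
        p = 2 * scipy.stats.norm.sf(np.abs(t))
    q = multipletests(p, method="fdr_bh")[1]
    return t, p, q


class TestModeratedT:
    @staticmethod
    def _toy(seed=3, genes=50, per_group=3, effect=4.0):
        rng = np.random.default_rng(seed)
        X = rng.normal(0, 1, (genes, 2 * per_group))
        X[0, :per_group] += effect
        mat = pd.DataFrame(X, index=[f"g{i}" for i in range(genes)])
        labels = np.array(["up"] * per_group + ["no_up"] * per_group)
        return mat, labels

    def test_matches_independent_oracle(self):
        mat, labels = self._toy()
        res = moderated_t(mat, labels)
        t, p, q = oracle_moderated_t(mat.to_numpy(), labels == "up")
        np.testing.assert_allclose(res["t"], t, rtol=1e-8)
        np.testing.assert_allclose(res["p"], p, rtol=1e-7)
        np.testing.assert_allclose(res["q"], q, rtol=1e-7)
        assert res["t"].abs().idxmax() == "g0"

    def test_zero_prior_recovers_ordinary_pooled_t(self):
        mat, labels = self._toy()
        res = moderated_t(mat, labels, prior_df=0)
        t_ref = scipy.stats.ttest_ind(mat.loc[:, labels == "up"],
                                      mat.loc[:, labels == "no_up"],
                                      axis=1, equal_var=True)
        np.testing.assert_allclose(res["t"], t_ref.statistic, rtol=1e-10)
        np.testing.assert_allclose(res["p"], t_ref.pvalue, rtol=1e-10)

    def test_equal_variances_make_shrinkage_a_noop(self):
        # every gene has identical sample variance -> s2_tilde == s2
        base = np.array([0.0, 1.0, 2.0, 0.5, 1.5, 2.5])
        X = np.vstack([base + k for k in range(12)])
        mat = pd.DataFrame(X)
        labels = np.array(["up"] * 3 + ["no_up"] * 3)
        res = moderated_t(mat, labels)
        t_ref = scipy.stats.ttest_ind(X[:, :3], X[:, 3:], axis=1,
                                      equal_var=True)
        np.testing.assert_allclose(res["t"], t_ref.statistic, rtol=1e-9)

    def test_null_pvalues_uniform(self):
        rng = np.random.default_rng(9)
        X = rng.normal(0, 1, (2000, 16))
        labels = np.array(["up"] * 8 + ["no_up"] * 8)
        res = moderated_t(pd.DataFrame(X), labels)
        ks = scipy.stats.kstest(res["p"], "uniform")
        assert ks.pvalue > 0.01

    def test_bh_q_properties(self):
        mat, labels = self._toy(seed=11, genes=200)
        res = moderated_t(mat, labels).sort_values("p")
        q = res["q"].to_numpy()
        assert np.all(np.diff(q) >= -1e-12)  # monotone in p rank
        assert q.max() <= 1.0
        assert np.all(q >= res["p"].to_numpy() - 1e-12)


class TestSelectSignature:
    def test_thresholds_applied_jointly(self):
        de = pd.DataFrame({
            "log2_fc": [2.0, 0.9, -1.5, 1.2],
            "t": [8.0, 7.0, -6.0, 1.0],
            "p": [1e-6, 0.04, 1e-4, 0.04],
            "q": [1e-5, 0.04, 1e-3, 0.2],
        }, index=["keep_up", "fc_fail", "keep_down", "q_fail"])
        sel = select_signature(de)
        assert list(sel.index) == ["keep_up", "keep_down"]
        assert list(sel["direction"]) == ["up", "down"]

    def test_null_data_selects_nothing(self):
        rng = np.random.default_rng(21)
        empty = 0
        for _ in range(30):
            X = rng.normal(0, 1, (500, 30))
            labels = np.array(["up"] * 15 + ["no_up"] * 15)
            de = moderated_t(pd.DataFrame(X), labels)
            empty += len(select_signature(de)) == 0
        assert empty >= 27

    def test_recall_and_fdr_on_simulated_effects(self, compendium):
        """On the default compendium the selected genes recover the true
        signature with high recall and controlled false discovery."""
        tum = compendium.tumors
        learn = [s for s in tum.index if tum.loc[s, "dataset_id"] == "D01"]
        de = moderated_t(compendium.pooled.matrix[learn],
                         tum.loc[learn, "pdl1"].to_numpy(), group_up="up")
        sel = select_signature(de)
        truth = compendium.truth.genes
        true_sig = set(truth.index[truth["is_signature"]]) | {"CD274"}
        hits = sum(g in true_sig for g in sel.index)
        recall = hits / truth["is_signature"].sum()
        fdr = 1 - hits / len(sel)
        assert recall >= 0.9
        assert fdr <= 0.1


class TestMetagene:
    def test_separable_scores_split_at_midpoint(self):
        mat = pd.DataFrame([[0.0, 1.0, 2.0, 3.0]], index=["gA"])
        labels = ["no_up", "no_up", "up", "up"]
        model = fit_metagene(mat, ["gA"], labels)
        assert model.threshold == pytest.approx(1.5)
        assert model.training_accuracy == 1.0
        assert model.youden_j == pytest.approx(1.0)

    def test_threshold_shifts_with_constant_offset(self):
        rng = np.random.default_rng(23)
        X = np.vstack([rng.normal(0, 1, 40) + np.r_[np.zeros(20), np.ones(20) * 2]
                       for _ in range(5)])
        labels = ["no_up"] * 20 + ["up"] * 20
        m1 = fit_metagene(pd.DataFrame(X, index=list("abcde")),
                          list("abcde"), labels)
        m2 = fit_metagene(pd.DataFrame(X + 7.0, index=list("abcde")),
                          list("abcde"), labels)
        assert m2.threshold - m1.threshold == pytest.approx(7.0, abs=1e-9)

    def test_permuted_labels_give_no_discrimination(self):
        rng = np.random.default_rng(29)
        js = []
        for _ in range(30):
            X = rng.normal(0, 1, (5, 60))
            labels = rng.permutation(["up"] * 20 + ["no_up"] * 40)
            m = fit_metagene(pd.DataFrame(X, index=list("abcde")),
                             list("abcde"), labels)
            js.append(m.youden_j)
        # optimistic training J is positive but small on permuted labels
        assert np.median(js) < 0.4

    def test_validation_on_learning_set_equals_training_accuracy(self):
        rng = np.random.default_rng(31)
        X = np.vstack([np.r_[rng.normal(0, 1, 25),
                             rng.normal(2.5, 1, 25)] for _ in range(4)])
        mat = pd.DataFrame(X, index=list("wxyz"))
        labels = ["no_up"] * 25 + ["up"] * 25
        model = fit_metagene(mat, list("wxyz"), labels)
        res = validate_metagene(model, mat, labels)
        assert res["accuracy"] == pytest.approx(model.training_accuracy)

    def test_constant_scores_rejected(self):
        mat = pd.DataFrame([[1.0, 1.0, 1.0]], index=["gA"])
        with pytest.raises(ValueError):
            fit_metagene(mat, ["gA"], ["up", "no_up", "up"])

    def test_learning_auc_high_on_default_compendium(self, compendium):
        tum = compendium.tumors
        learn = [s for s in tum.index if tum.loc[s, "dataset_id"] == "D01"]
        labels = tum.loc[learn, "pdl1"].to_numpy()
        de = moderated_t(compendium.pooled.matrix[learn], labels,
                         group_up="up")
        sel = select_signature(de)
        up_genes = sel.index[sel["direction"] == "up"].tolist()
        model = fit_metagene(compendium.pooled.matrix[learn], up_genes, labels)
        assert model.auc >= 0.9
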