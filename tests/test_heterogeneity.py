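import numpy as np
import pandas as pd
import pytest

from lmdhet import (hier_cluster, mad_select, pairwise_spearman,
                    patient_dendrogram, secreted_variance_test)
from lmdhet.heterogeneity import eligible_patients


class TestMadSelect:
    def test_constant_row_excluded(self):
        m = pd.DataFrame({"a": [1.0, 5.0], "b": [1.0, 0.0], "c": [1.0, 9.0]},
                         index=["const", "varies"])
        assert "const" not in mad_select(m, 0.0)

    def test_strict_threshold(self):
        # row 0..4 has MAD exactly 1 -> excluded at mad_min=1
        m = pd.DataFrame([np.arange(5.0), np.arange(0.0, 50.0, 10.0)],
                         index=["mad1", "mad10"], columns=list("abcde"))
        assert mad_select(m, 1.0) == ["mad10"]
        assert mad_select(m, 0.5) == ["mad10", "mad1"]

    def test_selection_monotone_in_threshold(self):
        rng = np.random.default_rng(0)
        m = pd.DataFrame(rng.normal(0, 2, (50, 10)))
        m.index = [f"P{i}" for i in range(50)]
        assert set(mad_select(m, 1.0)) <= set(mad_select(m, 0.5))


class TestHierCluster:
    def _matrix(self):
        rng = np.random.default_rng(1)
        base = rng.normal(0, 1, 30)
        return pd.DataFrame({
            "dup1": base, "dup2": base,
            "anti": -base,
            "other": rng.normal(0, 1, 30),
        }, index=[f"P{i}" for i in range(30)])

    def test_duplicate_profiles_merge_at_zero(self):
        tree, _ = hier_cluster(self._matrix(), cluster_proteins=False)
        Z = tree.linkage
        i, j = tree.labels.index("dup1"), tree.labels.index("dup2")
        first = Z[0]
        assert {int(first[0]), int(first[1])} == {i, j}
        assert first[2] == pytest.approx(0.0, abs=1e-12)

    def test_anticorrelated_distance_is_two(self):
        m = self._matrix()[["dup1", "anti"]]
        tree, _ = hier_cluster(m, cluster_proteins=False)
        assert tree.linkage[-1][2] == pytest.approx(2.0, abs=1e-10)

    def test_zero_variance_sample_named_in_error(self):
        m = self._matrix()
        m["flat"] = 3.14
        with pytest.raises(ValueError, match="flat"):
            hier_cluster(m, cluster_proteins=False)

    def test_empty_protein_selection_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            hier_cluster(self._matrix(), proteins=[])

    def test_newick_deterministic(self):
        m = self._matrix()
        t1, _ = hier_cluster(m, cluster_proteins=False)
        t2, _ = hier_cluster(m[list(reversed(m.columns))],
                             cluster_proteins=False)
        assert t1.to_newick() == t2.to_newick()


class TestPairwiseSpearman:
    def test_identical_columns_correlate_perfectly(self):
        rng = np.random.default_rng(2)
        col = rng.normal(0, 1, 20)
        m = pd.DataFrame({"a": col, "b": col, "c": col})
        res = pairwise_spearman(m)
        assert np.allclose(res.offdiag(), 1.0)
        assert res.summary["median"] == pytest.approx(1.0)

    def test_rank_reversal_gives_minus_one(self):
        m = pd.DataFrame({"a": np.arange(10.0), "b": np.arange(10.0)[::-1]})
        res = pairwise_spearman(m)
        assert res.offdiag()[0] == pytest.approx(-1.0)

    def test_hand_computed_three_level_example(self):
        # ranks chosen so rho = 1 - 6*sum(d^2)/(n(n^2-1)) is easy by hand:
        # A vs B: d^2 sum = 4 -> 0.8 ; A vs C: reversal -> -1 ; B vs C: -0.8
        m = pd.DataFrame({"A": [1.0, 2.0, 3.0, 4.0, 5.0],
                          "B": [2.0, 1.0, 4.0, 3.0, 5.0],
                          "C": [5.0, 4.0, 3.0, 2.0, 1.0]})
        res = pairwise_spearman(m)
        assert res.corr.loc["A", "B"] == pytest.approx(0.8)
        assert res.corr.loc["A", "C"] == pytest.approx(-1.0)
        assert res.corr.loc["B", "C"] == pytest.approx(-0.8)
        assert res.summary["n_pairs"] == 3

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(3)
        m = pd.DataFrame(rng.normal(0, 1, (30, 4)), columns=list("abcd"))
        res1 = pairwise_spearman(m)
        res2 = pairwise_spearman(np.exp(m) * 3 + 1)
        pd.testing.assert_frame_equal(res1.corr, res2.corr)

    def test_single_sample_group_warns_empty_summary(self):
        m = pd.DataFrame({"only": np.arange(5.0)})
        with pytest.warns(UserWarning, match="< 2 samples"):
            res = pairwise_spearman(m)
        assert res.summary == {}


def _patient_matrix(rng, rho_es_noise=2.0):
    """One patient, 3 ET levels nearly identical, 3 ES levels independent."""
    rows = []
    for ct, lv in [("ET", 1), ("ET", 2), ("ET", 3),
                   ("ES", 1), ("ES", 2), ("ES", 3)]:
        rows.append({"sample_id": f"PA_{ct}_L{lv}", "patient": "PA",
                     "collection_type": ct, "level": lv})
    annot = pd.DataFrame(rows)
    base = rng.normal(0, 2, 60)
    cols = {}
    for lv in (1, 2, 3):
        cols[f"PA_ET_L{lv}"] = base + rng.normal(0, 0.05, 60)
        cols[f"PA_ES_L{lv}"] = rng.normal(0, rho_es_noise, 60)
    m = pd.DataFrame(cols, index=[f"P{i}" for i in range(60)])
    return m, annot


class TestPatientDendrogram:
    def test_tight_et_vs_loose_es(self):
        rng = np.random.default_rng(7)
        m, annot = _patient_matrix(rng)
        res = patient_dendrogram(m, annot, "PA", mad_min=0.0)
        assert res is not None
        assert res.more_correlated == "ET"
        assert (res.intra_et > res.intra_es.max()).all()
        # 3v3 values, ET all above ES: exact two-sided p = 2/C(6,3) = 0.1
        assert res.test.statistic == pytest.approx(9.0)
        assert res.test.pvalue == pytest.approx(0.1)

    def test_inclusion_rule_skips_with_none(self):
        rng = np.random.default_rng(8)
        m, annot = _patient_matrix(rng)
        annot2 = annot[annot["sample_id"] != "PA_ES_L3"]
        assert patient_dendrogram(m, annot2, "PA", mad_min=0.0) is None

    def test_direction_flag_over_replicates(self):
        """When ES profiles drift twice as hard as ET, ES is flagged more
        heterogeneous in a clear majority of replicates."""
        wins = 0
        n_rep = 50
        for rep in range(n_rep):
            rng = np.random.default_rng(1000 + rep)
            rows, cols = [], {}
            base_et = rng.normal(0, 2, 40)
            base_es = rng.normal(0, 2, 40)
            for lv in (1, 2, 3, 4):
                rows.append({"sample_id": f"PA_ET_L{lv}", "patient": "PA",
                             "collection_type": "ET", "level": lv})
                rows.append({"sample_id": f"PA_ES_L{lv}", "patient": "PA",
                             "collection_type": "ES", "level": lv})
                cols[f"PA_ET_L{lv}"] = base_et + rng.normal(0, 0.3, 40)
                cols[f"PA_ES_L{lv}"] = base_es + rng.normal(0, 0.6, 40)
            m = pd.DataFrame(cols, index=[f"P{i}" for i in range(40)])
            res = patient_dendrogram(m, pd.DataFrame(rows), "PA", mad_min=0.0)
            if res.more_correlated == "ET":  # ES less internally correlated
                wins += 1
        assert wins >= int(0.75 * n_rep)


class TestSecretedVariance:
    def _setup(self, inflate):
        rng = np.random.default_rng(5)
        rows = []
        for lv in range(1, 6):
            rows.append({"sample_id": f"PA_ET_L{lv}", "patient": "PA",
                         "collection_type": "ET", "level": lv})
        annot = pd.DataFrame(rows)
        n = 200
        flags = pd.Series([i < 50 for i in range(n)],
                          index=[f"P{i:03d}" for i in range(n)])
        sd = np.where(flags.to_numpy(), 0.3 * inflate, 0.3)
        m = pd.DataFrame(rng.normal(0, 1, (n, 5)) * sd[:, None],
                         index=flags.index,
                         columns=annot["sample_id"])
        return m, annot, flags

    def test_inflated_class_detected(self):
        m, annot, flags = self._setup(3.0)
        res = secreted_variance_test(m, annot, flags, "PA", "ET")
        assert res.test.pvalue < 0.01
        assert res.median_mad_secreted > res.median_mad_other

    def test_all_flagged_is_degenerate(self):
        m, annot, flags = self._setup(1.0)
        with pytest.raises(ValueError, match="both"):
            secreted_variance_test(m, annot, pd.Series(True, index=m.index),
                                   "PA", "ET")

    def test_eligible_patients_requires_deep_sampling_in_both_types(self):
        rows = []
        for p, n_et, n_es in [("PA", 5, 4), ("PB", 5, 2), ("PC", 3, 5)]:
            for ct, n in (("ET", n_et), ("ES", n_es)):
                for lv in range(1, n + 1):
                    rows.append({"sample_id": f"{p}_{ct}_L{lv}", "patient": p,
                                 "collection_type": ct, "level": lv})
        assert eligible_patients(pd.DataFrame(rows)) == ["PA"]
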