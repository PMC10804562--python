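import numpy as np
import pandas as pd
import pytest

from lmdhet import (SimConfig, filter_psms, impute_knn, merge_plexes,
                    normalize_medians, psm_ratios, quantify_cohort,
                    rollup_proteins, simulate_cohort)

from oracles import knn_impute_oracle


def _toy_psms(rows):
    base = {"plex_id": "PX", "spectrum_id": "", "peptide": "PEP",
            "protein_accession": "P1", "q_value": 0.005,
            "isolation_interference_pct": 10.0,
            "intensity_126": 100.0, "intensity_127N": 100.0}
    recs = []
    for i, r in enumerate(rows):
        rec = dict(base)
        rec["spectrum_id"] = f"S{i}"
        rec.update(r)
        recs.append(rec)
    return pd.DataFrame(recs)


class TestFilterPsms:
    def test_interference_exactly_at_threshold_is_excluded(self):
        psms = _toy_psms([{"isolation_interference_pct": 50.0}])
        assert len(filter_psms(psms)) == 0

    def test_all_rules_passed_is_retained(self):
        psms = _toy_psms([{"q_value": 0.005, "isolation_interference_pct": 10.0}])
        assert len(filter_psms(psms)) == 1

    def test_five_row_worked_example_retains_exactly_one(self):
        # rules hit: q-value, interference, missing reference, no other signal
        psms = _toy_psms([
            {"q_value": 0.005},
            {"q_value": 0.02},
            {"q_value": 0.005, "isolation_interference_pct": 60.0},
            {"q_value": 0.005, "intensity_126": np.nan},
            {"q_value": 0.005, "intensity_127N": np.nan},
        ])
        out, counts = filter_psms(psms, return_counts=True)
        assert len(out) == 1
        assert out["spectrum_id"].tolist() == ["S0"]
        assert counts == {"input": 5, "fail_q_value": 1,
                          "fail_interference": 1, "fail_reference_signal": 1,
                          "fail_no_other_signal": 1, "retained": 1}

    def test_relaxing_thresholds_never_drops_psms(self):
        rng = np.random.default_rng(0)
        psms = _toy_psms([{"q_value": q, "isolation_interference_pct": i}
                          for q, i in zip(rng.uniform(0, 0.05, 50),
                                          rng.uniform(0, 100, 50))])
        n = [len(filter_psms(psms, q_max=q, interference_max_pct=i))
             for q, i in [(0.005, 25), (0.01, 25), (0.01, 50), (0.02, 75)]]
        assert n == sorted(n)

    def test_unknown_reference_channel_is_an_error(self):
        with pytest.raises(ValueError, match="reference channel"):
            filter_psms(_toy_psms([{}]), reference_channel="135N")


def _design(channels_samples, plex="PX"):
    rows = [{"plex_id": plex, "channel": "126", "sample_id": "POOL",
             "is_reference": True}]
    for ch, s in channels_samples:
        rows.append({"plex_id": plex, "channel": ch, "sample_id": s,
                     "is_reference": False})
    return pd.DataFrame(rows)


class TestPsmRatios:
    def test_doubling_gives_log2_of_two(self):
        psms = _toy_psms([{"intensity_126": 100.0, "intensity_127N": 200.0}])
        out = psm_ratios(psms, _design([("127N", "s1")]))
        assert out["s1"].iloc[0] == pytest.approx(1.0)

    def test_equal_intensities_give_zero(self):
        psms = _toy_psms([{"intensity_126": 100.0, "intensity_127N": 100.0}])
        out = psm_ratios(psms, _design([("127N", "s1")]))
        assert out["s1"].iloc[0] == 0.0

    def test_hand_computed_ratios(self):
        psms = _toy_psms([{"intensity_126": 100.0, "intensity_127N": 25.0,
                           "intensity_127C": 400.0}])
        out = psm_ratios(psms, _design([("127N", "s1"), ("127C", "s2")]))
        assert out["s1"].iloc[0] == pytest.approx(-2.0)
        assert out["s2"].iloc[0] == pytest.approx(2.0)

    def test_zero_reference_is_an_error(self):
        psms = _toy_psms([{"intensity_126": 0.0}])
        with pytest.raises(ValueError, match="reference"):
            psm_ratios(psms, _design([("127N", "s1")]))


class TestRollup:
    def _ratios(self, rows):
        return pd.DataFrame(rows)

    def test_single_psm_protein_absent(self):
        ratios = self._ratios([{"protein_accession": "P1", "s1": 0.5}])
        assert len(rollup_proteins(ratios, min_psms=2)) == 0

    def test_median_of_two(self):
        ratios = self._ratios([{"protein_accession": "P1", "s1": 0.4},
                               {"protein_accession": "P1", "s1": 0.6}])
        assert rollup_proteins(ratios).loc["P1", "s1"] == pytest.approx(0.5)

    def test_median_robust_to_outlier(self):
        ratios = self._ratios([{"protein_accession": "P1", "s1": v}
                               for v in (0.0, 1.0, 10.0)])
        assert rollup_proteins(ratios).loc["P1", "s1"] == pytest.approx(1.0)

    def test_psm_row_order_does_not_matter(self):
        rng = np.random.default_rng(3)
        rows = [{"protein_accession": f"P{i % 5}", "s1": rng.normal(),
                 "s2": rng.normal()} for i in range(40)]
        ratios = pd.DataFrame(rows)
        shuffled = ratios.sample(frac=1.0, random_state=7).reset_index(drop=True)
        pd.testing.assert_frame_equal(rollup_proteins(ratios),
                                      rollup_proteins(shuffled))


class TestNormalize:
    def test_median_shift(self):
        m = pd.DataFrame({"s1": [1.0, 2.0, 3.0]})
        assert normalize_medians(m)["s1"].tolist() == [-1.0, 0.0, 1.0]

    def test_idempotent(self):
        m = pd.DataFrame({"s1": [0.2, 0.2, 5.0, np.nan]})
        once = normalize_medians(m)
        np.testing.assert_allclose(once["s1"].to_numpy()[:3], [0.0, 0.0, 4.8])
        pd.testing.assert_frame_equal(normalize_medians(once), once)

    def test_all_missing_column_names_the_sample(self):
        m = pd.DataFrame({"good": [1.0, 2.0], "bad": [np.nan, np.nan]})
        with pytest.raises(ValueError, match="bad"):
            normalize_medians(m)


class TestMerge:
    def test_disjoint_protein_sets_union(self):
        a = pd.DataFrame(np.zeros((5, 2)), index=[f"A{i}" for i in range(5)],
                         columns=["s1", "s2"])
        b = pd.DataFrame(np.zeros((7, 2)), index=[f"B{i}" for i in range(7)],
                         columns=["s3", "s4"])
        merged = merge_plexes([a, b])
        assert merged.shape == (12, 4)
        assert merged.loc["A0", "s3"] != merged.loc["A0", "s3"]  # NaN
        assert merged.loc["B0", "s1"] != merged.loc["B0", "s1"]

    def test_identical_protein_sets_no_missingness(self):
        a = pd.DataFrame(np.ones((4, 2)), index=list("wxyz"),
                         columns=["s1", "s2"])
        b = pd.DataFrame(np.ones((4, 2)), index=list("wxyz"),
                         columns=["s3", "s4"])
        assert not merge_plexes([a, b]).isna().any().any()

    def test_duplicate_sample_ids_rejected(self):
        a = pd.DataFrame(np.ones((2, 1)), index=["p", "q"], columns=["s1"])
        with pytest.raises(ValueError, match="duplicate"):
            merge_plexes([a, a.copy()])


class TestImputeKnn:
    def test_proteins_below_quant_fraction_dropped(self):
        m = pd.DataFrame({"s1": [1.0, 1.0], "s2": [1.0, np.nan],
                          "s3": [1.0, np.nan], "s4": [1.0, np.nan],
                          "s5": [1.0, 1.0]}, index=["keep", "drop"])
        out = impute_knn(m, k=1, min_quant_frac=0.5)
        assert list(out.matrix.index) == ["keep"]

    def test_exactly_half_observed_is_kept(self):
        m = pd.DataFrame([[1.0, 2.0, np.nan, np.nan],
                          [1.0, 2.0, 3.0, 4.0],
                          [1.1, 2.1, 3.1, 4.1]],
                         index=["half", "full1", "full2"],
                         columns=list("abcd"))
        out = impute_knn(m, k=2, min_quant_frac=0.5)
        assert "half" in out.matrix.index
        assert not out.matrix.isna().any().any()

    def test_identical_neighbor_at_distance_zero(self):
        m = pd.DataFrame([[1.0, 2.0, np.nan],
                          [1.0, 2.0, 7.5],
                          [9.0, 9.0, 0.0]],
                         index=["target", "twin", "far"], columns=list("abc"))
        out = impute_knn(m, k=1)
        assert out.matrix.loc["target", "c"] == pytest.approx(7.5)
        assert out.imputed_mask.loc["target", "c"]
        assert not out.imputed_mask.loc["twin", "c"]

    def test_fully_observed_rows_untouched(self):
        rng = np.random.default_rng(5)
        from conftest import random_missing_matrix
        m = random_missing_matrix(rng, 20, 8, 0.15)
        out = impute_knn(m, k=3)
        full = m.loc[m.notna().all(axis=1)]
        pd.testing.assert_frame_equal(out.matrix.loc[full.index], full)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        from conftest import random_missing_matrix
        m = random_missing_matrix(rng, 15, 8, 0.12)
        expected = knn_impute_oracle(m, k=3)
        out = impute_knn(m, k=3)
        pd.testing.assert_frame_equal(out.matrix, expected)

    def test_k_larger_than_candidates_warns_and_uses_all(self):
        m = pd.DataFrame([[1.0, np.nan], [1.0, 5.0], [2.0, 7.0]],
                         index=["t", "n1", "n2"], columns=["a", "b"])
        with pytest.warns(UserWarning, match="using all"):
            out = impute_knn(m, k=10)
        assert out.matrix.loc["t", "b"] == pytest.approx(6.0)


def test_zero_noise_round_trip_small_cohort():
    """noise_sd=0, no dropout, passing nuisance values: the quantified
    matrix equals the latent log2 ratios after the column-median shift."""
    cfg = SimConfig(n_patients=2, n_proteins=80, noise_sd=0.0,
                    frac_missing_per_plex=0.0, frac_q_fail=0.0,
                    frac_interference_fail=0.0, psm_count_model="fixed",
                    seed=17)
    truth, psms, designs, annot = simulate_cohort(cfg)
    res = quantify_cohort(psms, designs, annotation=annot)
    latent = truth.latent_ratio_matrix()
    expected = latent - latent.median(axis=0)
    diff = (res.matrix - expected[res.matrix.columns].loc[res.matrix.index])
    assert diff.abs().to_numpy().max() < 1e-9
    assert not res.imputed_mask.any().any()
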