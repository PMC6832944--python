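"""Contingency, purity matrices, capture, ACP/AEP/ACEP and agreement."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

import acticlust as ac
from acticlust.evaluation import CategoryMap, ContingencyTable


def _ct(rows):
    arr = np.asarray(rows, dtype=int)
    df = pd.DataFrame(arr,
                      index=[f"c{i}" for i in range(arr.shape[0])],
                      columns=[f"e{j}" for j in range(arr.shape[1])])
    return ContingencyTable(df)


class TestContingency:
    def test_exact_counts(self):
        ct = ac.contingency(["a", "a", "b"], [1, 1, 2])
        assert ct.counts.loc[1, "a"] == 2
        assert ct.counts.loc[2, "b"] == 1
        assert ct.total == 3

    def test_empty_input(self):
        with pytest.raises(ValueError, match="empty"):
            ac.contingency([], [])

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            ac.contingency(["a"], [1, 2])

    @given(st.integers(1, 500), st.integers(0, 10 ** 6))
    @settings(deadline=None, max_examples=30)
    def test_marginals_consistent(self, n, seed):
        rng = np.random.default_rng(seed)
        labels = rng.choice(list("abc"), size=n)
        clusters = rng.integers(0, 4, size=n)
        ct = ac.contingency(labels, clusters)
        assert ct.cluster_totals.sum() == ct.class_totals.sum() == n


class TestPurityMatrix:
    def test_diagonal_gives_hundreds(self):
        pm = ac.purity_matrix(_ct(np.diag([3, 7, 2])))
        np.testing.assert_allclose(np.diag(pm.values.loc[["e0", "e1", "e2"],
                                                         ["c0", "c1", "c2"]]),
                                   100.0)

    def test_single_cluster(self):
        pm = ac.purity_matrix(_ct([[5, 5]]))
        assert (pm.values["c0"] == 100.0).all()
        assert pm.cluster_share["c0"] == 100.0

    def test_rows_sum_to_hundred(self, lab_model, lab_study):
        _, _, fm = lab_study
        model, assignments = lab_model
        letters, _ = ac.apply_letters(model, fm, assignments)
        pm = ac.purity_matrix(ac.contingency(fm["label"], letters))
        np.testing.assert_allclose(pm.values.sum(axis=1), 100.0)
        assert pm.cluster_share.sum() == pytest.approx(100.0)

    def test_zero_class_excluded_with_warning(self):
        ct = _ct([[2, 0], [3, 0]])
        with pytest.warns(UserWarning, match="zero windows"):
            pm = ac.purity_matrix(ct)
        assert list(pm.values.index) == ["e0"]


class TestCategoryCapture:
    def test_reference_development_standing(self):
        pm = ac.load_reference_purity("development")
        cap = ac.category_capture(pm, ac.DEFAULT_CATEGORY_MAP)
        assert cap.loc["standing", "standing_mixed_slow"] == pytest.approx(97.6)

    def test_reference_freeliving_stepping(self):
        pm = ac.load_reference_purity("freeliving")
        cm = CategoryMap({"ambulatory_or_running": ("G", "H", "I", "J")})
        cap = ac.category_capture(pm, cm)
        assert cap.loc["stepping", "ambulatory_or_running"] == pytest.approx(78.2)

    @pytest.mark.parametrize("sample", ["development", "child_lab",
                                        "adult_lab", "freeliving"])
    def test_full_partition_sums_to_hundred(self, sample):
        pm = ac.load_reference_purity(sample)
        cap = ac.category_capture(pm, ac.DEFAULT_CATEGORY_MAP)
        np.testing.assert_allclose(cap.sum(axis=1), 100.0, atol=0.2)

    def test_unknown_cluster_letter(self):
        pm = ac.load_reference_purity("development")
        with pytest.raises(ValueError, match="unknown cluster"):
            ac.category_capture(pm, CategoryMap({"x": ("Z",)}))

    def test_category_map_disjointness_enforced(self):
        with pytest.raises(ValueError, match="more than one"):
            CategoryMap({"a": ("A", "B"), "b": ("B",)})


class TestPurityStatistics:
    def test_diagonal_is_perfect(self):
        ct = _ct(np.diag([4, 6, 2]))
        assert ac.acp(ct) == 1.0
        assert ac.aep(ct) == 1.0
        assert ac.acep(ct) == 1.0

    def test_single_cluster_even_split(self):
        ct = _ct([[5, 5]])
        assert ac.acp(ct) == pytest.approx(0.5)
        assert ac.aep(ct) == pytest.approx(1.0)

    def test_symmetric_mixing(self):
        ct = _ct([[4, 1], [1, 4]])
        assert ac.acp(ct) == pytest.approx(0.68)
        assert ac.aep(ct) == pytest.approx(0.68)
        assert ac.acep(ct) == pytest.approx(0.68 ** 2)
        assert ac.acep(ct, combine="geometric") == pytest.approx(0.68)

    def test_matches_brute_force_oracle(self, rng):
        # weighted-sum-of-squared-shares formulation, independent double loop
        for _ in range(100):
            arr = rng.integers(0, 20, size=(rng.integers(1, 6),
                                            rng.integers(1, 6)))
            if arr.sum() == 0:
                continue
            ct = _ct(arr)
            N = arr.sum()
            acp_ref = sum(
                (arr[i].sum() / N) * sum((arr[i, j] / arr[i].sum()) ** 2
                                         for j in range(arr.shape[1]))
                for i in range(arr.shape[0]) if arr[i].sum() > 0)
            aep_ref = sum(
                (arr[:, j].sum() / N) * sum((arr[i, j] / arr[:, j].sum()) ** 2
                                            for i in range(arr.shape[0]))
                for j in range(arr.shape[1]) if arr[:, j].sum() > 0)
            assert ac.acp(ct) == pytest.approx(acp_ref, abs=1e-12)
            assert ac.aep(ct) == pytest.approx(aep_ref, abs=1e-12)

    @given(arrays(np.int64, (3, 4), elements=st.integers(0, 50)),
           st.integers(1, 7))
    @settings(deadline=None, max_examples=50)
    def test_invariance_to_relabeling_and_scaling(self, arr, scale):
        if arr.sum() == 0:
            return
        ct = _ct(arr)
        perm_rows = _ct(arr[::-1])
        scaled = _ct(arr * scale)
        assert ac.acp(perm_rows) == pytest.approx(ac.acp(ct), abs=1e-12)
        assert ac.aep(perm_rows) == pytest.approx(ac.aep(ct), abs=1e-12)
        assert ac.acp(scaled) == pytest.approx(ac.acp(ct), abs=1e-12)
        assert ac.aep(scaled) == pytest.approx(ac.aep(ct), abs=1e-12)
        assert 0.0 < ac.acp(ct) <= 1.0
        assert 0.0 < ac.aep(ct) <= 1.0


class TestDailyMinutes:
    def test_full_day_in_one_cluster(self):
        minutes, _ = ac.daily_minutes(["A"] * 8640, ac.DEFAULT_CATEGORY_MAP,
                                      window_seconds=10)
        assert minutes["sedentary"] == pytest.approx(1440.0)
        assert minutes["running"] == 0.0

    def test_percent_sums_to_hundred(self, rng):
        clusters = rng.choice(list("ABCDEFGHIJ"), size=500)
        _, percent = ac.daily_minutes(clusters, ac.DEFAULT_CATEGORY_MAP)
        assert percent.sum() == pytest.approx(100.0)


class TestBlandAltman:
    def test_identical_vectors(self):
        ba = ac.bland_altman([10.0, 20.0, 30.0], [10.0, 20.0, 30.0])
        assert ba.bias == 0.0
        assert ba.loa_half_width == 0.0

    def test_needs_pairs(self):
        with pytest.raises(ValueError):
            ac.bland_altman([1.0], [2.0])

    def test_known_offset_and_noise(self, rng):
        delta, sigma, n = 5.0, 3.0, 20000
        c = rng.uniform(500, 1500, size=n)
        m = c + delta + rng.normal(0, sigma, size=n)
        ba = ac.bland_altman(m, c)
        assert ba.bias == pytest.approx(delta, abs=0.1)
        assert ba.loa_half_width == pytest.approx(1.96 * sigma, rel=0.02)

    def test_report_bias_identity(self, rng):
        m, c = rng.normal(1000, 50, 8), rng.normal(1100, 50, 8)
        rep = ac.agreement_report({"sedentary": (m, c)})
        assert rep.loc["sedentary", "bias"] == pytest.approx(
            rep.loc["sedentary", "model_mean"] - rep.loc["sedentary", "criterion_mean"])


class TestFeatureProfile:
    def test_single_cluster_equals_column_means(self, rng):
        fm = pd.DataFrame(rng.normal(size=(30, 3)), columns=list("abc"))
        prof = ac.feature_profile(fm, [0] * 30)
        np.testing.assert_allclose(prof.loc[0], fm.mean())

    def test_training_profile_equals_centroids(self, lab_model, lab_study):
        # centroid = member mean, so the normalized training profile must
        # reproduce the stored centroids exactly
        _, _, fm = lab_study
        model, assignments = lab_model
        fm_norm = model.normalizer().transform(fm)
        prof = ac.feature_profile(fm_norm, assignments)
        np.testing.assert_allclose(prof.to_numpy(),
                                   np.asarray(model.centroids)[prof.index],
                                   atol=1e-9)

    def test_static_posture_clusters_have_near_zero_z_sd(self, lab_model,
                                                         lab_study):
        _, _, fm = lab_study
        model, assignments = lab_model
        prof = ac.feature_profile(fm, assignments, ["acc_z_sd"])
        dominant = (pd.DataFrame({"label": fm["label"], "cluster": assignments})
                    .groupby("cluster")["label"]
                    .agg(lambda s: s.mode().iloc[0]))
        static = dominant[dominant.isin(["lying", "seated", "standing"])].index
        ambulatory = dominant[dominant.isin(
            ["brisk_walking", "running"])].index
        assert prof.loc[static, "acc_z_sd"].max() < 0.05
        assert prof.loc[static, "acc_z_sd"].max() < \
            prof.loc[ambulatory, "acc_z_sd"].min()
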