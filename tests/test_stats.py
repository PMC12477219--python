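"""PCA, IQR fence, differential abundance, overlaps, uptake statistics."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from evuptake import stats
from evuptake.containers import OmicsMatrix


def _matrix(arr, design=None):
    arr = np.asarray(arr, dtype=float)
    cols = pd.Index([f"F{j}" for j in range(arr.shape[1])])
    values = pd.DataFrame(arr, columns=cols,
                          index=[f"S{i}" for i in range(arr.shape[0])])
    return OmicsMatrix(
        values=values,
        feature_kind=pd.Series("lipid", index=cols),
        center=pd.Series(0.0, index=cols),
        scale=pd.Series(1.0, index=cols),
        design=design,
    )


class TestPCA:
    def test_variance_fractions_sum_to_one(self, rng):
        res = stats.pca(_matrix(rng.normal(size=(8, 5))))
        assert res.variance_fractions.sum() == pytest.approx(1.0)

    def test_rank_one_matrix_single_component(self, rng):
        t = rng.normal(size=6)
        res = stats.pca(_matrix(np.outer(t, rng.normal(size=4))))
        assert res.variance_fractions[0] == pytest.approx(1.0)

    def test_fractions_match_covariance_eigenvalues(self):
        arr = np.array([[1.0, 2.0, 0.5], [2.0, 1.0, 1.5],
                        [0.0, 4.0, -1.0], [3.0, 3.0, 2.0]])
        res = stats.pca(_matrix(arr))
        eig = np.sort(np.linalg.eigvalsh(np.cov(arr.T)))[::-1]
        np.testing.assert_allclose(res.variance_fractions[:3],
                                   eig / eig.sum(), atol=1e-10)

    def test_scores_loadings_reconstruct_centered_matrix(self, rng):
        arr = rng.normal(size=(6, 10))
        res = stats.pca(_matrix(arr))
        recon = res.scores.to_numpy() @ res.loadings.to_numpy().T
        np.testing.assert_allclose(recon, arr - arr.mean(axis=0), atol=1e-8)

    def test_scores_carry_design_labels(self, rng):
        design = pd.DataFrame(
            {"cell_type": ["CPC", "MSC", "CEC"], "oxygen": ["normoxic"] * 3,
             "replicate": [1, 1, 1]},
            index=["S0", "S1", "S2"],
        )
        res = stats.pca(_matrix(rng.normal(size=(3, 4)), design=design))
        assert list(res.scores["cell_type"]) == ["CPC", "MSC", "CEC"]


class TestIQRFence:
    def test_symmetric_clean_data_untouched(self):
        vals = np.array([8.0, 9.0, 10.0, 11.0, 12.0])
        np.testing.assert_array_equal(stats.iqr_outlier_removal(vals), vals)

    def test_fence_matches_direct_computation(self):
        vals = np.array([8.0, 9.0, 10.0, 11.0, 12.0, 100.0])
        q1, q3 = np.percentile(vals, [25, 75])
        lo = vals.mean() - 1.5 * (q3 - q1)
        hi = vals.mean() + 1.5 * (q3 - q1)
        expected = vals[(vals >= lo) & (vals <= hi)]
        np.testing.assert_array_equal(stats.iqr_outlier_removal(vals),
                                      expected)

    def test_constant_group_untouched(self):
        vals = np.full(4, 7.0)
        np.testing.assert_array_equal(stats.iqr_outlier_removal(vals), vals)

    def test_single_point_rejected(self):
        with pytest.raises(ValueError, match="size"):
            stats.iqr_outlier_removal(np.array([1.0]))


class TestDifferentialAbundance:
    def _frame(self, groups):
        rows = {}
        for feat, (a, b) in groups.items():
            rows[feat] = list(a) + list(b)
        frame = pd.DataFrame(rows)
        n1 = len(next(iter(groups.values()))[0])
        frame.index = [f"A{i}" for i in range(n1)] + [
            f"B{i}" for i in range(len(frame) - n1)]
        return frame, [f"A{i}" for i in range(n1)], \
            [f"B{i}" for i in range(len(frame) - n1)]

    def test_identical_groups_null_result(self):
        frame, g1, g2 = self._frame({"F1": ([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])})
        res = stats.differential_abundance(frame, g1, g2)
        assert res.loc["F1", "fold_change"] == pytest.approx(1.0)
        assert res.loc["F1", "p"] == pytest.approx(1.0)

    def test_matches_welch_oracle(self):
        a, b = [1.0, 1.1, 0.9], [2.0, 2.1, 1.9]
        frame, g1, g2 = self._frame({"F1": (a, b)})
        res = stats.differential_abundance(frame, g1, g2)
        t_exp, p_exp = sps.ttest_ind(a, b, equal_var=False)
        assert res.loc["F1", "t"] == pytest.approx(t_exp)
        assert res.loc["F1", "p"] == pytest.approx(p_exp)
        assert res.loc["F1", "log10_fc"] == pytest.approx(-1.0)

    def test_student_variant_behind_flag(self):
        a, b = [1.0, 1.4, 0.8], [2.0, 2.3, 1.7]
        frame, g1, g2 = self._frame({"F1": (a, b)})
        res = stats.differential_abundance(frame, g1, g2, equal_var=True)
        t_exp, p_exp = sps.ttest_ind(a, b, equal_var=True)
        assert res.loc["F1", "t"] == pytest.approx(t_exp)
        assert res.loc["F1", "p"] == pytest.approx(p_exp)

    def test_fold_change_exactly_two_fails_strict_screen(self):
        # log10 difference of exactly log10(2): fold change == 2
        d = np.log10(2.0)
        frame, g1, g2 = self._frame(
            {"F1": ([d, d, d], [0.0, 0.0, 0.0])})
        res = stats.differential_abundance(frame, g1, g2)
        assert res.loc["F1", "fold_change"] == pytest.approx(2.0)
        assert not res.loc["F1", "passes_2fold"]

    def test_group_swap_inverts_fold_change(self, rng):
        frame, g1, g2 = self._frame({
            f"F{i}": (rng.normal(3, 0.2, 4), rng.normal(3.5, 0.2, 4))
            for i in range(5)
        })
        fwd = stats.differential_abundance(frame, g1, g2)
        rev = stats.differential_abundance(frame, g2, g1)
        np.testing.assert_allclose(fwd["fold_change"],
                                   1.0 / rev["fold_change"])
        np.testing.assert_allclose(fwd["p"], rev["p"])

    def test_outlier_removal_feeds_the_test(self):
        # group A carries points the fence removes; the t-test must run on
        # the fenced values
        a = [1.0, 1.1, 0.9, 1.05, 1.5]
        b = [2.0, 2.1, 1.9, 2.05, 1.95]
        frame, g1, g2 = self._frame({"F1": (a, b)})
        res = stats.differential_abundance(frame, g1, g2)
        kept = stats.iqr_outlier_removal(np.array(a))
        assert 2 <= len(kept) < len(a)
        assert res.loc["F1", "n1"] == len(kept)
        t_exp, _ = sps.ttest_ind(kept, np.array(b), equal_var=False)
        assert res.loc["F1", "t"] == pytest.approx(t_exp)

    def test_pathological_fence_skips_feature_with_reason(self):
        # a far outlier drags the mean outside the bulk while the IQR stays
        # tiny: the literal mean-based fence then removes every point and
        # the feature is skipped, not silently tested
        a = [1.0, 1.1, 0.9, 1.05, 50.0]
        b = [2.0, 2.1, 1.9, 2.05, 1.95]
        assert len(stats.iqr_outlier_removal(np.array(a))) == 0
        frame, g1, g2 = self._frame({"F1": (a, b)})
        res = stats.differential_abundance(frame, g1, g2)
        assert np.isnan(res.loc["F1", "p"])
        assert res.loc["F1", "note"] == "degenerate group after outlier removal"

    def test_overlapping_groups_rejected(self):
        frame, g1, g2 = self._frame({"F1": ([1.0, 2.0], [3.0, 4.0])})
        with pytest.raises(ValueError, match="overlap"):
            stats.differential_abundance(frame, g1, g1)

    def test_bh_adjustment_flag(self, rng):
        frame, g1, g2 = self._frame({
            f"F{i}": (rng.normal(3, 0.2, 4), rng.normal(3.2, 0.2, 4))
            for i in range(10)
        })
        res = stats.differential_abundance(frame, g1, g2, fdr=True)
        assert "p_adj" in res.columns
        assert (res["p_adj"] >= res["p"] - 1e-12).all()


class TestPresenceOverlap:
    def test_identical_sets_all_central(self):
        sets = {ct: {"a", "b", "c"} for ct in ["CPC", "MSC", "CEC", "CF"]}
        regions = stats.presence_overlap(sets)
        assert regions == {("CEC", "CF", "CPC", "MSC"): 3}

    def test_disjoint_sets_only_unique_regions(self):
        sets = {"CPC": {"a"}, "MSC": {"b"}, "CEC": {"c"}, "CF": {"d"}}
        regions = stats.presence_overlap(sets)
        assert regions == {("CPC",): 1, ("MSC",): 1, ("CEC",): 1, ("CF",): 1}

    def test_matches_brute_force_enumeration(self, rng):
        universe = [f"x{i}" for i in range(120)]
        sets = {name: set(rng.choice(universe, size=50, replace=False))
                for name in ["CPC", "MSC", "CEC", "CF"]}
        regions = stats.presence_overlap(sets)
        names = sorted(sets)
        for r in range(1, 5):
            for members in itertools.combinations(names, r):
                inside = set.intersection(*(sets[m] for m in members))
                outside = set.union(
                    *(sets[m] for m in names if m not in members), set()
                ) if len(members) < 4 else set()
                expected = len(inside - outside)
                assert regions.get(members, 0) == expected
        assert sum(regions.values()) == len(set.union(*sets.values()))

    def test_detected_sets_use_any_presence(self):
        values = pd.DataFrame(
            {"S1": [1.0, np.nan], "S2": [np.nan, np.nan],
             "S3": [np.nan, 2.0]},
            index=["F1", "F2"],
        )
        groups = pd.Series(["CPC", "CPC", "MSC"],
                           index=["S1", "S2", "S3"])
        sets = stats.detected_feature_sets(values, groups)
        assert sets == {"CPC": {"F1"}, "MSC": {"F2"}}


class TestUptake:
    def test_normalization_identity_and_above_one(self):
        raw = pd.DataFrame({"clathrin_CEC": [10.0, 12.0]}, index=["a", "b"])
        control = pd.Series([10.0, 10.0], index=["a", "b"])
        out = stats.normalize_uptake(raw, control)
        assert out.loc["a", "clathrin_CEC"] == 1.0
        assert out.loc["b", "clathrin_CEC"] == pytest.approx(1.2)

    def test_zero_control_rejected(self):
        raw = pd.DataFrame({"clathrin_CEC": [10.0]}, index=["a"])
        with pytest.raises(ValueError, match="control"):
            stats.normalize_uptake(raw, pd.Series([0.0], index=["a"]))

    def test_correlation_limits_and_oracle(self):
        v = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        assert stats.condition_correlation(v, v) == pytest.approx(1.0)
        assert stats.condition_correlation(v, 2 * v.mean() - v) == \
            pytest.approx(-1.0)
        w = np.array([2.0, 1.0, 4.0, 3.0, 6.0])
        expected = np.cov(v, w, ddof=1)[0, 1] / (v.std(ddof=1) * w.std(ddof=1))
        assert stats.condition_correlation(v, w) == pytest.approx(expected)

    def test_short_vectors_rejected(self):
        with pytest.raises(ValueError, match="n >= 3"):
            stats.condition_correlation([1.0, 2.0], [3.0, 4.0])


def test_cluster_samples_groups_by_structure(rng):
    blocks = []
    for shift in (0.0, 5.0, 10.0, 15.0):
        blocks.append(rng.normal(shift, 0.1, size=(3, 6)))
    labels = stats.cluster_samples(_matrix(np.vstack(blocks)), n_clusters=4)
    for b in range(4):
        assert labels.iloc[3 * b:3 * b + 3].nunique() == 1
    assert labels.nunique() == 4
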