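"""Kruskal-Wallis, Dunn pairwise comparisons, difference counts and box summaries."""

import numpy as np
import pytest
from scipy import stats as sps

from toiseg import (
    box_stats,
    compare_groups,
    compare_subjects,
    difference_counts,
    kruskal_wallis,
    pairwise_multicompare,
)
from toiseg.stats import dunn_pvalues


class TestKruskalWallis:
    def test_hand_ranked_example(self):
        # {1,2,3} vs {4,5,6}: ranks 1..6, H = 27/7, p = chi2(1) tail
        h, p = kruskal_wallis([np.array([1, 2, 3]), np.array([4, 5, 6])])
        assert h == pytest.approx(27 / 7, rel=1e-9)
        assert p == pytest.approx(sps.chi2.sf(27 / 7, 1), rel=1e-9)
        assert p == pytest.approx(0.0495, abs=5e-4)

    def test_identical_multisets_h_zero(self):
        h, p = kruskal_wallis([np.array([1, 3, 5]), np.array([1, 3, 5])])
        assert h == pytest.approx(0.0, abs=1e-12)

    def test_all_values_identical_degenerate(self):
        h, p = kruskal_wallis([np.ones(4), np.ones(5)])
        assert (h, p) == (0.0, 1.0)

    def test_type_i_error_calibration(self):
        """4 null groups, 2000 reps: rejection rate ~ 0.05 (+-0.01)."""
        rng = np.random.default_rng(2024)
        rejects = 0
        reps = 2000
        for _ in range(reps):
            groups = [rng.uniform(size=25) for _ in range(4)]
            _, p = kruskal_wallis(groups)
            rejects += p < 0.05
        assert abs(rejects / reps - 0.05) <= 0.01

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(1)
        groups = [rng.normal(size=7), rng.normal(1, 1, size=9), rng.normal(size=5)]
        h1, p1 = kruskal_wallis(groups)
        h2, p2 = kruskal_wallis([np.exp(g) for g in groups])
        assert h1 == pytest.approx(h2, rel=1e-12)
        s1 = pairwise_multicompare(groups, alpha=0.2)
        s2 = pairwise_multicompare([np.exp(g) for g in groups], alpha=0.2)
        assert np.array_equal(s1, s2)


class TestDunn:
    def test_closed_form_two_groups(self):
        # mean ranks 2 and 5; z = 3 / sqrt((6*7/12)*(2/3))
        z, p = dunn_pvalues([np.array([1.0, 2, 3]), np.array([4.0, 5, 6])])
        z_expect = 3.0 / np.sqrt(3.5 * (2 / 3))
        assert z[0, 1] == pytest.approx(z_expect, rel=1e-12)
        assert p[0, 1] == pytest.approx(2 * sps.norm.sf(z_expect), rel=1e-12)

    def test_closed_form_three_groups_holm(self):
        groups = [np.array([1.0, 2]), np.array([3.0, 4]), np.array([5.0, 6])]
        z, p = dunn_pvalues(groups)
        assert z[0, 2] == pytest.approx(4.0 / np.sqrt(3.5), rel=1e-12)
        # raw p(1,3) ~ 0.0325; Holm multiplies by 3 -> not significant at 0.05
        assert not pairwise_multicompare(groups, alpha=0.05).any()
        sig = pairwise_multicompare(groups, alpha=0.12)
        assert sig[0, 2] and sig[2, 0] and not sig[0, 1]

    def test_tie_correction_enters(self):
        a = [np.array([1.0, 1, 2]), np.array([2.0, 3, 3])]
        z_t, _ = dunn_pvalues(a)
        b = [np.array([1.0, 1.5, 2]), np.array([2.5, 3.0, 3.5])]
        z_u, _ = dunn_pvalues(b)
        assert z_t[0, 1] != pytest.approx(z_u[0, 1])

    def test_symmetry_and_identical_groups(self):
        rng = np.random.default_rng(3)
        groups = [rng.normal(size=6) for _ in range(4)]
        sig = pairwise_multicompare(groups, alpha=0.5)
        assert np.array_equal(sig, sig.T)
        assert not sig.diagonal().any()
        same = [np.array([1.0, 3, 5])] * 4
        assert not pairwise_multicompare(same).any()

    def test_shifted_group_detected(self):
        rng = np.random.default_rng(4)
        groups = [rng.normal(0, 1, 30) for _ in range(8)]
        groups[3] = groups[3] + 50.0
        sig = pairwise_multicompare(groups, alpha=0.05)
        assert sig[3].sum() == 7  # the shifted group differs from every other
        off = np.delete(np.delete(sig, 3, 0), 3, 1)
        assert not off.any()

    def test_bonferroni_no_less_conservative_than_holm(self):
        rng = np.random.default_rng(5)
        groups = [rng.normal(i * 0.5, 1, 12) for i in range(5)]
        holm = pairwise_multicompare(groups, alpha=0.05, method="dunn-holm")
        bonf = pairwise_multicompare(groups, alpha=0.05, method="dunn-bonferroni")
        assert not (bonf & ~holm).any()


class TestDifferenceCounts:
    def test_publication_format(self):
        # one subject significantly different from all 32 others (15 same-group,
        # 17 other-group) must print "32: 15 WT and 17 LNAME"
        n = 33
        sig = np.zeros((n, n), dtype=bool)
        sig[8, :] = True
        sig[:, 8] = True
        sig[8, 8] = False
        labels = ["control"] * 16 + ["experimental"] * 17
        counts = difference_counts(sig, labels)
        assert counts[8]["formatted"] == "32: 15 WT and 17 LNAME"
        assert counts[8]["total"] == 32

    def test_all_false_matrix(self):
        counts = difference_counts(np.zeros((5, 5), dtype=bool), ["control"] * 5)
        assert all(c["total"] == 0 for c in counts)

    def test_total_conservation(self):
        rng = np.random.default_rng(6)
        n = 20
        sig = rng.random((n, n)) < 0.3
        sig = np.triu(sig, 1)
        sig = sig | sig.T
        labels = ["control" if i < 9 else "experimental" for i in range(n)]
        for c in difference_counts(sig, labels):
            assert c["total"] == c["vs_control"] + c["vs_experimental"]


class TestBoxStats:
    def test_seven_point_example(self):
        b = box_stats([1, 2, 3, 4, 5, 6, 7])
        assert b["median"] == 4 and b["q1"] == 2 and b["q3"] == 6
        assert b["outliers"] == []

    def test_constant_series(self):
        b = box_stats([5.0] * 10)
        assert b["q3"] - b["q1"] == 0 and b["outliers"] == []

    def test_far_point_flagged_outlier(self):
        b = box_stats([1, 2, 3, 4, 5, 6, 7, 100])
        assert b["outliers"] == [100]
        assert b["whisker_high"] <= 7


class TestComparisonReports:
    def test_subject_report_coherent(self):
        rng = np.random.default_rng(7)
        samples = [rng.normal(0, 1, 40) for _ in range(6)]
        samples[0] += 10.0
        rep = compare_subjects(samples, ["control"] * 3 + ["experimental"] * 3)
        assert rep.kw_p < 0.001
        assert rep.counts[0]["total"] == 5
        assert len(rep.box) == 6

    def test_group_pooling_modes(self):
        rng = np.random.default_rng(8)
        samples = [rng.normal(0, 1, 30) for _ in range(8)]
        keys = ["a", "a", "b", "b", "c", "c", "d", "d"]
        pooled = compare_groups(samples, keys, pooling="pool")
        med = compare_groups(samples, keys, pooling="subject-median")
        assert pooled.labels == ["a", "b", "c", "d"]
        assert len(med.box) == 4
        with pytest.raises(ValueError):
            compare_groups(samples, keys, pooling="nope")
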