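"""Nearest-rank classification, abnormality calls, and discordance tables."""

from __future__ import annotations

import numpy as np
import pytest

from normatlas import (
    DiscordanceCategory,
    LabelVolume,
    MaskedVolume,
    VolumeGrid,
    assign_rank,
    build_atlas,
    classify_subject,
    discordance,
    summarize_discordance,
)


class TestAssignRank:
    def test_nearest_by_inspection(self):
        rv = np.array([0.1, 0.3, 0.5, 0.7, 0.9])
        assert assign_rank(0.52, rv) == 3  # nearest to 0.5 (rank 3 of 5)

    def test_exact_midpoint_breaks_to_lower_rank(self):
        rv = np.array([0.1, 0.3, 0.5, 0.7, 0.9])
        assert assign_rank(0.6, rv) == 3  # midway 0.5/0.7 -> lower rank

    def test_below_all_ranks_assigns_lowest(self):
        rv = np.array([0.1, 0.3, 0.5, 0.7, 0.9])
        assert assign_rank(-5.0, rv) == 1

    def test_above_all_ranks_assigns_highest(self):
        rv = np.array([0.1, 0.3, 0.5, 0.7, 0.9])
        assert assign_rank(2.0, rv) == 5

    def test_decreasing_rank_values_rejected(self):
        with pytest.raises(ValueError):
            assign_rank(0.5, np.array([0.9, 0.1]))


def _cohort_and_atlases(flat_cohort_factory, n=98, n_vox=150, seed=31):
    rng = np.random.default_rng(seed)
    data = rng.beta(2, 6, size=(n, n_vox))
    cohort = flat_cohort_factory(data)
    par = build_atlas(cohort, "parametric")
    nonpar = build_atlas(cohort, "nonparametric")
    return cohort, par, nonpar


class TestClassifySubject:
    def test_median_volume_classifies_as_median_rank(self, flat_cohort_factory):
        cohort, _, atlas = _cohort_and_atlases(flat_cohort_factory)
        median_subject = MaskedVolume(cohort.grid, cohort.mask, atlas.rank_values(50.0))
        cls = classify_subject(median_subject, atlas, "median")
        assert np.all(cls.assigned_rank == 3)
        assert cls.n_abnormal == 0

    def test_value_at_lower_limit_is_normal(self, flat_cohort_factory):
        """Strict inequality: a subject exactly at the 2.5th limit is normal."""
        cohort, _, atlas = _cohort_and_atlases(flat_cohort_factory)
        subject = MaskedVolume(cohort.grid, cohort.mask, atlas.lower_limit.copy())
        cls = classify_subject(subject, atlas, "edge")
        assert cls.n_abnormal == 0

    def test_self_classification_abnormal_fraction_bound(self, flat_cohort_factory):
        """Cohort members vs their own nonparametric atlas: per-voxel
        abnormal fraction <= 2/n (only x_1, x_2 fall strictly below x_3)."""
        cohort, _, nonpar = _cohort_and_atlases(flat_cohort_factory)
        n = cohort.n_subjects
        abnormal_counts = np.zeros(cohort.n_voxels)
        for i in range(n):
            cls = classify_subject(cohort.subject(i), nonpar, f"s{i}")
            abnormal_counts += cls.abnormal
        assert np.all(abnormal_counts / n <= 2.0 / n + 1e-12)

    def test_monotone_sensitivity(self, flat_cohort_factory):
        """Lowering a voxel value never flips abnormal -> normal."""
        cohort, par, nonpar = _cohort_and_atlases(flat_cohort_factory, n=40)
        subject = cohort.subject(0)
        for atlas in (par, nonpar):
            base = classify_subject(subject, atlas, "s").abnormal
            lowered = MaskedVolume(cohort.grid, cohort.mask, subject.values - 0.05)
            after = classify_subject(lowered, atlas, "s").abnormal
            assert np.all(after >= base)

    def test_negative_parametric_limit_shields_proportions(self, flat_cohort_factory):
        """Where the parametric 2.5th limit is negative, no [0,1]-valued
        subject can ever be parametric-abnormal — the discordance mechanism."""
        cohort, par, _ = _cohort_and_atlases(flat_cohort_factory)
        neg = par.lower_limit < 0
        assert neg.any()
        worst = MaskedVolume(cohort.grid, cohort.mask, np.zeros(cohort.n_voxels))
        cls = classify_subject(worst, par, "zeros")
        assert not cls.abnormal[neg].any()

    def test_grid_mismatch_rejected(self, flat_cohort_factory):
        cohort, par, _ = _cohort_and_atlases(flat_cohort_factory, n=10, n_vox=8)
        other_grid = VolumeGrid((8, 1, 1), np.diag([3.0, 1, 1, 1]))
        subject = MaskedVolume(other_grid, np.ones((8, 1, 1), bool), np.zeros(8))
        with pytest.raises(Exception, match="[Gg]rid"):
            classify_subject(subject, par, "bad")


class TestDiscordance:
    def test_identical_classifications_all_concordant(self, flat_cohort_factory):
        cohort, par, nonpar = _cohort_and_atlases(flat_cohort_factory, n=30)
        subject = cohort.subject(1)
        c_p = classify_subject(subject, par, "s1")
        c_np = classify_subject(subject, nonpar, "s1")
        # force agreement by reusing the same abnormality vector
        c_np.abnormal = c_p.abnormal.copy()
        cat = discordance(c_p, c_np)
        assert set(np.unique(cat)) <= {
            int(DiscordanceCategory.CONCORDANT_NORMAL),
            int(DiscordanceCategory.CONCORDANT_ABNORMAL),
        }

    def test_categories_partition_the_mask(self, flat_cohort_factory):
        cohort, par, nonpar = _cohort_and_atlases(flat_cohort_factory)
        subject = MaskedVolume(cohort.grid, cohort.mask,
                               np.maximum(cohort.subject(0).values - 0.1, 0.0))
        c_p = classify_subject(subject, par, "s")
        c_np = classify_subject(subject, nonpar, "s")
        cat = discordance(c_p, c_np)
        counts = [int(np.sum(cat == c)) for c in DiscordanceCategory]
        assert sum(counts) == cohort.n_voxels

    def test_known_discordant_voxel_counts(self, flat_cohort_factory):
        cohort, par, nonpar = _cohort_and_atlases(flat_cohort_factory, n=20, n_vox=10)
        subject = cohort.subject(0)
        c_p = classify_subject(subject, par, "s")
        c_np = classify_subject(subject, nonpar, "s")
        c_p.abnormal = np.zeros(10, bool)
        c_np.abnormal = np.zeros(10, bool)
        c_np.abnormal[:3] = True  # P-normal everywhere, NP-abnormal at 3 voxels
        cat = discordance(c_p, c_np)
        assert int(np.sum(cat == DiscordanceCategory.NORMAL_P_ABNORMAL_NP)) == 3
        assert int(np.sum(cat == DiscordanceCategory.ABNORMAL_P_NORMAL_NP)) == 0

    def test_mismatched_subjects_rejected(self, flat_cohort_factory):
        cohort, par, nonpar = _cohort_and_atlases(flat_cohort_factory, n=10, n_vox=8)
        c_p = classify_subject(cohort.subject(0), par, "a")
        c_np = classify_subject(cohort.subject(1), nonpar, "b")
        with pytest.raises(ValueError, match="subject"):
            discordance(c_p, c_np)

    def test_wrong_method_order_rejected(self, flat_cohort_factory):
        cohort, par, nonpar = _cohort_and_atlases(flat_cohort_factory, n=10, n_vox=8)
        c_p = classify_subject(cohort.subject(0), par, "a")
        c_np = classify_subject(cohort.subject(0), nonpar, "a")
        with pytest.raises(ValueError, match="parametric"):
            discordance(c_np, c_p)


def _toy_categories(n_vox=20):
    cat = np.full(n_vox, int(DiscordanceCategory.CONCORDANT_NORMAL), dtype=np.int8)
    # NP-abnormal at 4 voxels, one of which is P-normal
    cat[0] = DiscordanceCategory.NORMAL_P_ABNORMAL_NP
    cat[1:4] = DiscordanceCategory.CONCORDANT_ABNORMAL
    return cat


class TestSummarizeDiscordance:
    def test_toy_percentages(self):
        cat = _toy_categories()
        report = summarize_discordance([cat], ["s0"])
        row = report.per_subject.loc["s0"]
        assert row["pct_normalP_abnormalNP"] == pytest.approx(25.0)  # 1 of 4
        assert row["pct_abnormalP_normalNP"] == pytest.approx(0.0)

    def test_all_discordance_in_one_region(self):
        grid = VolumeGrid((20, 1, 1), np.eye(4))
        mask = np.ones((20, 1, 1), bool)
        labels = np.ones((20, 1, 1), dtype=np.int32) * 2
        labels[10:] = 1
        lv = LabelVolume(grid, labels, {1: "frontal", 2: "temporal"})
        cat = np.full(20, int(DiscordanceCategory.CONCORDANT_NORMAL), dtype=np.int8)
        cat[:5] = DiscordanceCategory.NORMAL_P_ABNORMAL_NP  # all in temporal
        report = summarize_discordance([cat], ["s0"], labels=lv, mask=mask)
        assert report.per_region.loc["normalP_abnormalNP", "temporal"] == pytest.approx(1.0)
        assert report.per_region.loc["normalP_abnormalNP", "frontal"] == pytest.approx(0.0)

    def test_regional_proportions_sum_to_one(self):
        rng = np.random.default_rng(5)
        grid = VolumeGrid((50, 1, 1), np.eye(4))
        mask = np.ones((50, 1, 1), bool)
        labels = rng.integers(1, 5, size=(50, 1, 1)).astype(np.int32)
        lv = LabelVolume(grid, labels, {1: "f", 2: "t", 3: "p", 4: "o"})
        cats = [rng.integers(0, 4, size=50).astype(np.int8) for _ in range(3)]
        report = summarize_discordance(cats, ["a", "b", "c"], labels=lv, mask=mask)
        for name in ("normalP_abnormalNP", "abnormalP_normalNP"):
            assert report.per_region.loc[name].sum() == pytest.approx(1.0)

    def test_zero_denominator_subjects_excluded_from_summary(self):
        all_normal = np.zeros(20, dtype=np.int8)
        report = summarize_discordance([_toy_categories(), all_normal], ["s0", "s1"])
        assert np.isnan(report.per_subject.loc["s1", "pct_normalP_abnormalNP"])
        assert report.n_excluded["pct_normalP_abnormalNP"] == 1
        assert report.summary.loc["pct_normalP_abnormalNP", "n_subjects"] == 1
        assert report.summary.loc["pct_normalP_abnormalNP", "median"] == pytest.approx(25.0)

    def test_cohort_median_and_iqr(self):
        cats = []
        for k in (1, 2, 3):  # pct = 25k%
            cat = np.zeros(20, dtype=np.int8)
            cat[:k] = DiscordanceCategory.NORMAL_P_ABNORMAL_NP
            cat[k:4] = DiscordanceCategory.CONCORDANT_ABNORMAL
            cats.append(cat)
        report = summarize_discordance(cats, ["a", "b", "c"])
        assert report.summary.loc["pct_normalP_abnormalNP", "median"] == pytest.approx(50.0)
        assert report.summary.loc["pct_normalP_abnormalNP", "iqr"] == pytest.approx(25.0)
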