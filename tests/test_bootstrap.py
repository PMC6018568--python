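"""Resampling study: index draws, record stats, summaries, deciles, power."""

import numpy as np
import pandas as pd
import pytest

from lesionboot import (
    classify_against_interval,
    credible_interval_r2,
    critical_r2,
    draw_bootstrap_indices,
    partial_correlation,
    record_indices,
    roi_power_summary,
    run_resampling_study,
    select_decile_resamples,
    summarize_by_significance,
)
from lesionboot.config import COVARIATE_COLUMNS

from conftest import STUDY_SEED


class TestIndexDraws:
    def test_full_size_without_replacement_is_permutation(self):
        rng = np.random.default_rng(0)
        idx = draw_bootstrap_indices(50, 50, False, rng)
        assert sorted(idx) == list(range(50))

    def test_oversized_subset_rejected(self):
        rng = np.random.default_rng(1)
        with pytest.raises(ValueError, match="without replacement"):
            draw_bootstrap_indices(30, 31, False, rng)

    def test_expected_distinct_count_matches_occupancy_formula(self):
        """E[#distinct] for 30 draws from 360 is 360*(1-(359/360)^30)."""
        rng = np.random.default_rng(2)
        distinct = [
            len(np.unique(draw_bootstrap_indices(360, 30, True, rng)))
            for _ in range(5000)
        ]
        expected = 360 * (1 - (359 / 360) ** 30)
        assert np.mean(distinct) == pytest.approx(expected, abs=0.2)

    def test_record_reproducible_in_isolation(self, fixed_cohort):
        """A single (size, replicate) substream can be replayed alone."""
        a = record_indices(STUDY_SEED, 360, 30, 17)
        b = record_indices(STUDY_SEED, 360, 30, 17)
        np.testing.assert_array_equal(a, b)
        assert not np.array_equal(a, record_indices(STUDY_SEED, 360, 30, 18))


class TestRunResamplingStudy:
    def test_identity_resample_recovers_full_sample_estimate(self, fixed_cohort):
        cohort, load = fixed_cohort
        rec = run_resampling_study(cohort, load, sizes=[360], B=1,
                                   with_replacement=False, seed=1)
        assert rec.loc[0, "r2"] == pytest.approx(0.11, abs=1e-10)
        assert rec.loc[0, "sign"] == -1

    def test_record_layout_and_ranges(self, study_records):
        assert len(study_records) == 36_000
        assert set(study_records["size"].unique()) == {30, 60, 90, 120, 180, 360}
        assert study_records["p"].between(0, 1).all()
        assert study_records["r2"].between(0, 1).all()
        assert set(study_records["sign"].unique()) <= {-1, 1}

    def test_records_match_isolated_replay(self, fixed_cohort, study_records):
        """Any single record can be recomputed from its substream."""
        cohort, load = fixed_cohort
        c = cohort.loc[:, list(COVARIATE_COLUMNS)].to_numpy()
        y = cohort["score_repn"].to_numpy()
        for size, rep in [(30, 0), (90, 1234), (360, 5999)]:
            idx = record_indices(STUDY_SEED, 360, size, rep)
            res = partial_correlation(y[idx], load[idx], c[idx])
            row = study_records[(study_records["size"] == size)
                                & (study_records["replicate"] == rep)].iloc[0]
            assert row["r2"] == pytest.approx(res.r2, abs=1e-9)
            assert row["p"] == pytest.approx(res.p_two_sided, abs=1e-9)

    def test_seed_required(self, fixed_cohort):
        cohort, load = fixed_cohort
        with pytest.raises(ValueError, match="seed"):
            run_resampling_study(cohort, load, B=2)

    def test_undersized_resample_rejected(self, fixed_cohort):
        cohort, load = fixed_cohort
        with pytest.raises(ValueError, match="degrees of freedom"):
            run_resampling_study(cohort, load, sizes=[6], B=2, seed=1)

    def test_significance_rate_increases_with_size(self, study_records):
        props = [
            (study_records[study_records["size"] == s]["p"] < 0.05).mean()
            for s in (30, 60, 90, 120, 180, 360)
        ]
        assert np.all(np.diff(props) >= 0)
        assert sum(d > 0 for d in np.diff(props)) >= 3

    def test_mean_r2_stable_across_sizes(self, study_records):
        """Overall (not significance-filtered) effect estimates stay near 0.11."""
        for s in (90, 120, 180, 360):
            grp = study_records[study_records["size"] == s]
            assert grp["r2"].mean() == pytest.approx(0.11, abs=0.02)
        small = study_records[study_records["size"] == 30]["r2"].mean()
        assert 0.11 - 0.005 < small < 0.11 + 0.04  # upward bias only, < 0.04


class TestSummaries:
    def test_counts_partition_records(self, study_records):
        summ = summarize_by_significance(study_records)
        for (size, alpha), grp in summ.groupby(["size", "alpha"]):
            assert grp["count"].sum() == 6000

    def test_min_significant_r2_respects_critical_floor(self, study_records):
        summ = summarize_by_significance(study_records)
        sig = summ[(summ["group"] == "significant") & (summ["count"] > 0)]
        for _, row in sig.iterrows():
            floor = critical_r2(int(row["size"]), 5, row["alpha"])
            assert row["min_r2"] >= floor

    def test_empty_cell_keeps_nan_moments(self):
        rec = pd.DataFrame({"size": [30] * 5, "replicate": range(5),
                            "r2": [0.01] * 5, "p": [0.9] * 5, "sign": [-1] * 5})
        summ = summarize_by_significance(rec, alphas=[0.05])
        sig = summ[summ["group"] == "significant"].iloc[0]
        assert sig["count"] == 0 and np.isnan(sig["mean_r2"])

    def test_classification_partitions_and_places_records(self, study_records):
        ci = credible_interval_r2(0.11, 360, 5)
        cls = classify_against_interval(study_records, ci)
        totals = cls.groupby("size")[["above", "within", "below"]].sum().sum(axis=1)
        assert (totals == 6000).all()
        # a record inside the interval is "within" regardless of p
        rec = pd.DataFrame({"size": [30], "replicate": [0], "r2": [0.10],
                            "p": [0.9], "sign": [-1]})
        one = classify_against_interval(rec, ci)
        assert one.loc[one["group"] == "not_significant", "within"].iloc[0] == 1


class TestDecileSelection:
    def test_eleven_distinct_records_select_themselves(self):
        r2 = np.linspace(0.01, 0.5, 11)
        rec = pd.DataFrame({"size": 30, "replicate": range(11), "r2": r2,
                            "p": np.linspace(0.9, 0.001, 11), "sign": -1})
        dec = select_decile_resamples(rec)
        np.testing.assert_allclose(dec["r2"].to_numpy(), r2)

    def test_ties_break_to_lowest_replicate(self):
        rec = pd.DataFrame({"size": 30, "replicate": range(11),
                            "r2": [0.2] * 11, "p": [0.5] * 11, "sign": -1})
        dec = select_decile_resamples(rec)
        assert dec.loc[dec["percentile"] == 0, "replicate"].iloc[0] == 0

    def test_r2_monotone_across_percentiles(self, study_records):
        dec = select_decile_resamples(study_records)
        for _, grp in dec.groupby("size"):
            assert grp.sort_values("percentile")["r2"].is_monotonic_increasing

    def test_median_r2_stable_while_p_collapses(self, study_records):
        """The 50th-percentile resample keeps R2 ~ 0.11 at every size while
        its p value falls steadily with size."""
        dec = select_decile_resamples(study_records)
        mid = dec[dec["percentile"] == 50].sort_values("size")
        assert np.allclose(mid["r2"], 0.11, atol=0.02)
        assert mid["p"].is_monotonic_decreasing


class TestReplacementModes:
    def test_without_replacement_at_full_size_is_degenerate(
            self, study_records_without_replacement):
        full = study_records_without_replacement[
            study_records_without_replacement["size"] == 360]
        np.testing.assert_allclose(full["r2"], 0.11, atol=1e-9)

    def test_without_replacement_power_slightly_higher_mid_curve(
            self, study_records, study_records_without_replacement):
        """Subsampling (no replacement) never loses power relative to the
        bootstrap below full size: duplicates cost information."""
        for s in (60, 90, 120, 180):
            wr = (study_records[study_records["size"] == s]["p"] < 0.05).mean()
            wo = (study_records_without_replacement[
                study_records_without_replacement["size"] == s]["p"] < 0.05).mean()
            assert wo >= wr - 0.01


class TestRoiPowerSummary:
    def test_zero_effect_gives_zero_percent(self):
        from lesionboot.glm import RoiMask, build_design_matrix
        from lesionboot.lesion_io import FuzzyLesionVolume

        from conftest import make_null_design

        rng = np.random.default_rng(40)
        cohort = make_null_design(30, rng)
        design = build_design_matrix(cohort)
        # voxel values depend only on nuisance columns: observed target
        # effect is tiny, so no voxel reaches 80% power
        base = design.reduced() @ rng.standard_normal(6) * 0.01
        vols = [FuzzyLesionVolume(
            np.clip(0.5 + base[i] + 1e-3 * rng.standard_normal(4), 0, 1
                    ).reshape(4, 1, 1), 2.0) for i in range(30)]
        roi = RoiMask(voxels=[(v, 0, 0) for v in range(4)], threshold_used=0,
                      method="bonferroni", grid_shape=(4, 1, 1), alpha=0.05)
        pct = roi_power_summary(vols, design, roi, alpha_corrected=1e-4)
        assert pct == 0.0

    def test_voxel_order_invariance(self, fixed_cohort):
        from lesionboot.glm import RoiMask, build_design_matrix
        from lesionboot.lesion_io import FuzzyLesionVolume

        rng = np.random.default_rng(41)
        cohort, load = fixed_cohort
        design = build_design_matrix(cohort)
        vals = np.clip(load[:, None] + 0.05 * rng.standard_normal((360, 5)), 0, 1)
        vols = [FuzzyLesionVolume(vals[i].reshape(5, 1, 1), 2.0)
                for i in range(360)]
        vox = [(v, 0, 0) for v in range(5)]
        roi_a = RoiMask(voxels=vox, threshold_used=0, method="bonferroni",
                        grid_shape=(5, 1, 1), alpha=0.05)
        roi_b = RoiMask(voxels=vox[::-1], threshold_used=0, method="bonferroni",
                        grid_shape=(5, 1, 1), alpha=0.05)
        assert roi_power_summary(vols, design, roi_a, 1e-5) == \
            roi_power_summary(vols, design, roi_b, 1e-5)

    def test_median_decile_resample_is_well_powered(self, fixed_cohort,
                                                    study_records):
        """At the size-360 median-decile resample, at least 80% of strongly
        load-coupled voxels have sufficient power at a corrected alpha."""
        from lesionboot.glm import RoiMask, DesignMatrix, build_design_matrix
        from lesionboot.lesion_io import FuzzyLesionVolume

        rng = np.random.default_rng(42)
        cohort, load = fixed_cohort
        dec = select_decile_resamples(study_records)
        rep = int(dec[(dec["size"] == 360) & (dec["percentile"] == 50)]
                  ["replicate"].iloc[0])
        idx = record_indices(STUDY_SEED, 360, 360, rep)
        sub = cohort.iloc[idx].reset_index(drop=True)
        design = build_design_matrix(sub)
        vals = np.clip(load[idx][:, None]
                       + 0.03 * rng.standard_normal((360, 8)), 0, 1)
        vols = [FuzzyLesionVolume(vals[i].reshape(8, 1, 1), 2.0)
                for i in range(360)]
        roi = RoiMask(voxels=[(v, 0, 0) for v in range(8)], threshold_used=0,
                      method="bonferroni", grid_shape=(8, 1, 1), alpha=0.05)
        pct = roi_power_summary(vols, design, roi,
                                alpha_corrected=0.05 / 15000)
        assert pct >= 80.0

    def test_empty_roi_rejected(self, fixed_cohort):
        from lesionboot.glm import RoiMask, build_design_matrix

        cohort, _ = fixed_cohort
        roi = RoiMask(voxels=np.empty((0, 3)), threshold_used=0,
                      method="bonferroni", grid_shape=(2, 2, 2), alpha=0.05)
        with pytest.raises(ValueError, match="empty ROI"):
            roi_power_summary([], build_design_matrix(cohort), roi, 0.001)
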