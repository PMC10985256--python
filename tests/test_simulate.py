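"""Synthetic cohort generator: calibration, linkage, ground-truth recovery."""

import numpy as np
import pytest

from acticohort import (
    ActivityProfile,
    ChoiParams,
    CohortConfig,
    classify_intensity,
    detect_nonwear_choi,
    sample_subject,
    simulate_cohort,
    simulate_epoch_series,
    steps_calibration,
    summarize_cohort,
)
from acticohort.simulate import BASE_OCCUPANCY


class TestStepsCalibration:
    def test_control_waist_anchor(self):
        rate_light, rate_mvpa = steps_calibration(0.218, 0.105, 16.0)
        assert rate_light == pytest.approx(30.0, abs=0.1)
        assert rate_mvpa == pytest.approx(90.0, abs=0.3)
        assert 0.218 * rate_light + 0.105 * rate_mvpa == pytest.approx(16.0)

    def test_zero_mvpa_all_steps_from_light(self):
        rate_light, _ = steps_calibration(0.25, 0.0, 5.0)
        assert rate_light == pytest.approx(20.0)

    def test_infeasible_target_rejected(self):
        with pytest.raises(ValueError):
            steps_calibration(0.0, 0.0, 10.0)
        with pytest.raises(ValueError):
            steps_calibration(0.2, 0.1, -1.0)


class TestActivityProfile:
    def test_transition_rows_sum_to_one(self):
        prof = ActivityProfile(np.array([0.7, 0.2, 0.08, 0.02]), "waist")
        T = prof.transition_matrix
        assert np.allclose(T.sum(axis=1), 1.0)

    def test_occupancy_is_stationary_law(self):
        pi = np.array([0.6, 0.25, 0.1, 0.05])
        T = ActivityProfile(pi, "waist", persistence=0.9).transition_matrix
        assert np.allclose(pi @ T, pi)

    def test_invalid_occupancy_rejected(self):
        with pytest.raises(ValueError):
            ActivityProfile(np.array([0.5, 0.5, 0.5, 0.5]), "waist")


class TestSampleSubject:
    def test_deterministic_given_seed(self):
        cfg = CohortConfig(seed=3)
        a = sample_subject("FRDA", cfg, np.random.default_rng(42), "P01")
        b = sample_subject("FRDA", cfg, np.random.default_rng(42), "P01")
        assert a.baseline == b.baseline
        for key in a.profiles:
            assert np.allclose(a.profiles[key].occupancy, b.profiles[key].occupancy)

    def test_mean_severity_profile_near_calibration_target(self):
        # with noise sources shrunk, a subject at the severity mean sits on
        # the group occupancy anchor
        cfg = CohortConfig(
            sara_sd=1e-6, subject_sd_sed=1e-6, subject_sd_mvpa=1e-6,
            day_sd_sed=1e-6, visit_sd_sed=1e-6,
        )
        subj = sample_subject("FRDA", cfg, np.random.default_rng(0), "P01")
        p_sed = subj.profiles[("waist", "baseline")].stationary[0]
        assert p_sed == pytest.approx(BASE_OCCUPANCY[("FRDA", "waist")][0], abs=0.02)

    def test_zero_linkage_decouples_severity(self):
        cfg = CohortConfig(sev_slope_sed=0.0, sev_slope_mvpa=0.0)
        rng = np.random.default_rng(5)
        saras, seds = [], []
        for i in range(40):
            s = sample_subject("FRDA", cfg, rng, f"P{i:02d}")
            saras.append(s.baseline.sara)
            seds.append(s.profiles[("waist", "baseline")].stationary[0])
        r = np.corrcoef(saras, seds)[0, 1]
        assert abs(r) < 0.35

    def test_severity_raises_sedentary_dwell(self):
        cfg = CohortConfig()
        rng = np.random.default_rng(5)
        saras, seds = [], []
        for i in range(60):
            s = sample_subject("FRDA", cfg, rng, f"P{i:02d}")
            saras.append(s.baseline.sara)
            seds.append(s.profiles[("waist", "baseline")].stationary[0])
        assert np.corrcoef(saras, seds)[0, 1] > 0.5

    def test_frda_inclusion_rules(self):
        rng = np.random.default_rng(9)
        for i in range(50):
            rec = sample_subject("FRDA", CohortConfig(), rng, f"P{i}").baseline
            assert rec.sara_gait < 8
            assert 18 <= rec.age <= 45


class TestSimulateEpochSeries:
    def test_pure_sedentary_profile(self):
        prof = ActivityProfile(np.array([1.0, 0.0, 0.0, 0.0]), "waist")
        sim = simulate_epoch_series(
            prof, 2, np.random.default_rng(1), nonwear_prob_per_day=0.0
        )
        worn = sim.states >= 0
        assert np.all(sim.series.axis1[worn] < 100)
        assert sim.series.steps.sum() == 0

    def test_state_labels_recovered_from_counts(self):
        prof = ActivityProfile(np.array(BASE_OCCUPANCY[("CTR", "waist")]), "waist")
        sim = simulate_epoch_series(prof, 7, np.random.default_rng(2))
        worn = sim.states >= 0
        levels = classify_intensity(sim.series.axis1[worn].astype(float))
        assert np.array_equal(levels, sim.states[worn])

    def test_inserted_nonwear_blocks_fully_detected(self):
        prof = ActivityProfile(np.array(BASE_OCCUPANCY[("FRDA", "waist")]), "waist")
        found = 0
        for seed in range(5):
            sim = simulate_epoch_series(
                prof, 7, np.random.default_rng(seed),
                nonwear_prob_per_day=1.0, nonwear_len_range=(120, 120),
            )
            wear = detect_nonwear_choi(sim.series, ChoiParams())
            for start, end in sim.nonwear_blocks:
                found += 1
                assert not wear[start:end].any()
        assert found >= 30  # 7 days x 5 seeds, one block per day

    def test_night_gap_is_zero_counts(self):
        prof = ActivityProfile(np.array(BASE_OCCUPANCY[("CTR", "wrist")]), "wrist")
        sim = simulate_epoch_series(prof, 1, np.random.default_rng(3))
        assert sim.series.axis1[: 6 * 60].sum() == 0  # before 06:00
        assert sim.series.axis1[22 * 60 :].sum() == 0  # after 22:00


class TestSimulateCohort:
    def test_bit_identical_reproduction(self):
        cfg = CohortConfig(n_frda=3, n_ctr=2, seed=77)
        a = simulate_cohort(cfg)
        b = simulate_cohort(cfg)
        assert [s.baseline for s in a.subjects] == [s.baseline for s in b.subjects]
        for key in a.series:
            assert np.array_equal(a.series[key].series.axis1, b.series[key].series.axis1)
            assert np.array_equal(a.series[key].series.steps, b.series[key].series.steps)

    def test_group_means_match_calibration_bands(self):
        """Monte-Carlo averaged waist sedentary means hit the published
        group anchors (patients ~81%, controls ~68%)."""
        frda, ctr = [], []
        for seed in range(3):
            coh = simulate_cohort(CohortConfig(seed=seed))
            summary, _ = summarize_cohort(coh)
            base = summary[(summary.placement == "waist") & (summary.visit == "baseline")]
            frda.append(base[base.group == "FRDA"].pct_sedentary.mean())
            ctr.append(base[base.group == "CTR"].pct_sedentary.mean())
        assert 79.0 <= np.mean(frda) <= 84.0
        assert 65.0 <= np.mean(ctr) <= 71.0

    def test_zero_decline_keeps_longitudinal_null(self):
        from acticohort import paired_change_test

        coh = simulate_cohort(CohortConfig(n_frda=20, n_ctr=2, seed=21, annual_decline=0.0))
        summary, _ = summarize_cohort(coh)
        waist = summary[summary.placement == "waist"]
        base = waist[waist.visit == "baseline"].set_index("subject_id")
        fu = waist[waist.visit == "followup"].set_index("subject_id")
        frda = base[base.group == "FRDA"].index
        res = paired_change_test(base.loc[frda, "pct_sedentary"], fu.loc[frda, "pct_sedentary"])
        assert abs(res.mean_change) < 2.5
        assert res.pvalue > 0.001

    def test_written_files_round_trip(self, tmp_path, small_cohort):
        from acticohort import read_clinical_table, read_diary_csv, read_epoch_csv

        small_cohort.write(tmp_path)
        records = read_clinical_table(tmp_path / "clinical.csv")
        assert len(records) == 2 * (6 + 4)
        diaries = read_diary_csv(tmp_path / "diary.csv")
        assert len(diaries) == 10
        key = ("FRDA01", "waist", "baseline")
        back = read_epoch_csv(tmp_path / "epochs" / "FRDA01_waist_baseline.csv")
        assert back == small_cohort.series[key].series
        truth = (tmp_path / "truth.json").read_text()
        assert "occupancy" in truth
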