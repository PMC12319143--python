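"""Synthetic-cohort generator: screening, kinematic form, schedules, determinism."""

import numpy as np
import pandas as pd
import pytest

from reachstop import StudyConfig, generate_cohort, screen_participants
from reachstop.cohort import (
    PEAK_ACCELERATION_COEF,
    PEAK_VELOCITY_COEF,
    _balanced_schedule,
    draw_candidates,
    generate_feature_table,
    generate_participant_trials,
    generate_vr_trial,
    minjerk_position,
)


class TestScreening:
    def _valid(self, **over):
        row = {"id": "X", "age": 25.0, "bmi": 22.0,
               "handedness_score": 80.0, "fcq_trait": 38.0}
        row.update(over)
        return row

    def test_craving_threshold_is_strict(self):
        df = pd.DataFrame([self._valid(fcq_trait=37.0),
                           self._valid(fcq_trait=38.0)])
        kept, log = screen_participants(df)
        assert kept["fcq_trait"].tolist() == [38.0]
        assert any("fcq_trait" in line for line in log)

    def test_all_rules_satisfied_included(self):
        kept, log = screen_participants(pd.DataFrame([self._valid()]))
        assert len(kept) == 1 and log == []

    @pytest.mark.parametrize("field,bad", [
        ("bmi", 18.4), ("bmi", 30.0), ("age", 17.0), ("age", 36.0),
        ("handedness_score", 50.0),
    ])
    def test_boundary_exclusions(self, field, bad):
        kept, _ = screen_participants(pd.DataFrame([self._valid(**{field: bad})]))
        assert len(kept) == 0

    def test_missing_field_rejected_with_log(self):
        df = pd.DataFrame([self._valid(), self._valid(bmi=np.nan)])
        kept, log = screen_participants(df)
        assert len(kept) == 1
        assert any("missing" in line for line in log)

    def test_matches_bruteforce_filter_and_preserves_order(self, rng):
        df = draw_candidates(100, rng)
        df["fcq_trait"] = rng.integers(30, 46, 100).astype(float)
        df["bmi"] = 22.0
        df["age"] = 25.0
        df["handedness_score"] = 80.0
        kept, _ = screen_participants(df)
        expected = df[df["fcq_trait"] >= 38]
        assert kept["id"].tolist() == expected["id"].tolist()


class TestVRTrialGeneration:
    def test_minjerk_peak_closed_forms(self, flat_participant, rng):
        # discretized minimum-jerk depth profile vs closed-form peaks
        cfg = StudyConfig(object_depth=0.6)
        s, _ = generate_vr_trial(flat_participant, "chocolate", "go", cfg, rng,
                                 it_ms=200.0, t_reach_ms=1000.0, noise_sd=0.0,
                                 with_gaze=False)
        t_s = s["t_ms"] / 1000.0
        v = np.gradient(s["x1_m"], t_s)
        a = np.gradient(v, t_s)
        assert v.max() == pytest.approx(PEAK_VELOCITY_COEF * 0.6, rel=0.01)
        assert a.max() == pytest.approx(PEAK_ACCELERATION_COEF * 0.6, rel=0.02)

    def test_zero_stop_latency_halts_at_onset_depth(self, flat_participant, rng):
        cfg = StudyConfig()
        s, gt = generate_vr_trial(flat_participant, "chocolate", "stop", cfg,
                                  rng, ssd_ms=150.0, it_ms=300.0,
                                  t_reach_ms=512.0, stop_lat_ms=0.0,
                                  noise_sd=0.0)
        assert gt["stop_success"]
        assert gt["bd_true_m"] == pytest.approx(0.0)
        onset_depth = cfg.object_depth * minjerk_position(150.0 / 512.0)
        after = s["x1_m"][s["t_ms"] > gt["stop_onset_ms"]]
        # hand never advances past the onset depth; it retracts afterwards
        assert after.max() <= onset_depth + 1e-12
        assert np.all(np.diff(after) <= 1e-12)

    def test_nonpositive_reach_duration_raises(self, flat_participant, rng):
        with pytest.raises(ValueError):
            generate_vr_trial(flat_participant, "chocolate", "go",
                              StudyConfig(), rng, t_reach_ms=0.0)

    def test_trial_record_invariants(self, flat_participant, rng):
        cfg = StudyConfig()
        s, gt = generate_vr_trial(flat_participant, "neutral", "stop", cfg,
                                  rng, ssd_ms=200.0)
        assert s["t_ms"][0] == 0.0
        assert np.all(np.diff(s["t_ms"]) > 0)
        assert len(s["gaze_hit"]) == len(s["t_ms"])
        assert np.isfinite(gt["stop_onset_ms"])
        s2, gt2 = generate_vr_trial(flat_participant, "neutral", "go", cfg, rng)
        assert not np.isfinite(gt2["stop_onset_ms"])


class TestSchedulesAndStaircase:
    def test_trial_counts_match_design(self, rng):
        # 400 trials, 25% stop, categories balanced within trial type
        cfg = StudyConfig(n_vr_trials=400, stop_fraction=0.25)
        sched = _balanced_schedule(cfg, rng)
        tally = pd.Series(sched).value_counts()
        assert tally[("chocolate", "stop")] == 50
        assert tally[("neutral", "stop")] == 50
        assert tally[("chocolate", "go")] == 150
        assert tally[("neutral", "go")] == 150

    def test_stop_fraction_must_divide_trials(self):
        with pytest.raises(ValueError):
            StudyConfig(n_vr_trials=10, stop_fraction=0.25)

    def test_stop_success_rate_in_observed_band(self, flat_participant, rng):
        cfg = StudyConfig()
        _, gts = generate_participant_trials("P0", flat_participant, cfg, rng)
        stop = gts[gts["trial_type"] == "stop"]
        rate = stop["stop_success"].mean()
        assert 0.519 <= rate <= 1.0


class TestCohort:
    def test_same_seed_gives_byte_identical_dataset(self, small_config, tmp_path):
        d1 = generate_cohort(small_config)
        d2 = generate_cohort(small_config)
        p1 = d1.write(tmp_path / "a")
        p2 = d2.write(tmp_path / "b")
        for a, b in zip(p1, p2):
            assert a.read_bytes() == b.read_bytes()

    def test_single_weight_zero_noise_gives_perfect_correlation(self):
        from reachstop.config import IntakeModel
        cfg = StudyConfig(
            n_participants=500,
            intake_model=IntakeModel(true_weights={"pv_choc": 80.0},
                                     noise_sd=0.0))
        feat = generate_feature_table(cfg, np.random.default_rng(0))
        r = np.corrcoef(feat["pv_choc"], feat["intake_kcal"])[0, 1]
        assert r > 0.999

    def test_intake_floored_at_zero_and_fcq_in_range(self, small_config):
        feat = generate_feature_table(StudyConfig(n_participants=200,
                                                  rng_seed=3),
                                      np.random.default_rng(3))
        assert (feat["intake_kcal"] >= 0).all()
        assert feat["fcq_trait"].between(15, 90).all()

    def test_ground_truth_not_in_analysis_tables(self, small_config):
        data = generate_cohort(small_config)
        assert "stop_lat_ms" not in data.trials.columns
        assert "tts_true_ms" not in data.trials.columns
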