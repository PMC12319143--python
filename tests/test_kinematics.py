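"""Segmentation, differentiation, parameter extraction and aggregation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq

from reachstop import StudyConfig
from reachstop.cohort import generate_vr_trial, minjerk_position
from reachstop.kinematics import (
    SegmentedTrial,
    TrialUnusable,
    center_and_segment,
    compute_velocity_acceleration,
    detect_initiation,
    extract_parameters,
    extract_trials,
    filter_and_aggregate,
    time_standardize,
    zscore_filter,
)


def _trial_from_depth(depth, dt_ms=100.0):
    t = np.arange(len(depth)) * dt_ms
    xyz = np.column_stack([depth, np.zeros(len(depth)), np.zeros(len(depth))])
    return t, xyz


class TestSegmentation:
    def test_stationary_trial_keeps_all_and_maxz_zero(self):
        t, xyz = _trial_from_depth([0.0] * 5)
        seg = center_and_segment(t, xyz)
        assert seg.t_ms.size >= 2 and seg.x1.max() == 0.0

    def test_monotone_ramp_keeps_full_trial(self):
        t, xyz = _trial_from_depth(np.linspace(0, 0.6, 10))
        seg = center_and_segment(t, xyz)
        assert seg.t_ms.size == 10

    def test_earliest_max_tie_rule(self):
        # depth 0, 0.3, 0.55, 0.54, 0.55 -> segment ends at the 200 ms sample
        t, xyz = _trial_from_depth([0.0, 0.3, 0.55, 0.54, 0.55])
        seg = center_and_segment(t, xyz)
        assert seg.t_ms[-1] == 200.0

    def test_too_short_or_bad_clock_flagged(self):
        with pytest.raises(TrialUnusable):
            center_and_segment([0, 10], [[0, 0, 0], [1, 0, 0]])
        with pytest.raises(TrialUnusable):
            center_and_segment([0, 10, 10], np.zeros((3, 3)))

    def test_centering_subtracts_first_sample(self):
        t, xyz = _trial_from_depth([0.2, 0.5, 0.9])
        seg = center_and_segment(t, xyz)
        assert np.allclose(seg.pos[0], 0.0)
        assert seg.x1[-1] == pytest.approx(0.7)

    @given(st.lists(st.integers(min_value=0, max_value=9), min_size=3,
                    max_size=40))
    @settings(deadline=None, max_examples=200)
    def test_matches_bruteforce_argmax_on_random_sequences(self, depth):
        t, xyz = _trial_from_depth(np.array(depth, dtype=float))
        seg = center_and_segment(t, xyz)
        centred = np.array(depth, dtype=float) - depth[0]
        best, best_i = -np.inf, 0
        for i, v in enumerate(centred):     # brute-force earliest-max scan
            if v > best:
                best, best_i = v, i
        assert seg.t_ms[-1] == t[max(best_i, 1)]


class TestInitiation:
    def test_stationary_flags_no_movement(self):
        t, xyz = _trial_from_depth([0.0] * 5)
        assert np.isnan(detect_initiation(center_and_segment(t, xyz)))

    def test_constant_speed_crossing_interpolated(self):
        # 1 m/s depth motion crosses the 1 cm threshold at exactly 10 ms
        t, xyz = _trial_from_depth(np.arange(5) * 0.1)  # dt 100 ms
        it = detect_initiation(center_and_segment(t, xyz), threshold=0.01)
        assert it == pytest.approx(10.0)

    def test_minjerk_detection_vs_analytic_inversion(self, flat_participant,
                                                     rng):
        cfg = StudyConfig(object_depth=0.6)
        D, T, IT, thr = 0.6, 1000.0, 200.0, 0.01
        s, _ = generate_vr_trial(flat_participant, "chocolate", "go", cfg, rng,
                                 it_ms=IT, t_reach_ms=T, noise_sd=0.0,
                                 with_gaze=False)
        seg = center_and_segment(s["t_ms"],
                                 np.column_stack([s["x1_m"], s["x2_m"],
                                                  s["x3_m"]]))
        detected = detect_initiation(seg, thr)
        # invert the 3D displacement of the generator's path for the threshold
        def disp(tau):
            x1 = D * minjerk_position(tau)
            x2 = 0.02 * np.sin(np.pi * x1 / D)
            x3 = 0.05 * x1 / D
            return np.sqrt(x1**2 + x2**2 + x3**2) - thr
        tau_star = brentq(disp, 1e-9, 0.5)
        expected = IT + tau_star * T
        assert abs(detected - expected) < 1000.0 / 120.0 + 1.0


class TestDifferentiation:
    def test_linear_motion_recovers_constant_speed(self):
        t = np.arange(20) * (1000.0 / 120.0)
        xyz = np.column_stack([2.0 * t / 1000.0, np.zeros(20), np.zeros(20)])
        seg = SegmentedTrial(t_ms=t, pos=xyz)
        speed, accel = compute_velocity_acceleration(seg)
        # smoothing windows shrink asymmetrically at the edges, so only the
        # interior (window + stencil margin) is exact
        assert np.allclose(speed[5:-5], 2.0, atol=1e-9)
        assert np.allclose(accel[6:-6], 0.0, atol=1e-6)

    def test_minjerk_peaks_within_stated_tolerance(self, flat_participant,
                                                   rng):
        cfg = StudyConfig(object_depth=0.6)
        s, _ = generate_vr_trial(flat_participant, "chocolate", "go", cfg, rng,
                                 it_ms=200.0, t_reach_ms=1000.0, noise_sd=0.0,
                                 with_gaze=False)
        seg = center_and_segment(s["t_ms"],
                                 np.column_stack([s["x1_m"], s["x2_m"],
                                                  s["x3_m"]]))
        speed, accel = compute_velocity_acceleration(seg)
        assert speed.max() == pytest.approx(1.125, rel=0.01)
        assert accel.max() == pytest.approx(3.464, rel=0.02)

    def test_sinusoid_peak_speed_within_taylor_bound(self):
        # x1 = A sin(wt): central-difference peak speed attenuated by at most
        # (w dt)^2 / 6 relative to A w (grid chosen so samples hit the peaks)
        A, f = 0.1, 1.5
        w = 2 * np.pi * f
        dt = 1000.0 / 120.0
        t = np.arange(241) * dt               # 2 s, peaks land on the grid
        x1 = A * np.sin(w * t / 1000.0)
        seg = SegmentedTrial(t_ms=t, pos=np.column_stack(
            [x1, np.zeros_like(x1), np.zeros_like(x1)]))
        speed, _ = compute_velocity_acceleration(seg, window=1)
        err = abs(speed[2:-2].max() - A * w)
        bound = (w * dt / 1000.0) ** 2 / 6.0 * A * w
        assert err <= bound * 1.01

    def test_sampling_gap_flags_trial(self):
        t = np.array([0.0, 8.33, 16.7, 100.0, 108.3])
        seg = SegmentedTrial(t_ms=t, pos=np.column_stack(
            [np.linspace(0, 0.4, 5), np.zeros(5), np.zeros(5)]))
        with pytest.raises(TrialUnusable):
            compute_velocity_acceleration(seg)


class TestExtractParameters:
    def _seg(self, depth, dt=100.0, stop_onset=np.nan):
        t, xyz = _trial_from_depth(depth, dt)
        return center_and_segment(t, xyz, stop_onset_ms=stop_onset)

    def test_tts_and_bd_definitions(self):
        # stop onset 600 ms, max depth at 850 ms -> TTS 250 ms;
        # depth 0.40 m at onset, max 0.45 m -> BD 0.05 m
        t = np.array([0.0, 600.0, 850.0, 950.0])
        depth = np.array([0.0, 0.40, 0.45, 0.45])
        xyz = np.column_stack([depth, np.zeros(4), np.zeros(4)])
        seg = center_and_segment(t, xyz, stop_onset_ms=600.0)
        speed, accel = compute_velocity_acceleration(seg)
        rec = extract_parameters(seg, speed, accel, is_stop=True,
                                 object_depth=0.5705)
        assert rec["tts"] == pytest.approx(250.0)
        assert rec["bd"] == pytest.approx(0.05)
        assert rec["acc"] == 1.0

    def test_stop_trial_without_onset_errors(self):
        seg = self._seg(np.linspace(0, 0.5, 6))
        speed, accel = compute_velocity_acceleration(seg)
        with pytest.raises(ValueError):
            extract_parameters(seg, speed, accel, is_stop=True)

    def test_batch_recovery_of_stopping_parameters(self, flat_participant):
        # noiseless stop trials: extracted TTS within one sample period of
        # truth on average; BD and maxZ within 1 mm
        cfg = StudyConfig()
        rng = np.random.default_rng(21)
        errs = {"tts": [], "bd": [], "maxz": []}
        n_ok = 0
        for _ in range(80):
            s, gt = generate_vr_trial(flat_participant, "chocolate", "stop",
                                      cfg, rng,
                                      ssd_ms=rng.uniform(80, 260),
                                      noise_sd=0.0, with_gaze=False)
            if not gt["stop_success"]:
                continue
            n_ok += 1
            seg = center_and_segment(
                s["t_ms"], np.column_stack([s["x1_m"], s["x2_m"], s["x3_m"]]),
                stop_onset_ms=gt["stop_onset_ms"])
            speed, accel = compute_velocity_acceleration(seg)
            rec = extract_parameters(seg, speed, accel, is_stop=True,
                                     object_depth=cfg.object_depth)
            errs["tts"].append(rec["tts"] - gt["tts_true_ms"])
            errs["bd"].append(rec["bd"] - gt["bd_true_m"])
            errs["maxz"].append(rec["maxz"] - gt["maxz_true_m"])
        assert n_ok > 50
        assert abs(np.mean(errs["tts"])) < 1000.0 / 120.0
        assert abs(np.mean(errs["bd"])) < 1e-3
        assert abs(np.mean(errs["maxz"])) < 1e-3

    def test_pv_bias_under_positional_noise_below_2pct(self, flat_participant):
        # smoothing contract: 1 mm sensor noise must not bias PV by > 2%
        cfg = StudyConfig()
        rng = np.random.default_rng(31)
        rel = []
        for _ in range(150):
            s, gt = generate_vr_trial(flat_participant, "chocolate", "go",
                                      cfg, rng, noise_sd=0.001,
                                      with_gaze=False)
            seg = center_and_segment(
                s["t_ms"], np.column_stack([s["x1_m"], s["x2_m"], s["x3_m"]]))
            speed, _ = compute_velocity_acceleration(seg)
            rel.append(speed.max() / gt["pv_true"] - 1.0)
        assert abs(np.mean(rel)) < 0.02


class TestTimeStandardize:
    def test_two_point_line_resampled_exactly(self):
        seg = SegmentedTrial(t_ms=np.array([0.0, 100.0, 200.0]),
                             pos=np.column_stack([np.array([0, 0.1, 0.2]),
                                                  np.zeros(3), np.zeros(3)]))
        out = time_standardize(seg, 21)
        assert np.allclose(out[:, 0], np.linspace(0, 0.2, 21))

    def test_identity_when_steps_match_uniform_samples(self):
        t, xyz = _trial_from_depth(np.linspace(0, 0.6, 7))
        seg = center_and_segment(t, xyz)
        out = time_standardize(seg, 7)
        assert np.allclose(out, seg.pos)

    def test_minjerk_interpolation_error_below_half_mm(self, flat_participant,
                                                       rng):
        cfg = StudyConfig(object_depth=0.6)
        s, _ = generate_vr_trial(flat_participant, "chocolate", "go", cfg, rng,
                                 it_ms=200.0, t_reach_ms=1000.0, noise_sd=0.0,
                                 with_gaze=False)
        seg = center_and_segment(s["t_ms"], np.column_stack(
            [s["x1_m"], s["x2_m"], s["x3_m"]]))
        out = time_standardize(seg, 101)
        tq = np.linspace(seg.t_ms[0], seg.t_ms[-1], 101)
        analytic = 0.6 * minjerk_position((tq - 200.0) / 1000.0)
        assert np.abs(out[:, 0] - analytic).max() < 5e-4


class TestAggregation:
    def test_all_equal_values_kept(self):
        assert zscore_filter(np.full(8, 3.0)).all()

    def test_hand_computed_outlier_removed(self):
        vals = np.array([10.0] * 9 + [60.0])     # z(60) = 2.85 > 2.5
        keep = zscore_filter(vals, 2.5)
        assert keep.sum() == 9 and not keep[-1]
        assert vals[keep].mean() == pytest.approx(10.0)

    def test_hand_computed_inlier_survives(self):
        vals = np.array([10.0, 10, 10, 10, 100])  # z(100) = 1.79 <= 2.5
        assert zscore_filter(vals, 2.5).all()

    def test_matches_bruteforce_groupby_oracle(self, rng):
        records = pd.DataFrame({
            "participant_id": rng.choice(["a", "b"], 200),
            "category": rng.choice(["chocolate", "neutral"], 200),
            "trial_type": rng.choice(["go", "stop"], 200),
            "pv": rng.normal(2.0, 0.5, 200),
        })
        out = filter_and_aggregate(records, variables=("pv",))
        for _, row in out.iterrows():
            cell = records[
                (records["participant_id"] == row["participant_id"])
                & (records["category"] == row["category"])
                & (records["trial_type"] == row["trial_type"])]["pv"].to_numpy()
            m, s = cell.mean(), cell.std(ddof=1)
            surv = cell if (len(cell) < 2 or s == 0) else \
                cell[np.abs(cell - m) <= 2.5 * s]
            assert row["mean"] == pytest.approx(surv.mean())
            assert row["n_trials_used"] == len(surv)

    def test_low_trial_cells_flagged(self):
        records = pd.DataFrame({
            "participant_id": ["a"] * 3, "category": ["chocolate"] * 3,
            "trial_type": ["go"] * 3, "pv": [1.0, 2.0, 3.0]})
        out = filter_and_aggregate(records, variables=("pv",))
        assert out["low_n"].all()

    def test_failed_stops_masked_in_extraction(self, small_config):
        from reachstop import generate_cohort
        data = generate_cohort(small_config)
        recs, _ = extract_trials(data.trials,
                                 object_depth=small_config.object_depth)
        failed = recs[(recs["trial_type"] == "stop") & (recs["acc"] == 0.0)]
        assert failed["tts"].isna().all()
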