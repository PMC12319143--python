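"""Reach-trajectory preprocessing and biometric parameter extraction.

Each trial's 3D hand samples are centred to the starting position, segmented
from stimulus onset to the first attainment of maximal depth displacement
(the approach phase), and differentiated into speed/acceleration series.
From these the per-trial biometric parameters are read off: peak velocity
(PV) and acceleration (PA) with their times, initiation time (IT), maximal
depth displacement (maxZ), reaction time (RT), and on stop trials the direct
stopping latency (TTS = time from stop-signal onset to maximal displacement),
braking distance (BD) and stop accuracy (ACC).  Per-trial records are then
aggregated to participant x category x trial-type cell means after a z-score
outlier filter.

Distances are metres, times milliseconds, speeds m/s, accelerations m/s^2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


class TrialUnusable(ValueError):
    """Raised when a trial cannot enter the analysis (too short, bad clock)."""


@dataclass
class SegmentedTrial:
    """Centred samples from stimulus onset to maximal depth displacement."""
    t_ms: np.ndarray
    pos: np.ndarray                      # (n, 3): depth, lateral, height
    stop_onset_ms: float = np.nan
    ssd_ms: float = np.nan

    @property
    def x1(self) -> np.ndarray:
        return self.pos[:, 0]


def center_and_segment(t_ms, xyz, stop_onset_ms=np.nan,
                       ssd_ms=np.nan) -> SegmentedTrial:
    """Centre to the first sample and truncate after the earliest attainment
    of maximal depth displacement (ties broken by the earliest sample)."""
    t = np.asarray(t_ms, dtype=float)
    x = np.asarray(xyz, dtype=float)
    if t.size < 3:
        raise TrialUnusable("fewer than 3 samples")
    if np.any(np.diff(t) <= 0):
        raise TrialUnusable("timestamps not strictly increasing")
    x = x - x[0]
    end = int(np.argmax(x[:, 0]))        # first occurrence of the max
    end = max(end, 1)                    # keep at least two samples
    return SegmentedTrial(t_ms=t[:end + 1], pos=x[:end + 1],
                          stop_onset_ms=float(stop_onset_ms),
                          ssd_ms=float(ssd_ms))


def detect_initiation(trial: SegmentedTrial, threshold: float = 0.01) -> float:
    """Interpolated time (ms) at which 3D displacement from the origin first
    exceeds ``threshold`` metres; NaN if the hand never moves that far."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    disp = np.linalg.norm(trial.pos, axis=1)
    above = np.nonzero(disp > threshold)[0]
    if above.size == 0:
        return np.nan
    i = above[0]
    if i == 0:
        return float(trial.t_ms[0])
    d0, d1 = disp[i - 1], disp[i]
    frac = (threshold - d0) / (d1 - d0)
    return float(trial.t_ms[i - 1] + frac * (trial.t_ms[i] - trial.t_ms[i - 1]))


def _moving_average(y: np.ndarray, window: int) -> np.ndarray:
    """Centred moving average with window shrinking at the boundaries."""
    if window <= 1:
        return y.astype(float)
    half = window // 2
    c = np.cumsum(np.concatenate([[0.0], y]))
    n = y.size
    lo = np.maximum(np.arange(n) - half, 0)
    hi = np.minimum(np.arange(n) + half + 1, n)
    return (c[hi] - c[lo]) / (hi - lo)


def _derivative(y: np.ndarray, t_s: np.ndarray) -> np.ndarray:
    """Central differences, one-sided at the boundaries (np.gradient)."""
    return np.gradient(y, t_s)


def compute_velocity_acceleration(trial: SegmentedTrial, window: int = 5,
                                  depth_only: bool = False):
    """Per-sample speed and acceleration of the hand.

    Positions are moving-average smoothed (default 5 samples), speed is the
    magnitude of the central-difference velocity vector (or |dx1/dt| with
    ``depth_only``), smoothed again, and acceleration is the derivative of
    the smoothed speed series.
    """
    if trial.t_ms.size < 3:
        raise TrialUnusable("fewer than 3 samples")
    dts = np.diff(trial.t_ms)
    nominal = np.median(dts)
    if np.any(dts > 3.0 * nominal):
        raise TrialUnusable("sampling gap exceeds 3 nominal periods")
    t_s = trial.t_ms / 1000.0
    if depth_only:
        v = _derivative(_moving_average(trial.x1, window), t_s)
        speed = np.abs(v)
    else:
        vel = np.column_stack([
            _derivative(_moving_average(trial.pos[:, k], window), t_s)
            for k in range(3)])
        speed = np.linalg.norm(vel, axis=1)
    speed = _moving_average(speed, window)
    accel = _derivative(speed, t_s)
    return speed, accel


def time_standardize(trial: SegmentedTrial, n_steps: int = 101) -> np.ndarray:
    """Linear resampling of each coordinate at ``n_steps`` equally spaced
    time fractions of the segment (endpoints preserved exactly)."""
    if n_steps < 2:
        raise ValueError("n_steps must be >= 2")
    tq = np.linspace(trial.t_ms[0], trial.t_ms[-1], n_steps)
    out = np.column_stack([np.interp(tq, trial.t_ms, trial.pos[:, k])
                           for k in range(3)])
    out[0], out[-1] = trial.pos[0], trial.pos[-1]
    return out


def extract_parameters(trial: SegmentedTrial, speed: np.ndarray,
                       accel: np.ndarray, *, is_stop: bool,
                       object_depth: float | None = None,
                       collision_radius: float = 0.02,
                       initiation_threshold: float = 0.01) -> dict:
    """Per-trial biometric parameter record (times relative to stimulus onset)."""
    t = trial.t_ms
    i_pv = int(np.argmax(speed))
    i_pa = int(np.argmax(accel))
    rec = {
        "pv": float(speed[i_pv]), "ttpv": float(t[i_pv]),
        "pa": float(accel[i_pa]), "ttpa": float(t[i_pa]),
        "maxz": float(trial.x1[-1]),
        "rt": float(t[-1]),
        "it": detect_initiation(trial, initiation_threshold),
        "tts": np.nan, "bd": np.nan, "acc": np.nan, "ssd": trial.ssd_ms,
    }
    if is_stop:
        if not np.isfinite(trial.stop_onset_ms):
            raise ValueError("stop trial without stop_signal_onset")
        x_at_stop = float(np.interp(trial.stop_onset_ms, t, trial.x1))
        rec["tts"] = float(t[-1] - trial.stop_onset_ms)
        rec["bd"] = float(trial.x1[-1] - x_at_stop)
        if object_depth is not None:
            rec["acc"] = float(rec["maxz"] < object_depth - collision_radius)
    return rec


# -- batch driver -------------------------------------------------------------


def _iter_trials(trials: pd.DataFrame):
    """Yield (pid, idx, meta, t_ms, xyz) per trial via numpy slicing.

    Equivalent to a participant/trial groupby but without per-group pandas
    overhead, which dominates on cohorts with tens of thousands of trials.
    """
    pid = trials["participant_id"].to_numpy()
    idx = trials["trial_index"].to_numpy()
    t = trials["t_ms"].to_numpy(dtype=float)
    order = np.lexsort((t, idx, pid))
    pid, idx, t = pid[order], idx[order], t[order]
    xyz = trials[["x1_m", "x2_m", "x3_m"]].to_numpy(dtype=float)[order]
    meta_cols = {}
    for c in ("category", "trial_type", "stop_onset_ms", "ssd_ms"):
        if c in trials.columns:
            meta_cols[c] = trials[c].to_numpy()[order]
    new = np.flatnonzero((pid[1:] != pid[:-1]) | (idx[1:] != idx[:-1])) + 1
    bounds = np.concatenate([[0], new, [len(pid)]])
    for a, b in zip(bounds[:-1], bounds[1:]):
        meta = {c: v[a] for c, v in meta_cols.items()}
        yield pid[a], idx[a], meta, t[a:b], xyz[a:b]


#: Variables entering outlier filtering and cell aggregation.
PARAMETER_COLUMNS = ("pv", "pa", "ttpv", "ttpa", "tts", "bd", "maxz",
                     "acc", "it", "ssd", "rt")


def extract_trials(trials: pd.DataFrame, *, window: int = 5,
                   object_depth: float | None = None,
                   collision_radius: float = 0.02,
                   initiation_threshold: float = 0.01,
                   depth_only: bool = False,
                   correct_stops_only: bool = True):
    """Run the full extraction on a long-format sample table.

    ``trials`` needs columns participant_id, trial_index, category,
    trial_type, t_ms, x1_m, x2_m, x3_m and (for stop trials) stop_onset_ms /
    ssd_ms.  Returns ``(records, log)``: one parameter row per usable trial
    and a list of messages for trials that were flagged unusable.

    With ``correct_stops_only`` (the default) the kinematic parameters of
    failed stop trials are masked to NaN — stopping latency, braking
    distance and displacement are only meaningful where the stop succeeded,
    and averaging completed reaches into them would inflate every stop-trial
    cell mean.  Stop accuracy, SSD and initiation time stay available on all
    stop trials.
    """
    records, log = [], []
    for pid, idx, meta, t, xyz in _iter_trials(trials):
        is_stop = meta["trial_type"] == "stop"
        try:
            seg = center_and_segment(
                t, xyz,
                stop_onset_ms=meta.get("stop_onset_ms", np.nan),
                ssd_ms=meta.get("ssd_ms", np.nan))
            speed, accel = compute_velocity_acceleration(seg, window=window,
                                                         depth_only=depth_only)
            rec = extract_parameters(
                seg, speed, accel, is_stop=is_stop,
                object_depth=object_depth, collision_radius=collision_radius,
                initiation_threshold=initiation_threshold)
        except TrialUnusable as e:
            log.append(f"{pid} trial {idx}: {e}")
            continue
        if correct_stops_only and is_stop and rec["acc"] == 0.0:
            for var in ("pv", "pa", "ttpv", "ttpa", "tts", "bd", "maxz", "rt"):
                rec[var] = np.nan
        rec.update(participant_id=pid, trial_index=idx,
                   category=meta["category"], trial_type=meta["trial_type"])
        records.append(rec)
    cols = ["participant_id", "trial_index", "category", "trial_type",
            *PARAMETER_COLUMNS]
    return pd.DataFrame(records, columns=cols), log


def zscore_filter(values: np.ndarray, z_cut: float = 2.5) -> np.ndarray:
    """Boolean keep-mask of a single-pass z-score outlier filter.

    Sample SD (n-1 denominator); a zero-SD or length<2 cell removes nothing.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        return np.ones(v.size, dtype=bool)
    m, s = v.mean(), v.std(ddof=1)
    if s == 0:
        return np.ones(v.size, dtype=bool)
    return np.abs(v - m) <= z_cut * s


def filter_and_aggregate(records: pd.DataFrame, z_cut: float = 2.5,
                         min_trials: int = 5,
                         variables=PARAMETER_COLUMNS) -> pd.DataFrame:
    """Outlier-filtered cell means, tidy long format.

    Within each participant x category x trial-type cell and per variable,
    values more than ``z_cut`` sample SDs from the cell mean are removed in a
    single pass before averaging.  Cells with fewer than ``min_trials``
    usable values are flagged.
    """
    if z_cut <= 0:
        raise ValueError("z_cut must be positive")
    rows = []
    for (pid, cat, ttype), g in records.groupby(
            ["participant_id", "category", "trial_type"], sort=True):
        for var in variables:
            vals = g[var].dropna().to_numpy(dtype=float)
            if vals.size == 0:
                continue
            keep = zscore_filter(vals, z_cut)
            used = vals[keep]
            rows.append({
                "participant_id": pid, "category": cat, "trial_type": ttype,
                "variable": var, "mean": used.mean(),
                "n_trials_used": int(used.size), "n_trials": int(vals.size),
                "low_n": bool(used.size < min_trials),
            })
    return pd.DataFrame(rows)


def cell_means(summary: pd.DataFrame, variable: str) -> pd.DataFrame:
    """Wide participant x (category, trial_type) table of one variable's means."""
    sub = summary[summary["variable"] == variable]
    return sub.pivot_table(index="participant_id",
                           columns=["category", "trial_type"],
                           values="mean")
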