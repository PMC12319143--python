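"""Dwell-time analysis of gaze--AOI collision streams.

The eye tracker reports, per trajectory sample, whether the gaze vector
collides with the stimulus area of interest.  First dwell time is the
duration of the first contiguous hit-run (stimulus onset until the first
gaze detachment); total dwell time sums all hit-runs in the trial.  Short
tracker dropouts (gaps up to ``dropout_tolerance`` samples) are bridged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class GazeSummary:
    dwell_first_ms: float
    dwell_total_ms: float
    n_fixation_bouts: int
    no_fixation: bool = False


def _hit_runs(hits: np.ndarray, tolerance: int) -> list[tuple[int, int]]:
    """(start, length) of hit-runs after bridging gaps <= tolerance samples."""
    runs: list[tuple[int, int]] = []
    n = hits.size
    i = 0
    while i < n:
        if not hits[i]:
            i += 1
            continue
        start = i
        last_hit = i
        j = i + 1
        while j < n:
            if hits[j]:
                last_hit = j
            elif j - last_hit > tolerance:
                break
            j += 1
        runs.append((start, last_hit - start + 1))
        i = last_hit + 1
    return runs


def compute_dwell(gaze_hits, sample_period_ms: float,
                  dropout_tolerance: int = 1) -> GazeSummary:
    """Dwell summary of one trial's boolean gaze stream.

    Durations are run length x sample period; bridged dropout samples count
    as part of their run.  An all-miss stream yields zeros with a flag.
    """
    if dropout_tolerance < 0:
        raise ValueError("dropout_tolerance must be >= 0")
    hits = np.asarray(gaze_hits, dtype=bool)
    runs = _hit_runs(hits, dropout_tolerance)
    if not runs:
        return GazeSummary(0.0, 0.0, 0, no_fixation=True)
    total = sum(length for _, length in runs) * sample_period_ms
    first = runs[0][1] * sample_period_ms
    return GazeSummary(first, total, len(runs))


def extract_gaze(trials: pd.DataFrame, sample_period_ms: float,
                 dropout_tolerance: int = 1) -> pd.DataFrame:
    """Per-trial dwell records from the long-format sample table."""
    rows = []
    for (pid, idx), g in trials.groupby(["participant_id", "trial_index"],
                                        sort=True):
        s = compute_dwell(g["gaze_hit"].to_numpy(), sample_period_ms,
                          dropout_tolerance)
        rows.append({
            "participant_id": pid, "trial_index": idx,
            "category": g["category"].iloc[0],
            "trial_type": g["trial_type"].iloc[0],
            "dwell_first": s.dwell_first_ms, "dwell_total": s.dwell_total_ms,
            "n_fixation_bouts": s.n_fixation_bouts,
            "no_fixation": s.no_fixation,
        })
    return pd.DataFrame(rows)
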