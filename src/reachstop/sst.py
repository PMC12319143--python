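"""Stop-signal task scoring: SSRT by the integration method.

Under the horse-race model the stop-signal reaction time is estimated per
category as the p-th quantile of the go-RT distribution minus the mean
stop-signal delay, where p is the probability of responding on stop trials.
Go omissions are replaced by the maximum go RT before taking the quantile
(integration method with replacement of response omissions).  A session is
flagged invalid when the tracking assumption fails: stop-response rate
outside [0.25, 0.75], or mean signal-respond RT exceeding mean go RT (race
violation).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class SSTResult:
    category: str
    ssrt: float               # ms; NaN when invalid
    go_rt_mean: float
    ssd_mean: float
    p_respond_stop: float
    n_go: int
    n_stop: int
    valid: bool
    invalid_reason: str       # stop_prob_out_of_band | race_violation | none


def estimate_ssrt(session: pd.DataFrame, category: str,
                  p_band: tuple[float, float] = (0.25, 0.75),
                  include_choice_errors: bool = True) -> SSTResult:
    """Integration-method SSRT for one category of one session.

    ``session`` needs columns trial_type, category, rt_ms, responded, ssd_ms.
    Raises ValueError if the category has no stop or no go trials.
    """
    sub = session[session["category"] == category]
    go = sub[sub["trial_type"] == "go"]
    stop = sub[sub["trial_type"] == "stop"]
    if len(stop) == 0 or len(go) == 0:
        raise ValueError(f"category {category!r} needs >=1 go and >=1 stop trial")
    if not include_choice_errors and "correct" in go:
        go = go[go["responded"].astype(bool) & go["correct"].astype(bool)
                | ~go["responded"].astype(bool)]

    responded = go["responded"].astype(bool).to_numpy()
    go_rts = go["rt_ms"].to_numpy(dtype=float)
    observed = go_rts[responded & np.isfinite(go_rts)]
    if observed.size == 0:
        raise ValueError("no observed go RTs")
    # replace omissions with the maximum observed go RT
    filled = np.concatenate([observed,
                             np.full((~responded).sum(), observed.max())])
    filled.sort()

    p = float(stop["responded"].astype(bool).mean())
    ssd_mean = float(stop["ssd_ms"].mean())
    go_rt_mean = float(observed.mean())

    reason = "none"
    if not p_band[0] <= p <= p_band[1]:
        reason = "stop_prob_out_of_band"
    else:
        sr = stop.loc[stop["responded"].astype(bool), "rt_ms"].to_numpy(float)
        if sr.size and np.nanmean(sr) > go_rt_mean:
            reason = "race_violation"
    valid = reason == "none"

    ssrt = np.nan
    if valid:
        n = min(max(math.ceil(p * filled.size), 1), filled.size)
        ssrt = float(filled[n - 1] - ssd_mean)
    return SSTResult(category=category, ssrt=ssrt, go_rt_mean=go_rt_mean,
                     ssd_mean=ssd_mean, p_respond_stop=p,
                     n_go=int(filled.size), n_stop=int(len(stop)),
                     valid=valid, invalid_reason=reason)


def score_sessions(sst_trials: pd.DataFrame,
                   categories=("chocolate", "neutral")) -> pd.DataFrame:
    """Per-participant, per-category SSRT table with validity flags."""
    rows = []
    for pid, g in sst_trials.groupby("participant_id", sort=True):
        for cat in categories:
            r = estimate_ssrt(g, cat)
            rows.append({"participant_id": pid, **r.__dict__})
    return pd.DataFrame(rows)
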