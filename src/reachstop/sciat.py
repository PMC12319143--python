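"""Single-category IAT scoring (standardized difference score).

The D-score contrasts the chocolate+approach (compatible) and
chocolate+avoidance (incompatible) test blocks following the improved
scoring algorithm conventions: trials above 10 s are discarded, a
participant is rejected when more than 10% of trials are faster than 300 ms
or overall accuracy is too low, error-trial RTs are replaced by the block's
correct-RT mean plus a 600 ms penalty, and

    d = (mean_incompatible - mean_compatible) / pooled SD,

with the pooled SD taken over all correct and penalized RTs of both blocks.
A negative d means the avoidance pairing was answered faster.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

BLOCKS = ("compatible", "incompatible")


@dataclass
class DScoreRules:
    rt_cap_ms: float = 10_000.0
    fast_rt_ms: float = 300.0
    max_fast_fraction: float = 0.10
    min_accuracy: float = 0.70
    error_penalty_ms: float = 600.0
    test_phase_only: bool = True


@dataclass
class DScoreResult:
    d: float
    valid: bool
    invalid_reason: str   # fast_trials | low_accuracy | empty_block | none
    mean_compatible: float = np.nan
    mean_incompatible: float = np.nan
    pooled_sd: float = np.nan


def compute_dscore(session: pd.DataFrame,
                   rules: DScoreRules | None = None) -> DScoreResult:
    """D-score of one session (columns: block, phase, rt_ms, correct)."""
    rules = rules or DScoreRules()
    s = session
    if rules.test_phase_only and "phase" in s:
        s = s[s["phase"] == "test"]
    s = s[s["rt_ms"] <= rules.rt_cap_ms]
    if len(s) == 0:
        return DScoreResult(np.nan, False, "empty_block")

    fast_frac = float((s["rt_ms"] < rules.fast_rt_ms).mean())
    if fast_frac > rules.max_fast_fraction:
        return DScoreResult(np.nan, False, "fast_trials")
    if float(s["correct"].astype(bool).mean()) < rules.min_accuracy:
        return DScoreResult(np.nan, False, "low_accuracy")

    penalized = {}
    for block in BLOCKS:
        b = s[s["block"] == block]
        correct = b.loc[b["correct"].astype(bool), "rt_ms"].to_numpy(float)
        if correct.size == 0:
            return DScoreResult(np.nan, False, "empty_block")
        rts = b["rt_ms"].to_numpy(dtype=float).copy()
        rts[~b["correct"].astype(bool).to_numpy()] = \
            correct.mean() + rules.error_penalty_ms
        penalized[block] = rts

    pooled = np.concatenate([penalized[b] for b in BLOCKS])
    sd = float(np.std(pooled, ddof=1))
    if sd == 0:
        return DScoreResult(0.0, True, "none",
                            float(penalized["compatible"].mean()),
                            float(penalized["incompatible"].mean()), 0.0)
    m_c = float(penalized["compatible"].mean())
    m_i = float(penalized["incompatible"].mean())
    return DScoreResult((m_i - m_c) / sd, True, "none", m_c, m_i, sd)


def score_sessions(iat_trials: pd.DataFrame,
                   rules: DScoreRules | None = None) -> pd.DataFrame:
    """Per-participant D-score table with validity flags."""
    rows = []
    for pid, g in iat_trials.groupby("participant_id", sort=True):
        r = compute_dscore(g, rules)
        rows.append({"participant_id": pid, "d_score": r.d,
                     "valid": r.valid, "invalid_reason": r.invalid_reason,
                     "mean_compatible": r.mean_compatible,
                     "mean_incompatible": r.mean_incompatible,
                     "pooled_sd": r.pooled_sd})
    return pd.DataFrame(rows)
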