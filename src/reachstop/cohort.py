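"""Synthetic study generator.

Produces a complete synthetic cohort for a VR reach-to-grasp stop-signal
experiment with an ad-libitum chocolate intake outcome: participant tables,
per-sample 3D hand trajectories with gaze--AOI collision streams, web-based
stop-signal and single-category IAT trial tables, and a ground-truth record
for every generated quantity so downstream extraction can be validated by
parameter recovery.

The kinematic model is a minimum-jerk reach along the depth axis

    x1(t) = D * (10 tau^3 - 15 tau^4 + 6 tau^5),   tau = (t - IT) / T,

whose speed peaks at 1.875 * D / T (tau = 0.5) and whose acceleration peaks
at (10 / sqrt(3)) * D / T^2.  On stop trials a stop signal is scheduled at
movement initiation plus the current stop-signal delay (SSD, adaptive
staircase); if the sampled stopping latency brakes the hand before it enters
the object's collision radius the stop succeeds (depth velocity decays
linearly to zero over the stopping latency), otherwise the reach completes.

Intake (kcal) is generated from a known sparse linear model over the
standardized true per-participant features, which makes support-recovery
tests of the downstream feature-selection stage possible.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import CATEGORIES, PREDICTORS, StudyConfig

# -- minimum-jerk primitives (tau in [0, 1]; position in units of D,
#    velocity in D/T, acceleration in D/T^2) --------------------------------

PEAK_VELOCITY_COEF = 1.875
PEAK_ACCELERATION_COEF = 10.0 / np.sqrt(3.0)


def minjerk_position(tau):
    tau = np.clip(tau, 0.0, 1.0)
    return 10 * tau**3 - 15 * tau**4 + 6 * tau**5


def minjerk_velocity(tau):
    tau = np.clip(tau, 0.0, 1.0)
    return 30 * tau**2 - 60 * tau**3 + 30 * tau**4


def minjerk_acceleration(tau):
    tau = np.clip(tau, 0.0, 1.0)
    return 60 * tau - 180 * tau**2 + 120 * tau**3


# -- population norms used both for drawing latents and for standardizing
#    the true features inside the intake model (mean, sd) -------------------

POPULATION_NORMS: dict[str, tuple[float, float]] = {
    "fcq_trait": (58.74, 9.93),
    "fcq_state": (51.21, 12.18),
    "bis15": (25.2, 5.9),
    "ssrt_choc": (326.0, 68.0),
    "rt_go": (693.0, 154.0),
    "ssd_mean": (367.0, 173.0),
    "fa_rate": (0.46, 0.05),
    "d_score": (-0.137, 0.22),
    "pv_choc": (2.09, 0.31),
    "pa_choc": (12.85, 3.7),
    "tts_choc": (247.0, 25.0),
    "bd_choc": (0.10, 0.02),
    "maxz_choc": (0.546, 0.031),
    "it_choc": (300.0, 40.0),
    "dwell_first_choc": (396.0, 105.0),
    "dwell_total_choc": (677.0, 174.0),
}


#: Between-participant SD of the chocolate-minus-neutral category effects
#: (same units as the corresponding CategoryEffects field).  Constant shifts
#: for everyone would make paired contrasts implausibly clean; this spread
#: puts the group-level t statistics in a realistic range.
EFFECT_HETEROGENEITY_SD = {"tts": 35.0, "dwell_first": 75.0,
                           "dwell_total": 120.0}

#: Hand retraction after the movement ends (placing/withdrawing), m/s.
#: Gives the depth profile a sharp, noise-robust maximum.
RETRACT_SPEED = 0.15
RETRACT_MAX_M = 0.04


# -- screening ---------------------------------------------------------------


@dataclass
class ScreeningRules:
    """Eligibility gates applied to the recruitment survey.

    Trait chocolate craving must exceed the pilot-sample median (37); BMI and
    age windows and the right-handedness cutoff follow the study's exclusion
    criteria.
    """

    fcq_trait_min_exclusive: float = 37.0
    bmi_range: tuple[float, float] = (18.5, 29.9)
    age_range: tuple[float, float] = (18.0, 35.0)
    handedness_min_exclusive: float = 50.0

    required_fields = ("age", "bmi", "handedness_score", "fcq_trait")


def screen_participants(candidates: pd.DataFrame,
                        rules: ScreeningRules | None = None,
                        ) -> tuple[pd.DataFrame, list[str]]:
    """Filter a candidate table to eligible participants, order preserved.

    Returns the kept rows and a log of per-candidate rejection reasons.
    Candidates with a missing required field are rejected and logged.
    """
    rules = rules or ScreeningRules()
    keep_mask = []
    log: list[str] = []
    for _, row in candidates.iterrows():
        cid = row.get("id", "?")
        missing = [f for f in rules.required_fields
                   if f not in row or pd.isna(row[f])]
        if missing:
            log.append(f"candidate {cid}: missing field(s) {missing}")
            keep_mask.append(False)
            continue
        reasons = []
        if not row["fcq_trait"] > rules.fcq_trait_min_exclusive:
            reasons.append(f"fcq_trait {row['fcq_trait']} <= "
                           f"{rules.fcq_trait_min_exclusive}")
        if not rules.bmi_range[0] <= row["bmi"] <= rules.bmi_range[1]:
            reasons.append(f"bmi {row['bmi']} outside {rules.bmi_range}")
        if not rules.age_range[0] <= row["age"] <= rules.age_range[1]:
            reasons.append(f"age {row['age']} outside {rules.age_range}")
        if not row["handedness_score"] > rules.handedness_min_exclusive:
            reasons.append(f"handedness {row['handedness_score']} <= "
                           f"{rules.handedness_min_exclusive}")
        if reasons:
            log.append(f"candidate {cid}: " + "; ".join(reasons))
        keep_mask.append(not reasons)
    return candidates.loc[keep_mask].copy(), log


def draw_candidates(n: int, rng: np.random.Generator) -> pd.DataFrame:
    """Draw an unscreened recruitment-survey population (wider than eligible)."""
    return pd.DataFrame({
        "id": [f"C{i:03d}" for i in range(n)],
        "age": rng.uniform(16, 40, n).round(0),
        "bmi": rng.normal(23.5, 3.5, n).round(1),
        "handedness_score": rng.integers(-100, 101, n).astype(float),
        "fcq_trait": rng.integers(20, 81, n).astype(float),
    })


# -- participant latents and the true feature table --------------------------


def _draw(rng, name, n, lo=None, hi=None):
    m, s = POPULATION_NORMS[name]
    x = rng.normal(m, s, n)
    if lo is not None or hi is not None:
        x = np.clip(x, lo, hi)
    return x


def generate_feature_table(config: StudyConfig,
                           rng: np.random.Generator) -> pd.DataFrame:
    """Per-participant true features plus intake generated from them.

    Intake: ``intercept + sum_j w_j * z_j + N(0, noise_sd)`` floored at 0 kcal,
    where z_j standardizes feature j by its population norm, so weights read
    as kcal per population SD.  Also carries the generator latents needed to
    synthesize trajectories and task sessions conditioned on these features.
    """
    n = config.n_participants
    eff = config.category_effects
    t = pd.DataFrame({"id": [f"P{i:03d}" for i in range(n)]})

    t["age"] = np.round(rng.normal(22.85, 3.73, n).clip(18, 35), 0)
    t["bmi"] = np.round(rng.normal(22.55, 2.66, n).clip(18.5, 29.9), 1)
    t["handedness_score"] = rng.integers(55, 101, n).astype(float)

    t["fcq_trait"] = np.round(_draw(rng, "fcq_trait", n, 38, 90))
    t["fcq_state"] = np.round(_draw(rng, "fcq_state", n, 15, 90))
    t["bis15"] = np.round(_draw(rng, "bis15", n, 15, 60))

    t["ssrt_choc"] = _draw(rng, "ssrt_choc", n, 150, 600)
    t["ssrt_neutral"] = t["ssrt_choc"] - 6.0
    t["rt_go"] = _draw(rng, "rt_go", n, 350, 1200)
    t["rt_go_neutral"] = t["rt_go"] - 34.0
    # race equilibrium plus staircase wander
    t["ssd_mean"] = t["rt_go"] - t["ssrt_choc"] + rng.normal(0, 40, n)
    t["fa_rate"] = _draw(rng, "fa_rate", n, 0.30, 0.65)
    t["d_score"] = _draw(rng, "d_score", n)

    # Chocolate latents are primary draws (they enter the intake model with
    # the population norms above); the neutral condition is the chocolate
    # value minus a per-participant category effect whose mean comes from
    # the config and whose between-participant spread makes group-level
    # paired contrasts realistically noisy.
    t["pv_choc"] = _draw(rng, "pv_choc", n, 1.3, 3.0)
    t["pv_neutral"] = t["pv_choc"] - eff.pv
    D = config.object_depth
    for cat in CATEGORIES:
        key = "choc" if cat == "chocolate" else "neutral"
        t[f"t_reach_{key}"] = 1000.0 * PEAK_VELOCITY_COEF * D / t[f"pv_{key}"]  # ms
    t["pa_choc"] = PEAK_ACCELERATION_COEF * D / (t["t_reach_choc"] / 1000.0) ** 2

    het = EFFECT_HETEROGENEITY_SD
    t["tts_choc"] = _draw(rng, "tts_choc", n, 150, 400)
    t["tts_neutral"] = np.clip(
        t["tts_choc"] - rng.normal(eff.tts, het["tts"], n), 120, 450)
    t["bd_choc"] = _draw(rng, "bd_choc", n, 0.02, 0.25)
    t["maxz_choc"] = _draw(rng, "maxz_choc", n, 0.40, config.object_depth)
    t["it_choc"] = _draw(rng, "it_choc", n, 150, 500)
    t["it_neutral"] = t["it_choc"]

    t["dwell_first_choc"] = _draw(rng, "dwell_first_choc", n, 80, 900)
    t["dwell_first_neutral"] = np.clip(
        t["dwell_first_choc"]
        - rng.normal(eff.dwell_first, het["dwell_first"], n), 60, 900)
    t["dwell_total_choc"] = np.maximum(
        _draw(rng, "dwell_total_choc", n, 150, 1600),
        t["dwell_first_choc"])
    t["dwell_total_neutral"] = np.maximum(
        t["dwell_total_choc"]
        - rng.normal(eff.dwell_total, het["dwell_total"], n),
        t["dwell_first_neutral"])

    im = config.intake_model
    expected = np.full(n, float(im.intercept))
    for name, w in im.true_weights.items():
        if w == 0:
            continue
        m, s = POPULATION_NORMS[name]
        expected = expected + w * (t[name].to_numpy() - m) / s
    t["intake_expected"] = expected
    t["intake_kcal"] = np.maximum(
        expected + rng.normal(0, im.noise_sd, n), 0.0)
    return t


# -- single VR trial ----------------------------------------------------------


def generate_vr_trial(participant, category: str, trial_type: str,
                      config: StudyConfig, rng: np.random.Generator,
                      *, ssd_ms: float | None = None,
                      it_ms: float | None = None,
                      t_reach_ms: float | None = None,
                      stop_lat_ms: float | None = None,
                      noise_sd: float | None = None,
                      with_gaze: bool = True):
    """Synthesize one trial's sample block and its ground truth.

    Returns ``(samples, ground_truth)`` where ``samples`` is a dict of equal
    length arrays (t_ms, x1_m, x2_m, x3_m, gaze_hit) and ``ground_truth``
    records every latent used (initiation time, reach duration, stopping
    latency, stop success, analytic peak velocity, realized dwell times ...).
    For stop trials the stop signal is scheduled at the true initiation time
    plus ``ssd_ms``; the stop succeeds iff the braked hand halts before the
    object's collision radius.
    """
    key = "choc" if category == "chocolate" else "neutral"
    D = config.object_depth
    dt = config.sample_period_ms
    noise = config.position_noise_sd if noise_sd is None else noise_sd

    it = float(it_ms if it_ms is not None
               else max(rng.normal(participant[f"it_{key}"], 30.0), 100.0))
    T = float(t_reach_ms if t_reach_ms is not None
              else max(participant[f"t_reach_{key}"] * rng.normal(1.0, 0.05),
                       200.0))
    if T <= 0:
        raise ValueError("non-positive reach duration")

    is_stop = trial_type == "stop"
    success = None
    stop_onset = bd_true = maxz_true = tts_true = np.nan
    L = np.nan
    if is_stop:
        if ssd_ms is None:
            raise ValueError("stop trial requires ssd_ms")
        L = float(stop_lat_ms if stop_lat_ms is not None
                  else max(rng.normal(participant[f"tts_{key}"], 40.0), 60.0))
        if L < 0:
            raise ValueError("negative stop latency")
        stop_onset = it + ssd_ms
        tau_s = min(ssd_ms / T, 1.0)
        x_s = D * float(minjerk_position(tau_s))
        v_s = (D / (T / 1000.0)) * float(minjerk_velocity(tau_s))  # m/s
        halt_depth = x_s + v_s * (L / 1000.0) / 2.0
        success = bool(halt_depth < D - config.collision_radius
                       and tau_s < 1.0)
        if success:
            bd_true = v_s * (L / 1000.0) / 2.0
            maxz_true = x_s + bd_true
            tts_true = L

    tail = 200.0
    if is_stop and success:
        dur = stop_onset + L + tail
    else:
        dur = it + T + tail
    n = int(np.floor(dur / dt)) + 1
    t = np.arange(n) * dt

    tau = (t - it) / T
    x1 = D * minjerk_position(tau)
    if is_stop and success:
        brake = t > stop_onset
        u = (t[brake] - stop_onset) / 1000.0  # s
        Ls = L / 1000.0
        if Ls > 0:
            xb = x_s + v_s * (u - u**2 / (2.0 * Ls))
            xb[u >= Ls] = x_s + v_s * Ls / 2.0
        else:                      # immediate halt at the stop-onset position
            xb = np.full(u.shape, x_s)
        x1 = x1.copy()
        x1[brake] = xb

    # retraction after the movement ends keeps the depth maximum sharp
    t_end = stop_onset + L if (is_stop and success) else it + T
    after = t > t_end
    x1[after] -= np.minimum(RETRACT_SPEED * (t[after] - t_end) / 1000.0,
                            RETRACT_MAX_M)

    prog = np.clip(x1, 0.0, None) / D
    x2 = 0.02 * np.sin(np.pi * prog)   # small lateral arc toward the plate
    x3 = 0.05 * prog                   # start slightly below the target height
    if noise > 0:
        x1 = x1 + rng.normal(0, noise, n)
        x2 = x2 + rng.normal(0, noise, n)
        x3 = x3 + rng.normal(0, noise, n)
    # centring contract: the recording starts exactly at the origin
    x1[0], x2[0], x3[0] = 0.0, 0.0, 0.0

    gaze = np.zeros(n, dtype=bool)
    d1_true = dtot_true = 0.0
    if with_gaze:
        d1 = max(participant[f"dwell_first_{key}"] + rng.normal(0, 30.0),
                 2 * dt)
        extra = max(participant[f"dwell_total_{key}"]
                    - participant[f"dwell_first_{key}"]
                    + (120.0 if is_stop else 0.0) + rng.normal(0, 40.0), 0.0)
        k1 = min(int(round(d1 / dt)), n)
        gap = 3  # > default dropout tolerance, so detachment is detectable
        k2 = min(int(round(extra / dt)), max(n - k1 - gap, 0))
        gaze[:k1] = True
        if k2 > 0:
            gaze[k1 + gap:k1 + gap + k2] = True
        d1_true = k1 * dt
        dtot_true = (k1 + k2) * dt

    samples = {"t_ms": t, "x1_m": x1, "x2_m": x2, "x3_m": x3,
               "gaze_hit": gaze}
    gt = {
        "category": category, "trial_type": trial_type,
        "it_true_ms": it, "t_reach_ms": T,
        "ssd_ms": float(ssd_ms) if is_stop else np.nan,
        "stop_onset_ms": stop_onset,
        "stop_lat_ms": L, "stop_success": success,
        "tts_true_ms": tts_true, "bd_true_m": bd_true,
        "maxz_true_m": maxz_true if is_stop else D,
        "pv_true": PEAK_VELOCITY_COEF * D / (T / 1000.0),
        "pa_true": PEAK_ACCELERATION_COEF * D / (T / 1000.0) ** 2,
        "dwell_first_true_ms": d1_true, "dwell_total_true_ms": dtot_true,
    }
    return samples, gt


# -- trial schedules and sessions ---------------------------------------------


def _balanced_schedule(config: StudyConfig, rng: np.random.Generator):
    """Random trial order with exact go/stop x category counts."""
    cells = []
    for ttype, total in (("go", config.n_go_trials),
                         ("stop", config.n_stop_trials)):
        per_cat = total // 2
        for cat in CATEGORIES:
            cells += [(cat, ttype)] * per_cat
    order = rng.permutation(len(cells))
    return [cells[i] for i in order]


def generate_participant_trials(pid: str, participant, config: StudyConfig,
                                rng: np.random.Generator):
    """All VR trials for one participant.

    A single SSD staircase spans both stimulus categories (the delay adapts
    to the participant's stopping, not to the stimulus), so category
    contrasts in stop-trial kinematics are not confounded by diverging
    per-category delay equilibria.
    """
    ssd = config.vr_ssd_start
    blocks, gts = [], []
    for idx, (cat, ttype) in enumerate(_balanced_schedule(config, rng)):
        kwargs = {}
        if ttype == "stop":
            kwargs["ssd_ms"] = ssd
        samples, gt = generate_vr_trial(participant, cat, ttype, config, rng,
                                        **kwargs)
        if ttype == "stop":
            if gt["stop_success"]:
                ssd = min(ssd + config.vr_ssd_step_up, config.vr_ssd_max)
            else:
                ssd = max(ssd - config.vr_ssd_step_down, config.vr_ssd_min)
        n = len(samples["t_ms"])
        blocks.append({
            "participant_id": np.repeat(pid, n),
            "trial_index": np.repeat(idx, n),
            "category": np.repeat(cat, n),
            "trial_type": np.repeat(ttype, n),
            **samples,
            "ssd_ms": np.repeat(gt["ssd_ms"], n),
            "stop_onset_ms": np.repeat(gt["stop_onset_ms"], n),
        })
        gt.update(participant_id=pid, trial_index=idx)
        gts.append(gt)
    cols = list(blocks[0].keys())
    trials = pd.DataFrame({c: np.concatenate([b[c] for b in blocks])
                           for c in cols})
    return trials, pd.DataFrame(gts)


def generate_sst_session(pid: str, participant, config: StudyConfig,
                         rng: np.random.Generator) -> pd.DataFrame:
    """Web stop-signal session under the horse-race model.

    Independent go and stop finishing times race on stop trials; SSD follows
    a symmetric +-step staircase per category tracking ~50% stop success.
    """
    n_stop = int(round(config.sst_n_trials * config.sst_stop_fraction))
    n_go = config.sst_n_trials - n_stop
    cells = ([("go", c) for c in CATEGORIES] * (n_go // 2)
             + [("stop", c) for c in CATEGORIES] * (n_stop // 2))
    order = rng.permutation(len(cells))
    ssd = {c: config.sst_ssd_start for c in CATEGORIES}
    rows = []
    for i in order:
        ttype, cat = cells[i]
        key = "choc" if cat == "chocolate" else "neutral"
        rt_mean = participant["rt_go"] if key == "choc" \
            else participant["rt_go_neutral"]
        go_finish = max(rng.normal(rt_mean, 120.0), 150.0)
        if ttype == "go":
            responded = rng.random() >= config.sst_go_omission_rate
            rows.append({"trial_type": "go", "category": cat,
                         "rt_ms": go_finish if responded else np.nan,
                         "responded": responded, "ssd_ms": np.nan,
                         "correct": bool(responded and rng.random() < 0.97)})
        else:
            stop_finish = ssd[cat] + max(
                rng.normal(participant[f"ssrt_{key}"], 50.0), 80.0)
            responded = go_finish < stop_finish
            rows.append({"trial_type": "stop", "category": cat,
                         "rt_ms": go_finish if responded else np.nan,
                         "responded": bool(responded), "ssd_ms": ssd[cat],
                         "correct": not responded})
            if responded:   # failed stop -> make stopping easier
                ssd[cat] = max(ssd[cat] - config.sst_ssd_step, 50.0)
            else:           # successful stop -> make stopping harder
                ssd[cat] = min(ssd[cat] + config.sst_ssd_step, 900.0)
    out = pd.DataFrame(rows)
    out.insert(0, "participant_id", pid)
    return out


def simulate_race_session(rng: np.random.Generator, n_trials: int = 400,
                          stop_fraction: float = 0.25,
                          go_rt_mean: float = 693.0, go_rt_sd: float = 120.0,
                          ssrt_mean: float = 326.0, ssrt_sd: float = 30.0,
                          ssd_start: float = 200.0, ssd_step: float = 50.0,
                          omission_rate: float = 0.02,
                          category: str = "chocolate") -> pd.DataFrame:
    """Single-race stop-signal session for estimator-validation studies.

    Independent normal go and stop finishing times race on stop trials; the
    SSD follows a symmetric staircase tracking 50% stop success.  The true
    stopping latency is ``ssrt_mean``, which the integration method should
    recover from the session it returns.
    """
    n_stop = int(round(n_trials * stop_fraction))
    cells = ["go"] * (n_trials - n_stop) + ["stop"] * n_stop
    order = rng.permutation(n_trials)
    ssd = ssd_start
    rows = []
    for i in order:
        go_finish = max(rng.normal(go_rt_mean, go_rt_sd), 150.0)
        if cells[i] == "go":
            responded = rng.random() >= omission_rate
            rows.append({"trial_type": "go", "category": category,
                         "rt_ms": go_finish if responded else np.nan,
                         "responded": responded, "ssd_ms": np.nan,
                         "correct": bool(responded)})
        else:
            stop_finish = ssd + max(rng.normal(ssrt_mean, ssrt_sd), 80.0)
            responded = go_finish < stop_finish
            rows.append({"trial_type": "stop", "category": category,
                         "rt_ms": go_finish if responded else np.nan,
                         "responded": bool(responded), "ssd_ms": ssd,
                         "correct": not responded})
            ssd = max(ssd - ssd_step, 50.0) if responded \
                else min(ssd + ssd_step, 900.0)
    return pd.DataFrame(rows)


def generate_iat_session(pid: str, participant, config: StudyConfig,
                         rng: np.random.Generator) -> pd.DataFrame:
    """Single-category IAT session with the participant's true D as latent.

    Block means are separated by ``d_true * sigma_within`` so that the
    standardized difference score recovers ``d_true`` up to sampling noise.
    """
    sigma = 150.0
    base = max(rng.normal(609.0, 80.0), 350.0)
    means = {"compatible": base,
             "incompatible": base + participant["d_score"] * sigma}
    rows = []
    for block in ("compatible", "incompatible"):
        for phase, n in (("practice", config.iat_practice_per_block),
                         ("test", config.iat_trials_per_block)):
            rts = np.maximum(rng.normal(means[block], sigma, n), 250.0)
            errs = rng.random(n) < config.iat_error_rate
            for rt, err in zip(rts, errs):
                rows.append({"block": block, "phase": phase,
                             "rt_ms": float(rt), "correct": bool(~err)})
    out = pd.DataFrame(rows)
    out.insert(0, "participant_id", pid)
    return out


# -- full cohort --------------------------------------------------------------


@dataclass
class CohortData:
    """Everything one synthetic study run produces."""
    config: StudyConfig
    participants: pd.DataFrame
    features_true: pd.DataFrame
    trials: pd.DataFrame
    ground_truth: pd.DataFrame
    sst_trials: pd.DataFrame
    iat_trials: pd.DataFrame

    def write(self, out_dir: str | Path) -> list[Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        written = []
        for name in ("participants", "features_true", "trials",
                     "ground_truth", "sst_trials", "iat_trials"):
            path = out / f"{name}.csv"
            getattr(self, name).to_csv(path, index=False)
            written.append(path)
        cfg_path = out / "config.yaml"
        self.config.save(cfg_path)
        written.append(cfg_path)
        return written


def generate_cohort(config: StudyConfig,
                    with_trajectories: bool = True) -> CohortData:
    """Generate the full synthetic study for ``config`` (deterministic in
    ``config.rng_seed``).

    ``with_trajectories=False`` skips the per-sample VR data (fast path for
    feature-level simulations); trial tables for the web tasks and the true
    feature table are always produced.
    """
    rng = np.random.default_rng(config.rng_seed)
    features = generate_feature_table(config, rng)

    trial_frames, gt_frames, sst_frames, iat_frames = [], [], [], []
    for _, row in features.iterrows():
        pid = row["id"]
        if with_trajectories:
            trials, gts = generate_participant_trials(pid, row, config, rng)
            trial_frames.append(trials)
            gt_frames.append(gts)
        sst_frames.append(generate_sst_session(pid, row, config, rng))
        iat_frames.append(generate_iat_session(pid, row, config, rng))

    empty = pd.DataFrame()
    participants = features[["id", "age", "bmi", "handedness_score",
                             "fcq_trait", "fcq_state", "bis15",
                             "intake_kcal"]].copy()
    return CohortData(
        config=config,
        participants=participants,
        features_true=features[["id", *PREDICTORS,
                                "intake_expected", "intake_kcal"]].copy(),
        trials=pd.concat(trial_frames, ignore_index=True)
        if trial_frames else empty,
        ground_truth=pd.concat(gt_frames, ignore_index=True)
        if gt_frames else empty,
        sst_trials=pd.concat(sst_frames, ignore_index=True),
        iat_trials=pd.concat(iat_frames, ignore_index=True),
    )
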