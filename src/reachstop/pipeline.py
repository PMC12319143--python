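"""Pipeline orchestration: simulate -> extract -> score -> analyze -> fit.

Every stage reads and writes plain CSV/JSON/YAML files in a run directory,
so stages can be re-run individually (from the CLI or the analysis scripts)
and the whole chain is reproducible: a run manifest records the config
snapshot, the seed and a SHA-256 digest of every output file, and identical
config+seed yields identical digests.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import generate_cohort
from .config import PREDICTORS, StudyConfig
from .gaze import extract_gaze
from .intake import fit_models, weights_table
from .kinematics import extract_trials, filter_and_aggregate
from .sciat import score_sessions as score_iat_sessions
from .sst import score_sessions as score_sst_sessions
from .stats import compare_conditions, rm_anova_2x2

#: Variables analysed chocolate-vs-neutral in the condition table.
CONDITION_VARIABLES = {
    "pv": ("go", "kinematic"), "pa": ("go", "kinematic"),
    "tts": ("stop", "kinematic"), "maxz": ("stop", "kinematic"),
    "stop_error": ("stop", "kinematic"),
    "dwell_first": ("go", "gaze"), "dwell_total": ("go", "gaze"),
}

#: Variables submitted to the 2x2 Category x Trial-type ANOVA.
ANOVA_VARIABLES = ("maxz", "pv", "dwell_first", "dwell_total")


def _require(stage: str, *paths: Path) -> None:
    for p in paths:
        if not p.exists():
            raise FileNotFoundError(f"stage {stage!r}: missing input {p}")


def stage_simulate(config: StudyConfig, out: Path) -> None:
    data = generate_cohort(config)
    data.write(out)


def stage_extract(config: StudyConfig, out: Path) -> None:
    trials_csv = out / "trials.csv"
    _require("extract", trials_csv)
    trials = pd.read_csv(trials_csv)
    records, log = extract_trials(
        trials, object_depth=config.object_depth,
        collision_radius=config.collision_radius)
    records.to_csv(out / "trial_params.csv", index=False)
    summary = filter_and_aggregate(records)
    summary.to_csv(out / "cell_summary.csv", index=False)
    (out / "extract_log.txt").write_text(
        "\n".join([f"usable trials: {len(records)}", *log]) + "\n")


def stage_gaze(config: StudyConfig, out: Path) -> None:
    trials_csv = out / "trials.csv"
    _require("gaze", trials_csv)
    trials = pd.read_csv(trials_csv)
    per_trial = extract_gaze(trials, config.sample_period_ms)
    per_trial.to_csv(out / "gaze_trials.csv", index=False)
    summary = filter_and_aggregate(per_trial,
                                   variables=("dwell_first", "dwell_total"))
    summary.to_csv(out / "gaze_summary.csv", index=False)


def stage_score_sst(config: StudyConfig, out: Path) -> None:
    sst_csv = out / "sst_trials.csv"
    _require("score-sst", sst_csv)
    results = score_sst_sessions(pd.read_csv(sst_csv))
    results.to_csv(out / "sst_results.csv", index=False)


def stage_score_iat(config: StudyConfig, out: Path) -> None:
    iat_csv = out / "iat_trials.csv"
    _require("score-iat", iat_csv)
    scores = score_iat_sessions(pd.read_csv(iat_csv))
    scores.to_csv(out / "iat_scores.csv", index=False)


def _cell_wide(summary: pd.DataFrame, variable: str,
               trial_type: str) -> pd.DataFrame:
    sub = summary[(summary["variable"] == variable)
                  & (summary["trial_type"] == trial_type)]
    return sub.pivot_table(index="participant_id", columns="category",
                           values="mean")


def assemble_features(out: Path) -> pd.DataFrame:
    """Merge all scored outputs into the per-participant feature table."""
    _require("features", out / "participants.csv", out / "cell_summary.csv",
             out / "gaze_summary.csv", out / "sst_results.csv",
             out / "iat_scores.csv")
    participants = pd.read_csv(out / "participants.csv").set_index("id")
    cells = pd.read_csv(out / "cell_summary.csv")
    gaze = pd.read_csv(out / "gaze_summary.csv")
    sst = pd.read_csv(out / "sst_results.csv")
    iat = pd.read_csv(out / "iat_scores.csv")

    f = participants[["fcq_trait", "fcq_state", "bis15", "intake_kcal"]].copy()

    def cell(variable, trial_type):
        wide = _cell_wide(cells, variable, trial_type)
        return wide["chocolate"] if "chocolate" in wide else pd.Series(dtype=float)

    f["pv_choc"] = cell("pv", "go")
    f["pa_choc"] = cell("pa", "go")
    f["it_choc"] = cell("it", "go")
    f["tts_choc"] = cell("tts", "stop")
    f["bd_choc"] = cell("bd", "stop")
    f["maxz_choc"] = cell("maxz", "stop")
    gw = _cell_wide(gaze, "dwell_first", "go")
    f["dwell_first_choc"] = gw.get("chocolate")
    gw = _cell_wide(gaze, "dwell_total", "go")
    f["dwell_total_choc"] = gw.get("chocolate")

    choc = sst[sst["category"] == "chocolate"].set_index("participant_id")
    f["ssrt_choc"] = choc["ssrt"].where(choc["valid"])
    f["rt_go"] = choc["go_rt_mean"]
    f["ssd_mean"] = choc["ssd_mean"]
    f["fa_rate"] = choc["p_respond_stop"]

    iat = iat.set_index("participant_id")
    f["d_score"] = iat["d_score"].where(iat["valid"])

    f.index.name = "participant_id"
    return f.reset_index()[["participant_id", *PREDICTORS, "intake_kcal"]]


def stage_features(config: StudyConfig, out: Path) -> None:
    assemble_features(out).to_csv(out / "features.csv", index=False)


def stage_stats(config: StudyConfig, out: Path) -> None:
    """Condition comparisons (Table-style) and 2x2 ANOVAs."""
    _require("stats", out / "cell_summary.csv", out / "gaze_summary.csv",
             out / "participants.csv")
    cells = pd.read_csv(out / "cell_summary.csv")
    gaze = pd.read_csv(out / "gaze_summary.csv")
    participants = pd.read_csv(out / "participants.csv").set_index("id")
    intake = participants["intake_kcal"]

    rows = []
    for var, (ttype, source) in CONDITION_VARIABLES.items():
        table = cells if source == "kinematic" else gaze
        if var == "stop_error":
            wide = 1.0 - _cell_wide(table, "acc", ttype)
        else:
            wide = _cell_wide(table, var, ttype)
        if wide.empty or wide.shape[1] < 2:
            continue
        rep = compare_conditions(wide, intake, var)
        rows.append({
            "variable": var, "trial_type": ttype,
            "mean_choc": rep.mean_choc, "sd_choc": rep.sd_choc,
            "mean_neutral": rep.mean_neutral, "sd_neutral": rep.sd_neutral,
            "t": rep.t.statistic, "df": rep.t.df[0], "p": rep.t.p,
            "cohens_d": rep.t.effect_size,
            "r_choc": rep.r_choc.statistic, "p_r_choc": rep.r_choc.p,
            "r_neutral": rep.r_neutral.statistic,
            "p_r_neutral": rep.r_neutral.p,
        })
    pd.DataFrame(rows).to_csv(out / "condition_table.csv", index=False)

    anova = {}
    for var in ANOVA_VARIABLES:
        table = gaze if var.startswith("dwell") else cells
        long = table[table["variable"] == var][
            ["participant_id", "category", "trial_type", "mean"]
        ].rename(columns={"mean": "value"})
        try:
            effects = rm_anova_2x2(long, dv="value")
        except ValueError:
            continue
        anova[var] = {
            key: {"F": rep.statistic, "df": list(rep.df), "p": rep.p,
                  "partial_eta_sq": rep.effect_size, "n": rep.n}
            for key, rep in effects.items()}
    (out / "anova.json").write_text(json.dumps(anova, indent=2))


def stage_fit(config: StudyConfig, out: Path, seed: int,
              folds: int = 5) -> None:
    _require("fit", out / "features.csv")
    features = pd.read_csv(out / "features.csv")
    reports = fit_models(features, cv=folds, seed=seed)
    payload = {name: dataclasses.asdict(rep) for name, rep in reports.items()}
    (out / "fit_reports.json").write_text(json.dumps(payload, indent=2))
    weights_table(reports).to_csv(out / "weights_table.csv", index=False)


STAGES = (
    ("simulate", stage_simulate),
    ("extract", stage_extract),
    ("gaze", stage_gaze),
    ("score-sst", stage_score_sst),
    ("score-iat", stage_score_iat),
    ("features", stage_features),
    ("stats", stage_stats),
)


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: StudyConfig, out_dir: str | Path,
                 seed: int | None = None, folds: int = 5) -> dict:
    """Execute all stages in order and write ``manifest.json``.

    ``seed`` overrides ``config.rng_seed`` and also seeds the CV split of the
    fitting stage.  The manifest's ``digests`` section is a pure function of
    config and seed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if seed is not None:
        config = StudyConfig.from_dict({**config.to_dict(), "rng_seed": seed})
    fit_seed = config.rng_seed

    for name, fn in STAGES:
        fn(config, out)
    stage_fit(config, out, seed=fit_seed, folds=folds)

    digests = {p.name: _digest(p)
               for p in sorted(out.iterdir())
               if p.is_file() and p.name != "manifest.json"}
    manifest = {
        "package_version": __version__,
        "seed": fit_seed,
        "config": config.to_dict(),
        "stages": [name for name, _ in STAGES] + ["fit"],
        "digests": digests,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
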