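"""Study configuration.

A :class:`StudyConfig` bundles every tunable of the synthetic study and of the
downstream extraction/scoring stages, so a run is fully determined by a config
plus a seed.  Defaults mirror the study conditions the pipeline emulates:
400 VR trials per participant, 25% stop trials, two balanced stimulus
categories (chocolate vs. neutral), 120 Hz tracking, and a sparse linear
ground-truth model for ad-libitum chocolate intake in kcal.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

CATEGORIES = ("chocolate", "neutral")

#: Predictor set entering the intake models (one row per participant).
PREDICTORS = (
    "fcq_trait",
    "fcq_state",
    "bis15",
    "ssrt_choc",
    "rt_go",
    "ssd_mean",
    "fa_rate",
    "d_score",
    "pv_choc",
    "pa_choc",
    "tts_choc",
    "bd_choc",
    "maxz_choc",
    "it_choc",
    "dwell_first_choc",
    "dwell_total_choc",
)


@dataclass
class CategoryEffects:
    """Additive chocolate-minus-neutral shifts applied during generation.

    ``pv`` is applied by rescaling reach duration (the kinematic model pins
    peak acceleration to peak velocity, so the PA shift is emergent, not a
    free parameter). ``tts`` shifts the true stopping latency; the dwell
    shifts act on the gaze bout durations. Units: m/s for pv, ms otherwise.
    """

    pv: float = -0.02
    tts: float = -13.0
    dwell_first: float = 107.0
    dwell_total: float = 216.0


@dataclass
class IntakeModel:
    """Sparse linear ground truth for intake (kcal).

    ``true_weights`` maps predictor name -> kcal per population SD of that
    predictor; unnamed predictors have weight zero.  Defaults put signal on
    trait craving, chocolate SSRT and total dwell time with noise_sd chosen
    so the linear signal explains roughly 20% of intake variance.
    """

    intercept: float = 529.0
    true_weights: dict[str, float] = field(
        default_factory=lambda: {
            "fcq_trait": 60.0,
            "ssrt_choc": -60.0,
            "dwell_total_choc": 45.0,
        }
    )
    noise_sd: float = 192.0


@dataclass
class StudyConfig:
    n_participants: int = 72
    n_vr_trials: int = 400
    stop_fraction: float = 0.25
    sample_rate: float = 120.0           # Hz
    object_depth: float = 0.5705         # m, start -> object centre
    collision_radius: float = 0.02       # m, stop counts iff hand stays outside
    position_noise_sd: float = 0.001     # m
    rng_seed: int = 0

    # VR adaptive stop-signal delay staircase (ms). Asymmetric steps hold the
    # per-participant stop-success rate near step_down/(step_up+step_down).
    vr_ssd_start: float = 200.0
    vr_ssd_step_up: float = 25.0
    vr_ssd_step_down: float = 75.0
    vr_ssd_min: float = 50.0
    vr_ssd_max: float = 450.0

    # Web stop-signal task: symmetric staircase tracking ~50% stop success.
    sst_n_trials: int = 400
    sst_stop_fraction: float = 0.25
    sst_ssd_start: float = 200.0
    sst_ssd_step: float = 50.0
    sst_go_omission_rate: float = 0.02

    # Single-category IAT.
    iat_trials_per_block: int = 36
    iat_practice_per_block: int = 12
    iat_error_rate: float = 0.07

    category_effects: CategoryEffects = field(default_factory=CategoryEffects)
    intake_model: IntakeModel = field(default_factory=IntakeModel)

    def __post_init__(self) -> None:
        n_stop = self.n_vr_trials * self.stop_fraction
        if abs(n_stop - round(n_stop)) > 1e-9:
            raise ValueError("n_vr_trials * stop_fraction must be an integer")
        if round(n_stop) % 2 or (self.n_vr_trials - round(n_stop)) % 2:
            raise ValueError("stop and go trial counts must split evenly by category")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if self.object_depth <= 0:
            raise ValueError("object_depth must be positive")

    @property
    def n_stop_trials(self) -> int:
        return round(self.n_vr_trials * self.stop_fraction)

    @property
    def n_go_trials(self) -> int:
        return self.n_vr_trials - self.n_stop_trials

    @property
    def sample_period_ms(self) -> float:
        return 1000.0 / self.sample_rate

    def to_dict(self) -> dict:
        return asdict(self)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        d = dict(d)
        if isinstance(d.get("category_effects"), dict):
            d["category_effects"] = CategoryEffects(**d["category_effects"])
        if isinstance(d.get("intake_model"), dict):
            d["intake_model"] = IntakeModel(**d["intake_model"])
        return cls(**d)

    @classmethod
    def load(cls, path: str | Path) -> "StudyConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))
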