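"""Extract biometric parameters from the simulated hand trajectories.

Segments each trial from stimulus onset to maximal depth displacement,
differentiates the smoothed 3D path, and reads off peak velocity and
acceleration, initiation time, and -- on successful stop trials -- the
direct stopping latency (TTS), braking distance and maximal displacement.
Aggregates to participant x category x trial-type cell means after the
2.5 SD outlier filter.
"""

from pathlib import Path

import pandas as pd

from reachstop import StudyConfig
from reachstop.pipeline import stage_extract

OUT = Path(__file__).resolve().parents[1] / "results" / "run"


def main():
    cfg = StudyConfig.load(OUT / "config.yaml")
    stage_extract(cfg, OUT)
    cells = pd.read_csv(OUT / "cell_summary.csv")
    pv = cells[(cells["variable"] == "pv") & (cells["trial_type"] == "go")]
    tts = cells[(cells["variable"] == "tts")]
    print("per-cell summaries written to cell_summary.csv")
    print(f"go-trial peak velocity, cohort mean: {pv['mean'].mean():.3f} m/s")
    print(f"stopping latency (successful stops): {tts['mean'].mean():.0f} ms")


if __name__ == "__main__":
    main()
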