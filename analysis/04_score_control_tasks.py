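"""Score the web-based control tasks.

Stop-signal sessions are scored per category with the integration method
(go omissions replaced by the maximum go RT; SSRT = p-th go-RT quantile
minus mean SSD), gated on stop probability in [0.25, 0.75] and the race
assumption.  SC-IAT sessions get the standardized D-score with the improved
algorithm's rejection rules; a negative D means the chocolate+avoidance
block was answered faster.
"""

from pathlib import Path

import pandas as pd

from reachstop import StudyConfig
from reachstop.pipeline import stage_score_iat, stage_score_sst

OUT = Path(__file__).resolve().parents[1] / "results" / "run"


def main():
    cfg = StudyConfig.load(OUT / "config.yaml")
    stage_score_sst(cfg, OUT)
    stage_score_iat(cfg, OUT)
    sst = pd.read_csv(OUT / "sst_results.csv")
    iat = pd.read_csv(OUT / "iat_scores.csv")
    choc = sst[sst["category"] == "chocolate"]
    print(f"SSRT (chocolate): {choc['ssrt'].mean():.0f} ms, "
          f"{int(choc['valid'].sum())}/{len(choc)} sessions valid")
    print(f"D-score: mean {iat['d_score'].mean():.3f} "
          f"({int(iat['valid'].sum())}/{len(iat)} valid); negative values "
          "indicate faster avoidance pairing")


if __name__ == "__main__":
    main()
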