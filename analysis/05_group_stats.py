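"""Group-level statistics on the extracted parameters.

Chocolate-vs-neutral condition comparisons (paired t with Cohen's
d = t/sqrt(n)) and raw Pearson correlations with intake for each biometric
parameter, plus 2x2 Category x Trial-type repeated-measures ANOVAs with
partial eta squared on displacement, peak velocity and the dwell measures.
"""

import json
from pathlib import Path

import pandas as pd

from reachstop import StudyConfig
from reachstop.pipeline import stage_features, stage_stats

OUT = Path(__file__).resolve().parents[1] / "results" / "run"


def main():
    cfg = StudyConfig.load(OUT / "config.yaml")
    stage_stats(cfg, OUT)
    stage_features(cfg, OUT)
    table = pd.read_csv(OUT / "condition_table.csv")
    print("condition table (chocolate vs neutral):")
    cols = ["variable", "mean_choc", "mean_neutral", "t", "p", "cohens_d"]
    print(table[cols].round(3).to_string(index=False))
    anova = json.loads((OUT / "anova.json").read_text())
    for var, effects in anova.items():
        cat = effects["category"]
        print(f"ANOVA {var}: category F({cat['df'][0]},{cat['df'][1]}) = "
              f"{cat['F']:.2f}, p = {cat['p']:.4f}, "
              f"eta_p^2 = {cat['partial_eta_sq']:.2f}")


if __name__ == "__main__":
    main()
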