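#!/usr/bin/env python
"""Population summaries over the cohort's per-neuron metrics.

Aggregates the pipeline outputs into the study's headline views: whisking
and running modulation-index distributions, touch-responsive fractions and
percent-suppression medians per layer, perturbation up/down-modulated
fractions, speed-tuning class fractions, and the functional-category
percentages per layer.  Writes results/population_summary.csv and prints
the table.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

PIPE = Path("results/pipeline")
OUT = Path("results/population_summary.csv")


def main():
    rows = []
    report = json.loads((PIPE / "report.json").read_text())
    frames = []
    for sid, summary in report["sessions"].items():
        f = PIPE / sid / "neuron_responses.csv"
        if f.exists():
            df = pd.read_csv(f)
            df["session"] = sid
            df["layer"] = summary["layer"]
            frames.append(df)
    resp = pd.concat(frames, ignore_index=True)
    for layer, grp in resp.groupby("layer"):
        rows += [
            {"layer": layer, "metric": "n_neuron_sessions", "value": len(grp)},
            {"layer": layer, "metric": "whisk_mi_median", "value": grp["whisk_mi"].median()},
            {"layer": layer, "metric": "run_mi_median", "value": grp["run_mi"].median()},
            {"layer": layer, "metric": "touch_responsive_pct",
             "value": 100 * grp["responsive_touch"].mean()},
            {"layer": layer, "metric": "suppression_median_pct",
             "value": grp.loc[grp["responsive_touch"], "suppression_pct"].median()},
            {"layer": layer, "metric": "perturbation_up_pct",
             "value": 100 * grp["up_modulated"].mean()},
            {"layer": layer, "metric": "perturbation_down_pct",
             "value": 100 * grp["down_modulated"].mean()},
        ]
    # speed tuning classes
    tuning_frames = [
        pd.read_csv(p) for p in PIPE.glob("*/speed_tuning.csv") if p.stat().st_size > 10
    ]
    if tuning_frames:
        tun = pd.concat(tuning_frames, ignore_index=True)
        modulated = tun["modulated"].mean()
        rows.append({"layer": "all", "metric": "speed_modulated_pct", "value": 100 * modulated})
        for cls, n in tun.loc[tun["modulated"], "tuning_class"].value_counts().items():
            rows.append({"layer": "all", "metric": f"tuning_{cls}_pct",
                         "value": 100 * n / max(1, tun["modulated"].sum())})
    # functional categories
    cats = PIPE / "categories.csv"
    if cats.exists():
        cat = pd.read_csv(cats)
        for (layer, c), n in cat.groupby(["layer", "category"]).size().items():
            rows.append({"layer": layer, "metric": f"category_{c}_pct",
                         "value": 100 * n / (cat["layer"] == layer).sum()})
    out = pd.DataFrame(rows)
    OUT.parent.mkdir(parents=True, exist_ok=True)
    out.to_csv(OUT, index=False, float_format="%.3f")
    print(out.to_string(index=False))
    print(f"\nwrote {OUT}")


if __name__ == "__main__":
    main()
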