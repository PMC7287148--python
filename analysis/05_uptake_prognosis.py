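#!/usr/bin/env python
"""Baseline metabolic burden as a marker of outcome on synthetic cohorts.

Synthesizes baseline-only sessions for a controlled group (CR, n=120) and
two relapse groups (DR, n=36; LR, n=43) whose lesion radii are shifted one
standard deviation upward, segments the 40 % SUVmax sub-volume, and
compares metabolic tumor volume (MTV) and total lesion glycolysis (TLG)
between each relapse group (and their pool) and the controlled group with
Mann-Whitney U tests.  Writes per-patient metrics and the comparison table
under results/.
"""

import dataclasses
from pathlib import Path

import pandas as pd

from hotspot_overlap.pipeline import run_uptake_study
from hotspot_overlap.stats import compare_uptake_groups

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    metrics = run_uptake_study({"CR": 120, "DR": 36, "LR": 43}, seed=1)
    comps = compare_uptake_groups(metrics)

    OUT.mkdir(exist_ok=True)
    metrics.to_csv(OUT / "uptake_prognosis_metrics.csv", index=False,
                   float_format="%.6g")
    pd.DataFrame([dataclasses.asdict(c) for c in comps]).to_csv(
        OUT / "uptake_prognosis_comparisons.csv", index=False, float_format="%.4g"
    )

    by_group = metrics.groupby("outcome")[["mtv_cc", "tlg_g"]].agg(["mean", "std"])
    print("baseline uptake by outcome group:")
    for outcome, row in by_group.iterrows():
        print(f"  {outcome:<6} (n={len(metrics[metrics.outcome == outcome]):>3}): "
              f"MTV {row[('mtv_cc', 'mean')]:.1f} ± {row[('mtv_cc', 'std')]:.1f} cc, "
              f"TLG {row[('tlg_g', 'mean')]:.0f} ± {row[('tlg_g', 'std')]:.0f} g")
    print("\ncomparisons vs controlled group (Mann-Whitney U):")
    for c in comps:
        star = "*" if c.p_value < 0.05 else " "
        print(f"  {c.contrast:<24} {c.mean_1:.1f} vs {c.mean_2:.1f}, p={c.p_value:.4f}{star}")
    print(f"\nwrote uptake_prognosis_metrics.csv and comparisons under {OUT}")


if __name__ == "__main__":
    main()
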