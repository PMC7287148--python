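#!/usr/bin/env python
"""Aggregate the overlap study into subgroup tables and run the cohort
comparisons.

Reads results/overlap_indices.csv (produced by 02_run_overlap_study.py),
builds the four subgroup summaries (NTP-RR, NTP-ER, TP-RR, TP-ER) over the
full threshold grid, then tests

* ER vs RR within each position group (Wilcoxon signed-rank, paired), and
* TP vs NTP within each method (Mann-Whitney U, independent),

reporting raw p-values (no multiplicity correction; the test count is
printed).  Writes subgroup_means.csv, method_comparisons.csv and
position_comparisons.csv under results/.
"""

import dataclasses
from pathlib import Path

import pandas as pd

from hotspot_overlap.io import read_overlap_table
from hotspot_overlap.stats import compare_methods, compare_positions, summarize_subgroups

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    results = read_overlap_table(OUT / "overlap_indices.csv")

    summaries = summarize_subgroups(results)
    tables = []
    for s in summaries:
        t = s.table.copy()
        t.insert(0, "subgroup", s.subgroup)
        tables.append(t)
    pd.concat(tables).to_csv(OUT / "subgroup_means.csv", index=False,
                             float_format="%.4g")

    method_rows, position_rows = [], []
    for group in ("TP", "NTP"):
        method_rows += [dataclasses.asdict(c) for c in compare_methods(results, group)]
    for method in ("RR", "ER"):
        position_rows += [dataclasses.asdict(c) for c in compare_positions(results, method)]
    mdf = pd.DataFrame(method_rows)
    pdf = pd.DataFrame(position_rows)
    mdf.to_csv(OUT / "method_comparisons.csv", index=False, float_format="%.4g")
    pdf.to_csv(OUT / "position_comparisons.csv", index=False, float_format="%.4g")

    n_tests = len(mdf) + len(pdf)
    print(f"ran {n_tests} tests ({len(mdf)} paired method, {len(pdf)} position); "
          "p-values reported raw")

    cells = mdf[(mdf["index"] == "of") & mdf.a_label.isin(["A_30", "A_40", "A_50"])
                & (mdf.r_label == "R_40")]
    print("\nER vs RR, overlap fraction OF(A_X, R_40), x = 30-50%:")
    for _, c in cells.iterrows():
        star = "*" if c.p_value < 0.05 else " "
        print(f"  {c.contrast:<20} {c.a_label}: ER {c.mean_1:.2f} vs RR {c.mean_2:.2f}"
              f"  p={c.p_value:.3f}{star}")

    pcells = pdf[(pdf["index"] == "of") & pdf.a_label.isin(["A_30", "A_40", "A_50"])
                 & (pdf.r_label == "R_40") & pdf.contrast.str.endswith("RR")]
    print("\nTP vs NTP under RR, overlap fraction OF(A_X, R_40):")
    for _, c in pcells.iterrows():
        print(f"  {c.a_label}: TP {c.mean_1:.2f} vs NTP {c.mean_2:.2f}  p={c.p_value:.3f}")

    print(f"\nwrote subgroup_means.csv, method_comparisons.csv, "
          f"position_comparisons.csv under {OUT}")


if __name__ == "__main__":
    main()
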