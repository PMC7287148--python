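"""Subgroup summaries and nonparametric comparisons of overlap indices.

The overlap analysis is aggregated over four subgroups (NTP-RR, NTP-ER,
TP-RR, TP-ER).  Registration methods are compared within a position group
by Wilcoxon signed-rank tests on per-case paired differences; position
groups are compared within a method by Mann-Whitney U tests; lesion uptake
burden (MTV, TLG) is compared between outcome groups by Mann-Whitney U.
P-values are reported raw — no multiple-testing correction is applied
across the threshold grid, but every report carries the number of tests
performed.  Significance is read at p < 0.05.

Small samples (n <= 25) use exact null distributions where ties permit,
larger ones the normal approximation with tie correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .overlap import INDEX_NAMES, classify_agreement

__all__ = [
    "SubgroupSummary",
    "ComparisonResult",
    "summarize_subgroups",
    "compare_methods",
    "compare_positions",
    "compare_uptake_groups",
    "SIGNIFICANCE_LEVEL",
]

SIGNIFICANCE_LEVEL = 0.05

_EXACT_N = 25


@dataclass
class SubgroupSummary:
    """Per-subgroup mean/SD/n of every index over the threshold grid."""

    subgroup: str  # e.g. "NTP-RR"
    table: pd.DataFrame  # columns: a_label, r_label, index, mean, sd, n, band

    def cell(self, index: str, a_label: str, r_label: str) -> pd.Series:
        t = self.table
        row = t[(t["index"] == index) & (t["a_label"] == a_label) & (t["r_label"] == r_label)]
        if row.empty:
            raise KeyError(f"no cell ({index}, {a_label}, {r_label}) in {self.subgroup}")
        return row.iloc[0]


@dataclass(frozen=True)
class ComparisonResult:
    """One two-sample (or paired) contrast for one (index, threshold) cell."""

    contrast: str  # e.g. "ER-vs-RR within NTP", "TP-vs-NTP under RR"
    test: str  # "Wilcoxon signed-rank" or "Mann-Whitney U"
    index: str
    a_label: str
    r_label: str
    statistic: float
    p_value: float
    mean_1: float
    sd_1: float
    mean_2: float
    sd_2: float
    n_1: int
    n_2: int
    group_1: str = ""
    group_2: str = ""

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")

    @property
    def significant(self) -> bool:
        return self.p_value < SIGNIFICANCE_LEVEL

    @property
    def direction(self) -> float:
        """Sign of mean_1 - mean_2 (+1, 0 or -1)."""
        return float(np.sign(self.mean_1 - self.mean_2))


def _require_columns(df: pd.DataFrame, cols) -> None:
    missing = set(cols) - set(df.columns)
    if missing:
        raise ValueError(f"results table missing columns {sorted(missing)}")


_SUBGROUPS = ("NTP-RR", "NTP-ER", "TP-RR", "TP-ER")


def summarize_subgroups(results: pd.DataFrame) -> list[SubgroupSummary]:
    """Mean values of the overlap indices per subgroup and threshold cell.

    *results* is a tidy overlap table (one row per case/method/A/R pair).
    Under the default study this yields 4 summaries, each covering the full
    7 x 2 threshold grid for all five indices.  An SD is reported as NaN
    (absent) when a cell has a single contributing case; the agreement band
    is the banding of the cell mean.
    """
    _require_columns(
        results, ["case_id", "position_group", "method", "a_label", "r_label", *INDEX_NAMES]
    )
    if results.empty:
        raise ValueError("results table is empty")
    bad = set(results["position_group"]) - {"TP", "NTP"}
    if bad:
        raise ValueError(f"unknown position group label(s): {sorted(bad)}")
    bad = set(results["method"]) - {"RR", "ER"}
    if bad:
        raise ValueError(f"unknown registration method label(s): {sorted(bad)}")

    long = results.melt(
        id_vars=["case_id", "position_group", "method", "a_label", "r_label"],
        value_vars=list(INDEX_NAMES),
        var_name="index",
        value_name="value",
    )
    out = []
    for (group, method), sub in long.groupby(["position_group", "method"], sort=True):
        agg = (
            sub.groupby(["index", "a_label", "r_label"], sort=True)["value"]
            .agg(mean="mean", sd=lambda v: v.std(ddof=1), n="count")
            .reset_index()
        )
        agg["band"] = agg["mean"].map(classify_agreement)
        out.append(SubgroupSummary(subgroup=f"{group}-{method}", table=agg))
    return out


def _wilcoxon_paired(diff: np.ndarray) -> tuple[float, float]:
    diff = np.asarray(diff, dtype=float)
    if np.all(diff == 0):
        return 0.0, 1.0
    nonzero = diff[diff != 0]
    has_ties = len(np.unique(np.abs(nonzero))) < len(nonzero)
    if len(nonzero) <= _EXACT_N and not has_ties:
        method = "exact"
    else:
        method = "approx"
    res = sps.wilcoxon(diff, zero_method="wilcox", method=method)
    return float(res.statistic), float(res.pvalue)


def _mannwhitney(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    if max(len(x), len(y)) <= _EXACT_N and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def compare_methods(results: pd.DataFrame, position_group: str) -> list[ComparisonResult]:
    """Paired ER-vs-RR Wilcoxon signed-rank tests within one position group.

    Every case must contribute both an RR and an ER value in every
    (index, A-threshold, R-threshold) cell; one test is run per cell.
    ``mean_1``/``sd_1`` describe ER, ``mean_2``/``sd_2`` RR.
    """
    _require_columns(results, ["case_id", "position_group", "method", "a_label", "r_label"])
    sub = results[results["position_group"] == position_group]
    if sub.empty:
        raise ValueError(f"no results for position group {position_group!r}")
    out = []
    for (a_label, r_label), cell in sub.groupby(["a_label", "r_label"], sort=True):
        wide = cell.pivot(index="case_id", columns="method", values=list(INDEX_NAMES))
        for index in INDEX_NAMES:
            block = wide[index]
            if "ER" not in block or "RR" not in block or block[["ER", "RR"]].isna().any().any():
                raise ValueError(
                    "unpaired input: every case needs both RR and ER values; "
                    "use compare_positions for independent groups"
                )
            er = block["ER"].to_numpy()
            rr = block["RR"].to_numpy()
            statistic, p = _wilcoxon_paired(er - rr)
            out.append(
                ComparisonResult(
                    contrast=f"ER-vs-RR within {position_group}",
                    test="Wilcoxon signed-rank",
                    index=index,
                    a_label=a_label,
                    r_label=r_label,
                    statistic=statistic,
                    p_value=p,
                    mean_1=float(er.mean()),
                    sd_1=float(er.std(ddof=1)) if len(er) > 1 else float("nan"),
                    mean_2=float(rr.mean()),
                    sd_2=float(rr.std(ddof=1)) if len(rr) > 1 else float("nan"),
                    n_1=len(er),
                    n_2=len(rr),
                    group_1="ER",
                    group_2="RR",
                )
            )
    return out


def compare_positions(results: pd.DataFrame, method: str) -> list[ComparisonResult]:
    """Independent TP-vs-NTP Mann-Whitney U tests under one registration
    method, one per (index, threshold) cell.  ``mean_1`` describes TP."""
    _require_columns(results, ["case_id", "position_group", "method", "a_label", "r_label"])
    sub = results[results["method"] == method]
    for grp in ("TP", "NTP"):
        n = sub[sub["position_group"] == grp]["case_id"].nunique()
        if n < 2:
            raise ValueError(f"position group {grp!r} has {n} case(s); need >= 2")
    out = []
    for (a_label, r_label), cell in sub.groupby(["a_label", "r_label"], sort=True):
        for index in INDEX_NAMES:
            tp = cell.loc[cell["position_group"] == "TP", index].to_numpy()
            ntp = cell.loc[cell["position_group"] == "NTP", index].to_numpy()
            statistic, p = _mannwhitney(tp, ntp)
            out.append(
                ComparisonResult(
                    contrast=f"TP-vs-NTP under {method}",
                    test="Mann-Whitney U",
                    index=index,
                    a_label=a_label,
                    r_label=r_label,
                    statistic=statistic,
                    p_value=p,
                    mean_1=float(tp.mean()),
                    sd_1=float(tp.std(ddof=1)),
                    mean_2=float(ntp.mean()),
                    sd_2=float(ntp.std(ddof=1)),
                    n_1=len(tp),
                    n_2=len(ntp),
                    group_1="TP",
                    group_2="NTP",
                )
            )
    return out


def compare_uptake_groups(metrics: pd.DataFrame, control_label: str = "CR") -> list[ComparisonResult]:
    """Mann-Whitney U of baseline MTV and TLG: each relapse group (and their
    pool) against the controlled group.

    *metrics* has one row per patient with columns ``outcome``, ``mtv_cc``
    and ``tlg_g``.  ``mean_1`` describes the relapse group, ``mean_2`` the
    control group.
    """
    _require_columns(metrics, ["outcome", "mtv_cc", "tlg_g"])
    groups = metrics["outcome"].unique().tolist()
    if control_label not in groups:
        raise ValueError(f"no control group {control_label!r} in metrics")
    relapse_labels = [g for g in groups if g != control_label]
    if not relapse_labels:
        raise ValueError("need at least one relapse group besides the control group")
    control = metrics[metrics["outcome"] == control_label]
    if len(control) < 2:
        raise ValueError("control group needs >= 2 members")

    contrasts = [(lbl, metrics[metrics["outcome"] == lbl]) for lbl in relapse_labels]
    if len(relapse_labels) > 1:
        pooled = metrics[metrics["outcome"] != control_label]
        contrasts.append(("+".join(sorted(relapse_labels)), pooled))

    out = []
    for lbl, grp in contrasts:
        if len(grp) < 2:
            raise ValueError(f"group {lbl!r} needs >= 2 members")
        for quantity in ("mtv_cc", "tlg_g"):
            x = grp[quantity].to_numpy()
            y = control[quantity].to_numpy()
            statistic, p = _mannwhitney(x, y)
            out.append(
                ComparisonResult(
                    contrast=f"{lbl}-vs-{control_label} for {quantity}",
                    test="Mann-Whitney U",
                    index=quantity,
                    a_label="",
                    r_label="",
                    statistic=statistic,
                    p_value=p,
                    mean_1=float(x.mean()),
                    sd_1=float(x.std(ddof=1)),
                    mean_2=float(y.mean()),
                    sd_2=float(y.std(ddof=1)),
                    n_1=len(x),
                    n_2=len(y),
                    group_1=lbl,
                    group_2=control_label,
                )
            )
    return out
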