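import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from hotspot_overlap.overlap import INDEX_NAMES
from hotspot_overlap.stats import (
    compare_methods,
    compare_positions,
    compare_uptake_groups,
    summarize_subgroups,
)


def make_results(
    n_tp=3, n_ntp=4, methods=("RR", "ER"), a_labels=("A_30", "A_40"),
    r_labels=("R_40",), seed=0, er_bonus=0.0,
):
    """Tidy synthetic overlap table; ER values get +er_bonus (clipped)."""
    rng = np.random.default_rng(seed)
    rows = []
    for group, n in (("TP", n_tp), ("NTP", n_ntp)):
        for i in range(n):
            case = f"{group.lower()}_{i}"
            base = {
                (a, r): rng.uniform(0.2, 0.7) for a in a_labels for r in r_labels
            }
            for method in methods:
                for (a, r), v in base.items():
                    val = min(v + (er_bonus if method == "ER" else 0.0), 1.0)
                    rows.append(
                        dict(
                            case_id=case, position_group=group, method=method,
                            a_label=a, r_label=r,
                            **{idx: val for idx in INDEX_NAMES},
                        )
                    )
    return pd.DataFrame(rows)


class TestSummarizeSubgroups:
    def test_default_four_subgroups_full_grid(self):
        res = make_results()
        summaries = summarize_subgroups(res)
        assert sorted(s.subgroup for s in summaries) == [
            "NTP-ER", "NTP-RR", "TP-ER", "TP-RR",
        ]
        for s in summaries:
            assert len(s.table) == 2 * 1 * len(INDEX_NAMES)  # A x R x index

    def test_single_case_sd_absent(self):
        res = make_results(n_tp=1, n_ntp=0, methods=("RR",))
        (summary,) = summarize_subgroups(res)
        assert summary.table["n"].eq(1).all()
        assert summary.table["sd"].isna().all()

    def test_identical_values_zero_sd(self):
        res = make_results(n_tp=3, n_ntp=0, methods=("RR",))
        res[list(INDEX_NAMES)] = 0.42
        (summary,) = summarize_subgroups(res)
        assert summary.table["mean"].eq(0.42).all()
        assert summary.table["sd"].eq(0.0).all()
        assert summary.table["band"].eq("moderate").all()

    def test_unknown_group_label_errors(self):
        res = make_results()
        res.loc[0, "position_group"] = "XX"
        with pytest.raises(ValueError, match="unknown position group"):
            summarize_subgroups(res)


class TestCompareMethods:
    def test_no_effect_gives_p_one(self):
        res = make_results(er_bonus=0.0)
        for comp in compare_methods(res, "NTP"):
            assert comp.p_value == 1.0
            assert comp.mean_1 == comp.mean_2

    def test_consistent_er_advantage_detected(self):
        res = make_results(n_ntp=10, er_bonus=0.08, seed=3)
        for comp in compare_methods(res, "NTP"):
            assert comp.mean_1 > comp.mean_2
            assert comp.p_value < 0.05

    def test_unpaired_input_errors(self):
        res = make_results()
        res = res[~((res.case_id == "ntp_0") & (res.method == "ER"))]
        with pytest.raises(ValueError, match="compare_positions"):
            compare_methods(res, "NTP")

    def test_agrees_with_permutation_oracle(self):
        res = make_results(n_ntp=8, er_bonus=0.05, seed=5)
        comp = [c for c in compare_methods(res, "NTP") if c.a_label == "A_30"][0]
        wide = res[(res.position_group == "NTP") & (res.a_label == "A_30")].pivot(
            index="case_id", columns="method", values="of"
        )
        diff = (wide["ER"] - wide["RR"]).to_numpy()
        perm = sps.permutation_test(
            (diff,),
            lambda d: np.mean(d),
            permutation_type="samples",
            n_resamples=20000,
            random_state=7,
        )
        assert comp.p_value == pytest.approx(perm.pvalue, abs=0.03)


class TestComparePositions:
    def test_identical_distributions_p_one(self):
        res = make_results(n_tp=3, n_ntp=3, methods=("RR",), seed=8)
        # give both groups literally the same three case value-sets
        tp = res[res.position_group == "TP"].copy()
        ntp = tp.copy()
        ntp["position_group"] = "NTP"
        ntp["case_id"] = ntp["case_id"].str.replace("tp", "ntp")
        res = pd.concat([tp, ntp], ignore_index=True)
        for comp in compare_positions(res, "RR"):
            assert comp.p_value == 1.0

    def test_swap_groups_same_p_reversed_direction(self):
        res = make_results(n_tp=5, n_ntp=6, methods=("RR",), seed=9)
        res.loc[res.position_group == "TP", list(INDEX_NAMES)] += 0.15
        comps = compare_positions(res, "RR")
        swapped = res.copy()
        swapped["position_group"] = swapped["position_group"].map({"TP": "NTP", "NTP": "TP"})
        comps_swapped = compare_positions(swapped, "RR")
        for c, cs in zip(comps, comps_swapped):
            assert c.p_value == pytest.approx(cs.p_value, abs=1e-12)
            assert c.direction == -cs.direction

    def test_empty_group_errors(self):
        res = make_results(n_tp=0, n_ntp=4, methods=("RR",))
        with pytest.raises(ValueError, match="TP"):
            compare_positions(res, "RR")

    def test_agrees_with_permutation_oracle(self):
        res = make_results(n_tp=5, n_ntp=5, methods=("RR",), seed=10)
        res.loc[res.position_group == "TP", list(INDEX_NAMES)] += 0.1
        comp = [c for c in compare_positions(res, "RR") if c.a_label == "A_30"][0]
        sub = res[res.a_label == "A_30"]
        tp = sub[sub.position_group == "TP"]["of"].to_numpy()
        ntp = sub[sub.position_group == "NTP"]["of"].to_numpy()
        perm = sps.permutation_test(
            (tp, ntp),
            lambda x, y: np.mean(x) - np.mean(y),
            permutation_type="independent",
            n_resamples=20000,
            random_state=11,
        )
        assert comp.p_value == pytest.approx(perm.pvalue, abs=0.03)


class TestCompareUptakeGroups:
    def _metrics(self, rng, sizes, shift=0.0):
        rows = []
        for outcome, n in sizes.items():
            mu = 7.0 + (shift if outcome != "CR" else 0.0)
            for i in range(n):
                mtv = max(rng.normal(mu, 2.0), 0.5)
                suv_mean = rng.uniform(8, 14)
                rows.append(
                    dict(outcome=outcome, mtv_cc=mtv, tlg_g=mtv * suv_mean)
                )
        return pd.DataFrame(rows)

    def test_null_case_no_systematic_direction(self, rng):
        ps, dirs = [], []
        for trial in range(8):
            m = self._metrics(rng, {"CR": 15, "LR": 12}, shift=0.0)
            (c_mtv, _) = compare_uptake_groups(m)
            ps.append(c_mtv.p_value)
            dirs.append(c_mtv.direction)
        assert min(ps) > 0.001  # no spurious strong effect
        assert abs(sum(dirs)) < 8  # directions not all one way

    def test_larger_relapse_lesions_detected(self, rng):
        m = self._metrics(rng, {"CR": 40, "LR": 25}, shift=2.0)  # 1 SD effect
        c_mtv, c_tlg = compare_uptake_groups(m)
        assert c_mtv.p_value < 0.05
        assert c_mtv.mean_1 > c_mtv.mean_2
        # TLG direction follows MTV when SUV distributions are shared
        assert c_tlg.direction == c_mtv.direction

    def test_pooled_relapse_contrast_added(self, rng):
        m = self._metrics(rng, {"CR": 10, "DR": 6, "LR": 7}, shift=1.0)
        comps = compare_uptake_groups(m)
        contrasts = {c.contrast for c in comps}
        assert any(c.startswith("DR+LR-vs-CR") for c in contrasts)
        assert len(comps) == 6  # (DR, LR, pooled) x (MTV, TLG)

    def test_missing_control_errors(self, rng):
        m = self._metrics(rng, {"LR": 5, "DR": 5})
        with pytest.raises(ValueError, match="control"):
            compare_uptake_groups(m, control_label="CR")
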