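"""Event tables, logOR effects, DerSimonian-Laird pooling, subgroup ops."""

import math

import numpy as np
import pandas as pd
import pytest

from admeta.meta import (
    assign_subgroup,
    build_event_table,
    log_odds_ratio,
    pool_random_effects,
    recurrence_summary,
    run_meta,
    run_subgroup_meta,
    subgroup_concordance,
)
from admeta.types import ComparisonResult, EventTable2x2, StudyEffect


def frame(case_vals, ctrl_vals, gene="G1"):
    samples = [f"c{i}" for i in range(len(case_vals))] + [f"h{i}" for i in range(len(ctrl_vals))]
    group = pd.Series(["case"] * len(case_vals) + ["control"] * len(ctrl_vals), index=samples)
    matrix = pd.DataFrame([list(case_vals) + list(ctrl_vals)], index=[gene], columns=samples)
    return matrix, group


def comparison(cid, degs, measured=()):
    """A ComparisonResult whose DEG list is exactly `degs` (symbol->direction).

    ``measured`` adds symbols present in the table but not significant.
    """
    all_syms = sorted(set(degs) | set(measured))
    table = pd.DataFrame(
        {
            "p_adj": [0.001 if s in degs else 0.9 for s in all_syms],
            "is_deg": [s in degs for s in all_syms],
            "direction": [degs.get(s, "up") for s in all_syms],
        },
        index=all_syms,
    )
    return ComparisonResult(cid, table)


class TestBuildEventTable:
    def test_counting_and_haldane_correction(self):
        matrix, group = frame([4.0, 5.0, 6.0], [1.0, 2.0, 3.0, 4.0, 5.0])
        t = build_event_table(matrix, group, "G1")
        # control median 3; case events 3/3, control events 2/5; b=0 -> +0.5
        assert t.corrected
        assert (t.a, t.b, t.c, t.d) == (3.5, 0.5, 2.5, 3.5)

    def test_identical_groups_give_near_zero_logor(self):
        vals = [1.0, 2.0, 3.0, 4.0, 5.0]
        matrix, group = frame(vals, vals)
        t = build_event_table(matrix, group, "G1")
        assert abs(log_odds_ratio(t).theta) < 1e-12

    def test_all_cases_below_control_median_gives_negative_theta(self):
        matrix, group = frame([0.0, 0.1, 0.2], [1.0, 2.0, 3.0, 4.0, 5.0])
        t = build_event_table(matrix, group, "G1")
        assert t.corrected and log_odds_ratio(t).theta < 0

    def test_absent_symbol_rejected(self):
        matrix, group = frame([1.0, 2.0], [3.0, 4.0])
        with pytest.raises(KeyError):
            build_event_table(matrix, group, "MISSING")


class TestLogOddsRatio:
    def test_hand_arithmetic(self):
        eff = log_odds_ratio(EventTable2x2("c", "g", 6, 2, 3, 5))
        assert eff.theta == pytest.approx(math.log(5.0))
        assert eff.v == pytest.approx(1.2)
        assert eff.w == pytest.approx(1 / 1.2)

    def test_symmetric_table_zero_theta(self):
        assert log_odds_ratio(EventTable2x2("c", "g", 5, 5, 5, 5)).theta == 0.0

    def test_haldane_corrected_table(self):
        eff = log_odds_ratio(EventTable2x2("c", "g", 4.5, 0.5, 2.5, 2.5, corrected=True))
        assert eff.theta == pytest.approx(math.log(9.0))

    def test_zero_cell_without_correction_rejected(self):
        with pytest.raises(ValueError):
            log_odds_ratio(EventTable2x2("c", "g", 4, 0, 2, 2))

    def test_antisymmetry_under_case_control_swap(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            a, b, c, d = rng.integers(1, 30, size=4).astype(float)
            fwd = log_odds_ratio(EventTable2x2("c", "g", a, b, c, d)).theta
            rev = log_odds_ratio(EventTable2x2("c", "g", c, d, a, b)).theta
            assert fwd == pytest.approx(-rev)


class TestPoolRandomEffects:
    def test_homogeneous_effects_closed_form(self):
        pe = pool_random_effects([StudyEffect(1.0, 0.5), StudyEffect(1.0, 0.5)])
        assert pe.q == 0.0 and pe.tau2 == 0.0
        assert pe.theta == pytest.approx(1.0)
        assert pe.se == pytest.approx(0.5)

    def test_dersimonian_laird_chain_by_hand(self):
        pe = pool_random_effects([StudyEffect(0.0, 1.0), StudyEffect(2.0, 1.0)])
        assert pe.q == pytest.approx(2.0)
        assert pe.tau2 == pytest.approx(1.0)
        assert pe.theta == pytest.approx(1.0)
        assert pe.se == pytest.approx(1.0)
        assert pe.z == pytest.approx(1.0)
        assert pe.p == pytest.approx(0.3173, abs=2e-4)

    def test_single_effect_passthrough(self):
        pe = pool_random_effects([StudyEffect(0.7, 0.2)])
        assert pe.theta == pytest.approx(0.7)
        assert pe.tau2 == 0.0
        assert pe.se == pytest.approx(math.sqrt(0.2))

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            pool_random_effects([])

    def test_pooled_estimate_is_convex_combination(self):
        rng = np.random.default_rng(4)
        for _ in range(30):
            effects = [
                StudyEffect(rng.normal(), float(rng.uniform(0.05, 2.0)))
                for _ in range(rng.integers(2, 7))
            ]
            pe = pool_random_effects(effects)
            thetas = [e.theta for e in effects]
            assert min(thetas) - 1e-12 <= pe.theta <= max(thetas) + 1e-12

    def test_q_and_tau2_invariant_under_study_permutation(self):
        effects = [StudyEffect(0.3, 0.4), StudyEffect(-0.9, 0.8), StudyEffect(1.4, 0.2)]
        fwd = pool_random_effects(effects)
        rev = pool_random_effects(effects[::-1])
        assert fwd.q == pytest.approx(rev.q)
        assert fwd.tau2 == pytest.approx(rev.tau2)
        assert fwd.theta == pytest.approx(rev.theta)


class TestRunMeta:
    def _cohort_data(self, rng, genes, shift_gene=None, shift=0.0, n=10):
        samples = [f"s{i}" for i in range(2 * n)]
        group = pd.Series(["case"] * n + ["control"] * n, index=samples)
        mat = pd.DataFrame(rng.normal(8, 0.5, size=(len(genes), 2 * n)), index=genes, columns=samples)
        if shift_gene is not None:
            mat.loc[shift_gene, group == "case"] += shift
        return mat, group

    def test_single_report_gene_excluded(self):
        rng = np.random.default_rng(6)
        genes = ["Gshared", "Gsolo"]
        data = {
            "c1": self._cohort_data(rng, genes, "Gshared", 3.0),
            "c2": self._cohort_data(rng, genes, "Gshared", 3.0),
        }
        comps = [
            comparison("c1", {"Gshared": "up", "Gsolo": "up"}),
            comparison("c2", {"Gshared": "up"}),
        ]
        table = run_meta(comps, data)
        assert set(table["symbol"]) == {"Gshared"}
        assert table.iloc[0]["direction"] == "up"
        assert table.iloc[0]["k"] == 2

    def test_min_reports_below_two_rejected(self):
        with pytest.raises(ValueError, match="min_reports"):
            run_meta([], {}, min_reports=1)

    def test_no_recurrent_gene_returns_empty_with_warning(self, caplog):
        rng = np.random.default_rng(7)
        data = {"c1": self._cohort_data(rng, ["G1"])}
        with caplog.at_level("WARNING"):
            table = run_meta([comparison("c1", {"G1": "up"})], data)
        assert table.empty

    def test_use_all_comparisons_pools_more_studies(self):
        rng = np.random.default_rng(8)
        genes = ["Gup"]
        data = {f"c{i}": self._cohort_data(rng, genes, "Gup", 3.0) for i in range(3)}
        comps = [comparison(f"c{i}", {"Gup": "up"}) for i in range(2)]
        comps.append(comparison("c2", {}, measured=["Gup"]))  # measured, not a DEG
        table_deg = run_meta(comps, data)
        table_all = run_meta(comps, data, use_all_comparisons=True)
        assert table_deg.iloc[0]["k"] == 2
        assert table_all.iloc[0]["k"] == 3


class TestRecurrenceSummary:
    def test_printed_count_arithmetic(self):
        # 16,810 of 21,064 DEG symbols recur; 100*16810/21064 = 79.80 (2 dp)
        comps = [
            comparison("c1", {f"G{i}": "up" for i in range(21_064)}),
            comparison("c2", {f"G{i}": "up" for i in range(16_810)}),
        ]
        out = recurrence_summary(comps)
        assert out == {"n_unique_degs": 21_064, "n_recurrent": 16_810, "pct_recurrent": 79.8}

    def test_no_recurrence_zero_percent(self):
        comps = [comparison("c1", {"G1": "up"}), comparison("c2", {"G2": "down"})]
        assert recurrence_summary(comps)["pct_recurrent"] == 0.0

    def test_full_recurrence_hundred_percent(self):
        comps = [comparison("c1", {"G1": "up"}), comparison("c2", {"G1": "up"})]
        assert recurrence_summary(comps)["pct_recurrent"] == 100.0

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            recurrence_summary([])


def meta_table(rows):
    return pd.DataFrame(rows, columns=["symbol", "p_adj", "direction"])


class TestSubgroupConcordance:
    def test_breakdown_sums_to_shared(self):
        a_rows = (
            [(f"U{i}", 0.01, "up") for i in range(359)]
            + [(f"D{i}", 0.01, "down") for i in range(1020)]
            + [(f"X{i}", 0.01, "up") for i in range(11)]
        )
        b_rows = (
            [(f"U{i}", 0.01, "up") for i in range(359)]
            + [(f"D{i}", 0.01, "down") for i in range(1020)]
            + [(f"X{i}", 0.01, "down") for i in range(11)]
        )
        out = subgroup_concordance(meta_table(a_rows), meta_table(b_rows))
        assert out["n_shared"] == 1390
        assert out["n_concordant_up"] == 359
        assert out["n_concordant_down"] == 1020
        assert out["n_discordant"] == 11

    def test_disjoint_tables_all_zero(self):
        out = subgroup_concordance(
            meta_table([("A", 0.01, "up")]), meta_table([("B", 0.01, "up")])
        )
        assert out == {"n_shared": 0, "n_concordant_up": 0, "n_concordant_down": 0, "n_discordant": 0}

    def test_identical_tables_fully_concordant(self):
        t = meta_table([("A", 0.01, "up"), ("B", 0.01, "down")])
        out = subgroup_concordance(t, t)
        assert out["n_shared"] == 2 and out["n_discordant"] == 0

    def test_only_significant_rows_enter(self):
        a = meta_table([("A", 0.01, "up"), ("B", 0.5, "up")])
        b = meta_table([("A", 0.01, "up"), ("B", 0.01, "up")])
        assert subgroup_concordance(a, b)["n_shared"] == 1


class TestSubgroups:
    @pytest.mark.parametrize(
        "region,branch",
        [
            ("hippocampus", "amygdala_hippocampus"),
            ("Amygdala", "amygdala_hippocampus"),
            ("frontal cortex", "cerebral_neocortex"),
            ("superior frontal gyrus", "cerebral_neocortex"),
            ("cerebellum", "cerebellum"),
            ("putamen", "putamen_nucleus_accumbens"),
            ("nucleus accumbens", "putamen_nucleus_accumbens"),
            ("brain stem", "other_branch"),
        ],
    )
    def test_region_to_branch_mapping(self, region, branch):
        assert assign_subgroup(region) == branch

    def test_unmapped_branch_excluded_with_warning(self, caplog):
        rng = np.random.default_rng(9)
        genes = ["Gup"]
        samples_data = {}
        comps = []
        region_map = {}
        for i in range(4):
            cid = f"c{i}"
            samples_data[cid] = TestRunMeta._cohort_data(TestRunMeta(), rng, genes, "Gup", 3.0)
            comps.append(comparison(cid, {"Gup": "up"}))
            region_map[cid] = "amygdala_hippocampus" if i < 2 else "other_branch"
        with caplog.at_level("WARNING"):
            out = run_subgroup_meta(comps, samples_data, region_map)
        assert set(out) == {"amygdala_hippocampus"}
        assert "Gup" in set(out["amygdala_hippocampus"]["symbol"])
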