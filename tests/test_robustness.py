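import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from robustscreen import (
    GroupingScheme,
    InsufficientDataError,
    MeasurementTable,
    PRESET_SCHEMES,
    UndefinedRobustnessError,
    fano_factor,
    robustness_across_conditions,
    robustness_across_population,
    robustness_across_systems,
    robustness_generic,
    robustness_over_time,
    robustness_score,
    summarize_replicate_results,
    to_efficiency,
)

from conftest import grid_table, make_table
from oracles import brute_R, brute_mode


def random_grid_table(rng, n_sys=3, n_cond=4, n_rep=3):
    rows = {}
    for s in range(n_sys):
        for c in range(n_cond):
            for r in range(1, n_rep + 1):
                rows[(f"S{s}", f"C{c}", r)] = float(rng.uniform(0.1, 5.0))
    return grid_table(rows)


def random_series_table(rng, n_sys=2, n_cond=2, n_rep=2, n_t=6):
    rows = []
    for s in range(n_sys):
        for c in range(n_cond):
            for r in range(1, n_rep + 1):
                for i in range(n_t):
                    rows.append({"system": f"S{s}", "condition": f"C{c}", "replicate": r,
                                 "time_h": float(i), "value": float(rng.uniform(0.1, 5.0))})
    return make_table(rows)


def random_cell_table(rng, n_sys=2, n_cond=2, n_t=2, n_cells=8):
    rows = []
    for s in range(n_sys):
        for c in range(n_cond):
            for ti in range(n_t):
                for j in range(n_cells):
                    rows.append({"system": f"S{s}", "condition": f"C{c}",
                                 "time_h": float(4 * ti), "cell_id": f"c{j}",
                                 "value": float(rng.uniform(0.1, 5.0))})
    return make_table(rows)


class TestFanoFactor:
    def test_constant_sample_is_zero(self):
        assert fano_factor([5.0, 5.0, 5.0]) == 0.0

    def test_hand_computed(self):
        assert fano_factor([1.0, 2.0, 3.0]) == pytest.approx(0.5, abs=1e-12)

    def test_all_zero_sample_resolves_to_zero(self):
        assert fano_factor([0.0, 0.0, 0.0]) == 0.0

    def test_too_few_values(self):
        with pytest.raises(InsufficientDataError):
            fano_factor([1.0])

    def test_zero_mean_nonzero_variance_undefined(self):
        with pytest.raises(UndefinedRobustnessError):
            fano_factor([-1.0, 1.0])

    def test_population_variance_switch(self):
        assert fano_factor([1.0, 2.0, 3.0], ddof=0) == pytest.approx((2.0 / 3.0) / 2.0)


class TestRobustnessScore:
    def test_hand_computed(self):
        res = robustness_score([1.0, 2.0, 3.0], m=2.0)
        assert res.R == pytest.approx(-0.25, abs=1e-12)
        assert (res.sigma2, res.xbar, res.m, res.n) == (1.0, 2.0, 2.0, 3)

    def test_zero_variance_scores_zero_whatever_m(self):
        assert robustness_score([5.0, 5.0, 5.0], m=7.0).R == 0.0
        assert robustness_score([0.0, 0.0], m=0.0).R == 0.0

    def test_scale_invariance_pairwise(self):
        a = robustness_score([1.0, 2.0, 3.0], m=2.0).R
        b = robustness_score([10.0, 20.0, 30.0], m=20.0).R
        assert a == pytest.approx(b, abs=1e-12)

    def test_zero_m_with_variance_is_error(self):
        with pytest.raises(UndefinedRobustnessError):
            robustness_score([1.0, 2.0], m=0.0)

    def test_monotone_decreasing_in_variance(self):
        # same xbar and m, increasing spread -> strictly lower R
        spreads = [0.1, 0.5, 1.0, 2.0]
        rs = [robustness_score([3.0 - d, 3.0, 3.0 + d], m=3.0).R for d in spreads]
        assert all(a > b for a, b in zip(rs, rs[1:]))


class TestModesAgainstOracle:
    def test_worked_example_across_conditions(self):
        # S1 constant, S2 spread 0.1..0.5 over three shared conditions
        table = grid_table({("S1", f"C{i}", 1): 0.30 for i in range(3)}
                           | {("S2", "C0", 1): 0.10, ("S2", "C1", 1): 0.30,
                              ("S2", "C2", 1): 0.50})
        res = {r.group_key["system"]: r for r in robustness_across_conditions(table, "f")}
        assert res["S1"].m == pytest.approx(0.30)
        assert res["S1"].R == 0.0
        assert res["S2"].R == pytest.approx(-(0.04 / 0.30) / 0.30, abs=1e-12)

    def test_no_growth_condition_scores_zero_maximum(self):
        # all systems at exactly zero growth in one condition: R(s) = 0
        table = grid_table({(f"S{i}", "Harsh", 1): 0.0 for i in range(3)}
                           | {(f"S{i}", "Control", 1): 0.3 + 0.05 * i for i in range(3)})
        res = {r.group_key["condition"]: r.R for r in robustness_across_systems(table, "f")}
        assert res["Harsh"] == 0.0
        assert res["Control"] < 0.0

    def test_time_series_example(self):
        rows = [{"time_h": float(i), "value": float(v)}
                for i, v in enumerate([1, 2, 3, 4, 5])]
        table = make_table(rows)
        res = robustness_over_time(table, "f")[0]
        assert res.m == pytest.approx(3.0)
        assert res.R == pytest.approx(-(2.5 / 3.0) / 3.0, abs=1e-12)

    def test_identical_cells_score_zero(self):
        rows = [{"cell_id": f"c{i}", "time_h": 0.0, "value": 2.0} for i in range(25)]
        res = robustness_across_population(make_table(rows), "f")[0]
        assert res.R == 0.0 and res.n == 25

    def test_mixture_population_scores_lower(self, rng):
        rows = []
        for i in range(200):
            rows.append({"system": "hom", "cell_id": f"c{i}", "time_h": 0.0,
                         "value": 1.5 * rng.lognormal(0, 0.05)})
        for i in range(200):
            comp = 1.0 if i < 100 else 2.0
            rows.append({"system": "mix", "cell_id": f"c{i}", "time_h": 0.0,
                         "value": comp * rng.lognormal(0, 0.05)})
        res = {r.group_key["system"]: r.R
               for r in robustness_across_population(make_table(rows), "f")}
        assert res["hom"] > res["mix"]

    def test_conditions_mode_matches_brute_force(self, rng):
        for _ in range(50):
            table = random_grid_table(rng, n_sys=int(rng.integers(2, 7)),
                                      n_cond=int(rng.integers(2, 9)),
                                      n_rep=int(rng.integers(2, 5)))
            records = table.data.to_dict("records")
            expected = brute_mode(records, ("condition",), ("system",))
            got = {(r.group_key["system"],): r.R
                   for r in robustness_across_conditions(table, "f")}
            for key, value in expected.items():
                assert got[key] == pytest.approx(value, abs=1e-12)

    def test_time_mode_matches_brute_force(self, rng):
        table = random_series_table(rng, n_sys=3, n_cond=2, n_rep=3, n_t=8)
        records = table.data.to_dict("records")
        expected = brute_mode(records, ("time_h",), ("system", "condition", "replicate"),
                              min_n=3)
        got = {(r.group_key["system"], r.group_key["condition"], r.group_key["replicate"]): r.R
               for r in robustness_over_time(table, "f")}
        for key, value in expected.items():
            assert got[key] == pytest.approx(value, abs=1e-12)

    def test_population_mode_matches_brute_force(self, rng):
        table = random_cell_table(rng, n_cells=30)
        records = table.data.to_dict("records")
        expected = brute_mode(records, ("cell_id",), ("system", "condition", "time_h"),
                              min_n=25)
        got = {(r.group_key["system"], r.group_key["condition"], r.group_key["time_h"]): r.R
               for r in robustness_across_population(table, "f")}
        for key, value in expected.items():
            assert got[key] == pytest.approx(value, abs=1e-12)

    def test_replicate_averaging_happens_before_grouping(self):
        # two replicates that average to the same per-condition value as a
        # single-replicate table must give identical R
        averaged = grid_table({("S1", "C0", 1): 1.0, ("S1", "C1", 1): 2.0,
                               ("S2", "C0", 1): 2.0, ("S2", "C1", 1): 4.0})
        split = grid_table({("S1", "C0", 1): 0.5, ("S1", "C0", 2): 1.5,
                            ("S1", "C1", 1): 1.0, ("S1", "C1", 2): 3.0,
                            ("S2", "C0", 1): 2.0, ("S2", "C0", 2): 2.0,
                            ("S2", "C1", 1): 4.0, ("S2", "C1", 2): 4.0})
        ra = {r.group_key["system"]: r.R for r in robustness_across_conditions(averaged, "f")}
        rs = {r.group_key["system"]: r.R for r in robustness_across_conditions(split, "f")}
        assert ra == pytest.approx(rs, abs=1e-12)

    def test_small_group_reported_missing_with_reason(self):
        table = grid_table({("S1", "C0", 1): 1.0, ("S1", "C1", 1): 2.0,
                            ("S2", "C0", 1): 3.0})
        res = {r.group_key["system"]: r for r in robustness_across_conditions(table, "f")}
        assert res["S1"].status == "ok"
        assert res["S2"].status == "missing"
        assert "minimum" in res["S2"].reason

    def test_unknown_function_lists_available(self):
        with pytest.raises(KeyError, match="mu_max"):
            robustness_across_conditions(grid_table({("S", "C", 1): 1.0},
                                                    function_name="mu_max"), "lag_h")


class TestProperties:
    @pytest.mark.parametrize("k", [1e-3, 1.0, 1e3])
    def test_scale_invariance_all_modes(self, rng, k):
        grid = random_grid_table(rng)
        series = random_series_table(rng)
        cells = random_cell_table(rng, n_cells=25)
        for table, fn in ((grid, robustness_across_conditions),
                          (grid, robustness_across_systems),
                          (series, robustness_over_time),
                          (cells, robustness_across_population)):
            scaled = MeasurementTable(table.data.assign(value=table.data["value"] * k))
            for a, b in zip(fn(table, "f"), fn(scaled, "f")):
                assert a.group_key == b.group_key
                assert b.R == pytest.approx(a.R, abs=1e-12)

    def test_sign_law_for_positive_functions(self, rng):
        table = random_grid_table(rng, n_sys=5, n_cond=6)
        for r in (robustness_across_conditions(table, "f")
                  + robustness_across_systems(table, "f")):
            assert r.R <= 0.0
            assert (r.R == 0.0) == (r.sigma2 == 0.0)

    @given(st.lists(st.floats(min_value=0.01, max_value=10.0), min_size=2, max_size=12),
           st.floats(min_value=0.1, max_value=10.0))
    @settings(derandomize=True, max_examples=100, deadline=None)
    def test_score_matches_textbook_formula(self, values, m):
        assert robustness_score(values, m).R == pytest.approx(brute_R(values, m), abs=1e-10)

    def test_ranking_recovery_low_cv_beats_high_cv(self):
        wins = 0
        for seed in range(100):
            g = np.random.default_rng(seed)
            rows = {}
            for c in range(6):
                mean_a = 1.0 * (1 + 0.05 * g.standard_normal())
                mean_b = 1.0 * (1 + 0.30 * g.standard_normal())
                for r in range(1, 4):
                    rows[("A", f"C{c}", r)] = abs(mean_a * (1 + 0.02 * g.standard_normal()))
                    rows[("B", f"C{c}", r)] = abs(mean_b * (1 + 0.02 * g.standard_normal()))
            res = {r.group_key["system"]: r.R
                   for r in robustness_across_conditions(grid_table(rows), "f")}
            wins += res["A"] > res["B"]
        assert wins >= 99


class TestGenericScheme:
    @pytest.mark.parametrize("mode,fn", [
        ("c", robustness_across_conditions), ("s", robustness_across_systems),
        ("t", robustness_over_time), ("p", robustness_across_population),
    ])
    def test_presets_recover_dedicated_modes(self, rng, mode, fn):
        table = {"c": random_grid_table(rng), "s": random_grid_table(rng),
                 "t": random_series_table(rng), "p": random_cell_table(rng, n_cells=25)}[mode]
        min_n = {"c": 2, "s": 2, "t": 3, "p": 25}[mode]
        generic = robustness_generic(table, "f", PRESET_SCHEMES[mode], min_n=min_n,
                                     mode_label=mode)
        dedicated = fn(table, "f")
        assert len(generic) == len(dedicated)
        for a, b in zip(generic, dedicated):
            assert a.group_key == b.group_key
            if a.R is None:
                assert b.R is None
            else:
                assert a.R == pytest.approx(b.R, abs=1e-15)

    def test_empty_within_axes_is_configuration_error(self):
        with pytest.raises(ValueError, match="within_axes"):
            GroupingScheme((), ("system",), ()).validate()

    def test_overlapping_axes_is_configuration_error(self):
        with pytest.raises(ValueError, match="disjoint"):
            GroupingScheme(("condition",), ("condition",), ("condition",)).validate()

    def test_m_axes_must_contain_within(self):
        with pytest.raises(ValueError, match="m_axes"):
            GroupingScheme(("condition",), ("system",), ("system",)).validate()

    def test_restricted_m_axes_gives_per_group_normalisation(self, rng):
        # m pooled per system instead of globally: each system's m is its own mean
        table = random_grid_table(rng, n_sys=2, n_cond=4, n_rep=1)
        scheme = GroupingScheme(("condition",), ("system",), ("condition",))
        res = robustness_generic(table, "f", scheme)
        for r in res:
            sub = table.data[table.data["system"] == r.group_key["system"]]
            assert r.m == pytest.approx(float(sub["value"].mean()), abs=1e-12)


class TestEfficiency:
    def test_arithmetic(self):
        np.testing.assert_allclose(to_efficiency([0.40, 0.45], 0.51),
                                    [0.40 / 0.51, 0.45 / 0.51])

    def test_at_theoretical_max(self):
        np.testing.assert_allclose(to_efficiency([0.51, 0.51], 0.51), [1.0, 1.0])

    def test_shared_max_leaves_R_unchanged(self):
        values = [0.30, 0.35, 0.40]
        raw = robustness_score(values, m=0.35).R
        eff = robustness_score(to_efficiency(values, 0.51), m=0.35 / 0.51).R
        assert eff == pytest.approx(raw, abs=1e-12)

    def test_nonpositive_max_is_error(self):
        with pytest.raises(ValueError):
            to_efficiency([0.4], 0.0)


class TestReplicateSummary:
    def test_time_mode_summary_aggregates_replicates(self, rng):
        table = random_series_table(rng, n_sys=1, n_cond=1, n_rep=3, n_t=6)
        res = robustness_over_time(table, "f")
        summary = summarize_replicate_results(res)
        assert len(summary) == 1
        row = summary.iloc[0]
        rvals = [r.R for r in res]
        assert row["n_replicates"] == 3
        assert row["R_mean"] == pytest.approx(np.mean(rvals))
        assert row["R_sd"] == pytest.approx(np.std(rvals, ddof=1))
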