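"""Surrogate operating model: dynamics contracts, Q-90, trade-off matrix."""

import numpy as np
import pytest

from corridorplan import fixtures as fx
from corridorplan.simulate import (
    BoxPolygon,
    Ecosystem,
    FunctionalGroup,
    INDICATOR_NAMES,
    Scenario,
    ScenarioError,
    indicator_vector,
    indicator_vector_from_arrays,
    q90_statistic,
    run_scenario,
    step_dynamics,
    tradeoff_table,
)


def single_box_ecosystem(r=0.2, k=100.0, f=0.0, **kw):
    g = FunctionalGroup("g", "demersal", 3.0, np.array([k]), r, commercial=True)
    return Ecosystem(
        groups=[g], boxes=[BoxPolygon(0, 100.0)], fleets=["gillnet"],
        base_f={("g", "gillnet"): f}, adjacency=[], movement_rate=0.0, **kw,
    )


class TestStepDynamics:
    def test_logistic_step_closed_form(self):
        eco = single_box_ecosystem(r=0.2, k=100.0)
        nxt, catch = step_dynamics(np.array([[50.0]]), eco, Scenario("s"), 2008)
        assert nxt[0, 0] == pytest.approx(55.0)  # B + rB(1 - B/K)
        assert catch.sum() == 0.0

    def test_equilibrium_at_capacity_without_fishing(self):
        eco = single_box_ecosystem()
        nxt, _ = step_dynamics(np.array([[100.0]]), eco, Scenario("s"), 2008)
        assert nxt[0, 0] == pytest.approx(100.0)

    def test_full_closure_gives_zero_catch(self, ecosystem):
        closures = {b.box_id: "full" for b in ecosystem.boxes}
        scen = Scenario("closed", refuge_network=closures, refuge_start_year=2008)
        k = np.stack([g.carrying_capacity for g in ecosystem.groups])
        _, catch = step_dynamics(0.5 * k, ecosystem, scen, 2010)
        assert catch.sum() == 0.0

    def test_partial_closure_halves_f(self):
        eco = single_box_ecosystem(f=0.4)
        open_scen = Scenario("open")
        part = Scenario("part", refuge_network={0: "partial"}, refuge_start_year=2008)
        b0 = np.array([[50.0]])
        _, c_open = step_dynamics(b0, eco, open_scen, 2010)
        _, c_part = step_dynamics(b0, eco, part, 2010)
        grown = 55.0
        assert c_open.sum() == pytest.approx(grown * (1 - np.exp(-0.4)))
        assert c_part.sum() == pytest.approx(grown * (1 - np.exp(-0.2)))

    def test_negative_biomass_rejected(self):
        eco = single_box_ecosystem()
        with pytest.raises(ScenarioError):
            step_dynamics(np.array([[-1.0]]), eco, Scenario("s"), 2008)

    def test_movement_conserves_mass(self):
        g = FunctionalGroup("g", "pelagic", 3.0, np.array([100.0, 50.0]), 0.3)
        eco = Ecosystem(groups=[g], boxes=[BoxPolygon(0, 1.0), BoxPolygon(1, 1.0)],
                        fleets=[], base_f={}, adjacency=[(0, 1)], movement_rate=0.2)
        b0 = np.array([[80.0, 10.0]])
        nxt, _ = step_dynamics(b0, eco, Scenario("s"), 2008)
        grown = b0 + 0.3 * b0 * (1 - b0 / np.array([[100.0, 50.0]]))
        assert nxt.sum() == pytest.approx(grown.sum())


class TestRunScenario:
    def test_inclusive_horizon_yields_26_states(self, ecosystem):
        res = run_scenario(Scenario("base", horizon=(2008, 2033)), ecosystem)
        assert len(res.years) == 26

    def test_snapshots_truncated_with_warning(self, ecosystem):
        scen = Scenario("r", refuge_network={0: "full"}, refuge_start_year=2019)
        with pytest.warns(UserWarning, match="truncated"):
            res = run_scenario(scen, ecosystem)
        assert res.snapshot_years == [2024, 2029, 2033]

    def test_identity_scenario_equals_base(self, ecosystem):
        base = run_scenario(Scenario("base"), ecosystem)
        noop = Scenario("noop", f_reductions={("*", "*"): 0.0},
                        reduction_start_year=2018, refuge_network={}, refuge_start_year=2019)
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            same = run_scenario(noop, ecosystem)
        assert np.allclose(base.biomass, same.biomass)
        assert np.allclose(base.catch, same.catch)

    def test_unfished_biomass_monotone_toward_capacity(self, ecosystem):
        eco = Ecosystem(
            groups=ecosystem.groups, boxes=ecosystem.boxes, fleets=ecosystem.fleets,
            base_f={k: 0.0 for k in ecosystem.base_f}, adjacency=ecosystem.adjacency,
            movement_rate=ecosystem.movement_rate,
        )
        res = run_scenario(Scenario("unfished"), eco)
        per_group = res.biomass.sum(axis=2)  # (T, groups)
        assert np.all(np.diff(per_group, axis=0) >= -1e-9)
        k_tot = np.array([g.carrying_capacity.sum() for g in eco.groups])
        assert np.all(per_group[-1] <= k_tot + 1e-6)

    def test_larger_f_reduction_yields_no_less_biomass(self):
        eco = single_box_ecosystem(r=0.4, k=100.0, f=0.3)
        results = {}
        for name, red in [("base", None), ("r1", 0.01), ("r10", 0.10)]:
            scen = Scenario(name) if red is None else Scenario(
                name, f_reductions={("*", "*"): red}, reduction_start_year=2018)
            results[name] = run_scenario(scen, eco).biomass[-1].sum()
        assert results["r10"] >= results["r1"] >= results["base"]


class TestQ90:
    def test_even_community_closed_form(self):
        n = 10
        # cumulative of an even community is proportional to rank
        ranks = np.arange(1, n + 1)
        r10, r90 = 1 + 0.1 * (n - 1), 1 + 0.9 * (n - 1)
        expected = (np.interp(r90, ranks, np.log10(ranks)) -
                    np.interp(r10, ranks, np.log10(ranks))) / (r90 - r10)
        assert q90_statistic(np.full(n, 7.3)) == pytest.approx(expected)

    def test_geometric_series_brute_force(self):
        a = 0.5 ** np.arange(10)
        ranked = np.sort(a)[::-1]
        log_cum = np.log10(np.cumsum(ranked))
        ranks = np.arange(1, 11)
        r10, r90 = 1.9, 9.1
        expected = (np.interp(r90, ranks, log_cum) - np.interp(r10, ranks, log_cum)) / (r90 - r10)
        assert q90_statistic(a) == pytest.approx(expected)

    def test_zero_abundance_group_ignored(self):
        a = np.array([5.0, 3.0, 2.0, 1.0])
        assert q90_statistic(np.r_[a, 0.0]) == pytest.approx(q90_statistic(a))

    def test_dominated_community_scores_lower_than_even(self):
        even = q90_statistic(np.full(12, 4.0))
        skewed = q90_statistic(np.r_[1000.0, np.full(11, 0.5)])
        assert skewed < even

    def test_too_few_groups_rejected(self):
        with pytest.raises(ScenarioError):
            q90_statistic(np.array([1.0, 2.0]))


class TestIndicators:
    def test_vector_has_exactly_ten_stable_names(self, ecosystem):
        res = run_scenario(Scenario("base"), ecosystem)
        vec = indicator_vector(res, 2020, ecosystem)
        assert tuple(vec) == INDICATOR_NAMES
        assert len(vec) == 10

    def test_zero_catch_zero_value(self, ecosystem):
        n_g, n_b, n_f = len(ecosystem.groups), len(ecosystem.boxes), len(ecosystem.fleets)
        k = np.stack([g.carrying_capacity for g in ecosystem.groups])
        vec = indicator_vector_from_arrays(k, np.zeros((n_g, n_b, n_f)), ecosystem)
        assert vec["catch_value"] == 0.0
        assert vec["total_catch"] == 0.0

    def test_mean_trophic_level_weighted(self):
        g1 = FunctionalGroup("a", "pelagic", 2.0, np.array([10.0]), 0.5)
        g2 = FunctionalGroup("b", "demersal", 4.0, np.array([10.0]), 0.5)
        eco = Ecosystem(groups=[g1, g2], boxes=[BoxPolygon(0, 1.0)], fleets=[], base_f={})
        vec = indicator_vector_from_arrays(
            np.array([[5.0], [5.0]]), np.zeros((2, 1, 0)), eco)
        assert vec["mean_trophic_level"] == pytest.approx(3.0)

    def test_missing_demersal_biomass_reported_as_nan(self):
        g = FunctionalGroup("a", "pelagic", 2.0, np.array([10.0]), 0.5)
        eco = Ecosystem(groups=[g], boxes=[BoxPolygon(0, 1.0)], fleets=[], base_f={})
        vec = indicator_vector_from_arrays(np.array([[5.0]]), np.zeros((1, 1, 0)), eco)
        assert np.isnan(vec["pelagic_demersal_ratio"])


class TestTradeoff:
    def test_min_max_normalization(self, ecosystem):
        base = run_scenario(Scenario("base"), ecosystem)
        red = run_scenario(
            Scenario("red", f_reductions={("*", "*"): 0.5}, reduction_start_year=2010),
            ecosystem)
        raw, norm, _ = tradeoff_table({"base": base, "red": red}, 2033, ecosystem)
        changing = [c for c in raw.columns if not np.isclose(raw[c].min(), raw[c].max())]
        assert changing  # the halved-F run must move some indicator
        for c in changing:
            assert set(norm[c].round(9)) == {0.0, 1.0}

    def test_identical_scenarios_constant_note(self, ecosystem):
        a = run_scenario(Scenario("a"), ecosystem)
        b = run_scenario(Scenario("b"), ecosystem)
        _, norm, notes = tradeoff_table({"a": a, "b": b}, 2033, ecosystem)
        assert (norm == 0.5).all().all()
        assert len(notes) == len(INDICATOR_NAMES)

    def test_single_scenario_rejected(self, ecosystem):
        res = run_scenario(Scenario("only"), ecosystem)
        with pytest.raises(ScenarioError):
            tradeoff_table({"only": res}, 2033, ecosystem)
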