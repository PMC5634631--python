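"""FBA / FVA / alternate-optima engine, with cobrapy as independent oracle."""

import numpy as np
import pytest

from engroflux.fba import (
    FLUX_EPSILON,
    Objective,
    add_virtual_efflux,
    constrain_biomass_production,
    enumerate_alternate_optima,
    fba_optimize,
    fva,
)
from engroflux.network import Reaction, build_network, set_availability
from engroflux.sampling import SamplerConfig, draw_objectives
from engroflux.synthetic import ToyNetworkSpec, make_toy_network

from conftest import brute_force_optimal_patterns, to_cobra


class TestFBA:
    def test_toy_chain_optimum_is_uptake_bound(self):
        net, ans = make_toy_network(ToyNetworkSpec(topology="chain", uptake_bound=5))
        state = fba_optimize(net, ans.objective_reaction)
        assert state.status == "optimal"
        assert state.objective_value == pytest.approx(5.0)

    def test_all_exchanges_closed_means_zero_growth(self, engro1):
        net = engro1.copy()
        for r in net.reactions:
            if r.is_exchange:
                net.set_bounds(r.id, lower=0.0, upper=0.0)
        state = fba_optimize(net, net.biomass_reaction_id)
        assert state.objective_value == pytest.approx(0.0, abs=1e-9)

    def test_unbounded_objective_reported(self):
        net = build_network(
            [
                Reaction("make", {"A": 1.0}, 0, 1000),
                Reaction("grow", {"A": -1.0, "B": 1.0}, -1000, 1000),
                Reaction("out", {"B": -1.0}, -1000, 1000),
            ]
        )
        # open the bounds fully to create an unbounded direction
        for r in net.reactions:
            r.lower_bound, r.upper_bound = float("-inf"), float("inf")
        state = fba_optimize(net, "out")
        assert state.status == "unbounded"

    def test_infeasible_bounds_reported(self):
        net = build_network(
            [
                Reaction("up", {"A": 1.0}, 0, 1),
                Reaction("out", {"A": -1.0}, 5, 10),  # demands more than supply
            ]
        )
        state = fba_optimize(net, "out")
        assert state.status == "infeasible"

    def test_deterministic_vertex(self, critical_net):
        a = fba_optimize(critical_net, critical_net.biomass_reaction_id)
        b = fba_optimize(critical_net, critical_net.biomass_reaction_id)
        assert a.fluxes == b.fluxes

    def test_critical_point_pattern(self, critical_net):
        """At the critical-oxygen boundary the growth optimum ferments all
        glucose (PDH off) and runs aconitase in reverse."""
        state = fba_optimize(critical_net, critical_net.biomass_reaction_id)
        assert state[critical_net.named_reactions["pdh"]] == pytest.approx(0.0, abs=1e-6)
        assert state[critical_net.named_reactions["aconitase"]] < -FLUX_EPSILON

    def test_steady_state_and_bounds_invariants(self, engro1):
        """Every optimal state satisfies S v = 0 (1e-6) and bounds (1e-9),
        across a batch of random objectives."""
        S = engro1.stoichiometric_matrix()
        lb, ub = engro1.bounds()
        objectives = draw_objectives(SamplerConfig(n_samples=50, seed=7), engro1)
        from engroflux.fba import _LPProblem

        lp = _LPProblem(engro1)
        for obj in objectives:
            status, _, flux = lp.solve(obj.weights)
            assert status == "optimal"
            assert np.max(np.abs(S @ flux)) < 1e-6
            assert np.all(flux >= lb - 1e-9)
            assert np.all(flux <= ub + 1e-9)

    def test_agrees_with_cobrapy(self, critical_net):
        """Independent oracle: cobrapy/GLPK reaches the same optimum."""
        cobra_model = to_cobra(critical_net)
        cobra_model.objective = critical_net.biomass_reaction_id
        sol = cobra_model.optimize()
        ours = fba_optimize(critical_net, critical_net.biomass_reaction_id)
        assert ours.objective_value == pytest.approx(sol.objective_value, rel=1e-6)


class TestFVA:
    def test_equal_parallel_branches_span_full_range(self):
        net, _ = make_toy_network(ToyNetworkSpec(topology="diamond", uptake_bound=8))
        res = fva(net, "out")
        for rid in ("b0", "b1"):
            assert res.minimum[rid] == pytest.approx(0.0, abs=1e-6)
            assert res.maximum[rid] == pytest.approx(8.0, abs=1e-6)

    def test_objective_reaction_has_zero_range(self, critical_net):
        rid = critical_net.biomass_reaction_id
        res = fva(critical_net, rid, reactions=[rid])
        assert res.range(rid) == pytest.approx(0.0, abs=1e-5)

    def test_ranges_bracket_the_fba_vertex(self, critical_net):
        state = fba_optimize(critical_net, critical_net.biomass_reaction_id)
        res = fva(critical_net, critical_net.biomass_reaction_id)
        for rid, lo in res.minimum.items():
            hi = res.maximum[rid]
            assert lo <= hi + 1e-9
            assert lo - 1e-5 <= state[rid] <= hi + 1e-5

    def test_bad_fraction_rejected(self, engro1):
        with pytest.raises(ValueError):
            fva(engro1, engro1.biomass_reaction_id, fraction_of_optimum=0.0)

    def test_agrees_with_cobrapy_fva(self, critical_net):
        from cobra.flux_analysis import flux_variability_analysis

        tracked = [
            critical_net.named_reactions[r]
            for r in ("pdh", "aconitase", "lactate_efflux", "malate_dehydrogenase")
        ]
        cobra_model = to_cobra(critical_net)
        cobra_model.objective = critical_net.biomass_reaction_id
        ref = flux_variability_analysis(
            cobra_model, reaction_list=tracked, fraction_of_optimum=1.0
        )
        ours = fva(critical_net, critical_net.biomass_reaction_id, reactions=tracked)
        for rid in tracked:
            assert ours.minimum[rid] == pytest.approx(ref.loc[rid, "minimum"], abs=2e-4)
            assert ours.maximum[rid] == pytest.approx(ref.loc[rid, "maximum"], abs=2e-4)


class TestAlternateOptima:
    @pytest.mark.parametrize(
        "spec",
        [
            ToyNetworkSpec(topology="chain"),
            ToyNetworkSpec(topology="diamond"),
            ToyNetworkSpec(topology="parallel", branches=3),
            ToyNetworkSpec(topology="parallel", branches=5),
            ToyNetworkSpec(topology="loop_pair"),
        ],
        ids=lambda s: f"{s.topology}-{s.branches}",
    )
    def test_matches_brute_force_oracle(self, spec):
        """Pattern-for-pattern agreement with exhaustive vertex enumeration."""
        net, ans = make_toy_network(spec)
        optima = enumerate_alternate_optima(net, ans.objective_reaction)
        oracle = brute_force_optimal_patterns(net, ans.objective_reaction)
        assert optima.sign_patterns() == oracle
        assert optima.count == ans.optima_count
        assert optima.complete

    def test_asymmetric_capacities_match_oracle(self):
        """A non-symmetric toy (capped branch, reversible shunt) also agrees."""
        net = build_network(
            [
                Reaction("up", {"A": 1.0}, 0, 6),
                Reaction("b1", {"A": -1.0, "B": 1.0}, 0, 4),
                Reaction("b2", {"A": -1.0, "B": 1.0}, 0, 1000),
                Reaction("shunt", {"B": -1.0, "A": 1.0}, -1000, 1000),
                Reaction("out", {"B": -1.0}, 0, 1000),
            ]
        )
        optima = enumerate_alternate_optima(net, "out")
        oracle = brute_force_optimal_patterns(net, "out")
        assert optima.sign_patterns() == oracle

    def test_objective_value_shared_by_all_members(self, critical_net):
        optima = enumerate_alternate_optima(
            critical_net, critical_net.biomass_reaction_id, max_count=100
        )
        z = optima.shared_objective_value
        for v in optima.vertices:
            assert abs(v.objective_value - z) <= 1e-8 * max(1.0, abs(z))

    def test_members_pairwise_distinct(self, critical_net):
        optima = enumerate_alternate_optima(
            critical_net, critical_net.biomass_reaction_id, max_count=100
        )
        assert len(optima.sign_patterns()) == optima.count

    def test_max_count_truncates_and_flags(self):
        net, _ = make_toy_network(ToyNetworkSpec(topology="parallel", branches=4))
        optima = enumerate_alternate_optima(net, "out", max_count=2)
        assert optima.count == 2
        assert not optima.complete


class TestNetworkEdits:
    def test_constrain_biomass_floor(self, critical_net):
        net = constrain_biomass_production(critical_net, 0.5)
        state = fba_optimize(net, net.named_reactions["atp_maintenance"])
        assert state[net.biomass_reaction_id] >= 0.5 - 1e-9

    def test_constrain_above_optimum_is_infeasible(self, critical_net):
        opt = fba_optimize(critical_net, critical_net.biomass_reaction_id)
        net = constrain_biomass_production(critical_net, opt.objective_value * 2 + 1)
        assert fba_optimize(net, net.biomass_reaction_id).status == "infeasible"

    def test_negative_floor_rejected(self, engro1):
        with pytest.raises(ValueError):
            constrain_biomass_production(engro1, -0.1)

    def test_virtual_efflux_adds_columns(self, engro1):
        aug = add_virtual_efflux(engro1, ["pyr", "mal"])
        assert aug.n_reactions == engro1.n_reactions + 2
        assert aug.reaction("VEX_pyr").stoichiometry == {"pyr": -1.0}
        assert aug.reaction("VEX_pyr").is_exchange

    def test_closed_virtual_effluxes_keep_the_optimum(self, critical_net):
        base = fba_optimize(critical_net, critical_net.biomass_reaction_id)
        aug = add_virtual_efflux(
            critical_net, ["pyr", "cit", "succ"], upper_bound=0.0
        )
        again = fba_optimize(aug, aug.biomass_reaction_id)
        assert again.objective_value == pytest.approx(base.objective_value, rel=1e-9)

    def test_unknown_metabolite_rejected(self, engro1):
        with pytest.raises(KeyError):
            add_virtual_efflux(engro1, ["unobtainium"])

    def test_measured_panel_adds_twenty_effluxes(self, engro1):
        from engroflux.shifts import MEASURED_PANEL

        present = sorted(
            {m for m in MEASURED_PANEL.values() if m and engro1.has_metabolite(m)}
        )
        aug = add_virtual_efflux(engro1, present)
        assert aug.n_reactions == engro1.n_reactions + len(present)
        assert len(present) == 20  # 23-species panel minus 3 unrepresentable


def test_objective_requires_nonzero_weight():
    with pytest.raises(ValueError):
        Objective({"x": 0.0})
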