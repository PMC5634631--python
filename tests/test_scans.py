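"""Growth landscapes, critical oxygen, TCA modes, yields, blood gas."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from engroflux.fba import fba_optimize
from engroflux.network import set_availability
from engroflux.scans import (
    BloodGasParams,
    blood_oxygen_availability,
    constrained_tca_modes,
    find_critical_o2,
    growth_landscape,
    sensitivity_scans,
    set_biomass_variant,
    set_pros,
)
from engroflux.yields import (
    PO_SENTINEL,
    effective_po,
    route_ledger,
    route_yield_table,
)


class TestGrowthLandscape:
    def test_all_zero_availability_means_no_growth(self, engro1):
        df = growth_landscape(engro1, {"glucose": [0.0], "oxygen": [0.0]})
        assert df["biomass"].iloc[0] == pytest.approx(0.0, abs=1e-9)

    def test_oxygen_surplus_plateau(self, engro1):
        """With minimal glutamine, growth stops responding to oxygen once
        O2GR >= 6 (all glucose already fully oxidized)."""
        base = set_availability(engro1, "glutamine_uptake", 1.0)
        df = growth_landscape(base, {"glucose": [3.0], "oxygen": [22.5, 30, 60]})
        vals = df["biomass"].to_numpy()
        assert vals[1] == pytest.approx(vals[0], rel=1e-6)
        assert vals[2] == pytest.approx(vals[0], rel=1e-6)

    def test_growth_nondecreasing_in_each_axis(self, engro1):
        df = growth_landscape(
            engro1,
            {"glucose": [2.0, 5.0, 10.0], "oxygen": [5.0, 10.0, 20.0]},
        )
        piv = df.pivot(index="glucose", columns="oxygen", values="biomass")
        assert (piv.diff(axis=0).iloc[1:] >= -1e-8).all().all()
        assert (piv.diff(axis=1).iloc[:, 1:] >= -1e-8).all().all()

    @settings(max_examples=15, deadline=None)
    @given(st.floats(0.5, 20.0), st.floats(0.5, 20.0))
    def test_relaxing_any_bound_never_lowers_the_optimum(self, engro1, glc, o2):
        a = growth_landscape(engro1, {"glucose": [glc], "oxygen": [o2]})
        b = growth_landscape(engro1, {"glucose": [glc * 1.5], "oxygen": [o2]})
        assert b["biomass"].iloc[0] >= a["biomass"].iloc[0] - 1e-8

    def test_fva_check_reports_ranges(self, engro1):
        df = growth_landscape(engro1, {"glucose": [10.0]}, fva_check=True)
        assert "range_lactate" in df.columns
        assert np.isfinite(df["range_lactate"].iloc[0])


class TestCriticalOxygen:
    def test_criteria_agree_within_resolution(self, engro1):
        a = find_critical_o2(engro1, 5.0, 20.0, "pdh-zero")
        b = find_critical_o2(engro1, 5.0, 20.0, "lactate-max")
        assert abs(a.critical_oxygen - b.critical_oxygen) <= 0.2

    def test_nondecreasing_in_glutamine(self, engro1):
        """More glutamine soaks up more oxygen before glucose oxidation
        becomes worthwhile: critical O2GR non-decreasing in QGR."""
        crits = [
            find_critical_o2(engro1, 5.0, q, "pdh-zero").critical_oxygen
            for q in (5.0, 10.0, 20.0)
        ]
        assert crits == sorted(crits)

    def test_rejects_nonpositive_nutrients(self, engro1):
        with pytest.raises(ValueError):
            find_critical_o2(engro1, 0.0, 10.0)

    def test_unmet_criterion_reports_range(self, engro1):
        with pytest.raises(RuntimeError, match="criterion not met"):
            find_critical_o2(engro1, 1.0, 1.0, "pdh-zero", o2_max=2.0)


class TestTCAModes:
    @pytest.mark.parametrize(
        "scenario,objective,expected_mode",
        [
            ("control", "biomass", "branched"),
            ("control", "ATP", "truncated"),
            ("no-lactate", "biomass", "cyclic"),
            ("no-glucose", "biomass", "branched"),
            ("no-glucose-no-lactate-pyruvate-allowed", "biomass", "branched"),
        ],
    )
    def test_flux_modes_at_critical_oxygen(
        self, critical_net, scenario, objective, expected_mode
    ):
        _, mode = constrained_tca_modes(critical_net, scenario, objective)
        assert mode == expected_mode

    def test_blocking_lactate_costs_a_modest_drop(self, critical_net):
        grow, _ = constrained_tca_modes(critical_net, "control", "biomass")
        no_lac, _ = constrained_tca_modes(critical_net, "no-lactate", "biomass")
        assert no_lac.objective_value < grow.objective_value
        assert no_lac.objective_value > 0.7 * grow.objective_value

    def test_unknown_scenario_rejected(self, engro1):
        with pytest.raises(KeyError):
            constrained_tca_modes(engro1, "no-caffeine")


class TestEffectivePO:
    @pytest.mark.parametrize("pros,expected", [(0.0, 3.0), (0.25, 1.8), (0.5, 1.0)])
    def test_formula_values(self, pros, expected):
        assert effective_po(pros) == pytest.approx(expected)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            effective_po(1.0)

    @settings(max_examples=40, deadline=None)
    @given(st.floats(0.0, 0.95))
    def test_matches_route_accounting_for_nadh_only_route(self, engro1, pros):
        """Closed-form vs ledger equivalence: a route whose only output is
        NAD(P)H has P/O equal to the effective P/O formula, at any pROS."""
        from engroflux.yields import _yield_from_ledger

        ry = _yield_from_ledger("nadh_only", {"nadh": 1.0}, pros)
        assert ry.po == pytest.approx(effective_po(pros), rel=1e-12)

    def test_route_ledger_rejects_unbalanced_route(self, engro1):
        with pytest.raises(ValueError, match="unbalanced"):
            route_ledger(engro1, {"HEX1": 1.0})  # stray g6p

    def test_route_ledger_rejects_respiratory_reactions(self, engro1):
        with pytest.raises(ValueError, match="respiratory"):
            route_ledger(engro1, {"CPLX1": 1.0})


class TestYieldTable:
    def test_fermentation_sentinel(self, engro1):
        df = route_yield_table(engro1, pros=0.25)
        assert df.loc["glc_to_lactate", "po"] == PO_SENTINEL
        assert df.loc["glc_to_lactate", "o2"] == pytest.approx(0.0)

    def test_glutamine_beats_glucose_per_oxygen(self, engro1):
        """The core energetic argument: partial glutamine oxidation to
        lactate yields more ATP per O than respiring glucose instead of
        fermenting it, once Complex I leaks electrons to superoxide."""
        df = route_yield_table(engro1, pros=0.25)
        gln = df.loc["gln_to_lactate", "po"]
        glc = df.loc["glc_respiration_vs_fermentation", "po"]
        assert gln > glc
        assert gln == pytest.approx(2.2, abs=1e-9)
        assert glc == pytest.approx(2.0, abs=1e-9)

    def test_without_ros_all_respiration_is_equivalent(self, engro1):
        df = route_yield_table(engro1, pros=0.0)
        for row in (
            "gln_to_lactate",
            "gln_to_pyruvate",
            "gln_respiration",
            "glc_respiration_vs_fermentation",
            "glc_to_pyruvate_vs_lactate",
        ):
            assert df.loc[row, "po"] == pytest.approx(3.0, abs=1e-9)

    def test_acetyl_coa_yields(self, engro1):
        df = route_yield_table(engro1, pros=0.25)
        assert df.loc["glc_to_accoa_vs_lactate", "accoa_yield"] == pytest.approx(2.0)
        assert df.loc["gln_to_accoa_reductive", "accoa_yield"] == pytest.approx(1.0)
        assert df.loc["gln_to_two_accoa_combined", "accoa_yield"] == pytest.approx(2.0)


class TestSensitivity:
    def test_bundled_pros_reproduces_baseline(self, engro1):
        """Rebuilding Complex I at the bundled pROS (0.25) is a no-op."""
        rebuilt = set_pros(engro1, 0.25)
        a = fba_optimize(engro1, engro1.biomass_reaction_id)
        b = fba_optimize(rebuilt, rebuilt.biomass_reaction_id)
        assert b.objective_value == pytest.approx(a.objective_value, rel=1e-9)

    def test_more_ros_means_more_fermentation(self, critical_net):
        df = sensitivity_scans(critical_net, "pros", [0.0, 0.25, 0.5])
        lac = df["lactate"].to_numpy()
        assert lac[2] > lac[0]

    def test_biomass_variants_mostly_spare_the_carbon_backbone(self, critical_net):
        """Skewing the NEAA composition mainly reroutes amino-acid synthesis:
        serine synthesis per unit growth swings several-fold, while the
        growth optimum, the lactate yield and the reductive-carboxylation
        mode barely move (PDH stays a small fraction of glycolytic flux)."""
        df = sensitivity_scans(
            critical_net, "biomass_variant", ["NEAA_STD", "NEAA_80_20", "NEAA_20_80"]
        )
        assert (df["aconitase"] < 0).all()
        biomass = df["biomass"].to_numpy()
        assert np.ptp(biomass) < 0.02 * biomass.max()
        lac_per_glc = (df["lactate"] / 10.0).to_numpy()
        assert np.ptp(lac_per_glc) < 0.15 * lac_per_glc.max()
        glycolytic_pyruvate = 2 * 10.0
        assert (df["pdh"] < 0.15 * glycolytic_pyruvate).all()
        sers = []
        for variant in ("NEAA_STD", "NEAA_80_20", "NEAA_20_80"):
            v = set_biomass_variant(critical_net, variant)
            state = fba_optimize(v, v.biomass_reaction_id)
            sers.append(state["SERS"] / state.objective_value)
        assert max(sers) > min(sers) * 2.0

    def test_complex_i_capacity_mirrors_oxygen_limitation(self, engro1):
        """Capping Complex I reproduces the qualitative oxygen-availability
        response: less capacity, less growth, more lactate per biomass."""
        df = sensitivity_scans(engro1, "complexI_capacity", [5.0, 20.0, 60.0])
        bio = df["biomass"].to_numpy()
        assert np.all(np.diff(bio) >= -1e-8)
        ratio = df["lactate"] / df["biomass"]
        assert ratio.iloc[0] > ratio.iloc[-1]


class TestBloodGas:
    def test_gas_law_route(self):
        out = blood_oxygen_availability(BloodGasParams())
        assert out["oxygen_gas_law_mM"] == pytest.approx(
            760 * 0.2 / (62 * 310) * 1000, rel=1e-12
        )
        assert out["oxygen_gas_law_mM"] == pytest.approx(8.0, abs=0.2)

    def test_hemoglobin_route(self):
        out = blood_oxygen_availability(BloodGasParams())
        assert out["oxygen_hemoglobin_mM"] == pytest.approx(9.4, abs=0.1)

    def test_ratio_far_below_full_respiration(self):
        out = blood_oxygen_availability(BloodGasParams())
        assert out["o2_glucose_ratio"] < 2.0

    def test_nonpositive_parameter_rejected(self):
        with pytest.raises(ValueError):
            BloodGasParams(pressure_mmHg=0.0)
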