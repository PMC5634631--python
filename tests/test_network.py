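"""Model container, IO dialects and structural validation."""

import numpy as np
import pytest

from engroflux.network import (
    ModelParseError,
    NetworkValidationError,
    Reaction,
    build_network,
    format_equation,
    load_network,
    parse_equation,
    set_availability,
    verify_loopless,
    write_network,
)
from engroflux.fba import fba_optimize
from engroflux.synthetic import ToyNetworkSpec, make_toy_network

PATHWAY_CARDINALITIES = {
    "glycolysis": 10,
    "tca": 9,
    "oxphos": 2,
    "glutamine": 4,
    "glutathione": 10,
    "urea": 5,
    "fatty acid": 2,
    "ppp": 5,
    "amino acid": 13,
}


class TestCoreModel:
    def test_dimensions(self, engro1):
        assert engro1.n_reactions == 84
        assert engro1.n_metabolites == 67
        assert engro1.stoichiometric_matrix().shape == (67, 84)

    def test_pathway_cardinalities(self, engro1):
        for pathway, count in PATHWAY_CARDINALITIES.items():
            assert len(engro1.reactions_in_pathway(pathway)) == count, pathway

    def test_role_map_resolves(self, engro1):
        from engroflux.network import ROLE_NAMES

        for role in ROLE_NAMES:
            assert engro1.role(role).id  # raises KeyError if unmapped

    def test_exchanges_are_single_metabolite(self, engro1):
        for rxn in engro1.exchange_reactions():
            assert len(rxn.stoichiometry) == 1

    def test_acetyl_coa_dual_pool(self, engro1):
        assert engro1.has_metabolite("accoa")
        assert engro1.has_metabolite("accoa_c")

    def test_columns_match_file_equations(self, engro1, tmp_path):
        """No silent coefficient drops: every nonzero of S equals the
        coefficient written in the model file."""
        S = engro1.stoichiometric_matrix()
        for j, rxn in enumerate(engro1.reactions):
            col = {
                engro1.metabolites[i].id: S[i, j] for i in np.nonzero(S[:, j])[0]
            }
            assert col == rxn.stoichiometry


class TestEquations:
    @pytest.mark.parametrize(
        "eq,expected",
        [
            ("a => b", {"a": -1.0, "b": 1.0}),
            ("2 a + b <=> 3 c", {"a": -2.0, "b": -1.0, "c": 3.0}),
            ("=> glc", {"glc": 1.0}),
            ("lac =>", {"lac": -1.0}),
            ("0.5 x + x => y", {"x": -1.5, "y": 1.0}),
        ],
    )
    def test_parse(self, eq, expected):
        assert parse_equation(eq) == expected

    def test_round_trip(self):
        stoich = {"glc": -1.0, "atp": -1.0, "g6p": 1.0, "adp": 1.0}
        assert parse_equation(format_equation(stoich)) == stoich

    def test_no_arrow_is_parse_error(self):
        with pytest.raises(ModelParseError):
            parse_equation("a + b", "RX1")


class TestIO:
    def test_malformed_row_names_line(self, tmp_path):
        bad = tmp_path / "bad.tsv"
        bad.write_text(
            "id\tname\tequation\tlower_bound\tupper_bound\tpathway\n"
            "R1\tok\ta => b\t0\t10\tp\n"
            "R2\tbroken\ta ++ b\t0\t10\tp\n"
        )
        with pytest.raises(ModelParseError, match="R2"):
            load_network(bad)

    def test_duplicate_ids_rejected(self, tmp_path):
        bad = tmp_path / "dup.tsv"
        bad.write_text(
            "id\tname\tequation\tlower_bound\tupper_bound\tpathway\n"
            "R1\tx\ta => b\t0\t10\tp\n"
            "R1\ty\tb => a\t0\t10\tp\n"
        )
        with pytest.raises(NetworkValidationError, match="duplicate"):
            load_network(bad)

    def test_three_reaction_toy_file(self, tmp_path):
        toy = tmp_path / "toy.tsv"
        toy.write_text(
            "id\tname\tequation\tlower_bound\tupper_bound\tpathway\n"
            "up\t\t=> A\t0\t5\texchange\n"
            "conv\t\tA => B\t0\t1000\tcore\n"
            "out\t\tB =>\t0\t1000\texchange\n"
        )
        net = load_network(toy)
        assert net.n_reactions == 3
        assert net.n_metabolites == 2
        assert {r.id for r in net.exchange_reactions()} == {"up", "out"}

    @pytest.mark.parametrize("dialect", ["tabular", "sbml"])
    def test_round_trip_engro1(self, engro1, tmp_path, dialect):
        """Write -> read preserves matrix, bounds and reversibilities."""
        path = tmp_path / f"model.{dialect}"
        write_network(engro1, path, dialect=dialect)
        back = load_network(path, dialect=dialect)
        assert [r.id for r in back.reactions] == [r.id for r in engro1.reactions]
        np.testing.assert_allclose(
            back.stoichiometric_matrix(), engro1.stoichiometric_matrix(), atol=1e-9
        )
        np.testing.assert_allclose(back.bounds()[0], engro1.bounds()[0])
        np.testing.assert_allclose(back.bounds()[1], engro1.bounds()[1])
        assert [r.reversible for r in back.reactions] == [
            r.reversible for r in engro1.reactions
        ]

    def test_sbml_preserves_pathways(self, engro1, tmp_path):
        path = tmp_path / "m.xml"
        write_network(engro1, path, dialect="sbml")
        back = load_network(path, dialect="sbml")
        assert [r.pathway for r in back.reactions] == [r.pathway for r in engro1.reactions]


class TestAvailability:
    def test_sets_upper_bound_only(self, engro1):
        net = set_availability(engro1, "glucose_uptake", 7.5)
        rid = net.named_reactions["glucose_uptake"]
        assert net.reaction(rid).upper_bound == 7.5
        assert net.reaction(rid).lower_bound == 0.0
        others = [r for r in net.reactions if r.id != rid]
        for mine, orig in zip(others, (r for r in engro1.reactions if r.id != rid)):
            assert (mine.lower_bound, mine.upper_bound) == (
                orig.lower_bound,
                orig.upper_bound,
            )

    def test_fix_pins_both_bounds(self, engro1):
        net = set_availability(engro1, "glutamine_uptake", 3.0, fix=True)
        rxn = net.role("glutamine_uptake")
        assert (rxn.lower_bound, rxn.upper_bound) == (3.0, 3.0)

    def test_negative_value_rejected(self, engro1):
        with pytest.raises(ValueError):
            set_availability(engro1, "glucose_uptake", -1.0)

    def test_unknown_role_rejected(self, engro1):
        with pytest.raises(KeyError):
            set_availability(engro1, "caffeine_uptake", 1.0)

    def test_no_oxygen_means_no_growth(self, engro1):
        net = set_availability(engro1, "oxygen_uptake", 0.0)
        state = fba_optimize(net, net.biomass_reaction_id)
        assert state.status == "optimal"
        assert state.objective_value == pytest.approx(0.0, abs=1e-9)


class TestLoopless:
    def test_core_model_is_loop_free(self, engro1):
        assert verify_loopless(engro1) == []

    def test_loop_pair_flagged(self):
        net, answers = make_toy_network(ToyNetworkSpec(topology="loop_pair"))
        assert tuple(verify_loopless(net)) == answers.loop_members

    def test_linear_chain_clean(self):
        net, _ = make_toy_network(ToyNetworkSpec(topology="chain", length=4))
        assert verify_loopless(net) == []


def test_build_network_infers_boundary_metabolites():
    net = build_network(
        [
            Reaction("up", {"A": 1.0}, 0, 5),
            Reaction("conv", {"A": -1.0, "B": 1.0}, 0, 10),
            Reaction("out", {"B": -1.0}, 0, 10),
        ]
    )
    assert net.metabolite("A").is_boundary
    assert net.metabolite("B").is_boundary
    S = net.stoichiometric_matrix()
    j = net.reaction_index("conv")
    col = S[:, j]
    assert sorted(col) == [-1.0, 1.0]


def test_empty_network_matrix():
    with pytest.raises(NetworkValidationError):
        Reaction("empty", {}, 0, 1)
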