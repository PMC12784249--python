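"""eGPR network construction and the forward-closure oracle."""

import json

import pytest

from conftest import network
from gmisnet.egpr import (
    InterventionSet,
    aux_node,
    build_egpr_network,
    forward_closure,
    gene_node,
)
from gmisnet.model import ModelValidationError


class TestConstruction:
    def test_single_input_gene_shape(self):
        net = network("g")
        expected = {gene_node("g", s) for s in ("ON", "OFF")}
        expected |= {aux_node(k, "g", s) for k in "yue" for s in ("ON", "OFF")}
        expected |= {f"R::R::{s}" for s in ("ON", "OFF")}
        assert expected <= set(net.nodes)
        assert len(net.H) == 4
        assert len(net.output_exchanges) == 2
        # every y/u/e node has exactly one input exchange
        for node in expected:
            if node.split("::")[0] in ("y", "u", "e"):
                assert node in net.input_exchanges

    def test_h_size_scales_with_genes(self, fig1_networks):
        for net in fig1_networks.values():
            assert len(net.H) == 4 * len(net.genes)

    def test_negation_compiles_to_off_side(self):
        net = network("not g")
        on_gates = [g for g in net.gates if g.output == "R::R::ON"]
        off_gates = [g for g in net.gates if g.output == "R::R::OFF"]
        assert on_gates and on_gates[0].inputs == {gene_node("g", "OFF")}
        assert off_gates and off_gates[0].inputs == {gene_node("g", "ON")}

    def test_stoichiometry_is_boolean_and_irreversible(self, r3_network):
        S, nodes, rxns = r3_network.stoichiometry()
        assert S.shape == (len(nodes), len(rxns))
        assert set(S.data) <= {-1.0, 1.0}
        # each gate produces exactly one node
        for gate in r3_network.gates:
            assert sum(1 for _ in [gate.output]) == 1

    def test_shared_subexpressions_share_intermediates(self):
        net = network("(g1 and g2) or ((g1 and g2) and g3)")
        inter = [n for n in net.nodes if n.startswith("I::")]
        # the duplicated (g1 and g2) conjunct maps to one shared node per side
        assert len(inter) == len(set(inter))

    def test_json_dump_round_trips(self, r3_network, tmp_path):
        r3_network.to_json(tmp_path / "net.json")
        payload = json.loads((tmp_path / "net.json").read_text())
        assert payload["reaction"] == "r3"
        assert sorted(payload["H"]) == sorted(r3_network.H)
        assert len(payload["gates"]) == r3_network.gate_count()


class TestForwardClosure:
    @pytest.mark.parametrize(
        "atoms,on_derivable,off_derivable",
        [
            ((), True, True),          # free input: both sides reachable
            (("g-",), False, True),
            (("g+",), True, False),
        ],
    )
    def test_single_gene_cases(self, atoms, on_derivable, off_derivable):
        net = network("g")
        iv = InterventionSet.of(*atoms) if atoms else None
        closure = forward_closure(net, iv)
        assert ("R::R::ON" in closure) is on_derivable
        assert ("R::R::OFF" in closure) is off_derivable

    def test_committed_sides_only(self):
        net = network("g")
        closure = forward_closure(net, InterventionSet.of("g-"))
        assert aux_node("y", "g", "OFF") in closure
        assert aux_node("y", "g", "ON") not in closure
        assert aux_node("u", "g", "OFF") in closure
        assert aux_node("u", "g", "ON") not in closure

    def test_unknown_gene_rejected(self):
        net = network("g")
        with pytest.raises(ModelValidationError):
            forward_closure(net, InterventionSet.of("h-"))

    def test_ko_ki_same_gene_rejected(self):
        with pytest.raises(ValueError):
            InterventionSet.of("g-", "g+")

    def test_fixpoint_is_stable(self, r3_network):
        iv = InterventionSet.of("g3-")
        first = forward_closure(r3_network, iv)
        second = forward_closure(r3_network, iv)
        assert first == second

    def test_regulated_gene_semantics(self, r3_network):
        # g4 = g7 or not g6: knock-in of g6 alone leaves g4 ON via free g7
        closure = forward_closure(r3_network, InterventionSet.of("g6+"))
        assert gene_node("g4", "ON") in closure
        closure = forward_closure(r3_network, InterventionSet.of("g6+", "g7-"))
        assert gene_node("g4", "ON") not in closure
        assert gene_node("g4", "OFF") in closure

    def test_augmentation_semantics_per_commitment(self):
        """g = (e AND y) OR u behaves as the committed intervention state.

        With no intervention both sides of the gene are reachable (the e
        node is genuinely free); KO removes the ON side; KI removes the OFF
        side.  This pins the equivalence of the two augmentation readings
        on the feasible (no KO+KI) space.
        """
        net = network("g")
        for atoms, on_ok, off_ok in [((), True, True), (("g-",), False, True),
                                     (("g+",), True, False)]:
            closure = forward_closure(net, InterventionSet.of(*atoms) if atoms else None)
            assert (gene_node("g", "ON") in closure) is on_ok
            assert (gene_node("g", "OFF") in closure) is off_ok


def test_reconvergent_negation_divergence_documented():
    """Flux derivability lets a free input feed both polarities at once.

    With R = g and (not g), strict Boolean satisfiability would make R
    impossible, but the ON/OFF relaxation derives R from the two free e
    sides.  The oracle implements the relaxation (which is what the dual
    MILP encodes); this test documents the divergence case.
    """
    net = network("g and not g")
    closure = forward_closure(net, None)
    assert "R::R::ON" in closure
    # committing either intervention resolves the polarity and blocks R
    assert "R::R::ON" not in forward_closure(net, InterventionSet.of("g-"))
    assert "R::R::ON" not in forward_closure(net, InterventionSet.of("g+"))
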