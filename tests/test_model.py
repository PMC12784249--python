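"""Model I/O, regulatory layers and eGPR rule construction."""

import numpy as np
import pytest


from gmisnet.model import (
    MetabolicModel,
    ModelValidationError,
    RegulatoryLayer,
    build_egpr_rule,
    load_json_model,
    load_regulatory_layer,
    load_sbml_model,
    save_json_model,
    save_regulatory_layer,
)
from gmisnet.rules import parse_gpr


def test_json_round_trip(fig1, tmp_path):
    model, _ = fig1
    save_json_model(model, tmp_path / "m.json")
    back = load_json_model(tmp_path / "m.json")
    assert back.reactions == model.reactions
    assert back.metabolites == model.metabolites
    assert back.biomass_reaction == model.biomass_reaction
    assert back.lower_bounds == model.lower_bounds
    assert back.upper_bounds == model.upper_bounds
    assert {r: back.gpr[r] for r in back.reactions} == model.gpr
    assert np.allclose(back.stoichiometry.toarray(), model.stoichiometry.toarray())


def test_sbml_round_trip(fig1, tmp_path):
    import cobra
    import cobra.io

    model, _ = fig1
    cb = cobra.Model(model.id)
    mets = {m: cobra.Metabolite(m, compartment="c") for m in model.metabolites}
    dense = model.stoichiometry.toarray()
    for j, rid in enumerate(model.reactions):
        rxn = cobra.Reaction(rid)
        rxn.lower_bound = model.lower_bounds[j]
        rxn.upper_bound = model.upper_bounds[j]
        cb.add_reactions([rxn])
        rxn.add_metabolites(
            {mets[m]: dense[i, j] for i, m in enumerate(model.metabolites) if dense[i, j]}
        )
        rule = model.gpr[rid]
        rxn.gene_reaction_rule = "" if rule.is_true() else rule.to_string()
    cb.objective = "rBIO"
    cobra.io.write_sbml_model(cb, str(tmp_path / "m.xml"))

    back = load_sbml_model(tmp_path / "m.xml")
    assert set(back.reactions) == set(model.reactions)
    assert back.biomass_reaction == "rBIO"
    assert back.gpr["r3"] == parse_gpr("g3 or g4")
    assert back.gpr["rBIO"].is_true()


def test_model_invariants(fig1):
    model, _ = fig1
    with pytest.raises(ModelValidationError):
        MetabolicModel(
            id="bad",
            metabolites=model.metabolites,
            reactions=model.reactions,
            stoichiometry=model.stoichiometry,
            lower_bounds=[0, 0, 0, 10.0],
            upper_bounds=[1000, 1000, 1000, 5.0],  # lb > ub on rBIO
            biomass_reaction="rBIO",
            gpr=dict(model.gpr),
        )
    with pytest.raises(ModelValidationError):
        MetabolicModel(
            id="bad",
            metabolites=model.metabolites,
            reactions=model.reactions,
            stoichiometry=model.stoichiometry,
            lower_bounds=model.lower_bounds,
            upper_bounds=model.upper_bounds,
            biomass_reaction="nope",
            gpr=dict(model.gpr),
        )


class TestRegulatoryLayer:
    def test_tsv_round_trip_and_aliases(self, tmp_path):
        p = tmp_path / "layer.tsv"
        p.write_text(
            "source\ttarget\tsign\n"
            "g6\tg3\t+\n"
            "g6\tg3\t+1\n"          # duplicate, dropped
            "g7\tg4\tactivation\n"
            "g6\tg4\tinhibition\n"
        )
        layer = load_regulatory_layer(p)
        assert layer.edges == [("g6", "g3", 1), ("g7", "g4", 1), ("g6", "g4", -1)]
        save_regulatory_layer(layer, tmp_path / "back.tsv")
        assert load_regulatory_layer(tmp_path / "back.tsv").edges == layer.edges

    def test_self_loop_rejected(self):
        with pytest.raises(ModelValidationError):
            RegulatoryLayer(edges=[("g6", "g6", 1)])

    def test_bad_sign_rejected(self, tmp_path):
        p = tmp_path / "layer.tsv"
        p.write_text("source\ttarget\tsign\ng6\tg3\tmaybe\n")
        with pytest.raises(ModelValidationError):
            load_regulatory_layer(p)

    def test_conflicting_signs_kept_with_warning(self):
        with pytest.warns(UserWarning):
            layer = RegulatoryLayer(edges=[("g6", "g3", 1), ("g6", "g3", -1)])
        assert len(layer.edges) == 2


class TestBuildEgprRule:
    def test_depth_zero_is_plain_gpr(self, fig1):
        model, layers = fig1
        for rxn in model.reactions:
            rs = build_egpr_rule(rxn, model, layers, depth=0)
            assert rs.rules[rxn] == model.gpr[rxn]
            assert rs.input_genes == model.gpr[rxn].genes()
            assert rs.all_genes == model.gpr[rxn].genes()

    def test_r3_gains_regulators(self, fig1):
        model, layers = fig1
        rs = build_egpr_rule("r3", model, layers, depth=1)
        assert rs.all_genes - model.gpr["r3"].genes() == {"g6", "g7"}
        assert rs.input_genes == {"g3", "g6", "g7"}
        assert rs.rules["g4"] == parse_gpr("g7 or not g6")

    def test_monotone_growth_in_depth(self, fig1):
        model, layers = fig1
        two = layers + [RegulatoryLayer(edges=[("g8", "g7", 1)], layer_index=2)]
        previous = frozenset()
        for depth in (0, 1, 2):
            rs = build_egpr_rule("r3", model, two, depth=depth)
            assert previous <= rs.all_genes
            previous = rs.all_genes
        assert "g8" in previous

    def test_cycle_edges_dropped_deterministically(self, fig1):
        model, _ = fig1
        loopy = RegulatoryLayer(edges=[("g1", "g3", 1), ("g3", "g1", 1)])
        rs = build_egpr_rule("r1", model, [loopy], depth=2)
        rs.check_acyclic()
        assert rs.dropped_edges == [("g1", "g3", 1)]
        # stable edge order: g3 -> g1 (loaded first reachable) survives
        assert rs.rules["g1"] == parse_gpr("g3")

    def test_depth_cap(self, fig1):
        model, layers = fig1
        with pytest.raises(ModelValidationError):
            build_egpr_rule("r3", model, layers, depth=3)

    def test_conjunctive_strategy_hook(self, fig1):
        model, layers = fig1
        rs = build_egpr_rule("r3", model, layers, depth=1, strategy="conjunctive")
        assert rs.rules["g4"] == parse_gpr("g7 and not g6")

    def test_topological_order_is_checkable(self, fig1):
        model, layers = fig1
        rs = build_egpr_rule("r3", model, layers, depth=1)
        order = rs.topological_genes()
        pos = {g: i for i, g in enumerate(order)}
        for gene, rule in rs.rules.items():
            if gene == rs.reaction:
                continue
            assert all(pos[dep] < pos[gene] for dep in rule.genes())
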