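"""Genome-level gMIS enumeration, FBA primitive and taxonomy."""

import pytest

from conftest import random_toys
from gmisnet.egpr import InterventionSet
from gmisnet.fixtures import FIG1_GMCS_LABELS, FIG1_GMIS_LABELS
from gmisnet.gf import build_gf, blocked_reactions
from gmisnet.gmis import classify_gmis, enumerate_gmis, max_biomass
from gmisnet.model import ModelValidationError
from gmisnet.pipeline import per_reaction_mcs
from gmisnet.config import MilpParams


@pytest.fixture(scope="module")
def fig1_gf(fig1, fast_params):
    model, layers = fig1
    per, _ = per_reaction_mcs(model, layers, 1, fast_params)
    return build_gf(per, reactions=model.reactions)


class TestMaxBiomass:
    def test_wild_type_grows(self, fig1):
        model, _ = fig1
        assert max_biomass(model) > 1.0

    def test_deleting_any_pathway_reaction_is_lethal(self, fig1):
        model, _ = fig1
        for rxn in ("r1", "r2", "r3", "rBIO"):
            assert max_biomass(model, {rxn}) <= 1e-6

    def test_unknown_deletion_rejected(self, fig1):
        model, _ = fig1
        with pytest.raises(ModelValidationError):
            max_biomass(model, {"nope"})


class TestWorkedExample:
    def test_six_gmis(self, fig1, fig1_gf):
        model, _ = fig1
        results = enumerate_gmis(model, fig1_gf)
        assert sorted(r.interventions.label() for r in results) == \
            sorted(FIG1_GMIS_LABELS)
        assert len(results) == 6

    def test_four_ko_only_gmcs(self, fig1, fig1_gf):
        model, _ = fig1
        results = enumerate_gmis(model, fig1_gf, allow_ki=False)
        assert sorted(r.interventions.label() for r in results) == \
            sorted(FIG1_GMCS_LABELS)
        assert len(results) == 4

    def test_categories(self, fig1, fig1_gf):
        model, _ = fig1
        by_label = {
            r.interventions.label(): r.category
            for r in enumerate_gmis(model, fig1_gf)
        }
        assert by_label["g1-"] == "essential-gene"
        assert by_label["g2-;g7+"] == "SDL"
        assert by_label["g3-;g6+;g7-"] == "mixed"
        assert by_label["g3-;g4-"] == "SL"


@pytest.mark.parametrize(
    "atoms,category",
    [
        (("gA-",), "essential-gene"),
        (("gA-", "gB-"), "SL"),
        (("gA-", "gB-", "gC-"), "SL"),
        (("gA+",), "TSG"),
        (("gA-", "gB+"), "SDL"),
        (("gA+", "gB+"), "TSGC"),
        (("gA-", "gB-", "gC+"), "mixed"),
    ],
)
def test_taxonomy(atoms, category):
    assert classify_gmis(InterventionSet.of(*atoms)) == category


def _toy_gf(model, layers, params):
    per, _ = per_reaction_mcs(model, layers, 1, params)
    return build_gf(per, reactions=model.reactions)


class TestEngines:
    def test_milp_engine_matches_exhaustive(self, fig1, fig1_gf, fast_params):
        model, _ = fig1
        a = enumerate_gmis(model, fig1_gf, engine="exhaustive")
        b = enumerate_gmis(model, fig1_gf, engine="milp", params=fast_params)
        assert [r.interventions for r in a] == [r.interventions for r in b]

    def test_engine_equivalence_on_random_toys(self, fast_params):
        for _spec, model, layers in random_toys(
            8, start_seed=200, n_metabolites=3, n_regulators=2,
            inhibition_fraction=0.4,
        ):
            gf = _toy_gf(model, layers, fast_params)
            a = enumerate_gmis(model, gf, max_length=4, engine="exhaustive")
            b = enumerate_gmis(model, gf, max_length=4, engine="milp",
                               params=fast_params)
            assert [r.interventions for r in a] == [r.interventions for r in b]

    def test_negation_free_models_need_no_knockins(self, fast_params):
        for _spec, model, layers in random_toys(
            5, start_seed=300, n_metabolites=3, n_regulators=2,
            inhibition_fraction=0.0,
        ):
            gf = _toy_gf(model, layers, fast_params)
            full = enumerate_gmis(model, gf, max_length=4)
            ko_only = enumerate_gmis(model, gf, max_length=4, allow_ki=False)
            assert all(not r.interventions.knockins() for r in full)
            assert [r.interventions for r in full] == \
                [r.interventions for r in ko_only]


class TestSolutionContracts:
    def test_lethality_and_subset_minimality(self, fig1, fig1_gf):
        model, _ = fig1
        for r in enumerate_gmis(model, fig1_gf):
            assert max_biomass(model, r.blocked) <= 1e-6
            for drop in r.interventions:
                rest = r.interventions.interventions - {drop}
                if not rest:
                    continue
                sub = InterventionSet(rest)
                assert max_biomass(model, blocked_reactions(fig1_gf, sub)) > 1e-6

    def test_antichain(self, fig1, fig1_gf):
        model, _ = fig1
        results = enumerate_gmis(model, fig1_gf)
        for a in results:
            for b in results:
                if a is not b:
                    assert not a.interventions.issubset(b.interventions)

    def test_atoms_outside_f_cannot_matter(self, fig1_gf):
        base = InterventionSet.of("g3-", "g4-")
        extended = InterventionSet.of("g3-", "g4-", "zz+")
        assert blocked_reactions(fig1_gf, base) == \
            blocked_reactions(fig1_gf, extended)

    def test_dead_wild_type_rejected(self, fig1, fig1_gf):
        model, _ = fig1
        import copy

        dead = copy.deepcopy(model)
        j = dead.reaction_index("r1")
        dead.upper_bounds[j] = 0.0
        with pytest.raises(ModelValidationError, match="no biomass"):
            enumerate_gmis(dead, fig1_gf)
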