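import pytest

from gmisnet.config import MilpParams
from gmisnet.egpr import build_egpr_network
from gmisnet.fixtures import FixtureSpec, fig1_fixture, random_imr_model
from gmisnet.model import EgprRuleSet, build_egpr_rule
from gmisnet.rules import parse_gpr


def rule_set(reaction_rule: str, gene_rules: dict[str, str] | None = None,
             reaction: str = "R") -> EgprRuleSet:
    """Hand-build an eGPR rule set from GPR-style strings."""
    gene_rules = gene_rules or {}
    rules = {reaction: parse_gpr(reaction_rule)}
    rules.update({g: parse_gpr(r) for g, r in gene_rules.items()})
    genes = set()
    for r in rules.values():
        genes |= r.genes()
    genes |= set(gene_rules)
    inputs = frozenset(g for g in genes if g not in gene_rules)
    return EgprRuleSet(
        reaction=reaction,
        rules=rules,
        input_genes=inputs,
        all_genes=frozenset(genes),
    )


def network(reaction_rule: str, gene_rules: dict[str, str] | None = None):
    return build_egpr_network(rule_set(reaction_rule, gene_rules))


@pytest.fixture(scope="session")
def fig1():
    return fig1_fixture()


@pytest.fixture(scope="session")
def fig1_rule_sets(fig1):
    model, layers = fig1
    return {
        rxn: build_egpr_rule(rxn, model, layers, depth=1)
        for rxn in model.reactions
    }


@pytest.fixture(scope="session")
def fig1_networks(fig1_rule_sets):
    return {rxn: build_egpr_network(rs) for rxn, rs in fig1_rule_sets.items()}


@pytest.fixture(scope="session")
def r3_network(fig1_networks):
    return fig1_networks["r3"]


@pytest.fixture(scope="session")
def fast_params():
    return MilpParams(max_size=5, time_limit_per_solution=30.0)


def random_toys(n: int, start_seed: int = 0, **overrides):
    """Deterministic stream of small random iMR models."""
    toys = []
    seed = start_seed
    while len(toys) < n:
        spec = FixtureSpec(seed=seed, **overrides)
        toys.append((spec, *random_imr_model(spec)))
        seed += 1
    return toys
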