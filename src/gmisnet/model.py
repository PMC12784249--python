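"""Integrated metabolic-regulatory (iMR) model containers and loaders.

The metabolic layer is a standard constraint-based model: stoichiometric
matrix ``S``, flux bounds, a designated biomass reaction and one GPR rule
per reaction.  Regulatory layers are signed directed edge lists
(activation +1 / inhibition -1) over gene symbols.  :func:`build_egpr_rule`
merges up to two regulatory levels into a reaction's GPR, producing the
extended GPR (eGPR) rule set from which artificial intervention networks
are compiled.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import networkx as nx
import pandas as pd
from scipy import sparse

from .rules import TRUE, BooleanRule, and_, lit, not_, or_, parse_gpr

__all__ = [
    "MetabolicModel",
    "RegulatoryLayer",
    "EgprRuleSet",
    "ModelValidationError",
    "load_json_model",
    "save_json_model",
    "load_sbml_model",
    "load_regulatory_layer",
    "save_regulatory_layer",
    "build_egpr_rule",
    "COMBINATION_STRATEGIES",
]

logger = logging.getLogger(__name__)


class ModelValidationError(ValueError):
    """A model, layer or rule set violates one of its structural invariants."""


@dataclass
class MetabolicModel:
    """A constraint-based metabolic model with GPR rules.

    ``stoichiometry`` is a sparse metabolites x reactions matrix; ``gpr``
    maps every reaction to a :class:`BooleanRule` (TRUE for spontaneous
    reactions).
    """

    id: str
    metabolites: list[str]
    reactions: list[str]
    stoichiometry: sparse.csc_matrix
    lower_bounds: list[float]
    upper_bounds: list[float]
    biomass_reaction: str
    gpr: dict[str, BooleanRule]

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        m, n = self.stoichiometry.shape
        if m != len(self.metabolites) or n != len(self.reactions):
            raise ModelValidationError(
                f"stoichiometry shape {self.stoichiometry.shape} does not match "
                f"{len(self.metabolites)} metabolites x {len(self.reactions)} reactions"
            )
        if self.biomass_reaction not in self.reactions:
            raise ModelValidationError(
                f"biomass reaction {self.biomass_reaction!r} not in reaction list"
            )
        if len(self.lower_bounds) != n or len(self.upper_bounds) != n:
            raise ModelValidationError("bound vectors do not match reaction count")
        for rxn, lb, ub in zip(self.reactions, self.lower_bounds, self.upper_bounds):
            if lb > ub:
                raise ModelValidationError(f"reaction {rxn}: lb {lb} > ub {ub}")
        missing = set(self.gpr) - set(self.reactions)
        if missing:
            raise ModelValidationError(f"GPR rules for unknown reactions: {sorted(missing)}")
        for rxn in self.reactions:
            self.gpr.setdefault(rxn, TRUE)

    @property
    def genes(self) -> list[str]:
        out: set[str] = set()
        for rule in self.gpr.values():
            out |= rule.genes()
        return sorted(out)

    def reaction_index(self, rxn: str) -> int:
        return self.reactions.index(rxn)


@dataclass
class RegulatoryLayer:
    """One signed directed regulatory layer (edge list)."""

    edges: list[tuple[str, str, int]]
    layer_index: int = 1

    def __post_init__(self) -> None:
        if self.layer_index < 1:
            raise ModelValidationError("layer_index must be positive")
        seen: set[tuple[str, str, int]] = set()
        clean: list[tuple[str, str, int]] = []
        for src, tgt, sign in self.edges:
            src, tgt = src.strip(), tgt.strip()
            if sign not in (+1, -1):
                raise ModelValidationError(
                    f"edge {src}->{tgt}: sign must be +1 or -1, got {sign!r}"
                )
            if src == tgt:
                raise ModelValidationError(f"self-loop edge on {src!r} not allowed")
            key = (src, tgt, sign)
            if key in seen:
                continue
            if (src, tgt, -sign) in seen:
                warnings.warn(
                    f"conflicting duplicate edge {src}->{tgt}: keeping both signs",
                    stacklevel=2,
                )
            seen.add(key)
            clean.append(key)
        self.edges = clean

    def regulators_of(self, gene: str) -> tuple[list[str], list[str]]:
        """(activators, repressors) of ``gene``, in stable edge order."""
        activators = [s for s, t, sign in self.edges if t == gene and sign == +1]
        repressors = [s for s, t, sign in self.edges if t == gene and sign == -1]
        return activators, repressors


@dataclass
class EgprRuleSet:
    """Extended GPR rule set for one target reaction.

    ``rules`` holds one Boolean rule per regulated gene plus the reaction
    node itself (key ``reaction``); ``input_genes`` (L(k)) are genes with no
    rule, free to take either state; ``all_genes`` is B(k), every gene the
    rule set mentions.
    """

    reaction: str
    rules: dict[str, BooleanRule]
    input_genes: frozenset[str]
    all_genes: frozenset[str]
    dropped_edges: list[tuple[str, str, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.reaction not in self.rules:
            raise ModelValidationError("rule set lacks a rule for the reaction node")
        if not self.input_genes <= self.all_genes:
            raise ModelValidationError("L(k) must be a subset of B(k)")
        bad = self.rules[self.reaction].genes() - self.all_genes
        if bad:
            raise ModelValidationError(f"reaction rule references unknown genes: {sorted(bad)}")
        self.check_acyclic()

    def dependency_graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.all_genes | {self.reaction})
        for node, rule in self.rules.items():
            for dep in rule.genes():
                g.add_edge(dep, node)
        return g

    def check_acyclic(self) -> None:
        g = self.dependency_graph()
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise ModelValidationError(f"cyclic rule dependencies: {cycle}")

    def topological_genes(self) -> list[str]:
        order = list(nx.topological_sort(self.dependency_graph()))
        return [n for n in order if n != self.reaction]


# ---------------------------------------------------------------------------
# JSON / SBML I/O
# ---------------------------------------------------------------------------

def load_json_model(path: str | Path) -> MetabolicModel:
    """Read the JSON model dialect.

    Layout: ``{"id": ..., "metabolites": [...], "reactions": [{"id", "lb",
    "ub", "stoich": {met: coef}, "gpr"}], "biomass": reaction_id}``.
    """
    data = json.loads(Path(path).read_text())
    metabolites = list(data["metabolites"])
    met_idx = {m: i for i, m in enumerate(metabolites)}
    reactions, lbs, ubs, gpr = [], [], [], {}
    mat = sparse.lil_matrix((len(metabolites), len(data["reactions"])))
    for j, rxn in enumerate(data["reactions"]):
        reactions.append(rxn["id"])
        lbs.append(float(rxn.get("lb", 0.0)))
        ubs.append(float(rxn.get("ub", 1000.0)))
        gpr[rxn["id"]] = parse_gpr(rxn.get("gpr", ""))
        for met, coef in rxn.get("stoich", {}).items():
            mat[met_idx[met], j] = float(coef)
    return MetabolicModel(
        id=data.get("id", Path(path).stem),
        metabolites=metabolites,
        reactions=reactions,
        stoichiometry=mat.tocsc(),
        lower_bounds=lbs,
        upper_bounds=ubs,
        biomass_reaction=data["biomass"],
        gpr=gpr,
    )


def save_json_model(model: MetabolicModel, path: str | Path) -> None:
    mat = model.stoichiometry.tocsc()
    rxns = []
    for j, rxn in enumerate(model.reactions):
        col = mat.getcol(j).tocoo()
        stoich = {model.metabolites[i]: float(v) for i, v in zip(col.row, col.data)}
        rule = model.gpr[rxn]
        rxns.append(
            {
                "id": rxn,
                "lb": model.lower_bounds[j],
                "ub": model.upper_bounds[j],
                "stoich": stoich,
                "gpr": "" if rule.is_true() else rule.to_string(),
            }
        )
    payload = {
        "id": model.id,
        "metabolites": model.metabolites,
        "reactions": rxns,
        "biomass": model.biomass_reaction,
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")


def load_sbml_model(path: str | Path, biomass_reaction: str | None = None) -> MetabolicModel:
    """Read an SBML (Level 3 + fbc) model; GPRs come from the fbc
    geneProductAssociation strings.  ``biomass_reaction`` defaults to the
    reaction carrying the model objective."""
    import cobra.io

    cb = cobra.io.read_sbml_model(str(path))
    metabolites = [m.id for m in cb.metabolites]
    met_idx = {m: i for i, m in enumerate(metabolites)}
    reactions, lbs, ubs, gpr = [], [], [], {}
    mat = sparse.lil_matrix((len(metabolites), len(cb.reactions)))
    for j, rxn in enumerate(cb.reactions):
        reactions.append(rxn.id)
        lbs.append(rxn.lower_bound)
        ubs.append(rxn.upper_bound)
        gpr[rxn.id] = parse_gpr(rxn.gene_reaction_rule)
        for met, coef in rxn.metabolites.items():
            mat[met_idx[met.id], j] = coef
    if biomass_reaction is None:
        objective = [r.id for r in cb.reactions if r.objective_coefficient]
        if len(objective) != 1:
            raise ModelValidationError(
                "cannot infer the biomass reaction; pass biomass_reaction explicitly"
            )
        biomass_reaction = objective[0]
    return MetabolicModel(
        id=cb.id or Path(path).stem,
        metabolites=metabolites,
        reactions=reactions,
        stoichiometry=mat.tocsc(),
        lower_bounds=lbs,
        upper_bounds=ubs,
        biomass_reaction=biomass_reaction,
        gpr=gpr,
    )


_SIGN_ALIASES = {
    "+": +1, "-": -1, "1": +1, "-1": -1, "+1": +1,
    "activation": +1, "inhibition": -1,
}


def load_regulatory_layer(path: str | Path, layer_index: int = 1) -> RegulatoryLayer:
    """Read a headered ``source<TAB>target<TAB>sign`` TSV edge list."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 3:
        raise ModelValidationError("regulatory layer TSV needs three columns")
    edges = []
    for _, row in df.iterrows():
        raw = str(row.iloc[2]).strip().lower()
        if raw not in _SIGN_ALIASES:
            raise ModelValidationError(f"unparseable regulatory sign {row.iloc[2]!r}")
        edges.append((str(row.iloc[0]), str(row.iloc[1]), _SIGN_ALIASES[raw]))
    return RegulatoryLayer(edges=edges, layer_index=layer_index)


def save_regulatory_layer(layer: RegulatoryLayer, path: str | Path) -> None:
    df = pd.DataFrame(layer.edges, columns=["source", "target", "sign"])
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# eGPR rule construction
# ---------------------------------------------------------------------------

def _combine_disjunctive(prior: BooleanRule | None,
                         activators: Sequence[str],
                         repressors: Sequence[str]) -> BooleanRule:
    """Gene is ON when some activator is ON or some repressor is OFF.

    This release-of-repression reading keeps joint requirements on the
    regulators when forcing the gene OFF (every activator must be silenced
    and every repressor engaged), which is what makes combined knock-in /
    knock-out interventions informative.  Default strategy.
    """
    block = or_([lit(a) for a in activators] + [not_(lit(r)) for r in repressors])
    if prior is None:
        return block
    return and_([prior, block])


def _combine_conjunctive(prior: BooleanRule | None,
                         activators: Sequence[str],
                         repressors: Sequence[str]) -> BooleanRule:
    """Gene needs some activator ON and every repressor OFF (strict AND)."""
    parts: list[BooleanRule] = []
    if activators:
        parts.append(or_(lit(a) for a in activators))
    parts.extend(not_(lit(r)) for r in repressors)
    block = and_(parts) if parts else TRUE
    if prior is None:
        return block
    return and_([prior, block])


COMBINATION_STRATEGIES: dict[str, Callable[..., BooleanRule]] = {
    "disjunctive": _combine_disjunctive,
    "conjunctive": _combine_conjunctive,
}


def build_egpr_rule(
    reaction: str,
    model: MetabolicModel,
    layers: Sequence[RegulatoryLayer],
    depth: int = 1,
    strategy: str = "disjunctive",
) -> EgprRuleSet:
    """Attach up to ``depth`` levels of upstream regulation to a GPR.

    Level ``d`` regulators of the genes reached at level ``d-1`` are drawn
    from ``layers[d-1]`` (the single layer is reused when only one is
    given).  Genes first reached at the deepest level keep no rule and form
    the free-input set L(k).  Regulatory edges whose inclusion would close
    a cycle in the rule dependency graph are dropped deterministically (in
    stable edge order) and reported via ``dropped_edges``.
    """
    if depth not in (0, 1, 2):
        raise ModelValidationError(
            f"regulatory depth {depth} unsupported: deeper rule sets are "
            "dominated by cycles and are not considered"
        )
    if reaction not in model.reactions:
        raise ModelValidationError(f"unknown reaction {reaction!r}")
    if strategy not in COMBINATION_STRATEGIES:
        raise ModelValidationError(f"unknown combination strategy {strategy!r}")
    combine = COMBINATION_STRATEGIES[strategy]

    gpr = model.gpr[reaction]
    rules: dict[str, BooleanRule] = {reaction: gpr}
    frontier = sorted(gpr.genes())
    known: set[str] = set(frontier)
    dropped: list[tuple[str, str, int]] = []

    # dependency edges currently implied by the rule set (dep -> node)
    dep_graph = nx.DiGraph()
    dep_graph.add_node(reaction)
    for g in frontier:
        dep_graph.add_edge(g, reaction)

    for level in range(1, depth + 1):
        if not layers or not frontier:
            break
        layer = layers[level - 1] if level - 1 < len(layers) else layers[-1]
        next_frontier: list[str] = []
        for gene in frontier:
            activators, repressors = layer.regulators_of(gene)
            kept_act, kept_rep = [], []
            for src, bucket, sign in (
                [(a, kept_act, +1) for a in activators]
                + [(r, kept_rep, -1) for r in repressors]
            ):
                dep_graph.add_edge(src, gene)
                if not nx.is_directed_acyclic_graph(dep_graph):
                    dep_graph.remove_edge(src, gene)
                    dropped.append((src, gene, sign))
                    logger.warning(
                        "dropped regulatory edge %s -> %s (sign %+d): closes a cycle",
                        src, gene, sign,
                    )
                    continue
                bucket.append(src)
            if not kept_act and not kept_rep:
                continue
            rules[gene] = combine(rules.get(gene), kept_act, kept_rep)
            for src in kept_act + kept_rep:
                if src not in known:
                    known.add(src)
                    next_frontier.append(src)
        frontier = sorted(next_frontier)

    all_genes = frozenset(known)
    input_genes = frozenset(g for g in all_genes if g not in rules)
    return EgprRuleSet(
        reaction=reaction,
        rules=rules,
        input_genes=input_genes,
        all_genes=all_genes,
        dropped_edges=dropped,
    )
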