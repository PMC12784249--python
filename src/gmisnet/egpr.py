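"""Compile eGPR rule sets into artificial ON/OFF reaction networks.

Every entity of a rule set (gene, auxiliary knock-out node ``y``, knock-in
node ``u``, free-input node ``e``, intermediate node, reaction node) is
split into an ON and an OFF species.  Boolean rules become irreversible
"gate" reactions: each OR branch is a separate gate producing the node,
each AND is a single multi-substrate gate.  Input exchange reactions feed
the ``e``/``y``/``u`` species; removing the exchange of ``y_i ON`` models
the knock-out of gene *i* and removing the exchange of ``u_i OFF`` models
its knock-in.  The set of those four-per-gene intervention exchanges is
``H(k)``.  Output exchanges drain the reaction node's ON and OFF species.

:func:`forward_closure` is the deterministic oracle on this construction:
it commits every gene's intervention state and computes the least fixpoint
of derivable species; the network blocks the target reaction iff its ON
species is underivable.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from scipy import sparse

from .model import EgprRuleSet, ModelValidationError
from .rules import BooleanRule, and_, or_

__all__ = [
    "Intervention",
    "InterventionSet",
    "Gate",
    "EgprNetwork",
    "build_egpr_network",
    "forward_closure",
    "KO",
    "KI",
]

KO = "KO"
KI = "KI"
_SUFFIX = {KO: "-", KI: "+"}


@dataclass(frozen=True, order=True)
class Intervention:
    """A single gene intervention: knock-out (``g-``) or knock-in (``g+``)."""

    gene: str
    direction: str

    def __post_init__(self) -> None:
        if self.direction not in (KO, KI):
            raise ValueError(f"direction must be KO or KI, got {self.direction!r}")

    @property
    def atom(self) -> str:
        return f"{self.gene}{_SUFFIX[self.direction]}"

    @classmethod
    def from_atom(cls, atom: str) -> "Intervention":
        atom = atom.strip()
        if atom.endswith("-"):
            return cls(atom[:-1], KO)
        if atom.endswith("+"):
            return cls(atom[:-1], KI)
        raise ValueError(f"intervention atom must end in '+' or '-': {atom!r}")


@dataclass(frozen=True)
class InterventionSet:
    """A set of gene interventions (an MCS / gMIS candidate or solution).

    A gene may not be knocked out and knocked in at the same time, and the
    set must be nonempty.
    """

    interventions: frozenset[Intervention]
    provenance: str = ""

    def __post_init__(self) -> None:
        if not self.interventions:
            raise ValueError("intervention set must be nonempty")
        per_gene: dict[str, set[str]] = {}
        for iv in self.interventions:
            per_gene.setdefault(iv.gene, set()).add(iv.direction)
        clash = sorted(g for g, dirs in per_gene.items() if len(dirs) > 1)
        if clash:
            raise ValueError(
                f"gene(s) {clash} carry both a knock-out and a knock-in; "
                "simultaneous KO and KI of one gene is excluded"
            )

    @classmethod
    def of(cls, *atoms: str, provenance: str = "") -> "InterventionSet":
        return cls(frozenset(Intervention.from_atom(a) for a in atoms), provenance)

    def __iter__(self) -> Iterator[Intervention]:
        return iter(sorted(self.interventions))

    def __len__(self) -> int:
        return len(self.interventions)

    def __contains__(self, item: Intervention) -> bool:
        return item in self.interventions

    @property
    def genes(self) -> frozenset[str]:
        return frozenset(iv.gene for iv in self.interventions)

    def knockouts(self) -> list[str]:
        return sorted(iv.gene for iv in self.interventions if iv.direction == KO)

    def knockins(self) -> list[str]:
        return sorted(iv.gene for iv in self.interventions if iv.direction == KI)

    def atoms(self) -> tuple[str, ...]:
        return tuple(iv.atom for iv in self)

    def label(self) -> str:
        return ";".join(self.atoms())

    def sort_key(self) -> tuple[int, tuple[str, ...]]:
        return (len(self), self.atoms())

    def issubset(self, other: "InterventionSet") -> bool:
        return self.interventions <= other.interventions


# ---------------------------------------------------------------------------
# Node naming
# ---------------------------------------------------------------------------

def gene_node(gene: str, side: str) -> str:
    return f"{gene}::{side}"


def aux_node(kind: str, gene: str, side: str) -> str:
    return f"{kind}::{gene}::{side}"


def reaction_node(reaction: str, side: str) -> str:
    return f"R::{reaction}::{side}"


def _nlit(node: str) -> BooleanRule:
    # internal literal over a network node name (bypasses gene-symbol checks)
    return BooleanRule("lit", gene=node)


@dataclass(frozen=True)
class Gate:
    """An irreversible gate reaction: consumes ``inputs``, produces ``output``.

    Duplicate consumption collapses by Boolean idempotence, so inputs form a
    set and all stoichiometric coefficients are 1.  A gate with no inputs is
    a source (the TRUE rule).
    """

    id: str
    inputs: frozenset[str]
    output: str


@dataclass
class EgprNetwork:
    """The artificial ON/OFF reaction network for one target reaction."""

    reaction: str
    genes: list[str]
    input_genes: list[str]
    nodes: list[str]
    gates: list[Gate]
    input_exchanges: dict[str, str]   # node -> reaction id
    output_exchanges: dict[str, str]  # node -> reaction id
    H: list[str]                      # y/u input-exchange reaction ids
    target_node: str = field(init=False)

    def __post_init__(self) -> None:
        self.target_node = reaction_node(self.reaction, "ON")
        assert len(self.H) == 4 * len(self.genes), "H(k) must hold 4 exchanges per gene"

    # -- matrix view ---------------------------------------------------
    def reaction_ids(self) -> list[str]:
        return (
            [g.id for g in self.gates]
            + [self.input_exchanges[n] for n in sorted(self.input_exchanges)]
            + [self.output_exchanges[n] for n in sorted(self.output_exchanges)]
        )

    def stoichiometry(self) -> tuple[sparse.csc_matrix, list[str], list[str]]:
        """(S^k, node order, reaction order); all reactions irreversible."""
        node_idx = {n: i for i, n in enumerate(self.nodes)}
        rxn_ids = self.reaction_ids()
        mat = sparse.lil_matrix((len(self.nodes), len(rxn_ids)))
        j = 0
        for gate in self.gates:
            for inp in gate.inputs:
                mat[node_idx[inp], j] = -1.0
            mat[node_idx[gate.output], j] = 1.0
            j += 1
        for n in sorted(self.input_exchanges):
            mat[node_idx[n], j] = 1.0
            j += 1
        for n in sorted(self.output_exchanges):
            mat[node_idx[n], j] = -1.0
            j += 1
        return mat.tocsc(), list(self.nodes), rxn_ids

    def h_members(self) -> dict[str, tuple[str, str, str]]:
        """Map H(k) exchange reaction id -> (kind, gene, side)."""
        out = {}
        for g in self.genes:
            for kind in ("y", "u"):
                for side in ("ON", "OFF"):
                    node = aux_node(kind, g, side)
                    out[self.input_exchanges[node]] = (kind, g, side)
        return out

    def gate_count(self) -> int:
        return len(self.gates)

    def to_json(self, path: str | Path | None = None) -> str:
        """Debug dump of nodes, gates and exchanges."""
        payload = {
            "reaction": self.reaction,
            "genes": self.genes,
            "input_genes": self.input_genes,
            "nodes": self.nodes,
            "gates": [
                {"id": g.id, "inputs": sorted(g.inputs), "output": g.output}
                for g in self.gates
            ],
            "input_exchanges": self.input_exchanges,
            "output_exchanges": self.output_exchanges,
            "H": self.H,
        }
        text = json.dumps(payload, indent=1, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


# ---------------------------------------------------------------------------
# Compilation
# ---------------------------------------------------------------------------

def _map_side(rule_nnf: BooleanRule) -> BooleanRule:
    """Map an NNF rule over genes to a rule over ON/OFF node literals."""
    if rule_nnf.op == "lit":
        return _nlit(gene_node(rule_nnf.gene, "ON"))
    if rule_nnf.op == "not":
        inner = rule_nnf.children[0]
        if inner.op != "lit":  # pragma: no cover - NNF guarantees literals
            raise AssertionError("NOT survived negation normal form")
        return _nlit(gene_node(inner.gene, "OFF"))
    if rule_nnf.op == "and":
        return and_(_map_side(c) for c in rule_nnf.children)
    if rule_nnf.op == "or":
        return or_(_map_side(c) for c in rule_nnf.children)
    return rule_nnf  # TRUE / FALSE


class _GateEmitter:
    def __init__(self) -> None:
        self.gates: dict[tuple[str, frozenset[str]], Gate] = {}
        self.intermediates: set[str] = set()

    def _add(self, inputs: frozenset[str], output: str) -> None:
        key = (output, inputs)
        if key not in self.gates:
            digest = hashlib.sha1(
                (output + "<=" + "&".join(sorted(inputs))).encode()
            ).hexdigest()[:10]
            self.gates[key] = Gate(id=f"gate::{digest}", inputs=inputs, output=output)

    def _operand_node(self, rule: BooleanRule) -> str:
        """Node carrying the value of an operand; complex operands get a
        content-addressed intermediate node shared across identical
        sub-expressions."""
        if rule.op == "lit":
            return rule.gene  # already a node name
        digest = hashlib.sha1(rule.to_string().encode()).hexdigest()[:10]
        name = f"I::{digest}"
        if name not in self.intermediates:
            self.intermediates.add(name)
            self.emit(rule, name)
        return name

    def emit(self, rule: BooleanRule, output: str) -> None:
        """Compile ``rule`` (over node-name literals, negation-free) into
        gates producing ``output``."""
        if rule.op == "false":
            return
        if rule.op == "true":
            self._add(frozenset(), output)
            return
        if rule.op == "lit":
            self._add(frozenset([rule.gene]), output)
            return
        if rule.op == "or":
            for branch in rule.children:
                if branch.op == "and":
                    inputs = frozenset(self._operand_node(c) for c in branch.children)
                    self._add(inputs, output)
                else:
                    self._add(frozenset([self._operand_node(branch)]), output)
            return
        if rule.op == "and":
            inputs = frozenset(self._operand_node(c) for c in rule.children)
            self._add(inputs, output)
            return
        raise AssertionError(f"negation reached the gate compiler: {rule}")


def build_egpr_network(rules: EgprRuleSet) -> EgprNetwork:
    """Build the ON/OFF-split artificial reaction network for a rule set.

    Every gene rule rho_i is first augmented to ``g_i = (rho_i AND y_i) OR
    u_i`` (with ``rho_i = e_i`` for free-input genes); the OFF side is the
    De Morgan image ``g_i OFF = u_i OFF AND (rho_i OFF OR y_i OFF)``.
    """
    rules.check_acyclic()
    emitter = _GateEmitter()
    genes = sorted(rules.all_genes)
    input_exchanges: dict[str, str] = {}
    output_exchanges: dict[str, str] = {}

    for g in genes:
        if g in rules.input_genes:
            rho_on = _nlit(aux_node("e", g, "ON"))
            rho_off = _nlit(aux_node("e", g, "OFF"))
        else:
            rho = rules.rules[g]
            rho_on = _map_side(rho.nnf())
            rho_off = _map_side(rho.negate())
        y_on, y_off = _nlit(aux_node("y", g, "ON")), _nlit(aux_node("y", g, "OFF"))
        u_on, u_off = _nlit(aux_node("u", g, "ON")), _nlit(aux_node("u", g, "OFF"))
        emitter.emit(or_([and_([rho_on, y_on]), u_on]), gene_node(g, "ON"))
        emitter.emit(and_([u_off, or_([rho_off, y_off])]), gene_node(g, "OFF"))

    target_rule = rules.rules[rules.reaction]
    emitter.emit(_map_side(target_rule.nnf()), reaction_node(rules.reaction, "ON"))
    emitter.emit(_map_side(target_rule.negate()), reaction_node(rules.reaction, "OFF"))

    H: list[str] = []
    for g in genes:
        for kind in ("y", "u"):
            for side in ("ON", "OFF"):
                node = aux_node(kind, g, side)
                rid = f"EX_in::{node}"
                input_exchanges[node] = rid
                H.append(rid)
        if g in rules.input_genes:
            for side in ("ON", "OFF"):
                node = aux_node("e", g, side)
                input_exchanges[node] = f"EX_in::{node}"
    for side in ("ON", "OFF"):
        node = reaction_node(rules.reaction, side)
        output_exchanges[node] = f"EX_out::{node}"

    gates = sorted(emitter.gates.values(), key=lambda gt: gt.id)
    nodes = set(input_exchanges) | set(output_exchanges)
    for gate in gates:
        nodes |= gate.inputs
        nodes.add(gate.output)
    for g in genes:
        nodes.add(gene_node(g, "ON"))
        nodes.add(gene_node(g, "OFF"))

    return EgprNetwork(
        reaction=rules.reaction,
        genes=genes,
        input_genes=sorted(rules.input_genes),
        nodes=sorted(nodes),
        gates=gates,
        input_exchanges=input_exchanges,
        output_exchanges=output_exchanges,
        H=sorted(H),
    )


# ---------------------------------------------------------------------------
# Derivability oracle
# ---------------------------------------------------------------------------

def forward_closure(
    net: EgprNetwork, interventions: InterventionSet | Iterable[Intervention] | None
) -> frozenset[str]:
    """Least fixpoint of derivable species under a committed intervention set.

    Base facts follow the exactly-one-exchange-per-pair regime: a knocked-out
    gene keeps only ``y OFF``, an untouched gene only ``y ON``; a knocked-in
    gene keeps only ``u ON``, an untouched gene only ``u OFF``; both ``e``
    species of free-input genes are always available.  A species is then
    derivable iff some gate producing it has every substrate derivable.
    The network blocks its target reaction iff ``net.target_node`` is not in
    the returned set.
    """
    ivs = list(interventions) if interventions is not None else []
    per_gene: dict[str, str] = {}
    for iv in ivs:
        if iv.gene not in net.genes:
            raise ModelValidationError(
                f"intervention on {iv.gene!r}: gene not in B({net.reaction})"
            )
        if iv.gene in per_gene and per_gene[iv.gene] != iv.direction:
            raise ValueError(f"gene {iv.gene} carries both KO and KI")
        per_gene[iv.gene] = iv.direction

    derivable: set[str] = set()
    for g in net.genes:
        state = per_gene.get(g)
        derivable.add(aux_node("y", g, "OFF" if state == KO else "ON"))
        derivable.add(aux_node("u", g, "ON" if state == KI else "OFF"))
        if g in net.input_genes:
            derivable.add(aux_node("e", g, "ON"))
            derivable.add(aux_node("e", g, "OFF"))

    changed = True
    while changed:
        changed = False
        for gate in net.gates:
            if gate.output not in derivable and gate.inputs <= derivable:
                derivable.add(gate.output)
                changed = True
    return frozenset(derivable)


def blocks_target(net: EgprNetwork, interventions) -> bool:
    """True iff the interventions make the target's ON species underivable."""
    return net.target_node not in forward_closure(net, interventions)
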