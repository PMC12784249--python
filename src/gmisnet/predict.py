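"""Context-specific predictions from a gMIS catalogue and expression data.

A knock-out gene is called *essential* in a sample, via a particular gMIS,
when it is the unique highly expressed gene among that gMIS's knock-outs
and every knock-in gene of the gMIS is highly expressed (so the cell's own
state already supplies the knock-ins).  Mirror-image, a knock-in gene is
called a context-specific *tumor suppressor* when it is the unique lowly
expressed gene among the gMIS's knock-ins and every knock-out gene is
lowly expressed.  An adaptation check then discards calls where applying
the candidate intervention, propagated through the regulatory Boolean
rules, flips a partner gene into the state that rescues the cell.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd

from .egpr import KI, KO, Intervention, InterventionSet
from .gmis import GmisResult
from .model import ModelValidationError
from .rules import BooleanRule

__all__ = [
    "ExpressionState",
    "PredictionRecord",
    "binarize_expression",
    "predict_essential_genes",
    "predict_tumor_suppressors",
    "adaptation_check",
    "depmap_essential_flag",
    "predictions_to_frame",
]

HIGH = "HIGH"
LOW = "LOW"

DEPMAP_ESSENTIAL_CUTOFF = -0.6


@dataclass
class ExpressionState:
    """Binarized expression of one sample.

    ``states`` maps gene -> HIGH/LOW; genes absent from the map resolve to
    ``default`` (LOW by default: conservative for essentiality calls).
    """

    sample: str
    states: dict[str, str]
    method: str = "absolute"
    threshold: float = 1.0
    default: str = LOW

    def __getitem__(self, gene: str) -> str:
        return self.states.get(gene, self.default)

    def is_high(self, gene: str) -> bool:
        return self[gene] == HIGH

    def mirrored(self) -> "ExpressionState":
        """HIGH <-> LOW swapped everywhere (used by symmetry checks)."""
        flip = {HIGH: LOW, LOW: HIGH}
        return ExpressionState(
            sample=self.sample,
            states={g: flip[s] for g, s in self.states.items()},
            method=self.method,
            threshold=self.threshold,
            default=flip[self.default],
        )


@dataclass
class PredictionRecord:
    sample: str
    gene: str
    role: str                     # "essential" | "tumor-suppressor"
    supports: list[InterventionSet]
    adaptation: str = "skipped"   # "passed" | "failed" | "skipped"


def binarize_expression(
    expression: dict[str, float] | pd.Series,
    threshold: float = 1.0,
    sample: str = "sample",
    method: str = "absolute",
    default: str = LOW,
) -> ExpressionState:
    """HIGH iff log2(TPM+1) value >= threshold (absolute-cutoff rule).

    The threshold rule is pluggable in principle; the shipped default is an
    absolute cutoff of 1.0 on the log2(TPM+1) scale, i.e. TPM >= 1.
    Negative values are rejected (impossible on a TPM-derived scale).
    """
    items = expression.items() if hasattr(expression, "items") else expression
    states: dict[str, str] = {}
    for gene, value in items:
        if value is None or (isinstance(value, float) and math.isnan(value)):
            continue
        if value < 0:
            raise ModelValidationError(
                f"negative expression value {value} for {gene}: "
                "expected log2(TPM+1) scale"
            )
        states[gene] = HIGH if value >= threshold else LOW
    return ExpressionState(
        sample=sample, states=states, method=method, threshold=threshold,
        default=default,
    )


def _gmis_sets(gmis_list: Sequence[GmisResult | InterventionSet]) -> list[InterventionSet]:
    out = []
    for g in gmis_list:
        out.append(g.interventions if isinstance(g, GmisResult) else g)
    return out


def predict_essential_genes(
    gmis_list: Sequence[GmisResult | InterventionSet],
    state: ExpressionState,
) -> list[PredictionRecord]:
    """Essential-gene calls for one sample (see module docstring).

    Calls for the same gene through several gMISs collapse into one record
    with every supporting gMIS attached.
    """
    calls: dict[str, list[InterventionSet]] = {}
    for s in _gmis_sets(gmis_list):
        kos = s.knockouts()
        if not kos:
            continue
        high_kos = [g for g in kos if state.is_high(g)]
        if len(high_kos) != 1:
            continue
        if any(not state.is_high(g) for g in s.knockins()):
            continue
        calls.setdefault(high_kos[0], []).append(s)
    return [
        PredictionRecord(sample=state.sample, gene=g, role="essential", supports=sup)
        for g, sup in sorted(calls.items())
    ]


def predict_tumor_suppressors(
    gmis_list: Sequence[GmisResult | InterventionSet],
    state: ExpressionState,
) -> list[PredictionRecord]:
    """Tumor-suppressor calls: mirror image of the essential-gene rule."""
    calls: dict[str, list[InterventionSet]] = {}
    for s in _gmis_sets(gmis_list):
        kis = s.knockins()
        if not kis:
            continue
        low_kis = [g for g in kis if not state.is_high(g)]
        if len(low_kis) != 1:
            continue
        if any(state.is_high(g) for g in s.knockouts()):
            continue
        calls.setdefault(low_kis[0], []).append(s)
    return [
        PredictionRecord(
            sample=state.sample, gene=g, role="tumor-suppressor", supports=sup
        )
        for g, sup in sorted(calls.items())
    ]


# ---------------------------------------------------------------------------
# Adaptation mechanisms
# ---------------------------------------------------------------------------

def _propagate(
    rules: dict[str, BooleanRule],
    base: dict[str, bool],
    forced: dict[str, bool],
) -> dict[str, bool]:
    graph = nx.DiGraph()
    graph.add_nodes_from(rules)
    for gene, rule in rules.items():
        for dep in rule.genes():
            graph.add_edge(dep, gene)
    if not nx.is_directed_acyclic_graph(graph):
        raise ModelValidationError("adaptation check requires acyclic rules")
    state = dict(base)
    state.update(forced)
    for node in nx.topological_sort(graph):
        if node in forced:
            continue
        if node in rules:
            state[node] = rules[node].evaluate(
                {g: state.get(g, False) for g in rules[node].genes()}
            )
    return state


def adaptation_check(
    rules: dict[str, BooleanRule],
    state: ExpressionState,
    intervention: Intervention,
    partners: Iterable[Intervention],
) -> str:
    """Propagate the candidate intervention through the regulatory rules and
    test whether any partner flips into a rescuing state.

    Unregulated genes are fixed to their observed HIGH/LOW state; regulated
    genes are recomputed from their Boolean rules in topological order with
    the intervention forced (KO -> inactive, KI -> active).  The check
    *fails* when a partner knock-out gene becomes active or a partner
    knock-in gene becomes inactive.  Propagation on acyclic rules is a
    single topological pass and hence idempotent.
    """
    referenced: set[str] = set(rules)
    for rule in rules.values():
        referenced |= rule.genes()
    base = {g: state.is_high(g) for g in referenced}
    forced = {intervention.gene: intervention.direction == KI}
    after = _propagate(rules, base, forced)
    for p in partners:
        if p.gene == intervention.gene:
            continue
        value = after.get(p.gene, state.is_high(p.gene))
        if p.direction == KO and value:
            return "failed"
        if p.direction == KI and not value:
            return "failed"
    return "passed"


def depmap_essential_flag(score: float | None) -> bool | None:
    """Dependency-screen essentiality rule: essential iff score < -0.6.

    Missing scores return None and are excluded from any metric.
    """
    if score is None or (isinstance(score, float) and math.isnan(score)):
        return None
    return score < DEPMAP_ESSENTIAL_CUTOFF


def predictions_to_frame(records: Sequence[PredictionRecord]) -> pd.DataFrame:
    """Flatten prediction records into the output CSV layout."""
    rows = []
    for r in records:
        for s in r.supports:
            rows.append(
                {
                    "sample": r.sample,
                    "gene": r.gene,
                    "role": r.role,
                    "gmis": s.label(),
                    "adaptation": r.adaptation,
                }
            )
    return pd.DataFrame(rows, columns=["sample", "gene", "role", "gmis", "adaptation"])
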