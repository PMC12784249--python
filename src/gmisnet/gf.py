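"""Integration of per-reaction MCS lists into paired G/F matrices.

Each F row is one minimal intervention set (binary over gene x direction
atoms); its paired G row marks every reaction that set blocks.  Identical
intervention sets found for different reactions merge into a single row;
rows touching more than ``max_row_size`` genes are discarded (longer sets
contribute negligibly to genome-level predictions), and rows dominated by
a smaller-or-equal set blocking at least the same reactions can be pruned.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.io import mmread, mmwrite

from .egpr import Intervention, InterventionSet

__all__ = ["GFMatrices", "build_gf", "blocked_reactions", "save_gf", "load_gf"]


@dataclass
class GFMatrices:
    """Paired binary matrices: F rows = intervention sets, G rows = blocked
    reactions.  ``atoms`` and ``reactions`` give the column orders."""

    F: sparse.csr_matrix
    G: sparse.csr_matrix
    atoms: list[str]
    reactions: list[str]
    row_sets: list[InterventionSet]
    discarded: list[tuple[InterventionSet, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.F.shape[0] != self.G.shape[0]:
            raise ValueError("F and G must have the same number of rows")
        if self.F.shape[1] != len(self.atoms) or self.G.shape[1] != len(self.reactions):
            raise ValueError("column counts do not match atom/reaction indices")

    @property
    def n_rows(self) -> int:
        return self.F.shape[0]

    def row_reactions(self, i: int) -> list[str]:
        return [self.reactions[j] for j in self.G.getrow(i).indices]

    def iter_rows(self):
        for i, s in enumerate(self.row_sets):
            yield s, frozenset(self.row_reactions(i))


def _atom_universe(per_reaction: dict[str, list[InterventionSet]]) -> list[str]:
    atoms: set[str] = set()
    for sets in per_reaction.values():
        for s in sets:
            atoms.update(s.atoms())
    return sorted(atoms)


def build_gf(
    per_reaction_mcs: dict[str, list[InterventionSet]],
    reactions: list[str] | None = None,
    max_row_size: int = 5,
    prune_dominated: bool = True,
) -> GFMatrices:
    """Merge per-reaction MCS lists into G/F.

    ``reactions`` fixes the G column order (defaults to the sorted keys).
    Rows are ordered by (size, lexicographic atoms).  A row is dominated,
    and pruned when ``prune_dominated``, if a proper subset of its atoms
    blocks a superset of its reactions.
    """
    if reactions is None:
        reactions = sorted(per_reaction_mcs)
    unknown = set(per_reaction_mcs) - set(reactions)
    if unknown:
        raise ValueError(f"MCS lists for reactions outside the model: {sorted(unknown)}")

    merged: dict[frozenset[Intervention], set[str]] = {}
    discarded: list[tuple[InterventionSet, str]] = []
    for rxn, sets in per_reaction_mcs.items():
        for s in sets:
            if not isinstance(s, InterventionSet):
                raise TypeError("per-reaction entries must be InterventionSet")
            if len(s.genes) > max_row_size:
                discarded.append((s, f"row exceeds {max_row_size} genes (from {rxn})"))
                continue
            merged.setdefault(s.interventions, set()).add(rxn)

    rows = sorted(
        ((InterventionSet(k, provenance="GF"), frozenset(v)) for k, v in merged.items()),
        key=lambda kv: kv[0].sort_key(),
    )

    if prune_dominated:
        kept = []
        for s, rxns in rows:
            dominated = any(
                s2.interventions < s.interventions and rxns <= rxns2
                for s2, rxns2 in rows
                if s2.interventions != s.interventions
            )
            if dominated:
                discarded.append((s, "dominated by a smaller row"))
            else:
                kept.append((s, rxns))
        rows = kept

    atoms = sorted({a for s, _ in rows for a in s.atoms()})
    atom_idx = {a: j for j, a in enumerate(atoms)}
    rxn_idx = {r: j for j, r in enumerate(reactions)}
    F = sparse.lil_matrix((len(rows), len(atoms)), dtype=np.int8)
    G = sparse.lil_matrix((len(rows), len(reactions)), dtype=np.int8)
    for i, (s, rxns) in enumerate(rows):
        for a in s.atoms():
            F[i, atom_idx[a]] = 1
        for r in rxns:
            G[i, rxn_idx[r]] = 1
    return GFMatrices(
        F=F.tocsr(),
        G=G.tocsr(),
        atoms=atoms,
        reactions=list(reactions),
        row_sets=[s for s, _ in rows],
        discarded=discarded,
    )


def blocked_reactions(gf: GFMatrices, interventions: InterventionSet) -> frozenset[str]:
    """Union of G rows over every F row whose atom set is contained in the
    given interventions (the G/F reading of 'these interventions delete
    those reactions')."""
    chosen = interventions.interventions
    blocked: set[str] = set()
    for i, s in enumerate(gf.row_sets):
        if s.interventions <= chosen:
            blocked.update(gf.row_reactions(i))
    return frozenset(blocked)


# ---------------------------------------------------------------------------
# Persistence: Matrix Market + TSV indices
# ---------------------------------------------------------------------------

def save_gf(gf: GFMatrices, directory: str | Path, prefix: str = "gf") -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    mmwrite(directory / f"{prefix}_F.mtx", sparse.coo_matrix(gf.F), field="integer")
    mmwrite(directory / f"{prefix}_G.mtx", sparse.coo_matrix(gf.G), field="integer")
    pd.DataFrame({"atom": gf.atoms}).to_csv(
        directory / f"{prefix}_atoms.tsv", sep="\t", index=False
    )
    pd.DataFrame({"reaction": gf.reactions}).to_csv(
        directory / f"{prefix}_reactions.tsv", sep="\t", index=False
    )


def load_gf(directory: str | Path, prefix: str = "gf") -> GFMatrices:
    directory = Path(directory)
    F = sparse.csr_matrix(mmread(directory / f"{prefix}_F.mtx"), dtype=np.int8)
    G = sparse.csr_matrix(mmread(directory / f"{prefix}_G.mtx"), dtype=np.int8)
    atoms = pd.read_csv(directory / f"{prefix}_atoms.tsv", sep="\t")["atom"].tolist()
    reactions = pd.read_csv(
        directory / f"{prefix}_reactions.tsv", sep="\t"
    )["reaction"].tolist()
    row_sets = []
    for i in range(F.shape[0]):
        row_atoms = [atoms[j] for j in F.getrow(i).indices]
        row_sets.append(InterventionSet.of(*row_atoms, provenance="GF"))
    return GFMatrices(F=F, G=G, atoms=atoms, reactions=reactions, row_sets=row_sets)
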