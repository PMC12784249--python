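"""Minimal cut set enumeration on eGPR networks (knock-outs + knock-ins).

The primal statement "some flux distribution pushes r* units through the
target's ON exchange while every committed intervention exchange is shut"
is infeasible exactly when the intervention set blocks the target.  The
enumerator therefore works on the Farkas dual of that primal: dual
variables ``u`` (one per species, free) certify mass balance, ``v >= 0``
(one per intervention exchange in H(k)) certify the committed shut
exchanges, and a scalar ``w`` bounded away from zero certifies the target
demand.  Binary indicators ``z`` select which intervention constraints are
committed; per gene exactly one of the y ON/OFF exchanges and one of the u
ON/OFF exchanges is committed, committing ``y_i ON`` means knocking out
gene *i* and committing ``u_i OFF`` means knocking it in, and the two are
mutually exclusive.  Minimising the number of committed ``y ON``/``u OFF``
indicators yields a smallest blocking intervention set; integer no-good
cuts on the support then exclude each solution (and all its supersets) and
the solve repeats until infeasibility or a stopping limit.

:func:`brute_force_mcs` is the independent oracle: it enumerates candidate
intervention sets by increasing size and keeps those that block the target
under :func:`~gmisnet.egpr.forward_closure` while no kept subset does.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from math import comb

import numpy as np
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint, milp

from .config import MilpParams
from .egpr import KI, KO, EgprNetwork, Intervention, InterventionSet, forward_closure

__all__ = [
    "enumerate_mcs_milp",
    "brute_force_mcs",
    "verify_intervention_set",
    "McsEnumeration",
    "BruteForceGuardError",
]

logger = logging.getLogger(__name__)


class BruteForceGuardError(RuntimeError):
    """The brute-force candidate space exceeds the tractability guard."""


@dataclass
class McsEnumeration:
    """Result of an MCS enumeration run."""

    solutions: list[InterventionSet]
    truncated: bool = False
    truncation_reason: str = ""
    solver: str = "highs"
    params: dict = field(default_factory=dict)

    def __iter__(self):
        return iter(self.solutions)

    def __len__(self) -> int:
        return len(self.solutions)


def _canonical(solutions: list[InterventionSet]) -> list[InterventionSet]:
    uniq = {s.interventions: s for s in solutions}
    return sorted(uniq.values(), key=lambda s: s.sort_key())


# ---------------------------------------------------------------------------
# Dual MILP enumeration
# ---------------------------------------------------------------------------

def enumerate_mcs_milp(
    net: EgprNetwork, params: MilpParams | None = None
) -> McsEnumeration:
    """Enumerate minimal KO/KI intervention sets blocking ``net``'s target.

    Returns the canonically sorted solution list (by size, then atom
    lexicographic order).  If a single solve times out or fails, the partial
    list is returned with ``truncated=True``.
    """
    params = params or MilpParams()
    if not net.genes:
        return McsEnumeration([], solver=params.solver, params=params.to_dict())

    S, _nodes, rxn_ids = net.stoichiometry()
    S = S.tocsc()
    m, n = S.shape
    rxn_pos = {r: j for j, r in enumerate(rxn_ids)}
    h_info = net.h_members()  # exchange id -> (kind, gene, side)
    h_ids = sorted(h_info)
    nH = len(h_ids)
    h_rows = np.array([rxn_pos[r] for r in h_ids])  # reaction row of each H member
    target_j = rxn_pos[net.output_exchanges[net.target_node]]

    # variable layout: [u (m, free), v (nH, >=0), w (1, >= c/r*), z (nH, binary)]
    nvar = m + nH + 1 + nH
    v_off, w_off, z_off = m, m + nH, m + nH + 1

    atom_idx: dict[tuple[str, str], int] = {}  # (gene, direction) -> z index
    pair_rows = []
    for g in net.genes:
        idx = {}
        for i, rid in enumerate(h_ids):
            kind, gene, side = h_info[rid]
            if gene == g:
                idx[(kind, side)] = i
        atom_idx[(g, KO)] = idx[("y", "ON")]
        atom_idx[(g, KI)] = idx[("u", "OFF")]
        pair_rows.append((idx[("y", "ON")], idx[("y", "OFF")],
                          idx[("u", "ON")], idx[("u", "OFF")]))

    # objective: count committed y_ON / u_OFF, with a tiny index-based weight
    # so ties inside one optimum break lexicographically
    c_obj = np.zeros(nvar)
    intervention_z = sorted(atom_idx.values())
    eps = 1e-6 / max(nH, 1)
    for rank, zi in enumerate(intervention_z):
        c_obj[z_off + zi] = 1.0 + eps * rank

    constraints: list[LinearConstraint] = []

    # dual feasibility rows: (S^T u)_j + [j in H] v_j - t_j w >= 0
    P = sparse.csc_matrix(
        (np.ones(nH), (h_rows, np.arange(nH))), shape=(n, nH)
    )
    t_col = sparse.csc_matrix(
        (np.array([-1.0]), (np.array([target_j]), np.array([0]))), shape=(n, 1)
    )
    A_dual = sparse.hstack([S.T, P, t_col, sparse.csc_matrix((n, nH))]).tocsc()
    constraints.append(LinearConstraint(A_dual, 0.0, np.inf))

    # indicator link: alpha z <= v <= M z
    I_v = sparse.eye(nH, format="csc")
    Z_m = sparse.csc_matrix((nH, m))
    z_w = sparse.csc_matrix((nH, 1))
    A_lo = sparse.hstack([Z_m, I_v, z_w, -params.alpha * I_v]).tocsc()
    constraints.append(LinearConstraint(A_lo, 0.0, np.inf))
    A_hi = sparse.hstack([Z_m, -I_v, z_w, params.M * I_v]).tocsc()
    constraints.append(LinearConstraint(A_hi, 0.0, np.inf))

    # per-gene commitment: z_yON + z_yOFF = 1, z_uON + z_uOFF = 1,
    # exclusion z_yON + z_uOFF <= 1
    rows, cols, vals, lo, hi = [], [], [], [], []
    r = 0
    for y_on, y_off, u_on, u_off in pair_rows:
        for a, b, lb, ub in (
            (y_on, y_off, 1.0, 1.0),
            (u_on, u_off, 1.0, 1.0),
            (y_on, u_off, -np.inf, 1.0),
        ):
            rows += [r, r]
            cols += [z_off + a, z_off + b]
            vals += [1.0, 1.0]
            lo.append(lb)
            hi.append(ub)
            r += 1
    A_pair = sparse.csc_matrix((vals, (rows, cols)), shape=(r, nvar))
    constraints.append(LinearConstraint(A_pair, np.array(lo), np.array(hi)))

    # at least one intervention
    a_one = np.zeros(nvar)
    for zi in intervention_z:
        a_one[z_off + zi] = 1.0
    constraints.append(LinearConstraint(a_one, 1.0, np.inf))

    if not params.allow_ki:
        for g in net.genes:
            fix = np.zeros(nvar)
            fix[z_off + atom_idx[(g, KI)]] = 1.0
            constraints.append(LinearConstraint(fix, 0.0, 0.0))

    lb = np.concatenate([
        np.full(m, -np.inf),
        np.zeros(nH),
        [params.c / params.target_flux],
        np.zeros(nH),
    ])
    ub = np.concatenate([
        np.full(m, np.inf),
        np.full(nH, params.M),
        [np.inf],
        np.ones(nH),
    ])
    integrality = np.concatenate([np.zeros(m + nH + 1), np.ones(nH)])

    solutions: list[InterventionSet] = []
    cuts: list[LinearConstraint] = []
    truncated, reason = False, ""
    # presolve stays off: on this indicator-heavy structure HiGHS presolve
    # can misdeclare infeasibility, which would silently truncate the
    # enumeration
    options = {"time_limit": params.time_limit_per_solution, "presolve": False}

    while len(solutions) < params.max_solutions:
        res = milp(
            c=c_obj,
            constraints=constraints + cuts,
            integrality=integrality,
            bounds=Bounds(lb, ub),
            options=options,
        )
        if res.status == 2:  # infeasible: enumeration exhausted
            break
        if res.status == 1:  # iteration/time limit
            truncated, reason = True, "solver time limit reached"
            break
        if res.status != 0 or res.x is None:
            truncated, reason = True, f"solver failure: {res.message}"
            break
        z = res.x[z_off:]
        atoms = [
            Intervention(g, d)
            for (g, d), zi in atom_idx.items()
            if z[zi] > 0.5
        ]
        if not atoms:
            raise RuntimeError("dual MILP returned an empty intervention support")
        if len(atoms) > params.max_size:
            break
        sol = InterventionSet(frozenset(atoms), provenance=f"MCS:{net.reaction}")
        if net.target_node in forward_closure(net, sol):
            # Spurious incumbent: numerical big-M leakage can let a tiny
            # fractional z carry a nonzero v.  The closure oracle is exact,
            # so exclude exactly this commitment and re-solve.
            logger.debug("excluding spurious incumbent %s on %s",
                         sol.label(), net.reaction)
            cut_vec = np.zeros(nvar)
            for zi in intervention_z:
                cut_vec[z_off + zi] = -1.0
            for iv in atoms:
                cut_vec[z_off + atom_idx[(iv.gene, iv.direction)]] = 1.0
            cuts.append(LinearConstraint(cut_vec, -np.inf, len(atoms) - 1))
            continue
        solutions.append(sol)
        # no-good cut: exclude this support and all its supersets
        cut_vec = np.zeros(nvar)
        for iv in atoms:
            cut_vec[z_off + atom_idx[(iv.gene, iv.direction)]] = 1.0
        cuts.append(LinearConstraint(cut_vec, -np.inf, len(atoms) - 1))

    return McsEnumeration(
        solutions=_canonical(solutions),
        truncated=truncated,
        truncation_reason=reason,
        solver=params.solver,
        params=params.to_dict(),
    )


# ---------------------------------------------------------------------------
# Brute-force oracle
# ---------------------------------------------------------------------------

def brute_force_mcs(
    net: EgprNetwork,
    max_size: int = 5,
    allow_ki: bool = True,
    guard: int = 1_000_000,
) -> list[InterventionSet]:
    """Independent enumeration of all minimal blocking intervention sets.

    Candidates are drawn by increasing size from the valid (no KO+KI on one
    gene) atom combinations over B(k); a candidate is kept iff it blocks the
    target and no kept set is a proper subset.  Refuses to run when the
    candidate count exceeds ``guard``.
    """
    atoms = [Intervention(g, d) for g in net.genes
             for d in ((KO, KI) if allow_ki else (KO,))]
    n_atoms = len(atoms)
    total = sum(comb(n_atoms, s) for s in range(1, min(max_size, n_atoms) + 1))
    if total > guard:
        raise BruteForceGuardError(
            f"{total} candidate sets exceed the brute-force guard of {guard}; "
            "use the MILP enumerator"
        )
    kept: list[InterventionSet] = []
    for size in range(1, min(max_size, n_atoms) + 1):
        for combo in itertools.combinations(atoms, size):
            genes = [iv.gene for iv in combo]
            if len(set(genes)) < len(genes):
                continue  # KO+KI of the same gene
            cand = frozenset(combo)
            if any(k.interventions < cand for k in kept):
                continue
            sol = InterventionSet(cand, provenance=f"MCS:{net.reaction}")
            if net.target_node not in forward_closure(net, sol):
                kept.append(sol)
    return _canonical(kept)


def verify_intervention_set(
    net: EgprNetwork, interventions: InterventionSet
) -> dict[str, bool]:
    """Definition check: does the set block the target, and is it minimal?

    Minimal means the set blocks while no (|I|-1)-subset blocks.
    Construction of the :class:`InterventionSet` already rejects KO+KI of
    the same gene.
    """
    blocks = net.target_node not in forward_closure(net, interventions)
    minimal = blocks
    if blocks and len(interventions) > 1:
        for drop in interventions:
            sub = InterventionSet(interventions.interventions - {drop})
            if net.target_node not in forward_closure(net, sub):
                minimal = False
                break
    return {"blocks": blocks, "minimal": minimal}
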