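"""Synthetic iMR models: the worked-example toy network and seeded
random generators.

:func:`fig1_fixture` is the repository's golden anchor: a three-metabolite,
four-reaction, seven-gene toy with one signed regulatory layer, transcribed
so that the full pipeline reproduces the reference outcomes — six gMISs
blocking the biomass reaction, four of which are knock-out-only gMCSs, and
per-reaction enumeration on r3 returning exactly {g3-, g4-} and
{g3-, g6+, g7-}.

Transcription, field by field:

* metabolites ``m1, m2, m3``; irreversible reactions
  ``r1: -> m1`` (GPR ``g1``), ``r2: m1 -> m2`` (GPR ``g2 or g5``),
  ``r3: m1 -> m3`` (GPR ``g3 or g4``), ``rBIO: m2 + m3 ->`` (spontaneous
  biomass drain).  Biomass needs both branches, so deleting any reaction is
  lethal.
* regulatory layer: ``g7 -> g2`` (activation), ``g7 -| g5`` (inhibition),
  ``g7 -> g4`` (activation), ``g6 -| g4`` (inhibition).  Under the default
  disjunctive combination the regulated rules read ``g2 = g7``,
  ``g5 = not g7`` and ``g4 = g7 or not g6``; the free-input genes of r3's
  eGPR rule set are then g3, g6 and g7, and the inhibition arc on g4 is
  what makes the g6 knock-in intervention useful.

The drawing admits more than one reading of how the two regulators of g4
combine; this transcription adopts the reading that reproduces all of the
reference outcomes above (see the combination-strategy discussion in
:mod:`gmisnet.model`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse

from .model import MetabolicModel, RegulatoryLayer
from .rules import parse_gpr

__all__ = [
    "FixtureSpec",
    "fig1_fixture",
    "random_imr_model",
    "random_expression",
    "FIG1_GMIS_LABELS",
    "FIG1_GMCS_LABELS",
    "FIG1_R3_MCS_LABELS",
]

# Reference outcomes the golden fixture must reproduce end to end.
FIG1_R3_MCS_LABELS = ["g3-;g4-", "g3-;g6+;g7-"]
FIG1_GMIS_LABELS = [
    "g1-",
    "g2-;g5-",
    "g2-;g7+",
    "g3-;g4-",
    "g5-;g7-",
    "g3-;g6+;g7-",
]
FIG1_GMCS_LABELS = ["g1-", "g2-;g5-", "g3-;g4-", "g5-;g7-"]


def _make_model(
    model_id: str,
    metabolites: list[str],
    reactions: list[tuple[str, dict[str, float], float, float, str]],
    biomass: str,
) -> MetabolicModel:
    met_idx = {m: i for i, m in enumerate(metabolites)}
    mat = sparse.lil_matrix((len(metabolites), len(reactions)))
    ids, lbs, ubs, gpr = [], [], [], {}
    for j, (rid, stoich, lb, ub, rule) in enumerate(reactions):
        ids.append(rid)
        lbs.append(lb)
        ubs.append(ub)
        gpr[rid] = parse_gpr(rule)
        for met, coef in stoich.items():
            mat[met_idx[met], j] = coef
    return MetabolicModel(
        id=model_id,
        metabolites=metabolites,
        reactions=ids,
        stoichiometry=mat.tocsc(),
        lower_bounds=lbs,
        upper_bounds=ubs,
        biomass_reaction=biomass,
        gpr=gpr,
    )


def fig1_fixture() -> tuple[MetabolicModel, list[RegulatoryLayer]]:
    """The worked-example toy iMR network (see module docstring)."""
    model = _make_model(
        "fig1-toy",
        ["m1", "m2", "m3"],
        [
            ("r1", {"m1": 1.0}, 0.0, 1000.0, "g1"),
            ("r2", {"m1": -1.0, "m2": 1.0}, 0.0, 1000.0, "g2 or g5"),
            ("r3", {"m1": -1.0, "m3": 1.0}, 0.0, 1000.0, "g3 or g4"),
            ("rBIO", {"m2": -1.0, "m3": -1.0}, 0.0, 1000.0, ""),
        ],
        "rBIO",
    )
    layer = RegulatoryLayer(
        edges=[
            ("g7", "g2", +1),
            ("g7", "g5", -1),
            ("g7", "g4", +1),
            ("g6", "g4", -1),
        ],
        layer_index=1,
    )
    return model, [layer]


@dataclass
class FixtureSpec:
    """Shape of a random iMR toy model."""

    seed: int = 0
    n_metabolites: int = 3
    n_parallel: int = 2          # parallel isozyme branches per conversion
    genes_per_reaction: int = 2
    n_regulators: int = 3
    n_layers: int = 1
    inhibition_fraction: float = 0.3
    reg_edge_prob: float = 0.6
    n_samples: int = 4

    def __post_init__(self) -> None:
        for name in ("n_metabolites", "n_parallel", "genes_per_reaction",
                     "n_layers", "n_samples"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.n_regulators < 0:
            raise ValueError("n_regulators must be nonnegative")
        if not 0.0 <= self.inhibition_fraction <= 1.0:
            raise ValueError("inhibition_fraction must lie in [0, 1]")


def _random_gpr(rng: np.random.Generator, genes: list[str]) -> str:
    if len(genes) == 1:
        return genes[0]
    op = " or " if rng.random() < 0.5 else " and "
    return op.join(genes)


def random_imr_model(
    spec: FixtureSpec,
) -> tuple[MetabolicModel, list[RegulatoryLayer]]:
    """Seeded random substrate-to-biomass chain with random GPRs and a
    random acyclic signed regulatory layer per level.

    The metabolic scaffold is a linear chain m1 -> ... -> mN feeding the
    biomass drain, with an uptake reaction and ``n_parallel`` alternative
    conversion steps between consecutive metabolites, so biomass is always
    producible in the unperturbed model.  Regulator genes are fresh symbols
    (``t1, t2, ...``); edges always point from regulator to metabolic gene
    (or, for deeper layers, to the previous layer's regulators), which
    guarantees acyclic rules.  The same spec yields a byte-identical model.
    """
    for attempt in range(5):
        rng = np.random.default_rng((spec.seed, attempt))
        model, layers = _build_random(spec, rng)
        from .gmis import max_biomass

        if max_biomass(model) > 1e-6:
            return model, layers
    raise RuntimeError("could not generate a feasible random model")


def _build_random(spec: FixtureSpec, rng: np.random.Generator):
    mets = [f"m{i + 1}" for i in range(spec.n_metabolites)]
    gene_counter = 0
    reactions: list[tuple[str, dict[str, float], float, float, str]] = []
    metabolic_genes: list[str] = []

    def fresh_genes(k: int) -> list[str]:
        nonlocal gene_counter
        out = [f"g{gene_counter + i + 1}" for i in range(k)]
        gene_counter += k
        metabolic_genes.extend(out)
        return out

    reactions.append(("r_up", {mets[0]: 1.0}, 0.0, 1000.0,
                      _random_gpr(rng, fresh_genes(spec.genes_per_reaction))))
    rid = 0
    for i in range(len(mets) - 1):
        n_branch = 1 + int(rng.integers(0, spec.n_parallel))
        for _b in range(n_branch):
            rid += 1
            k = 1 + int(rng.integers(0, spec.genes_per_reaction))
            reactions.append(
                (f"r{rid}", {mets[i]: -1.0, mets[i + 1]: 1.0}, 0.0, 1000.0,
                 _random_gpr(rng, fresh_genes(k)))
            )
    reactions.append(("rBIO", {mets[-1]: -1.0}, 0.0, 1000.0, ""))
    model = _make_model(f"random-{spec.seed}", mets, reactions, "rBIO")

    layers: list[RegulatoryLayer] = []
    targets = sorted(set(metabolic_genes))
    for li in range(spec.n_layers):
        regulators = [f"t{li + 1}_{j + 1}" for j in range(spec.n_regulators)]
        edges = []
        for tgt in targets:
            for reg in regulators:
                if rng.random() < spec.reg_edge_prob:
                    sign = -1 if rng.random() < spec.inhibition_fraction else +1
                    edges.append((reg, tgt, sign))
        layers.append(RegulatoryLayer(edges=edges, layer_index=li + 1))
        targets = regulators
    return model, layers


def random_expression(
    model: MetabolicModel,
    n_samples: int,
    seed: int = 0,
    extra_genes: list[str] | None = None,
    silent_weight: float = 0.4,
) -> pd.DataFrame:
    """Seeded log2(TPM+1)-scale expression matrix (genes x samples).

    Values come from a two-component mixture: silent genes near zero and
    expressed genes on a lognormal TPM scale, so both HIGH and LOW states
    occur under an absolute threshold of 1.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = np.random.default_rng(seed)
    genes = sorted(set(model.genes) | set(extra_genes or []))
    values = np.empty((len(genes), n_samples))
    for i in range(len(genes)):
        for j in range(n_samples):
            if rng.random() < silent_weight:
                tpm = rng.uniform(0.0, 0.3)
            else:
                tpm = rng.lognormal(mean=2.0, sigma=1.0)
            values[i, j] = np.log2(tpm + 1.0)
    return pd.DataFrame(
        values, index=genes, columns=[f"s{j + 1}" for j in range(n_samples)]
    )
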