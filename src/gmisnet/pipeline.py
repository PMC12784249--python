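"""End-to-end pipeline: rules -> eGPR networks -> per-reaction MCS -> G/F ->
gMIS -> optional expression-based predictions."""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd

from .config import MilpParams, RunConfig
from .egpr import build_egpr_network
from .gf import build_gf, save_gf
from .gmis import GmisResult, enumerate_gmis
from .mcs import enumerate_mcs_milp
from .model import (
    MetabolicModel,
    RegulatoryLayer,
    build_egpr_rule,
    load_json_model,
    load_regulatory_layer,
    load_sbml_model,
)
from .predict import (
    adaptation_check,
    binarize_expression,
    predict_essential_genes,
    predict_tumor_suppressors,
    predictions_to_frame,
)
from .rules import BooleanRule

logger = logging.getLogger(__name__)

__all__ = [
    "load_model_any",
    "per_reaction_mcs",
    "merged_gene_rules",
    "gmis_table",
    "run_full_pipeline",
]


def load_model_any(path: str | Path) -> MetabolicModel:
    path = Path(path)
    if path.suffix.lower() in (".xml", ".sbml"):
        return load_sbml_model(path)
    return load_json_model(path)


def per_reaction_mcs(
    model: MetabolicModel,
    layers: list[RegulatoryLayer],
    depth: int,
    params: MilpParams,
    strategy: str = "disjunctive",
) -> tuple[dict, dict]:
    """Enumerate MCSs for every reaction's eGPR network.

    Returns (reaction -> solution list, reaction -> EgprRuleSet).
    """
    per, rule_sets = {}, {}
    for rxn in model.reactions:
        rs = build_egpr_rule(rxn, model, layers, depth=depth, strategy=strategy)
        rule_sets[rxn] = rs
        net = build_egpr_network(rs)
        enum = enumerate_mcs_milp(net, params)
        if enum.truncated:
            logger.warning("MCS enumeration truncated for %s: %s",
                           rxn, enum.truncation_reason)
        per[rxn] = enum.solutions
    return per, rule_sets


def merged_gene_rules(rule_sets: dict) -> dict[str, BooleanRule]:
    """Union of per-reaction gene rules (reaction nodes excluded)."""
    merged: dict[str, BooleanRule] = {}
    for rxn, rs in sorted(rule_sets.items()):
        for gene, rule in rs.rules.items():
            if gene == rxn:
                continue
            merged.setdefault(gene, rule)
    return merged


def gmis_table(results: list[GmisResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "id": [f"gmis_{i + 1}" for i in range(len(results))],
            "length": [len(r.interventions) for r in results],
            "category": [r.category for r in results],
            "interventions": [r.interventions.label() for r in results],
        }
    )


def run_full_pipeline(cfg: RunConfig) -> dict:
    """Execute the full pipeline and write all artifacts to
    ``cfg.output_dir``.  Returns the summary dictionary (also written as
    JSON).  Reruns with the same configuration produce identical files."""
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    model = load_model_any(cfg.model_path)
    layers = [
        load_regulatory_layer(p, layer_index=i + 1)
        for i, p in enumerate(cfg.layer_paths)
    ]
    cfg.milp.allow_ki = cfg.allow_ki
    per, rule_sets = per_reaction_mcs(
        model, layers, cfg.depth, cfg.milp, cfg.combination_strategy
    )
    gf = build_gf(per, reactions=model.reactions, max_row_size=cfg.gf_row_cap)
    save_gf(gf, out)

    try:
        results = enumerate_gmis(
            model, gf, max_length=cfg.max_length, engine="exhaustive",
            allow_ki=cfg.allow_ki,
        )
    except Exception:
        logger.info("exhaustive gMIS engine unavailable; falling back to MILP")
        results = enumerate_gmis(
            model, gf, max_length=cfg.max_length, engine="milp",
            allow_ki=cfg.allow_ki, params=cfg.milp,
        )
    gmis_table(results).to_csv(out / "gmis.csv", index=False)

    category_counts: dict[str, int] = {}
    for r in results:
        category_counts[r.category] = category_counts.get(r.category, 0) + 1

    prediction_counts: dict[str, dict[str, int]] = {}
    if cfg.expression_path is not None:
        expr = pd.read_csv(cfg.expression_path, sep="\t", index_col=0)
        gene_rules = merged_gene_rules(rule_sets)
        all_records = []
        for sample in expr.columns:
            state = binarize_expression(
                expr[sample], threshold=cfg.expression_threshold, sample=sample
            )
            records = predict_essential_genes(results, state) + \
                predict_tumor_suppressors(results, state)
            for rec in records:
                direction = "KO" if rec.role == "essential" else "KI"
                from .egpr import Intervention

                candidate = Intervention(rec.gene, direction)
                verdicts = set()
                for support in rec.supports:
                    partners = [iv for iv in support if iv.gene != rec.gene]
                    verdicts.add(
                        adaptation_check(gene_rules, state, candidate, partners)
                    )
                rec.adaptation = "failed" if "failed" in verdicts else "passed"
            records = [r for r in records if r.adaptation != "failed"]
            all_records.extend(records)
            prediction_counts[sample] = {
                "essential": sum(1 for r in records if r.role == "essential"),
                "tumor-suppressor": sum(
                    1 for r in records if r.role == "tumor-suppressor"
                ),
            }
        predictions_to_frame(all_records).to_csv(out / "predictions.csv", index=False)

    summary = {
        "model": model.id,
        "n_reactions": len(model.reactions),
        "n_genes": len(model.genes),
        "depth": cfg.depth,
        "combination_strategy": cfg.combination_strategy,
        "allow_ki": cfg.allow_ki,
        "max_length": cfg.max_length,
        "gf_rows": gf.n_rows,
        "gf_discarded": len(gf.discarded),
        "n_gmis": len(results),
        "categories": category_counts,
        "gmis": [r.interventions.label() for r in results],
        "milp": cfg.milp.to_dict(),
        "seed": cfg.seed,
        "predictions": prediction_counts,
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True) + "\n")
    return summary
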