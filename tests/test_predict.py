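"""Context-specific essentiality / tumor-suppressor calling rules."""

import math

import numpy as np
import pytest

from gmisnet.egpr import Intervention, InterventionSet, KI, KO
from gmisnet.model import ModelValidationError
from gmisnet.predict import (
    ExpressionState,
    adaptation_check,
    binarize_expression,
    depmap_essential_flag,
    predict_essential_genes,
    predict_tumor_suppressors,
)
from gmisnet.rules import parse_gpr


def state(sample="s", **genes):
    return ExpressionState(sample=sample, states={g: v for g, v in genes.items()})


class TestBinarize:
    def test_absolute_cutoff(self):
        st = binarize_expression({"a": 5.0, "b": 0.2}, threshold=1.0)
        assert st["a"] == "HIGH" and st["b"] == "LOW"

    def test_missing_gene_defaults_low(self):
        st = binarize_expression({"a": 5.0})
        assert st["zz"] == "LOW"

    def test_negative_value_rejected(self):
        with pytest.raises(ModelValidationError):
            binarize_expression({"a": -0.1})

    def test_nan_treated_as_missing(self):
        st = binarize_expression({"a": float("nan"), "b": 2.0})
        assert st["a"] == "LOW" and st["b"] == "HIGH"


class TestEssentialCalls:
    gmis = [InterventionSet.of("EZH2-", "JUN-", "RELA+")]

    def test_call_made(self):
        st = state(EZH2="HIGH", JUN="LOW", RELA="HIGH")
        records = predict_essential_genes(self.gmis, st)
        assert [r.gene for r in records] == ["EZH2"]
        assert records[0].supports == [self.gmis[0]]

    def test_withdrawn_when_knockin_gene_low(self):
        st = state(EZH2="HIGH", JUN="LOW", RELA="LOW")
        assert predict_essential_genes(self.gmis, st) == []

    def test_withdrawn_when_uniqueness_fails(self):
        st = state(EZH2="HIGH", JUN="HIGH", RELA="HIGH")
        assert predict_essential_genes(self.gmis, st) == []

    def test_supports_collapse_across_gmis(self):
        gmis = [InterventionSet.of("A-", "B-"), InterventionSet.of("A-", "C-")]
        st = state(A="HIGH", B="LOW", C="LOW")
        records = predict_essential_genes(gmis, st)
        assert len(records) == 1 and len(records[0].supports) == 2


class TestTumorSuppressorCalls:
    def test_sdl_partner_low(self):
        gmis = [InterventionSet.of("DUSP4+", "GADD45B-")]
        st = state(DUSP4="LOW", GADD45B="LOW")
        records = predict_tumor_suppressors(gmis, st)
        assert [r.gene for r in records] == ["DUSP4"]

    def test_complex_with_one_low_member(self):
        gmis = [InterventionSet.of("CDK5RAP3+", "SHC1+")]
        st = state(CDK5RAP3="HIGH", SHC1="LOW")
        records = predict_tumor_suppressors(gmis, st)
        assert [r.gene for r in records] == ["SHC1"]

    def test_withdrawn_when_ko_partner_high(self):
        gmis = [InterventionSet.of("DUSP4+", "GADD45B-")]
        st = state(DUSP4="LOW", GADD45B="HIGH")
        assert predict_tumor_suppressors(gmis, st) == []


def _random_case(rng):
    genes = [f"g{i}" for i in range(rng.integers(2, 6))]
    dirs = [KO if rng.random() < 0.6 else KI for _ in genes]
    gmis = InterventionSet(
        frozenset(Intervention(g, d) for g, d in zip(genes, dirs))
    )
    st = {g: ("HIGH" if rng.random() < 0.5 else "LOW") for g in genes}
    return gmis, st


def test_mirror_symmetry_between_roles():
    """Swapping HIGH/LOW and KO/KI maps essential calls onto
    tumor-suppressor calls."""
    rng = np.random.default_rng(7)
    flip_dir = {KO: KI, KI: KO}
    for _ in range(200):
        gmis, states = _random_case(rng)
        st = ExpressionState(sample="s", states=states)
        mirrored_gmis = InterventionSet(
            frozenset(Intervention(iv.gene, flip_dir[iv.direction]) for iv in gmis)
        )
        ess = {r.gene for r in predict_essential_genes([gmis], st)}
        ts = {
            r.gene
            for r in predict_tumor_suppressors([mirrored_gmis], st.mirrored())
        }
        assert ess == ts


class TestAdaptation:
    def test_no_regulatory_path_passes(self):
        rules = {"x": parse_gpr("y")}
        st = state(y="HIGH", A="HIGH", B="LOW")
        verdict = adaptation_check(
            rules, st, Intervention("A", KO), [Intervention("B", KO)]
        )
        assert verdict == "passed"

    def test_repressor_release_fails(self):
        # partner B is repressed by A; knocking A out activates B
        rules = {"B": parse_gpr("not A")}
        st = state(A="HIGH", B="LOW")
        verdict = adaptation_check(
            rules, st, Intervention("A", KO), [Intervention("B", KO)]
        )
        assert verdict == "failed"

    def test_knockin_partner_inactivation_fails(self):
        # knock-in of A switches off partner C that must stay active
        rules = {"C": parse_gpr("not A")}
        st = state(A="LOW", C="HIGH")
        verdict = adaptation_check(
            rules, st, Intervention("A", KI), [Intervention("C", KI)]
        )
        assert verdict == "failed"

    def test_unchanged_partner_passes(self):
        rules = {"B": parse_gpr("A or D")}
        st = state(A="HIGH", B="HIGH", D="HIGH")
        verdict = adaptation_check(
            rules, st, Intervention("A", KO), [Intervention("B", KI)]
        )
        assert verdict == "passed"

    def test_cyclic_rules_rejected(self):
        rules = {"A": parse_gpr("B"), "B": parse_gpr("A")}
        with pytest.raises(ModelValidationError):
            adaptation_check(
                rules, state(A="HIGH", B="HIGH"),
                Intervention("A", KO), [Intervention("B", KO)],
            )

    def test_propagation_idempotent(self):
        from gmisnet.predict import _propagate

        rules = {"B": parse_gpr("not A"), "C": parse_gpr("B")}
        base = {"A": False, "B": False, "C": False}
        once = _propagate(rules, base, {"A": False})
        twice = _propagate(rules, once, {"A": False})
        assert once == twice


@pytest.mark.parametrize(
    "score,expected",
    [(-0.7, True), (-0.5, False), (-0.6, False), (None, None),
     (math.nan, None)],
)
def test_depmap_essential_flag(score, expected):
    assert depmap_essential_flag(score) is expected
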