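# Methods

## Model and scope

`gmisnet` works on integrated metabolic–regulatory (iMR) models: a
constraint-based metabolic layer (stoichiometric matrix `S`, flux bounds,
a biomass reaction, one Boolean GPR rule per reaction) plus up to two
signed, directed, acyclic regulatory layers over gene symbols. The object
of study is the **genetic minimal intervention set (gMIS)**: a
subset-minimal set of gene knock-outs and knock-ins whose induced reaction
deletions make the biomass LP maximum zero. Knock-out-only gMISs are the
classical gMCSs; gMISs additionally expose synthetic dosage lethality
(KO+KI), global tumor suppressors (single KI) and tumor suppressor gene
complexes (several KIs).

The pipeline has five stages: eGPR rule construction → ON/OFF artificial
network compilation → per-reaction minimal cut set (MCS) enumeration →
G/F matrix integration → genome-level gMIS enumeration, with an optional
expression-mapping stage for context-specific calls.

## Regulator combination

How several activators and repressors of one gene combine into a Boolean
rule is a genuine modelling choice; the package ships two strategies and a
hook to add more:

* **disjunctive** (default): `g = OR(activators) OR OR(NOT repressor)` —
  the gene is available when some activator is present *or* some repressor
  is absent; it is unavailable only when every activator is silenced and
  every repressor engaged. Forcing the gene OFF therefore requires a
  *joint* intervention on its regulators, which is exactly what makes
  combined KO/KI solutions (e.g. `g3-;g6+;g7-` in the bundled toy)
  informative. This reading is the one consistent with the worked-example
  outcomes that anchor the test suite.
* **conjunctive**: `g = OR(activators) AND AND(NOT repressor)` — a strict
  reading where any engaged repressor alone silences the gene. Under this
  convention single repressors produce singleton knock-in cuts; it is kept
  selectable (`--strategy conjunctive`) for sensitivity analyses.

A gene regulated in a later layer that already has a rule gets
`prior AND block`. Regulatory depth is capped at 2: deeper compositions of
real regulatory networks are dominated by cycles, which the Boolean/flux
machinery cannot represent. Edges that would close a cycle within one rule
set are dropped deterministically in stable load order and reported.

## The ON/OFF artificial network

Each gene rule `ρ_i` is augmented to `g_i = (ρ_i AND y_i) OR u_i`
(`ρ_i = e_i` for free inputs). The two readings of where the free-input
node enters (`(e AND y) OR u` vs. `e` OR'd elsewhere) coincide on the
feasible space because KO and KI of one gene are mutually exclusive; the
equivalence is pinned by a unit test enumerating all three commitments per
gene. The OFF side is the De Morgan image `g_OFF = u_OFF AND (ρ_OFF OR
y_OFF)` — fixed, not configurable. Negation-normal-form rules compile into
gates: one gate per OR branch, one multi-substrate gate per AND;
nested subexpressions get content-addressed intermediate nodes (SHA-1 of
the canonical serialisation), so identical subrules share a node and
networks are bit-reproducible. All stoichiometric coefficients are 1;
duplicate consumption collapses by idempotence.

Derivability (`forward_closure`) is the deterministic semantics: base
facts commit exactly one exchange per y/u pair per gene, then the least
fixpoint over gates. This matches the flux semantics of the MILP on these
gate-acyclic networks. On rules where a gene reaches the target through
reconvergent paths of opposite polarity, derivability with no intervention
lets both polarities of a free input feed the network at once — strict
Boolean satisfiability would not. The enumerators implement derivability
(what the optimisation encodes); the divergence case is constructed and
documented in `tests/test_egpr.py`.

## Per-reaction MCS enumeration

Blocking is certified through the Farkas dual of the primal system
"`S^k r = 0`, `r ≥ 0`, committed intervention exchanges `≤ 0`, target ON
exchange flux `≥ r*`". Dual variables: `u` free per species, `v ≥ 0` per
intervention exchange, scalar `w ≥ c/r*`; rows `Sᵀu + Pv − t·w ≥ 0`.
Binaries `z` gate `v` through `α·z ≤ v ≤ M·z`; per gene
`z_yON + z_yOFF = 1`, `z_uON + z_uOFF = 1`, `z_yON + z_uOFF ≤ 1` (no
simultaneous KO+KI), at least one intervention overall. The objective
minimises the number of committed `y ON` / `u OFF` exchanges (i.e. the
intervention count) plus an index-weighted `1e-6` tie-break for
deterministic ordering inside one optimum; after each optimum an integer
no-good cut excludes the support and all supersets, which, combined with
nondecreasing optima, guarantees every emitted set is subset-minimal.

Constants: `α = 1e-3`, `M = 1e3`, `r* = 1`, `c = 1e-3`; blocking tolerance
`1e-6`; per-solution time limit 300 s (60 s in the bundled sweeps); all
recorded with every run. Backend: HiGHS through `scipy.optimize.milp` —
the solver name travels in the run metadata.

Two HiGHS-specific safeguards, found necessary in practice: (i) presolve
is disabled for the enumeration MILPs, since presolve can misdeclare this
indicator-heavy structure infeasible and silently truncate the
enumeration; (ii) every incumbent is re-checked against the exact closure
oracle — a tiny fractional `z` can leak a nonzero `v` through the big-M
link — and spurious incumbents are excluded with an exact-assignment cut
before re-solving. Neither safeguard changes the mathematical contract;
both make it robust to solver tolerances.

`brute_force_mcs` is the independent oracle: exhaustive candidate
enumeration by increasing size over the valid atom combinations, kept iff
the closure blocks and no kept subset does, guarded at ~10⁶ candidates.

## G/F integration and the genome level

Identical intervention sets from different reactions merge into one F row
whose G row marks all of them; rows with more than five genes are
discarded (longer sets contribute negligibly to genetic-vulnerability
prediction) and counted in a discard report. Rows whose atoms are a
superset of another row with at least the same blocked reactions are
dominated and pruned by default; a test proves gMIS output is unchanged
with pruning off. G/F persist as Matrix Market files plus TSV indices and
round-trip bit-exactly.

`enumerate_gmis` restricts candidate atoms to those occurring in F (an
atom in no F row cannot change the blocked set — asserted by a test) and
offers two engines with identical contracts: the exhaustive reference
engine walks the atom-subset lattice by increasing size with memoised FBA
calls (guarded by a candidate cap), while the MILP engine selects atoms
with binaries and embeds a Farkas-dual certificate of biomass
infeasibility under the induced deletions (deletion duals `μ` gated by
big-M binaries tied to covered F rows; growth demand `bmin = 1e-2`,
far below any nonzero toy optimum, which is ≥ 1 by construction).
Minimality is with respect to the full atom lattice, not just row unions.
Lethality tolerance on biomass is `1e-6`; the LP solver is independent of
the MILP backend. Output order is deterministic: (length, atoms).

Taxonomy of a lethal set: 1 KO → essential gene; ≥2 KO only → SL; 1 KI →
TSG; 1 KO + 1 KI → SDL; ≥2 KI only → TSGC; anything else mixed. (The
narrative definition of TSGC as "length 1" contradicts its own two-gene
worked example; the all-KI, length ≥ 2 reading is implemented.)

## Expression mapping and adaptation

Expression is binarized HIGH/LOW by an absolute cutoff on the
log2(TPM+1) scale, default 1.0 (TPM ≥ 1), exposed as `--expr-threshold`
and pluggable; genes missing from the matrix default to LOW, which is
conservative for essentiality calls. The published per-sample threshold
family this emulates is defined in external tooling; an honest
configurable cutoff was preferred over guessing its exact semantics, and
the method name is recorded in every output.

Essentiality: gene `g` is called via gMIS `m` iff `g ∈ KO(m)` is the
unique HIGH knock-out of `m` and every KI gene of `m` is HIGH. Tumor
suppression is the exact mirror image, and a property test checks the
HIGH↔LOW / KO↔KI symmetry on random cases. The adaptation check replaces
an optimisation formulation with deterministic topological propagation —
exact on acyclic rules: unregulated genes are pinned to their observed
state, the candidate intervention is forced, rules are evaluated once in
topological order (hence idempotent), and the call is discarded if any
partner knock-out gene activates or partner knock-in gene inactivates.

## Synthetic data

`fig1_fixture` encodes the worked-example toy (three metabolites, four
reactions, seven genes, one regulatory layer with two inhibition arcs);
its transcription is documented field by field in the fixture docstring
and is the golden anchor: the pipeline must keep producing its six gMISs,
four gMCSs and the two `r3` MCSs. `random_imr_model` generates linear
substrate→biomass chains with parallel isozyme branches, random AND/OR
GPRs, and regulator-to-target edge layers (fresh regulator symbols per
layer, so rules are acyclic by construction); signs are Bernoulli with a
configurable inhibition fraction; identical specs give byte-identical
models, and infeasible draws regenerate deterministically from
incremented sub-seeds. `random_expression` mixes silent (~0) and
lognormal TPM components so both states occur under the default cutoff.

What the generators do **not** emulate: genome-scale topology (thousands
of reactions, branched cofactor coupling), reversible exchange metabolism,
regulatory cycles, dosage (non-Boolean) regulation, or realistic
expression covariance. Passing tests therefore demonstrate algorithmic
correctness — enumeration completeness/minimality against oracles and
rule-level prediction logic — not biological accuracy on real models.

## Problem sizes and limits

The shipped sweeps use 100 random rule sets (≤ 6 genes, depths 1–2) for
the MILP-vs-brute-force equivalence and 30–50 random toys (≤ 8 reactions)
for the engine equivalence; worked-example runs finish in seconds.
Known limitations: no regulatory cycles (edges are dropped, not modelled);
no network compression, so genome-scale models would need the external
preprocessing used in large-scale studies; enumeration beyond length 5 is
deliberately unsupported; the MILP engines' big-M constants are tuned for
unit-coefficient gate networks.
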