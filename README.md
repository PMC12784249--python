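# gmisnet

Enumeration of **genetic minimal intervention sets (gMIS)** — smallest
combinations of gene knock-outs (`g-`) and gene knock-ins (`g+`) that
abolish biomass production — in integrated metabolic–regulatory (iMR)
network models, and prediction of context-specific essential genes and
tumor suppressors from expression data.

## Who this is for

Systems biologists working with constraint-based metabolic models who want
to go beyond synthetic lethality (pairs/sets of knock-outs) and also
capture **synthetic dosage lethality** (a knock-out combined with a
knock-in) and **tumor suppressor gene complexes** (joint knock-ins that are
lethal), in models where gene–protein–reaction (GPR) rules are extended
with signed, acyclic transcriptional/signaling regulation.

## The method in brief

1. **eGPR rules.** Each reaction's GPR Boolean rule is extended with up to
   two levels of upstream regulators (activation `+1`, inhibition `-1`),
   giving a rule set `B(k)` with free-input genes `L(k)`.
2. **ON/OFF network.** Every gene rule `ρ_i` is augmented to
   `g_i = (ρ_i AND y_i) OR u_i`, where removing the exchange of `y_i ON`
   knocks gene *i* out and removing the exchange of `u_i OFF` knocks it in;
   free inputs get `e_i` exchanges. Nodes are split into ON/OFF species by
   De Morgan's laws and rules compile into an irreversible gate-reaction
   network `S^k`.
3. **Per-reaction MCS.** Minimal blocking sets are enumerated by a
   mixed-integer program over the Farkas dual of "flux `r*` is forced
   through the target's ON exchange": binaries `z` select which
   intervention exchanges are shut (`α·z ≤ v ≤ M·z`, per gene
   `z_{yON}+z_{yOFF}=1`, `z_{uON}+z_{uOFF}=1`, `z_{yON}+z_{uOFF} ≤ 1`),
   minimising `Σ z_{yON}+z_{uOFF}` with integer no-good cuts between
   solutions. A brute-force closure oracle provides an independent check.
4. **G/F matrices.** Per-reaction solutions merge into paired binary
   matrices: each **F** row is a minimal intervention set, its **G** row
   the reactions it deletes (rows above 5 genes discarded).
5. **gMIS.** Sets of F-atoms whose induced deletions drive the biomass LP
   maximum to zero, subset-minimal, up to length 5 — enumerated by an
   exhaustive reference engine and an equivalent MILP engine.
6. **Context predictions.** With binarized expression (HIGH iff
   log2(TPM+1) ≥ 1 by default), a knock-out gene is *essential* in a sample
   when it is the unique HIGH gene among a gMIS's knock-outs and all its
   knock-ins are HIGH; a knock-in gene is a *tumor suppressor* when it is
   the unique LOW gene among the knock-ins and all knock-outs are LOW.
   An adaptation check propagates the intervention through the regulatory
   rules and discards calls whose partners flip state.

## Worked example

The bundled toy iMR network (3 metabolites; reactions `r1`, `r2`, `r3`,
`rBIO`; genes `g1..g7`; one regulatory layer with two inhibition arcs):

```sh
gmisnet make-fixture --kind toy --out fixture
gmisnet run fixture/model.json --layer fixture/layer1.tsv --out run
```

prints

```
6 intervention sets ({"SDL": 1, "SL": 3, "essential-gene": 1, "mixed": 1}) -> run
```

i.e. six gMISs block the biomass reaction — `g1-` (essential gene),
`g2-;g5-`, `g3-;g4-`, `g5-;g7-` (synthetic lethality), `g2-;g7+`
(synthetic dosage lethality) and `g3-;g6+;g7-` (mixed) — of which four are
knock-out-only gMCSs. Per-reaction enumeration on `r3` alone:

```sh
gmisnet enumerate-mcs fixture/model.json r3 --layer fixture/layer1.tsv
g3-;g4-
g3-;g6+;g7-
```

The second set reads: knocking out `g3` and `g7` while knocking **in** the
repressor `g6` leaves `r3` without a functional enzyme — an intervention
invisible to knock-out-only analysis. `run/` contains the G/F matrices
(Matrix Market + TSV indices), `gmis.csv`, and a `summary.json`; adding
`--expression fixture/expression.tsv` also writes per-sample
`predictions.csv`.

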