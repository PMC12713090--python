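# Methods

## 1. Model representation

A model is a list of metabolites and reactions. Each reaction carries a
stoichiometry map (metabolite id → coefficient, negative = consumed),
flux bounds `lb ≤ v ≤ ub` in mmol·gDW⁻¹·h⁻¹ (biomass flux in h⁻¹), an
optional boolean gene–protein–reaction (GPR) rule over `and`/`or`, and an
optional subsystem tag. A reaction touching exactly one metabolite is
treated as an exchange (boundary) reaction. The stoichiometric matrix
`S ∈ ℝ^(m×n)` is assembled sparse (CSR) in insertion order.

Validation reports dangling metabolites, elementally unbalanced internal
reactions (checked per element whenever all participants carry formulas;
exchanges and the biomass pseudo-reaction are exempt), malformed GPRs,
and inverted bounds; a model is "solvable" iff the zero flux vector is
feasible (every bound interval straddles 0).

`set_medium` rebounds exchange fluxes orientation-aware (an exporter
written `{met: +1}` gets its upper bound set; an importer `{met: −1}`
gets `lb = −rate`) and closes all other carbon-source exchanges, keeping
a small inorganic-carbon whitelist (CO₂, bicarbonate, carbonate) open.

## 2. Linear programming

All optimization is `scipy.optimize.linprog` with the HiGHS solver and
primal/dual feasibility tolerances of 1e-9.

- **FBA**: maximize `v_j` subject to `S·v = 0`, bounds, and optional
  pins. A pin fixes `v_k = c` by intersecting `[c − ε, c + ε]`
  (ε = 1e-9·max(1, |c|)) with the reaction's bounds; an empty
  intersection short-circuits to an infeasible status without an LP call.
- **pFBA**: minimize `Σ|v|` at fixed pins via forward/backward variable
  splitting (`v = v⁺ − v⁻`, `v⁺, v⁻ ≥ 0`), the standard LP
  reformulation of the ℓ₁ objective.
- **Production envelope**: maximum product flux at growth enforced to a
  fraction grid of its maximum.
- Every returned solution is re-checked against `‖S·v‖∞ ≤ 1e-6` and the
  bounds before use.

## 3. The modified FSEOF scan

1. **Control state**: maximize growth, pin it at its maximum μ*, take
   the parsimonious distribution as the reference (wild-type-like) state.
2. **Production states**: for each fraction `f ∈ {0.2, 0.3, …, 0.8}`
   (configurable), pin growth at `f·μ*`, maximize the product flux, pin
   it at that maximum, and take the parsimonious distribution.
   Per-level failures are recorded as warnings; the scan continues.
3. **Scores**: for each reaction, with control flux `c` and mean
   production flux `p̄` (aggregation configurable: mean flux, mean of
   per-level ratios, or max flux):
   - inactive everywhere (|flux| ≤ 1e-6 at all levels and control):
     excluded;
   - `|c| ≤ 1e-6`, active in production: **ACTIVATED** (no finite ratio);
   - sign flip between control and production: excluded as
     direction-inconsistent;
   - otherwise `score = |p̄| / |c|`.
4. **Classification**: amplification targets are ACTIVATED reactions
   followed by `score > 1 + δ`; attenuation targets satisfy
   `0 < score < 1 − δ` (dead band δ = 0.05). The biomass reaction, the
   target itself and all exchange reactions are excluded
   unconditionally; `gene_only` additionally drops reactions without a
   GPR. Ordering is deterministic: ACTIVATED first by mean production
   flux, then by score (descending for up, ascending for down), ties by
   reaction id.
5. **Gene folding**: a gene inherits the extremal score over the
   reactions whose GPR mentions it (max for amplification, ACTIVATED
   dominating; min for attenuation).

Closed forms used in testing: because the biomass flux at level `f` is
exactly `f·μ*` and its control flux is `μ*`, the biomass reaction's score
is `mean(fractions)` for any model; a reaction whose flux is constant
across control and all levels scores exactly 1.

## 4. Spinosad pathway module

The graftable module factors spinosyn biosynthesis into three branches,
with per-step reactions (`branch` granularity) or single lumped steps:

- **rhamnose**: G1P → TDP-glucose → 4-keto → epimerized → TDP-rhamnose
  (4 steps, gene tags gtt/gdh/epi/kre);
- **forosamine**: one lumped TDP-forosamine synthesis from G1P
  (dTTP, 2 NADPH, glutamate, 2 SAM as currency);
- **aglycone**: polyketide assembly from 1 starter acyl-CoA +
  7 malonyl-CoA + 2 methylmalonyl-CoA with 10 NADPH, releasing 9 CO₂
  (acetyl-CoA starter → spinosyn A series; propionyl-CoA → D series);

followed by pseudoaglycone (rhamnosylation), final forosaminylation plus
3 SAM methylations, and demand reactions for spinosyn A, spinosyn D and
a fixed 0.85/0.15 A/D blend (closed by default). Currency species
resolve to host metabolites by id or through an explicit mapping (a
BiGG-style mapping is shipped); unresolved species raise an error
listing every orphan. Grafting never edits host reactions, so host
optima are preserved exactly.

A second module supplies malonyl-CoA through a carbon-conserving,
ATP-independent two-step route (pyruvate → malonate semialdehyde →
malonyl-CoA, NADP⁺-coupled); its structural guarantees — carbon
conserved in every step, no CO₂/bicarbonate, no ATP — are asserted from
declared formulas, not from the solver.

Interventions on a model: `amplify` (multiply both bounds by a factor —
copy-number increase), `knockout` (zero bounds), `add_module` (graft),
`enable_degradation` (open a closed storage-mobilization reaction).
Scenario comparison applies intervention lists in order, maximizes the
product with growth held at ≥ 10 % (configurable) of each scenario's own
maximum, and reports flux, yield per substrate and delta against the
unedited base.

## 5. Synthetic models and ground truth

- **Linear toy (T1)**: uptake (ub 10) feeding growth and a gene-tagged
  product branch. All scan quantities are closed forms (see §3).
- **Redundant toy (T3)**: one-step and two-step routes to the product;
  pFBA at product 10 must put all flux on the short route, total
  `Σ|v| = 30` analytically.
- **Branched generator (T2)**: seeded. Uptake `U ~ logU(5, 15)` feeds a
  core chain (redundant pair of unequal lengths, so the parsimonious
  optimum is a unique vertex), a capacity-limited precursor bottleneck
  `b ~ logU(0.11·U, 0.16·U)`, a competing branch, and a biomass reaction
  draining precursor and core metabolite 10:1. The parametrization
  guarantees analytically that the bottleneck saturates at every
  enforcement level (score `b/(0.0909·U) ∈ (1.21, 1.76)`, above the dead
  band) and the competing branch tracks biomass (score 0.5, below it),
  so ground-truth recovery is exact by construction, not by tuning. The
  generator refuses degenerate parametrizations (no producible product)
  rather than emitting them. Realism is limited by design: no cofactor
  stoichiometry, no thermodynamics, single compartment — the generator
  exists to make the scan's decision boundary provable, not to imitate a
  genome-scale network.
- **Host toy**: 24 metabolites / 23 reactions with the precursor pools
  the spinosad module needs (acyl-CoAs via ACC/PCC/PPS, G1P/dTTP–TDP
  cycle, SAM/SAH cycle, glutamate, NADPH, ATP maintenance, a closed
  triacylglycerol storage pool). Glucose uptake 10 gives maximum growth
  12.5 and, after grafting, maximum spinosyn A 0.8367.

## 6. Verification oracle

`oracle_scores` recomputes FSEOF scores through a deliberately different
code path: dense matrices, the dual-simplex HiGHS interface, an
independent pin/pFBA implementation, and a dense 0.01-step enforcement
grid from which the configured fractions are selected. It shares no scan
code and is restricted to ≤ 25 reactions. Agreement within 1e-6 across
the fixtures and seeded toys (observed: ≤ 2.3e-16) is the primary
correctness evidence; `cobra` + GLPK serves as a second, fully foreign
cross-check for FBA/pFBA optima and SBML round trips in the test suite.

## 7. Determinism and outputs

Model ordering is insertion-stable, all exports sort deterministically,
floats print as `%.10g`, and HiGHS is deterministic for fixed input, so
pipeline reruns are byte-identical (checked via SHA-256 in the run
manifest). The pipeline writes `targets.tsv`, `scan_matrix.tsv`,
`gene_scores.tsv`, `summary.json`, optionally `scenarios.tsv`, and a
`manifest.json` with per-stage status, wall time and input/output
checksums; a stage failure is recorded and downstream stages are skipped
rather than crashing the run.

## 8. Problem sizes and budgets

Toy problems are 4–40 reactions; a full seven-level scan plus scoring
runs in ~0.25 s, the oracle in ~0.2 s. The acceptance script (52 oracle
comparisons + 50 recovery toys + pathway and determinism checks) runs in
~18 s; the full test suite in ~45 s. Genome-scale models (thousands of
reactions) are within `linprog`'s reach but outside the shipped
fixtures; the oracle intentionally refuses them.
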