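# Methods

This note records the mathematical model implemented by fluxfit, the
numerical choices and their rationale, and the known limitations. Symbols:
S is the stoichiometric matrix over internal metabolites, v the flux vector,
v_Bio the biomass flux, T the per-condition viability threshold.

## 1. Phenotype prediction

A *condition* is a knockout-gene set, a medium (bound overrides restricted to
exchange reactions), an observed label (growth / non-growth) and a threshold
T > 0. Reactions whose GPR boolean evaluates false under the knockout set are
clamped to zero flux; genes absent from every GPR are warned about and
treated as absent. The FBA LP is

max v_Bio  s.t.  S·v = 0,  lb ≤ v ≤ ub,  0 ≤ v_Bio,

solved with scipy's HiGHS interface (deterministic). The biomass reaction is
kept separate from the reaction list: its column is the biomass
stoichiometry −(substrates) + (products), which is what the biomass-edit
machinery modifies.

**Growth classification is strict:** growth iff optimum > T + tol with
tol = 1e-6. A value exactly at the threshold counts as non-growth. This
guards against trickle flow (numerically tiny flux crossing the threshold)
and makes the two MILP blocks complementary: the growth block requires
v_Bio ≥ T, the non-growth block requires max v_Bio ≤ T, and the knife-edge
value T itself is assigned to non-growth deterministically.

Thresholds default to `cutoff_fraction` (default 0.05) × the wild-type
optimum on the condition's medium, the usual viability-cutoff construction.

## 2. The repair search space

Binary decision per candidate change, each with a penalty weight
(default 1.0):

| binary | meaning | effect on bounds / biomass |
|---|---|---|
| RF r | remove forward direction | ub_r ← 0 |
| RB r | remove backward direction | lb_r ← 0 |
| I r | make irreversible r reversible | lb_r ← −M |
| ADD z | add database reaction z | 0 ≤ v_z ≤ M·δ |
| RS/RP m | drop biomass substrate/product m | coefficient → 0 |
| AS/AP m | add biomass substrate/product m with coefficient c | coefficient → c |

M = 1000 (the conventional flux bound; all model bounds must lie within it).
Database entries are stored forward-only; reversible source equations are
split into `_f`/`_b` irreversible entries. Database reactions carry GPRs and
are knockout-clamped per condition like native reactions. Exchange-reaction
removals can be given a smaller weight (e.g. 0.1) to model chemically
undefined media, where deleting a nutrient from the medium representation
should be cheaper than deleting a transporter. Condition-exclusion binaries
(weight ~1e3) are optional and off by default.

Candidate **pruning** (on by default) works on the *supermodel* — the input
model with every reversal candidate applied and every database candidate
added: directions blocked there can never carry flux anywhere in the search
space, so their binaries are dropped; directions essential to some observed
growth condition even in the supermodel can never be removed, so their
removal binaries are dropped. Both screens are exact (two LPs per direction;
per-direction bound-zeroing re-solves), not heuristics.

## 3. Single-level reformulation

For each observed-**growth** condition the MILP carries a primal flux copy
with binary-coupled bounds, e.g. v ≤ ub·(1−δ^RF), v ≥ lb·(1−δ^RB) − M·δ^I,
0 ≤ v_z ≤ M·δ^add, plus the threshold row v_Bio ≥ T. Knocked-out reactions
get clamped bounds with *no* binary coupling — a repair cannot re-enable a
gene the experiment removed.

For each observed-**non-growth** condition, "max v_Bio ≤ T" is a statement
about an inner optimum, encoded by **weak LP duality**: the block carries
dual variables λ (free, equality rows) and μ ≥ 0 (bound rows), the dual
feasibility rows EᵀΛ + Aᵀμ = c, and the certificate row (dual objective)
≤ T. Any feasible certificate upper-bounds the inner maximum, so feasibility
of the block is exactly "the modified network cannot grow". This is sound
because the inner LP is always feasible (v = 0; positive lower bounds are
clamped to 0 for non-growth conditions — minimal maintenance fluxes are not
enforced in non-growth cases, and the clamp is logged) and bounded (box
bounds). Products δ·μ arising from binary-dependent bounds are linearized
exactly by McCormick inequalities, valid because δ is binary and μ lives in
an explicit dual box.

**Biomass edits** enter both blocks through auxiliary drain variables u per
optional biomass metabolite, pinned by four inequality rows to
u = c·(1−δ)·v_Bio (removal candidates) or u = c·δ·v_Bio (addition
candidates); the exhaustive subset test in `tests/test_milp.py` verifies this
linearization against explicitly rebuilt biomass reactions for every binary
assignment.

## 4. Numerical safeguards

* **Dual box.** μ is boxed at 1e4 by default. A too-small box can only force
  *over*-repair (any in-box certificate stays valid), never an invalid
  solution — the returned repair is always re-verified by plain FBA. On box
  contact the instance is re-solved with a tenfold larger box; the solution
  is accepted once the repair cost is stable under enlargement, and a
  warning is emitted if it moved (up to `max_dual_box_retries`). A tiny
  epsilon objective (1e-9) on the dual variables keeps certificates
  near-minimal where the LP path honors it.
* **Determinism / tie-breaking.** HiGHS with `mip_rel_gap=0`; a secondary
  objective of `tie_break_eps`·index (1e-6, far below the smallest penalty
  step) makes the chosen optimum reproducible across runs; alternative
  optima are enumerated explicitly with integer cuts (no-good cuts over the
  change binaries only), which yield nondecreasing objectives.
* **Verification.** Every solution is decoded to a concrete change set,
  applied to the model, and every condition re-simulated by plain FBA; a
  mismatch with the solver's claim raises. The reported objective is the
  exact weight sum over active binaries, with epsilons stripped.

## 5. Run modes

* **global** — one MILP over all conditions; minimal total penalty; with
  exclusion binaries the count of binaries is exactly (number of candidate
  changes) + (number of excludable conditions).
* **subset** — iterative approximation: false growth predictions first, then
  false non-growth, lexicographic by condition id. Each false growth case is
  solved jointly with the designated wild-type growth case per medium (so
  trivially lethal "fixes" are rejected); false non-growth cases solo first.
  Accepted changes are frozen into the working model and leave the candidate
  pool. After each acceptance the whole panel is re-simulated; newly false
  predictions put the triggering case back on the table jointly with the
  full conflict set, until stable (bounded rounds). Exclusion is not
  available here; unresolvable cases are reported. The paired-motif fixture
  demonstrates the mode's designed limitation: per-case solving cannot see
  repairs that only pay off jointly.
* **simple** — all change weights zeroed, unit-cost exclusion per condition:
  the optimum is a maximal condition subset that some admissible network
  satisfies, for data triage.
* **isoenzyme preprocessing** — separate from the MILP (which never touches
  GPRs): given a reciprocal-homology table, partners of false-non-growth
  genes with both e-values < 1e-13 are OR-ed into the affected GPRs.

## 6. Synthetic benchmark generator

`fluxfit.synth` builds seeded toy networks (parallel linear pathways with
transport, optional isozymes/complexes, a biomass drawing on all pathway
terminals, a byproduct sink) and corrupts them with planted defects from five
categories — deleted reaction (restorable from the database),
spurious reaction, wrongly irreversible reaction, missing biomass metabolite,
spurious biomass metabolite — plus decoy candidates (tempting transport
removals that silence errors but starve the wild type, and dead-end database
additions). Every scenario is self-checked: the truth model reproduces all
panel labels and the planted change set reconciles the corrupted model.
A brute-force oracle enumerates all change subsets up to a cardinality bound
by plain FBA, independent of the MILP code path.

Realism limits: toy networks are loop-free and small (tens of reactions), so
they do not exercise thermodynamically infeasible cycles, large degenerate
flux spaces, or numerically ill-scaled stoichiometries; thresholds sit well
away from achievable optima by construction. Problem sizes in the tests and
acceptance script (2–3 pathways, depth 2–3, ≤ ~15 candidate binaries) are
chosen so that the brute-force oracle stays exhaustive within seconds; they
are a package choice, not an external constraint.

## 7. Known limitations

* Whole-condition exclusion and per-condition media are supported, but
  gene-dosage or partial-knockdown phenotypes are not representable.
* The subset strategy's conflict loop is bounded (default 10 rounds per
  case); pathological candidate sets can leave cases unresolved, which is
  reported rather than silently dropped.
* MILP size grows linearly in conditions × reactions; global mode on
  genome-scale models with thousands of conditions is expected to be out of
  reach of the bundled open-source solver — that is precisely what subset
  mode is for.
* `simple` mode's repaired model is a by-product (weights are zero); only
  its feasible condition set is meaningful.
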