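# fluxfit

Reconcile constraint-based metabolic network models with observed gene-knockout
growth phenotypes by finding a **globally minimal set of network repairs**.

## The problem

A genome-scale metabolic model predicts growth of a knockout strain by flux
balance analysis (FBA): maximize the biomass flux v<sub>Bio</sub> subject to
steady state **S·v = 0** and flux bounds, with reactions disabled when the
knocked-out genes inactivate their gene–protein–reaction (GPR) rule. A strain
is predicted viable when the optimum exceeds a viability threshold.

Real reconstructions disagree with knockout screens in two ways:

* **false growth predictions** — the model grows where the organism does not
  (a spurious reaction, a wrongly reversible reaction, or a biomass component
  the organism actually needs is missing from the biomass reaction);
* **false non-growth predictions** — the model fails where the organism grows
  (a missing reaction, an unannotated isozyme, or a superfluous biomass
  component).

Classical curation fixes one wrong prediction at a time, which accumulates
changes that are not globally optimal — and some defects *cannot* be found one
case at a time: a paired remove+add repair may look useless for every single
case yet resolve several cases jointly. fluxfit instead solves the bi-level
problem

> minimize Σ penalties of applied modifications
> subject to: for every observed-growth condition, the modified network can
> reach the viability threshold; for every observed-non-growth condition, the
> modified network's **maximal** biomass flux stays below it

over discrete modifications: per-direction reaction removals, irreversible →
reversible conversions, reaction additions from a candidate database, biomass
composition edits, and (optionally) exclusion of irreconcilable conditions at
a high penalty. The inner "maximal biomass" condition is made single-level
through LP duality: a feasible dual certificate within explicit bounds proves
non-growth, and the certificate's products with the decision binaries are
linearized exactly (McCormick), so the whole problem is one MILP solved to
proven optimality with HiGHS. See [docs/methods.md](docs/methods.md) for the
formulation, numerical safeguards and design decisions.

## Worked example

Generate a seeded synthetic benchmark — a toy network whose "true" version is
corrupted by planted defects (here: one deleted reaction and one spurious
bypass), together with the knockout panel labeled from the truth and a
candidate reaction database containing the deleted reaction among decoys:

```text
$ fluxfit synth --seed 11 --out demo --defects delete_reaction=1,spurious_reaction=1
wrote scenario (seed 11, 7 conditions, planted penalty 2) to demo

$ head -4 demo/experiments.tsv
condition_id	genes	medium_id	observed	threshold
WT			growth	0.5
KO_g0_1	g0_1		non-growth	0.5
KO_g0_2	g0_2		non-growth	0.5
```

Fit a globally minimal repair:

```text
$ fluxfit fit --model demo/model.xml --experiments demo/experiments.tsv \
      --media demo/media.tsv --database demo/database.tsv \
      --mode global --out demo/fit
penalty=2 changes=2 tp=1	fp=0	fn=0	tn=6	accuracy=100.0%	mcc=1.00

$ cat demo/fit/changes.tsv
add_reaction	R1_1	1
remove_forward	Y0	1
```

The solver recovered exactly the planted corruption: re-adding the deleted
chain reaction `R1_1` from the database and removing the spurious bypass
`Y0`. `demo/fit/result.json` holds the full report (per-condition
predictions, confusion matrix, alternative optima, input digests) and
`demo/fit/repaired_model.xml` the repaired model.

Other subcommands: `fluxfit simulate` (plain FBA panel predictions),
`fluxfit metrics --tp … --fp … --fn … --tn …` (accuracy/MCC from a confusion
matrix), and `fluxfit fit --mode subset|simple` for the iterative strategy
and the maximal-consistent-condition-set preprocessing mode.

## Library use

```python
from fluxfit import (
    CandidatePolicy, enumerate_change_candidates, run_global_mode,
)
from fluxfit.io import read_sbml_model, read_reaction_database, read_media, read_experiments

model = read_sbml_model("model.xml")
media = read_media("media.tsv")
conditions = read_experiments("experiments.tsv", model, media, cutoff_fraction=0.05)
db = read_reaction_database("database.tsv")

candidates = enumerate_change_candidates(model, db, CandidatePolicy(), conditions)
report = run_global_mode(model, conditions, candidates, db, n_alternatives=3)
print(report.final_changes.describe(), report.confusion)
```

## Run modes

* **global** — one MILP over all conditions; provably minimal total penalty;
  enumerate alternative optima with `--alternatives`.
* **subset** — the scalable iterative strategy: each false growth prediction
  is solved jointly with the wild-type growth case(s), each false non-growth
  prediction alone first; accepted changes accumulate, and conflicts (a
  change flipping a previously correct prediction) trigger joint re-solves.
* **simple** — ignores penalties and finds the maximal set of conditions
  that *some* admissible network can satisfy simultaneously (cheap data
  triage before a full run).

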