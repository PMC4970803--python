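"""Run modes orchestrating the repair MILP over experiment collections.

*Global mode* solves one MILP over every condition at once and is guaranteed
to return a penalty-minimal repair, but its size grows with the number of
conditions.  *Subset mode* approximates it at a fraction of the cost: each
false growth prediction is solved jointly with the wild-type growth case(s)
(so trivially lethal "fixes" are rejected), each false non-growth prediction
is first solved alone, accepted changes accumulate, and whenever an accepted
change flips a previously correct prediction the triggering case is re-solved
jointly with the full set of conflicting cases until the panel is stable.
*Simple mode* ignores change penalties entirely and only minimizes the
number of excluded conditions, yielding a maximal consistent condition set
for preprocessing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .fba import GROWTH, NON_GROWTH, Condition, predict_phenotype
from .metrics import ConfusionMatrix
from .milp import (
    BinName,
    ChangeCandidates,
    ExclusionPolicy,
    InfeasibleRepairError,
    MILPConfig,
    RepairSolution,
    assemble_bilevel_milp,
    enumerate_alternative_solutions,
    solve_milp,
)
from .model import ChangeSet, MetabolicModel, ReactionDatabase, apply_change_set

logger = logging.getLogger(__name__)


@dataclass
class RunReport:
    mode: str  # global | subset | simple
    solutions: list[RepairSolution]
    iterations: list[tuple[tuple[str, ...], str]]
    final_model: MetabolicModel
    final_changes: ChangeSet
    predictions: dict[str, str]
    confusion_by_medium: dict[str, ConfusionMatrix]
    confusion: ConfusionMatrix
    unresolved: list[str] = field(default_factory=list)
    excluded: set[str] = field(default_factory=set)

    @property
    def total_penalty(self) -> float:
        return sum(s.objective for s in self.solutions)


def _final_report(
    mode: str,
    model: MetabolicModel,
    conditions: list[Condition],
    solutions: list[RepairSolution],
    iterations: list[tuple[tuple[str, ...], str]],
    changes: ChangeSet,
    unresolved: list[str] | None = None,
    excluded: set[str] | None = None,
) -> RunReport:
    """Re-simulate everything from scratch so the confusion matrix is
    guaranteed to describe the final model, not the solver's claims."""
    predictions = {c.id: predict_phenotype(model, c) for c in conditions}
    by_medium: dict[str, ConfusionMatrix] = {}
    for mid in sorted({c.medium_id for c in conditions}):
        pairs = [(predictions[c.id], c.observed) for c in conditions if c.medium_id == mid]
        by_medium[mid] = ConfusionMatrix.from_labels(pairs)
    combined = ConfusionMatrix.from_labels([(predictions[c.id], c.observed) for c in conditions])
    return RunReport(
        mode=mode,
        solutions=solutions,
        iterations=iterations,
        final_model=model,
        final_changes=changes,
        predictions=predictions,
        confusion_by_medium=by_medium,
        confusion=combined,
        unresolved=unresolved or [],
        excluded=excluded or set(),
    )


def run_global_mode(
    model: MetabolicModel,
    conditions: list[Condition],
    candidates: ChangeCandidates,
    db: ReactionDatabase | None = None,
    exclusion: ExclusionPolicy | None = None,
    config: MILPConfig | None = None,
    n_alternatives: int = 1,
) -> RunReport:
    """One MILP over all conditions: the globally minimal repair."""
    config = config or MILPConfig()
    inst = assemble_bilevel_milp(model, conditions, candidates, db, exclusion, config)
    logger.info("global mode: %d binaries over %d conditions", inst.n_binaries, len(conditions))
    if n_alternatives > 1:
        solutions = enumerate_alternative_solutions(inst, n_alternatives, config)
    else:
        solutions = [solve_milp(inst, config)]
    best = solutions[0]
    final = apply_change_set(model, best.change_set, db, bigm=config.bigm)
    return _final_report(
        "global",
        final,
        conditions,
        solutions,
        [(tuple(c.id for c in conditions), f"solved, objective {best.objective:g}")],
        best.change_set,
        excluded=set(best.excluded_conditions),
    )


def _merge_change_sets(a: ChangeSet, b: ChangeSet) -> ChangeSet:
    return ChangeSet(
        remove_forward=a.remove_forward | b.remove_forward,
        remove_backward=a.remove_backward | b.remove_backward,
        make_reversible=a.make_reversible | b.make_reversible,
        add_reactions=a.add_reactions | b.add_reactions,
        biomass_remove_substrate=a.biomass_remove_substrate | b.biomass_remove_substrate,
        biomass_remove_product=a.biomass_remove_product | b.biomass_remove_product,
        biomass_add_substrate={**a.biomass_add_substrate, **b.biomass_add_substrate},
        biomass_add_product={**a.biomass_add_product, **b.biomass_add_product},
    )


def _drop_candidates(cand: ChangeCandidates, used: set[BinName]) -> ChangeCandidates:
    """Freeze accepted changes: they are applied to the working model, so
    their binaries leave the candidate universe."""

    def keep(d: dict, kind: str) -> dict:
        return {k: v for k, v in d.items() if (kind, k) not in used}

    return ChangeCandidates(
        removable_forward=keep(cand.removable_forward, "RF"),
        removable_backward=keep(cand.removable_backward, "RB"),
        reversible=keep(cand.reversible, "I"),
        database=keep(cand.database, "ADD"),
        biomass_removable_substrates=keep(cand.biomass_removable_substrates, "RS"),
        biomass_removable_products=keep(cand.biomass_removable_products, "RP"),
        biomass_addable_substrates=keep(cand.biomass_addable_substrates, "AS"),
        biomass_addable_products=keep(cand.biomass_addable_products, "AP"),
        allow_zero_weights=cand.allow_zero_weights,
    )


def run_subset_mode(
    model: MetabolicModel,
    conditions: list[Condition],
    candidates: ChangeCandidates,
    db: ReactionDatabase | None = None,
    config: MILPConfig | None = None,
    max_conflict_rounds: int = 10,
) -> RunReport:
    """Iterative pairwise strategy over the false predictions.

    Deterministic order: false growth predictions first, then false
    non-growth predictions, lexicographic by condition id within each group.
    Every false-growth solve is contrasted with all designated wild-type
    growth cases (one per assayed medium); false non-growth cases are first
    solved alone.  After each tentative acceptance the whole panel is
    re-simulated; if previously correct predictions flipped, the triggering
    case is re-solved jointly with the accumulated conflict set.  Accepted
    changes are frozen into the working model.  Condition exclusion is not
    available in this mode — unresolvable cases are recorded and skipped.
    """
    config = config or MILPConfig()
    current = model
    cand = candidates
    accepted = ChangeSet()
    solutions: list[RepairSolution] = []
    iterations: list[tuple[tuple[str, ...], str]] = []
    unresolved: list[str] = []

    wt_growth = [c for c in conditions if c.is_wild_type and c.observed == GROWTH]

    def predictions(m: MetabolicModel) -> dict[str, str]:
        return {c.id: predict_phenotype(m, c) for c in conditions}

    preds = predictions(current)
    fpp = sorted(
        (c for c in conditions if preds[c.id] == GROWTH and c.observed == NON_GROWTH),
        key=lambda c: c.id,
    )
    fnp = sorted(
        (c for c in conditions if preds[c.id] == NON_GROWTH and c.observed == GROWTH),
        key=lambda c: c.id,
    )

    for case in fpp + fnp:
        if predict_phenotype(current, case) == case.observed:
            iterations.append(((case.id,), "already resolved"))
            continue
        contrast = [c for c in wt_growth if c.id != case.id] if case.observed == NON_GROWTH else []
        conflict: list[Condition] = []
        resolved = False
        for _ in range(max_conflict_rounds + 1):
            subset = [case] + contrast + conflict
            ids = tuple(c.id for c in subset)
            try:
                inst = assemble_bilevel_milp(
                    current, subset, cand, db, ExclusionPolicy(allow_exclusion=False), config
                )
                sol = solve_milp(inst, config)
            except InfeasibleRepairError:
                iterations.append((ids, "infeasible"))
                break
            tentative = apply_change_set(current, sol.change_set, db, bigm=config.bigm)
            new_preds = predictions(tentative)
            newly_false = sorted(
                c.id
                for c in conditions
                if new_preds[c.id] != c.observed and preds[c.id] == c.observed
            )
            if not newly_false:
                current = tentative
                preds = new_preds
                cand = _drop_candidates(cand, set(sol.active_binaries))
                accepted = _merge_change_sets(accepted, sol.change_set)
                solutions.append(sol)
                iterations.append((ids, f"accepted {len(sol.change_set)} change(s)"))
                resolved = True
                break
            iterations.append((ids, f"conflicts with {','.join(newly_false)}; re-solving"))
            known = {c.id for c in conflict}
            conflict += [c for c in conditions if c.id in set(newly_false) - known]
        if not resolved:
            unresolved.append(case.id)

    return _final_report(
        "subset", current, conditions, solutions, iterations, accepted, unresolved=unresolved
    )


def run_simple_mode(
    model: MetabolicModel,
    conditions: list[Condition],
    candidates: ChangeCandidates,
    db: ReactionDatabase | None = None,
    config: MILPConfig | None = None,
) -> tuple[list[Condition], RunReport]:
    """Maximal consistent condition set, ignoring the number of changes.

    All change penalties are zeroed and every condition gets a unit-cost
    exclusion binary, so the optimum excludes the fewest conditions for
    which *some* admissible modified network predicts the rest correctly.
    Returns (feasible conditions, report).
    """
    config = config or MILPConfig()
    free = candidates.with_uniform_weight(0.0)
    exclusion = ExclusionPolicy(allow_exclusion=True, default_weight=1.0)
    inst = assemble_bilevel_milp(model, conditions, free, db, exclusion, config)
    sol = solve_milp(inst, config)
    feasible = [c for c in conditions if c.id not in sol.excluded_conditions]
    final = apply_change_set(model, sol.change_set, db, bigm=config.bigm)
    report = _final_report(
        "simple",
        final,
        conditions,
        [sol],
        [(tuple(c.id for c in conditions), f"excluded {sorted(sol.excluded_conditions)}")],
        sol.change_set,
        excluded=set(sol.excluded_conditions),
    )
    return feasible, report


def apply_isoenzyme_updates(
    model: MetabolicModel,
    homology_table: list[tuple[str, str, float, float]],
    fnp_genes: set[str],
    evalue_cutoff: float = 1e-13,
) -> tuple[MetabolicModel, list[str]]:
    """Add OR-clauses for unannotated isozymes of false-non-growth genes.

    A pair qualifies when both reciprocal e-values fall below the cutoff and
    one member is a false-non-growth gene whose partner is present in the
    genome; the partner is then OR-ed into the GPR of every reaction
    associated with the affected gene.  Returns the updated model and a log
    of the edits (the only place gene-reaction associations are touched —
    the repair MILP itself never rewrites GPRs).
    """
    from .model import gpr_genes

    out = model.copy()
    log: list[str] = []
    model_genes = model.genes
    for gene_a, gene_b, ev_ab, ev_ba in homology_table:
        for gene, partner in ((gene_a, gene_b), (gene_b, gene_a)):
            if gene not in fnp_genes:
                continue
            if max(ev_ab, ev_ba) >= evalue_cutoff:
                continue
            if gene not in model_genes:
                log.append(f"skipped {gene}: not associated with any reaction")
                continue
            for r in out.reactions:
                genes = gpr_genes(r.gpr)
                if gene in genes and partner not in genes:
                    r.gpr = f"({r.gpr}) or {partner}"
                    log.append(f"{r.id}: added isozyme {partner} for {gene}")
    out._index()
    return out, log
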