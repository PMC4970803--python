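"""Seeded toy metabolic networks with planted defects, plus the exhaustive
repair oracle used to validate the MILP.

The generator builds small but biologically shaped networks: one exchange
and transport reaction per nutrient, linear pathways of enzymatic steps with
single-gene, isozyme (OR) and complex (AND) GPRs, and a biomass reaction
consuming each pathway's terminal metabolite (and excreting a byproduct).
``plant_defects`` then corrupts a copy of the truth network in one of five
ways — deleting a reaction, fixing a reversible reaction irreversible,
adding a spurious bypass, dropping a biomass component, or adding a spurious
biomass component — and labels a knockout-panel of conditions by simulating
the *truth* network, so the corrupted network mispredicts some of them.
The inverse repair is recorded and guaranteed to be in the candidate
universe, alongside decoy candidates.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np

from .fba import GROWTH, NON_GROWTH, Condition, max_biomass, optimize_fba, predict_phenotype
from .metrics import ConfusionMatrix
from .milp import BinName, ChangeCandidates
from .model import (
    BIGM,
    BiomassSpec,
    ChangeSet,
    MetabolicModel,
    Metabolite,
    Reaction,
    ReactionDatabase,
    apply_change_set,
)

logger = logging.getLogger(__name__)

DEFAULT_UPTAKE = 10.0
DEFAULT_CUTOFF_FRACTION = 0.05


@dataclass
class PlantedScenario:
    truth_model: MetabolicModel
    corrupted_model: MetabolicModel
    planted_changes: ChangeSet
    conditions: list[Condition]
    candidate_universe: ChangeCandidates
    db: ReactionDatabase
    seed: int = 0

    @property
    def planted_penalty(self) -> float:
        w = self.candidate_universe.weights()
        return sum(w[n] for n in self.planted_changes.as_tuples())

    def false_predictions(self) -> list[str]:
        return [
            c.id
            for c in self.conditions
            if predict_phenotype(self.corrupted_model, c) != c.observed
        ]


def generate_toy_network(
    n_pathways: int = 2,
    depth: int = 3,
    n_isozymes: int = 0,
    seed: int = 0,
    n_complexes: int = 0,
    uptake: float = DEFAULT_UPTAKE,
    with_byproduct: bool = True,
) -> MetabolicModel:
    """A seeded toy network: nutrients → transport → pathways → biomass.

    Each pathway ``p`` is a chain ``n{p}_e → m{p}_0 → … → m{p}_{depth-1}``;
    biomass consumes every terminal metabolite with coefficient drawn from
    {1, 2} and (optionally) produces a byproduct drained by a sink.  The RNG
    places ``n_isozymes`` isozyme (OR) and ``n_complexes`` two-gene complex
    (AND) GPRs on random chain steps.  The wild type grows by construction.
    """
    if min(n_pathways, depth) < 1:
        raise ValueError("n_pathways and depth must be >= 1")
    rng = np.random.default_rng(seed)
    mets: list[Metabolite] = []
    rxns: list[Reaction] = []
    substrates: dict[str, float] = {}

    steps = [(p, d) for p in range(n_pathways) for d in range(depth)]
    n_special = min(len(steps), n_isozymes + n_complexes)
    special = rng.choice(len(steps), size=n_special, replace=False) if n_special else []
    iso_steps = {steps[i] for i in special[:n_isozymes]}
    cpx_steps = {steps[i] for i in special[n_isozymes:]}

    for p in range(n_pathways):
        ext = f"n{p}_e"
        mets.append(Metabolite(ext, "e"))
        rxns.append(Reaction(f"EX_n{p}", {ext: -1.0}, lb=-uptake, ub=BIGM, is_exchange=True))
        prev = ext
        for d in range(depth):
            met = f"m{p}_{d}"
            mets.append(Metabolite(met, "c"))
            if d == 0:
                rxns.append(Reaction(f"T{p}", {prev: -1.0, met: 1.0}, gpr=f"tg{p}"))
            else:
                gene = f"g{p}_{d}"
                if (p, d) in iso_steps:
                    gpr = f"{gene} or iso{p}_{d}"
                elif (p, d) in cpx_steps:
                    gpr = f"{gene} and cx{p}_{d}"
                else:
                    gpr = gene
                rxns.append(Reaction(f"R{p}_{d}", {prev: -1.0, met: 1.0}, gpr=gpr))
            prev = met
        substrates[prev] = float(rng.integers(1, 3))

    products: dict[str, float] = {}
    if with_byproduct:
        mets.append(Metabolite("waste_c", "c"))
        products["waste_c"] = 1.0
        rxns.append(Reaction("SK_waste", {"waste_c": -1.0}, lb=0.0, ub=BIGM, is_exchange=True))

    model = MetabolicModel(
        metabolites=mets,
        reactions=rxns,
        biomass=BiomassSpec(substrates=substrates, products=products),
        id=f"toy_p{n_pathways}_d{depth}_s{seed}",
    )
    res = optimize_fba(model)
    assert res.ok and res.objective > 0, "generated wild type must grow"
    return model


def knockout_panel(
    truth: MetabolicModel,
    cutoff_fraction: float = DEFAULT_CUTOFF_FRACTION,
    genes: list[str] | None = None,
) -> list[Condition]:
    """WT plus one single-gene knockout per gene, labeled from the truth
    network with threshold = cutoff_fraction × truth wild-type optimum."""
    wt_opt = optimize_fba(truth).objective
    thr = cutoff_fraction * wt_opt
    conds = [Condition.make("WT", observed=GROWTH, threshold=thr)]
    for g in sorted(genes if genes is not None else truth.genes):
        cond = Condition.make(f"KO_{g}", {g}, threshold=thr)
        label = predict_phenotype(truth, cond)
        conds.append(
            Condition.make(f"KO_{g}", {g}, observed=label, threshold=thr)
        )
    return conds


def _chain_reactions(model: MetabolicModel) -> list[str]:
    return sorted(
        r.id for r in model.reactions if r.id.startswith("R") and "_" in r.id and r.gpr
    )


def plant_defects(
    model: MetabolicModel,
    defect_spec: dict[str, int],
    seed: int = 0,
    cutoff_fraction: float = DEFAULT_CUTOFF_FRACTION,
    n_decoys: int = 3,
    max_retries: int = 20,
) -> PlantedScenario:
    """Corrupt a truth network and return the full planted scenario.

    ``defect_spec`` counts per category: ``delete_reaction``,
    ``wrongly_irreversible``, ``spurious_reaction``,
    ``missing_biomass_metabolite``, ``spurious_biomass_metabolite``.
    Some categories extend the truth network with the structural motif they
    need (a reversible cross-link between pathway terminals; a side branch
    feeding an extra biomass component) before corrupting it.  Retries with
    fresh random choices until the corrupted network mispredicts at least
    one condition.
    """
    known = {
        "delete_reaction",
        "wrongly_irreversible",
        "spurious_reaction",
        "missing_biomass_metabolite",
        "spurious_biomass_metabolite",
    }
    unknown = set(defect_spec) - known
    if unknown:
        raise ValueError(f"unknown defect categories: {sorted(unknown)}")

    for attempt in range(max_retries):
        rng = np.random.default_rng((seed, attempt))
        try:
            scenario = _plant_once(model, defect_spec, rng, cutoff_fraction, n_decoys, seed)
        except _PlantingImpossible as exc:
            logger.debug("planting attempt %d failed: %s", attempt, exc)
            continue
        if scenario.false_predictions():
            return scenario
    raise RuntimeError(f"could not plant defects {defect_spec} within {max_retries} attempts")


class _PlantingImpossible(Exception):
    pass


def _plant_once(model, defect_spec, rng, cutoff_fraction, n_decoys, seed) -> PlantedScenario:
    truth = model.copy()
    planted = ChangeSet()
    db_rows: list[tuple[str, dict[str, float], str]] = []
    cand = ChangeCandidates()
    pathways = sorted({r.id[1:].split("_")[0] for r in truth.reactions if r.id.startswith("T")})

    # -- motifs that need truth-side structure --------------------------------
    for _ in range(defect_spec.get("wrongly_irreversible", 0)):
        if len(pathways) < 2:
            raise _PlantingImpossible("wrongly_irreversible needs >= 2 pathways")
        p1, p2 = rng.choice(pathways, size=2, replace=False)
        t1, t2 = _terminal(truth, p1), _terminal(truth, p2)
        lid = f"L{p1}{p2}"
        if truth.has_reaction(lid):
            raise _PlantingImpossible("cross-link already present")
        truth.reactions.append(Reaction(lid, {t1: -1.0, t2: 1.0}, lb=-BIGM, ub=BIGM))
        truth._index()
        planted.make_reversible.add(lid)
        cand.reversible[lid] = 1.0

    for _ in range(defect_spec.get("spurious_biomass_metabolite", 0)):
        p = rng.choice(pathways)
        xid = f"x{p}_side"
        if truth.has_reaction(f"SR{p}"):
            raise _PlantingImpossible("side branch already present")
        truth.metabolites.append(Metabolite(xid, "c"))
        truth.reactions.append(
            Reaction(f"SR{p}", {f"m{p}_0": -1.0, xid: 1.0}, gpr=f"sg{p}")
        )
        truth._index()
        planted.biomass_remove_substrate.add(xid)
        cand.biomass_removable_substrates[xid] = 1.0

    corrupted = truth.copy()

    # -- corruption -----------------------------------------------------------
    for lid in planted.make_reversible:
        corrupted.reaction(lid).lb = 0.0
    for xid in planted.biomass_remove_substrate:
        corrupted.biomass.substrates[xid] = 1.0

    chain = _chain_reactions(truth)
    rng.shuffle(chain)
    for _ in range(defect_spec.get("delete_reaction", 0)):
        if not chain:
            raise _PlantingImpossible("no chain reaction left to delete")
        rid = chain.pop()
        rxn = corrupted.reaction(rid)
        db_rows.append((rid, dict(rxn.stoichiometry), rxn.gpr))
        corrupted.reactions = [r for r in corrupted.reactions if r.id != rid]
        corrupted._index()
        planted.add_reactions.add(rid)
        cand.database[rid] = 1.0

    for _ in range(defect_spec.get("spurious_reaction", 0)):
        p = rng.choice(pathways)
        yid = f"Y{p}"
        if corrupted.has_reaction(yid):
            raise _PlantingImpossible("bypass already present")
        corrupted.reactions.append(
            Reaction(yid, {f"m{p}_0": -1.0, _terminal(truth, p): 1.0})
        )
        corrupted._index()
        planted.remove_forward.add(yid)
        cand.removable_forward[yid] = 1.0

    for _ in range(defect_spec.get("missing_biomass_metabolite", 0)):
        removable = sorted(set(corrupted.biomass.substrates) & set(truth.biomass.substrates))
        removable = [m for m in removable if m.startswith("m")]
        if not removable:
            raise _PlantingImpossible("no biomass substrate left to drop")
        met = removable[int(rng.integers(len(removable)))]
        coef = corrupted.biomass.substrates.pop(met)
        planted.biomass_add_substrate[met] = coef
        cand.biomass_addable_substrates[met] = (coef, 1.0)

    # -- decoys ---------------------------------------------------------------
    _add_decoys(corrupted, cand, db_rows, rng, n_decoys)

    db = ReactionDatabase(db_rows)
    conditions = knockout_panel(truth, cutoff_fraction)
    scenario = PlantedScenario(
        truth_model=truth,
        corrupted_model=corrupted,
        planted_changes=planted,
        conditions=conditions,
        candidate_universe=cand,
        db=db,
        seed=seed,
    )
    _check_scenario(scenario)
    return scenario


def _terminal(model: MetabolicModel, p: str) -> str:
    depths = [
        int(m.id.split("_")[1])
        for m in model.metabolites
        if m.id.startswith(f"m{p}_") and m.id.split("_")[1].isdigit()
    ]
    return f"m{p}_{max(depths)}"


def _add_decoys(corrupted, cand: ChangeCandidates, db_rows, rng, n_decoys: int) -> None:
    """Decoy candidates at the same unit weight as the planted repairs.

    Includes at least one *tempting* decoy: removal of a transport reaction,
    which silences any misprediction on its pathway but also starves the
    wild type — exercising the conflict-handling paths.
    """
    transports = sorted(r.id for r in corrupted.reactions if r.id.startswith("T"))
    pool: list[BinName] = [("RF", t) for t in transports]
    pool += [("RF", r) for r in _chain_reactions(corrupted) if r not in cand.removable_forward]
    # guarantee at least one addition decoy in the candidate universe
    pool.insert(1, ("ADD", "DECOY0"))
    existing_db = {rid for rid, _, _ in db_rows}
    mets = [m.id for m in corrupted.metabolites if not m.is_external]
    for i in range(2):
        did = f"DECOY{i}"
        if did in existing_db:
            continue
        a, b = rng.choice(len(mets), size=2, replace=False)
        db_rows.append((did, {mets[a]: -1.0, f"dead{i}_c": 1.0}, ""))
        pool.append(("ADD", did))
    need_mets = {f"dead{i}_c" for i in range(2)} - {m.id for m in corrupted.metabolites}
    for met in sorted(need_mets):
        corrupted.metabolites.append(Metabolite(met, "c"))
    corrupted._index()

    picked = 0
    for kind, target in pool:
        if picked >= n_decoys:
            break
        if kind == "RF" and target not in cand.removable_forward:
            cand.removable_forward[target] = 1.0
            picked += 1
        elif kind == "ADD" and target not in cand.database:
            cand.database[target] = 1.0
            picked += 1


def _check_scenario(s: PlantedScenario) -> None:
    for cond in s.conditions:
        assert predict_phenotype(s.truth_model, cond) == cond.observed, (
            f"truth model does not reproduce {cond.id}"
        )
    repaired = apply_change_set(s.corrupted_model, s.planted_changes, s.db)
    for cond in s.conditions:
        if predict_phenotype(repaired, cond) != cond.observed:
            raise _PlantingImpossible(
                f"planted repair does not reconcile condition {cond.id}"
            )


# ---------------------------------------------------------------------------
# hand-built motif scenarios
# ---------------------------------------------------------------------------

def paired_repair_scenario(cutoff_fraction: float = DEFAULT_CUTOFF_FRACTION) -> PlantedScenario:
    """The remove+add motif where greedy single-change repair must fail.

    A byproduct A of the essential central reaction must be drained at
    steady state.  In reality the only drain is the two-step excretion
    D1 (gene x1) → D2 (gene x2), and the biomass precursor Q is made by
    E (gene x3) → N; so x1, x2, x3 are all essential.  The corrupted model
    lacks N but carries a gene-free two-step shunt Z2→Z1 that both drains A
    and produces Q, so knockouts of x1, x2 and x3 are all predicted viable
    (three false growth predictions).  No single change helps: removing Z1
    or Z2 starves the wild type of Q (each is essential to the corrupted
    network, and removing either blocks the other), and adding N alone
    leaves the shunt draining A.  The unique two-change repair removes Z2
    (or equivalently Z1) *and* adds N.
    """
    mets = [
        Metabolite("s_e", "e"),
        Metabolite("s_c", "c"),
        Metabolite("p_c", "c"),
        Metabolite("a_c", "c"),
        Metabolite("w1_c", "c"),
        Metabolite("w2_c", "c"),
        Metabolite("b_c", "c"),
        Metabolite("b2_c", "c"),
        Metabolite("q_c", "c"),
    ]
    rxns = [
        Reaction("EX_s", {"s_e": -1.0}, lb=-DEFAULT_UPTAKE, ub=BIGM, is_exchange=True),
        Reaction("T", {"s_e": -1.0, "s_c": 1.0}, gpr="tg"),
        Reaction("C", {"s_c": -1.0, "p_c": 1.0, "a_c": 1.0}, gpr="gc"),
        Reaction("D1", {"a_c": -1.0, "w1_c": 1.0}, gpr="x1"),
        Reaction("D2", {"w1_c": -1.0, "w2_c": 1.0}, gpr="x2"),
        Reaction("EX_w2", {"w2_c": -1.0}, lb=0.0, ub=BIGM, is_exchange=True),
        Reaction("E", {"s_c": -1.0, "b2_c": 1.0}, gpr="x3"),
        # the spurious shunt (gene-free, like the original pair of reactions)
        Reaction("Z2", {"s_c": -1.0, "b_c": 1.0}),
        Reaction("Z1", {"a_c": -1.0, "b_c": -1.0, "q_c": 1.0}),
    ]
    biomass = BiomassSpec(substrates={"p_c": 1.0, "q_c": 1.0})
    corrupted = MetabolicModel(
        metabolites=mets, reactions=rxns, biomass=biomass, id="paired_corrupted"
    )
    db = ReactionDatabase(
        [
            ("N", {"b2_c": -1.0, "q_c": 1.0}, ""),
            ("DECOY_PQ", {"p_c": -1.0, "q_c": 1.0}, ""),
        ]
    )
    planted = ChangeSet(remove_forward={"Z2"}, add_reactions={"N"})
    truth = apply_change_set(corrupted, planted, db)
    truth.id = "paired_truth"
    cand = ChangeCandidates(
        removable_forward={"Z1": 1.0, "Z2": 1.0, "D1": 1.0, "E": 1.0},
        database={"N": 1.0, "DECOY_PQ": 1.0},
    )
    conditions = knockout_panel(truth, cutoff_fraction)
    scenario = PlantedScenario(
        truth_model=truth,
        corrupted_model=corrupted,
        planted_changes=planted,
        conditions=conditions,
        candidate_universe=cand,
        db=db,
        seed=0,
    )
    _check_scenario(scenario)
    return scenario


def symmetric_repair_scenario(cutoff_fraction: float = DEFAULT_CUTOFF_FRACTION) -> PlantedScenario:
    """One false growth prediction fixable by either of two equal-weight
    single removals (a gene-free two-step bypass in series)."""
    truth = generate_toy_network(n_pathways=1, depth=3, seed=11)
    corrupted = truth.copy()
    corrupted.metabolites.append(Metabolite("by_c", "c"))
    corrupted.reactions.append(Reaction("B1", {"m0_0": -1.0, "by_c": 1.0}))
    corrupted.reactions.append(Reaction("B2", {"by_c": -1.0, "m0_2": 1.0}))
    corrupted._index()
    planted = ChangeSet(remove_forward={"B1"})
    cand = ChangeCandidates(removable_forward={"B1": 1.0, "B2": 1.0, "T0": 1.0})
    conditions = knockout_panel(truth, cutoff_fraction)
    scenario = PlantedScenario(
        truth_model=truth,
        corrupted_model=corrupted,
        planted_changes=planted,
        conditions=conditions,
        candidate_universe=cand,
        db=ReactionDatabase([]),
        seed=11,
    )
    _check_scenario(scenario)
    return scenario


# ---------------------------------------------------------------------------
# exhaustive oracle
# ---------------------------------------------------------------------------

def brute_force_minimal_repair(
    scenario: PlantedScenario,
    max_cardinality: int = 3,
    tol: float = 1e-6,
) -> tuple[float | None, list[ChangeSet]]:
    """Exhaustively enumerate change subsets and simulate every condition.

    Returns the minimal total penalty over subsets (up to the cardinality
    bound) under which plain FBA reproduces every observed label — growth
    conditions above threshold, non-growth conditions' LP maximum below it —
    together with *all* penalty-optimal change sets.  ``(None, [])`` means
    no repair exists within the bound.  Independent of the MILP: it applies
    each subset to a copy of the corrupted model and re-solves plain LPs.
    """
    names = scenario.candidate_universe.binaries()
    weights = scenario.candidate_universe.weights()
    best: float | None = None
    optima: list[ChangeSet] = []
    for k in range(0, max_cardinality + 1):
        for combo in itertools.combinations(names, k):
            penalty = sum(weights[n] for n in combo)
            if best is not None and penalty > best + tol:
                continue
            cs = scenario.candidate_universe.decode(set(combo))
            try:
                repaired = apply_change_set(scenario.corrupted_model, cs, scenario.db)
            except (ValueError, KeyError):
                continue
            ok = True
            for cond in scenario.conditions:
                v = max_biomass(repaired, cond)
                predicted = GROWTH if v > cond.threshold + tol else NON_GROWTH
                if predicted != cond.observed:
                    ok = False
                    break
            if not ok:
                continue
            if best is None or penalty < best - tol:
                best = penalty
                optima = [cs]
            elif abs(penalty - best) <= tol:
                optima.append(cs)
    return best, optima


def scenario_confusion(model: MetabolicModel, conditions: list[Condition]) -> ConfusionMatrix:
    pairs = [(predict_phenotype(model, c), c.observed) for c in conditions]
    return ConfusionMatrix.from_labels(pairs)
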