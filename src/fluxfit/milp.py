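"""Single-level MILP encoding of the bi-level network-repair problem.

The outer problem chooses binary network modifications (per-direction
reaction removals, reversibility changes, database additions, biomass
composition edits) plus optional per-condition exclusion binaries, and
minimizes their total penalty.  Each growth condition contributes its own
copy of the flux variables with steady state, binary-coupled bounds, and a
biomass threshold row.  Each non-growth condition is an inner LP (maximize
biomass) that must stay below its threshold; instead of solving that inner
problem per binary assignment, its LP dual is embedded: dual feasibility
rows plus a weak-duality *certificate row* bounding the dual objective by
T_h (relaxable by the condition's exclusion binary).  Because the inner LP
is always feasible (the zero flux vector) and bounded (box bounds), a
certificate below T_h exists exactly when the inner maximum is ≤ T_h, so
the encoding is exact.

Bilinear products of change binaries with dual multipliers (the binaries
enter the primal right-hand sides) are linearized by McCormick envelopes
within a dual box; after every solve the box is checked and enlarged if any
multiplier comes close to it.

Binary variables are named by (kind, target) tuples:
``("RF", rid)`` / ``("RB", rid)``  remove forward/backward direction,
``("I", rid)``   make an irreversible reaction reversible,
``("ADD", zid)`` add database reaction,
``("RS", met)`` / ``("RP", met)``  remove biomass substrate/product,
``("AS", met)`` / ``("AP", met)``  add biomass substrate/product,
``("XG", cid)`` / ``("XN", cid)``  exclude a growth / non-growth condition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import scipy.sparse as sp
from scipy.optimize import Bounds, LinearConstraint, milp

from .fba import (
    GROWTH,
    NON_GROWTH,
    Condition,
    effective_bounds,
    find_blocked_reactions,
    max_biomass,
)
from .model import (
    BIGM,
    ChangeSet,
    MetabolicModel,
    ReactionDatabase,
    build_supermodel,
    gpr_is_active,
)

logger = logging.getLogger(__name__)

BinName = tuple[str, str]


@dataclass
class ChangeCandidates:
    """The allowed modification universe with per-change penalties.

    All weights must be strictly positive unless ``allow_zero_weights`` is
    set (used internally by the simple mode, whose objective counts only
    condition exclusions).
    """

    removable_forward: dict[str, float] = field(default_factory=dict)
    removable_backward: dict[str, float] = field(default_factory=dict)
    reversible: dict[str, float] = field(default_factory=dict)
    database: dict[str, float] = field(default_factory=dict)
    biomass_removable_substrates: dict[str, float] = field(default_factory=dict)
    biomass_removable_products: dict[str, float] = field(default_factory=dict)
    biomass_addable_substrates: dict[str, tuple[float, float]] = field(default_factory=dict)
    biomass_addable_products: dict[str, tuple[float, float]] = field(default_factory=dict)
    allow_zero_weights: bool = False

    def __post_init__(self) -> None:
        for name, w in self.weights().items():
            if w < 0 or (w == 0 and not self.allow_zero_weights):
                raise ValueError(f"candidate weight for {name} must be > 0, got {w}")
        for met, (coef, _) in list(self.biomass_addable_substrates.items()) + list(
            self.biomass_addable_products.items()
        ):
            if coef <= 0:
                raise ValueError(f"addable biomass metabolite {met}: coefficient must be > 0")

    def binaries(self) -> list[BinName]:
        out: list[BinName] = []
        out += [("RF", r) for r in sorted(self.removable_forward)]
        out += [("RB", r) for r in sorted(self.removable_backward)]
        out += [("I", r) for r in sorted(self.reversible)]
        out += [("ADD", z) for z in sorted(self.database)]
        out += [("RS", m) for m in sorted(self.biomass_removable_substrates)]
        out += [("RP", m) for m in sorted(self.biomass_removable_products)]
        out += [("AS", m) for m in sorted(self.biomass_addable_substrates)]
        out += [("AP", m) for m in sorted(self.biomass_addable_products)]
        return out

    def weights(self) -> dict[BinName, float]:
        out: dict[BinName, float] = {}
        out.update({("RF", r): w for r, w in self.removable_forward.items()})
        out.update({("RB", r): w for r, w in self.removable_backward.items()})
        out.update({("I", r): w for r, w in self.reversible.items()})
        out.update({("ADD", z): w for z, w in self.database.items()})
        out.update({("RS", m): w for m, w in self.biomass_removable_substrates.items()})
        out.update({("RP", m): w for m, w in self.biomass_removable_products.items()})
        out.update({("AS", m): cw[1] for m, cw in self.biomass_addable_substrates.items()})
        out.update({("AP", m): cw[1] for m, cw in self.biomass_addable_products.items()})
        return out

    @property
    def n_changes(self) -> int:
        return len(self.binaries())

    def with_uniform_weight(self, w: float) -> "ChangeCandidates":
        def rw(d):
            return {k: w for k in d}

        return ChangeCandidates(
            removable_forward=rw(self.removable_forward),
            removable_backward=rw(self.removable_backward),
            reversible=rw(self.reversible),
            database=rw(self.database),
            biomass_removable_substrates=rw(self.biomass_removable_substrates),
            biomass_removable_products=rw(self.biomass_removable_products),
            biomass_addable_substrates={
                m: (c, w) for m, (c, _) in self.biomass_addable_substrates.items()
            },
            biomass_addable_products={
                m: (c, w) for m, (c, _) in self.biomass_addable_products.items()
            },
            allow_zero_weights=(w == 0),
        )

    def decode(self, active: set[BinName]) -> ChangeSet:
        """Turn a set of active change binaries into a ChangeSet."""
        return ChangeSet(
            remove_forward={t for k, t in active if k == "RF"},
            remove_backward={t for k, t in active if k == "RB"},
            make_reversible={t for k, t in active if k == "I"},
            add_reactions={t for k, t in active if k == "ADD"},
            biomass_remove_substrate={t for k, t in active if k == "RS"},
            biomass_remove_product={t for k, t in active if k == "RP"},
            biomass_add_substrate={
                t: self.biomass_addable_substrates[t][0] for k, t in active if k == "AS"
            },
            biomass_add_product={
                t: self.biomass_addable_products[t][0] for k, t in active if k == "AP"
            },
        )

    def encode(self, changes: ChangeSet) -> set[BinName]:
        return set(changes.as_tuples())


@dataclass
class ExclusionPolicy:
    """Whether and at what price conditions may be left unexplained."""

    allow_exclusion: bool = False
    default_weight: float = 1e3
    weights: dict[str, float] = field(default_factory=dict)

    def weight(self, cid: str) -> float:
        w = self.weights.get(cid, self.default_weight)
        if w <= 0:
            raise ValueError(f"exclusion weight for {cid} must be > 0")
        return w


@dataclass
class MILPConfig:
    bigm: float = BIGM
    dual_bound: float = 1e4
    feasibility_tol: float = 1e-7
    verify_tol: float = 1e-5
    tie_break_eps: float = 1e-6
    #: tiny penalty on dual multipliers: keeps certificates near-minimal so
    #: the post-solve dual-box check only fires when the box truly binds
    dual_obj_eps: float = 1e-9
    max_changes: int | None = None
    time_limit: float | None = None
    seed: int = 0
    verify: bool = True
    max_dual_box_retries: int = 3


@dataclass
class RepairSolution:
    change_set: ChangeSet
    excluded_conditions: set[str]
    objective: float
    per_condition_biomass: dict[str, float]
    per_condition_predicted: dict[str, str]
    status: str  # optimal | feasible | infeasible
    active_binaries: frozenset[BinName] = frozenset()

    @property
    def ok(self) -> bool:
        return self.status in ("optimal", "feasible")


class InfeasibleRepairError(RuntimeError):
    def __init__(self, condition_ids: list[str]):
        super().__init__(
            "no admissible repair reconciles the conditions "
            f"{condition_ids} (exclusion disallowed or over-constrained)"
        )
        self.condition_ids = condition_ids


# ---------------------------------------------------------------------------
# candidate enumeration with preprocessing reductions
# ---------------------------------------------------------------------------

@dataclass
class CandidatePolicy:
    """Selects the modification universe and its penalties."""

    allow_removal: bool = True
    allow_reversal: bool = True
    allow_addition: bool = True
    allow_biomass_removal: bool = False
    allow_biomass_addition: bool = False
    removal_weight: float = 1.0
    reversal_weight: float = 1.0
    addition_weight: float = 1.0
    biomass_removal_weight: float = 1.0
    biomass_addition_weight: float = 1.0
    #: lower penalty for removing exchange reactions (undefined-medium runs)
    exchange_removal_weight: float | None = None
    addable_substrates: dict[str, float] = field(default_factory=dict)
    addable_products: dict[str, float] = field(default_factory=dict)
    per_change_weights: dict[BinName, float] = field(default_factory=dict)
    removable_ids: set[str] | None = None
    reversible_ids: set[str] | None = None
    database_ids: set[str] | None = None
    preprocess: bool = True


def enumerate_change_candidates(
    model: MetabolicModel,
    db: ReactionDatabase | None,
    policy: CandidatePolicy,
    conditions: list[Condition] | None = None,
    bigm: float = BIGM,
) -> ChangeCandidates:
    """Build the candidate universe, then prune it with supermodel screens.

    Pruning (when ``policy.preprocess``): directions blocked in the
    supermodel lose their removal/reversal/addition binaries (they can never
    carry flux anywhere in the search space), and removal binaries of
    directions essential to some growth condition even in the supermodel are
    fixed to zero (no admissible network can do without them).
    """

    def w_for(kind: str, target: str, default: float) -> float:
        return policy.per_change_weights.get((kind, target), default)

    rf: dict[str, float] = {}
    rb: dict[str, float] = {}
    if policy.allow_removal:
        for r in model.reactions:
            if policy.removable_ids is not None and r.id not in policy.removable_ids:
                continue
            base = (
                policy.exchange_removal_weight
                if (r.is_exchange and policy.exchange_removal_weight is not None)
                else policy.removal_weight
            )
            if r.ub > 0:
                rf[r.id] = w_for("RF", r.id, base)
            if r.lb < 0:
                rb[r.id] = w_for("RB", r.id, base)

    rev: dict[str, float] = {}
    if policy.allow_reversal:
        for r in model.reactions:
            if policy.reversible_ids is not None and r.id not in policy.reversible_ids:
                continue
            if r.lb >= 0 and not r.is_exchange:
                rev[r.id] = w_for("I", r.id, policy.reversal_weight)

    add: dict[str, float] = {}
    if policy.allow_addition and db is not None:
        for zid in db.ids():
            if policy.database_ids is not None and zid not in policy.database_ids:
                continue
            add[zid] = w_for("ADD", zid, policy.addition_weight)

    brs: dict[str, float] = {}
    brp: dict[str, float] = {}
    if policy.allow_biomass_removal:
        brs = {m: w_for("RS", m, policy.biomass_removal_weight) for m in model.biomass.substrates}
        brp = {m: w_for("RP", m, policy.biomass_removal_weight) for m in model.biomass.products}

    bas: dict[str, tuple[float, float]] = {}
    bap: dict[str, tuple[float, float]] = {}
    if policy.allow_biomass_addition:
        bas = {
            m: (c, w_for("AS", m, policy.biomass_addition_weight))
            for m, c in policy.addable_substrates.items()
            if m not in model.biomass.substrates
        }
        bap = {
            m: (c, w_for("AP", m, policy.biomass_addition_weight))
            for m, c in policy.addable_products.items()
            if m not in model.biomass.products
        }

    if policy.preprocess:
        supermodel = build_supermodel(
            model, db, reversible_candidates=set(rev), db_candidates=set(add), bigm=bigm
        )
        blocked = find_blocked_reactions(supermodel, open_exchanges=True)
        rf = {r: w for r, w in rf.items() if (r, "forward") not in blocked}
        rb = {r: w for r, w in rb.items() if (r, "backward") not in blocked}
        rev = {r: w for r, w in rev.items() if (r, "backward") not in blocked}
        add = {z: w for z, w in add.items() if (supermodel.has_reaction(z)) and (z, "forward") not in blocked}

        growth_conds = [c for c in (conditions or []) if c.observed == GROWTH]
        if growth_conds:
            rf = {r: w for r, w in rf.items() if not _direction_essential(supermodel, r, "forward", growth_conds)}
            rb = {r: w for r, w in rb.items() if not _direction_essential(supermodel, r, "backward", growth_conds)}

    return ChangeCandidates(
        removable_forward=rf,
        removable_backward=rb,
        reversible=rev,
        database=add,
        biomass_removable_substrates=brs,
        biomass_removable_products=brp,
        biomass_addable_substrates=bas,
        biomass_addable_products=bap,
    )


def _direction_essential(
    supermodel: MetabolicModel, rid: str, direction: str, growth_conds: list[Condition]
) -> bool:
    from .fba import _solve_lp

    for cond in growth_conds:
        bounds = effective_bounds(supermodel, cond)
        lb, ub = bounds[rid]
        bounds[rid] = (lb, 0.0) if direction == "forward" else (max(lb, 0.0), ub)
        res = _solve_lp(supermodel, bounds, {supermodel.biomass_reaction_id: 1.0})
        if not res.ok or res.objective < cond.threshold - 1e-9:
            return True
    return False


# ---------------------------------------------------------------------------
# instance assembly
# ---------------------------------------------------------------------------

class MILPInstance:
    """A sparse MILP: variables, rows, and metadata needed to decode."""

    def __init__(
        self,
        model: MetabolicModel,
        conditions: list[Condition],
        candidates: ChangeCandidates,
        db: ReactionDatabase | None,
        exclusion: ExclusionPolicy,
        config: MILPConfig,
    ):
        self.model = model
        self.conditions = conditions
        self.candidates = candidates
        self.db = db
        self.exclusion = exclusion
        self.config = config
        self.var_names: list = []
        self.var_index: dict = {}
        self.lo: list[float] = []
        self.hi: list[float] = []
        self.integrality: list[int] = []
        self.obj: list[float] = []
        self.rows: list[tuple[list[tuple[int, float]], float, float]] = []
        self.change_binaries: list[BinName] = []
        self.exclusion_binaries: list[BinName] = []
        self.dual_var_indices: list[int] = []
        #: (row1_idx, row3_idx, delta_idx) per McCormick product, for box rescaling
        self.mccormick: list[tuple[int, int, int]] = []

    # -- construction helpers ---------------------------------------------
    def add_var(self, name, lo: float, hi: float, integral: bool = False, obj: float = 0.0) -> int:
        idx = len(self.var_names)
        self.var_names.append(name)
        self.var_index[name] = idx
        self.lo.append(lo)
        self.hi.append(hi)
        self.integrality.append(1 if integral else 0)
        self.obj.append(obj)
        return idx

    def add_row(self, coeffs: dict, lb: float, ub: float) -> None:
        self.rows.append(([(self.var_index[n], c) for n, c in coeffs.items() if c != 0.0], lb, ub))

    @property
    def n_binaries(self) -> int:
        return len(self.change_binaries) + len(self.exclusion_binaries)

    def fix_binary(self, name: BinName, value: int) -> None:
        idx = self.var_index[name]
        self.lo[idx] = self.hi[idx] = float(value)

    def copy(self) -> "MILPInstance":
        import copy as _copy

        new = MILPInstance(
            self.model, self.conditions, self.candidates, self.db, self.exclusion, self.config
        )
        new.var_names = list(self.var_names)
        new.var_index = dict(self.var_index)
        new.lo = list(self.lo)
        new.hi = list(self.hi)
        new.integrality = list(self.integrality)
        new.obj = list(self.obj)
        new.rows = [(list(r), lb, ub) for r, lb, ub in self.rows]
        new.change_binaries = list(self.change_binaries)
        new.exclusion_binaries = list(self.exclusion_binaries)
        new.dual_var_indices = list(self.dual_var_indices)
        new.mccormick = list(self.mccormick)
        return new

    def add_integer_cut(self, active: set[BinName]) -> None:
        """No-good cut excluding one exact assignment of the change binaries."""
        coeffs = {}
        rhs = 1.0
        for name in self.change_binaries:
            if name in active:
                coeffs[name] = -1.0
                rhs -= 1.0
            else:
                coeffs[name] = 1.0
        self.add_row(coeffs, rhs, np.inf)


def _primal_system(
    model: MetabolicModel,
    cond: Condition,
    candidates: ChangeCandidates,
    db: ReactionDatabase | None,
    bigm: float,
    clamp_nonneg: bool = False,
):
    """The condition's inner LP in the canonical form used on both paths.

    Returns (xvars, obj, eqrows, ineqrows) where every inequality row is
    ``sum(coeffs·x) ≤ b0 + sum(bins·δ)``.  Knockouts and the medium are
    folded into the base bounds; change binaries appear only in the
    right-hand sides.  The biomass column is expanded: fixed biomass
    metabolites enter the mass balance directly, while each editable biomass
    metabolite gets an auxiliary drain flux u tied to v_Bio by four rows
    that pin u = c·(1−δ)·v_Bio (removals) or u = c·δ·v_Bio (additions).
    """
    xvars: list = []
    boxes: dict = {}
    obj: dict = {}
    eqcontrib: dict[str, dict] = {m: {} for m in model.internal_metabolite_ids}
    ineq: list[tuple[dict, float, dict]] = []

    bounds = effective_bounds(model, cond)
    ko = set(cond.knockout_genes)

    for r in model.reactions:
        xv = ("v", r.id)
        xvars.append(xv)
        boxes[xv] = (-bigm, bigm)
        lb0, ub0 = bounds[r.id]
        if clamp_nonneg:
            # the inner maximization requires the zero flux vector feasible:
            # strictly positive lower bounds (e.g. maintenance demands) are
            # relaxed to 0 for non-growth conditions
            if lb0 > 0 or ub0 < 0:
                logger.debug("condition %s: clamping bounds of %s to include 0", cond.id, r.id)
            lb0, ub0 = min(lb0, 0.0), max(ub0, 0.0)
        for met, coef in r.stoichiometry.items():
            if met in eqcontrib:
                eqcontrib[met][xv] = eqcontrib[met].get(xv, 0.0) + coef
        knocked = lb0 == 0.0 and ub0 == 0.0 and r.gpr and not gpr_is_active(r.gpr, ko)
        # upper bound row
        ub_bins: dict[BinName, float] = {}
        if not knocked and ub0 > 0 and r.id in candidates.removable_forward:
            ub_bins[("RF", r.id)] = -ub0
        ineq.append(({xv: 1.0}, ub0, ub_bins))
        # lower bound row, written as −v ≤ −lb(δ)
        lb_bins: dict[BinName, float] = {}
        if not knocked:
            if lb0 < 0 and r.id in candidates.removable_backward:
                lb_bins[("RB", r.id)] = -lb0  # δ^RB=1 lifts −v ≤ −lb0 to −v ≤ 0
            if lb0 >= 0 and r.id in candidates.reversible:
                lb_bins[("I", r.id)] = bigm  # δ^I=1 relaxes to −v ≤ bigm
        ineq.append(({xv: -1.0}, -lb0, lb_bins))

    if db is not None:
        for zid in sorted(candidates.database):
            _, stoich, gpr = db.entry(zid)
            xv = ("vdb", zid)
            xvars.append(xv)
            boxes[xv] = (0.0, bigm)
            for met, coef in stoich.items():
                if met in eqcontrib:
                    eqcontrib[met][xv] = eqcontrib[met].get(xv, 0.0) + coef
            active = gpr_is_active(gpr, ko)
            ineq.append(({xv: 1.0}, 0.0, {("ADD", zid): bigm} if active else {}))
            ineq.append(({xv: -1.0}, 0.0, {}))

    bio = ("bio",)
    xvars.append(bio)
    boxes[bio] = (0.0, bigm)
    obj[bio] = 1.0
    ineq.append(({bio: 1.0}, bigm, {}))
    ineq.append(({bio: -1.0}, 0.0, {}))

    bm = model.biomass
    fixed_sub = {m: c for m, c in bm.substrates.items() if m not in candidates.biomass_removable_substrates}
    fixed_prod = {m: c for m, c in bm.products.items() if m not in candidates.biomass_removable_products}
    for met, coef in fixed_sub.items():
        if met in eqcontrib:
            eqcontrib[met][bio] = eqcontrib[met].get(bio, 0.0) - coef
    for met, coef in fixed_prod.items():
        if met in eqcontrib:
            eqcontrib[met][bio] = eqcontrib[met].get(bio, 0.0) + coef

    def add_aux(kind: str, met: str, coef: float, delta: BinName, sign: float, removal: bool):
        xv = ("u", kind, met)
        xvars.append(xv)
        boxes[xv] = (0.0, coef * bigm)
        if met in eqcontrib:
            eqcontrib[met][xv] = eqcontrib[met].get(xv, 0.0) + sign
        cb = coef * bigm
        if removal:  # u = c·(1−δ)·v_Bio
            ineq.append(({xv: 1.0, bio: -coef}, 0.0, {}))
            ineq.append(({xv: -1.0, bio: coef}, 0.0, {delta: cb}))
            ineq.append(({xv: 1.0}, cb, {delta: -cb}))
        else:  # u = c·δ·v_Bio
            ineq.append(({xv: 1.0, bio: -coef}, 0.0, {}))
            ineq.append(({xv: 1.0}, 0.0, {delta: cb}))
            ineq.append(({xv: -1.0, bio: coef}, cb, {delta: -cb}))
        ineq.append(({xv: -1.0}, 0.0, {}))

    for met in sorted(candidates.biomass_removable_substrates):
        add_aux("RS", met, bm.substrates[met], ("RS", met), -1.0, removal=True)
    for met in sorted(candidates.biomass_removable_products):
        add_aux("RP", met, bm.products[met], ("RP", met), +1.0, removal=True)
    for met, (coef, _) in sorted(candidates.biomass_addable_substrates.items()):
        add_aux("AS", met, coef, ("AS", met), -1.0, removal=False)
    for met, (coef, _) in sorted(candidates.biomass_addable_products.items()):
        add_aux("AP", met, coef, ("AP", met), +1.0, removal=False)

    eqrows = [contrib for contrib in eqcontrib.values() if contrib]
    return xvars, boxes, obj, eqrows, ineq


def assemble_bilevel_milp(
    model: MetabolicModel,
    conditions: list[Condition],
    candidates: ChangeCandidates,
    db: ReactionDatabase | None = None,
    exclusion: ExclusionPolicy | None = None,
    config: MILPConfig | None = None,
) -> MILPInstance:
    """Build the full single-level MILP over all conditions.

    Free binary count is (number of candidate changes) + (number of
    excludable conditions).
    """
    if not conditions:
        raise ValueError("at least one condition is required")
    exclusion = exclusion or ExclusionPolicy()
    config = config or MILPConfig()
    inst = MILPInstance(model, conditions, candidates, db, exclusion, config)
    bigm = config.bigm
    weights = candidates.weights()

    for i, name in enumerate(candidates.binaries()):
        w = weights[name] + config.tie_break_eps * (i + 1)
        inst.add_var(name, 0.0, 1.0, integral=True, obj=w)
        inst.change_binaries.append(name)

    for cond in conditions:
        if exclusion.allow_exclusion:
            kind = "XG" if cond.observed == GROWTH else "XN"
            name = (kind, cond.id)
            inst.add_var(name, 0.0, 1.0, integral=True, obj=exclusion.weight(cond.id))
            inst.exclusion_binaries.append(name)

    if config.max_changes is not None:
        inst.add_row({n: 1.0 for n in inst.change_binaries}, -np.inf, float(config.max_changes))

    for cond in conditions:
        is_growth = cond.observed == GROWTH
        xvars, boxes, obj, eqrows, ineq = _primal_system(
            model, cond, candidates, db, bigm, clamp_nonneg=not is_growth
        )
        if is_growth:
            _emit_growth(inst, cond, xvars, boxes, eqrows, ineq, bigm)
        else:
            _emit_non_growth(inst, cond, xvars, obj, eqrows, ineq, bigm)
    return inst


def _emit_growth(inst: MILPInstance, cond: Condition, xvars, boxes, eqrows, ineq, bigm: float) -> None:
    """Primal flux copy with binary-coupled bounds plus the threshold row."""
    c = cond.id
    for xv in xvars:
        lo, hi = boxes[xv]
        inst.add_var(("x", c) + xv, lo, hi)
    for row in eqrows:
        inst.add_row({("x", c) + xv: coef for xv, coef in row.items()}, 0.0, 0.0)
    for coeffs, b0, bins in ineq:
        merged = {("x", c) + xv: coef for xv, coef in coeffs.items()}
        for bname, bcoef in bins.items():
            merged[bname] = merged.get(bname, 0.0) - bcoef
        inst.add_row(merged, -np.inf, b0)
    thr = {("x", c, "bio"): 1.0}
    if inst.exclusion.allow_exclusion:
        thr[("XG", c)] = bigm
    inst.add_row(thr, cond.threshold, np.inf)


def _emit_non_growth(inst: MILPInstance, cond: Condition, xvars, obj, eqrows, ineq, bigm: float) -> None:
    """Dual certificate block for a non-growth condition.

    Dual feasibility (one equality per primal variable) plus the weak-duality
    bound row; products δ·μ are McCormick-linearized in [0, dual_bound].
    """
    c = cond.id
    U = inst.config.dual_bound
    eps = inst.config.dual_obj_eps
    for i in range(len(eqrows)):
        idx = inst.add_var(("lam", c, i), -U, U)
        inst.dual_var_indices.append(idx)
    for r in range(len(ineq)):
        idx = inst.add_var(("mu", c, r), 0.0, U, obj=eps)
        inst.dual_var_indices.append(idx)

    products: list[tuple[int, BinName]] = []
    for r, (_, _, bins) in enumerate(ineq):
        for bname in bins:
            inst.add_var(("p", c, r, bname), 0.0, U, obj=eps)
            products.append((r, bname))

    # dual feasibility: E^T λ + A^T μ = c_obj
    cols: dict = {xv: {} for xv in xvars}
    for i, row in enumerate(eqrows):
        for xv, coef in row.items():
            cols[xv][("lam", c, i)] = coef
    for r, (coeffs, _, _) in enumerate(ineq):
        for xv, coef in coeffs.items():
            cols[xv][("mu", c, r)] = cols[xv].get(("mu", c, r), 0.0) + coef
    for xv in xvars:
        inst.add_row(cols[xv], obj.get(xv, 0.0), obj.get(xv, 0.0))

    # certificate row: Σ b0_r μ_r + Σ B_{r,δ} p_{r,δ} ≤ T_h + bigm·δ^N
    cert: dict = {}
    for r, (_, b0, bins) in enumerate(ineq):
        if b0 != 0.0:
            cert[("mu", c, r)] = cert.get(("mu", c, r), 0.0) + b0
        for bname, bcoef in bins.items():
            cert[("p", c, r, bname)] = cert.get(("p", c, r, bname), 0.0) + bcoef
    if inst.exclusion.allow_exclusion:
        cert[("XN", c)] = -bigm
    inst.add_row(cert, -np.inf, cond.threshold)

    # McCormick rows pinning p = δ·μ
    for r, bname in products:
        p = ("p", c, r, bname)
        mu = ("mu", c, r)
        row1 = len(inst.rows)
        inst.add_row({p: 1.0, bname: -U}, -np.inf, 0.0)
        inst.add_row({p: 1.0, mu: -1.0}, -np.inf, 0.0)
        row3 = len(inst.rows)
        inst.add_row({p: -1.0, mu: 1.0, bname: U}, -np.inf, U)
        inst.mccormick.append((row1, row3, inst.var_index[bname]))


# ---------------------------------------------------------------------------
# solving
# ---------------------------------------------------------------------------

def _scipy_solve(inst: MILPInstance):
    n = len(inst.var_names)
    c = np.array(inst.obj)
    integrality = np.array(inst.integrality)
    bounds = Bounds(np.array(inst.lo), np.array(inst.hi))
    data, ri, ci, lbs, ubs = [], [], [], [], []
    for k, (coeffs, lb, ub) in enumerate(inst.rows):
        for j, v in coeffs:
            data.append(v)
            ri.append(k)
            ci.append(j)
        lbs.append(lb)
        ubs.append(ub)
    A = sp.csr_matrix((data, (ri, ci)), shape=(len(inst.rows), n))
    options = {"mip_rel_gap": 0.0}
    if inst.config.time_limit is not None:
        options["time_limit"] = inst.config.time_limit
    return milp(
        c,
        constraints=LinearConstraint(A, np.array(lbs), np.array(ubs)),
        integrality=integrality,
        bounds=bounds,
        options=options,
    )


def solve_milp(inst: MILPInstance, config: MILPConfig | None = None) -> RepairSolution:
    """Solve the assembled instance and decode + verify the repair.

    The reported objective is recomputed exactly as the weight sum over
    active binaries (tie-break epsilons stripped).  After each solve the
    dual box is checked: if any dual multiplier lies within 1% of the box,
    the box is enlarged tenfold and the instance re-solved, so big-M
    correctness is certified rather than assumed.  Finally the change set is
    applied to the model and every condition is re-simulated by plain FBA;
    a mismatch with the claimed phenotypes raises.
    """
    config = config or inst.config
    work = inst
    weights = inst.candidates.weights()

    def true_objective(x) -> float:
        act = [n for n in work.change_binaries if x[work.var_index[n]] > 0.5]
        exc = [n for n in work.exclusion_binaries if x[work.var_index[n]] > 0.5]
        return sum(weights[n] for n in act) + sum(inst.exclusion.weight(n[1]) for n in exc)

    prev_obj: float | None = None
    for attempt in range(config.max_dual_box_retries + 1):
        res = _scipy_solve(work)
        if res.status == 2:
            raise InfeasibleRepairError([c.id for c in inst.conditions])
        if res.x is None:
            raise RuntimeError(f"MILP solver failed with status {res.status}: {res.message}")
        if not _dual_box_tight(work, res.x):
            break
        # A dual at its box can only ever force *over*-repair (a feasible
        # certificate within any box remains valid by weak duality), so the
        # decisive test is whether the repair cost survives a tenfold box
        # enlargement unchanged.
        obj_now = true_objective(res.x)
        if prev_obj is not None and abs(obj_now - prev_obj) <= 1e-9:
            logger.debug("dual box contact but objective stable under enlargement; accepting")
            break
        if prev_obj is not None:
            logger.warning(
                "objective changed from %g to %g after dual box enlargement; enlarging again",
                prev_obj,
                obj_now,
            )
        else:
            logger.info("dual variable near box bound; enlarging dual box and re-solving")
        prev_obj = obj_now
        work = work.copy()
        work.config = replace(work.config, dual_bound=work.config.dual_bound * 10)
        _rescale_dual_box(work)
    status = "optimal" if res.status == 0 else "feasible"

    active = {
        name
        for name in work.change_binaries
        if res.x[work.var_index[name]] > 0.5
    }
    excluded = {
        name[1]
        for name in work.exclusion_binaries
        if res.x[work.var_index[name]] > 0.5
    }
    change_set = inst.candidates.decode(active)
    weights = inst.candidates.weights()
    objective = sum(weights[n] for n in active) + sum(
        inst.exclusion.weight(cid) for cid in excluded
    )

    per_biomass: dict[str, float] = {}
    per_pred: dict[str, str] = {}
    if config.verify:
        per_biomass, per_pred = verify_solution(
            inst.model, inst.conditions, change_set, excluded, inst.db, config
        )
    return RepairSolution(
        change_set=change_set,
        excluded_conditions=excluded,
        objective=objective,
        per_condition_biomass=per_biomass,
        per_condition_predicted=per_pred,
        status=status,
        active_binaries=frozenset(active),
    )


def _dual_box_tight(inst: MILPInstance, x: np.ndarray, margin: float = 0.01) -> bool:
    """Check whether any bound multiplier μ sits near its box.

    Only the sign-constrained multipliers are checked: they carry the
    certificate objective and are kept near-minimal by ``dual_obj_eps``, so
    a value at the box means the box genuinely binds.  The free equality
    multipliers are degenerate (any constant shift along the nullspace is
    optimal) and may park at the box harmlessly.
    """
    U = inst.config.dual_bound
    for idx in inst.dual_var_indices:
        if inst.var_names[idx][0] == "lam":
            continue
        if abs(x[idx]) > (1 - margin) * U:
            return True
    return False


def _rescale_dual_box(inst: MILPInstance) -> None:
    """Widen dual variable boxes and McCormick rows to the new dual bound."""
    U = inst.config.dual_bound
    for idx in inst.dual_var_indices:
        name = inst.var_names[idx]
        if name[0] == "lam":
            inst.lo[idx], inst.hi[idx] = -U, U
        else:
            inst.lo[idx], inst.hi[idx] = 0.0, U
    for j, name in enumerate(inst.var_names):
        if isinstance(name, tuple) and name[0] == "p":
            inst.hi[j] = U
    for row1, row3, delta_idx in inst.mccormick:
        coeffs1, lb1, _ub1 = inst.rows[row1]
        inst.rows[row1] = ([(j, -U if j == delta_idx else v) for j, v in coeffs1], lb1, 0.0)
        coeffs3, lb3, _ub3 = inst.rows[row3]
        inst.rows[row3] = ([(j, U if j == delta_idx else v) for j, v in coeffs3], lb3, U)


def verify_solution(
    model: MetabolicModel,
    conditions: list[Condition],
    change_set: ChangeSet,
    excluded: set[str],
    db: ReactionDatabase | None,
    config: MILPConfig,
) -> tuple[dict[str, float], dict[str, str]]:
    """Independent soundness check: apply the repair, re-run plain FBA.

    Non-excluded growth conditions must reach their threshold; non-excluded
    non-growth conditions' independently maximized biomass must stay below
    theirs.  Raises on violation — this catches any big-M or duality defect.
    """
    from .model import apply_change_set

    repaired = apply_change_set(model, change_set, db, bigm=config.bigm)
    per_biomass: dict[str, float] = {}
    per_pred: dict[str, str] = {}
    tol = config.verify_tol
    for cond in conditions:
        v = max_biomass(repaired, cond)
        per_biomass[cond.id] = v
        per_pred[cond.id] = GROWTH if v > cond.threshold + 1e-6 else NON_GROWTH
        if cond.id in excluded:
            continue
        if cond.observed == GROWTH and v < cond.threshold - tol:
            raise RuntimeError(
                f"verification failed: growth condition {cond.id} reaches only {v:.6g} "
                f"< threshold {cond.threshold:.6g} after repair"
            )
        if cond.observed == NON_GROWTH and v > cond.threshold + tol:
            raise RuntimeError(
                f"verification failed: non-growth condition {cond.id} reaches {v:.6g} "
                f"> threshold {cond.threshold:.6g} after repair"
            )
    return per_biomass, per_pred


def enumerate_alternative_solutions(
    inst: MILPInstance, k: int, config: MILPConfig | None = None
) -> list[RepairSolution]:
    """Best-first enumeration of repairs via integer cuts.

    After each solve a no-good cut over the change binaries (condition
    exclusions are not cut) removes that exact change set; objectives are
    nondecreasing.  Returns fewer than ``k`` solutions when the cut pool
    exhausts the feasible assignments.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    config = config or inst.config
    work = inst.copy()
    out: list[RepairSolution] = []
    for _ in range(k):
        try:
            sol = solve_milp(work, config)
        except InfeasibleRepairError:
            logger.info("alternative enumeration exhausted after %d solutions", len(out))
            break
        out.append(sol)
        work.add_integer_cut(set(sol.active_binaries))
    return out


# ---------------------------------------------------------------------------
# certificate/inner-LP equivalence helper (also used by tests)
# ---------------------------------------------------------------------------

def certificate_exists(
    model: MetabolicModel,
    cond: Condition,
    candidates: ChangeCandidates,
    active: set[BinName],
    db: ReactionDatabase | None = None,
    config: MILPConfig | None = None,
) -> bool:
    """Does a dual non-growth certificate exist for this binary assignment?

    Builds the dual block for the single non-growth condition, fixes every
    change binary to the given assignment, and tests MILP feasibility.
    """
    config = config or MILPConfig(verify=False)
    inst = assemble_bilevel_milp(
        model, [cond], candidates, db=db, exclusion=ExclusionPolicy(False), config=config
    )
    for name in inst.change_binaries:
        inst.fix_binary(name, 1 if name in active else 0)
    res = _scipy_solve(inst)
    return res.status != 2
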