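"""Flux balance analysis, knockout simulation and preprocessing screens.

FBA is the inner workhorse everywhere: maximize the biomass flux v_Bio
subject to steady state (S·v = 0 over internal metabolites) and flux bounds.
A *condition* bundles one experiment: the knocked-out genes, the medium
(exchange-bound overrides), the observed growth/non-growth label, and the
viability threshold the prediction is judged against.

LPs are solved with scipy's HiGHS interface, which is deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linprog

from .model import BIGM, MetabolicModel, gpr_is_active

logger = logging.getLogger(__name__)

#: numerical tolerance used for growth classification and blocked screens
TOL = 1e-6

GROWTH = "growth"
NON_GROWTH = "non-growth"


@dataclass(frozen=True)
class Condition:
    """One growth or non-growth experiment."""

    id: str
    knockout_genes: frozenset[str] = frozenset()
    medium: tuple[tuple[str, float, float], ...] = ()
    observed: str = GROWTH
    threshold: float = TOL
    medium_id: str = ""

    def __post_init__(self) -> None:
        if self.observed not in (GROWTH, NON_GROWTH):
            raise ValueError(f"observed must be growth/non-growth, got {self.observed!r}")
        if self.threshold <= 0:
            raise ValueError("threshold must be > 0")

    @staticmethod
    def make(
        cid: str,
        knockout_genes: set[str] | frozenset[str] = frozenset(),
        medium: dict[str, tuple[float, float]] | None = None,
        observed: str = GROWTH,
        threshold: float = TOL,
        medium_id: str = "",
    ) -> "Condition":
        med = tuple(sorted((k, lb, ub) for k, (lb, ub) in (medium or {}).items()))
        return Condition(cid, frozenset(knockout_genes), med, observed, threshold, medium_id)

    @property
    def medium_dict(self) -> dict[str, tuple[float, float]]:
        return {rid: (lb, ub) for rid, lb, ub in self.medium}

    @property
    def is_wild_type(self) -> bool:
        return not self.knockout_genes


@dataclass
class FBAResult:
    objective: float
    fluxes: dict[str, float]
    status: str  # optimal | infeasible | unbounded | error

    @property
    def ok(self) -> bool:
        return self.status == "optimal"


def effective_bounds(model: MetabolicModel, condition: Condition | None) -> dict[str, tuple[float, float]]:
    """Per-reaction bounds with the condition's medium and knockouts applied.

    Medium overrides must reference exchange reactions; reactions whose GPR
    evaluates false under the knockout set are clamped to zero flux.
    """
    bounds = {r.id: (r.lb, r.ub) for r in model.reactions}
    if condition is None:
        return bounds
    for rid, (lb, ub) in condition.medium_dict.items():
        if not model.has_reaction(rid):
            raise KeyError(f"medium override references unknown reaction {rid}")
        if not model.reaction(rid).is_exchange:
            raise ValueError(f"medium override {rid} is not an exchange reaction")
        bounds[rid] = (lb, ub)
    if condition.knockout_genes:
        known = model.genes
        unknown = set(condition.knockout_genes) - known
        if unknown:
            logger.warning(
                "condition %s: knockout genes %s not in any GPR", condition.id, sorted(unknown)
            )
        for r in model.reactions:
            if r.gpr and not gpr_is_active(r.gpr, set(condition.knockout_genes)):
                bounds[r.id] = (0.0, 0.0)
    return bounds


def _solve_lp(
    model: MetabolicModel,
    bounds: dict[str, tuple[float, float]],
    objective: dict[str, float],
    maximize: bool = True,
    biomass_bounds: tuple[float, float] = (0.0, BIGM),
) -> FBAResult:
    """Solve max/min cᵀv s.t. S·v = 0 and the given box bounds.

    The variable vector is [reactions..., v_Bio]; ``objective`` maps reaction
    ids (or the biomass reaction id) to objective coefficients.
    """
    S = model.stoichiometric_matrix(include_biomass=True)
    n = len(model.reactions) + 1
    col = {r.id: j for j, r in enumerate(model.reactions)}
    col[model.biomass_reaction_id] = n - 1
    c = np.zeros(n)
    for rid, coef in objective.items():
        c[col[rid]] = coef
    if maximize:
        c = -c
    lo = np.empty(n)
    hi = np.empty(n)
    for r in model.reactions:
        lo[col[r.id]], hi[col[r.id]] = bounds[r.id]
    lo[n - 1], hi[n - 1] = biomass_bounds
    res = linprog(
        c,
        A_eq=S,
        b_eq=np.zeros(S.shape[0]),
        bounds=np.column_stack([lo, hi]),
        method="highs",
    )
    if res.status == 0:
        fluxes = {rid: float(res.x[j]) for rid, j in col.items()}
        obj = float(-res.fun if maximize else res.fun)
        return FBAResult(objective=obj, fluxes=fluxes, status="optimal")
    status = {2: "infeasible", 3: "unbounded"}.get(res.status, "error")
    logger.warning("LP for model %s finished with status %s", model.id, status)
    return FBAResult(objective=float("nan"), fluxes={}, status=status)


def optimize_fba(model: MetabolicModel, condition: Condition | None = None) -> FBAResult:
    """Maximize biomass flux under the condition's medium (no knockouts)."""
    if condition is not None and condition.knockout_genes:
        return simulate_knockout_condition(model, condition)
    bounds = effective_bounds(model, condition)
    return _solve_lp(model, bounds, {model.biomass_reaction_id: 1.0})


def simulate_knockout_condition(model: MetabolicModel, condition: Condition) -> FBAResult:
    """FBA after clamping all GPR-disabled reactions to zero flux."""
    bounds = effective_bounds(model, condition)
    return _solve_lp(model, bounds, {model.biomass_reaction_id: 1.0})


def classify_growth(result: FBAResult, threshold: float, tol: float = TOL) -> str:
    """Growth iff the optimum strictly exceeds the viability threshold.

    A value exactly at the threshold counts as non-growth (strict-inequality
    convention, guarding against trickle flow); non-optimal solver statuses
    are classified as non-growth with a logged reason.
    """
    if not result.ok:
        logger.info("non-optimal FBA status %s classified as non-growth", result.status)
        return NON_GROWTH
    return GROWTH if result.objective > threshold + tol else NON_GROWTH


def predict_phenotype(model: MetabolicModel, condition: Condition, tol: float = TOL) -> str:
    return classify_growth(simulate_knockout_condition(model, condition), condition.threshold, tol)


def open_all_exchanges(model: MetabolicModel, uptake: float = BIGM) -> MetabolicModel:
    """Copy of the model with every exchange lower bound opened to −uptake.

    Models the chemically undefined medium case: every nutrient with a
    transporter in the model is allowed to be taken up.
    """
    out = model.copy()
    for r in out.reactions:
        if r.is_exchange:
            r.lb = min(r.lb, -uptake)
    return out


def find_blocked_reactions(
    model: MetabolicModel,
    open_exchanges: bool = True,
    tol: float = TOL,
) -> set[tuple[str, str]]:
    """Reaction directions that can never carry flux at steady state.

    Returns ``(reaction_id, "forward"|"backward")`` pairs: a forward
    direction is blocked when max v < tol, a backward direction when
    min v > −tol (flux-variability screen, two LPs per reaction, no
    heuristics).  Only directions the bounds actually allow are reported.
    """
    work = open_all_exchanges(model) if open_exchanges else model
    bounds = effective_bounds(work, None)
    blocked: set[tuple[str, str]] = set()
    for r in work.reactions:
        lb, ub = bounds[r.id]
        if ub > tol:
            res = _solve_lp(work, bounds, {r.id: 1.0}, maximize=True)
            if not res.ok or res.objective < tol:
                blocked.add((r.id, "forward"))
        if lb < -tol:
            res = _solve_lp(work, bounds, {r.id: 1.0}, maximize=False)
            if not res.ok or res.objective > -tol:
                blocked.add((r.id, "backward"))
    return blocked


def find_essential_reactions(
    model: MetabolicModel,
    conditions_G: list[Condition],
    tol: float = TOL,
) -> set[str]:
    """Reactions whose removal drops some growth condition below threshold."""
    essential: set[str] = set()
    for r in model.reactions:
        for cond in conditions_G:
            if cond.observed != GROWTH:
                continue
            bounds = effective_bounds(model, cond)
            bounds[r.id] = (0.0, 0.0)
            res = _solve_lp(model, bounds, {model.biomass_reaction_id: 1.0})
            if not res.ok or res.objective < cond.threshold - tol:
                essential.add(r.id)
                break
    return essential


def max_biomass(model: MetabolicModel, condition: Condition) -> float:
    """Maximal biomass flux for a condition; 0.0 when the LP is not optimal."""
    res = simulate_knockout_condition(model, condition)
    return res.objective if res.ok else 0.0
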