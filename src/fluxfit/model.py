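"""Core in-memory representation of constraint-based metabolic models.

A :class:`MetabolicModel` holds the stoichiometric matrix implicitly as a list
of :class:`Reaction` objects, plus a structured biomass specification
(:class:`BiomassSpec`) that keeps biomass substrates and products addressable
individually — the repair machinery edits the biomass composition metabolite
by metabolite, so the biomass pseudo-reaction is not stored as an ordinary
stoichiometry column.

Sign convention: negative stoichiometric coefficients consume a metabolite,
positive coefficients produce it.  Fluxes are in mmol·gDW⁻¹·h⁻¹.
"""

from __future__ import annotations

import copy
import logging
import re
from dataclasses import dataclass, field, replace

import numpy as np
import scipy.sparse as sp

logger = logging.getLogger(__name__)

#: default "effectively unbounded" flux magnitude
BIGM = 1000.0


class EquationParseError(ValueError):
    """Raised when a reaction-equation string cannot be parsed."""


@dataclass(frozen=True)
class Metabolite:
    id: str
    compartment: str = ""
    is_external: bool = False


@dataclass
class Reaction:
    """A reaction column: stoichiometry plus flux bounds and a GPR string.

    ``gpr`` is a boolean expression over gene identifiers using ``and`` /
    ``or`` / parentheses; the empty string means the reaction is not gene
    associated and survives every knockout.
    """

    id: str
    stoichiometry: dict[str, float]
    lb: float = 0.0
    ub: float = BIGM
    gpr: str = ""
    is_exchange: bool = False

    def __post_init__(self) -> None:
        if self.lb > self.ub + 1e-12:
            raise ValueError(f"reaction {self.id}: lb {self.lb} > ub {self.ub}")

    @property
    def reversible(self) -> bool:
        return self.lb < 0

    def copy(self) -> "Reaction":
        return replace(self, stoichiometry=dict(self.stoichiometry))


@dataclass
class BiomassSpec:
    """Biomass composition: positive coefficients on both sides.

    ``substrates[m] = c`` means the biomass reaction consumes ``c`` units of
    metabolite ``m`` per unit of biomass flux; ``products[m] = c`` means it
    produces ``c`` units (e.g. ADP, uncharged tRNAs).
    """

    substrates: dict[str, float] = field(default_factory=dict)
    products: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for side_name, side in (("substrate", self.substrates), ("product", self.products)):
            for met, coef in side.items():
                if coef <= 0:
                    raise ValueError(
                        f"biomass {side_name} {met}: coefficient must be > 0, got {coef}"
                    )
        overlap = set(self.substrates) & set(self.products)
        if overlap:
            raise ValueError(f"metabolites on both biomass sides: {sorted(overlap)}")

    def copy(self) -> "BiomassSpec":
        return BiomassSpec(dict(self.substrates), dict(self.products))

    def net_stoichiometry(self) -> dict[str, float]:
        """Signed stoichiometry of the biomass column (substrates negative)."""
        out = {m: -c for m, c in self.substrates.items()}
        out.update(self.products)
        return out


@dataclass
class MetabolicModel:
    metabolites: list[Metabolite]
    reactions: list[Reaction]
    biomass: BiomassSpec
    biomass_reaction_id: str = "Biomass"
    id: str = "model"

    def __post_init__(self) -> None:
        self._index()

    def _index(self) -> None:
        self._met_by_id = {m.id: m for m in self.metabolites}
        if len(self._met_by_id) != len(self.metabolites):
            raise ValueError("duplicate metabolite ids")
        self._rxn_by_id = {r.id: r for r in self.reactions}
        if len(self._rxn_by_id) != len(self.reactions):
            raise ValueError("duplicate reaction ids")
        if self.biomass_reaction_id in self._rxn_by_id:
            raise ValueError("biomass reaction must not appear in model.reactions")
        for r in self.reactions:
            missing = set(r.stoichiometry) - set(self._met_by_id)
            if missing:
                raise ValueError(f"reaction {r.id} references unknown metabolites {sorted(missing)}")
        for m in list(self.biomass.substrates) + list(self.biomass.products):
            if m not in self._met_by_id:
                raise ValueError(f"biomass references unknown metabolite {m}")

    # -- lookups -----------------------------------------------------------
    def metabolite(self, met_id: str) -> Metabolite:
        return self._met_by_id[met_id]

    def reaction(self, rxn_id: str) -> Reaction:
        return self._rxn_by_id[rxn_id]

    def has_reaction(self, rxn_id: str) -> bool:
        return rxn_id in self._rxn_by_id

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    @property
    def internal_metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites if not m.is_external]

    @property
    def genes(self) -> set[str]:
        out: set[str] = set()
        for r in self.reactions:
            out |= gpr_genes(r.gpr)
        return out

    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            metabolites=list(self.metabolites),
            reactions=[r.copy() for r in self.reactions],
            biomass=self.biomass.copy(),
            biomass_reaction_id=self.biomass_reaction_id,
            id=self.id,
        )

    def stoichiometric_matrix(self, include_biomass: bool = True):
        """Sparse S over internal metabolites; columns ordered as
        ``self.reactions`` (+ biomass column last when requested)."""
        rows = {m: i for i, m in enumerate(self.internal_metabolite_ids)}
        data, ri, ci = [], [], []
        cols = list(self.reactions)
        for j, r in enumerate(cols):
            for met, coef in r.stoichiometry.items():
                if met in rows:
                    data.append(coef)
                    ri.append(rows[met])
                    ci.append(j)
        ncols = len(cols) + (1 if include_biomass else 0)
        if include_biomass:
            j = len(cols)
            for met, coef in self.biomass.net_stoichiometry().items():
                if met in rows:
                    data.append(coef)
                    ri.append(rows[met])
                    ci.append(j)
        return sp.csr_matrix((data, (ri, ci)), shape=(len(rows), ncols))


@dataclass
class ReactionDatabase:
    """Candidate reactions for gap filling, all oriented forward (flux ≥ 0).

    Reversible source reactions are stored as two irreversible entries with
    ``_f`` / ``_b`` suffixes (the backward entry has negated stoichiometry).
    """

    entries: list[tuple[str, dict[str, float], str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [e[0] for e in self.entries]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate reaction ids in database")
        self._by_id = {e[0]: e for e in self.entries}

    def __len__(self) -> int:
        return len(self.entries)

    def ids(self) -> list[str]:
        return [e[0] for e in self.entries]

    def entry(self, rid: str) -> tuple[str, dict[str, float], str]:
        return self._by_id[rid]

    @staticmethod
    def from_equations(rows: list[tuple[str, str, str]]) -> "ReactionDatabase":
        """Build from (id, equation, gpr) rows, splitting reversible ones."""
        entries: list[tuple[str, dict[str, float], str]] = []
        for rid, eq, gpr in rows:
            stoich, reversible = parse_reaction_equation(eq)
            if reversible:
                entries.append((rid + "_f", dict(stoich), gpr))
                entries.append((rid + "_b", {m: -c for m, c in stoich.items()}, gpr))
            else:
                entries.append((rid, stoich, gpr))
        return ReactionDatabase(entries)


@dataclass
class ChangeSet:
    """A concrete set of network modifications (the decoded repair binaries)."""

    remove_forward: set[str] = field(default_factory=set)
    remove_backward: set[str] = field(default_factory=set)
    make_reversible: set[str] = field(default_factory=set)
    add_reactions: set[str] = field(default_factory=set)
    biomass_remove_substrate: set[str] = field(default_factory=set)
    biomass_remove_product: set[str] = field(default_factory=set)
    biomass_add_substrate: dict[str, float] = field(default_factory=dict)
    biomass_add_product: dict[str, float] = field(default_factory=dict)

    def __len__(self) -> int:
        return (
            len(self.remove_forward)
            + len(self.remove_backward)
            + len(self.make_reversible)
            + len(self.add_reactions)
            + len(self.biomass_remove_substrate)
            + len(self.biomass_remove_product)
            + len(self.biomass_add_substrate)
            + len(self.biomass_add_product)
        )

    def as_tuples(self) -> tuple[tuple[str, str], ...]:
        """Canonical hashable identity: sorted (kind, target) pairs."""
        items: list[tuple[str, str]] = []
        items += [("RF", r) for r in self.remove_forward]
        items += [("RB", r) for r in self.remove_backward]
        items += [("I", r) for r in self.make_reversible]
        items += [("ADD", r) for r in self.add_reactions]
        items += [("RS", m) for m in self.biomass_remove_substrate]
        items += [("RP", m) for m in self.biomass_remove_product]
        items += [("AS", m) for m in self.biomass_add_substrate]
        items += [("AP", m) for m in self.biomass_add_product]
        return tuple(sorted(items))

    def describe(self) -> list[str]:
        return [f"{kind}\t{target}" for kind, target in self.as_tuples()]


# ---------------------------------------------------------------------------
# reaction-equation parsing
# ---------------------------------------------------------------------------

_ARROWS = ("<=>", "<->", "-->", "->")
_NUM_RE = re.compile(r"^[+-]?(\d+\.?\d*|\.\d+)([eE][+-]?\d+)?$")


def _parse_side(text: str, side_name: str) -> dict[str, float]:
    stoich: dict[str, float] = {}
    text = text.strip()
    if not text:
        return stoich
    for term in text.split("+"):
        tokens = term.split()
        if not tokens:
            raise EquationParseError(f"empty term on {side_name} side")
        if len(tokens) == 1:
            coef, met = 1.0, tokens[0]
        elif len(tokens) == 2:
            if not _NUM_RE.match(tokens[0]):
                raise EquationParseError(f"non-numeric coefficient {tokens[0]!r}")
            coef, met = float(tokens[0]), tokens[1]
        else:
            raise EquationParseError(f"malformed term {term.strip()!r}")
        if met in stoich:
            raise EquationParseError(f"duplicate metabolite {met!r} on {side_name} side")
        stoich[met] = coef
    return stoich


def parse_reaction_equation(text: str) -> tuple[dict[str, float], bool]:
    """Parse ``coef met[comp] + ... <arrow> ...`` into signed stoichiometry.

    Substrates get negative coefficients, products positive; ``<=>`` (or
    ``<->``) marks the reaction reversible, ``->`` irreversible.  Omitted
    coefficients default to 1; either side may be empty (pure import/export).
    Compartment suffixes ``[c]`` and ``(c)`` are both accepted verbatim.
    """
    arrow = None
    for a in _ARROWS:
        if a in text:
            arrow = a
            break
    if arrow is None:
        raise EquationParseError(f"no reaction arrow found in {text!r}")
    left, _, right = text.partition(arrow)
    if arrow in left or arrow in right:
        raise EquationParseError(f"multiple arrows in {text!r}")
    reversible = arrow in ("<=>", "<->")
    lhs = _parse_side(left, "substrate")
    rhs = _parse_side(right, "product")
    dup = set(lhs) & set(rhs)
    if dup:
        raise EquationParseError(f"metabolite on both sides: {sorted(dup)}")
    if not lhs and not rhs:
        raise EquationParseError("equation has no metabolites")
    stoich = {m: -c for m, c in lhs.items()}
    stoich.update(rhs)
    return stoich, reversible


def format_reaction_equation(stoich: dict[str, float], reversible: bool) -> str:
    """Inverse of :func:`parse_reaction_equation` (canonical spacing)."""

    def fmt(coef: float, met: str) -> str:
        return met if coef == 1 else f"{coef:g} {met}"

    lhs = " + ".join(fmt(-c, m) for m, c in sorted(stoich.items()) if c < 0)
    rhs = " + ".join(fmt(c, m) for m, c in sorted(stoich.items()) if c > 0)
    arrow = "<=>" if reversible else "->"
    return f"{lhs} {arrow} {rhs}".strip()


# ---------------------------------------------------------------------------
# GPR helpers (parsing/evaluation delegated to COBRApy)
# ---------------------------------------------------------------------------

def _cobra_gpr(gpr: str):
    from cobra.core.gene import GPR

    return GPR.from_string(gpr)


def gpr_genes(gpr: str) -> set[str]:
    if not gpr.strip():
        return set()
    return set(_cobra_gpr(gpr).genes)


def gpr_is_active(gpr: str, knocked_out: set[str]) -> bool:
    """True when the boolean gene expression survives the knockout set.

    An empty GPR is always active (the reaction has no gene requirement).
    """
    if not gpr.strip():
        return True
    return bool(_cobra_gpr(gpr).eval(knockouts=knocked_out))


# ---------------------------------------------------------------------------
# applying repairs and building the preprocessing supermodel
# ---------------------------------------------------------------------------

def apply_change_set(
    model: MetabolicModel,
    changes: ChangeSet,
    db: ReactionDatabase | None = None,
    bigm: float = BIGM,
) -> MetabolicModel:
    """Return a new model with the given modifications applied.

    Semantics mirror the binary-to-bound coupling of the repair MILP:
    forward removal sets ub←0, backward removal sets lb←0, a reversibility
    change sets lb←−bigm on an irreversible reaction, database additions are
    appended with bounds [0, bigm], and biomass edits rewrite the
    :class:`BiomassSpec`.  The input model is left untouched.
    """
    bad = (set(changes.biomass_remove_substrate) & set(changes.biomass_add_substrate)) | (
        set(changes.biomass_remove_product) & set(changes.biomass_add_product)
    )
    if bad:
        raise ValueError(f"metabolite both removed from and added to a biomass side: {sorted(bad)}")

    out = model.copy()
    rxns = {r.id: r for r in out.reactions}

    for rid in sorted(changes.remove_forward):
        if rid not in rxns:
            raise KeyError(f"remove_forward: unknown reaction {rid}")
        r = rxns[rid]
        r.ub = 0.0
        r.lb = min(r.lb, 0.0)
    for rid in sorted(changes.remove_backward):
        if rid not in rxns:
            raise KeyError(f"remove_backward: unknown reaction {rid}")
        r = rxns[rid]
        r.lb = 0.0
        r.ub = max(r.ub, 0.0)
    for rid in sorted(changes.make_reversible):
        if rid not in rxns:
            raise KeyError(f"make_reversible: unknown reaction {rid}")
        r = rxns[rid]
        if r.lb < 0 and rid not in changes.remove_backward:
            raise ValueError(f"make_reversible: reaction {rid} is already reversible")
        r.lb = -bigm
    for rid in sorted(changes.add_reactions):
        if db is None:
            raise ValueError("add_reactions requested but no database given")
        if rid in rxns:
            raise ValueError(f"add_reactions: id {rid} already in model")
        _, stoich, gpr = db.entry(rid)
        new_mets = set(stoich) - {m.id for m in out.metabolites}
        for met in sorted(new_mets):
            out.metabolites.append(Metabolite(id=met, compartment=_compartment_of(met)))
        out.reactions.append(Reaction(id=rid, stoichiometry=dict(stoich), lb=0.0, ub=bigm, gpr=gpr))

    bm = out.biomass
    for met in sorted(changes.biomass_remove_substrate):
        if met not in bm.substrates:
            raise KeyError(f"biomass_remove_substrate: {met} is not a biomass substrate")
        del bm.substrates[met]
    for met in sorted(changes.biomass_remove_product):
        if met not in bm.products:
            raise KeyError(f"biomass_remove_product: {met} is not a biomass product")
        del bm.products[met]
    for met, coef in sorted(changes.biomass_add_substrate.items()):
        if met in bm.substrates:
            raise ValueError(f"biomass_add_substrate: {met} already a substrate")
        bm.substrates[met] = coef
    for met, coef in sorted(changes.biomass_add_product.items()):
        if met in bm.products:
            raise ValueError(f"biomass_add_product: {met} already a product")
        bm.products[met] = coef

    out._index()
    return out


def _compartment_of(met_id: str) -> str:
    m = re.search(r"[\[(]([^\])]+)[\])]$", met_id)
    return m.group(1) if m else ""


def build_supermodel(
    model: MetabolicModel,
    db: ReactionDatabase | None = None,
    reversible_candidates: set[str] | None = None,
    db_candidates: set[str] | None = None,
    bigm: float = BIGM,
) -> MetabolicModel:
    """Union model used only for blocked/essential preprocessing screens.

    Every reversibility candidate is made reversible and every database
    candidate is appended.  ID collisions with the database are resolved by
    suffixing ``_db`` (logged, never silent).
    """
    out = model.copy()
    out.id = model.id + "_super"
    rxn_ids = set(out.reaction_ids)
    for rid in sorted(reversible_candidates or set()):
        r = out.reaction(rid)
        if r.lb >= 0:
            r.lb = -bigm
    if db is not None:
        wanted = db.ids() if db_candidates is None else [i for i in db.ids() if i in db_candidates]
        for rid in wanted:
            _, stoich, gpr = db.entry(rid)
            use_id = rid
            if use_id in rxn_ids:
                use_id = rid + "_db"
                logger.warning("database id %s collides with model; renamed to %s", rid, use_id)
            rxn_ids.add(use_id)
            new_mets = set(stoich) - {m.id for m in out.metabolites}
            for met in sorted(new_mets):
                out.metabolites.append(Metabolite(id=met, compartment=_compartment_of(met)))
            out.reactions.append(
                Reaction(id=use_id, stoichiometry=dict(stoich), lb=0.0, ub=bigm, gpr=gpr)
            )
    out._index()
    return out
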