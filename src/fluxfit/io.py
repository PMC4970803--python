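"""File formats: SBML models, reaction-database / experiment / media /
homology tables, and plain-text repair reports.

SBML reading and writing is delegated to COBRApy (Level 3 + fbc on write;
Level 2 and Level 3 on read).  The tabular formats are tab-separated text:

* reaction database — 3 columns: reaction id, stoichiometric equation, GPR;
* experiments — condition_id, genes (semicolon-joined, empty = wild type),
  medium_id, observed {growth, non-growth}, threshold (optional);
* media — medium_id, exchange_id, lb, ub;
* homology — gene_a, gene_b, evalue_ab, evalue_ba.
"""

from __future__ import annotations

import csv
import logging
from pathlib import Path

from .fba import GROWTH, NON_GROWTH, Condition, optimize_fba
from .model import (
    BIGM,
    BiomassSpec,
    ChangeSet,
    MetabolicModel,
    Metabolite,
    Reaction,
    ReactionDatabase,
)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# SBML via COBRApy
# ---------------------------------------------------------------------------

def _looks_like_exchange(rxn_id: str, stoich: dict[str, float]) -> bool:
    # single-metabolite topology wins; the EX_ prefix is the fallback
    if len(stoich) == 1:
        return True
    return rxn_id.startswith("EX_")


def to_cobra(model: MetabolicModel):
    """Convert to a cobra.Model (biomass appended with objective 1)."""
    import cobra

    cm = cobra.Model(model.id)
    mets = {
        m.id: cobra.Metabolite(m.id, compartment=m.compartment or "c")
        for m in model.metabolites
    }
    cm.add_metabolites(list(mets.values()))
    rxns = []
    for r in model.reactions:
        cr = cobra.Reaction(r.id, lower_bound=r.lb, upper_bound=r.ub)
        rxns.append((cr, r))
    bio = cobra.Reaction(model.biomass_reaction_id, lower_bound=0.0, upper_bound=BIGM)
    cm.add_reactions([cr for cr, _ in rxns] + [bio])
    for cr, r in rxns:
        cr.add_metabolites({mets[m]: c for m, c in r.stoichiometry.items()})
        if r.gpr:
            cr.gene_reaction_rule = r.gpr
    bio.add_metabolites({mets[m]: c for m, c in model.biomass.net_stoichiometry().items()})
    cm.objective = bio
    return cm


def from_cobra(cm, biomass_reaction_id: str | None = None) -> MetabolicModel:
    """Convert a cobra.Model; the biomass reaction is found by objective
    coefficient unless named explicitly."""
    from cobra.util.solver import linear_reaction_coefficients

    if biomass_reaction_id is None:
        coeffs = linear_reaction_coefficients(cm)
        if not coeffs:
            raise ValueError(f"model {cm.id}: no objective reaction found; pass biomass_reaction_id")
        biomass_reaction_id = max(coeffs, key=lambda r: abs(coeffs[r])).id
    if biomass_reaction_id not in cm.reactions:
        raise ValueError(f"biomass reaction {biomass_reaction_id!r} not in model")
    bio = cm.reactions.get_by_id(biomass_reaction_id)

    metabolites = [
        Metabolite(id=m.id, compartment=m.compartment or "", is_external=False)
        for m in cm.metabolites
    ]
    reactions = []
    for r in cm.reactions:
        if r.id == biomass_reaction_id:
            continue
        stoich = {m.id: float(c) for m, c in r.metabolites.items()}
        try:
            gpr = r.gene_reaction_rule or ""
        except Exception:  # pragma: no cover - defensive
            logger.warning("unreadable GPR on %s; treated as empty", r.id)
            gpr = ""
        reactions.append(
            Reaction(
                id=r.id,
                stoichiometry=stoich,
                lb=float(r.lower_bound),
                ub=float(r.upper_bound),
                gpr=gpr,
                is_exchange=_looks_like_exchange(r.id, stoich),
            )
        )
    substrates = {m.id: -float(c) for m, c in bio.metabolites.items() if c < 0}
    products = {m.id: float(c) for m, c in bio.metabolites.items() if c > 0}
    return MetabolicModel(
        metabolites=metabolites,
        reactions=reactions,
        biomass=BiomassSpec(substrates=substrates, products=products),
        biomass_reaction_id=biomass_reaction_id,
        id=cm.id or "model",
    )


def read_sbml_model(path: str | Path, biomass_reaction_id: str | None = None) -> MetabolicModel:
    import cobra.io

    cm = cobra.io.read_sbml_model(str(path))
    return from_cobra(cm, biomass_reaction_id)


def write_sbml_model(model: MetabolicModel, path: str | Path) -> None:
    import cobra.io

    cobra.io.write_sbml_model(to_cobra(model), str(path))


# ---------------------------------------------------------------------------
# tabular formats
# ---------------------------------------------------------------------------

def _read_tsv(path: str | Path, ncols: int, what: str) -> list[list[str]]:
    rows = []
    with open(path, newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if row[0].lstrip().startswith("#"):
                continue
            if len(row) != ncols:
                raise ValueError(
                    f"{what} {path}: line {lineno}: expected {ncols} columns, got {len(row)}"
                )
            rows.append([c.strip() for c in row])
    return rows


def read_reaction_database(path: str | Path) -> ReactionDatabase:
    """Read the 3-column candidate-reaction table; reversible equations are
    split into ``_f``/``_b`` irreversible entries."""
    rows = _read_tsv(path, 3, "reaction database")
    if rows and rows[0][0].lower() in ("id", "reaction_id", "reaction id"):
        rows = rows[1:]
    return ReactionDatabase.from_equations([(r[0], r[1], r[2]) for r in rows])


def write_reaction_database_rows(rows: list[tuple[str, str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rid, eq, gpr in rows:
            fh.write(f"{rid}\t{eq}\t{gpr}\n")


def read_media(path: str | Path) -> dict[str, dict[str, tuple[float, float]]]:
    out: dict[str, dict[str, tuple[float, float]]] = {}
    rows = _read_tsv(path, 4, "media table")
    if rows and rows[0][0].lower() == "medium_id":
        rows = rows[1:]
    for mid, exch, lb, ub in rows:
        out.setdefault(mid, {})[exch] = (float(lb), float(ub))
    return out


def read_experiments(
    path: str | Path,
    model: MetabolicModel | None = None,
    media: dict[str, dict[str, tuple[float, float]]] | None = None,
    cutoff_fraction: float = 0.05,
) -> list[Condition]:
    """Read the experiment table into Conditions.

    A missing threshold column value is computed as ``cutoff_fraction`` times
    the wild-type optimum of ``model`` on that condition's medium (the usual
    viability-cutoff construction); this requires ``model``.
    """
    rows = _read_tsv(path, 5, "experiment table")
    if rows and rows[0][0].lower() == "condition_id":
        rows = rows[1:]
    media = media or {}
    wt_opt_cache: dict[str, float] = {}

    def wt_optimum(mid: str) -> float:
        if mid not in wt_opt_cache:
            if model is None:
                raise ValueError("threshold column empty and no model given to compute it")
            cond = Condition.make("__wt__", medium=media.get(mid, {}), observed=GROWTH,
                                  threshold=1e-6, medium_id=mid)
            res = optimize_fba(model, cond)
            if not res.ok or res.objective <= 0:
                raise ValueError(f"wild type does not grow on medium {mid!r}; cannot derive threshold")
            wt_opt_cache[mid] = res.objective
        return wt_opt_cache[mid]

    out = []
    for cid, genes, mid, observed, thr in rows:
        observed = observed.strip().lower().replace("_", "-")
        if observed not in (GROWTH, NON_GROWTH):
            raise ValueError(f"condition {cid}: observed must be growth/non-growth")
        knockouts = {g for g in genes.split(";") if g.strip()} if genes else set()
        threshold = float(thr) if thr else cutoff_fraction * wt_optimum(mid)
        out.append(
            Condition.make(
                cid,
                knockouts,
                medium=media.get(mid, {}),
                observed=observed,
                threshold=threshold,
                medium_id=mid,
            )
        )
    return out


def write_experiments(conditions: list[Condition], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("condition_id\tgenes\tmedium_id\tobserved\tthreshold\n")
        for c in conditions:
            genes = ";".join(sorted(c.knockout_genes))
            fh.write(f"{c.id}\t{genes}\t{c.medium_id}\t{c.observed}\t{c.threshold:.10g}\n")


def read_homology_table(path: str | Path) -> list[tuple[str, str, float, float]]:
    rows = _read_tsv(path, 4, "homology table")
    if rows and rows[0][0].lower() == "gene_a":
        rows = rows[1:]
    return [(a, b, float(eab), float(eba)) for a, b, eab, eba in rows]


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------

def format_change_report(changes: ChangeSet, weights: dict[tuple[str, str], float] | None = None) -> str:
    """One change per line: type, target, penalty — for human review."""
    kind_names = {
        "RF": "remove_forward",
        "RB": "remove_backward",
        "I": "make_reversible",
        "ADD": "add_reaction",
        "RS": "biomass_remove_substrate",
        "RP": "biomass_remove_product",
        "AS": "biomass_add_substrate",
        "AP": "biomass_add_product",
    }
    lines = []
    for kind, target in changes.as_tuples():
        w = "" if weights is None else f"\t{weights.get((kind, target), float('nan')):g}"
        lines.append(f"{kind_names[kind]}\t{target}{w}")
    return "\n".join(lines) + ("\n" if lines else "")


def parse_change_report(text: str, coefficients: dict[str, float] | None = None) -> ChangeSet:
    """Inverse of :func:`format_change_report` (penalty column ignored).

    ``coefficients`` supplies stoichiometric coefficients for biomass
    additions (default 1.0).
    """
    coefficients = coefficients or {}
    cs = ChangeSet()
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        kind, target = parts[0], parts[1]
        if kind == "remove_forward":
            cs.remove_forward.add(target)
        elif kind == "remove_backward":
            cs.remove_backward.add(target)
        elif kind == "make_reversible":
            cs.make_reversible.add(target)
        elif kind == "add_reaction":
            cs.add_reactions.add(target)
        elif kind == "biomass_remove_substrate":
            cs.biomass_remove_substrate.add(target)
        elif kind == "biomass_remove_product":
            cs.biomass_remove_product.add(target)
        elif kind == "biomass_add_substrate":
            cs.biomass_add_substrate[target] = coefficients.get(target, 1.0)
        elif kind == "biomass_add_product":
            cs.biomass_add_product[target] = coefficients.get(target, 1.0)
        else:
            raise ValueError(f"unknown change type {kind!r}")
    return cs
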