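"""Domain types: equation parsing, change application, supermodel, GPRs."""

import pytest

from fluxfit import (
    BiomassSpec,
    ChangeSet,
    MetabolicModel,
    Metabolite,
    Reaction,
    ReactionDatabase,
    apply_change_set,
    build_supermodel,
    format_reaction_equation,
    parse_reaction_equation,
)
from fluxfit.model import EquationParseError, gpr_genes, gpr_is_active


class TestEquationParser:
    def test_simple_irreversible(self):
        stoich, rev = parse_reaction_equation("2 a + b -> c")
        assert stoich == {"a": -2.0, "b": -1.0, "c": 1.0}
        assert rev is False

    @pytest.mark.parametrize("arrow", ["<=>", "<->"])
    def test_reversible_arrows(self, arrow):
        _, rev = parse_reaction_equation(f"a {arrow} b")
        assert rev is True

    @pytest.mark.parametrize("arrow", ["->", "-->"])
    def test_irreversible_arrows(self, arrow):
        _, rev = parse_reaction_equation(f"a {arrow} b")
        assert rev is False

    def test_fractional_coefficients(self):
        stoich, _ = parse_reaction_equation("0.5 a -> 1.5 b")
        assert stoich == {"a": -0.5, "b": 1.5}

    def test_empty_product_side(self):
        stoich, _ = parse_reaction_equation("a ->")
        assert stoich == {"a": -1.0}

    def test_no_arrow_raises(self):
        with pytest.raises(EquationParseError):
            parse_reaction_equation("a + b")

    def test_bad_coefficient_raises(self):
        with pytest.raises(EquationParseError):
            parse_reaction_equation("two a -> b")

    def test_duplicate_metabolite_raises(self):
        with pytest.raises(EquationParseError):
            parse_reaction_equation("a + a -> b")

    def test_metabolite_on_both_sides_raises(self):
        with pytest.raises(EquationParseError):
            parse_reaction_equation("a -> a")

    def test_format_parse_round_trip(self):
        for eq in ("2 a + b -> c", "a <=> 3 b"):
            stoich, rev = parse_reaction_equation(eq)
            stoich2, rev2 = parse_reaction_equation(format_reaction_equation(stoich, rev))
            assert stoich2 == stoich and rev2 == rev


class TestReactionDatabase:
    def test_reversible_split_into_directions(self):
        db = ReactionDatabase.from_equations([("R1", "a <=> b", "g1")])
        assert db.ids() == ["R1_f", "R1_b"]
        assert db.entry("R1_f")[1] == {"a": -1.0, "b": 1.0}
        assert db.entry("R1_b")[1] == {"a": 1.0, "b": -1.0}

    def test_irreversible_kept_whole(self):
        db = ReactionDatabase.from_equations([("R1", "a -> b", "")])
        assert db.ids() == ["R1"]

    def test_duplicate_ids_raise(self):
        with pytest.raises(ValueError):
            ReactionDatabase.from_equations([("R1", "a -> b", ""), ("R1", "b -> c", "")])


class TestGPR:
    def test_or_survives_single_knockout(self):
        assert gpr_is_active("(g1 and g2) or g3", {"g1"})

    def test_and_dies_on_single_knockout(self):
        assert not gpr_is_active("g1 and g2", {"g1"})

    def test_or_dies_only_when_all_knocked(self):
        assert not gpr_is_active("(g1 and g2) or g3", {"g1", "g3"})

    def test_empty_gpr_always_active(self):
        assert gpr_is_active("", {"g1"})

    def test_gene_extraction(self):
        assert gpr_genes("(g1 and g2) or g3") == {"g1", "g2", "g3"}


def _tiny():
    return MetabolicModel(
        metabolites=[Metabolite("a", "c"), Metabolite("b", "c")],
        reactions=[
            Reaction("EX", {"a": -1.0}, lb=-10.0, ub=1000.0, is_exchange=True),
            Reaction("R", {"a": -1.0, "b": 1.0}, lb=0.0, ub=1000.0),
            Reaction("RV", {"b": -1.0, "a": 1.0}, lb=-1000.0, ub=1000.0),
        ],
        biomass=BiomassSpec(substrates={"b": 1.0}),
        id="tiny",
    )


class TestApplyChangeSet:
    def test_identity(self):
        m = _tiny()
        out = apply_change_set(m, ChangeSet())
        assert [r.id for r in out.reactions] == [r.id for r in m.reactions]
        assert all(
            (a.lb, a.ub) == (b.lb, b.ub) for a, b in zip(out.reactions, m.reactions)
        )

    def test_original_untouched(self):
        m = _tiny()
        apply_change_set(m, ChangeSet(remove_forward={"R"}))
        assert m.reaction("R").ub == 1000.0

    def test_remove_forward_zeroes_upper_bound(self):
        out = apply_change_set(_tiny(), ChangeSet(remove_forward={"R"}))
        assert out.reaction("R").ub == 0.0

    def test_remove_backward_zeroes_lower_bound(self):
        out = apply_change_set(_tiny(), ChangeSet(remove_backward={"RV"}))
        assert out.reaction("RV").lb == 0.0

    def test_make_reversible_opens_lower_bound(self):
        out = apply_change_set(_tiny(), ChangeSet(make_reversible={"R"}))
        assert out.reaction("R").lb == -1000.0

    def test_make_reversible_on_reversible_raises(self):
        with pytest.raises(ValueError):
            apply_change_set(_tiny(), ChangeSet(make_reversible={"RV"}))

    def test_add_reaction_from_database(self):
        db = ReactionDatabase.from_equations([("N", "a -> b", "gN")])
        out = apply_change_set(_tiny(), ChangeSet(add_reactions={"N"}), db)
        r = out.reaction("N")
        assert (r.lb, r.ub) == (0.0, 1000.0)
        assert r.gpr == "gN"

    def test_add_reaction_creates_missing_metabolites(self):
        db = ReactionDatabase.from_equations([("N", "a -> zzz", "")])
        out = apply_change_set(_tiny(), ChangeSet(add_reactions={"N"}), db)
        assert any(m.id == "zzz" for m in out.metabolites)

    def test_add_unknown_reaction_raises(self):
        with pytest.raises(KeyError):
            apply_change_set(_tiny(), ChangeSet(add_reactions={"nope"}), ReactionDatabase([]))

    def test_biomass_substrate_removal(self):
        out = apply_change_set(_tiny(), ChangeSet(biomass_remove_substrate={"b"}))
        assert "b" not in out.biomass.substrates

    def test_biomass_substrate_addition(self):
        out = apply_change_set(_tiny(), ChangeSet(biomass_add_substrate={"a": 0.5}))
        assert out.biomass.substrates["a"] == 0.5

    def test_remove_unknown_biomass_metabolite_raises(self):
        with pytest.raises(KeyError):
            apply_change_set(_tiny(), ChangeSet(biomass_remove_substrate={"a"}))

    def test_remove_and_add_same_metabolite_same_side_raises(self):
        with pytest.raises(ValueError):
            apply_change_set(
                _tiny(),
                ChangeSet(biomass_remove_substrate={"b"}, biomass_add_substrate={"b": 2.0}),
            )

    def test_idempotent_on_repeated_application_of_removals(self):
        cs = ChangeSet(remove_forward={"R"})
        once = apply_change_set(_tiny(), cs)
        twice = apply_change_set(once, cs)
        assert twice.reaction("R").ub == 0.0

    def test_changes_commute(self):
        cs1 = ChangeSet(remove_forward={"R"})
        cs2 = ChangeSet(remove_backward={"RV"})
        a = apply_change_set(apply_change_set(_tiny(), cs1), cs2)
        b = apply_change_set(apply_change_set(_tiny(), cs2), cs1)
        assert {(r.id, r.lb, r.ub) for r in a.reactions} == {
            (r.id, r.lb, r.ub) for r in b.reactions
        }


class TestSupermodel:
    def test_contains_reversals_and_database(self):
        db = ReactionDatabase.from_equations([("N", "a -> b", "")])
        sup = build_supermodel(_tiny(), db, reversible_candidates={"R"})
        assert sup.reaction("R").lb < 0  # reversal applied
        assert sup.has_reaction("N")

    def test_id_collision_gets_suffix(self):
        db = ReactionDatabase.from_equations([("R", "a -> b", "")])
        sup = build_supermodel(_tiny(), db)
        assert sup.has_reaction("R_db")


class TestChangeSet:
    def test_as_tuples_canonical_order(self):
        cs = ChangeSet(remove_forward={"z", "a"}, add_reactions={"n"})
        assert cs.as_tuples() == (("ADD", "n"), ("RF", "a"), ("RF", "z"))

    def test_len_counts_all_changes(self):
        cs = ChangeSet(remove_forward={"a"}, biomass_add_substrate={"m": 1.0})
        assert len(cs) == 2


class TestValidation:
    def test_reaction_bounds_validated(self):
        with pytest.raises(ValueError):
            Reaction("R", {"a": -1.0}, lb=1.0, ub=-1.0)

    def test_biomass_coefficients_positive(self):
        with pytest.raises(ValueError):
            BiomassSpec(substrates={"a": -1.0})

    def test_biomass_sides_disjoint(self):
        with pytest.raises(ValueError):
            BiomassSpec(substrates={"a": 1.0}, products={"a": 1.0})

    def test_duplicate_reaction_ids_raise(self):
        with pytest.raises(ValueError):
            MetabolicModel(
                metabolites=[Metabolite("a", "c")],
                reactions=[
                    Reaction("R", {"a": 1.0}, 0.0, 1.0),
                    Reaction("R", {"a": -1.0}, 0.0, 1.0),
                ],
                biomass=BiomassSpec(substrates={"a": 1.0}),
            )
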