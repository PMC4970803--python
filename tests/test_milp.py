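"""The repair MILP: small hand-checkable instances, exhaustive checks of the
biomass-edit linearization, candidate pruning, enumeration and caps."""

import itertools

import pytest

from fluxfit import (
    GROWTH,
    NON_GROWTH,
    BiomassSpec,
    CandidatePolicy,
    ChangeCandidates,
    ChangeSet,
    Condition,
    ExclusionPolicy,
    InfeasibleRepairError,
    MILPConfig,
    MetabolicModel,
    Metabolite,
    Reaction,
    ReactionDatabase,
    apply_change_set,
    assemble_bilevel_milp,
    enumerate_alternative_solutions,
    enumerate_change_candidates,
    max_biomass,
    solve_milp,
)
from fluxfit.milp import _scipy_solve
from fluxfit.synth import paired_repair_scenario, symmetric_repair_scenario


def _bypass_conditions():
    return [
        Condition.make("WT", observed=GROWTH, threshold=0.5),
        Condition.make("KO", {"gT"}, observed=NON_GROWTH, threshold=0.5),
    ]


class TestTinyRepair:
    def test_removes_spurious_bypass(self, bypass_model):
        cand = ChangeCandidates(removable_forward={"Y": 1.0, "T": 1.0})
        inst = assemble_bilevel_milp(bypass_model, _bypass_conditions(), cand)
        sol = solve_milp(inst)
        assert sol.objective == pytest.approx(1.0)
        assert sol.change_set.as_tuples() == (("RF", "Y"),)

    def test_verified_predictions_match_labels(self, bypass_model):
        cand = ChangeCandidates(removable_forward={"Y": 1.0, "T": 1.0})
        sol = solve_milp(assemble_bilevel_milp(bypass_model, _bypass_conditions(), cand))
        assert sol.per_condition_predicted == {"WT": GROWTH, "KO": NON_GROWTH}

    def test_infeasible_without_candidates_raises(self, bypass_model):
        cand = ChangeCandidates(removable_forward={"T": 1.0})  # removing T kills WT too
        with pytest.raises(InfeasibleRepairError):
            solve_milp(assemble_bilevel_milp(bypass_model, _bypass_conditions(), cand))

    def test_exclusion_used_when_no_repair_exists(self, bypass_model):
        cand = ChangeCandidates(removable_forward={"T": 1.0})
        inst = assemble_bilevel_milp(
            bypass_model,
            _bypass_conditions(),
            cand,
            exclusion=ExclusionPolicy(allow_exclusion=True, default_weight=7.0),
        )
        sol = solve_milp(inst)
        assert sol.excluded_conditions == {"KO"}
        assert sol.objective == pytest.approx(7.0)

    def test_max_changes_cap_enforced(self):
        sc = paired_repair_scenario()
        config = MILPConfig(max_changes=1)
        inst = assemble_bilevel_milp(
            sc.corrupted_model, sc.conditions, sc.candidate_universe, sc.db, config=config
        )
        with pytest.raises(InfeasibleRepairError):
            solve_milp(inst, config)


class TestBinaryCount:
    def test_n_plus_m_rule(self, bypass_model):
        cand = ChangeCandidates(removable_forward={"Y": 1.0, "T": 1.0})
        conds = _bypass_conditions()
        inst = assemble_bilevel_milp(
            bypass_model, conds, cand, exclusion=ExclusionPolicy(allow_exclusion=True)
        )
        assert inst.n_binaries == cand.n_changes + len(conds)

    def test_no_exclusion_means_n_only(self, bypass_model):
        cand = ChangeCandidates(removable_forward={"Y": 1.0, "T": 1.0})
        inst = assemble_bilevel_milp(bypass_model, _bypass_conditions(), cand)
        assert inst.n_binaries == cand.n_changes


class TestBiomassEditLinearization:
    """Exhaustively compare the MILP's biomass-edit rows against rebuilding
    the biomass reaction explicitly, over every subset of edit binaries."""

    @pytest.fixture
    def model(self):
        return MetabolicModel(
            metabolites=[
                Metabolite("a_e", "e"),
                Metabolite("a_c", "c"),
                Metabolite("b_c", "c"),
                Metabolite("c_c", "c"),
            ],
            reactions=[
                Reaction("EX_a", {"a_e": -1.0}, lb=-10.0, ub=1000.0, is_exchange=True),
                Reaction("TA", {"a_e": -1.0, "a_c": 1.0}, 0.0, 1000.0),
                Reaction("AB", {"a_c": -1.0, "b_c": 1.0}, 0.0, 6.0),
                Reaction("AC", {"a_c": -1.0, "c_c": 1.0}, 0.0, 3.0),
            ],
            biomass=BiomassSpec(substrates={"a_c": 1.0, "b_c": 1.0}),
            id="bioedit",
        )

    @pytest.mark.parametrize("observed,threshold", [(GROWTH, 2.0), (NON_GROWTH, 4.5)])
    def test_all_subsets_match_rebuilt_biomass(self, model, observed, threshold):
        cand = ChangeCandidates(
            biomass_removable_substrates={"b_c": 1.0},
            biomass_addable_substrates={"c_c": (2.0, 1.0)},
        )
        cond = Condition.make("C", observed=observed, threshold=threshold)
        names = cand.binaries()
        for bits in itertools.product([0, 1], repeat=len(names)):
            active = {n for n, b in zip(names, bits) if b}
            inst = assemble_bilevel_milp(model, [cond], cand, config=MILPConfig(verify=False))
            for n in names:
                inst.fix_binary(n, 1 if n in active else 0)
            feasible = _scipy_solve(inst).status != 2
            rebuilt = apply_change_set(model, cand.decode(active))
            v = max_biomass(rebuilt, cond)
            expected = (v >= threshold) if observed == GROWTH else (v <= threshold)
            assert feasible == expected, (active, v)


class TestEnumeration:
    def test_symmetric_optima_listed_before_suboptimal(self):
        sc = symmetric_repair_scenario()
        inst = assemble_bilevel_milp(
            sc.corrupted_model, sc.conditions, sc.candidate_universe, sc.db
        )
        sols = enumerate_alternative_solutions(inst, 3)
        assert len(sols) == 3
        objs = [s.objective for s in sols]
        assert objs == sorted(objs)
        assert objs[0] == pytest.approx(objs[1])
        assert objs[2] > objs[1]
        assert sols[0].change_set.as_tuples() != sols[1].change_set.as_tuples()

    def test_enumeration_change_sets_distinct(self):
        sc = symmetric_repair_scenario()
        inst = assemble_bilevel_milp(
            sc.corrupted_model, sc.conditions, sc.candidate_universe, sc.db
        )
        sols = enumerate_alternative_solutions(inst, 4)
        seen = [s.change_set.as_tuples() for s in sols]
        assert len(set(seen)) == len(seen)


class TestCandidateEnumeration:
    def test_blocked_direction_pruned(self, chain_model):
        m = chain_model.copy()
        m.metabolites.append(Metabolite("dead_c", "c"))
        m.reactions.append(Reaction("D", {"a_e": -1.0, "dead_c": 1.0}, 0.0, 1000.0))
        m._index()
        conds = [Condition.make("WT", observed=GROWTH, threshold=0.5)]
        cand = enumerate_change_candidates(m, None, CandidatePolicy(), conds)
        assert "D" not in cand.removable_forward  # blocked even in the supermodel

    def test_essential_direction_pruned(self, chain_model):
        conds = [Condition.make("WT", observed=GROWTH, threshold=0.5)]
        cand = enumerate_change_candidates(chain_model, None, CandidatePolicy(), conds)
        # T is the only route to biomass even in the supermodel
        assert "T" not in cand.removable_forward

    def test_pruning_can_be_disabled(self, chain_model):
        conds = [Condition.make("WT", observed=GROWTH, threshold=0.5)]
        cand = enumerate_change_candidates(
            chain_model, None, CandidatePolicy(preprocess=False), conds
        )
        assert "T" in cand.removable_forward

    def test_exchange_removal_weight_override(self, chain_model):
        cand = enumerate_change_candidates(
            chain_model,
            None,
            CandidatePolicy(exchange_removal_weight=0.1, preprocess=False),
            [],
        )
        assert cand.removable_forward["EX_a"] == pytest.approx(0.1)
        assert cand.removable_forward["T"] == pytest.approx(1.0)

    def test_database_candidates_enumerated(self, chain_model):
        db = ReactionDatabase.from_equations([("N", "a_e -> b_c", "")])
        cand = enumerate_change_candidates(
            chain_model, db, CandidatePolicy(preprocess=False), []
        )
        assert "N" in cand.database


class TestDeterminism:
    def test_same_instance_solves_identically(self):
        sc = paired_repair_scenario()
        sols = [
            solve_milp(
                assemble_bilevel_milp(
                    sc.corrupted_model, sc.conditions, sc.candidate_universe, sc.db
                )
            )
            for _ in range(3)
        ]
        assert len({s.change_set.as_tuples() for s in sols}) == 1
        assert len({s.objective for s in sols}) == 1
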