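"""FBA correctness on hand-derived examples plus an independent COBRApy
cross-check, classification edge cases, and the preprocessing screens."""

import pytest

from fluxfit import (
    GROWTH,
    NON_GROWTH,
    BiomassSpec,
    Condition,
    MetabolicModel,
    Metabolite,
    Reaction,
    classify_growth,
    effective_bounds,
    find_blocked_reactions,
    find_essential_reactions,
    max_biomass,
    open_all_exchanges,
    optimize_fba,
    predict_phenotype,
)
from fluxfit.fba import FBAResult
from fluxfit.io import to_cobra
from fluxfit.synth import generate_toy_network, knockout_panel


class TestHandDerivedOptima:
    def test_chain_optimum_is_uptake_limit(self, chain_model):
        assert optimize_fba(chain_model).objective == pytest.approx(10.0)

    def test_branched_optimum_limited_by_double_coefficient(self, branched_model):
        # biomass needs 1 A + 2 B; both uptakes cap at 10 → v_Bio = 10/2 = 5
        assert optimize_fba(branched_model).objective == pytest.approx(5.0)

    def test_closed_medium_gives_zero(self, chain_model):
        cond = Condition.make("closed", medium={"EX_a": (0.0, 1000.0)}, threshold=0.1)
        assert optimize_fba(chain_model, cond).objective == pytest.approx(0.0)

    def test_tighter_medium_scales_optimum(self, chain_model):
        cond = Condition.make("half", medium={"EX_a": (-4.0, 1000.0)}, threshold=0.1)
        assert optimize_fba(chain_model, cond).objective == pytest.approx(4.0)


class TestKnockouts:
    def test_knockout_kills_chain(self, chain_model):
        cond = Condition.make("ko", {"gT"}, observed=NON_GROWTH, threshold=0.5)
        assert max_biomass(chain_model, cond) == pytest.approx(0.0)

    def test_isozyme_survives_single_knockout(self, branched_model):
        cond = Condition.make("ko", {"gB1"}, threshold=0.25)
        assert max_biomass(branched_model, cond) == pytest.approx(5.0)

    def test_isozyme_pair_knockout_is_lethal(self, branched_model):
        cond = Condition.make("ko", {"gB1", "gB2"}, threshold=0.25)
        assert max_biomass(branched_model, cond) == pytest.approx(0.0)

    def test_gene_free_reaction_unaffected(self, bypass_model):
        cond = Condition.make("ko", {"gT"}, threshold=0.5)
        assert max_biomass(bypass_model, cond) == pytest.approx(10.0)


class TestEffectiveBounds:
    def test_medium_override_on_non_exchange_raises(self, chain_model):
        cond = Condition.make("bad", medium={"T": (0.0, 1.0)}, threshold=0.1)
        with pytest.raises(ValueError):
            effective_bounds(chain_model, cond)

    def test_medium_override_on_unknown_reaction_raises(self, chain_model):
        cond = Condition.make("bad", medium={"EX_zzz": (0.0, 1.0)}, threshold=0.1)
        with pytest.raises(KeyError):
            effective_bounds(chain_model, cond)

    def test_knockout_clamps_gpr_disabled_reactions(self, chain_model):
        cond = Condition.make("ko", {"gT"}, threshold=0.1)
        assert effective_bounds(chain_model, cond)["T"] == (0.0, 0.0)


class TestClassifyGrowth:
    def _res(self, v, status="optimal"):
        return FBAResult(objective=v, fluxes={}, status=status)

    def test_above_threshold_is_growth(self):
        assert classify_growth(self._res(1.0), 0.5) == GROWTH

    def test_exactly_at_threshold_is_non_growth(self):
        assert classify_growth(self._res(0.5), 0.5) == NON_GROWTH

    def test_within_tolerance_above_is_non_growth(self):
        assert classify_growth(self._res(0.5 + 1e-9), 0.5) == NON_GROWTH

    def test_below_threshold_is_non_growth(self):
        assert classify_growth(self._res(0.1), 0.5) == NON_GROWTH

    def test_infeasible_is_non_growth(self):
        assert classify_growth(self._res(float("nan"), "infeasible"), 0.5) == NON_GROWTH


class TestPreprocessingScreens:
    def test_dead_end_branch_is_blocked(self, chain_model):
        m = chain_model.copy()
        m.metabolites.append(Metabolite("dead_c", "c"))
        m.reactions.append(Reaction("D", {"a_e": -1.0, "dead_c": 1.0}, 0.0, 1000.0))
        m._index()
        assert ("D", "forward") in find_blocked_reactions(m)

    def test_live_directions_not_blocked(self, chain_model):
        blocked = find_blocked_reactions(chain_model)
        assert ("T", "forward") not in blocked
        assert ("EX_a", "backward") not in blocked

    def test_blocked_matches_exhaustive_fva_on_toy(self):
        # independent oracle: maximize/minimize each reaction by plain FBA
        from fluxfit.fba import _solve_lp

        model = generate_toy_network(n_pathways=2, depth=2, seed=3)
        work = open_all_exchanges(model)
        bounds = {r.id: (r.lb, r.ub) for r in work.reactions}
        expected = set()
        for r in work.reactions:
            lb, ub = bounds[r.id]
            if ub > 1e-6:
                res = _solve_lp(work, bounds, {r.id: 1.0}, maximize=True)
                if not res.ok or res.objective < 1e-6:
                    expected.add((r.id, "forward"))
            if lb < -1e-6:
                res = _solve_lp(work, bounds, {r.id: 1.0}, maximize=False)
                if not res.ok or res.objective > -1e-6:
                    expected.add((r.id, "backward"))
        assert find_blocked_reactions(model) == expected

    def test_essential_reactions_on_chain(self, chain_model):
        growth = [Condition.make("WT", observed=GROWTH, threshold=0.5)]
        assert find_essential_reactions(chain_model, growth) == {"EX_a", "T"}

    def test_bypass_makes_transport_non_essential(self, bypass_model):
        growth = [Condition.make("WT", observed=GROWTH, threshold=0.5)]
        assert "T" not in find_essential_reactions(bypass_model, growth)


class TestCobraCrossCheck:
    """Independent oracle: the same model solved by COBRApy's own stack."""

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_wild_type_optimum_matches_cobra(self, seed):
        model = generate_toy_network(n_pathways=2, depth=3, n_isozymes=1, seed=seed)
        ours = optimize_fba(model).objective
        theirs = to_cobra(model).optimize().objective_value
        assert ours == pytest.approx(theirs, abs=1e-6)

    def test_knockout_panel_matches_cobra(self):
        model = generate_toy_network(n_pathways=2, depth=2, seed=5)
        cm = to_cobra(model)
        for cond in knockout_panel(model):
            ours = max_biomass(model, cond)
            with cm as tmp:
                for g in cond.knockout_genes:
                    if g in {x.id for x in tmp.genes}:
                        tmp.genes.get_by_id(g).knock_out()
                theirs = tmp.slim_optimize(error_value=0.0)
            assert ours == pytest.approx(theirs, abs=1e-6), cond.id


def test_predict_phenotype_consistent_with_panel_labels():
    truth = generate_toy_network(n_pathways=2, depth=3, seed=9)
    for cond in knockout_panel(truth):
        assert predict_phenotype(truth, cond) == cond.observed
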