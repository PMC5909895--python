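import numpy as np
import pandas as pd
import pytest

from cofswap import (
    FluxDistribution,
    IterativeOptConfig,
    core_acetate_model,
    degenerate_optima_model,
    enumerate_alternate_optima,
    fba,
    fix_subthreshold_fluxes,
    iterative_optimize,
    min_sum_squares_select,
    steady_state_residual,
)
from cofswap.model_edit import STRAIN_PHYSIOLOGY
from cofswap.synthetic_models import loopy_toy_sidecar


def _dist(values):
    fluxes = pd.Series(values, index=[f"R{i}" for i in range(len(values))],
                       dtype=float)
    return FluxDistribution(fluxes=fluxes, objective_value=0.0)


class TestMinSumSquaresSelect:
    def test_single_solution_is_itself(self):
        only = _dist([1.0, 2.0])
        assert min_sum_squares_select([only]) is only

    def test_arithmetic_example_with_stable_tie_break(self):
        a, b, c = _dist([1, 1, 0]), _dist([1, 0, 1]), _dist([2, 0, 0])
        assert min_sum_squares_select([c, a, b]) is a  # 2 < 4, first of ties
        assert min_sum_squares_select([c, b, a]) is b

    def test_all_zero_distribution_wins(self):
        zero = _dist([0, 0, 0])
        assert min_sum_squares_select([_dist([1, 0, 0]), zero]) is zero

    def test_empty_list_raises(self):
        with pytest.raises(ValueError):
            min_sum_squares_select([])


class TestEnumeration:
    def test_unique_optimum_gives_single_solution(self, chain_model):
        result = enumerate_alternate_optima(chain_model, "SINK", n=10)
        assert len(result) == 1
        assert result.exhausted
        assert result.solutions[0].objective_value == pytest.approx(10.0)

    @pytest.mark.parametrize("k", [1, 2, 5])
    def test_k_parallel_paths_give_exactly_k_optima(self, k):
        model = degenerate_optima_model(k)
        result = enumerate_alternate_optima(model, "SINK", n=400)
        assert len(result) == k
        assert result.exhausted
        supports = {s.support() for s in result.solutions}
        assert len(supports) == k  # all support-distinct
        for sol in result.solutions:
            assert sol.objective_value == pytest.approx(10.0, abs=1e-6)

    def test_requesting_fewer_than_available_stops_early(self):
        model = degenerate_optima_model(5)
        result = enumerate_alternate_optima(model, "SINK", n=3)
        assert len(result) == 3
        assert not result.exhausted

    def test_selection_prefers_shortest_path(self):
        """With one path longer (two steps), min-Σv² picks the short route."""
        model = degenerate_optima_model(2)
        # split PATH2 into two sequential reactions via an intermediate
        from cobra import Metabolite, Reaction

        mid = Metabolite("MID", compartment="c")
        model.add_metabolites([mid])
        p2 = model.reactions.PATH2
        p2.subtract_metabolites(p2.metabolites)
        p2.add_metabolites({model.metabolites.A: -1, mid: 1})
        tail = Reaction("PATH2b", lower_bound=0, upper_bound=1000)
        model.add_reactions([tail])
        tail.add_metabolites({mid: -1, model.metabolites.B: 1})
        result = enumerate_alternate_optima(model, "SINK", n=10)
        best = min_sum_squares_select(result)
        assert best["PATH1"] == pytest.approx(10.0, abs=1e-6)
        assert best["PATH2"] == pytest.approx(0.0, abs=1e-6)

    def test_infeasible_base_raises(self, chain_model):
        chain_model.reactions.UPTAKE.bounds = (5, 5)
        chain_model.reactions.SINK.bounds = (6, 6)
        with pytest.raises(RuntimeError, match="infeasible"):
            enumerate_alternate_optima(chain_model, "SINK", n=5)


class TestFixSubthreshold:
    def test_all_below_threshold_pins_everything(self, chain_model):
        dist = fba(chain_model, "SINK")
        fix_subthreshold_fluxes(chain_model, dist, threshold=500.0)
        for rxn in chain_model.reactions:
            assert rxn.lower_bound == rxn.upper_bound == dist[rxn.id]

    def test_loop_reactions_at_threshold_stay_free(self, loopy_model):
        fluxes = pd.Series({"SRC": 10, "CONV": 10, "SINK": 10,
                            "LOOP1": 800.0, "LOOP2": 800.0, "LOOP3": 800.0})
        dist = FluxDistribution(fluxes=fluxes, objective_value=10.0)
        fix_subthreshold_fluxes(loopy_model, dist, threshold=500.0)
        assert loopy_model.reactions.SRC.bounds == (10, 10)
        assert loopy_model.reactions.LOOP1.bounds == (-1000, 1000)

    def test_threshold_uses_absolute_value(self, loopy_model):
        fluxes = pd.Series({"SRC": 10, "CONV": 10, "SINK": 10,
                            "LOOP1": -800.0, "LOOP2": -800.0, "LOOP3": -800.0})
        fix_subthreshold_fluxes(
            loopy_model, FluxDistribution(fluxes=fluxes, objective_value=10.0),
            threshold=500.0)
        assert loopy_model.reactions.LOOP1.bounds == (-1000, 1000)


class TestIterativeOptimize:
    def test_matches_plain_fba_on_unique_optimum_fixture(self):
        """Steps 7-11 cannot change anything when the optimum is unique.

        Removing the duplicate transporter and the fumarate-reductase loop
        from the core network leaves (generically) a unique optimal vertex;
        the full procedure must then coincide with plain FBA plus the
        lexicographic O2 minimization.
        """
        from cofswap import apply_strain, knockout

        model = core_acetate_model()
        knockout(model, ["ACUP2", "FRD7"])
        pc = STRAIN_PHYSIOLOGY["wild_type"]
        dist, prov = iterative_optimize(model, pc)

        plain = apply_strain(model.copy(), pc)
        plain.reactions.ATPM.bounds = (0.0, 50.0)
        atpm_opt = fba(plain, "ATPM").objective_value
        plain.reactions.ATPM.lower_bound = atpm_opt
        o2_opt = fba(plain, "EX_o2_e").objective_value
        plain.reactions.EX_o2_e.bounds = (o2_opt, o2_opt)
        lex = fba(plain, "ATPM")

        assert dist.objective_value == pytest.approx(atpm_opt, rel=1e-6)
        assert np.allclose(dist.fluxes.reindex(lex.fluxes.index).to_numpy(),
                           lex.fluxes.to_numpy(), atol=1e-5)

    def test_final_distribution_satisfies_all_constraints(self):
        model = core_acetate_model()
        pc = STRAIN_PHYSIOLOGY["wild_type"]
        dist, prov = iterative_optimize(model, pc)
        assert steady_state_residual(model, dist) < 1e-6
        assert dist["BIOMASS"] == pytest.approx(pc.mu, abs=1e-9)
        assert dist["EX_ac_e"] == pytest.approx(-pc.qac, abs=1e-9)
        assert dist["EX_o2_e"] == pytest.approx(prov["min_o2_exchange"], abs=1e-6)
        assert dist["ATPM"] == pytest.approx(prov["max_atpm"], rel=1e-6)

    def test_enumeration_plus_selection_suppresses_internal_loop(self, loopy_model):
        """The internal cycle carries zero flux in the selected optimum."""
        # the loopy toy lacks ATPM/O2 machinery: exercise steps 7-8 directly
        result = enumerate_alternate_optima(loopy_model, "SINK", n=50)
        best = min_sum_squares_select(result)
        for rid, expected in loopy_toy_sidecar["loop_free_fluxes"].items():
            assert best[rid] == pytest.approx(expected, abs=1e-6)

    def test_deterministic_reruns_are_bit_identical(self):
        model = core_acetate_model()
        pc = STRAIN_PHYSIOLOGY["icd_nad"]
        d1, p1 = iterative_optimize(model, pc)
        d2, p2 = iterative_optimize(model, pc)
        assert d1.fluxes.equals(d2.fluxes)
        assert p1["max_atpm"] == p2["max_atpm"]

    def test_infeasible_growth_names_the_step(self):
        model = core_acetate_model()
        bad = STRAIN_PHYSIOLOGY["wild_type"].__class__(
            "impossible", mu=5.0, qac=7.88)
        with pytest.raises(RuntimeError, match="step 2"):
            iterative_optimize(model, bad)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            IterativeOptConfig(n_optima=0)
        with pytest.raises(ValueError):
            IterativeOptConfig(loop_threshold=0.0)
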