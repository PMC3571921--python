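import itertools

import numpy as np
import pytest
from scipy import sparse, stats

import kinfba
from kinfba._opt import InfeasibleProblem
from kinfba.bounds import FluxBoundSet
from kinfba.kfba import (audit_kfba_solution, evaluate_predictions,
                         min_violations, proportional_groups, sign_test,
                         solve_fba, solve_kfba)
from kinfba.network import StoichiometricModel, block_fermentation


def _chain_model():
    """EX -> R1 -> R2 -> BIO linear chain for hand-enumerable MILPs."""
    mets = ["A", "B", "C"]
    rxns = ["EX_A", "R1", "R2", "BIO"]
    S = sparse.lil_matrix((3, 4))
    S[0, 0] = 1.0
    S[0, 1] = -1.0
    S[1, 1] = 1.0
    S[1, 2] = -1.0
    S[2, 2] = 1.0
    S[2, 3] = -1.0
    lb = np.array([-1000.0, 0.0, 0.0, 0.0])
    ub = np.array([1000.0, 1000.0, 1000.0, 1000.0])
    return StoichiometricModel(
        metabolites=mets, reactions=rxns, S=S.tocsr(), lb=lb, ub=ub,
        reversible=lb < 0, biomass_rxn="BIO", glucose_uptake_rxn="EX_A")


class TestFBA:
    def test_fixture_optimum_cross_checked_against_glpk(self, network):
        """The HiGHS-based FBA optimum must match an independent run of
        the same LP through cobrapy's GLPK interface."""
        v = solve_fba(network, 0.2)
        from kinfba.network import to_cobra

        cm = to_cobra(block_fermentation(network))
        cm.solver = "glpk"
        bm = cm.reactions.get_by_id("BIOMASS")
        bm.lower_bound = bm.upper_bound = 0.2
        cm.objective = "PTS"
        sol = cm.optimize("minimize")
        assert sol.status == "optimal"
        assert v["PTS"] == pytest.approx(sol.objective_value, abs=1e-6)

    def test_zero_growth_zero_maintenance_needs_no_glucose(self, network):
        m = network.copy()
        m.lb[m.rxn_index("ATPM")] = 0.0
        v = solve_fba(m, 0.0)
        assert v["PTS"] == pytest.approx(0.0, abs=1e-8)

    def test_growth_beyond_capacity_is_infeasible(self, network):
        with pytest.raises(InfeasibleProblem):
            solve_fba(network, 50.0)

    def test_minimum_norm_makes_the_solution_unique(self, network):
        v1 = solve_fba(network, 0.3)
        v2 = solve_fba(network, 0.3)
        for r in network.reactions:
            assert v1[r] == pytest.approx(v2[r], abs=1e-9)


class TestMinViolations:
    def test_consistent_bounds_need_no_violations(self, network):
        v = solve_fba(network, 0.2)
        bounds = FluxBoundSet()
        for rxn in network.kinetic_rxns:
            bounds.add("c", rxn, v[rxn] - 0.1, v[rxn] + 0.1)
        assert min_violations(network, bounds, 0.2,
                              condition_id="c") == 0

    def test_empty_bound_set_is_trivially_consistent(self, network):
        assert min_violations(network, FluxBoundSet(), 0.2) == 0

    def test_chain_conflict_forces_exactly_one_violation(self):
        m = _chain_model()
        bounds = FluxBoundSet()
        bounds.add("c", "R1", 2.0, 3.0)
        bounds.add("c", "R2", 5.0, 6.0)  # conflicts: chain forces R1 = R2
        assert min_violations(m, bounds, 2.5, condition_id="c",
                              block_ferm=False) == 1

    def test_matches_exhaustive_binary_enumeration(self, network, rng):
        """On instances with few bounded reactions the MILP optimum must
        equal a brute-force scan over every relaxation pattern."""
        v = solve_fba(network, 0.2)
        rxns = ["PTS", "PGI", "PFK", "GAPD", "PPC"]
        bounds = FluxBoundSet()
        for i, rxn in enumerate(rxns):
            off = 0.4 * (1 if i % 2 == 0 else -1)
            width = 0.05
            bounds.add("c", rxn, v[rxn] + off - width, v[rxn] + off + width)
        milp_n = min_violations(network, bounds, 0.2, condition_id="c")
        # brute force: for each violated-set pattern, check LP feasibility
        m = block_fermentation(network)
        j = m.rxn_index("BIOMASS")
        m.lb[j] = m.ub[j] = 0.2
        best = None
        from kinfba._opt import solve_lp

        blist = sorted(bounds.for_condition("c").items())
        for pattern in itertools.product([0, 1], repeat=len(blist)):
            lb = m.lb.copy()
            ub = m.ub.copy()
            for keep, (rxn, (lo, hi)) in zip(pattern, blist):
                if keep == 0:  # bound enforced
                    jj = m.rxn_index(rxn)
                    lb[jj] = max(lb[jj], lo)
                    ub[jj] = min(ub[jj], hi)
            try:
                solve_lp(np.zeros(m.n_reactions), m.S,
                         np.zeros(m.n_metabolites), lb, ub)
            except InfeasibleProblem:
                continue
            n = sum(pattern)
            best = n if best is None else min(best, n)
        assert milp_n == best


class TestKFBA:
    def _bounds_from_truth(self, network, growth, width=0.05):
        v = solve_fba(network, growth)
        bounds = FluxBoundSet()
        for rxn in network.kinetic_rxns:
            bounds.add("c", rxn, v[rxn] - width, v[rxn] + width)
        return bounds, v

    def test_consistent_bounds_are_respected(self, network):
        bounds, v_true = self._bounds_from_truth(network, 0.2)
        sol = solve_kfba(network, bounds, 0.2, condition_id="c")
        assert sol.n_violations == 0
        for rxn, (lo, hi) in bounds.for_condition("c").items():
            assert lo - 1e-6 <= sol.v[rxn] <= hi + 1e-6

    def test_all_bounds_ignored_reduces_to_fba(self, network):
        """With the violation budget covering every bound, the KFBA flux
        vector equals plain FBA component-wise."""
        bounds = FluxBoundSet()
        for rxn in network.kinetic_rxns:
            bounds.add("c", rxn, 5.0, 5.0)  # nonsense bounds, all relaxed
        sol = solve_kfba(network, bounds, 0.2,
                         n_star=2 * len(bounds.bounds), condition_id="c")
        fba = solve_fba(network, 0.2)
        for r in network.reactions:
            assert sol.v[r] == pytest.approx(fba[r], abs=1e-6)

    def test_objective_nonincreasing_in_violation_budget(self, network):
        bounds = FluxBoundSet()
        v = solve_fba(network, 0.2)
        # tight, deliberately conflicting bounds away from the optimum
        for i, rxn in enumerate(network.kinetic_rxns[:6]):
            bounds.add("c", rxn, v[rxn] + 0.3, v[rxn] + 0.4)
        n0 = min_violations(network, bounds, 0.2, condition_id="c")
        objs = []
        for n in range(n0, len(bounds.bounds) + 1):
            sol = solve_kfba(network, bounds, 0.2, n_star=n,
                             condition_id="c")
            objs.append(sol.objective)
        assert all(a >= b - 1e-8 for a, b in zip(objs, objs[1:]))

    def test_wasteful_lower_bound_raises_glucose_demand(self, network):
        v = solve_fba(network, 0.2)
        bounds = FluxBoundSet()
        # force flux through the ATP-consuming PPCK/PPC pair far above
        # the FBA optimum: extra glucose is needed to pay for it
        bounds.add("c", "PPC", v["PPC"] + 1.0, v["PPC"] + 1.5)
        sol = solve_kfba(network, bounds, 0.2, n_star=0,
                         condition_id="c")
        assert sol.objective > v["PTS"] + 1e-6

    def test_infeasible_budget_reports(self, network):
        v = solve_fba(network, 0.2)
        bounds = FluxBoundSet()
        bounds.add("c", "PGI", v["PGI"] + 5.0, v["PGI"] + 6.0)
        bounds.add("c", "PFK", v["PFK"] - 6.0, v["PFK"] - 5.0)
        with pytest.raises(InfeasibleProblem, match="min_violations"):
            solve_kfba(network, bounds, 0.2, n_star=0, condition_id="c")

    def test_solutions_pass_substitution_audit(self, network):
        bounds, _ = self._bounds_from_truth(network, 0.4, width=0.02)
        sol = solve_kfba(network, bounds, 0.4, condition_id="c")
        m = block_fermentation(network)
        j = m.rxn_index(m.biomass_rxn)
        m.lb[j] = m.ub[j] = 0.4
        audit_kfba_solution(m, sorted(bounds.for_condition("c").items()),
                            sol, 0.4)


class TestEvaluation:
    def test_identical_predictions_have_zero_residual(self, network):
        v = solve_fba(network, 0.2)
        ev = evaluate_predictions(v, v, network, 0.2)
        assert ev.mean_residual == pytest.approx(0.0, abs=1e-12)

    def test_coupled_chain_counts_one_residual(self):
        m = _chain_model()
        pred = {"R1": 1.0, "R2": 1.0, "BIO": 1.0}
        meas = {"R1": 1.5, "R2": 1.5, "BIO": 1.5}
        ev = evaluate_predictions(pred, meas, m)
        # the whole chain is one proportional group: one representative
        assert len(ev.groups) == 1
        assert ev.mean_residual == pytest.approx(0.25)

    def test_biomass_yield_is_growth_over_uptake(self, network):
        v = solve_fba(network, 0.2)
        ev = evaluate_predictions(v, v, network, 0.2)
        assert ev.biomass_yield == pytest.approx(0.2 / v["PTS"])

    def test_zero_uptake_flags_undefined_yield(self, network):
        v = {r: 0.0 for r in network.reactions}
        ev = evaluate_predictions(v, v, network, 0.2)
        assert np.isnan(ev.biomass_yield)

    def test_proportional_groups_on_fixture(self, network):
        groups = proportional_groups(network, ["G6PDH", "GND", "PGI"])
        # G6PDH and GND are forced equal by the 6pg balance
        assert ["G6PDH", "GND"] in groups


class TestSignTest:
    @pytest.mark.parametrize("wins, n, expected", [
        (5, 5, 0.0625),
        (4, 5, 0.375),
        (2, 4, 1.0),
    ])
    def test_exact_binomial_values(self, wins, n, expected):
        a = [1.0] * n
        b = [0.0] * wins + [2.0] * (n - wins)
        assert sign_test(a, b) == pytest.approx(expected)

    def test_five_concordant_pairs_print_as_0_063(self):
        from decimal import ROUND_HALF_UP, Decimal

        p = sign_test([1, 1, 1, 1, 1], [2, 2, 2, 2, 2])
        printed = Decimal(str(p)).quantize(Decimal("0.001"),
                                           rounding=ROUND_HALF_UP)
        assert str(printed) == "0.063"

    def test_agrees_with_scipy_binomtest(self, rng):
        for _ in range(20):
            n = int(rng.integers(3, 12))
            a = rng.normal(size=n)
            b = rng.normal(size=n)
            k = int(np.sum(a - b > 0))
            ours = sign_test(a, b)
            ref = stats.binomtest(k, n, 0.5).pvalue
            assert ours == pytest.approx(ref, abs=1e-12)

    def test_all_ties_undefined(self):
        with pytest.raises(ValueError, match="tie"):
            sign_test([1.0, 2.0], [1.0, 2.0])
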