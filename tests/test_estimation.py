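import math

import numpy as np
import pytest
from scipy import stats

import kinfba
from kinfba.adjust import AdjustedFluxes
from kinfba.estimation import (CIEntry, ConfidenceIntervals, WSLSProblem,
                               WSLSInfeasibleError, condition_wsls,
                               estimate_confidence_intervals, fit_coverage,
                               profile_confidence_interval,
                               simplification_diagnostics, solve_wsls,
                               KineticParameterEstimator)
from kinfba.omics import ConditionRecord, Measurement, OmicsDataset
from kinfba.rate_laws import (KineticModel, ParameterSet, ParameterSpec,
                              build_simplified_model)


from conftest import make_pgm_only_problem as _pgm_only_problem


class TestSingleReactionFit:
    def test_recovers_parameters_against_grid_oracle(self):
        """The fitted (kcat, Keq) must coincide with the minimum of the
        WSLS landscape evaluated on a dense 2-D grid."""
        problem, theta_true = _pgm_only_problem()
        result = solve_wsls(problem, n_starts=3, seed=0)
        assert result.wsls <= 1e-8
        for name, true in theta_true.items():
            assert result.theta[name] == pytest.approx(true, rel=1e-4)

        # independent 2-D grid oracle around the optimum
        law = problem.kinetic_model.rate_laws["PGM"]
        conds = problem.dataset.conditions

        def wsls_at(kcat, keq):
            total = 0.0
            for cond in conds:
                c = {m: meas.mean for m, meas in cond.metabolites.items()}
                f = law.f(c, {"kcat_PGM": kcat, "Keq_PGM": keq})
                e = cond.fluxes["PGM"] / f
                w = problem.weights.enzyme(cond.condition_id, "PGM")
                total += w * (e - cond.enzymes["PGM"].mean) ** 2
            return total

        ks = np.geomspace(theta_true["kcat_PGM"] / 3,
                          theta_true["kcat_PGM"] * 3, 41)
        qs = np.geomspace(theta_true["Keq_PGM"] / 2,
                          theta_true["Keq_PGM"] * 2, 41)
        grid = [(wsls_at(k, q), k, q) for k in ks for q in qs]
        _, k_best, q_best = min(grid)
        assert result.theta["kcat_PGM"] == pytest.approx(k_best, rel=0.1)
        assert result.theta["Keq_PGM"] == pytest.approx(q_best, rel=0.05)

    def test_infeasible_energy_charge_bound_is_reported(self):
        problem, _ = _pgm_only_problem()
        problem.aec_min = 1.01
        with pytest.raises(WSLSInfeasibleError):
            solve_wsls(problem, n_starts=1, seed=0)


class TestNoiselessSelfConsistency:
    def test_wsls_reaches_zero(self, small_noiseless_fit):
        assert small_noiseless_fit.wsls <= 1e-6

    def test_inner_problem_is_exact_at_truth(self, small_noiseless_problem,
                                             small_noiseless_study):
        per_cond = condition_wsls(small_noiseless_problem,
                                  small_noiseless_study.theta_true,
                                  max_sweeps=1)
        for cid, w in per_cond.items():
            assert w <= 1e-8, cid

    def test_identifiable_parameters_match_truth(
            self, small_noiseless_problem, small_noiseless_fit,
            small_noiseless_study):
        ci = estimate_confidence_intervals(small_noiseless_problem,
                                           small_noiseless_fit)
        truth = small_noiseless_study.theta_true.values
        for name, entry in ci.entries.items():
            if entry.flag == "" and entry.relative_width < 10:
                assert small_noiseless_fit.theta[name] == pytest.approx(
                    truth[name], rel=0.01), name

    def test_feasibility_contract(self, small_noiseless_problem,
                                  small_noiseless_fit):
        problem, result = small_noiseless_problem, small_noiseless_fit
        km = problem.kinetic_model
        for cid, c in result.c_hat.items():
            aec = kinfba.adenylate_energy_charge(c["atp"], c["adp"],
                                                 c["amp"])
            assert aec >= problem.aec_min - 1e-9
            for rxn, law in km.rate_laws.items():
                v = problem.adjusted_fluxes.v[cid][rxn]
                e = result.e_hat[cid][rxn]
                assert abs(v - e * law.f(c, result.theta.values)) <= \
                    1e-6 * max(1.0, abs(v))
                lo, hi = problem.enzyme_bounds
                assert lo - 1e-9 <= e <= hi + 1e-9

    def test_monotone_data_use(self, small_noiseless_problem,
                               small_noiseless_study):
        """With theta fixed, adding a condition never changes the other
        conditions' optimal contributions (the objective is separable)."""
        problem = small_noiseless_problem
        theta = small_noiseless_study.theta_true
        all_ids = problem.dataset.condition_ids
        sub = WSLSProblem(problem.kinetic_model,
                          problem.dataset.subset(all_ids[:2]),
                          problem.weights, problem.adjusted_fluxes)
        w_sub = condition_wsls(sub, theta, max_sweeps=1)
        w_all = condition_wsls(problem, theta, max_sweeps=1)
        for cid in all_ids[:2]:
            assert w_all[cid] <= w_sub[cid] + 1e-6


class TestConfidenceIntervals:
    def test_quadratic_objective_reproduces_closed_form(self):
        """Profile CI machinery on W(theta) = (theta-mu)^2/s^2 must give
        half-width s * sqrt(chi2_{0.95,1})."""
        mu, s = 1.0, 0.05
        profile = lambda t: (t - mu) ** 2 / s ** 2
        entry = profile_confidence_interval(profile, mu, 0.0, delta=0.05,
                                            alpha=0.05, bounds=(1e-6, 1e4))
        expected = s * math.sqrt(stats.chi2.ppf(0.95, 1))
        assert (entry.upper - entry.value) == pytest.approx(expected,
                                                            rel=0.05)
        assert (entry.value - entry.lower) == pytest.approx(expected,
                                                            rel=0.05)

    def test_flat_profile_spans_global_bounds(self):
        entry = profile_confidence_interval(lambda t: 0.0, 1.0, 0.0,
                                            delta=0.05, alpha=0.05,
                                            bounds=(1e-6, 1e4))
        assert entry.flag == "flat"
        assert entry.lower == 1e-6 and entry.upper == 1e4
        assert entry.relative_width > 100

    def test_hessian_and_profile_agree_on_small_problem(self):
        problem, _ = _pgm_only_problem()
        result = solve_wsls(problem, n_starts=1, seed=0)
        hess = estimate_confidence_intervals(problem, result,
                                             method="hessian",
                                             scale_variance=False)
        prof = estimate_confidence_intervals(problem, result,
                                             method="profile",
                                             scale_variance=False)
        for name in ("Keq_PGM",):
            h, p = hess[name], prof[name]
            if h.flag or p.flag:
                continue
            width_h = h.upper - h.lower
            width_p = p.upper - p.lower
            assert width_h == pytest.approx(width_p, rel=0.5)

    def test_near_equilibrium_kcat_wider_than_keq(
            self, small_noiseless_problem, small_noiseless_fit):
        """For reactions operating near equilibrium the catalytic rate
        constant is poorly determined compared with Keq."""
        ci = estimate_confidence_intervals(small_noiseless_problem,
                                           small_noiseless_fit)
        # TPI runs close to equilibrium in the synthetic study: its kcat
        # profile is flat (interval spans the whole global box) while
        # its Keq stays tightly determined
        kcat = ci["kcat_TPI"]
        assert kcat.flag == "flat" or kcat.relative_width > 10
        assert kcat.lower == pytest.approx(1e-6)
        assert kcat.upper == pytest.approx(1e4)
        assert ci["Keq_TPI"].relative_width < 1.0


class TestCoverage:
    def test_perfect_estimates_give_full_coverage(self):
        problem, _ = _pgm_only_problem()
        result = solve_wsls(problem, n_starts=1, seed=0)
        cov = fit_coverage(result, problem.dataset)
        assert cov["metabolites"] == 1.0
        assert cov["enzymes"] == 1.0
        assert cov["pooled"] == 1.0

    def test_estimates_two_sd_off_give_zero_coverage(self):
        problem, _ = _pgm_only_problem()
        result = solve_wsls(problem, n_starts=1, seed=0)
        shifted = {
            cid: {m: v * 1.2 for m, v in cmap.items()}
            for cid, cmap in result.c_hat.items()}
        e_shift = {cid: {k: v * 1.2 for k, v in emap.items()}
                   for cid, emap in result.e_hat.items()}
        bad = type(result)(theta=result.theta, c_hat=shifted,
                           e_hat=e_shift, wsls=result.wsls)
        cov = fit_coverage(bad, problem.dataset)
        assert cov["pooled"] == 0.0


class TestSimplificationDiagnostics:
    def test_negligible_km_flagged_for_removal(self, small_noiseless_problem,
                                               small_noiseless_fit):
        result = small_noiseless_fit
        tweaked = ParameterSet(dict(result.theta.values))
        tweaked.values["Km_fdp_ALDO"] = 1e-6
        bad = type(result)(theta=tweaked, c_hat=result.c_hat,
                           e_hat=result.e_hat, wsls=result.wsls)
        flags = simplification_diagnostics(bad, small_noiseless_problem)
        entry = next(f for f in flags if f["parameter"] == "Km_fdp_ALDO")
        assert "at-lower-bound" in entry["flags"]
        assert "km-negligible" in entry["flags"]
        assert "drop" in entry["suggestion"]

    def test_dominant_km_suggests_dropping_the_metabolite(
            self, small_noiseless_problem, small_noiseless_fit):
        result = small_noiseless_fit
        tweaked = ParameterSet(dict(result.theta.values))
        tweaked.values["Km_6pg_GND"] = 5.0e3
        bad = type(result)(theta=tweaked, c_hat=result.c_hat,
                           e_hat=result.e_hat, wsls=result.wsls)
        flags = simplification_diagnostics(bad, small_noiseless_problem)
        entry = next(f for f in flags if f["parameter"] == "Km_6pg_GND")
        assert "km-dominant" in entry["flags"]
        assert "keep" in entry["suggestion"]

    def test_well_scaled_parameter_not_flagged(self, small_noiseless_problem,
                                               small_noiseless_fit):
        flags = simplification_diagnostics(small_noiseless_fit,
                                           small_noiseless_problem)
        flagged = {f["parameter"] for f in flags}
        # PPC's pep binding coefficient is on the concentration scale
        assert "Km_pep_PPC" not in flagged


class TestEstimatorFrontend:
    def test_sklearn_params_round_trip(self):
        est = KineticParameterEstimator(n_starts=3, seed=7)
        params = est.get_params()
        assert params["n_starts"] == 3
        est.set_params(seed=9)
        assert est.seed == 9

    def test_fit_exposes_fitted_attributes(self, network, kinetic_model,
                                           small_noiseless_study):
        study = small_noiseless_study
        adj = AdjustedFluxes(
            v={cid: dict(study.truth.fluxes[cid])
               for cid in study.train_ids},
            distance={cid: 0.0 for cid in study.train_ids})
        est = KineticParameterEstimator(kinetic_model=kinetic_model,
                                        network=network, n_starts=1,
                                        seed=0, max_sweeps=2)
        est.fit(study.train, adjusted_fluxes=adj)
        assert est.wsls_ <= 1e-4
        assert len(est.theta_.values) == 36
        assert set(est.c_hat_) == set(study.train_ids)

    def test_unfitted_estimator_raises(self):
        est = KineticParameterEstimator()
        with pytest.raises(RuntimeError, match="not fitted"):
            est.coverage()
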