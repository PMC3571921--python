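import math

import numpy as np
import pytest
import sympy
from hypothesis import given, settings, strategies as st

import kinfba
from kinfba.rate_laws import (FITTED_VALUES, IRREVERSIBLE_LAWS, RateLawError,
                              adenylate_energy_charge, evaluate_rate)


def _concentrations(rng, lo=0.001, hi=10.0):
    mets = kinfba.build_simplified_model().metabolite_ids
    return {m: math.exp(rng.uniform(math.log(lo), math.log(hi)))
            for m in mets}


class TestModelStructure:
    def test_19_laws_and_36_distinct_parameters(self, kinetic_model):
        assert len(kinetic_model.rate_laws) == 19
        assert kinetic_model.n_parameters == 36

    def test_pgm_touches_only_its_metabolites_and_parameters(
            self, kinetic_model):
        pgm = kinetic_model.rate_laws["PGM"]
        assert set(pgm.required_metabolites) == {"2pg", "3pg"}
        assert set(pgm.parameters) == {"kcat_PGM", "Keq_PGM"}

    def test_aldo_keq_carries_concentration_units(self, kinetic_model):
        assert kinetic_model.specs["Keq_ALDO"].units == "mM"

    def test_irreversibility_flags(self, kinetic_model):
        for rxn, law in kinetic_model.rate_laws.items():
            assert law.irreversible == (rxn in IRREVERSIBLE_LAWS)

    def test_keq_bounds_bracket_reference(self, kinetic_model):
        spec = kinetic_model.specs["Keq_PGI"]
        assert spec.global_lb == pytest.approx(0.35 * 1.23)
        assert spec.global_ub == pytest.approx(2.85 * 1.23)

    def test_non_keq_bounds_are_global_box(self, kinetic_model):
        spec = kinetic_model.specs["kcat_PTS"]
        assert spec.global_lb == 1e-6 and spec.global_ub == 1e4


class TestFittedParameters:
    def test_all_36_reference_values_load(self, fitted):
        params, halfwidths = fitted
        assert len(params.values) == 36
        assert len(halfwidths) == 36

    @pytest.mark.parametrize("name, value, half", [
        ("Keq_PGI", 1.23, 0.29),
        ("Keq_TPI", 0.11400, 0.00031),
        ("kcat_PTS", 20.7, 9.1),
        ("Keq_PGK", 5512.1, 1.2),
        ("Km_pyr_PDH", 0.000020, 0.000029),
    ])
    def test_reference_lookups(self, fitted, name, value, half):
        params, halfwidths = fitted
        assert params[name] == pytest.approx(value)
        assert halfwidths[name] == pytest.approx(half)

    def test_units_table_is_complete(self):
        assert all(len(v) == 3 for v in FITTED_VALUES.values())


class TestEvaluateRate:
    def test_pgi_hand_computed_flux(self, kinetic_model):
        law = kinetic_model.rate_laws["PGI"]
        v = evaluate_rate(law, 0.1, {"g6p": 1.0, "f6p": 0.5},
                          {"kcat_PGI": 40.2, "Keq_PGI": 1.23})
        assert v == pytest.approx(40.2 * 0.1 * (1 - 0.5 / 1.23), rel=1e-12)
        assert v == pytest.approx(2.386, abs=5e-4)

    def test_equilibrium_gives_zero_rate(self, kinetic_model):
        law = kinetic_model.rate_laws["PGI"]
        keq = 1.23
        v = evaluate_rate(law, 0.5, {"g6p": 2.0, "f6p": keq * 2.0},
                          {"kcat_PGI": 40.2, "Keq_PGI": keq})
        assert v == pytest.approx(0.0, abs=1e-12)

    def test_zero_enzyme_means_zero_flux(self, kinetic_model, fitted, rng):
        c = _concentrations(rng)
        for law in kinetic_model.rate_laws.values():
            assert evaluate_rate(law, 0.0, c, fitted[0]) == 0.0

    def test_missing_metabolite_is_named(self, kinetic_model, fitted):
        with pytest.raises(RateLawError, match="pyr"):
            evaluate_rate(kinetic_model.rate_laws["PTS"], 1.0,
                          {"pep": 1.0}, fitted[0])

    def test_zero_denominator_is_a_domain_error(self, kinetic_model,
                                                fitted):
        with pytest.raises(RateLawError, match="pyr"):
            evaluate_rate(kinetic_model.rate_laws["PTS"], 1.0,
                          {"pep": 1.0, "pyr": 0.0}, fitted[0])

    def test_homogeneity_in_enzyme_level(self, kinetic_model, fitted, rng):
        c = _concentrations(rng)
        for law in kinetic_model.rate_laws.values():
            v1 = evaluate_rate(law, 1.0, c, fitted[0])
            for alpha in (0.0, 0.25, 3.7):
                assert evaluate_rate(law, alpha, c, fitted[0]) == \
                    pytest.approx(alpha * v1, rel=1e-12, abs=1e-300)

    def test_callables_agree_with_expression_strings(self, kinetic_model,
                                                     fitted, rng):
        """The hand-written law callables are cross-checked against an
        independent sympy parse of their expression strings."""
        c = _concentrations(rng)
        syms = {f"c_{m}": val for m, val in c.items()}
        for law in kinetic_model.rate_laws.values():
            expr = sympy.parse_expr(law.expression)
            subs = {}
            for s in expr.free_symbols:
                if s.name.startswith("c_"):
                    subs[s] = syms[s.name]
                else:
                    subs[s] = fitted[0][s.name]
            expected = float(expr.evalf(subs=subs))
            assert law.f(c, fitted[0].values) == pytest.approx(
                expected, rel=1e-9)

    def test_irreversible_laws_nonnegative_on_biological_box(
            self, kinetic_model, fitted, rng):
        for _ in range(200):
            c = _concentrations(rng)
            for rxn in IRREVERSIBLE_LAWS:
                law = kinetic_model.rate_laws[rxn]
                assert law.f(c, fitted[0].values) >= 0

    def test_reversible_sign_flips_exactly_at_equilibrium(
            self, kinetic_model, fitted, rng):
        """Sweeping one product concentration across the equilibrium
        point changes the sign of every reversible law's rate."""
        for rxn, law in kinetic_model.rate_laws.items():
            if law.irreversible:
                continue
            c = _concentrations(rng)
            # pick the product with positive net stoichiometry
            prod = next(m for m, s in law.net_stoichiometry.items()
                        if s > 0)
            keq = fitted[0][law.keq_name]
            # solve for the product value at equilibrium given others
            from scipy.optimize import brentq

            def h(t, _c=dict(c), _m=prod, _law=law):
                _c[_m] = t
                return _law.f(_c, fitted[0].values)

            lo, hi = 1e-8, 1e8
            if h(lo) * h(hi) > 0:
                continue  # equilibrium outside the sweep for this draw
            root = brentq(h, lo, hi)
            assert h(root * 0.99) * h(root * 1.01) < 0


class TestAdenylateEnergyCharge:
    @pytest.mark.parametrize("atp, adp, amp, expected", [
        (1.0, 0.0, 0.0, 1.0),
        (0.0, 0.0, 1.0, 0.0),
        (0.8, 0.4, 0.0, 5.0 / 6.0),
    ])
    def test_reference_points(self, atp, adp, amp, expected):
        assert adenylate_energy_charge(atp, adp, amp) == \
            pytest.approx(expected)

    def test_all_zero_pool_is_undefined(self):
        with pytest.raises(ValueError):
            adenylate_energy_charge(0.0, 0.0, 0.0)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.floats(0, 10), st.floats(0, 10), st.floats(0, 10))
    def test_charge_stays_in_unit_interval(self, atp, adp, amp):
        if atp + adp + amp == 0:
            return
        aec = adenylate_energy_charge(atp, adp, amp)
        assert 0.0 <= aec <= 1.0


class TestSerialization:
    def test_json_round_trip_reproduces_rates(self, kinetic_model, fitted,
                                              tmp_path, rng):
        path = tmp_path / "model.json"
        kinetic_model.to_json(path)
        loaded = kinfba.KineticModel.from_json(path)
        assert loaded.n_parameters == 36
        c = _concentrations(rng)
        for rxn, law in kinetic_model.rate_laws.items():
            assert loaded.rate_laws[rxn].f(c, fitted[0].values) == \
                pytest.approx(law.f(c, fitted[0].values), rel=1e-9)

    def test_sbml_export_round_trips_parameters(self, kinetic_model,
                                                fitted, tmp_path):
        from kinfba.rate_laws import export_sbml, import_sbml_parameters

        path = tmp_path / "kinetic.xml"
        export_sbml(kinetic_model, fitted[0], path)
        values = import_sbml_parameters(path)
        assert len(values) == 36
        for name, val in fitted[0].values.items():
            assert values[name] == pytest.approx(val, rel=1e-12)
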