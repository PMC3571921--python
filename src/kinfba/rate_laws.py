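"""Simplified kinetic model of E. coli central carbon metabolism.

Each reaction in the kinetic model carries a rate law of the form

    v = e * f(c; theta)

where ``e`` is the enzyme concentration (mg protein/gDCW), ``c`` a map of
metabolite concentrations (mM) and ``theta`` the kinetic parameters.  Three
parameter kinds appear: catalytic rate constants (kcat), equilibrium
constants (Keq) and binding coefficients (Km).  Equilibrium constants are
bounded to 0.35-2.85 times a reference (in vitro) value, all other
parameters to the global box [1e-6, 1e4] in their own units.

The shipped model covers 19 reactions of glycolysis, the PTS and the
pentose phosphate pathway with 36 distinct parameters, together with the
fitted values and 95% confidence half-widths used as the reference
parameter set throughout the package.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np

GLOBAL_LB = 1e-6
GLOBAL_UB = 1e4
KEQ_LB_FACTOR = 0.35
KEQ_UB_FACTOR = 2.85

#: metabolite namespace of the kinetic model (concentrations in mM)
METABOLITE_IDS = (
    "glc", "g6p", "f6p", "fdp", "dhap", "gap", "13dpg", "3pg", "2pg", "pep",
    "pyr", "6pg", "ru5pD", "xu5pD", "r5p", "s7p", "e4p", "atp", "adp", "amp",
    "nad", "nadh", "nadp", "nadph",
)


class RateLawError(ValueError):
    """Raised for missing metabolites or singular concentrations."""


@dataclass(frozen=True)
class ParameterSpec:
    """Typed declaration of one kinetic parameter."""

    name: str
    kind: str  # "kcat" | "Keq" | "Km"
    units: str
    global_lb: float = GLOBAL_LB
    global_ub: float = GLOBAL_UB
    keq_reference: float | None = None

    def __post_init__(self):
        if self.kind not in ("kcat", "Keq", "Km"):
            raise ValueError(f"unknown parameter kind {self.kind!r}")
        if self.kind == "Keq" and self.keq_reference is not None:
            object.__setattr__(self, "global_lb",
                               KEQ_LB_FACTOR * self.keq_reference)
            object.__setattr__(self, "global_ub",
                               KEQ_UB_FACTOR * self.keq_reference)
        if not self.global_lb < self.global_ub:
            raise ValueError(f"{self.name}: lb must be < ub")


@dataclass
class ParameterSet:
    """A concrete assignment of values to parameter specs."""

    values: dict[str, float]
    provenance: str = ""

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    def subset(self, names) -> dict[str, float]:
        return {n: self.values[n] for n in names}


@dataclass
class RateLaw:
    """One reaction's mechanistic factor f(c; theta).

    ``f`` evaluates the factor (without the enzyme level); ``expression``
    is an equivalent sympy-parsable string over symbols ``c_<met>`` and the
    parameter names, used for serialization, SBML export and as an
    independent cross-check of the callable.  ``km_roles`` records, for each
    binding coefficient, the metabolite it binds, the exponent on the
    concentration and whether it acts in a saturating denominator or as an
    activation multiplier.  ``net_stoichiometry`` is the net transformation
    whose mass-action ratio the law's Keq refers to (reversible laws only).
    """

    reaction_id: str
    f: Callable[[Mapping[str, float], Mapping[str, float]], float]
    expression: str
    required_metabolites: tuple[str, ...]
    parameters: tuple[str, ...]
    irreversible: bool
    positive_metabolites: tuple[str, ...] = ()  # denominators: must be > 0
    km_roles: dict[str, tuple[str, int, str]] = field(default_factory=dict)
    net_stoichiometry: dict[str, float] = field(default_factory=dict)

    @property
    def keq_name(self) -> str | None:
        for p in self.parameters:
            if p.startswith("Keq_"):
                return p
        return None

    def __call__(self, c, params):
        return self.f(c, params)


@dataclass
class KineticModel:
    """The set K of reactions with rate laws plus the parameter registry."""

    rate_laws: dict[str, RateLaw]
    specs: dict[str, ParameterSpec]
    metabolite_ids: tuple[str, ...] = METABOLITE_IDS

    @property
    def reactions(self) -> list[str]:
        return list(self.rate_laws)

    @property
    def n_parameters(self) -> int:
        seen = set()
        for law in self.rate_laws.values():
            seen.update(law.parameters)
        return len(seen)

    def parameter_names(self) -> list[str]:
        names: list[str] = []
        for law in self.rate_laws.values():
            for p in law.parameters:
                if p not in names:
                    names.append(p)
        return names

    def validate_parameters(self, params: ParameterSet) -> None:
        for name, value in params.values.items():
            spec = self.specs[name]
            if not (spec.global_lb <= value <= spec.global_ub):
                raise ValueError(
                    f"{name}={value} outside [{spec.global_lb}, "
                    f"{spec.global_ub}]")

    def to_json(self, path) -> None:
        payload = {
            "metabolite_ids": list(self.metabolite_ids),
            "rate_laws": [
                {
                    "reaction_id": law.reaction_id,
                    "expression": law.expression,
                    "required_metabolites": list(law.required_metabolites),
                    "parameters": list(law.parameters),
                    "irreversible": law.irreversible,
                    "positive_metabolites": list(law.positive_metabolites),
                    "km_roles": {k: list(v) for k, v in law.km_roles.items()},
                    "net_stoichiometry": law.net_stoichiometry,
                }
                for law in self.rate_laws.values()
            ],
            "specs": [
                {
                    "name": s.name, "kind": s.kind, "units": s.units,
                    "global_lb": s.global_lb, "global_ub": s.global_ub,
                    "keq_reference": s.keq_reference,
                }
                for s in self.specs.values()
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "KineticModel":
        """Rebuild a model from the JSON schema, compiling expressions."""
        import sympy

        with open(path) as fh:
            payload = json.load(fh)
        specs = {}
        for s in payload["specs"]:
            spec = ParameterSpec(s["name"], s["kind"], s["units"],
                                 keq_reference=s["keq_reference"])
            if s["keq_reference"] is None:
                spec = ParameterSpec(s["name"], s["kind"], s["units"],
                                     s["global_lb"], s["global_ub"])
            specs[spec.name] = spec
        laws = {}
        for entry in payload["rate_laws"]:
            expr = sympy.parse_expr(entry["expression"])
            symbols = sorted(expr.free_symbols, key=lambda s: s.name)
            fn = sympy.lambdify(symbols, expr, "numpy")
            names = [s.name for s in symbols]
            mets = entry["required_metabolites"]
            pars = entry["parameters"]

            def f(c, p, _fn=fn, _names=names, _mets=mets, _pars=pars):
                args = []
                for nm in _names:
                    if nm.startswith("c_"):
                        args.append(c[nm[2:]])
                    else:
                        args.append(p[nm])
                return _fn(*args)

            laws[entry["reaction_id"]] = RateLaw(
                reaction_id=entry["reaction_id"],
                f=f,
                expression=entry["expression"],
                required_metabolites=tuple(mets),
                parameters=tuple(pars),
                irreversible=entry["irreversible"],
                positive_metabolites=tuple(entry["positive_metabolites"]),
                km_roles={k: tuple(v) for k, v in entry["km_roles"].items()},
                net_stoichiometry=entry["net_stoichiometry"],
            )
        return cls(rate_laws=laws, specs=specs,
                   metabolite_ids=tuple(payload["metabolite_ids"]))


# --------------------------------------------------------------------------
# fitted reference values: (reaction, kind-or-km-name) -> (value, halfwidth,
# units).  kcat units make fluxes come out in mmol/gDW/h when enzymes are in
# mg protein/gDCW and concentrations in mM.
# --------------------------------------------------------------------------
FITTED_VALUES: dict[tuple[str, str], tuple[float, float, str]] = {
    ("PTS", "kcat"): (20.7, 9.1, "mmol/mg protein/hr"),
    ("PGI", "kcat"): (40.2, 9.5, "mmol/mg protein/hr"),
    ("PGI", "Keq"): (1.23, 0.29, "dimensionless"),
    ("PFK", "kcat"): (26.0, 35.0, "mmol/mg protein/mM/hr"),
    ("ALDO", "kcat"): (3.965, 0.010, "mmol/mg protein/mM/hr"),
    ("ALDO", "Keq"): (0.18, 0.17, "mM"),
    ("ALDO", "Km_fdp"): (0.0074, 0.0036, "mM"),
    ("TPI", "kcat"): (10000.0, 14000.0, "mmol/mg protein/hr"),
    ("TPI", "Keq"): (0.11400, 0.00031, "dimensionless"),
    ("GAPD", "kcat"): (10000.0, 4100.0, "mmol/mg protein/mM^2/hr"),
    ("GAPD", "Keq"): (1.21, 0.14, "dimensionless"),
    ("PGM", "kcat"): (9995.0, 40.0, "mmol/mg protein/hr"),
    ("PGM", "Keq"): (0.53570, 0.00063, "dimensionless"),
    ("PGK", "kcat"): (54.3, 2.9, "mmol/mg protein/hr"),
    ("PGK", "Keq"): (5512.1, 1.2, "dimensionless"),
    ("ENO", "kcat"): (2.0, 45.0, "mmol/mg protein/mM/hr"),
    ("ENO", "Keq"): (1.4, 4.1, "dimensionless"),
    ("PYK", "kcat"): (40.0, 49.0, "mmol/mg protein/hr"),
    ("PDH", "kcat"): (10.4, 4.6, "mmol/mg protein/hr"),
    ("PDH", "Km_pyr"): (0.000020, 0.000029, "mM^4"),
    ("PPC", "kcat"): (2.15, 1.80, "mmol/mg protein/hr"),
    ("PPC", "Km_fdp"): (2.5, 6.5, "mM"),
    ("PPC", "Km_pep"): (0.10, 0.16, "mM"),
    ("G6PDH", "kcat"): (859.6, 1.1, "mmol/mg protein/mM^2/hr"),
    ("GND", "kcat"): (18.5, 10.8, "mmol*mM/mg protein/hr"),
    ("GND", "Km_6pg"): (0.021, 0.012, "mM"),
    ("RPI", "kcat"): (549.46, 0.69, "mmol/mg protein/mM/hr"),
    ("RPI", "Keq"): (1.40000, 0.00019, "dimensionless"),
    ("RPE", "kcat"): (10000.0, 13000.0, "mmol/mg protein/mM/hr"),
    ("RPE", "Keq"): (0.4900, 0.0044, "dimensionless"),
    ("TKT1", "kcat"): (10000.0, 7800.0, "mmol/mg protein/mM^2/hr"),
    ("TKT1", "Keq"): (1.99, 0.012, "dimensionless"),
    ("TKT2", "kcat"): (10000.0, 5800.0, "mmol/mg protein/mM^2/hr"),
    ("TKT2", "Keq"): (3.500, 0.013, "dimensionless"),
    ("TALA", "kcat"): (10000.0, 2300.0, "mmol/mg protein/mM^2/hr"),
    ("TALA", "Keq"): (0.3675, 0.0021, "dimensionless"),
}

IRREVERSIBLE_LAWS = ("PTS", "PFK", "PYK", "PDH", "PPC", "G6PDH", "GND")


def _param_name(rxn: str, key: str) -> str:
    # ("ALDO", "Km_fdp") -> "Km_fdp_ALDO"; ("PGI", "Keq") -> "Keq_PGI"
    return f"{key}_{rxn}"


def build_simplified_model(keq_references: Mapping[str, float] | None = None,
                           ) -> KineticModel:
    """Construct the 19-reaction simplified kinetic model.

    Parameters
    ----------
    keq_references
        Optional map reaction id -> reference equilibrium constant used to
        bracket the Keq parameters (0.35x to 2.85x).  By default the fitted
        reference values are used.
    """
    defs = _law_definitions()
    specs: dict[str, ParameterSpec] = {}
    laws: dict[str, RateLaw] = {}
    for rxn, d in defs.items():
        pnames = []
        for key in d["parameters"]:
            name = _param_name(rxn, key)
            kind = "Keq" if key == "Keq" else ("kcat" if key == "kcat"
                                               else "Km")
            units = FITTED_VALUES[(rxn, key)][2]
            if kind == "Keq":
                ref = (keq_references or {}).get(
                    rxn, FITTED_VALUES[(rxn, "Keq")][0])
                specs[name] = ParameterSpec(name, kind, units,
                                            keq_reference=ref)
            else:
                specs[name] = ParameterSpec(name, kind, units)
            pnames.append(name)
        laws[rxn] = RateLaw(
            reaction_id=rxn,
            f=d["f"],
            expression=d["expression"],
            required_metabolites=tuple(d["metabolites"]),
            parameters=tuple(pnames),
            irreversible=rxn in IRREVERSIBLE_LAWS,
            positive_metabolites=tuple(d.get("positive", ())),
            km_roles=d.get("km_roles", {}),
            net_stoichiometry=d.get("net", {}),
        )
    return KineticModel(rate_laws=laws, specs=specs)


def _law_definitions():
    """Hand-written callables plus equivalent expression strings."""

    def pts(c, p):
        return p["kcat_PTS"] * c["pep"] / c["pyr"]

    def pgi(c, p):
        return p["kcat_PGI"] * (1 - c["f6p"] / (c["g6p"] * p["Keq_PGI"]))

    def pfk(c, p):
        return p["kcat_PFK"] * c["atp"]

    def aldo(c, p):
        return (p["kcat_ALDO"]
                * (c["fdp"] - c["gap"] * c["dhap"] / p["Keq_ALDO"])
                / (p["Km_fdp_ALDO"] + c["fdp"]))

    def tpi(c, p):
        return p["kcat_TPI"] * (1 - c["gap"] / (c["dhap"] * p["Keq_TPI"]))

    def gapd(c, p):
        return p["kcat_GAPD"] * (c["nad"] * c["gap"]
                                 - c["13dpg"] * c["nadh"] / p["Keq_GAPD"])

    def pgk(c, p):
        return p["kcat_PGK"] * (1 - c["atp"] * c["3pg"]
                                / (c["adp"] * c["13dpg"] * p["Keq_PGK"]))

    def pgm(c, p):
        return p["kcat_PGM"] * (1 - c["2pg"] / (c["3pg"] * p["Keq_PGM"]))

    def eno(c, p):
        return p["kcat_ENO"] * (c["2pg"] - c["pep"] / p["Keq_ENO"])

    def pyk(c, p):
        return p["kcat_PYK"] * c["adp"] / c["atp"]

    def pdh(c, p):
        return (p["kcat_PDH"] * c["pyr"] ** 4
                / (p["Km_pyr_PDH"] + c["pyr"] ** 4))

    def ppc(c, p):
        return (p["kcat_PPC"] * c["pep"]
                * (1 + c["fdp"] / p["Km_fdp_PPC"])
                / (p["Km_pep_PPC"] + c["pep"]))

    def g6pdh(c, p):
        return p["kcat_G6PDH"] * c["nadp"] * c["g6p"]

    def gnd(c, p):
        return (p["kcat_GND"] * c["nadp"] * c["6pg"]
                / (c["nadph"] * c["atp"] * (p["Km_6pg_GND"] + c["6pg"])))

    def rpe(c, p):
        return p["kcat_RPE"] * (c["ru5pD"] - c["xu5pD"] / p["Keq_RPE"])

    def rpi(c, p):
        return p["kcat_RPI"] * (c["ru5pD"] - c["r5p"] / p["Keq_RPI"])

    def tkt1(c, p):
        return p["kcat_TKT1"] * (c["r5p"] * c["xu5pD"]
                                 - c["s7p"] * c["gap"] / p["Keq_TKT1"])

    def tkt2(c, p):
        return p["kcat_TKT2"] * (c["xu5pD"] * c["e4p"]
                                 - c["f6p"] * c["gap"] / p["Keq_TKT2"])

    def tala(c, p):
        return p["kcat_TALA"] * (c["gap"] * c["s7p"]
                                 - c["e4p"] * c["f6p"] / p["Keq_TALA"])

    return {
        "PTS": dict(
            f=pts, expression="kcat_PTS*c_pep/c_pyr",
            metabolites=["pep", "pyr"], parameters=["kcat"],
            positive=["pyr"]),
        "PGI": dict(
            f=pgi, expression="kcat_PGI*(1 - c_f6p/(c_g6p*Keq_PGI))",
            metabolites=["f6p", "g6p"], parameters=["kcat", "Keq"],
            positive=["g6p"], net={"g6p": -1, "f6p": 1}),
        "PFK": dict(
            f=pfk, expression="kcat_PFK*c_atp",
            metabolites=["atp"], parameters=["kcat"]),
        "ALDO": dict(
            f=aldo,
            expression=("kcat_ALDO*(c_fdp - c_gap*c_dhap/Keq_ALDO)"
                        "/(Km_fdp_ALDO + c_fdp)"),
            metabolites=["fdp", "gap", "dhap"],
            parameters=["kcat", "Keq", "Km_fdp"],
            km_roles={"Km_fdp_ALDO": ("fdp", 1, "denominator")},
            net={"fdp": -1, "gap": 1, "dhap": 1}),
        "TPI": dict(
            f=tpi, expression="kcat_TPI*(1 - c_gap/(c_dhap*Keq_TPI))",
            metabolites=["gap", "dhap"], parameters=["kcat", "Keq"],
            positive=["dhap"], net={"dhap": -1, "gap": 1}),
        "GAPD": dict(
            f=gapd,
            expression=("kcat_GAPD*(c_nad*c_gap "
                        "- c_13dpg*c_nadh/Keq_GAPD)"),
            metabolites=["nad", "gap", "13dpg", "nadh"],
            parameters=["kcat", "Keq"],
            net={"gap": -1, "nad": -1, "13dpg": 1, "nadh": 1}),
        "PGK": dict(
            f=pgk,
            expression=("kcat_PGK*(1 - c_atp*c_3pg"
                        "/(c_adp*c_13dpg*Keq_PGK))"),
            metabolites=["atp", "3pg", "adp", "13dpg"],
            parameters=["kcat", "Keq"], positive=["adp", "13dpg"],
            net={"13dpg": -1, "adp": -1, "3pg": 1, "atp": 1}),
        "PGM": dict(
            f=pgm, expression="kcat_PGM*(1 - c_2pg/(c_3pg*Keq_PGM))",
            metabolites=["2pg", "3pg"], parameters=["kcat", "Keq"],
            positive=["3pg"], net={"3pg": -1, "2pg": 1}),
        "ENO": dict(
            f=eno, expression="kcat_ENO*(c_2pg - c_pep/Keq_ENO)",
            metabolites=["2pg", "pep"], parameters=["kcat", "Keq"],
            net={"2pg": -1, "pep": 1}),
        "PYK": dict(
            f=pyk, expression="kcat_PYK*c_adp/c_atp",
            metabolites=["adp", "atp"], parameters=["kcat"],
            positive=["atp"]),
        "PDH": dict(
            f=pdh,
            expression="kcat_PDH*c_pyr**4/(Km_pyr_PDH + c_pyr**4)",
            metabolites=["pyr"], parameters=["kcat", "Km_pyr"],
            km_roles={"Km_pyr_PDH": ("pyr", 4, "denominator")}),
        "PPC": dict(
            f=ppc,
            expression=("kcat_PPC*c_pep*(1 + c_fdp/Km_fdp_PPC)"
                        "/(Km_pep_PPC + c_pep)"),
            metabolites=["pep", "fdp"],
            parameters=["kcat", "Km_fdp", "Km_pep"],
            km_roles={"Km_fdp_PPC": ("fdp", 1, "activation"),
                      "Km_pep_PPC": ("pep", 1, "denominator")}),
        "G6PDH": dict(
            f=g6pdh, expression="kcat_G6PDH*c_nadp*c_g6p",
            metabolites=["nadp", "g6p"], parameters=["kcat"]),
        "GND": dict(
            f=gnd,
            expression=("kcat_GND*c_nadp*c_6pg"
                        "/(c_nadph*c_atp*(Km_6pg_GND + c_6pg))"),
            metabolites=["nadp", "6pg", "nadph", "atp"],
            parameters=["kcat", "Km_6pg"],
            positive=["nadph", "atp"],
            km_roles={"Km_6pg_GND": ("6pg", 1, "denominator")}),
        "RPE": dict(
            f=rpe, expression="kcat_RPE*(c_ru5pD - c_xu5pD/Keq_RPE)",
            metabolites=["ru5pD", "xu5pD"], parameters=["kcat", "Keq"],
            net={"ru5pD": -1, "xu5pD": 1}),
        "RPI": dict(
            f=rpi, expression="kcat_RPI*(c_ru5pD - c_r5p/Keq_RPI)",
            metabolites=["ru5pD", "r5p"], parameters=["kcat", "Keq"],
            net={"ru5pD": -1, "r5p": 1}),
        "TKT1": dict(
            f=tkt1,
            expression=("kcat_TKT1*(c_r5p*c_xu5pD "
                        "- c_s7p*c_gap/Keq_TKT1)"),
            metabolites=["r5p", "xu5pD", "s7p", "gap"],
            parameters=["kcat", "Keq"],
            net={"r5p": -1, "xu5pD": -1, "s7p": 1, "gap": 1}),
        "TKT2": dict(
            f=tkt2,
            expression=("kcat_TKT2*(c_xu5pD*c_e4p "
                        "- c_f6p*c_gap/Keq_TKT2)"),
            metabolites=["xu5pD", "e4p", "f6p", "gap"],
            parameters=["kcat", "Keq"],
            net={"xu5pD": -1, "e4p": -1, "f6p": 1, "gap": 1}),
        "TALA": dict(
            f=tala,
            expression=("kcat_TALA*(c_gap*c_s7p "
                        "- c_e4p*c_f6p/Keq_TALA)"),
            metabolites=["gap", "s7p", "e4p", "f6p"],
            parameters=["kcat", "Keq"],
            net={"gap": -1, "s7p": -1, "e4p": 1, "f6p": 1}),
    }


def load_fitted_parameters() -> tuple[ParameterSet, dict[str, float]]:
    """Return the fitted reference parameter set and 95% CI half-widths."""
    values, half = {}, {}
    for (rxn, key), (val, hw, _units) in FITTED_VALUES.items():
        name = _param_name(rxn, key)
        values[name] = val
        half[name] = hw
    return (ParameterSet(values, provenance="fitted reference values"),
            half)


def evaluate_rate(law: RateLaw, e: float, c: Mapping[str, float],
                  params: ParameterSet | Mapping[str, float]) -> float:
    """Evaluate v = e * f(c; theta) in mmol/gDW/h."""
    if e < 0:
        raise RateLawError(f"{law.reaction_id}: enzyme concentration "
                           f"must be >= 0, got {e}")
    p = params.values if isinstance(params, ParameterSet) else params
    for m in law.required_metabolites:
        if m not in c:
            raise RateLawError(
                f"{law.reaction_id}: missing required metabolite {m!r}")
    for m in law.positive_metabolites:
        if c[m] <= 0:
            raise RateLawError(
                f"{law.reaction_id}: concentration of {m!r} must be > 0")
    return e * law.f(c, p)


def adenylate_energy_charge(c_atp: float, c_adp: float,
                            c_amp: float) -> float:
    """(ATP + ADP/2) / (ATP + ADP + AMP), dimensionless in [0, 1]."""
    if min(c_atp, c_adp, c_amp) < 0:
        raise ValueError("adenylate concentrations must be >= 0")
    total = c_atp + c_adp + c_amp
    if total == 0:
        raise ValueError("adenylate energy charge undefined for an "
                         "all-zero adenylate pool")
    return (c_atp + 0.5 * c_adp) / total


def atp_for_energy_charge(aec: float, c_adp: float, c_amp: float) -> float:
    """ATP concentration that yields the given energy charge exactly."""
    if not 0 < aec < 1:
        raise ValueError("energy charge must be in (0, 1) to invert")
    return (aec * (c_adp + c_amp) - 0.5 * c_adp) / (1.0 - aec)


def export_sbml(model: KineticModel, params: ParameterSet, path) -> None:
    """Write the kinetic model as an SBML document with kinetic laws."""
    import libsbml

    doc = libsbml.SBMLDocument(3, 2)
    sb = doc.createModel("simplified_kinetic_model")
    comp = sb.createCompartment()
    comp.setId("c")
    comp.setConstant(True)
    seen = set()
    for law in model.rate_laws.values():
        for m in law.required_metabolites:
            if m in seen:
                continue
            seen.add(m)
            sp = sb.createSpecies()
            sp.setId(f"c_{m}")
            sp.setCompartment("c")
            sp.setHasOnlySubstanceUnits(False)
            sp.setBoundaryCondition(False)
            sp.setConstant(False)
        sp = sb.createSpecies()
        sp.setId(f"e_{law.reaction_id}")
        sp.setCompartment("c")
        sp.setHasOnlySubstanceUnits(False)
        sp.setBoundaryCondition(True)
        sp.setConstant(False)
    for law in model.rate_laws.values():
        rx = sb.createReaction()
        rx.setId(law.reaction_id)
        rx.setReversible(not law.irreversible)
        for m, s in (law.net_stoichiometry or
                     {m: 0.0 for m in law.required_metabolites}).items():
            ref = rx.createReactant() if s < 0 else rx.createProduct()
            ref.setSpecies(f"c_{m}")
            ref.setStoichiometry(abs(s) or 1.0)
            ref.setConstant(True)
        kl = rx.createKineticLaw()
        ast = libsbml.parseL3Formula(
            f"e_{law.reaction_id} * ({law.expression})")
        kl.setMath(ast)
        for pname in law.parameters:
            lp = kl.createLocalParameter()
            lp.setId(pname)
            lp.setValue(float(params.values[pname]))
    libsbml.writeSBMLToFile(doc, str(path))


def import_sbml_parameters(path) -> dict[str, float]:
    """Read kinetic-law local parameter values back from an SBML export."""
    import libsbml

    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR):
        raise ValueError(doc.getError(0).getMessage())
    out: dict[str, float] = {}
    sb = doc.getModel()
    for i in range(sb.getNumReactions()):
        kl = sb.getReaction(i).getKineticLaw()
        if kl is None:
            continue
        for j in range(kl.getNumLocalParameters()):
            lp = kl.getLocalParameter(j)
            out[lp.getId()] = lp.getValue()
    return out
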