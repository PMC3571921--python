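"""Distance-from-equilibrium analysis and metabolite effects on enzymes.

Standard Gibbs free energy changes follow from fitted equilibrium
constants, dG0 = -RT ln Keq, with concentrations expressed in mM (the
same convention the kinetic model's Keq values use; the choice of
standard state cancels between conditions for balanced reactions).
Condition-specific values add the concentration term,
dG* = dG0 + RT * sum_i S_ij ln(c_i), and a reaction whose mean dG* is
below -10 kJ/mol is classified as operating far from equilibrium.
Water and protons are not part of the kinetic model and never enter the
concentration sum.  Irreversible rate laws carry no Keq and are excluded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .rate_laws import KineticModel, ParameterSet

R_KJ = 8.3145e-3  # kJ/mol/K
DEFAULT_T = 298.15  # K
FAR_THRESHOLD = -10.0  # kJ/mol
NEAR_WINDOW = (-2.0, 0.0)  # kJ/mol

NOT_COMPUTABLE = None


@dataclass
class ThermoResult:
    reaction_id: str
    dG_standard: float
    dG_star: dict[str, float | None] = field(default_factory=dict)

    @property
    def computable(self) -> list[float]:
        return [v for v in self.dG_star.values() if v is not None]

    @property
    def mean(self) -> float:
        vals = self.computable
        return float(np.mean(vals)) if vals else float("nan")

    @property
    def sd(self) -> float:
        vals = self.computable
        return float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0

    @property
    def far_from_equilibrium(self) -> bool:
        return bool(self.computable) and self.mean < FAR_THRESHOLD


@dataclass(frozen=True)
class MetaboliteEffect:
    enzyme_id: str
    metabolite_id: str
    mode: str  # "inhibition" | "activation"
    strength: str  # "strong" | "intermediate"
    median_ratio: float  # median concentration^exponent / Km


def delta_g_standard(keq: float, temperature: float = DEFAULT_T) -> float:
    """-RT ln Keq in kJ/mol."""
    if keq <= 0:
        raise ValueError(f"Keq must be > 0, got {keq}")
    if temperature <= 0:
        raise ValueError("temperature must be > 0 K")
    return -R_KJ * temperature * math.log(keq)


def delta_g_condition(stoichiometry: dict[str, float], dG_standard: float,
                      c: dict[str, float],
                      temperature: float = DEFAULT_T) -> float | None:
    """dG* = dG0 + RT sum_i S_ij ln c_i (c in mM); None when a
    participating concentration is missing."""
    total = 0.0
    for met, coeff in stoichiometry.items():
        if coeff == 0:
            continue
        value = c.get(met)
        if value is None or (isinstance(value, float)
                             and math.isnan(value)):
            return NOT_COMPUTABLE
        if value <= 0:
            raise ValueError(f"concentration of {met!r} must be > 0")
        total += coeff * math.log(value)
    return dG_standard + R_KJ * temperature * total


def reaction_thermo(model: KineticModel, params: ParameterSet,
                    c_by_condition: dict[str, dict[str, float]],
                    temperature: float = DEFAULT_T) -> dict[str, ThermoResult]:
    """ThermoResult per reversible kinetic reaction across conditions."""
    out: dict[str, ThermoResult] = {}
    for rxn, law in model.rate_laws.items():
        keq_name = law.keq_name
        if law.irreversible or keq_name is None:
            continue
        dg0 = delta_g_standard(params.values[keq_name], temperature)
        res = ThermoResult(rxn, dg0)
        for cid, c in c_by_condition.items():
            res.dG_star[cid] = delta_g_condition(
                law.net_stoichiometry, dg0, c, temperature)
        out[rxn] = res
    return out


def classify_equilibrium(results: dict[str, ThermoResult],
                         threshold: float = FAR_THRESHOLD) -> dict[str, dict]:
    """Label each reaction far / near / intermediate / unclassified."""
    report = {}
    for rxn, res in results.items():
        if not res.computable:
            label = "unclassified"
        elif res.mean < threshold:
            label = "far"
        elif NEAR_WINDOW[0] <= res.mean <= NEAR_WINDOW[1]:
            label = "near"
        else:
            label = "intermediate"
        report[rxn] = {
            "classification": label,
            "mean_dG_star": res.mean,
            "sd_dG_star": res.sd,
            "n_conditions": len(res.computable),
            "dG_standard": res.dG_standard,
        }
    return report


def classify_metabolite_effects(
        model: KineticModel, params: ParameterSet,
        c_by_condition: dict[str, dict[str, float]],
        strong_band: tuple[float, float] = (0.1, 10.0),
) -> list[MetaboliteEffect]:
    """Compare binding coefficients with concentration estimates.

    A binding coefficient acting as an activation multiplier (1 + c/Km)
    reports an activation effect; one acting in a saturating denominator
    reports inhibition.  The effect is strong when the median ratio
    c^n / Km falls outside ``strong_band`` (same order of magnitude =>
    intermediate).
    """
    effects = []
    for rxn, law in model.rate_laws.items():
        for pname, (met, exponent, role) in law.km_roles.items():
            km_val = params.values.get(pname)
            if km_val is None or km_val <= 0:
                continue
            ratios = [c[met] ** exponent / km_val
                      for c in c_by_condition.values()
                      if met in c and c[met] is not None
                      and not (isinstance(c[met], float)
                               and math.isnan(c[met]))]
            if not ratios:
                continue
            med = float(np.median(ratios))
            mode = "activation" if role == "activation" else "inhibition"
            strength = ("intermediate"
                        if strong_band[0] <= med <= strong_band[1]
                        else "strong")
            effects.append(MetaboliteEffect(rxn, met, mode, strength, med))
    return effects
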