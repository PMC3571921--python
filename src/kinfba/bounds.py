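"""Kinetic flux bounds from concentrations and parameter confidence boxes.

For a test condition with measured enzyme and metabolite concentrations,
each rate law's flux range is

    v_min = min over theta in CI box of e * f(c; theta)
    v_max = max likewise,

with the CI box truncated at the global parameter bounds.  Every shipped
rate law is monotone in each of its parameters at fixed concentrations
(kcat scales the law, Keq only appears in a single -X/Keq term, binding
coefficients only in a denominator or a (1 + c/Km) multiplier), so the
extrema are attained at vertices of the box and vertex enumeration is
exact; tests verify this against a dense parameter grid.  Unmeasured ATP
is ranged over the interval consistent with the adenylate energy charge
constraint, which widens the bounds accordingly.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

from .estimation import ConfidenceIntervals
from .omics import ConditionRecord
from .rate_laws import KineticModel, RateLaw, atp_for_energy_charge


@dataclass
class FluxBoundSet:
    """(v_min, v_max) per (condition, reaction), with provenance notes."""

    bounds: dict[tuple[str, str], tuple[float, float]] = \
        field(default_factory=dict)
    provenance: dict[tuple[str, str], str] = field(default_factory=dict)

    def for_condition(self, cid: str) -> dict[str, tuple[float, float]]:
        return {rxn: b for (c, rxn), b in self.bounds.items() if c == cid}

    def add(self, cid: str, rxn: str, vmin: float, vmax: float,
            note: str = "") -> None:
        if vmin > vmax:
            vmin, vmax = vmax, vmin
        self.bounds[(cid, rxn)] = (vmin, vmax)
        if note:
            self.provenance[(cid, rxn)] = note


def flux_range(law: RateLaw, e: float, c: dict[str, float],
               ci: ConfidenceIntervals | dict[str, tuple[float, float]],
               extra_ranges: dict[str, tuple[float, float]] | None = None,
               ) -> tuple[float, float]:
    """Range of e * f(c; theta) over the parameter CI box.

    ``extra_ranges`` may add concentration intervals (e.g. unmeasured ATP)
    that are enumerated together with the parameter box.
    """
    if e < 0:
        raise ValueError("enzyme concentration must be >= 0")
    box = ci.box(law.parameters) if isinstance(ci, ConfidenceIntervals) \
        else {p: ci[p] for p in law.parameters}
    for p, (lo, hi) in box.items():
        if lo > hi:
            raise ValueError(f"empty CI box for {p}")
    if e == 0:
        return (0.0, 0.0)
    extra = dict(extra_ranges or {})
    names = list(box) + list(extra)
    intervals = [box[p] for p in box] + [extra[m] for m in extra]
    vmin, vmax = math.inf, -math.inf
    for vertex in itertools.product(*[(lo, hi) if lo != hi else (lo,)
                                      for lo, hi in intervals]):
        params = {}
        conc = dict(c)
        for name, value in zip(names, vertex):
            if name in box:
                params[name] = value
            else:
                conc[name] = value
        v = e * law.f(conc, params)
        vmin = min(vmin, v)
        vmax = max(vmax, v)
    return (float(vmin), float(vmax))


def truncated_ci_box(model: KineticModel,
                     ci: ConfidenceIntervals) -> dict[str,
                                                      tuple[float, float]]:
    """CI intervals clipped to each parameter's global bounds."""
    out = {}
    for name, entry in ci.entries.items():
        spec = model.specs[name]
        lo = min(max(entry.lower, spec.global_lb), spec.global_ub)
        hi = min(max(entry.upper, spec.global_lb), spec.global_ub)
        out[name] = (lo, hi)
    return out


def compute_all_bounds(model: KineticModel, condition: ConditionRecord,
                       ci: ConfidenceIntervals,
                       aec_min: float = 0.8,
                       conc_bounds: tuple[float, float] = (0.001, 10.0),
                       ) -> FluxBoundSet:
    """One (v_min, v_max) per kinetic reaction with sufficient data.

    Reactions whose enzyme level or whose required metabolites (other
    than ATP) are unmeasured contribute no bound.  Unmeasured ATP is
    ranged over the energy-charge-feasible interval when ADP and AMP are
    measured, else over the full concentration box.
    """
    box = truncated_ci_box(model, ci)
    out = FluxBoundSet()
    cid = condition.condition_id
    measured_c = {m: meas.mean for m, meas in condition.metabolites.items()}
    for rxn, law in model.rate_laws.items():
        if rxn not in condition.enzymes:
            out.provenance[(cid, rxn)] = "unavailable: enzyme unmeasured"
            continue
        e = condition.enzymes[rxn].mean
        missing = [m for m in law.required_metabolites
                   if m != "atp" and m not in measured_c]
        if missing:
            out.provenance[(cid, rxn)] = \
                f"unavailable: unmeasured metabolites {missing}"
            continue
        extra = {}
        note = "all metabolites measured"
        if "atp" in law.required_metabolites and "atp" not in measured_c:
            extra["atp"] = _atp_interval(measured_c, aec_min, conc_bounds)
            note = ("atp ranged over energy-charge-feasible interval "
                    f"[{extra['atp'][0]:.4g}, {extra['atp'][1]:.4g}] mM")
        c = {m: measured_c[m] for m in law.required_metabolites
             if m in measured_c}
        vmin, vmax = flux_range(law, e, c, {p: box[p]
                                            for p in law.parameters},
                                extra_ranges=extra)
        out.add(cid, rxn, vmin, vmax, note)
    return out


def _atp_interval(measured_c, aec_min, conc_bounds):
    lo, hi = conc_bounds
    adp = measured_c.get("adp")
    amp = measured_c.get("amp")
    if adp is None or amp is None:
        return (lo, hi)
    atp_lo = atp_for_energy_charge(aec_min, adp, amp)
    return (min(max(atp_lo, lo), hi), hi)
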