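"""Synthetic chemostat studies with known kinetic ground truth.

A study emulates a multi-omic chemostat experiment on the central
network: a parental strain grown at several dilution rates plus
single-gene perturbation strains at a reference rate of 0.2 1/h.  For
every condition a steady-state flux distribution is sampled from the
constraint-based model (randomly perturbed glucose-minimizing objective,
then minimum-norm selection), after which metabolite and enzyme
concentrations are solved to be exactly consistent with the kinetic rate
laws at the true parameters: e = v / f(c; theta_true) for every kinetic
reaction, the adenylate energy charge at least 0.8, and all
concentrations inside [0.001, 10] mM.  Reported measurements add
multiplicative log-normal noise with a chosen coefficient of variation;
ATP is never reported (it was not measured in the emulated study design)
and enters estimation as a free variable.

Knockout strains force the enzyme of one kinetic reaction to the 0.001
mg protein/gDCW floor; the pool of knockout targets is restricted to
pentose phosphate reactions the network can route around (G6PDH, TALA,
TKT2, RPE), mirroring deletions whose flux burden other pathways or
isozymes can absorb.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, sparse

from ._opt import solve_diag_qp, solve_lp
from .network import StoichiometricModel, block_fermentation
from .omics import ConditionRecord, Measurement, OmicsDataset
from .rate_laws import (KineticModel, ParameterSet, adenylate_energy_charge,
                        atp_for_energy_charge, load_fitted_parameters)

DILUTION_RATES = (0.1, 0.2, 0.4, 0.5, 0.7)
REFERENCE_RATE = 0.2
KNOCKOUT_POOL = ("G6PDH", "TALA", "TKT2", "RPE")
ENZYME_FLOOR = 1e-3
CONC_BOUNDS = (0.001, 10.0)
ENZYME_BOUNDS = (0.001, 10.0)
AEC_MIN = 0.8
MEASURED_EXTRA_FLUXES = ("BIOMASS", "EX_glc__D_e", "EX_o2_e", "EX_co2_e")
UNMEASURED_METABOLITES = ("atp",)


@dataclass
class SyntheticTruth:
    fluxes: dict[str, dict[str, float]] = field(default_factory=dict)
    concentrations: dict[str, dict[str, float]] = field(default_factory=dict)
    enzymes: dict[str, dict[str, float]] = field(default_factory=dict)


@dataclass
class SyntheticStudy:
    theta_true: ParameterSet
    dataset: OmicsDataset
    truth: SyntheticTruth
    train_ids: list[str]
    test_ids: list[str]
    seed: int

    @property
    def train(self) -> OmicsDataset:
        return self.dataset.subset(self.train_ids)

    @property
    def test(self) -> OmicsDataset:
        return self.dataset.subset(self.test_ids)


class GenerationError(RuntimeError):
    pass


def _sample_flux_distribution(model: StoichiometricModel, rate: float,
                              knockout: str | None, rng,
                              objective_noise: float = 0.15) -> np.ndarray:
    """Steady-state fluxes: perturbed glucose-minimizing LP + minimum
    norm over the optimal face."""
    m = block_fermentation(model)
    j_bio = m.rxn_index(m.biomass_rxn)
    m.lb[j_bio] = m.ub[j_bio] = rate
    # keep irreversible kinetic fluxes clearly positive: their rate laws
    # are strictly positive, so a flux clamped to zero downstream (noise
    # plus steady-state projection) would be inconsistent with any
    # enzyme level at or above the floor
    for rxn in m.kinetic_rxns:
        j = m.rxn_index(rxn)
        if m.lb[j] == 0 and not m.reversible[j]:
            m.lb[j] = 0.05
    if knockout is not None:
        j = m.rxn_index(knockout)
        m.ub[j] = 0.05
        m.lb[j] = 0.02 if m.lb[j] > 0 else -0.05
    c = np.zeros(m.n_reactions)
    c[m.rxn_index(m.glucose_uptake_rxn)] = 1.0
    internal = [j for j, r in enumerate(m.reactions)
                if not r.startswith("EX_")]
    pert = rng.normal(0.0, objective_noise, size=len(internal))
    c[internal] += pert
    x, fun = solve_lp(c, m.S, np.zeros(m.n_metabolites), m.lb, m.ub)
    # minimum-norm selection with the sampled objective fixed
    n = m.n_reactions
    Aeq = sparse.vstack([m.S, sparse.csr_matrix(c)])
    beq = np.concatenate([np.zeros(m.n_metabolites), [fun]])
    x = solve_diag_qp(np.full(n, 2.0), np.zeros(n), Aeq, beq, m.lb, m.ub)
    return x


def _solve_concentrations(kin: KineticModel, theta: dict[str, float],
                          v: dict[str, float], knockout: str | None,
                          rng) -> tuple[dict[str, float], dict[str, float]]:
    """Find concentrations making e = v/f land inside the enzyme box."""
    varmets = [m for m in kin.metabolite_ids if m != "glc"]
    midx = {m: i for i, m in enumerate(varmets)}
    lo, hi = CONC_BOUNDS
    xlo, xhi = math.log(lo), math.log(hi)
    e_lb, e_ub = ENZYME_BOUNDS

    e_target = {}
    for rxn in kin.reactions:
        if knockout == rxn:
            e_target[rxn] = ENZYME_FLOOR
        else:
            e_target[rxn] = math.exp(rng.uniform(math.log(0.05),
                                                 math.log(2.0)))

    def residuals(x):
        c = {m: math.exp(x[i]) for m, i in midx.items()}
        out = []
        for rxn, law in kin.rate_laws.items():
            f = law.f(c, theta)
            scale = max(abs(v[rxn]), 0.05)
            out.append((e_target[rxn] * f - v[rxn]) / scale)
        # soft energy-charge target (validated afterwards)
        aec = adenylate_energy_charge(c["atp"], c["adp"], c["amp"])
        out.append(5.0 * max(0.0, (AEC_MIN + 0.02) - aec))
        return np.array(out)

    x0 = np.array([math.log(0.2)] * len(varmets))
    # start glycolytic intermediates in a forward-flux-friendly pattern
    for m, val in (("g6p", 1.0), ("f6p", 0.5), ("fdp", 0.3), ("dhap", 0.4),
                   ("gap", 0.15), ("13dpg", 0.05), ("3pg", 1.0),
                   ("2pg", 0.4), ("pep", 0.3), ("pyr", 0.4), ("6pg", 0.1),
                   ("ru5pD", 0.1), ("xu5pD", 0.12), ("r5p", 0.1),
                   ("s7p", 0.15), ("e4p", 0.08), ("atp", 3.0),
                   ("adp", 0.6), ("amp", 0.2), ("nad", 1.5),
                   ("nadh", 0.1), ("nadp", 0.1), ("nadph", 0.15)):
        x0[midx[m]] = math.log(val) + 0.2 * rng.normal()
    sol = optimize.least_squares(residuals, np.clip(x0, xlo, xhi),
                                 bounds=(xlo, xhi), xtol=1e-14,
                                 ftol=1e-14, max_nfev=400)
    c = {m: math.exp(sol.x[midx[m]]) for m in varmets}
    # exact enzyme recovery
    e = {}
    for rxn, law in kin.rate_laws.items():
        f = law.f(c, theta)
        if f == 0 or not math.copysign(1, f) == math.copysign(1, v[rxn]):
            raise GenerationError(f"{rxn}: rate-law factor sign "
                                  f"inconsistent with flux {v[rxn]:.3g}")
        e[rxn] = v[rxn] / f
        if not e_lb <= e[rxn] <= e_ub:
            raise GenerationError(
                f"{rxn}: implied enzyme level {e[rxn]:.3g} outside box")
    if knockout is not None and e[knockout] > ENZYME_FLOOR * 1.5:
        raise GenerationError(
            f"{knockout}: knockout enzyme level {e[knockout]:.3g} not at "
            "the floor")
    if adenylate_energy_charge(c["atp"], c["adp"], c["amp"]) < AEC_MIN:
        # lift ATP; only GND, PFK, PYK, PGK depend on it, and their
        # enzymes are recomputed below from the final concentrations
        c["atp"] = atp_for_energy_charge(AEC_MIN + 1e-6, c["adp"],
                                         c["amp"])
        if not lo <= c["atp"] <= hi:
            raise GenerationError("no AEC-feasible ATP level in box")
        for rxn, law in kin.rate_laws.items():
            if "atp" in law.required_metabolites:
                f = law.f(c, theta)
                if f == 0:
                    raise GenerationError(f"{rxn}: zero factor after "
                                          "ATP lift")
                e[rxn] = v[rxn] / f
                if not e_lb <= e[rxn] <= e_ub:
                    raise GenerationError(f"{rxn}: enzyme out of box "
                                          "after ATP lift")
    c["glc"] = float(np.clip(math.exp(rng.uniform(math.log(0.02),
                                                  math.log(2.0))), lo, hi))
    return c, e


def _consistent_fluxes(model: StoichiometricModel, raw: dict[str, float],
                       rate: float, knockout: str | None,
                       floor: float = 0.02) -> dict[str, float]:
    """Project noisy fluxes back onto the steady-state space.

    Flux measurements in chemostat studies come from metabolic flux
    analysis and therefore satisfy the network balances almost exactly;
    independent per-reaction noise does not.  The reported measurements
    are the projection of the noisy values, with irreversible kinetic
    reactions kept at a small detection-floor flux so that no reported
    flux is clamped to zero against a strictly positive rate law.
    """
    m = block_fermentation(model)
    j = m.rxn_index(m.biomass_rxn)
    m.lb[j] = m.ub[j] = rate
    for rxn in m.kinetic_rxns:
        jj = m.rxn_index(rxn)
        if m.lb[jj] == 0 and not m.reversible[jj]:
            m.lb[jj] = floor
    if knockout is not None:
        jj = m.rxn_index(knockout)
        m.ub[jj] = 0.06
        if m.lb[jj] >= 0:
            m.lb[jj] = min(m.lb[jj], 0.02)
        else:
            m.lb[jj] = -0.06
    n = m.n_reactions
    h = np.full(n, 2e-9)
    g = np.zeros(n)
    for rxn, vm in raw.items():
        jj = m.rxn_index(rxn)
        h[jj] = 2.0
        g[jj] = -2.0 * vm
    x = solve_diag_qp(h, g, m.S, np.zeros(m.n_metabolites), m.lb, m.ub)
    return {rxn: float(x[m.rxn_index(rxn)]) for rxn in raw}


def generate_study(model: StoichiometricModel, kin: KineticModel,
                   n_train: int = 20, n_test: int = 5,
                   noise_cv: float = 0.05, seed: int = 0,
                   theta_true: ParameterSet | None = None,
                   theta_scale: float = 1.0,
                   max_retries: int = 10) -> SyntheticStudy:
    """Generate a noisy multi-omic chemostat study with hidden truth.

    ``theta_scale`` multiplies every non-Keq true parameter (robustness
    experiments); the defaults emulate a 25-condition study (20 training,
    5 test) with 5% measurement noise.
    """
    if theta_true is None:
        theta_true, _ = load_fitted_parameters()
    theta = dict(theta_true.values)
    if theta_scale != 1.0:
        for name in theta:
            if not name.startswith("Keq_"):
                theta[name] *= theta_scale
    rng = np.random.default_rng(seed)
    n_total = n_train + n_test

    plan: list[tuple[str, float, str | None]] = []
    for i in range(n_total):
        if i < len(DILUTION_RATES):
            plan.append((f"WT_D{DILUTION_RATES[i]:.1f}",
                         DILUTION_RATES[i], None))
        else:
            ko = KNOCKOUT_POOL[(i - len(DILUTION_RATES))
                               % len(KNOCKOUT_POOL)] \
                if (i % 3 != 0) else None
            tag = f"d{ko}" if ko else "WT"
            plan.append((f"{tag}_r{i:02d}", REFERENCE_RATE, ko))

    truth = SyntheticTruth()
    records = []
    sigma = math.sqrt(math.log(1.0 + noise_cv ** 2)) if noise_cv > 0 else 0.0
    measured_mets = [m for m in kin.metabolite_ids
                     if m not in UNMEASURED_METABOLITES]
    for cid, rate, ko in plan:
        last_err: Exception | None = None
        for _ in range(max_retries):
            try:
                x = _sample_flux_distribution(model, rate, ko, rng)
                vmap = {r: float(x[j])
                        for j, r in enumerate(model.reactions)}
                vkin = {k: vmap[k] for k in kin.reactions}
                c, e = _solve_concentrations(kin, theta, vkin, ko, rng)
                break
            except (GenerationError, RuntimeError) as exc:
                last_err = exc
        else:
            raise GenerationError(
                f"{cid}: no rate-law-consistent condition found after "
                f"{max_retries} attempts: {last_err}")
        truth.fluxes[cid] = vmap
        truth.concentrations[cid] = c
        truth.enzymes[cid] = e

        def noisy(val: float) -> float:
            if sigma == 0.0:
                return val
            return val * math.exp(sigma * rng.normal())

        raw = {}
        for rxn in list(kin.reactions) + list(MEASURED_EXTRA_FLUXES):
            raw[rxn] = noisy(vmap[rxn])
        fluxes = _consistent_fluxes(model, raw, rate, ko)
        metabolites = {m: Measurement(noisy(c[m]), c[m] * noise_cv)
                       for m in measured_mets}
        enzymes = {k: Measurement(noisy(e[k]), e[k] * noise_cv)
                   for k in kin.reactions}
        records.append(ConditionRecord(
            condition_id=cid, dilution_rate=rate, knockout=ko,
            fluxes=fluxes, metabolites=metabolites, enzymes=enzymes))

    dataset = OmicsDataset(records, list(measured_mets),
                           list(kin.reactions))
    ids = [r.condition_id for r in records]
    test_ids = sorted(rng.choice(ids, size=n_test, replace=False).tolist())
    train_ids = [i for i in ids if i not in test_ids]
    return SyntheticStudy(
        theta_true=ParameterSet(theta, provenance="synthetic ground truth"),
        dataset=dataset, truth=truth,
        train_ids=train_ids, test_ids=test_ids, seed=seed)


def corrupt_measurements(study: SyntheticStudy, missing_fraction: float,
                         seed: int = 0) -> SyntheticStudy:
    """Flag an exact fraction of metabolite/enzyme cells as missing."""
    if not 0 <= missing_fraction < 1:
        raise ValueError("missing_fraction must be in [0, 1)")
    rng = np.random.default_rng(seed)
    cells = []
    for c in study.dataset.conditions:
        cells += [("metabolites", c.condition_id, m)
                  for m in c.metabolites]
        cells += [("enzymes", c.condition_id, e) for e in c.enzymes]
    n_drop = int(round(missing_fraction * len(cells)))
    idx = rng.choice(len(cells), size=n_drop, replace=False)
    drop_cells = {cells[int(i)] for i in idx}
    records = []
    for c in study.dataset.conditions:
        records.append(ConditionRecord(
            condition_id=c.condition_id, dilution_rate=c.dilution_rate,
            knockout=c.knockout, fluxes=dict(c.fluxes),
            metabolites={m: meas for m, meas in c.metabolites.items()
                         if ("metabolites", c.condition_id, m)
                         not in drop_cells},
            enzymes={e: meas for e, meas in c.enzymes.items()
                     if ("enzymes", c.condition_id, e) not in drop_cells},
        ))
    dataset = OmicsDataset(records, list(study.dataset.metabolite_ids),
                           list(study.dataset.enzyme_ids))
    return SyntheticStudy(theta_true=study.theta_true, dataset=dataset,
                          truth=study.truth, train_ids=study.train_ids,
                          test_ids=study.test_ids, seed=study.seed)


def hidden_truth_condition(study: SyntheticStudy,
                           cid: str) -> ConditionRecord:
    """Noise-free view of one condition (exact truth, zero sds)."""
    c = study.truth.concentrations[cid]
    e = study.truth.enzymes[cid]
    rec = study.dataset.condition(cid)
    return ConditionRecord(
        condition_id=cid, dilution_rate=rec.dilution_rate,
        knockout=rec.knockout, fluxes=dict(study.truth.fluxes[cid]),
        metabolites={m: Measurement(c[m], 0.0)
                     for m in study.dataset.metabolite_ids},
        enzymes={k: Measurement(e[k], 0.0) for k in e},
    )
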