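"""Projection of measured fluxes onto the steady-state flux space.

Measured flux distributions rarely satisfy the model's mass balances
exactly; they are adjusted by minimizing the Euclidean distance to the
measurements subject to S v = 0, the flux bounds (including the ATP
maintenance requirement carried by the model) and the biomass flux fixed
to the chemostat dilution rate.  Unmeasured fluxes are free up to a tiny
ridge that makes the projection unique.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._opt import InfeasibleProblem, solve_diag_qp, solve_lp
from .network import StoichiometricModel

RIDGE = 1e-9
STEADY_STATE_TOL = 1e-8


@dataclass
class AdjustedFluxes:
    """Adjusted flux maps and adjustment distances, per condition."""

    v: dict[str, dict[str, float]] = field(default_factory=dict)
    distance: dict[str, float] = field(default_factory=dict)

    def fluxes(self, condition_id: str) -> dict[str, float]:
        return self.v[condition_id]


def adjust_fluxes(model: StoichiometricModel,
                  measured: dict[str, float],
                  dilution_rate: float,
                  ridge: float = RIDGE) -> tuple[dict[str, float], float]:
    """Project one condition's measured fluxes onto the steady-state space.

    Returns (flux map over all model reactions, Euclidean distance over
    the measured subset).
    """
    for rid in measured:
        model.rxn_index(rid)  # raises KeyError for unknown reactions
    n = model.n_reactions
    lb = model.lb.copy()
    ub = model.ub.copy()
    j_bio = model.rxn_index(model.biomass_rxn)
    lb[j_bio] = ub[j_bio] = dilution_rate

    h = np.full(n, 2.0 * ridge)
    g = np.zeros(n)
    for rid, vm in measured.items():
        j = model.rxn_index(rid)
        h[j] = 2.0
        g[j] = -2.0 * vm

    b = np.zeros(model.n_metabolites)
    try:
        x = solve_diag_qp(h, g, model.S, b, lb, ub)
    except InfeasibleProblem:
        raise InfeasibleProblem(_infeasibility_report(model, lb, ub))

    resid = model.S @ x
    if np.max(np.abs(resid), initial=0.0) > STEADY_STATE_TOL:
        raise InfeasibleProblem(
            f"steady-state residual {np.max(np.abs(resid)):.2e} exceeds "
            f"tolerance {STEADY_STATE_TOL}")
    dist = float(np.sqrt(sum(
        (x[model.rxn_index(r)] - vm) ** 2 for r, vm in measured.items())))
    return {r: float(x[j]) for j, r in enumerate(model.reactions)}, dist


def adjust_dataset(model: StoichiometricModel, dataset,
                   ridge: float = RIDGE) -> AdjustedFluxes:
    """Adjust every condition of an OmicsDataset."""
    out = AdjustedFluxes()
    for cond in dataset.conditions:
        v, d = adjust_fluxes(model, cond.fluxes, cond.dilution_rate,
                             ridge=ridge)
        out.v[cond.condition_id] = v
        out.distance[cond.condition_id] = d
    return out


def _infeasibility_report(model: StoichiometricModel, lb, ub) -> str:
    """Name a small set of constraints blocking steady state (elastic LP)."""
    n = model.n_reactions
    m = model.n_metabolites
    # elastic bounds: v + s_up >= lb, v - s_dn <= ub, minimize slack
    import scipy.sparse as sp

    A = sp.hstack([model.S, sp.csr_matrix((m, 2 * n))])
    c = np.concatenate([np.zeros(n), np.ones(2 * n)])
    lo = np.concatenate([lb - 1e6, np.zeros(2 * n)])
    hi = np.concatenate([ub + 1e6, np.full(2 * n, 1e6)])
    # rewrite elastic boxes as equality-free: v_eff = v, with
    # lb - s_lo <= v <= ub + s_hi handled through shifted variables
    try:
        from scipy.optimize import linprog

        res = linprog(
            c,
            A_eq=A, b_eq=np.zeros(m),
            A_ub=sp.vstack([
                sp.hstack([-sp.eye(n), -sp.eye(n), sp.csr_matrix((n, n))]),
                sp.hstack([sp.eye(n), sp.csr_matrix((n, n)), -sp.eye(n)]),
            ]),
            b_ub=np.concatenate([-lb, ub]),
            bounds=list(zip(lo, hi)),
            method="highs")
        if res.status != 0:
            return "steady state infeasible (no elastic relaxation found)"
        s = res.x[n:]
        bad = []
        for j in range(n):
            slack = s[j] + s[n + j]
            if slack > 1e-7:
                bad.append(f"{model.reactions[j]} (relaxed by {slack:.3g})")
        return ("steady state infeasible; bound constraints needing "
                "relaxation: " + (", ".join(bad) if bad else "none found"))
    except Exception:
        return "steady state infeasible"


def feasible_flux(model: StoichiometricModel,
                  dilution_rate: float) -> dict[str, float]:
    """Any steady-state flux distribution at the given growth rate."""
    lb = model.lb.copy()
    ub = model.ub.copy()
    j = model.rxn_index(model.biomass_rxn)
    lb[j] = ub[j] = dilution_rate
    x, _ = solve_lp(np.zeros(model.n_reactions), model.S,
                    np.zeros(model.n_metabolites), lb, ub)
    return {r: float(x[k]) for k, r in enumerate(model.reactions)}
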