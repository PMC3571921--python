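"""Flux balance analysis with kinetic flux bounds (KFBA).

The base FBA problem minimizes glucose uptake through the PTS at a fixed
growth rate (chemostat dilution rate) with fermentative pathways blocked.
KFBA adds per-reaction kinetic flux bounds; because the bounds are not
always jointly consistent with steady state, binary variables y+/y-
relax individual bounds back to the general LB/UB and their total count
is capped at n*, the minimum number of violations needed for
feasibility.  Among alternate optima the flux vector with the smallest
sum of squared fluxes is selected, which makes solutions unique.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse, stats

from ._opt import (InfeasibleProblem, nullspace, solve_diag_qp, solve_lp,
                   solve_milp)
from .adjust import AdjustedFluxes
from .bounds import FluxBoundSet
from .network import StoichiometricModel, block_fermentation

MILP_INT_TOL = 1e-6
AUDIT_TOL = 1e-6


@dataclass
class KFBASolution:
    v: dict[str, float]
    violated_upper: set[str]
    violated_lower: set[str]
    n_star: int
    objective: float  # glucose uptake (v_PTS)
    norm2: float  # sum of squared fluxes after the uniqueness step

    @property
    def n_violations(self) -> int:
        return len(self.violated_upper) + len(self.violated_lower)


def _prepare(model: StoichiometricModel, growth_rate: float,
             block_ferm: bool) -> StoichiometricModel:
    m = block_fermentation(model) if block_ferm else model.copy()
    j = m.rxn_index(m.biomass_rxn)
    m.lb[j] = m.ub[j] = growth_rate
    return m


def _min_norm(model: StoichiometricModel, lb, ub,
              objective_rxn: str, objective_value: float) -> np.ndarray:
    """Minimum sum-of-squares flux vector on the optimal face."""
    n = model.n_reactions
    lb = lb.copy()
    ub = ub.copy()
    j = model.rxn_index(objective_rxn)
    lb[j] = ub[j] = objective_value
    return solve_diag_qp(np.full(n, 2.0), np.zeros(n), model.S,
                         np.zeros(model.n_metabolites), lb, ub)


def solve_fba(model: StoichiometricModel, growth_rate: float,
              block_ferm: bool = True) -> dict[str, float]:
    """Minimize glucose uptake at fixed growth; minimum-norm selection."""
    m = _prepare(model, growth_rate, block_ferm)
    c = np.zeros(m.n_reactions)
    c[m.rxn_index(m.glucose_uptake_rxn)] = 1.0
    x, fun = solve_lp(c, m.S, np.zeros(m.n_metabolites), m.lb, m.ub)
    x = _min_norm(m, m.lb, m.ub, m.glucose_uptake_rxn, fun)
    return {r: float(x[j]) for j, r in enumerate(m.reactions)}


def _kinetic_bound_rows(model: StoichiometricModel, bound_list):
    """Big-M rows of the bound-relaxation constraints.

    For each bounded reaction k with box [vmin, vmax]:
        v_k - (UB_k - vmax_k) y+_k <= vmax_k      (upper bound or relax)
        -v_k + (LB_k - vmin_k) y-_k <= -vmin_k    (lower bound or relax)
    Variables are ordered [v (n), y+ (m), y- (m)].
    """
    n = model.n_reactions
    m = len(bound_list)
    rows, cols, data, rhs = [], [], [], []
    r = 0
    for i, (rxn, (vmin, vmax)) in enumerate(bound_list):
        j = model.rxn_index(rxn)
        rows += [r, r]
        cols += [j, n + i]
        data += [1.0, -(model.ub[j] - vmax)]
        rhs.append(vmax)
        r += 1
        rows += [r, r]
        cols += [j, n + m + i]
        data += [-1.0, (model.lb[j] - vmin)]
        rhs.append(-vmin)
        r += 1
    A = sparse.csr_matrix((data, (rows, cols)), shape=(r, n + 2 * m))
    return A, np.array(rhs)


def _bound_list(bounds: FluxBoundSet, condition_id: str | None,
                model: StoichiometricModel):
    if condition_id is None:
        items = sorted(bounds.bounds.items())
        if len({cid for (cid, _), _ in items}) > 1:
            raise ValueError("bound set spans several conditions; pass "
                             "condition_id")
        return [(rxn, b) for (_, rxn), b in items]
    return sorted(bounds.for_condition(condition_id).items())


def min_violations(model: StoichiometricModel, bounds: FluxBoundSet,
                   growth_rate: float, condition_id: str | None = None,
                   block_ferm: bool = True) -> int:
    """Minimum number of kinetic bounds that must be violated (n*)."""
    blist = _bound_list(bounds, condition_id, model)
    if not blist:
        return 0
    m = _prepare(model, growth_rate, block_ferm)
    n = m.n_reactions
    nb = len(blist)
    A_ub, b_ub = _kinetic_bound_rows(m, blist)
    A_eq = sparse.hstack([m.S, sparse.csr_matrix((m.n_metabolites,
                                                  2 * nb))])
    c = np.concatenate([np.zeros(n), np.ones(2 * nb)])
    lb = np.concatenate([m.lb, np.zeros(2 * nb)])
    ub = np.concatenate([m.ub, np.ones(2 * nb)])
    integrality = np.concatenate([np.zeros(n), np.ones(2 * nb)])
    try:
        x, fun = solve_milp(c, integrality, A_eq=A_eq,
                            b_eq=np.zeros(m.n_metabolites),
                            A_ub=A_ub, b_ub=b_ub, lb=lb, ub=ub)
    except InfeasibleProblem:
        raise InfeasibleProblem(
            "structurally infeasible: no steady-state flux distribution "
            "exists even with every kinetic bound relaxed")
    return int(round(fun))


def solve_kfba(model: StoichiometricModel, bounds: FluxBoundSet,
               growth_rate: float, n_star: int | None = None,
               condition_id: str | None = None,
               block_ferm: bool = True) -> KFBASolution:
    """Minimize glucose uptake subject to kinetic bounds with at most
    n_star violations; unique minimum-norm alternate optimum."""
    blist = _bound_list(bounds, condition_id, model)
    if n_star is None:
        n_star = min_violations(model, bounds, growth_rate,
                                condition_id=condition_id,
                                block_ferm=block_ferm)
    m = _prepare(model, growth_rate, block_ferm)
    n = m.n_reactions
    nb = len(blist)
    j_obj = m.rxn_index(m.glucose_uptake_rxn)

    if nb == 0:
        v = solve_fba(model, growth_rate, block_ferm)
        varr = np.array([v[r] for r in m.reactions])
        return KFBASolution(v, set(), set(), 0, v[m.glucose_uptake_rxn],
                            float(np.sum(varr ** 2)))

    A_ub, b_ub = _kinetic_bound_rows(m, blist)
    budget = sparse.csr_matrix(
        (np.ones(2 * nb), (np.zeros(2 * nb, dtype=int),
                           np.arange(n, n + 2 * nb))),
        shape=(1, n + 2 * nb))
    A_ub_full = sparse.vstack([A_ub, budget])
    b_ub_full = np.concatenate([b_ub, [n_star]])
    A_eq = sparse.hstack([m.S, sparse.csr_matrix((m.n_metabolites,
                                                  2 * nb))])
    b_eq = np.zeros(m.n_metabolites)
    lb = np.concatenate([m.lb, np.zeros(2 * nb)])
    ub = np.concatenate([m.ub, np.ones(2 * nb)])
    integrality = np.concatenate([np.zeros(n), np.ones(2 * nb)])

    c1 = np.zeros(n + 2 * nb)
    c1[j_obj] = 1.0
    try:
        x, obj = solve_milp(c1, integrality, A_eq=A_eq, b_eq=b_eq,
                            A_ub=A_ub_full, b_ub=b_ub_full, lb=lb, ub=ub)
    except InfeasibleProblem:
        raise InfeasibleProblem(
            f"KFBA infeasible with n_star={n_star}; run min_violations "
            "to find the smallest feasible violation budget")

    # deterministic violation pattern: with the objective fixed, prefer
    # as few violations as possible and, among ties, later-indexed ones
    lb2 = lb.copy()
    ub2 = ub.copy()
    lb2[j_obj] = ub2[j_obj] = obj
    c2 = np.zeros(n + 2 * nb)
    c2[n:] = 1.0 + 1e-4 * np.arange(2 * nb)[::-1] / max(1, 2 * nb)
    x, _ = solve_milp(c2, integrality, A_eq=A_eq, b_eq=b_eq,
                      A_ub=A_ub_full, b_ub=b_ub_full, lb=lb2, ub=ub2)
    y_plus = np.round(x[n:n + nb]).astype(int)
    y_minus = np.round(x[n + nb:]).astype(int)

    # minimum-norm uniqueness step with binaries fixed
    lbv = m.lb.copy()
    ubv = m.ub.copy()
    for i, (rxn, (vmin, vmax)) in enumerate(blist):
        j = m.rxn_index(rxn)
        if not y_plus[i]:
            ubv[j] = min(ubv[j], vmax)
        if not y_minus[i]:
            lbv[j] = max(lbv[j], vmin)
    varr = _min_norm(m, lbv, ubv, m.glucose_uptake_rxn, obj)
    v = {r: float(varr[j]) for j, r in enumerate(m.reactions)}
    sol = KFBASolution(
        v=v,
        violated_upper={rxn for i, (rxn, _) in enumerate(blist)
                        if y_plus[i]},
        violated_lower={rxn for i, (rxn, _) in enumerate(blist)
                        if y_minus[i]},
        n_star=int(n_star),
        objective=float(obj),
        norm2=float(np.sum(varr ** 2)),
    )
    audit_kfba_solution(m, blist, sol, growth_rate)
    return sol


def audit_kfba_solution(model: StoichiometricModel, blist,
                        sol: KFBASolution, growth_rate: float,
                        tol: float = AUDIT_TOL) -> None:
    """Re-verify a KFBA solution by direct substitution (independent of
    solver status codes)."""
    varr = np.array([sol.v[r] for r in model.reactions])
    resid = np.max(np.abs(model.S @ varr), initial=0.0)
    if resid > 1e-6:
        raise AssertionError(f"steady-state residual {resid:.2e}")
    scale = np.maximum(1.0, np.maximum(np.abs(model.lb),
                                       np.abs(model.ub)))
    if np.any(varr < model.lb - tol * scale) or \
            np.any(varr > model.ub + tol * scale):
        raise AssertionError("general flux bounds violated")
    j = model.rxn_index(model.biomass_rxn)
    if abs(varr[j] - growth_rate) > 1e-6:
        raise AssertionError("biomass flux does not match growth rate")
    for rxn, (vmin, vmax) in blist:
        val = sol.v[rxn]
        if rxn not in sol.violated_upper and \
                val > vmax + tol * max(1.0, abs(vmax)):
            raise AssertionError(f"{rxn}: upper kinetic bound violated "
                                 "without a relaxation binary")
        if rxn not in sol.violated_lower and \
                val < vmin - tol * max(1.0, abs(vmin)):
            raise AssertionError(f"{rxn}: lower kinetic bound violated "
                                 "without a relaxation binary")
    if sol.n_violations > sol.n_star:
        raise AssertionError("violation budget exceeded")


# --------------------------------------------------------------------------
# evaluation
# --------------------------------------------------------------------------

def proportional_groups(model: StoichiometricModel,
                        reactions: list[str],
                        tol: float = 1e-8) -> list[list[str]]:
    """Group reactions whose steady-state fluxes are directly
    proportional (parallel rows of a null-space basis of S, with
    blocked reactions excluded from the flux space)."""
    open_cols = [j for j in range(model.n_reactions)
                 if not (model.lb[j] == 0 and model.ub[j] == 0)]
    col_of = {j: i for i, j in enumerate(open_cols)}
    S_open = np.asarray(model.S.todense())[:, open_cols]
    N = nullspace(S_open)
    groups: list[tuple[np.ndarray, list[str]]] = []
    blocked: list[str] = []
    for rxn in reactions:
        j = model.rxn_index(rxn)
        if j not in col_of:
            blocked.append(rxn)
            continue
        row = N[col_of[j]]
        nrm = np.linalg.norm(row)
        if nrm < tol:
            blocked.append(rxn)
            continue
        unit = row / nrm
        for ref, members in groups:
            if min(np.linalg.norm(unit - ref),
                   np.linalg.norm(unit + ref)) < 1e-6:
                members.append(rxn)
                break
        else:
            groups.append((unit, [rxn]))
    out = [sorted(members) for _, members in groups]
    if blocked:
        out.append(sorted(blocked))
    return sorted(out)


@dataclass
class PredictionEvaluation:
    residuals: dict[str, float]
    mean_residual: float
    groups: list[list[str]] = field(default_factory=list)
    biomass_yield: float | None = None  # gDCW per mmol glucose


def evaluate_predictions(predicted: dict[str, float],
                         adjusted: dict[str, float],
                         model: StoichiometricModel,
                         growth_rate: float | None = None,
                         ) -> PredictionEvaluation:
    """Squared flux residuals on the measured subset, deduplicated over
    proportionally coupled reactions, plus the predicted biomass yield."""
    common = sorted(set(predicted) & set(adjusted))
    residuals = {r: (adjusted[r] - predicted[r]) ** 2 for r in common}
    groups = proportional_groups(model, common)
    reps = [g[0] for g in groups]
    mean_residual = float(np.mean([residuals[r] for r in reps])) \
        if reps else float("nan")
    biomass_yield = None
    if growth_rate is not None:
        uptake = predicted.get(model.glucose_uptake_rxn)
        if uptake is not None:
            if uptake <= 0:
                biomass_yield = float("nan")
            else:
                biomass_yield = growth_rate / uptake
    return PredictionEvaluation(residuals=residuals,
                                mean_residual=mean_residual,
                                groups=groups,
                                biomass_yield=biomass_yield)


def sign_test(paired_a, paired_b) -> float:
    """Exact two-sided binomial sign test; ties dropped.

    p = 2 * P(X <= min(k, n-k)), X ~ Binomial(n, 1/2), capped at 1.
    """
    a = np.asarray(paired_a, float)
    b = np.asarray(paired_b, float)
    if a.shape != b.shape or a.size < 1:
        raise ValueError("paired samples of equal length >= 1 required")
    diff = a - b
    diff = diff[diff != 0]
    n = diff.size
    if n == 0:
        raise ValueError("all pairs tied: sign test undefined")
    k = int(np.sum(diff > 0))
    p = 2.0 * stats.binom.cdf(min(k, n - k), n, 0.5)
    return float(min(p, 1.0))
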