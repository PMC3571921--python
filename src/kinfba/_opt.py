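"""Shared LP / QP / MILP helpers built on scipy (HiGHS backends).

The QPs here are diagonal-Hessian problems with equality constraints and
box bounds (flux adjustment, minimum-norm flux selection).  They are solved
by a null-space KKT step with an active-set loop on the boxes, which gives
solver-tolerance-exact solutions for the small networks this package
targets; ``trust-constr`` is the fallback for degenerate cases.
"""

from __future__ import annotations

import numpy as np
from scipy import sparse
from scipy.optimize import LinearConstraint, Bounds, linprog, milp, minimize


class OptimizationError(RuntimeError):
    pass


class InfeasibleProblem(OptimizationError):
    pass


def solve_lp(c, A_eq, b_eq, lb, ub):
    """min c'x s.t. A_eq x = b_eq, lb <= x <= ub (HiGHS)."""
    res = linprog(c, A_eq=A_eq, b_eq=b_eq,
                  bounds=list(zip(lb, ub)), method="highs")
    if res.status == 2:
        raise InfeasibleProblem(res.message)
    if res.status != 0:
        raise OptimizationError(res.message)
    return res.x, res.fun


def solve_diag_qp(h, g, A_eq, b_eq, lb, ub, x0=None, tol=1e-10,
                  max_active_set_iter=200):
    """min 0.5 x'Hx + g'x with H = diag(h) >= 0, A_eq x = b_eq, boxes.

    Active-set on the box constraints: solve the equality-constrained KKT
    system, clamp the most-violated box variable, repeat.  Falls back to
    trust-constr when the KKT system is singular.
    """
    h = np.asarray(h, float)
    g = np.asarray(g, float)
    lb = np.asarray(lb, float)
    ub = np.asarray(ub, float)
    A = np.asarray(A_eq.todense() if sparse.issparse(A_eq) else A_eq, float)
    b = np.asarray(b_eq, float)
    n = len(g)
    # reduce the (possibly rank-deficient) equality system once
    u, s, vh = np.linalg.svd(A, full_matrices=False)
    rank = int(np.sum(s > max(A.shape) * (s[0] if s.size else 0) * 1e-12))
    R = s[:rank, None] * vh[:rank]
    d = u[:, :rank].T @ b
    fixed = {}  # var index -> bound value
    # variables with lb == ub are fixed from the start
    for j in np.nonzero(lb == ub)[0]:
        fixed[int(j)] = lb[j]

    for _ in range(max_active_set_iter):
        free = np.array([j for j in range(n) if j not in fixed], dtype=int)
        xfix = np.zeros(n)
        for j, v in fixed.items():
            xfix[j] = v
        rhs = d - R @ xfix
        Rf = R[:, free]
        # null-space step: x_f = x_p + N z, minimize the diagonal QP in z
        x_p, *_ = np.linalg.lstsq(Rf, rhs, rcond=None)
        if np.linalg.norm(Rf @ x_p - rhs) > 1e-7 * max(
                1.0, np.linalg.norm(rhs)):
            return _qp_osqp(h, g, A, b, lb, ub, R, d)
        N = nullspace(Rf)
        hf = h[free]
        gf = g[free]
        if N.shape[1]:
            M = N.T @ (hf[:, None] * N)
            r = -N.T @ (hf * x_p + gf)
            z, *_ = np.linalg.lstsq(M, r, rcond=None)
            xf = x_p + N @ z
        else:
            xf = x_p
        x = xfix.copy()
        x[free] = xf
        viol_lo = lb - x
        viol_hi = x - ub
        worst = None
        worst_v = tol
        for j in free:
            if viol_lo[j] > worst_v:
                worst, worst_v, side = int(j), viol_lo[j], "lo"
            if viol_hi[j] > worst_v:
                worst, worst_v, side = int(j), viol_hi[j], "hi"
        if worst is None:
            x = np.clip(x, lb, ub)
            if _is_qp_optimal(x, h, g, A, lb, ub):
                return x
            return _qp_osqp(h, g, A, b, lb, ub, R, d)
        fixed[worst] = lb[worst] if side == "lo" else ub[worst]
    return _qp_osqp(h, g, A, b, lb, ub, R, d)


def _qp_osqp(h, g, A, b, lb, ub, R=None, d=None):
    """Operator-splitting QP solve with an exact null-space re-polish."""
    import osqp

    n = len(g)
    P = sparse.diags(np.maximum(h, 1e-12), format="csc")
    Ac = sparse.vstack([sparse.csr_matrix(A), sparse.eye(n)],
                       format="csc")
    lo = np.concatenate([b, lb])
    hi = np.concatenate([b, ub])
    prob = osqp.OSQP()
    prob.setup(P=P, q=g, A=Ac, l=lo, u=hi, eps_abs=1e-9, eps_rel=1e-9,
               max_iter=200000, polishing=True, verbose=False)
    res = prob.solve()
    status = res.info.status.lower()
    if "infeasible" in status:
        raise InfeasibleProblem(f"QP infeasible ({res.info.status})")
    if res.x is None or np.any(~np.isfinite(res.x)):
        return _qp_trust_constr(h, g, A, b, lb, ub)
    x = np.clip(res.x, lb, ub)
    # exact re-polish: pin near-active boxes, solve the reduced
    # equality-constrained QP in closed form
    if R is None:
        u_, s_, vh_ = np.linalg.svd(np.asarray(A, float),
                                    full_matrices=False)
        rank = int(np.sum(s_ > max(A.shape) * (s_[0] if s_.size else 0)
                          * 1e-12))
        R = s_[:rank, None] * vh_[:rank]
        d = u_[:, :rank].T @ np.asarray(b, float)
    tol_act = 1e-7 * np.maximum(1.0, np.abs(ub - lb))
    act = (x - lb <= tol_act) | (ub - x <= tol_act)
    xfix = np.where(x - lb <= tol_act, lb, ub)
    free = np.nonzero(~act)[0]
    xtry = np.where(act, xfix, 0.0)
    rhs = d - R @ xtry
    Rf = R[:, free]
    x_p, *_ = np.linalg.lstsq(Rf, rhs, rcond=None)
    N = nullspace(Rf)
    if N.shape[1]:
        M = N.T @ (h[free][:, None] * N)
        r = -N.T @ (h[free] * x_p + g[free])
        z, *_ = np.linalg.lstsq(M, r, rcond=None)
        xf = x_p + N @ z
    else:
        xf = x_p
    xe = xtry.copy()
    xe[free] = xf
    feas = (np.all(xe >= lb - 1e-8) and np.all(xe <= ub + 1e-8)
            and np.linalg.norm(R @ xe - d) <= 1e-7
            * max(1.0, np.linalg.norm(d)))
    obj = lambda v: 0.5 * v @ (h * v) + g @ v
    if feas and obj(xe) <= obj(x) + 1e-9 * max(1.0, abs(obj(x))):
        return np.clip(xe, lb, ub)
    return x


def _is_qp_optimal(x, h, g, A, lb, ub, tol=1e-7):
    """KKT check: gradient reduced by A's rows and active-bound normals."""
    grad = h * x + g
    rows = [A] if A.size else []
    atol = 1e-9
    act_lo = x <= lb + atol
    act_hi = x >= ub - atol
    n = len(x)
    normals = []
    for j in range(n):
        if act_lo[j] or act_hi[j]:
            e = np.zeros(n)
            e[j] = 1.0
            normals.append(e)
    M = np.vstack(rows + [np.array(normals)]) if (rows or normals) else None
    if M is None or M.size == 0:
        return np.linalg.norm(grad) <= tol * max(1.0, np.linalg.norm(g))
    coef, res, *_ = np.linalg.lstsq(M.T, grad, rcond=None)
    resid = grad - M.T @ coef
    return np.linalg.norm(resid) <= tol * max(1.0, np.linalg.norm(grad))


def _qp_trust_constr(h, g, A, b, lb, ub, x0=None):
    n = len(g)
    if x0 is None:
        x0 = np.clip(np.zeros(n), lb, ub)
    H = np.diag(h)

    res = minimize(
        lambda x: 0.5 * x @ (h * x) + g @ x, x0,
        jac=lambda x: h * x + g,
        hess=lambda x: H,
        method="trust-constr",
        constraints=[LinearConstraint(A, b, b)],
        bounds=Bounds(lb, ub),
        options={"gtol": 1e-12, "xtol": 1e-14, "maxiter": 3000,
                 "verbose": 0},
    )
    if not res.success and res.constr_violation > 1e-6:
        raise InfeasibleProblem("QP infeasible or not converged: "
                                + res.message)
    return res.x


def solve_milp(c, integrality, A_eq=None, b_eq=None, A_ub=None, b_ub=None,
               lb=None, ub=None):
    """min c'x with mixed integrality via scipy.optimize.milp (HiGHS)."""
    constraints = []
    if A_eq is not None and np.size(b_eq):
        constraints.append(LinearConstraint(A_eq, b_eq, b_eq))
    if A_ub is not None and np.size(b_ub):
        constraints.append(
            LinearConstraint(A_ub, -np.inf * np.ones(len(b_ub)), b_ub))
    res = milp(c=c, constraints=constraints,
               integrality=integrality,
               bounds=Bounds(lb, ub),
               options={"mip_rel_gap": 0.0})
    if res.status == 2:
        raise InfeasibleProblem(res.message)
    if res.status != 0:
        raise OptimizationError(res.message)
    return res.x, res.fun


def nullspace(A, rtol=1e-10):
    """Orthonormal null-space basis of a dense/sparse matrix."""
    A = np.asarray(A.todense() if sparse.issparse(A) else A, float)
    if A.size == 0:
        return np.eye(A.shape[1])
    u, s, vh = np.linalg.svd(A, full_matrices=True)
    tol = max(A.shape) * (s[0] if len(s) else 0.0) * rtol
    rank = int(np.sum(s > tol))
    return vh[rank:].T
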