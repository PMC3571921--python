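"""Weighted-least-squares estimation of in vivo kinetic parameters.

The estimation problem adjusts kinetic parameters theta together with
per-condition metabolite and enzyme concentration estimates so that

* every kinetic reaction satisfies v = e * f(c; theta) exactly, with the
  fluxes fixed to their steady-state-adjusted measurements,
* the adenylate energy charge is at least ``aec_min`` in every condition
  (ATP is typically unmeasured and enters as a free, bounded variable),
* concentrations and enzyme levels stay inside biologically relevant
  boxes,

while minimizing the inverse-variance-weighted squared deviations of the
concentration estimates from their measurements.

The solver exploits the problem's separability: the enzyme level of each
kinetic reaction is eliminated through e = v / f(c; theta), after which
the decision variables decompose into per-condition concentration blocks
(solved by SLSQP in log space) and per-reaction parameter blocks (solved
by bounded least squares), iterated to convergence from multiple starting
points.  Confidence intervals come from one-at-a-time parameter
perturbation with re-optimization of everything else and a local quadratic
fit to the objective profile against a chi-square (1 dof) threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats
from sklearn.base import BaseEstimator

from .adjust import AdjustedFluxes, adjust_dataset
from .omics import OmicsDataset, WeightTable, compute_weights
from .rate_laws import (KineticModel, ParameterSet, adenylate_energy_charge,
                        atp_for_energy_charge, build_simplified_model)

EQ1B_TOL = 1e-6
AEC_TOL = 1e-9
_AEC_MARGIN = 1e-7
_F_FLOOR = 1e-12
_ZERO_FLUX = 1e-9


class WSLSInfeasibleError(RuntimeError):
    """No feasible point found; carries per-constraint diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


@dataclass
class WSLSProblem:
    kinetic_model: KineticModel
    dataset: OmicsDataset
    weights: WeightTable
    adjusted_fluxes: AdjustedFluxes
    aec_min: float = 0.8
    conc_bounds: tuple[float, float] = (0.001, 10.0)
    enzyme_bounds: tuple[float, float] = (0.001, 10.0)

    def __post_init__(self):
        if not 0 < self.aec_min:
            raise ValueError("aec_min must be positive")
        for cond in self.dataset.conditions:
            v = self.adjusted_fluxes.v.get(cond.condition_id, {})
            missing = [k for k in self.kinetic_model.reactions if k not in v]
            if missing:
                raise ValueError(
                    f"{cond.condition_id}: adjusted fluxes missing for "
                    f"kinetic reactions {missing}")

    @property
    def variable_metabolites(self) -> list[str]:
        used: set[str] = {"atp", "adp", "amp"}
        for law in self.kinetic_model.rate_laws.values():
            used.update(law.required_metabolites)
        return [m for m in self.kinetic_model.metabolite_ids if m in used]

    @property
    def passthrough_metabolites(self) -> list[str]:
        var = set(self.variable_metabolites)
        return [m for m in self.kinetic_model.metabolite_ids
                if m not in var]


@dataclass
class EstimationResult:
    theta: ParameterSet
    c_hat: dict[str, dict[str, float]]
    e_hat: dict[str, dict[str, float]]
    wsls: float
    n_starts: int = 1
    n_converged: int = 1
    best_start_seed: int | None = None
    condition_wsls: dict[str, float] = field(default_factory=dict)


@dataclass
class CIEntry:
    value: float
    lower: float
    upper: float
    relative_width: float
    flag: str = ""  # "", "flat", "unbounded-below", "unbounded-above", ...


@dataclass
class ConfidenceIntervals:
    entries: dict[str, CIEntry]
    alpha: float = 0.05

    def __getitem__(self, name: str) -> CIEntry:
        return self.entries[name]

    def box(self, names=None) -> dict[str, tuple[float, float]]:
        names = names if names is not None else list(self.entries)
        return {n: (self.entries[n].lower, self.entries[n].upper)
                for n in names}


# --------------------------------------------------------------------------
# inner per-condition concentration problem
# --------------------------------------------------------------------------

def _smooth_hinge(g, eps: float = 1e-6):
    """Smooth approximation of max(0, -g) (softplus at scale eps).

    Complex-step safe; exact to machine precision once |g| >> eps, so the
    trust-region model stays consistent near active constraints."""
    t = -g / eps
    tr = t.real if np.iscomplexobj(t) else t
    if tr > 40.0:
        return -g
    if tr < -40.0:
        return 0.0 * g
    return eps * np.log(1.0 + np.exp(t))


def _f_interval(v: float, e_lb: float, e_ub: float) -> tuple[float, float]:
    """Interval the rate factor f must lie in so that e = v/f is in box."""
    if abs(v) < _ZERO_FLUX:
        return (-1e-6, 1e-6)
    a, b = v / e_ub, v / e_lb
    return (min(a, b), max(a, b))


class _ConditionBlock:
    """Cached data and solvers for one experimental condition."""

    def __init__(self, problem: WSLSProblem, cond):
        self.problem = problem
        self.cond = cond
        self.cid = cond.condition_id
        km = problem.kinetic_model
        self.varmets = problem.variable_metabolites
        self.midx = {m: i for i, m in enumerate(self.varmets)}
        self.laws = [km.rate_laws[k] for k in km.reactions]
        vmap = problem.adjusted_fluxes.v[self.cid]
        self.v = {k: vmap[k] for k in km.reactions}
        self.w_c = np.array([problem.weights.metabolite(self.cid, m)
                             for m in self.varmets])
        self.c_exp = np.array([
            cond.metabolites[m].mean if m in cond.metabolites else np.nan
            for m in self.varmets])
        self.w_e = {k: problem.weights.enzyme(self.cid, k)
                    for k in km.reactions}
        self.e_exp = {k: (cond.enzymes[k].mean if k in cond.enzymes
                          else np.nan) for k in km.reactions}
        lo, hi = problem.conc_bounds
        self.xlo, self.xhi = math.log(lo), math.log(hi)
        # passthrough residual (constant given the measurements)
        self.passthrough_wsls = 0.0
        self.passthrough_c = {}
        for m in problem.passthrough_metabolites:
            if m in cond.metabolites:
                est = min(max(cond.metabolites[m].mean, lo), hi)
                w = problem.weights.metabolite(self.cid, m)
                self.passthrough_c[m] = est
                self.passthrough_wsls += w * (est -
                                              cond.metabolites[m].mean) ** 2

    # -- conversions ------------------------------------------------------
    def c_dict(self, x: np.ndarray) -> dict[str, float]:
        return {m: float(np.exp(x[i])) for m, i in self.midx.items()}

    def initial_x(self, rng=None) -> np.ndarray:
        lo, hi = self.problem.conc_bounds
        x = np.empty(len(self.varmets))
        for m, i in self.midx.items():
            if not np.isnan(self.c_exp[i]) and self.c_exp[i] > 0:
                x[i] = math.log(min(max(self.c_exp[i], lo), hi))
            else:
                x[i] = 0.5 * (self.xlo + self.xhi)
        # make sure the energy-charge constraint holds at the start
        c = self.c_dict(x)
        target = min(self.problem.aec_min + 0.05, 0.99)
        atp_req = atp_for_energy_charge(target, c["adp"], c["amp"])
        if c["atp"] < atp_req:
            x[self.midx["atp"]] = math.log(min(max(atp_req, lo), hi))
        return x

    # -- objective and constraints ---------------------------------------
    def enzyme_estimates(self, c: dict[str, float],
                         theta: dict[str, float]) -> dict[str, float]:
        e_lb, e_ub = self.problem.enzyme_bounds
        out = {}
        for law in self.laws:
            v = self.v[law.reaction_id]
            f = law.f(c, theta)
            if abs(f) < _F_FLOOR:
                out[law.reaction_id] = e_lb if abs(v) < _ZERO_FLUX else \
                    math.copysign(e_ub, 1.0)
            else:
                out[law.reaction_id] = v / f
        return out

    def objective(self, x: np.ndarray, theta: dict[str, float]) -> float:
        c = self.c_dict(x)
        cvec = np.exp(x)
        mask = ~np.isnan(self.c_exp)
        val = float(np.sum(self.w_c[mask]
                           * (cvec[mask] - self.c_exp[mask]) ** 2))
        e_lb, e_ub = self.problem.enzyme_bounds
        for law in self.laws:
            k = law.reaction_id
            w = self.w_e[k]
            if w == 0 or np.isnan(self.e_exp[k]):
                continue
            f = law.f(c, theta)
            if abs(f) < _F_FLOOR:
                f = math.copysign(_F_FLOOR, f if f != 0 else 1.0)
            e = self.v[k] / f
            e = min(max(e, -1e3), 1e3)  # keep finite off the feasible set
            val += w * (e - self.e_exp[k]) ** 2
        return val

    def constraints(self, x: np.ndarray,
                    theta: dict[str, float]) -> np.ndarray:
        """Vector of inequality constraints, feasible when >= 0."""
        cvec = np.exp(x)
        c = {m: cvec[i] for m, i in self.midx.items()}
        e_lb, e_ub = self.problem.enzyme_bounds
        out = [
            (c["atp"] + 0.5 * c["adp"])
            - (self.problem.aec_min + _AEC_MARGIN)
            * (c["atp"] + c["adp"] + c["amp"])
        ]
        for law in self.laws:
            f = law.f(c, theta)
            lo, hi = _f_interval(self.v[law.reaction_id], e_lb, e_ub)
            out.append(f - lo)
            out.append(hi - f)
        return np.array(out)

    def _ls_residuals(self, x: np.ndarray, theta: dict[str, float],
                      rho: float = 1e3) -> np.ndarray:
        """WSLS residual vector plus hinge penalties for the constraints.

        Written to be complex-step differentiable: all branching is on
        real parts, so evaluating at x + i*h*e_j yields exact
        derivatives in the imaginary part.
        """
        cvec = np.exp(x)
        c = {m: cvec[i] for m, i in self.midx.items()}
        mask = ~np.isnan(self.c_exp)
        out = list(np.sqrt(self.w_c[mask])
                   * (cvec[mask] - self.c_exp[mask]))
        e_lb, e_ub = self.problem.enzyme_bounds
        hinges = [
            (c["atp"] + 0.5 * c["adp"])
            - (self.problem.aec_min + _AEC_MARGIN)
            * (c["atp"] + c["adp"] + c["amp"])
        ]
        for law in self.laws:
            k = law.reaction_id
            f = law.f(c, theta)
            flo, fhi = _f_interval(self.v[k], e_lb, e_ub)
            hinges.append(f - flo)
            hinges.append(fhi - f)
            w = self.w_e[k]
            if w > 0 and not np.isnan(self.e_exp[k]):
                fr = f.real if np.iscomplexobj(f) else f
                if abs(fr) < _F_FLOOR:
                    f = _F_FLOOR if fr >= 0 else -_F_FLOOR
                e = self.v[k] / f
                er = e.real if np.iscomplexobj(e) else e
                if er > 1e3:
                    e = 1e3
                elif er < -1e3:
                    e = -1e3
                out.append(math.sqrt(w) * (e - self.e_exp[k]))
        for gi in hinges:
            out.append(rho * _smooth_hinge(gi))
        return np.array(out)

    def solve(self, theta: dict[str, float],
              x0: np.ndarray | None = None,
              maxiter: int = 200) -> tuple[np.ndarray, float, float]:
        """Minimize this condition's WSLS contribution over log c.

        The problem is a box-bounded nonlinear least-squares in log
        concentrations (trust-region reflective), with the energy-charge
        and enzyme-box constraints as hinge penalties; an SLSQP polish
        runs only when a constraint is active at the penalty solution.
        """
        x = self.initial_x() if x0 is None else np.clip(
            x0, self.xlo, self.xhi)
        x = self._restore_feasibility(x, theta)
        # escalate the constraint penalty until violations stop paying
        # off against heavily weighted measurements
        for rho in (1e3, 3e4, 1e6):
            try:
                res = optimize.least_squares(
                    lambda z: self._ls_residuals(z, theta, rho=rho), x,
                    jac=lambda z: _complex_step_jac(
                        lambda zz: self._ls_residuals(zz, theta, rho=rho),
                        z),
                    bounds=(self.xlo, self.xhi), method="trf",
                    xtol=1e-14, ftol=1e-14, gtol=1e-12,
                    max_nfev=60 * len(x))
                if self._merit(res.x, theta) < self._merit(x, theta):
                    x = np.clip(res.x, self.xlo, self.xhi)
            except Exception:
                pass
            if np.min(self.constraints(x, theta)) >= -1e-9:
                break
        x = self._lift_atp(x, theta)
        x = self._repair_f_bounds(x, theta)
        if np.min(self.constraints(x, theta)) < -1e-9:
            xp = self._lift_atp(self._polish_constrained(x, theta,
                                                         maxiter), theta)
            xp = self._repair_f_bounds(xp, theta)
            # feasibility outranks the objective when choosing between
            # the penalty solution and the constrained polish
            key = lambda z: (-min(np.min(self.constraints(z, theta)),
                                  0.0) > 1e-9,
                             self.objective(z, theta))
            x = min((x, xp), key=key)
        viol = float(-min(np.min(self.constraints(x, theta)), 0.0))
        return x, self.objective(x, theta) + self.passthrough_wsls, viol

    def _lift_atp(self, x, theta):
        """Exact repair of a marginal energy-charge violation: raise the
        free ATP level to the smallest charge-feasible value."""
        if self.constraints(x, theta)[0] >= 0:
            return x
        c = self.c_dict(x)
        target = min(self.problem.aec_min + 2 * _AEC_MARGIN, 0.999999)
        atp = atp_for_energy_charge(target, c["adp"], c["amp"])
        lo, hi = self.problem.conc_bounds
        if atp < lo or atp > hi or atp <= c["atp"]:
            return x
        x = x.copy()
        x[self.midx["atp"]] = math.log(atp)
        return x

    def _restore_feasibility(self, x0, theta, rho: float = 1e3,
                             tether: float = 0.3):
        """Move onto the feasible side of every constraint first.

        The WSLS residuals contain an e = v/f singularity at f = 0, so a
        start on the wrong side of a near-equilibrium rate law cannot
        cross over during the main solve.  The constraint hinges alone
        are singularity-free; minimizing them (with a weak tether to the
        start) crosses equilibrium freely and lands on the correct side.
        """
        if np.min(self.constraints(x0, theta)) >= -1e-10:
            return x0

        def resid(z):
            g = self.constraints(z, theta)
            out = [rho * _smooth_hinge(gi) for gi in g]
            out.extend(tether * (z - x0))
            return np.array(out)

        try:
            res = optimize.least_squares(
                resid, x0,
                jac=lambda z: _complex_step_jac(resid, z),
                bounds=(self.xlo, self.xhi), method="trf",
                xtol=1e-12, ftol=1e-12, gtol=1e-12,
                max_nfev=40 * len(x0))
            if (np.min(self.constraints(res.x, theta))
                    > np.min(self.constraints(x0, theta))):
                return np.clip(res.x, self.xlo, self.xhi)
        except Exception:
            pass
        return x0

    def _repair_f_bounds(self, x, theta, tol: float = 1e-9,
                         margin: float = 1e-8):
        """Exact repair of marginal rate-factor bound violations.

        An optimum frequently sits exactly on an f-interval boundary
        (e.g. a knocked-out enzyme pinned at the measurement floor), and
        the iterative solvers settle within ~1e-6 of it.  Each shipped
        rate law is monotone in every single concentration at fixed
        others, so a 1-D root find on one metabolite places f exactly on
        the feasible side.  Repairs are accepted only when they do not
        worsen feasibility elsewhere."""
        e_lb, e_ub = self.problem.enzyme_bounds
        for _ in range(6):
            g = self.constraints(x, theta)
            worst = int(np.argmin(g))
            if g[worst] >= -tol or worst == 0:
                break
            law = self.laws[(worst - 1) // 2]
            lo, hi = _f_interval(self.v[law.reaction_id], e_lb, e_ub)
            target = (lo + margin) if (worst - 1) % 2 == 0 else \
                (hi - margin)
            x_new = self._root_f(x, theta, law, target)
            if x_new is None:
                break
            g_new = self.constraints(x_new, theta)
            if np.min(g_new) <= np.min(g):
                break
            x = x_new
        return x

    def _root_f(self, x, theta, law, target):
        from scipy.optimize import brentq

        cvec = np.exp(x)
        candidates = sorted(
            (m for m in law.required_metabolites if m in self.midx),
            key=lambda m: self.w_c[self.midx[m]])
        for m in candidates:
            i = self.midx[m]

            def fdiff(t):
                c = {mm: cvec[jj] for mm, jj in self.midx.items()}
                c[m] = math.exp(t)
                return law.f(c, theta) - target

            flo, fhi = fdiff(self.xlo), fdiff(self.xhi)
            if flo * fhi > 0:
                continue
            try:
                t = brentq(fdiff, self.xlo, self.xhi, xtol=1e-14)
            except ValueError:
                continue
            x_new = x.copy()
            x_new[i] = t
            return x_new
        return None

    def _polish_constrained(self, x0, theta, maxiter):
        from scipy.optimize._numdiff import approx_derivative

        # small margin so SLSQP's approximate feasibility still clears
        # the strict tolerance after convergence
        confun = lambda z: self.constraints(z, theta) - 1e-8
        x = x0
        for _ in range(3):
            scale = max(1e-12, self.objective(x, theta))
            obj = lambda z: self.objective(z, theta) / scale
            res = optimize.minimize(
                obj, x, method="SLSQP",
                jac=lambda z: approx_derivative(obj, z, method="3-point",
                                                rel_step=1e-7),
                constraints=[{"type": "ineq", "fun": confun}],
                bounds=[(self.xlo, self.xhi)] * len(x),
                options={"maxiter": maxiter, "ftol": 1e-14})
            xc = np.clip(res.x, self.xlo, self.xhi)
            key = lambda z: (-min(np.min(self.constraints(z, theta)),
                                  0.0) > 1e-9,
                             self.objective(z, theta))
            if key(xc) < key(x):
                x = xc
            else:
                break
        return x

    def _merit(self, x, theta, rho=1e6):
        g = self.constraints(x, theta)
        return self.objective(x, theta) + rho * float(
            np.sum(np.minimum(g, 0.0) ** 2))


# --------------------------------------------------------------------------
# block-coordinate solver
# --------------------------------------------------------------------------

def _theta_step(problem: WSLSProblem, blocks: list[_ConditionBlock],
                theta: dict[str, float], xs: dict[str, np.ndarray],
                fixed: dict[str, float]) -> dict[str, float]:
    """Per-reaction bounded least-squares update of the kinetic parameters."""
    km = problem.kinetic_model
    theta = dict(theta)
    for rxn, law in km.rate_laws.items():
        names = [p for p in law.parameters if p not in fixed]
        if not names:
            continue
        conds = []
        for blk in blocks:
            w = blk.w_e[rxn]
            if w > 0 and not np.isnan(blk.e_exp[rxn]):
                conds.append((blk, math.sqrt(w)))
        if not conds:
            continue
        lo = np.array([math.log(km.specs[p].global_lb) for p in names])
        hi = np.array([math.log(km.specs[p].global_ub) for p in names])
        t0 = np.clip(np.array([math.log(theta[p]) for p in names]), lo, hi)

        def resid(t):
            trial = dict(theta)
            for p, tv in zip(names, t):
                trial[p] = math.exp(tv)
            out = []
            for blk, sw in conds:
                c = blk.c_dict(xs[blk.cid])
                f = law.f(c, trial)
                if abs(f) < _F_FLOOR:
                    f = math.copysign(_F_FLOOR, f if f != 0 else 1.0)
                e = min(max(blk.v[rxn] / f, -1e3), 1e3)
                out.append(sw * (e - blk.e_exp[rxn]))
            return np.array(out)

        try:
            sol = optimize.least_squares(resid, t0, bounds=(lo, hi),
                                         xtol=1e-12, ftol=1e-12,
                                         max_nfev=200)
        except Exception:
            continue
        if np.sum(sol.fun ** 2) <= np.sum(resid(t0) ** 2) + 1e-15:
            for p, tv in zip(names, sol.x):
                theta[p] = math.exp(tv)
    return theta


def _complex_step_jac(fun, x, h: float = 1e-30) -> np.ndarray:
    """Exact dense Jacobian of a complex-step-safe residual function."""
    x = np.asarray(x, float)
    n = len(x)
    cols = []
    for j in range(n):
        z = x.astype(complex)
        z[j] += 1j * h
        cols.append(np.imag(fun(z)) / h)
    return np.column_stack(cols)


def _joint_polish(problem: WSLSProblem, theta: dict[str, float],
                  blocks: list["_ConditionBlock"],
                  xs: dict[str, np.ndarray],
                  fixed: dict[str, float],
                  max_nfev: int = 400):
    """Simultaneous least-squares refinement of (theta, all c blocks).

    The Jacobian is block-structured (each condition's residuals touch
    only the shared parameters and that condition's concentrations) and
    is assembled exactly by block-wise complex-step differentiation; the
    dense trust-region solver is used because the problem is small but
    ill-conditioned along the shared-ATP valley.
    """
    km = problem.kinetic_model
    free_names = [p for p in km.parameter_names() if p not in fixed]
    npar = len(free_names)
    plo = np.array([math.log(km.specs[p].global_lb) for p in free_names])
    phi = np.array([math.log(km.specs[p].global_ub) for p in free_names])
    offsets = {}
    pos = npar
    for blk in blocks:
        offsets[blk.cid] = pos
        pos += len(blk.varmets)
    ntot = pos

    z0 = np.empty(ntot)
    z0[:npar] = np.clip([math.log(theta[p]) for p in free_names], plo, phi)
    lo = np.empty(ntot)
    hi = np.empty(ntot)
    lo[:npar] = plo
    hi[:npar] = phi
    for blk in blocks:
        o = offsets[blk.cid]
        k = len(blk.varmets)
        z0[o:o + k] = np.clip(xs[blk.cid], blk.xlo, blk.xhi)
        lo[o:o + k] = blk.xlo
        hi[o:o + k] = blk.xhi

    def unpack(z):
        th = dict(theta)
        th.update(fixed)
        for p, zv in zip(free_names, z[:npar]):
            th[p] = math.exp(zv)
        return th

    def fun(z):
        th = unpack(z)
        out = []
        for blk in blocks:
            o = offsets[blk.cid]
            out.append(blk._ls_residuals(z[o:o + len(blk.varmets)], th))
        return np.concatenate(out)

    r0 = fun(z0)
    row_of = {}
    row = 0
    for blk in blocks:
        k = len(blk.varmets)
        nrows = len(blk._ls_residuals(z0[offsets[blk.cid]:
                                         offsets[blk.cid] + k],
                                      unpack(z0)))
        row_of[blk.cid] = (row, row + nrows)
        row += nrows

    def jac(z):
        """Exact block-structured Jacobian by complex step."""
        th = unpack(z)
        J = np.zeros((len(r0), ntot))
        h = 1e-30
        for blk in blocks:
            o = offsets[blk.cid]
            k = len(blk.varmets)
            r0b, r1b = row_of[blk.cid]
            xb = z[o:o + k]
            for jloc in range(k):
                zz = xb.astype(complex)
                zz[jloc] += 1j * h
                J[r0b:r1b, o + jloc] = \
                    np.imag(blk._ls_residuals(zz, th)) / h
        for jp, p in enumerate(free_names):
            thc = dict(th)
            thc[p] = np.exp(z[jp] + 1j * h)
            for blk in blocks:
                o = offsets[blk.cid]
                k = len(blk.varmets)
                r0b, r1b = row_of[blk.cid]
                J[r0b:r1b, jp] = np.imag(
                    blk._ls_residuals(z[o:o + k].astype(complex), thc)) / h
        return J

    try:
        res = optimize.least_squares(
            fun, z0, jac=jac, bounds=(lo, hi), method="trf",
            tr_solver="exact", x_scale="jac", xtol=1e-13, ftol=1e-13,
            gtol=1e-13, max_nfev=max_nfev)
        z = res.x if np.sum(res.fun ** 2) <= np.sum(r0 ** 2) else z0
    except Exception:
        z = z0
    th = unpack(z)
    xs_new = {blk.cid: z[offsets[blk.cid]:offsets[blk.cid]
                         + len(blk.varmets)].copy() for blk in blocks}
    return th, xs_new


_ATP_SCALE_DIRECTION = {
    # signs that keep e = v/f invariant when every condition's ATP is
    # scaled by exp(+delta)
    "kcat_PFK": -1.0, "kcat_PYK": 1.0, "kcat_GND": 1.0, "Keq_PGK": 1.0,
}


def _atp_scale_step(problem: WSLSProblem, blocks, theta, xs):
    """Exact line search along the shared-ATP-scale valley.

    ATP is unmeasured; multiplying every condition's ATP by a common
    factor can be compensated almost exactly by rescaling the
    ATP-coupled parameters, producing a long curved valley that
    coordinate and trust-region steps traverse slowly.  A 1-D search
    along that direction jumps through it."""
    km = problem.kinetic_model
    dir_names = [p for p in _ATP_SCALE_DIRECTION if p in theta]

    def move(delta):
        th = dict(theta)
        for p in dir_names:
            spec = km.specs[p]
            th[p] = min(max(theta[p]
                            * math.exp(_ATP_SCALE_DIRECTION[p] * delta),
                            spec.global_lb), spec.global_ub)
        xs_new = {}
        for blk in blocks:
            x = xs[blk.cid].copy()
            i = blk.midx["atp"]
            x[i] = min(max(x[i] + delta, blk.xlo), blk.xhi)
            xs_new[blk.cid] = x
        return th, xs_new

    def obj(delta):
        th, xs_new = move(delta)
        total = 0.0
        for blk in blocks:
            total += blk.objective(xs_new[blk.cid], th)
            g = blk.constraints(xs_new[blk.cid], th)
            total += 1e6 * float(np.sum(np.minimum(g, 0.0) ** 2))
        return total

    res = optimize.minimize_scalar(obj, bounds=(-2.0, 2.0),
                                   method="bounded",
                                   options={"xatol": 1e-8})
    if res.fun < obj(0.0):
        return move(res.x)
    return theta, xs


def _bcd(problem: WSLSProblem, theta0: dict[str, float],
         fixed: dict[str, float] | None = None,
         xs0: dict[str, np.ndarray] | None = None,
         max_sweeps: int = 8, tol: float = 1e-8,
         inner_maxiter: int = 120):
    """Alternate concentration blocks and parameter blocks to convergence.

    Returns (theta, xs, wsls, per-condition wsls, max constraint violation).
    """
    fixed = dict(fixed or {})
    theta = dict(theta0)
    theta.update(fixed)
    blocks = [_ConditionBlock(problem, c) for c in problem.dataset.conditions]
    xs = {}
    for blk in blocks:
        xs[blk.cid] = (xs0[blk.cid].copy() if xs0 and blk.cid in xs0
                       else blk.initial_x())
    prev = np.inf
    wsls = np.inf
    per_cond: dict[str, float] = {}
    viol = np.inf
    for sweep in range(max_sweeps):
        wsls = 0.0
        viol = 0.0
        for blk in blocks:
            x, val, v = blk.solve(theta, xs[blk.cid],
                                  maxiter=inner_maxiter)
            xs[blk.cid] = x
            per_cond[blk.cid] = val
            wsls += val
            viol = max(viol, v)
        theta = _theta_step(problem, blocks, theta, xs, fixed)
        if abs(prev - wsls) <= tol * max(1.0, abs(wsls)):
            break
        prev = wsls
    # joint refinement escapes the slow coordinate-descent valley that
    # couples shared parameters with the unmeasured ATP levels
    if not fixed:
        theta, xs = _atp_scale_step(problem, blocks, theta, xs)
    theta, xs = _joint_polish(problem, theta, blocks, xs, fixed,
                              max_nfev=300 if not fixed else 80)
    # final concentration pass so (c, theta) are mutually consistent
    wsls = 0.0
    viol = 0.0
    for blk in blocks:
        x, val, v = blk.solve(theta, xs[blk.cid], maxiter=inner_maxiter)
        xs[blk.cid] = x
        per_cond[blk.cid] = val
        wsls += val
        viol = max(viol, v)
    return theta, xs, wsls, per_cond, viol


def _repair_energy_charge(problem, blk, c):
    """Lift free ATP minimally when the charge is a hair under the bound."""
    aec = adenylate_energy_charge(c["atp"], c["adp"], c["amp"])
    if aec >= problem.aec_min - AEC_TOL:
        return c
    atp = atp_for_energy_charge(min(problem.aec_min + 1e-9, 0.999999),
                                c["adp"], c["amp"])
    if problem.conc_bounds[0] <= atp <= problem.conc_bounds[1]:
        c = dict(c)
        c["atp"] = atp
    return c


def _default_theta(problem: WSLSProblem) -> dict[str, float]:
    km = problem.kinetic_model
    theta = {}
    for name in km.parameter_names():
        spec = km.specs[name]
        theta[name] = math.sqrt(spec.global_lb * spec.global_ub) \
            if spec.kind != "Keq" else (spec.keq_reference or math.sqrt(
                spec.global_lb * spec.global_ub))
        if spec.kind == "kcat":
            theta[name] = 10.0  # plausible central activity
    return theta


def _informed_start(problem: WSLSProblem):
    """Data-informed start: per-reaction fits at measured concentrations.

    ATP is unmeasured, yet it couples several rate laws through a shared
    per-condition level; v/(e_PFK) fixes each condition's ATP up to one
    global activity scale, which is profiled over a coarse grid before
    the per-reaction parameter fits.
    """
    blocks = [_ConditionBlock(problem, c) for c in problem.dataset.conditions]
    xs = {blk.cid: blk.initial_x() for blk in blocks}
    theta0 = _default_theta(problem)
    lo, hi = problem.conc_bounds
    q = {}
    for blk in blocks:
        e_pfk = blk.e_exp.get("PFK")
        v_pfk = blk.v.get("PFK")
        if e_pfk is not None and not np.isnan(e_pfk) and e_pfk > 0 \
                and v_pfk and v_pfk > 0:
            q[blk.cid] = v_pfk / e_pfk
    best = None
    kcat_grid = np.geomspace(0.1, 1e4, 11) if q else [None]
    for kcat in kcat_grid:
        xs_k = {cid: x.copy() for cid, x in xs.items()}
        if kcat is not None:
            for blk in blocks:
                if blk.cid in q:
                    atp = min(max(q[blk.cid] / kcat, lo), hi)
                    xs_k[blk.cid][blk.midx["atp"]] = math.log(atp)
        theta_k = _theta_step(problem, blocks, theta0, xs_k, {})
        obj = sum(blk.objective(xs_k[blk.cid], theta_k) for blk in blocks)
        if best is None or obj < best[0]:
            best = (obj, theta_k, xs_k)
    return best[1], best[2]


def _random_theta(problem: WSLSProblem, rng) -> dict[str, float]:
    km = problem.kinetic_model
    out = {}
    for name in km.parameter_names():
        spec = km.specs[name]
        out[name] = math.exp(rng.uniform(math.log(spec.global_lb),
                                         math.log(spec.global_ub)))
    return out


def solve_wsls(problem: WSLSProblem, n_starts: int = 200, seed: int = 0,
               max_sweeps: int = 8, tol: float = 1e-8) -> EstimationResult:
    """Multi-start solve of the estimation problem; best feasible local
    optimum wins."""
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    if problem.aec_min > 1.0:
        raise WSLSInfeasibleError(
            f"aec_min={problem.aec_min} exceeds 1: the adenylate energy "
            "charge (ATP + ADP/2)/(ATP + ADP + AMP) can never exceed 1",
            {"aec_min": problem.aec_min})
    rng = np.random.default_rng(seed)
    best = None
    n_converged = 0
    worst_diag: dict = {}
    for s in range(n_starts):
        if s == 0:
            theta0, xs0 = _informed_start(problem)
        else:
            theta0 = _random_theta(problem, rng)
            xs0 = None
        theta, xs, wsls, per_cond, viol = _bcd(
            problem, theta0, xs0=xs0, max_sweeps=max_sweeps, tol=tol)
        if viol <= 1e-6:
            n_converged += 1
            if best is None or wsls < best[2]:
                best = (theta, xs, wsls, per_cond, s)
        else:
            worst_diag = _violation_diagnostics(problem, theta, xs)
    if best is None:
        raise WSLSInfeasibleError(
            "no feasible start found", worst_diag)
    theta, xs, wsls, per_cond, best_seed = best
    blocks = {blk.cid: blk for blk in
              (_ConditionBlock(problem, c)
               for c in problem.dataset.conditions)}
    c_hat, e_hat = {}, {}
    for cid, x in xs.items():
        blk = blocks[cid]
        c = blk.c_dict(x)
        c = _repair_energy_charge(problem, blk, c)
        c_hat[cid] = {**c, **blk.passthrough_c}
        e_hat[cid] = blk.enzyme_estimates(c, theta)
    return EstimationResult(
        theta=ParameterSet(dict(theta), provenance="WSLS fit"),
        c_hat=c_hat, e_hat=e_hat, wsls=float(wsls),
        n_starts=n_starts, n_converged=n_converged,
        best_start_seed=best_seed,
        condition_wsls={k: float(v) for k, v in per_cond.items()})


def _violation_diagnostics(problem, theta, xs) -> dict:
    out = {}
    for cond in problem.dataset.conditions:
        blk = _ConditionBlock(problem, cond)
        g = blk.constraints(xs[cond.condition_id], theta)
        labels = ["AEC"]
        for law in blk.laws:
            labels += [f"{law.reaction_id}:f_lo", f"{law.reaction_id}:f_hi"]
        for lab, gv in zip(labels, g):
            if gv < -1e-6:
                out[f"{cond.condition_id}/{lab}"] = float(gv)
    return out


def condition_wsls(problem: WSLSProblem, theta: ParameterSet | dict,
                   max_sweeps: int = 1) -> dict[str, float]:
    """Optimal per-condition WSLS contributions with theta held fixed."""
    t = theta.values if isinstance(theta, ParameterSet) else dict(theta)
    _, _, _, per_cond, viol = _bcd(problem, t, fixed=dict(t),
                                   max_sweeps=max_sweeps)
    if viol > 1e-6:
        raise WSLSInfeasibleError("inner problem infeasible at this theta",
                                  {"max_violation": viol})
    return per_cond


# --------------------------------------------------------------------------
# confidence intervals
# --------------------------------------------------------------------------

def profile_confidence_interval(profile, value: float, w0: float,
                                delta: float, alpha: float,
                                bounds: tuple[float, float],
                                scale: float = 1.0) -> CIEntry:
    """CI from a local quadratic fit to an objective profile.

    ``profile(theta_p)`` returns the re-optimized objective with the
    parameter pinned at ``theta_p``.  The objective increase is modelled as
    0.5 * a * (theta_p - value)^2; the CI is where the increase stays below
    the chi-square quantile (1 dof), truncated at the global bounds.
    """
    chi2 = scale * stats.chi2.ppf(1.0 - alpha, df=1)
    lo_b, up_b = bounds
    step = delta * abs(value) if value != 0 else delta
    up_p = min(value + step, up_b)
    lo_p = max(value - step, lo_b)
    w_hi = profile(up_p) if up_p > value else w0
    w_lo = profile(lo_p) if lo_p < value else w0
    # second difference on a possibly asymmetric stencil
    h1 = value - lo_p
    h2 = up_p - value
    if h1 > 0 and h2 > 0:
        a = 2.0 * (h1 * (w_hi - w0) + h2 * (w_lo - w0)) \
            / (h1 * h2 * (h1 + h2))
    elif h2 > 0:
        a = 2.0 * (w_hi - w0) / h2 ** 2
    elif h1 > 0:
        a = 2.0 * (w_lo - w0) / h1 ** 2
    else:
        a = 0.0
    scale = max(abs(w0), 1e-12)
    if a <= 1e-10 * scale / max(step, 1e-300) ** 2:
        return CIEntry(value, lo_b, up_b,
                       (up_b - lo_b) / abs(value) if value else np.inf,
                       flag="flat")
    half = math.sqrt(2.0 * chi2 / a)
    lower, upper = value - half, value + half
    flag = ""
    if lower < lo_b:
        lower, flag = lo_b, "unbounded-below"
    if upper > up_b:
        upper = up_b
        flag = "unbounded-above" if not flag else "flat"
    rel = (upper - lower) / abs(value) if value else np.inf
    return CIEntry(value, lower, upper, rel, flag)


def estimate_confidence_intervals(problem: WSLSProblem,
                                  result: EstimationResult,
                                  alpha: float = 0.05,
                                  delta: float = 0.05,
                                  method: str = "hessian",
                                  scale_variance: bool = True,
                                  max_sweeps: int = 1) -> ConfidenceIntervals:
    """Confidence intervals from one-at-a-time parameter sensitivity.

    ``method="profile"`` perturbs each parameter by ``delta`` (relative),
    re-optimizes everything else and fits a local quadratic to the
    objective profile.  ``method="hessian"`` (default) evaluates the same
    local quadratic directly from the Gauss-Newton curvature of the
    residuals at the optimum (the Schur complement of the full curvature
    matrix onto the parameter's coordinate), which gives the identical
    interval in the quadratic regime at a fraction of the cost.  Both
    compare the objective increase against the chi-square quantile
    (1 dof) and truncate at the global parameter bounds.
    """
    scale = _variance_scale(problem, result) if scale_variance else 1.0
    if method == "profile":
        return _profile_cis(problem, result, alpha, delta, max_sweeps,
                            scale)
    if method != "hessian":
        raise ValueError("method must be 'hessian' or 'profile'")
    return _hessian_cis(problem, result, alpha, scale)


def _variance_scale(problem, result) -> float:
    """Residual variance factor (reduced chi-square), floored at 1.

    The weights model only the concentration measurement error; the
    fixed fluxes carry error of their own, which shows up as residual
    overdispersion.  Scaling the chi-square threshold by the reduced
    chi-square is the standard errors-in-objective correction (the same
    default scaling ordinary weighted nonlinear regression applies to
    parameter covariances)."""
    n_meas = 0
    for cond in problem.dataset.conditions:
        n_meas += len(cond.metabolites) + len(cond.enzymes)
    n_free = (problem.kinetic_model.n_parameters
              + len(problem.variable_metabolites)
              * len(problem.dataset.conditions))
    dof = n_meas - n_free
    if dof <= 0:
        return 1.0
    return max(1.0, result.wsls / dof)


def _optimum_coordinates(problem, result):
    blocks = [_ConditionBlock(problem, c) for c in problem.dataset.conditions]
    lo, hi = problem.conc_bounds
    xs_opt = {}
    for blk in blocks:
        xs_opt[blk.cid] = np.array([
            math.log(min(max(result.c_hat[blk.cid][m], lo), hi))
            for m in blk.varmets])
    return blocks, xs_opt


def _profile_cis(problem, result, alpha, delta, max_sweeps, scale=1.0):
    km = problem.kinetic_model
    theta_opt = dict(result.theta.values)
    blocks, xs_opt = _optimum_coordinates(problem, result)
    w0 = result.wsls
    entries = {}
    for name in km.parameter_names():
        spec = km.specs[name]
        value = theta_opt[name]

        def profile(theta_p, _name=name):
            fixed = {_name: theta_p}
            theta0 = dict(theta_opt)
            theta0[_name] = theta_p
            for attempt in range(2):
                try:
                    _, _, w, _, viol = _bcd(
                        problem, theta0, fixed=fixed, xs0=xs_opt,
                        max_sweeps=max_sweeps, inner_maxiter=60)
                except Exception:
                    viol, w = np.inf, np.inf
                if viol <= 1e-5 and np.isfinite(w):
                    return max(w, w0)
            return w0  # treat as uninformative rather than failing

        entries[name] = profile_confidence_interval(
            profile, value, w0, delta, alpha,
            (spec.global_lb, spec.global_ub), scale=scale)
    return ConfidenceIntervals(entries, alpha=alpha)


def _hessian_cis(problem, result, alpha, scale=1.0):
    """Schur-complement curvature of the WSLS profile per parameter."""
    km = problem.kinetic_model
    theta_opt = dict(result.theta.values)
    blocks, xs_opt = _optimum_coordinates(problem, result)
    free_names = km.parameter_names()
    _, _, J, offsets, npar = _joint_jacobian(problem, theta_opt, blocks,
                                             xs_opt, free_names)
    H = 2.0 * (J.T @ J)
    chi2 = scale * stats.chi2.ppf(1.0 - alpha, df=1)
    lam, Q = np.linalg.eigh(H)
    # curvatures below ~0.05 per (log unit)^2 produce intervals wider
    # than the whole parameter box; clamping there keeps numerically
    # null directions from being mistaken for stiff ones, and the
    # bound-truncation below reports them as flat/unbounded
    lam_eff = np.maximum(lam, 0.05)
    entries = {}
    for jp, name in enumerate(free_names):
        spec = km.specs[name]
        value = theta_opt[name]
        lo_b, up_b = spec.global_lb, spec.global_ub
        var_log = float(np.sum(Q[jp] ** 2 / lam_eff))
        if not np.isfinite(var_log) or var_log <= 0:
            entries[name] = CIEntry(
                value, lo_b, up_b,
                (up_b - lo_b) / abs(value) if value else np.inf,
                flag="flat")
            continue
        a_log = 1.0 / var_log  # profile curvature in log theta
        half_log = math.sqrt(2.0 * chi2 / a_log)
        half = value * half_log  # linearized to the parameter's scale
        lower, upper = value - half, value + half
        flag = ""
        if lower < lo_b:
            lower, flag = lo_b, "unbounded-below"
        if upper > up_b:
            upper = up_b
            flag = "unbounded-above" if not flag else "flat"
        rel = (upper - lower) / abs(value) if value else np.inf
        entries[name] = CIEntry(value, lower, upper, rel, flag)
    return ConfidenceIntervals(entries, alpha=alpha)


def _joint_jacobian(problem, theta, blocks, xs, free_names):
    """Residuals and exact Jacobian of the joint problem at a point."""
    h = 1e-30
    npar = len(free_names)
    offsets = {}
    pos = npar
    for blk in blocks:
        offsets[blk.cid] = pos
        pos += len(blk.varmets)
    ntot = pos
    z = np.empty(ntot)
    for jp, p in enumerate(free_names):
        z[jp] = math.log(theta[p])
    for blk in blocks:
        o = offsets[blk.cid]
        z[o:o + len(blk.varmets)] = xs[blk.cid]
    residuals = []
    row_of = {}
    row = 0
    for blk in blocks:
        r = blk._ls_residuals(xs[blk.cid], theta)
        residuals.append(r)
        row_of[blk.cid] = (row, row + len(r))
        row += len(r)
    r0 = np.concatenate(residuals)
    J = np.zeros((len(r0), ntot))
    for blk in blocks:
        o = offsets[blk.cid]
        r0b, r1b = row_of[blk.cid]
        xb = xs[blk.cid]
        for jloc in range(len(xb)):
            zz = xb.astype(complex)
            zz[jloc] += 1j * h
            J[r0b:r1b, o + jloc] = np.imag(
                blk._ls_residuals(zz, theta)) / h
    for jp, p in enumerate(free_names):
        thc = dict(theta)
        thc[p] = theta[p] * np.exp(1j * h)
        for blk in blocks:
            r0b, r1b = row_of[blk.cid]
            J[r0b:r1b, jp] = np.imag(
                blk._ls_residuals(xs[blk.cid].astype(complex), thc)) / h
    return z, r0, J, offsets, npar


# --------------------------------------------------------------------------
# fit quality and simplification diagnostics
# --------------------------------------------------------------------------

def fit_coverage(result: EstimationResult, dataset: OmicsDataset,
                 variance_floor: float = 0.05) -> dict[str, float]:
    """Fractions of measurements matched within one standard deviation."""
    weights = compute_weights(dataset, variance_floor)
    hits = {"metabolites": 0, "enzymes": 0}
    total = {"metabolites": 0, "enzymes": 0}
    for cond in dataset.conditions:
        cid = cond.condition_id
        for m, meas in cond.metabolites.items():
            est = result.c_hat.get(cid, {}).get(m)
            if est is None:
                continue
            sd = 1.0 / math.sqrt(weights.metabolite(cid, m))
            total["metabolites"] += 1
            if abs(est - meas.mean) <= sd + 1e-12:
                hits["metabolites"] += 1
        for k, meas in cond.enzymes.items():
            est = result.e_hat.get(cid, {}).get(k)
            if est is None:
                continue
            sd = 1.0 / math.sqrt(weights.enzyme(cid, k))
            total["enzymes"] += 1
            if abs(est - meas.mean) <= sd + 1e-12:
                hits["enzymes"] += 1
    out = {}
    for key in ("metabolites", "enzymes"):
        out[key] = hits[key] / total[key] if total[key] else float("nan")
    pooled_total = total["metabolites"] + total["enzymes"]
    out["pooled"] = ((hits["metabolites"] + hits["enzymes"]) / pooled_total
                     if pooled_total else float("nan"))
    out["n_measurements"] = pooled_total
    return out


def simplification_diagnostics(result: EstimationResult,
                               problem: WSLSProblem,
                               bound_frac: float = 0.01,
                               scale_ratio: float = 1e3) -> list[dict]:
    """Flag parameters pinned at global bounds or badly scaled binding
    coefficients, with the suggested rate-law simplification."""
    km = problem.kinetic_model
    flags = []
    for name, value in result.theta.values.items():
        spec = km.specs[name]
        entry = {"parameter": name, "value": value, "flags": [],
                 "suggestion": ""}
        if value <= spec.global_lb * (1 + bound_frac):
            entry["flags"].append("at-lower-bound")
        if value >= spec.global_ub * (1 - bound_frac):
            entry["flags"].append("at-upper-bound")
        if spec.kind == "Km":
            met, exponent, role = _km_role(km, name)
            if met is not None:
                concs = [ch[met] ** exponent
                         for ch in result.c_hat.values() if met in ch]
                if concs:
                    cmin, cmax = min(concs), max(concs)
                    if value < cmin / scale_ratio:
                        entry["flags"].append("km-negligible")
                        entry["suggestion"] = (
                            f"drop {name} from the denominator "
                            f"({name} << c_{met}^{exponent})")
                    elif value > cmax * scale_ratio:
                        entry["flags"].append("km-dominant")
                        entry["suggestion"] = (
                            f"drop c_{met} and keep {name} "
                            f"({name} >> c_{met}^{exponent})")
        if entry["flags"]:
            flags.append(entry)
    return flags


def _km_role(km: KineticModel, name: str):
    for law in km.rate_laws.values():
        if name in law.km_roles:
            met, exponent, role = law.km_roles[name]
            return met, exponent, role
    return None, None, None


# --------------------------------------------------------------------------
# scikit-learn style front end
# --------------------------------------------------------------------------

class KineticParameterEstimator(BaseEstimator):
    """Estimate in vivo kinetic parameters from a multi-omic dataset.

    Parameters
    ----------
    kinetic_model : KineticModel, optional
        Defaults to the shipped 19-reaction simplified model.
    network : StoichiometricModel, optional
        Used to steady-state-adjust measured fluxes when no pre-adjusted
        fluxes are supplied to :meth:`fit`; defaults to the shipped
        central network.
    n_starts, seed, aec_min, conc_bounds, enzyme_bounds, variance_floor,
    max_sweeps, tol
        Solver settings; see :func:`solve_wsls`.

    Attributes (after fit)
    ----------------------
    theta_ : ParameterSet          fitted kinetic parameters
    wsls_ : float                  objective at the optimum
    c_hat_, e_hat_ : dict          per-condition concentration estimates
    result_ : EstimationResult
    problem_ : WSLSProblem
    """

    def __init__(self, kinetic_model=None, network=None, n_starts=200,
                 seed=0, aec_min=0.8, conc_bounds=(0.001, 10.0),
                 enzyme_bounds=(0.001, 10.0), variance_floor=0.05,
                 max_sweeps=8, tol=1e-8):
        self.kinetic_model = kinetic_model
        self.network = network
        self.n_starts = n_starts
        self.seed = seed
        self.aec_min = aec_min
        self.conc_bounds = conc_bounds
        self.enzyme_bounds = enzyme_bounds
        self.variance_floor = variance_floor
        self.max_sweeps = max_sweeps
        self.tol = tol

    def fit(self, X: OmicsDataset, y=None, adjusted_fluxes=None):
        km = self.kinetic_model or build_simplified_model()
        if adjusted_fluxes is None:
            from .network import load_fixture

            net = self.network or load_fixture()
            adjusted_fluxes = adjust_dataset(net, X)
        weights = compute_weights(X, self.variance_floor)
        self.problem_ = WSLSProblem(
            kinetic_model=km, dataset=X, weights=weights,
            adjusted_fluxes=adjusted_fluxes, aec_min=self.aec_min,
            conc_bounds=tuple(self.conc_bounds),
            enzyme_bounds=tuple(self.enzyme_bounds))
        self.result_ = solve_wsls(self.problem_, n_starts=self.n_starts,
                                  seed=self.seed,
                                  max_sweeps=self.max_sweeps, tol=self.tol)
        self.theta_ = self.result_.theta
        self.wsls_ = self.result_.wsls
        self.c_hat_ = self.result_.c_hat
        self.e_hat_ = self.result_.e_hat
        return self

    def confidence_intervals(self, alpha=0.05, delta=0.05,
                             method="hessian",
                             max_sweeps=1) -> ConfidenceIntervals:
        self._check_fitted()
        return estimate_confidence_intervals(
            self.problem_, self.result_, alpha=alpha, delta=delta,
            method=method, max_sweeps=max_sweeps)

    def coverage(self) -> dict[str, float]:
        self._check_fitted()
        return fit_coverage(self.result_, self.problem_.dataset,
                            self.variance_floor)

    def diagnostics(self) -> list[dict]:
        self._check_fitted()
        return simplification_diagnostics(self.result_, self.problem_)

    def _check_fitted(self):
        if not hasattr(self, "result_"):
            raise RuntimeError("estimator is not fitted yet")
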