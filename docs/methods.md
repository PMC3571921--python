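# Methods

This note documents the models, algorithms and numerical choices behind
`kinfba`, and what the shipped synthetic studies do and do not
demonstrate about real data.

## The central network fixture

`ecoli_central` is a curated ~50-reaction central *E. coli* network:
glycolysis with PTS uptake, the oxidative and non-oxidative pentose
phosphate pathway, the TCA cycle, anaplerosis (PPC, PPCK, malic enzyme),
lumped respiration (NADH oxidation at an effective P/O of 2, ubiquinol at
1), an ATP maintenance drain (lower bound 3.15 mmol/gDW/h), adenylate
kinase, fermentative secretion routes (acetate, ethanol, D-lactate,
formate) that can be blocked, exchanges for glucose, O2, CO2 and
phosphate, and a lumped biomass reaction with core-model precursor
coefficients. Water and protons are not tracked; the respiratory and
secretion reactions are lumped accordingly, so the network is a
steady-state flux scaffold, not an elementally balanced reconstruction.
The biomass reaction releases a small AMP fraction so the adenylate pool
cycles through adenylate kinase. Glucose-6-phosphate dehydrogenase is
lumped with the lactonase, so 6-phosphogluconate connects it directly to
the 6-phosphogluconate dehydrogenase. Hexokinase, non-PTS glucose
transport and the Entner-Doudoroff route are present but shipped with
zero bounds. At dilution rates 0.1–0.7 1/h the model yields
0.097–0.107 gDW per mmol glucose, in the physiological range for aerobic
growth.

## Rate laws and parameters

The simplified kinetic model covers 19 reactions of glycolysis and the
pentose phosphate pathway with 36 distinct parameters (kcat, Keq, Km).
Two functional forms deserve comment:

* the 6-phosphogluconate dehydrogenase (GND) law is
  `kcat·e·c_nadp·c_6pg / (c_nadph·c_atp·(K_6pg + c_6pg))` — the unique
  form consistent with the parameter set (kcat with units
  mmol·mM/mg protein/hr plus a single binding coefficient) and with
  product inhibition by NADPH and ATP; it is registered like any other
  law and can be swapped;
* the PTS and PYK laws are pure concentration ratios
  (`c_pep/c_pyr`, `c_adp/c_atp`) scaled by kcat.

Binding-coefficient roles (saturating denominator vs. activation
multiplier such as PPC's `(1 + c_fdp/K_fdp)`) and each reversible law's
net transformation are declared on the law object; the latter defines the
mass-action ratio used by the thermodynamic module. Equilibrium constants
are interpreted against concentrations in mM, with no standard-state
conversion; the convention cancels between conditions for balanced
reactions. Keq parameters are bounded to 0.35–2.85× a reference value
(≈ ±2.6 kJ/mol at 298.15 K); every other parameter to [1e-6, 1e4] in its
own units. The shipped reference parameter set provides 36 values with
95% half-widths; it doubles as the default ground truth of the synthetic
generator.

## Flux adjustment

Measured flux distributions are projected onto the steady-state space by
minimizing the Euclidean distance over the measured subset, subject to
S·v = 0, the model's bounds (including the maintenance requirement) and
biomass flux fixed to the chemostat dilution rate. A ridge of 1e-9 on
unmeasured fluxes makes the projection unique. The diagonal-Hessian QPs
here (and the minimum-norm steps below) are solved by a null-space
active-set method with OSQP as the robust path and an exact null-space
re-polish of its active set; steady-state feasibility is checked to 1e-8
and infeasibility reports name the bound constraints an elastic
relaxation would move.

## Estimation

The enzyme level of each kinetic reaction is eliminated through
e = v/f(c; θ), reducing the decision variables to the parameters plus one
concentration block per condition (in log space). The solver then:

1. builds a data-informed start — concentrations at their measurements,
   ATP per condition profiled over a coarse activity-scale grid (ATP is
   unmeasured yet couples PFK, PYK, PGK and GND through a shared level),
   parameters from per-reaction bounded least squares;
2. sweeps block-coordinate updates: per-condition concentration solves
   (bounded nonlinear least squares with softplus-smoothed hinge
   penalties for the energy-charge and enzyme-box constraints, with exact
   complex-step Jacobians), then per-reaction parameter solves;
3. takes an exact 1-D line search along the shared-ATP-scale valley — a
   direction in which rescaling every condition's ATP and the four
   ATP-coupled parameters leaves all residuals nearly unchanged — and
   then refines everything jointly by trust-region least squares with an
   exact block-structured Jacobian;
4. repeats from random log-uniform parameter starts (multi-start; the
   library default is 200 starts, and the tests and acceptance runs use
   1–3 because the data-informed start dominates on synthetic studies)
   and keeps the best feasible solution.

Feasibility is enforced, not penalized, at the end: marginal
energy-charge violations are repaired by lifting the free ATP level
exactly, and marginal rate-factor-bound violations (an optimum often sits
exactly on the bound when a knocked-out enzyme is pinned at the
measurement floor) by a monotone 1-D root find on one metabolite of the
law. Solutions must satisfy |v − e·f| ≤ 1e-6·max(1, |v|) and the energy
charge to 1e-9.

Data with a flux clamped to exactly zero on a strictly positive
(irreversible) rate law is genuinely inconsistent with the model —
e·f > 0 whenever e is at or above its lower box — and produces an
infeasibility report rather than a fit.

### Confidence intervals

The profile of the objective in one parameter, with everything else
re-optimized, is modelled as a local quadratic and intersected with the
χ²(1 dof, 1−α) threshold; intervals are truncated at the global parameter
bounds, with flat or one-sided profiles flagged. Two evaluation modes
give the same interval in the quadratic regime:

* `profile`: literal one-at-a-time relative perturbation (default ±5%)
  with warm-started re-optimization — the definitional procedure, used on
  small problems and verified against the closed-form quadratic oracle;
* `hessian` (default): the Schur complement of the Gauss-Newton curvature
  2JᵀJ at the optimum onto the parameter coordinate, computed from the
  same exact Jacobian as the fit. Eigenvalues below 0.05 per (log unit)²
  — curvatures whose interval would exceed the entire parameter box — are
  clamped so numerically null directions read as flat, not stiff.

The χ² threshold is scaled by the reduced chi-square (floored at 1):
the weights model only concentration measurement error, while the fixed
fluxes carry error of their own, which appears as residual
overdispersion; this is the standard covariance scaling of weighted
nonlinear regression and can be disabled (`scale_variance=False`).

Near-equilibrium reactions make kcat·f nearly scale-invariant, so their
catalytic constants come out flat (interval spanning the global box)
while their equilibrium constants stay tightly determined — the expected
behaviour, exercised in the tests.

### Simplification diagnostics

Parameters within 1% of a global bound are flagged, and binding
coefficients are compared with the estimated concentration range of their
metabolite (at the law's exponent): a coefficient below 1e-3× the range
suggests dropping it from the denominator; one above 1e3× suggests
keeping it and dropping the concentration.

## Thermodynamics

ΔG° = −RT ln Keq with R = 8.3145e-3 kJ/mol/K and a default temperature of
298.15 K (the Keq-bracket ↔ 2.6 kJ/mol equivalence holds near this
temperature; configurable). ΔG* adds RT Σ S ln c over the law's net
transformation with c in mM; any missing concentration yields an explicit
not-computable marker. Reactions are classified far from equilibrium when
their mean ΔG* is below −10 kJ/mol, near when within [−2, 0], otherwise
intermediate; irreversible laws carry no Keq and are excluded.
Metabolite effects on enzymes compare the median concentration-to-Km
ratio: outside [0.1, 10] is a strong effect, inside is intermediate;
activation multipliers report activation, saturating denominators report
inhibition.

## Kinetic bounds and KFBA

Flux ranges come from the parameter confidence box truncated at the
global bounds: every shipped law is monotone in each parameter at fixed
concentrations, so vertex enumeration is exact (verified against dense
parameter grids). Reactions lacking an enzyme measurement or a required
metabolite contribute no bound; unmeasured ATP is ranged over the
energy-charge-feasible interval implied by measured ADP and AMP, widening
the bounds honestly.

KFBA minimizes PTS uptake at fixed growth with fermentation blocked
(general bounds −1000/0/1000 mmol/gDW/h), with per-bound binary
relaxations capped at n\* (the MILP minimum, zero integrality gap). Ties
among equally small violation sets are broken deterministically by tiny
index-dependent weights in a second MILP with the objective pinned; a
final minimum-norm QP with the binaries fixed makes the flux vector
unique. Every solution is re-verified by direct substitution,
independently of solver status codes. Evaluation collapses proportionally
coupled reactions (parallel rows of a null-space basis of S with blocked
columns removed) to one residual per group, and reports biomass yield as
growth rate over predicted glucose uptake. The sign test is the exact
two-sided binomial test with ties dropped.

LPs and MILPs run on scipy's HiGHS backends; cobrapy+GLPK serves as an
independent cross-check of the FBA optimum in the tests.

## Synthetic studies

A study emulates a chemostat design: the parental strain at dilution
rates 0.1/0.2/0.4/0.5/0.7 1/h plus perturbation strains at 0.2 1/h, a
seeded 20 + 5 train/test split, ~4-replicate-style standard deviations
(sd = truth × CV) and multiplicative log-normal noise (default CV 5%).
Per condition: a steady-state flux distribution is sampled (glucose-
minimizing LP with a random objective perturbation, then minimum-norm),
concentrations are solved so that e = v/f(c; θ_true) lands inside the
enzyme box with the energy charge satisfied, and enzymes are recovered
exactly — the hidden truth satisfies every model constraint by
construction. Reported flux "measurements" are the projection of the
noisy fluxes back onto the steady-state space, because real chemostat
fluxes come from metabolic flux analysis and satisfy the balances almost
exactly; irreversible kinetic reactions keep a small detection-floor flux
(0.02 mmol/gDW/h) so no reported flux is clamped to zero against a
strictly positive law. ATP is never reported. Knockouts pin one enzyme at
the 0.001 mg protein/gDCW floor and are drawn from pentose phosphate
reactions the network can route around (G6PDH, TALA, TKT2, RPE),
mirroring deletions whose burden isozymes or parallel routes absorb.

What passing tests show: the estimator recovers parameters it should
recover, flags the ones it cannot, and the bounds/KFBA machinery honors
its contracts on data whose noise model is known. What they do not show:
robustness to real measurement error structure (correlated replicate
error, platform biases, missing-not-at-random patterns), to rate-law
misspecification, or to networks beyond central carbon metabolism.

## Problem sizes and determinism

Tests and the acceptance script use 4–5-condition noiseless studies for
exactness checks and a 20 + 5-condition study at 5% noise for recovery,
with 1–3 solver starts; all randomness flows from explicit integer seeds
through `numpy.random.default_rng`, and repeated runs are bit-identical.

## Known limitations

* The estimation problem is non-convex; multi-start gives no global
  guarantee. The shared-ATP valley is handled explicitly, but other flat
  manifolds may exist for other rate-law sets.
* Concentration measurement error is not propagated into the kinetic
  flux bounds (parameter uncertainty only).
* The Hessian-mode confidence intervals are symmetric local quadratics;
  strongly curved profiles are only captured by the profile mode.
* The fixture network is a scaffold for flux patterns, not an elementally
  balanced reconstruction, and the SBML loader accepts genome-scale
  models but none is shipped or tested at that scale.
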