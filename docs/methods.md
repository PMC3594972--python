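# Methods

## The zonal rate model

Membrane chromatography capsules have hold-up volumes (distributors,
channels, tubing) of the same order as the membrane bed itself, and
extreme length-to-width ratios that make the flow over the membrane
cross-section inhomogeneous.  The zonal rate model (ZRM) partitions the
hold-up volumes and the membrane bed into interconnected *virtual
zones* so that flow non-idealities and binding non-idealities can be
quantified independently from breakthrough curves alone, without
knowing the internal capsule geometry:

* hold-up zones are ideally mixed tanks (CSTRs), connected in a
  capsule-family-specific directed network with flow fractions
  `Φ_k` that sum to one;
* each membrane zone is a 1-D convection–dispersion–adsorption slab,

      ∂c/∂t = D_a ∂²c/∂x² − v ∂c/∂x − ((1−ε)/ε) ∂q/∂t ,

  with the bound concentration `q` accounted per unit volume of
  *solid* membrane and the porosity factor converting it to the void
  volume basis;
* a plug-flow region (PFR) in series carries the dead-volume time lag
  `t_lag = V_PFR/Q` that contributes no dispersion.

Single-inlet tanks obey `dc/dt = (c_in − c)/τ` with `τ = V/Q`;
multi-inlet tanks (needed downstream of the membrane in the axial
family) obey `dc/dt = Σ_j c_in,j/τ_j − c/τ` with partial residence
times combining harmonically, `1/τ = Σ_j 1/τ_j`.

**Axial family** (stacked flat sheets): mirror-symmetric networks.
Solute crossing zone k passes tanks 1a..ka, the zone, then kb..1b.
With one zone and equal tanks this is exactly the classic
PFR–CSTR–membrane–CSTR chain (Roper–Lightfoot model); the test suite
asserts that equivalence numerically.

**Radial family** (pleated around a core): a peripheral distribution
channel feeds the bed from outside, a central channel collects; the
upstream and downstream volumes are unequal, and every flow path
crosses the same number of tanks.  With one membrane zone the
distributor/collector tanks are merged into the upstream/downstream
volumes, giving the three-parameter model that suffices for the
capsule studied; for two or more zones the volumes are split equally
over per-zone tank chains.

**Angular sectors.**  Irregular pleat packing causes local deviations
of the linear velocity through the bed.  The single radial membrane
zone can be split into parallel sectors sharing the same tanks, sector
i carrying flow fraction `f_i` at relative velocity `u_i` (the sector
frontal area follows as `A_i = (f_i/u_i)·A_total`; the model conserves
flow, `Σ f_i = 1`, the only constraint the data imposes).  For 16
sectors the flow-over-velocity distribution is reduced to three
parameters: a Gaussian peak (position `mu`, width `sigma`) and, left
of the peak, the maximum of the Gaussian and a linear ramp through the
origin (slope), renormalized to unit total flow.

## Binding kinetics

Langmuir:  `dq/dt = k_a c (q_m − q) − k_d q`.

Spreading (two bound orientations of an ellipsoidal protein competing
for the same sites; sideways occupies `β` times the area of end-on):

    dq1/dt = k_a1 c F − k_d1 q1 − k_12 q1 F + k_21 q2
    dq2/dt = k_a2 c F − k_d2 q2 + k_12 q1 F − k_21 q2
    F      = q_m − q1 − β q2

The spreading model appears in the literature in several variants;
the rate form used here is fixed by two constraints: dimensional
consistency with the published units of the calibrated constants
(`k_12` in L/(g s), `k_21` in 1/s) and the published characteristic
times 1/(k_a1 q_m), 1/(k_12 q_m), 1/k_21.  This forces the 1→2 reorientation
flux to be proportional to the free-site capacity `F` (a sideways
molecule needs more room), giving `k_12 q1 F`, and leaves `k_21 q2`
first-order, following the classic spreading formulation.  With this
form `q1 + β q2 ≤ q_m` is invariant for β ≥ 1 and the model reduces
exactly to Langmuir when all transition and state-2 rates vanish.
The reduced model used throughout sets `k_a2 = k_d2 = 0` (no direct
sideways adsorption/desorption).

At the fitted `k_d1 = 1.06e-5 1/s` the desorption time is
1/k_d1 ≈ 1572 min — effectively irreversible binding over a 15 min
loading; `characteristic_times` always returns the value computed
from the rate constant.

## Numerics

* **Spatial scheme**: cell-centred first-order upwind for convection,
  second-order central for dispersion; Dirichlet inlet (feeding tank's
  outlet concentration), zero-gradient outlet; N = 60 cells per zone
  by default.  The scheme's effective dispersion is `D_a + v·dx/2`;
  since membrane dispersion is physically negligible here (the tanks
  carry the system dispersion) this only thickens the intra-bed front,
  and the grid-convergence test bounds its effect on the breakthrough
  midpoint to < 0.5% on halving the cell size.  The transport module
  is validated against the closed-form advection–dispersion step
  solution evaluated at the effective dispersion.
* **Dispersion coefficient**: fixed to the molecular diffusion
  coefficient of BSA, 6e-7 cm²/s (configurable).
* **Integration**: scipy `solve_ivp` BDF, rtol 1e-6 / atol 1e-9 g/L by
  default; the linear (non-binding) part contributes an analytic
  sparse Jacobian, binding runs use the sparse Jacobian pattern.  The
  PFR is applied as an exact post-hoc time shift of the outlet signal,
  so the lag introduces no numerical dispersion.  Bound-state
  trajectories are reported on the experiment clock (shifted by the
  lag) so they align with the breakthrough curve.
* **Mass audit**: every simulation can be audited (feed in = outlet
  out + mobile hold-up + phase-ratio-weighted bound mass); the suite
  requires closure within 0.5% (typically ~1e-5 relative).
* **Units**: s, cm, mL, g/L throughout; 12 CV/min converts to
  1.0 mL/s (XT5, 5 mL bed) and 28.0 mL/s (XT140, 140 mL bed).  The
  XT5 preset carries both the nominal 5 mL bed volume and the stated
  geometry (0.22 cm × 22.06 cm² = 4.85 mL), which disagree by 3% in
  the manufacturer specification; transport uses the geometry,
  solid-volume arithmetic the nominal volume.

## Calibration

Calibration is staged, mirroring the experimental identification
procedure: (1) flow parameters from a *non-binding* (high-salt) curve
with binding switched off; (2) binding parameters from a binding curve
with the flow model frozen; (3) for radial capsules, the sector
velocity distribution with both frozen.  Each stage minimizes the
unweighted SSE on c/c0 at the recorded sample times (no weighting
scheme is implied by the data) using bounded trust-region least
squares in log10 parameter space, started from `n_starts` log-uniform
draws within the bounds (default 20, seed 42; deterministic given the
seed).  An optional `sse_stop` skips remaining starts once a target
SSE is reached — useful for noiseless self-consistency fits whose
optimum is exactly zero, and set in such fits to values far below any
measurement noise.  Zone-count selection fits nested models with
increasing zone counts and stops when the relative SSE improvement
falls below 5% (configurable).

Identifiability caveats established while validating the estimator:

* Under non-binding conditions the radial one-zone response is exactly
  invariant to exchanging the upstream and downstream tank volumes
  (linear blocks in series commute), so the pair is identifiable only
  up to order; fits are canonicalized with V_upstream ≥ V_downstream,
  matching the physical distributor/collector asymmetry.
* The small downstream collector volume (~0.7 s residence at
  28 mL/s) is weakly identified from 1%-noise data: across noise
  realizations its error is typically ~10% while the PFR and upstream
  volumes recover to a few percent.
* The end-on desorption constant `k_d1` (1/k_d1 ≈ 26 h against a
  15 min loading) barely moves the curve; recovering it from
  noiseless data requires tight integration tolerances (rtol ~1e-9)
  so the optimizer can resolve its residual signature above solver
  noise.
* Fitting the Langmuir model to spreading-generated data leaves a
  large residual (it cannot produce the slow tail) and its `q_m` is
  not separately identifiable there — only the equilibrium capacity
  is.
* A sector-distribution width `sigma` below about a quarter of the
  velocity-grid spacing makes the objective flat in `mu` between grid
  points (the Gaussian underflows on every sector); bounds should
  keep `sigma` above that resolution limit.

## Synthetic data

No public breakthrough data exist for these capsules, so the
generator emulates the study's experiments: step input at 1 g/L and
12 CV/min on the XT5 (axial, 5 mL) or XT140 (radial, 140 mL)
geometry, additive Gaussian detector noise on c/c0 (default
σ = 0.005, consistent with the appearance of published UV traces;
clipped at zero as a detector would report), and a fixed sampling
interval.  Ground-truth flow, binding and sector parameters are
stored in the curve metadata, enabling closed-loop recovery tests.
The generator reproduces the *model's* statistical structure plus
detector noise only: real curves additionally contain cleaning- and
storage-history capacity drift, pump ripple and detector drift, so
passing recovery tests demonstrate estimator correctness under the
model, not robustness to un-modelled experimental artefacts.

The irregular-pleat fixture imposes a known heterogeneous velocity
distribution on the radial capsule and serves as the target for the
scale-up studies: a sector-free prediction overshoots its slow
plateau approach, and including the true distribution closes the gap.

## Problem sizes used in the test suite

Simulation-heavy tests run on coarsened grids chosen by convergence
behaviour: recovery fits use 10–20 cells per zone and 0.5–15 s output
spacing; the deterministic landmark simulation uses the full default
grid (60 cells, 1 s sampling).  The reported landmark (the sideways-
orientation peak during loading of the axial capsule) computes to
~380 s on grids from 30 to 120 cells.

## Known limitations

* Loading step only; wash/elution/regeneration and multi-component
  competition are out of scope.
* Radial zones are flat slabs (bed height ≪ capsule radius); no true
  cylindrical transport, no intra-membrane film/pore-diffusion
  resistance.
* Topologies are restricted to the axial/radial families described
  above; no recirculation or arbitrary user graphs.
* No confidence intervals on fitted parameters; the multi-start
  records give qualitative basin information only.
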