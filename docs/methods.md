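# Methods

`fibroflow` models the dissolution of an occlusive fibrin clot perfused by a
pressure-driven flow carrying a lytic agent.  Two coupled descriptions are
implemented: a closed-form one-dimensional front-propagation model, and a
mesoscopic lattice-Boltzmann (LB) simulator in which the clot is a porous
medium that the reaction progressively opens.

## The one-dimensional front model (`fibroflow.analytic`)

The clot is a column of length `L` and fibrin concentration `F0` (mg/ml),
perfused at constant seepage speed `u_f`.  All pro-fibrinolytic species
(tPA, plasminogen, plasmin, their activation and inhibition) are lumped into
one anti-fibrin agent ("anti-FA") supplied at the inlet at concentration
`Fbar0`.  The model's two rules are:

1. **Front blocking.** Because the agent binds avidly to intact fibrin, it
   does not penetrate the clot: everything the flow delivers accumulates in
   the front slice of thickness `Delta`, so the local agent concentration
   grows linearly, `Fbar(t) = Fbar0 * u_f * t / Delta`.
2. **Second-order lysis.** Fibrin is consumed at rate
   `dF/dt = -k1 * F * Fbar`; when `F` falls below the threshold `Fstar`, the
   slice is lysed, the front advances, and the accumulated agent moves with
   it.

Integrating rule 2 under rule 1 gives the first-slice lysis time
`t0 = sqrt(2 Delta ln(F0/Fstar) / (k1 u_f Fbar0))` and the recursion
`t_k = Delta/u_f + sqrt(t_{k-1}^2 + 2 Delta ln(F0/Fstar)/(k1 u_f Fbar0))`.
Successive gaps shrink — the front *accelerates* even though the flow is
constant, purely because the agent inherited from lysed slices keeps
accumulating.  Without the travel term the squared times telescope exactly,
so the total time is independent of `Delta`; with it, the total time
converges as `Delta -> 0` and changes by <1% per halving once
`Delta <= L/50`.

`Delta` is snapped to `L/n` with `n = round(L/Delta)` so slices tile the
clot.  Slice times are labelled `t_0 .. t_{n-1}` from the inlet face; the
total lysis time is `t_{n-1}`.

**k1 calibration.** `fit_k1` minimizes the position-space L2 misfit between
a measured front trajectory and the model front over `log10(k1)` (bounded
Brent search in [1e-3, 1e5]).  Because the staircase model front makes the
loss piecewise constant, the fit uses the unbiased piecewise-linear
surrogate through the slice midpoints; the reported RMS residual uses it
too.  Points are unweighted.  The schedule depends on `k1` and `Fbar0` only
through their product, so the fit is identifiable only for a fixed `Fbar0`.
Self-generated noiseless fronts are recovered to well under 1%; with 5%
multiplicative position noise, recovery stays within a few percent.

## The mesoscopic simulator

### Flow (`fibroflow.lb`)

A D2Q9 BGK lattice-Boltzmann solver (D3Q19 constants and the generic
operators are provided for three dimensions).  Clot voxels use Walsh's
partial bounce-back (PBB): each voxel carries a reflection fraction
`gamma in [0, 1]`, and the outgoing population toward each neighbour is
`(1-gamma) f*_i + gamma f_opp(i)` with `f*` post-collision and `f_opp`
pre-collision.  `gamma = 0` is plain streaming, `gamma = 1` on-node
bounce-back (used for the channel walls, giving half-way no-slip planes).
The physically meaningful seepage velocity on PBB nodes carries the factor
`(1-gamma)`; it is the velocity handed to the transport stage and used in
every reported observable.

Driving is either a uniform body force (periodic benchmark cases) or
fixed-density inlet/outlet boundaries equivalent to a prescribed pressure
drop, closed by non-equilibrium extrapolation from the adjacent column.
Guards: `tau in (0.5, 2]`, lattice Mach < 0.1, `|delta rho|/rho <= 0.1`;
violations raise errors rather than warnings.

Benchmarks (also run as tests): plane Poiseuille flow matches the analytic
parabola to 0.6% at `tau = 2` on a 40-node channel; Darcy permeametry of a
uniform-`gamma` slab returns the encoded permeability to better than 1% for
`k` between 1e-13 and 1e-12 m^2; a decaying shear wave reproduces
`nu = cs^2 (tau - 1/2)` within 2%.

### Clot (`fibroflow.clot`)

Per voxel, fibrin concentration maps to hydraulic resistance through the
chain `F -> Rf -> ns -> k -> gamma`:

- radial uniform strand cleavage: `Rf = Rf0 sqrt(F/F0)` (the mass-per-
  cross-section constant is folded into the calibration by requiring
  `Rf(0) = 0`, the only closure consistent with complete dissolution);
- solid fraction `ns = pi Rf^2 lden`, with the strand-length density `lden`
  fixed at calibration;
- Davies' empirical law for fibrous media
  `k = Rf^2 / (16 ns^1.5 (1 + 56 ns^3))`;
- `gamma = 1 / (1 + 2k/(nu dt))`, the PBB fraction whose Darcy limit
  reproduces `k` (the ratio `k/(nu dt)` is dimensionless, so SI values can
  be used directly).

Calibration accepts either the initial solid fraction or, by monotone root
finding of Davies' law, the initial permeability (the default: `k0 = 1e-13
m^2` at `Rf0 = 140 nm` gives `ns0 ~ 0.054`).  Since `ns` is proportional to
`F` under this calibration, permeability strictly increases as lysis
proceeds.

**Synthetic clots.**  Three archetypes, all reproducible bit-for-bit per
seed: homogeneous; *type 1*, per-voxel fibrin drawn uniformly in
`F_mean*(1 +- d/100)` (the dispersion is interpreted as the half-range of
the uniform law, so 100% dispersion around 2 mg/ml spans 0-4 mg/ml); and
*type 2*, 25 disks of high concentration (default 3.5 mg/ml) dropped
uniformly over the clot (overlapping, clipped at the boundary), with the
matrix concentration solved so the whole-clot mean is exactly `F_mean`.
The disk radius defaults to 8.6% of the channel width (2.4 voxels on the
default grid), the disk-to-tube ratio of a 0.5 mm disk in a 5.8 mm tube;
layouts whose coverage would force a negative matrix concentration are
rejected (coverage must stay below `F_mean/F_disk`).

### Transport, reaction and coupling (`fibroflow.transport`)

The anti-FA is an Eulerian concentration field (not meso-particles), updated
by an explicit conservative finite-volume scheme: upwind-biased advection
with a minmod-limited second-order (MUSCL) donor reconstruction on
arithmetic-mean face velocities, plus central diffusion (`D = 3.3e-11
m^2/s` is the tPA value at reference scale).  Plain first-order upwind was
rejected: its numerical diffusivity `u dx/2` exceeds the physical
diffusivity at the cell Peclet numbers of interest and measurably smears
the front-fed agent spike, advancing slice lysis by tens of percent.
Faces whose donor stencil touches a wall or a blocked voxel fall back to
first-order, which keeps the front deposition law exact.  The binding of
the agent to intact fibrin is the **blocking rule**: on voxels with
`F >= Fstar` every incoming flux deposits and every outgoing advective or
diffusive flux vanishes.  In a 1D column this reproduces the front
accumulation law of the analytical model exactly (the tests verify the
slope `Fbar0 u / dx` to 0.002%).  This is the single most consequential
modelling rule in the package: a literal switch that simply froze transport
on blocked voxels would forbid the accumulation the front model requires.
The inlet holds the agent at `Fbar0` (Dirichlet); the outlet is free
outflow; the upstream lumen starts pre-filled at `Fbar0`, as in a
permeation experiment where the lytic solution sits on the clot face at
time zero.  The reaction `F <- F - k1 F Fbar dt` (explicit Euler, clamped
at zero) continues below `Fstar` until the voxel is empty — the threshold
governs transport blocking and lysed-slice bookkeeping, not the chemistry —
and consumes no agent, which acts catalytically at this level of
description.

**Quasi-steady coupling.**  Stokes-regime flow relaxes far faster than the
lysis advances, so the flow is re-solved to quasi-steady state only when
the clot's flow resistance has changed appreciably.  The trigger is a
relative change of `sum(gamma/(1-gamma))` over clot voxels — a proxy
proportional to `sum(1/k)` — measured against the total including an
open-channel offset, with a default threshold of 7.5% and a floor of one
re-solve per 200 reaction steps.  (A per-voxel `gamma` change trigger is
far too twitchy near `gamma ~ 1`, where a large change in one voxel's
`gamma` is a negligible change in total resistance.)  Each re-solve is
preconditioned by a Darcy/Brinkman resistor network — per-voxel
conductances `1/(1/k_voxel + 1/k_profile)`, where `k_profile` is the local
plane-Poiseuille conductance of the contiguous open run the voxel belongs
to; voxels add in parallel within a column, columns in series — which
supplies the density ramp and velocity field that the stiff in-clot
pressure-diffusion mode would otherwise take hundreds of thousands of LB
steps to establish.  Re-solves then run to a velocity-change tolerance of
3e-4 within a budget of 5000 steps.  Against fully converged reference
solves (tolerance 1e-6, up to 5e5 steps) on frozen mid-run fields, this
scheme reproduces the throughput to 5-10% through mid-lysis and to <1%
near the end.  Halving the cadence interval changes the total lysis time
by under 2% at the test settings.

The reaction/transport step is adaptive: it honours the advective CFL
limit, the diffusion number, explicit-Euler positivity
(`dt k1 max(Fbar) < 1/2`), and a 5 s ceiling; when the CFL clamp makes
steps tiny, up to 16 are batched between bookkeeping updates.  Once no
blocked voxel remains, the agent field is transport-equilibrated far faster
than the remaining fibrin decays, and the loop switches to quasi-static
transport relaxation with reaction-limited time steps.

A run ends when the remaining mass fraction reaches 1%, at `t_max`, or at a
hard step cap (recorded as censored).  Records are exactly reproducible for
a given config and seed.

### Observables and ensembles (`fibroflow.observables`)

Front position is the contiguous lysed depth from the inlet face (slice
lysed when its transverse-average fibrin is strictly below `Fstar`; trapped
pockets stop the front).  Throughput is the axial seepage velocity
integrated over a cross-section, averaged over the initial clot columns.
Quartile lysis times `t_1/4, t_1/2, t_3/4` are the interpolated first
instants at which 25/50/75% of the initial mass is gone; unreached
thresholds are NaN-censored and excluded from spread statistics.
Recanalization onset is the first instant the throughput exceeds a
configurable fraction — default 50% — of the final (end-of-run) value; the
paper-facing notion of "recanalization start" has no formal definition, so
the fraction used is always reported alongside.  Ensembles derive replicate
seeds from a base seed via `numpy.random.SeedSequence`; replicate failures
(e.g. an infeasible disk layout) are recorded and skipped.

## Desk-scale study conditions (`fibroflow.studies`)

The bundled studies run on a 30 x 50 node grid (2 wall rows, 5 inlet-lumen
columns, a 25-column occlusive clot, 20 outlet columns) at `dx = 2e-5 m`,
i.e. a 0.6 mm channel with a 0.5 mm clot — a reduced-scale analog of a
5.8 mm tube with a 5 mm clot.  Concentrations and clot microstructure keep
the reference in-vitro values: threshold 0.2 mg/ml, fiber radius 140 nm,
permeability 1e-13 m^2; the front-comparison study uses anti-FA 10 ng/ml
and `k1 = 280 (s mg/ml)^-1` at 2 mg/ml fibrin (at 3 mg/ml the two intact
wall rows alone pin the 28-row slice mean at 0.214 mg/ml, just above the
0.2 mg/ml threshold, and the slice-mean front metric degenerates at this
resolution); the ensembles use a mean of 2 mg/ml, anti-FA 20 ng/ml and
`k1 = 1400 (s mg/ml)^-1`.  Desk-scale
choices, made once for stability and tractability:

- `dt_LB = 2e-4 s` puts `tau = 2.0`, the upper edge of the stable window,
  where the benchmark errors above were verified;
- the pressure gradient across the clot is 400 Pa/m, chosen so the
  end-state open-channel flow stays inside the lattice Mach guard; the
  resulting initial seepage is ~4e-8 m/s;
- the agent diffusivity is reduced to 1e-13 m^2/s so that the front-cell
  Peclet number `u dx / D ~ 8` preserves the advection-dominated front
  feeding of the reference conditions (u ~ 5e-6 m/s, dx ~ 1e-4 m,
  D = 3.3e-11: Pe ~ 15); keeping the molecular value at the reduced
  velocity would flip the front into a diffusive regime the model does not
  describe.

What the synthetic studies do and do not show: they demonstrate that the
coupled solver reproduces the analytical front law where its assumptions
hold, departs from it for the physical reason the assumptions break
(constant-velocity violation as the clot shortens), and ranks clot
heterogeneity archetypes by recanalization variability.  They do not
calibrate against any particular experiment's absolute time scale — the
kinetics are the accelerated study values — and real thrombi carry cellular
components, mechanical fragmentation and pulsatile flow that are out of
scope here.

## Known limitations

- Quasi-steady flow with bounded re-solve budgets lags a fully converged
  steady state by up to ~10% through mid-lysis; late-time observables
  (final throughput, onset) inherit a few-percent cadence sensitivity.
- The PBB plug profile slightly favours wall-adjacent seepage, so lysis
  channels in this model tend to open along the walls; front-averaged
  metrics are insensitive to the pattern, but pattern-level conclusions
  should not be drawn at this resolution.
- The limited second-order transport still carries some numerical
  diffusion; front Peclet numbers are preserved by the study conditions
  as much as by the scheme.
- The agent is not consumed by the reaction (the governing transport
  equation carries no sink), so once a region is cleared the agent
  saturates it at the inlet concentration and feeds every exposed fibrin
  surface equally.  Ensemble variability that hinges on agent depletion or
  shadowing — e.g. starving of high-concentration pockets behind
  preferential channels — is therefore weaker here than in particle-based
  implementations that deposit and remove discrete agent parcels.
- 2D channel geometry: throughput is per unit depth; no tube curvature,
  no patient geometry import, no moving boundaries or fragment advection.
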