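# fibroflow

Flow-driven fibrinolysis modelling: an analytical one-dimensional model of
lysis-front propagation through a permeated fibrin clot, and a mesoscopic
lattice-Boltzmann simulator in which the clot is a partial-bounce-back
porous medium degraded by a transported anti-fibrin agent.

## Who this is for

Researchers studying thrombolysis — the biochemical dissolution of blood
clots, e.g. with tPA in ischemic stroke — who want a compact, testable model
of how a lytic agent carried by a pressure-driven permeation flow eats
through an occlusive fibrin clot: how fast the front moves, when flow is
restored (recanalization), and how clot heterogeneity changes both.

## The models

**1D front model.** A clot of length `L`, fibrin concentration `F0`, perfused
at constant seepage speed `u_f`.  The agent (inlet concentration `Fbar0`)
binds at the clot front and accumulates there; fibrin is consumed by the
second-order reaction `dF/dt = -k1 F Fbar` until the front slice (thickness
`Delta`) drops below the threshold `F*`.  The slice lysis instants obey

    t_0 = sqrt( 2 Delta ln(F0/F*) / (k1 u_f Fbar0) )
    t_k = Delta/u_f + sqrt( t_{k-1}^2 + 2 Delta ln(F0/F*) / (k1 u_f Fbar0) )

so the front *accelerates* even at constant flow.  The single free parameter
`k1` can be calibrated against measured front positions (`fit_k1`).

**Mesoscopic simulator.** A D2Q9 BGK lattice-Boltzmann flow solver where each
clot voxel reflects a fraction `gamma` of the populations (Walsh partial
bounce-back).  Fibrin concentration sets the voxel's fiber radius, solid
fraction and — through Davies' law for fibrous media — its permeability and
`gamma`.  The agent is advected and diffused by the computed seepage field,
deposits on intact fibrin (the front-blocking rule), and the reaction opens
the clot voxel by voxel, which feeds back into the flow.  Homogeneous,
uniformly random ("type 1") and disk-heterogeneous ("type 2") synthetic
clots are built in, with seeded ensemble drivers and recanalization metrics.

See `docs/methods.md` for assumptions, parameters, numerics and limitations.

## Worked example

```python
import numpy as np
from fibroflow import LysisParams1D, lysis_schedule, fit_k1, FrontTrajectory, front_position

p = LysisParams1D(F0=2.4, Fstar=0.2, Fbar0=1e-5, k1=12.5,
                  u_f=5e-6, Delta=5e-5, L=5e-3)
sched = lysis_schedule(p)
print(f"first slice lysed at {sched[0]:.0f} s, full clot at {sched[-1]:.0f} s")

t = np.linspace(60, sched[-1], 120)
traj = FrontTrajectory(times=t, positions=front_position(p, t))
fit = fit_k1(traj, p.with_k1(1.0))
print(f"recovered k1 = {fit.k1_hat:.2f} (s mg/ml)^-1, "
      f"rms residual {fit.rms_residual_m*1e6:.1f} um over {fit.n_points} points")
```

prints

```
first slice lysed at 631 s, full clot at 6993 s
recovered k1 = 12.50 (s mg/ml)^-1, rms residual 15.3 um over 120 points
```

i.e. with 2.4 mg/ml fibrin, a 0.2 mg/ml lysis threshold, 10 ng/ml of agent
and a 5 um/s permeation speed, the first 50 um slice takes ~10 minutes but
the whole 5 mm clot only ~117 minutes — the front accelerates — and the
calibration recovers the generating reaction rate from the front trace
alone.

A coupled simulation, from the command line:

```sh
fibroflow simulate --seed 1 --outdir run_out       # homogeneous defaults
fibroflow ensemble --n 10 --seed 7                 # seeded clot ensemble
fibroflow poiseuille-check                         # solver benchmarks
fibroflow permeability-check
```

`simulate` writes the time series (`record.csv`: front position, remaining
mass fraction, throughput, mean clot velocity), a `meta.json` with the
measured initial seepage velocity and termination reason, the resolved
config, and a content-hashed manifest.

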