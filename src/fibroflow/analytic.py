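"""Analytical one-dimensional model of flow-driven fibrinolysis.

The clot is a porous column of length ``L`` and fibrin concentration ``F0``
perfused at constant seepage velocity ``u_f``.  All pro-fibrinolytic species
are aggregated into one anti-fibrin agent (anti-FA) carried by the flow at
inlet concentration ``Fbar0``.  Anti-FA does not diffuse and is blocked at
the clot front: it accumulates in the front slice of thickness ``Delta``
until the local fibrin concentration, consumed by the second-order reaction

    dF/dt = -k1 * F * Fbar,

drops below the lysis threshold ``Fstar``; the front then advances one slice
and the accumulated agent moves with it.  Under these rules the time to lyse
the first slice is

    t0 = sqrt( 2 Delta ln(F0/Fstar) / (k1 u_f Fbar0) ),

and subsequent slice lysis instants obey the recursion

    t_k = Delta/u_f + sqrt( t_{k-1}^2 + 2 Delta ln(F0/Fstar)/(k1 u_f Fbar0) ),

whose increments shrink with k: the lysis front accelerates, as observed in
permeation lysis experiments.  The only free parameter is the lumped reaction
rate ``k1``; :func:`fit_k1` calibrates it against a measured front-position
time series.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import minimize_scalar

__all__ = [
    "LysisParams1D",
    "FrontTrajectory",
    "FitResult",
    "first_slice_time",
    "lysis_schedule",
    "front_position",
    "fit_k1",
    "delta_convergence",
    "load_trajectory",
]


@dataclass(frozen=True)
class LysisParams1D:
    """Parameters of the 1D lysis model (SI units; concentrations mg/ml).

    F0 : initial fibrin concentration (mg/ml)
    Fstar : lysis threshold concentration (mg/ml), 0 < Fstar < F0
    Fbar0 : inlet anti-FA concentration (mg/ml)
    k1 : lumped reaction rate ((s mg/ml)^-1)
    u_f : permeation (seepage) fluid speed (m/s)
    Delta : slice thickness (m); redefined internally to L/n with
        n = round(L/Delta) so that slices tile the clot exactly
    L : clot length (m)
    """

    F0: float
    Fstar: float
    Fbar0: float
    k1: float
    u_f: float
    Delta: float
    L: float

    def __post_init__(self) -> None:
        for name in ("F0", "Fstar", "Fbar0", "k1", "u_f", "Delta", "L"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if self.F0 <= self.Fstar:
            raise ValueError("F0 must exceed Fstar (otherwise no lysis needed)")
        if self.Delta > self.L:
            raise ValueError("Delta cannot exceed the clot length")
        if self.n_slices < 1:
            raise ValueError("need at least one slice")

    @property
    def n_slices(self) -> int:
        return max(1, round(self.L / self.Delta))

    @property
    def delta_eff(self) -> float:
        """Slice thickness after snapping to an integer slice count."""
        return self.L / self.n_slices

    def with_k1(self, k1: float) -> "LysisParams1D":
        return replace(self, k1=k1)


@dataclass(frozen=True)
class FrontTrajectory:
    """Measured lysed-front depth vs time (from the clot inlet face)."""

    times: np.ndarray
    positions: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        x = np.asarray(self.positions, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "positions", x)
        if t.ndim != 1 or t.shape != x.shape:
            raise ValueError("times and positions must be 1D arrays of equal length")
        if t.size and np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if t.size and (np.any(np.diff(x) < 0) or x[0] < 0):
            raise ValueError("positions must be non-negative and non-decreasing")

    def __len__(self) -> int:
        return self.times.size


def _slice_term(p: LysisParams1D) -> float:
    """2 Delta ln(F0/Fstar) / (k1 u_f Fbar0), with the snapped Delta."""
    return 2.0 * p.delta_eff * math.log(p.F0 / p.Fstar) / (p.k1 * p.u_f * p.Fbar0)


def first_slice_time(p: LysisParams1D) -> float:
    """Time for the accumulating anti-FA to lyse the first slice."""
    t0 = math.sqrt(_slice_term(p))
    if not math.isfinite(t0):
        raise ValueError("non-finite first-slice time; check parameters")
    return t0


def lysis_schedule(p: LysisParams1D, advection: bool = True) -> np.ndarray:
    """Instants t_0 .. t_{n-1} at which successive slices reach Fstar.

    With ``advection=False`` the Delta/u_f travel term is dropped, in which
    case t_k^2 - t_{k-1}^2 equals the slice term exactly (telescoping), and
    the final time reduces to sqrt(2 L ln(F0/Fstar)/(k1 u_f Fbar0)).
    """
    a2 = _slice_term(p)
    travel = p.delta_eff / p.u_f if advection else 0.0
    t = np.empty(p.n_slices)
    t[0] = math.sqrt(a2)
    for k in range(1, p.n_slices):
        t[k] = travel + math.sqrt(t[k - 1] ** 2 + a2)
    return t


def front_position(p: LysisParams1D, t) -> np.ndarray | float:
    """Lysed depth at time(s) t: piecewise-constant inverse of the schedule.

    The front sits at Delta * (number of slices whose lysis instant <= t)
    and equals L once the last slice is gone.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("time must be non-negative")
    sched = lysis_schedule(p)
    depth = p.delta_eff * np.searchsorted(sched, t_arr, side="right")
    depth = np.minimum(depth, p.L)
    return float(depth) if np.isscalar(t) or t_arr.ndim == 0 else depth


def _interp_front(p: LysisParams1D, t: np.ndarray) -> np.ndarray:
    """Continuous front surrogate used inside the fit.

    The model front is a staircase (whole slices lyse at the schedule
    instants); its unbiased piecewise-linear representative passes through
    the slice midpoints, (t_k, (k + 1/2) Delta), starting from (0, 0).
    """
    sched = lysis_schedule(p)
    knots_t = np.concatenate(([0.0], sched))
    knots_x = np.concatenate(([0.0], p.delta_eff * (np.arange(p.n_slices) + 0.5)))
    return np.interp(t, knots_t, knots_x, left=0.0, right=p.L - p.delta_eff / 2)


@dataclass(frozen=True)
class FitResult:
    k1_hat: float
    rms_residual_m: float
    n_points: int

    def to_dict(self) -> dict:
        return {
            "k1_hat": self.k1_hat,
            "rms_residual_m": self.rms_residual_m,
            "n_points": self.n_points,
        }


def fit_k1(
    traj: FrontTrajectory,
    p_known: LysisParams1D,
    k1_bounds: tuple[float, float] = (1e-3, 1e5),
) -> FitResult:
    """Least-squares calibration of k1 against a measured front trajectory.

    All other parameters are taken from ``p_known`` (its k1 is ignored).  The
    loss is the position-space L2 misfit of the model front, minimized over
    log k1 by bounded scalar minimization; the schedule depends on k1 only
    through the product k1*Fbar0, so the fit is identifiable only for a fixed
    Fbar0.  The reported residual is the RMS misfit in metres.
    """
    if len(traj) < 3:
        raise ValueError("need at least 3 trajectory points to fit k1")
    if np.all(traj.positions == 0):
        raise ValueError("degenerate trajectory: front never moved, no information on k1")

    t, x = traj.times, traj.positions

    def loss(log_k1: float) -> float:
        p = p_known.with_k1(10.0**log_k1)
        return float(np.sum((_interp_front(p, t) - x) ** 2))

    lo, hi = math.log10(k1_bounds[0]), math.log10(k1_bounds[1])
    res = minimize_scalar(loss, bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-10})
    k1_hat = float(10.0**res.x)
    p_hat = p_known.with_k1(k1_hat)
    resid = _interp_front(p_hat, t) - x
    return FitResult(k1_hat=k1_hat, rms_residual_m=float(np.sqrt(np.mean(resid**2))),
                     n_points=len(traj))


def delta_convergence(p: LysisParams1D, factors) -> tuple["pandas.DataFrame", float]:
    """Total lysis time under slice-thickness refinement.

    For each factor m the model is re-run with Delta = p.Delta / m.  Returns
    a table (delta_m, n_slices, t_total_s) and the maximum relative spread of
    the total time across rows.
    """
    import pandas as pd

    rows = []
    for m in factors:
        if m <= 0:
            raise ValueError("refinement factors must be positive")
        pm = replace(p, Delta=p.Delta / m)
        rows.append(
            {
                "factor": m,
                "delta_m": pm.delta_eff,
                "n_slices": pm.n_slices,
                "t_total_s": float(lysis_schedule(pm)[-1]),
            }
        )
    df = pd.DataFrame(rows)
    tt = df["t_total_s"].to_numpy()
    spread = float((tt.max() - tt.min()) / tt.min()) if len(tt) else 0.0
    return df, spread


def load_trajectory(path) -> FrontTrajectory:
    """Read a 2-column delimited text file (time_s, position_m).

    Lines starting with '#' are comments; an optional non-numeric header row
    is skipped; comma, semicolon, tab or whitespace delimiters are accepted.
    """
    rows = []
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            for sep in (",", ";", "\t"):
                line = line.replace(sep, " ")
            parts = line.split()
            try:
                vals = [float(v) for v in parts[:2]]
            except ValueError:
                continue  # header row
            if len(vals) == 2:
                rows.append(vals)
    if not rows:
        raise ValueError(f"no numeric (time, position) rows found in {path}")
    arr = np.asarray(rows, dtype=float)
    return FrontTrajectory(times=arr[:, 0], positions=arr[:, 1])
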