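"""Lattice-Boltzmann BGK solver with Walsh partial bounce-back (PBB) nodes.

The clot is represented as a field of bounce-back fractions ``gamma`` in
[0, 1]: gamma=0 is open fluid, gamma=1 a solid wall, intermediate values an
unresolved fibrous porous medium whose permeability follows from gamma (see
:mod:`fibroflow.clot`).  At each step a node scatters populations by the BGK
rule and emits, toward each neighbour, the weighted sum of the transmitted
post-collision population and the reflected pre-collision opposite
population:

    f_i(x + c_i, t+1) = (1 - gamma) f*_i(x, t) + gamma f_opp(i)(x, t)

Flow is driven either by a uniform body force (periodic validation cases) or
by fixed-density inlet/outlet boundaries implementing a pressure drop, with a
non-equilibrium extrapolation closure.

The functions in this module are dimension-agnostic pure-numpy references;
:func:`run_to_steady` switches to a fused numba kernel for 2D D2Q9 domains.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .lattice import Lattice, StabilityError, UnitSystem, D2Q9

__all__ = [
    "FluidState",
    "equilibrium",
    "collide_bgk",
    "stream",
    "bounce_back_walls",
    "pbb_stream",
    "macroscopic",
    "apply_pressure_drop",
    "apply_body_force",
    "step",
    "run_to_steady",
    "make_channel_2d",
]

MACH_LIMIT = 0.1


def equilibrium(lat: Lattice, rho: np.ndarray, u: np.ndarray) -> np.ndarray:
    """Second-order Maxwellian equilibrium populations.

    rho has the domain shape S, u has shape (dim,) + S.  Returns (q,) + S.
    """
    rho = np.asarray(rho, dtype=float)
    u = np.asarray(u, dtype=float)
    cs2 = lat.cs2
    cu = np.tensordot(lat.c.astype(float), u, axes=(1, 0))  # (q,)+S
    usq = np.sum(u * u, axis=0)
    poly = 1.0 + cu / cs2 + cu**2 / (2 * cs2**2) - usq / (2 * cs2)
    return lat.w.reshape((lat.q,) + (1,) * rho.ndim) * rho * poly


def collide_bgk(f: np.ndarray, feq: np.ndarray, tau: float) -> np.ndarray:
    """BGK relaxation toward equilibrium; conserves mass and momentum."""
    if tau <= 0.5:
        raise StabilityError(f"tau={tau} <= 1/2 is unconditionally unstable")
    return f - (f - feq) / tau


def stream(lat: Lattice, f: np.ndarray) -> np.ndarray:
    """Propagate each population one node along its velocity (periodic)."""
    out = np.empty_like(f)
    axes = tuple(range(1, f.ndim))
    for i in range(lat.q):
        out[i] = np.roll(f[i], shift=tuple(lat.c[i]), axis=tuple(a - 1 for a in axes))
    return out


def pbb_stream(
    lat: Lattice, f_star: np.ndarray, f_pre: np.ndarray, gamma: np.ndarray
) -> np.ndarray:
    """Partial-bounce-back streaming (Walsh).

    f_star are post-collision populations, f_pre the pre-collision populations
    of the same step (the reflected term uses the pre-collision opposite
    population).  Reduces to plain streaming at gamma=0 and to on-node
    bounce-back at gamma=1.
    """
    g = np.asarray(gamma, dtype=float)
    if np.any(g < 0) or np.any(g > 1):
        raise ValueError("gamma must lie in [0, 1]")
    out = (1.0 - g) * f_star + g * f_pre[lat.opp]
    return stream(lat, out)


def bounce_back_walls(
    lat: Lattice, f_star: np.ndarray, f_pre: np.ndarray, wall: np.ndarray
) -> np.ndarray:
    """Solid bounce-back at wall nodes: the PBB rule with gamma=1 on walls."""
    return pbb_stream(lat, f_star, f_pre, np.where(wall, 1.0, 0.0))


def macroscopic(
    lat: Lattice, f: np.ndarray, gamma: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Density and velocity moments; on PBB nodes the physically meaningful
    (seepage) velocity carries the factor (1 - gamma)."""
    rho = f.sum(axis=0)
    mom = np.tensordot(lat.c.astype(float).T, f, axes=(1, 0))  # (dim,)+S
    u = mom / rho
    if gamma is not None:
        u = u * (1.0 - np.asarray(gamma, dtype=float))
    return rho, u


@dataclass
class Drive:
    mode: str = "none"  # none | force | pressure
    accel: tuple = ()  # lattice acceleration, component per array axis
    rho_in: float = 1.0
    rho_out: float = 1.0


@dataclass
class FluidState:
    """Populations plus node metadata for one simulation domain.

    gamma=1 marks solid walls; the flow axis is the last array axis.
    """

    lattice: Lattice
    units: UnitSystem
    f: np.ndarray
    gamma: np.ndarray
    drive: Drive = field(default_factory=Drive)

    @classmethod
    def at_rest(cls, lattice: Lattice, units: UnitSystem, gamma: np.ndarray) -> "FluidState":
        gamma = np.ascontiguousarray(gamma, dtype=float)
        if np.any(gamma < 0) or np.any(gamma > 1):
            raise ValueError("gamma must lie in [0, 1]")
        shape = gamma.shape
        f = np.empty((lattice.q,) + shape)
        f[:] = lattice.w.reshape((lattice.q,) + (1,) * len(shape))
        return cls(lattice=lattice, units=units, f=f, gamma=gamma)

    @property
    def shape(self) -> tuple:
        return self.gamma.shape

    def macroscopic(self) -> tuple[np.ndarray, np.ndarray]:
        return macroscopic(self.lattice, self.f, self.gamma)

    def velocity_si(self) -> np.ndarray:
        _, u = self.macroscopic()
        return self.units.velocity_to_si(u)

    def copy(self) -> "FluidState":
        return FluidState(
            lattice=self.lattice,
            units=self.units,
            f=self.f.copy(),
            gamma=self.gamma.copy(),
            drive=Drive(self.drive.mode, self.drive.accel, self.drive.rho_in, self.drive.rho_out),
        )


def apply_body_force(state: FluidState, grad_P: float) -> FluidState:
    """Drive a periodic domain with the uniform body force equivalent to a
    pressure gradient grad_P (Pa/m) along the flow (last) axis."""
    a_phys = grad_P / state.units.rho0  # m/s^2
    a_lat = a_phys * state.units.dt**2 / state.units.dx
    accel = [0.0] * state.lattice.dim
    accel[-1] = a_lat
    state.drive = Drive(mode="force", accel=tuple(accel))
    return state


def apply_pressure_drop(
    state: FluidState, grad_P: float, over_length: float | None = None
) -> FluidState:
    """Fixed-density inlet/outlet boundaries on the first/last slice of the
    flow axis, equivalent to pressure gradient grad_P (Pa/m) applied over
    ``over_length`` metres (default: the whole domain length)."""
    nx = state.shape[-1]
    if over_length is None:
        over_length = nx * state.units.dx
    dP = grad_P * over_length
    dp_lat = state.units.pressure_drop_to_lat(dP)
    drho = dp_lat / state.units.cs2
    if abs(drho) > 0.1:
        raise StabilityError(
            f"pressure drop implies |delta rho|={abs(drho):.3g} > 0.1; "
            "reduce grad_P or the LB time step"
        )
    state.drive = Drive(mode="pressure", rho_in=1.0 + drho / 2, rho_out=1.0 - drho / 2)
    return state


def _pressure_bc_numpy(state: FluidState) -> None:
    """Non-equilibrium extrapolation fixed-density closure, generic dim."""
    lat, f = state.lattice, state.f
    open_in = state.gamma[..., 0] < 1.0
    open_out = state.gamma[..., -1] < 1.0
    for idx_b, idx_n, rho_bc in (
        (0, 1, state.drive.rho_in),
        (-1, -2, state.drive.rho_out),
    ):
        fn = f[..., idx_n]
        rho_n = fn.sum(axis=0)
        u_n = np.tensordot(lat.c.astype(float).T, fn, axes=(1, 0)) / rho_n
        feq_bc = equilibrium(lat, np.full_like(rho_n, rho_bc), u_n)
        feq_n = equilibrium(lat, rho_n, u_n)
        mask = open_in if idx_b == 0 else open_out
        f[..., idx_b][:, mask] = (feq_bc + fn - feq_n)[:, mask]


def step(state: FluidState) -> FluidState:
    """One collide + PBB-stream (+boundary) step, pure-numpy reference."""
    lat, units = state.lattice, state.units
    f = state.f
    rho, u_bare = macroscopic(lat, f)  # collision uses the bare velocity
    feq = equilibrium(lat, rho, u_bare)
    f_star = collide_bgk(f, feq, units.tau)
    if state.drive.mode == "force":
        a = np.asarray(state.drive.accel, dtype=float)
        ca = np.tensordot(lat.c.astype(float), a, axes=(1, 0))
        ca = ca.reshape((lat.q,) + (1,) * rho.ndim)
        f_star = f_star + lat.w.reshape((lat.q,) + (1,) * rho.ndim) * rho * ca / lat.cs2
    state.f = pbb_stream(lat, f_star, f, state.gamma)
    if state.drive.mode == "pressure":
        _pressure_bc_numpy(state)
    return state


def _step_numba(state: FluidState, ftmp: np.ndarray, fnew: np.ndarray) -> None:
    d = state.drive
    use_force = d.mode == "force"
    ay, ax = (d.accel if use_force else (0.0, 0.0))
    _kernels.d2q9_step(
        state.f, ftmp, fnew, state.gamma, state.units.tau,
        ay, ax, use_force, d.rho_in, d.rho_out, d.mode == "pressure",
    )


@dataclass
class ConvergenceReport:
    converged: bool
    steps: int
    residual: float
    u_max_lat: float

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        tag = "converged" if self.converged else "max_steps reached"
        return f"{tag} after {self.steps} steps (residual {self.residual:.3g})"


def run_to_steady(
    state: FluidState,
    tol: float = 1e-4,
    max_steps: int = 200_000,
    check_every: int = 100,
    u_floor: float = 1e-10,
) -> ConvergenceReport:
    """Iterate to a quasi-steady flow.

    Convergence is declared when the max velocity change over ``check_every``
    steps, relative to the current max velocity (floored), drops below tol.
    Raises StabilityError on NaN populations or a lattice Mach breach.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    use_numba = state.lattice.name == "D2Q9" and state.f.ndim == 3
    ftmp = np.empty_like(state.f) if use_numba else None
    fnew = np.empty_like(state.f) if use_numba else None
    _, u_prev = state.macroscopic()
    steps = 0
    residual = np.inf
    while steps < max_steps:
        for _ in range(check_every):
            if use_numba:
                _step_numba(state, ftmp, fnew)
                state.f, fnew = fnew, state.f
            else:
                step(state)
        steps += check_every
        _, u = state.macroscopic()
        u_mag = np.sqrt(np.sum(u * u, axis=0))
        u_max = float(u_mag.max())
        if not np.isfinite(u_max):
            raise StabilityError(
                f"flow diverged (NaN) at tau={state.units.tau:.4f}"
            )
        if u_max > MACH_LIMIT:
            raise StabilityError(
                f"lattice velocity {u_max:.3g} exceeds Mach guard {MACH_LIMIT} "
                f"(tau={state.units.tau:.4f}); reduce the driving or time step"
            )
        residual = float(np.max(np.abs(u - u_prev))) / max(u_max, u_floor)
        u_prev = u
        if residual < tol:
            return ConvergenceReport(True, steps, residual, u_max)
    return ConvergenceReport(False, steps, residual, float(np.max(np.abs(u_prev))))


def make_channel_2d(
    ny: int, nx: int, units: UnitSystem, walls: bool = True
) -> FluidState:
    """A 2D channel at rest: optional wall rows on the transverse edges."""
    gamma = np.zeros((ny, nx))
    if walls:
        gamma[0, :] = 1.0
        gamma[-1, :] = 1.0
    return FluidState.at_rest(D2Q9, units, gamma)
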