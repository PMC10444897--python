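"""Canonical solver validation cases with closed-form oracles.

Two benchmarks exercise the solver ends-to-end:

- plane Poiseuille flow in a 2D channel driven by a body force, against the
  analytic parabola with the no-slip planes at the wall link midpoints;
- Darcy permeametry of a uniform partial-bounce-back slab driven by a
  pressure drop, against the permeability that was encoded into gamma.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .clot import gamma_from_permeability
from .lattice import D2Q9, UnitSystem
from .lb import FluidState, apply_body_force, apply_pressure_drop, make_channel_2d, run_to_steady

__all__ = ["PoiseuilleResult", "poiseuille_check", "DarcyResult", "darcy_check"]


@dataclass
class PoiseuilleResult:
    max_rel_error: float
    u_numeric_si: np.ndarray
    u_analytic_si: np.ndarray
    steps: int


def poiseuille_check(
    ny: int = 40,
    nx: int = 100,
    grad_P: float = 10.0,
    units: UnitSystem | None = None,
    tol: float = 1e-7,
    max_steps: int = 400_000,
) -> PoiseuilleResult:
    """Body-force-driven channel flow vs the analytic parabola.

    The channel is periodic along the flow axis with one wall row on each
    transverse edge; with half-way bounce-back the no-slip planes sit half a
    node beyond the outermost fluid rows, so the effective width is
    (ny - 2) * dx.  The error is the max relative deviation of the axial
    velocity profile over the fluid rows.
    """
    if units is None:
        units = UnitSystem(dx=2e-5, dt=4e-5, nu=1e-6)
    state = make_channel_2d(ny, nx, units, walls=True)
    apply_body_force(state, grad_P)
    report = run_to_steady(state, tol=tol, max_steps=max_steps)
    u = state.velocity_si()
    profile = u[1].mean(axis=1)[1:-1]  # axial velocity per fluid row
    y = (np.arange(1, ny - 1) - 0.5) * units.dx  # distance from no-slip plane
    H = (ny - 2) * units.dx
    mu = units.rho0 * units.nu
    analytic = grad_P / (2.0 * mu) * y * (H - y)
    err = float(np.max(np.abs(profile - analytic) / analytic.max()))
    return PoiseuilleResult(err, profile, analytic, report.steps)


@dataclass
class DarcyResult:
    k_target: float
    k_measured: float
    rel_error: float
    seepage_velocity_si: float


def darcy_check(
    k_target: float,
    units: UnitSystem | None = None,
    ny: int = 10,
    nx: int = 60,
    slab: tuple[int, int] = (20, 40),
    dP: float = 5.0,
    tol: float = 1e-8,
    max_steps: int = 400_000,
) -> DarcyResult:
    """Pressure-driven seepage through a uniform-gamma slab vs Darcy's law.

    The domain is periodic transversally (no walls), so the only resistance
    is the slab itself and the pressure drop falls entirely across it at
    steady state.  The recovered permeability is k = mu * u * L_slab / dP
    with u the seepage (PBB-corrected) velocity inside the slab.
    """
    if units is None:
        units = UnitSystem(dx=2e-5, dt=4e-5, nu=1e-6)
    gamma = np.zeros((ny, nx))
    g = gamma_from_permeability(k_target, units)
    x0, x1 = slab
    gamma[:, x0:x1] = g
    state = FluidState.at_rest(D2Q9, units, gamma)
    grad_P = dP / (nx * units.dx)
    apply_pressure_drop(state, grad_P)  # over the whole domain length
    run_to_steady(state, tol=tol, max_steps=max_steps)
    u = state.velocity_si()
    u_seep = float(u[1][:, x0:x1].mean())
    L_slab = (x1 - x0) * units.dx
    mu = units.rho0 * units.nu
    k_meas = mu * u_seep * L_slab / dP
    return DarcyResult(k_target, k_meas, float(abs(k_meas - k_target) / k_target),
                       u_seep)
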