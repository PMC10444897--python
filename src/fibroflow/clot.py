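"""Clot representation: the fibrin -> fiber radius -> solid fraction ->
permeability -> bounce-back fraction chain, and synthetic clot generators.

A clot voxel holds fibrin at concentration F (mg/ml) distributed over fibers
of radius Rf threaded through the voxel with strand-length density
``lden = L_voxel_strand_length / voxel_volume`` (m^-2).  Lysis removes fibrin
radially and uniformly, so F is proportional to the fiber cross-section:

    Rf(F) = Rf0 * sqrt(F / F0),       ns = pi * Rf^2 * lden,

where the calibration constant folds the fibrin mass per unit strand length
into the initial condition (complete dissolution means Rf(0) = 0).  Voxel
permeability follows Davies' empirical law for fibrous media,

    k_D(Rf, ns) = Rf^2 / (16 ns^1.5 (1 + 56 ns^3)),

and maps onto the partial-bounce-back fraction of the LB solver through

    gamma = 1 / (1 + 2 k / (nu * dt)),

with nu the kinematic viscosity and dt the LB time step (k/(nu dt) is
dimensionless, so the expression may be evaluated directly in SI units).

Synthetic heterogeneous clots come in two archetypes observed to bracket
patient thrombus variability: per-voxel uniform random fibrin ("type 1") and
high-concentration disks in a lower-concentration matrix ("type 2").
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional

import numpy as np
from scipy.optimize import brentq

from .lattice import UnitSystem

__all__ = [
    "davies_permeability",
    "gamma_from_permeability",
    "radius_from_fibrin",
    "solid_fraction",
    "calibrate_clot",
    "ClotCalibration",
    "ClotField",
    "ClotSpec",
    "generate_clot",
    "generate_type1",
    "generate_type2",
    "clot_to_gamma",
]

#: solid fractions above this are treated as non-physical fiber packing
NS_MAX = 0.5
_NS_OPEN = 1e-12  # below this a voxel counts as fully dissolved / open


def davies_permeability(Rf, ns):
    """Davies permeability (m^2) of a fibrous medium.

    Strictly decreasing in the solid fraction ns and scaling as Rf^2.
    Voxels with ns ~ 0 are open: they carry infinite permeability, which the
    gamma map turns into gamma = 0.
    """
    Rf = np.asarray(Rf, dtype=float)
    ns = np.asarray(ns, dtype=float)
    if np.any(ns < 0) or np.any(ns >= 1):
        raise ValueError("solid fraction must lie in [0, 1)")
    if np.any(Rf < 0):
        raise ValueError("fiber radius must be non-negative")
    with np.errstate(divide="ignore"):
        k = np.where(
            ns > _NS_OPEN,
            Rf**2 / (16.0 * np.maximum(ns, _NS_OPEN) ** 1.5
                     * (1.0 + 56.0 * ns**3)),
            np.inf,
        )
    if k.ndim == 0:
        return float(k)
    return k


def gamma_from_permeability(k, units: UnitSystem):
    """Bounce-back fraction for a voxel of permeability k (m^2).

    gamma -> 0 as k -> inf (open fluid) and gamma -> 1 as k -> 0 (solid).
    """
    k = np.asarray(k, dtype=float)
    if np.any(k < 0):
        raise ValueError("permeability must be non-negative")
    with np.errstate(over="ignore"):
        g = 1.0 / (1.0 + 2.0 * k / (units.nu * units.dt))
    g = np.where(np.isinf(k), 0.0, g)
    if g.ndim == 0:
        return float(g)
    return g


def radius_from_fibrin(F, F0: float, Rf0: float, lden: float, Ccal: float):
    """Fiber radius after lysis has reduced the fibrin concentration to F.

    Radial, uniform strand cleavage removes fibrin mass proportionally to the
    lost cross-section: Rf^2 = Rf0^2 - (F0 - F)/(Ccal * lden).  Arguments of
    the square root that dip below zero (fully dissolved voxels) are clamped
    to radius zero.
    """
    F = np.asarray(F, dtype=float)
    if np.any(F < 0) or np.any(F > F0 * (1 + 1e-12)):
        raise ValueError("fibrin concentration must lie in [0, F0]")
    arg = Rf0**2 - (F0 - F) / (Ccal * lden)
    Rf = np.sqrt(np.maximum(arg, 0.0))
    if Rf.ndim == 0:
        return float(Rf)
    return Rf


def solid_fraction(Rf, lden: float):
    """Fiber volume fraction of a voxel: ns = pi Rf^2 lden."""
    Rf = np.asarray(Rf, dtype=float)
    if np.any(Rf < 0) or lden < 0:
        raise ValueError("Rf and lden must be non-negative")
    ns = np.pi * Rf**2 * lden
    if np.any(ns >= 1):
        raise ValueError("solid fraction >= 1: non-physical fiber packing")
    if ns.ndim == 0:
        return float(ns)
    return ns


@dataclass(frozen=True)
class ClotCalibration:
    """Initial-condition closure linking fibrin to the permeability chain.

    Exactly one of the initial solid fraction ns0 or permeability k0 is
    prescribed; the other follows from Davies' law.  The strand-length
    density and the mass-per-cross-section constant are then fixed by
    requiring Rf(F0) = Rf0 and Rf(0) = 0.
    """

    F0: float
    Rf0: float
    ns0: float
    k0: float
    lden: float
    Ccal: float


def calibrate_clot(
    F0: float,
    Rf0: float,
    ns0: Optional[float] = None,
    k0: Optional[float] = None,
) -> ClotCalibration:
    if F0 <= 0 or Rf0 <= 0:
        raise ValueError("F0 and Rf0 must be positive")
    if (ns0 is None) == (k0 is None):
        raise ValueError("give exactly one of ns0 or k0")
    if ns0 is None:
        # monotone root-find of Davies' law for the solid fraction
        def resid(ns: float) -> float:
            return davies_permeability(Rf0, ns) - k0

        lo, hi = 1e-9, NS_MAX
        if not (resid(lo) > 0 > resid(hi)):
            raise ValueError(
                f"no solid fraction in ({lo}, {hi}) reproduces k0={k0:.3g} m^2 "
                f"at Rf0={Rf0:.3g} m: infeasible parameters"
            )
        ns0 = float(brentq(resid, lo, hi, xtol=1e-15, rtol=1e-12))
    else:
        if not 0 < ns0 < NS_MAX:
            raise ValueError(f"ns0 must lie in (0, {NS_MAX})")
        k0 = float(davies_permeability(Rf0, ns0))
    lden = ns0 / (np.pi * Rf0**2)
    Ccal = F0 / (Rf0**2 * lden)
    return ClotCalibration(F0=F0, Rf0=Rf0, ns0=float(ns0), k0=float(k0),
                           lden=float(lden), Ccal=float(Ccal))


@dataclass
class ClotSpec:
    """Recipe for a synthetic clot field on a (ny, nx) voxel region.

    dispersion_pct is the half-range of the type-1 per-voxel uniform law as a
    percentage of the mean (100% spans 0..2*F_mean).  Type-2 disks may
    overlap and are clipped at the region boundary; the matrix concentration
    is solved so the whole-clot mean equals F_mean exactly.
    """

    kind: Literal["homogeneous", "type1", "type2"] = "homogeneous"
    F_mean: float = 2.0  # mg/ml
    dispersion_pct: float = 100.0
    F_disk: float = 3.5  # mg/ml
    n_disks: int = 25
    disk_radius_vox: float = 2.4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.F_mean <= 0:
            raise ValueError("F_mean must be positive")
        if not 0 <= self.dispersion_pct <= 100:
            raise ValueError("dispersion_pct must lie in [0, 100]")
        if self.kind == "type2" and self.F_disk < self.F_mean:
            raise ValueError("intra-disk concentration must be >= the target mean")


@dataclass
class ClotField:
    """Per-voxel clot state on the full simulation grid.

    mask flags clot voxels (the rest is lumen); F is the fibrin field
    (zero off-clot).  Derived fields are recomputed by :meth:`update`.
    """

    F: np.ndarray
    mask: np.ndarray
    calibration: ClotCalibration
    Rf: np.ndarray = field(init=False)
    ns: np.ndarray = field(init=False)
    k: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.F = np.asarray(self.F, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.F.shape != self.mask.shape:
            raise ValueError("F and mask shapes differ")
        if np.any(self.F < 0):
            raise ValueError("fibrin concentrations must be non-negative")
        self.update()

    def update(self) -> None:
        # Under the Rf(0)=0 calibration the radius chain reduces to
        # Rf = Rf0 sqrt(F/F0), which extends naturally to heterogeneous
        # voxels with F above the calibration reference F0.
        cal = self.calibration
        self.Rf = cal.Rf0 * np.sqrt(np.maximum(self.F, 0.0) / cal.F0)
        self.ns = solid_fraction(self.Rf, cal.lden)
        self.k = davies_permeability(self.Rf, self.ns)

    @property
    def initial_mass(self) -> float:
        return float(self.F[self.mask].sum())


def generate_type1(spec: ClotSpec, shape: tuple[int, int]) -> np.ndarray:
    """Per-voxel uniform random fibrin: F ~ U(F_M (1-d/100), F_M (1+d/100))."""
    rng = np.random.default_rng(spec.seed)
    d = spec.dispersion_pct / 100.0
    lo, hi = spec.F_mean * (1 - d), spec.F_mean * (1 + d)
    return rng.uniform(lo, hi, size=shape)


def generate_type2(spec: ClotSpec, shape: tuple[int, int]) -> np.ndarray:
    """High-concentration disks in a matrix whose concentration is solved so
    the whole-clot mean is exactly F_mean.

    Disk centres are uniform over the region; disks may overlap and are
    clipped at the boundary.  Raises if the disks cover so much area that the
    matrix concentration would be negative.
    """
    ny, nx = shape
    rng = np.random.default_rng(spec.seed)
    yy, xx = np.mgrid[0:ny, 0:nx]
    in_disk = np.zeros(shape, dtype=bool)
    for _ in range(spec.n_disks):
        cy = rng.uniform(-0.5, ny - 0.5)
        cx = rng.uniform(-0.5, nx - 0.5)
        in_disk |= (yy - cy) ** 2 + (xx - cx) ** 2 <= spec.disk_radius_vox**2
    n_total = ny * nx
    n_in = int(in_disk.sum())
    n_out = n_total - n_in
    if n_out == 0:
        raise ValueError("disks cover the whole clot: infeasible spec")
    F_out = (spec.F_mean * n_total - spec.F_disk * n_in) / n_out
    if F_out < 0:
        raise ValueError(
            f"disk coverage {n_in/n_total:.0%} at F_disk={spec.F_disk} would "
            f"need a negative matrix concentration: infeasible spec"
        )
    F = np.full(shape, F_out)
    F[in_disk] = spec.F_disk
    return F


def generate_clot(spec: ClotSpec, shape: tuple[int, int]) -> np.ndarray:
    """Dispatch on the heterogeneity kind; homogeneous is uniform F_mean."""
    if spec.kind == "homogeneous":
        return np.full(shape, spec.F_mean)
    if spec.kind == "type1":
        return generate_type1(spec, shape)
    if spec.kind == "type2":
        return generate_type2(spec, shape)
    raise ValueError(f"unknown clot kind {spec.kind!r}")


def clot_to_gamma(clot: ClotField, units: UnitSystem) -> np.ndarray:
    """Per-voxel chain F -> Rf -> ns -> k -> gamma; lumen voxels get 0."""
    gamma = np.where(clot.mask, gamma_from_permeability(clot.k, units), 0.0)
    return gamma
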