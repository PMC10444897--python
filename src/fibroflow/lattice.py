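"""Lattice stencils and unit conversion for the lattice-Boltzmann solver.

The solver works in lattice units internally: node spacing 1, time step 1,
reference density 1.  :class:`UnitSystem` holds the conversion factors to SI
and derives the BGK relaxation time ``tau`` from the physical kinematic
viscosity, enforcing the stability window.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Lattice", "UnitSystem", "get_lattice", "D2Q9", "D3Q19"]


@dataclass(frozen=True)
class Lattice:
    """A discrete-velocity stencil (DdQq).

    Velocity vectors are integer lattice displacements ``c[i] = (cx, cy[, cz])``.
    ``opp[i]`` is the index of the direction opposite to ``i``.  Weights obey
    the isotropy constraints sum(w)=1, sum(w c)=0, sum(w c_a c_b)=cs2*delta_ab.
    """

    name: str
    dim: int
    q: int
    c: np.ndarray
    w: np.ndarray
    cs2: float = 1.0 / 3.0
    opp: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        c = np.asarray(self.c, dtype=np.int64)
        w = np.asarray(self.w, dtype=np.float64)
        object.__setattr__(self, "c", c)
        object.__setattr__(self, "w", w)
        if c.shape != (self.q, self.dim):
            raise ValueError("velocity table shape mismatch")
        if not np.all(c[0] == 0):
            raise ValueError("direction 0 must be the rest velocity")
        if not np.isclose(w.sum(), 1.0):
            raise ValueError("weights must sum to 1")
        if not np.allclose(np.einsum("i,id->d", w, c.astype(float)), 0.0):
            raise ValueError("first moment of weights must vanish")
        second = np.einsum("i,ia,ib->ab", w, c.astype(float), c.astype(float))
        if not np.allclose(second, self.cs2 * np.eye(self.dim)):
            raise ValueError("second moment must be cs2 * identity")
        opp = np.empty(self.q, dtype=np.int64)
        for i in range(self.q):
            matches = np.flatnonzero((c == -c[i]).all(axis=1))
            if matches.size != 1:
                raise ValueError("stencil is not symmetric")
            opp[i] = matches[0]
        object.__setattr__(self, "opp", opp)


D2Q9 = Lattice(
    name="D2Q9",
    dim=2,
    q=9,
    c=np.array(
        [
            [0, 0],
            [1, 0], [0, 1], [-1, 0], [0, -1],
            [1, 1], [-1, 1], [-1, -1], [1, -1],
        ]
    ),
    w=np.array([4 / 9] + [1 / 9] * 4 + [1 / 36] * 4),
)

_D3_AXIS = [
    [1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1],
]
_D3_DIAG = [
    [1, 1, 0], [-1, -1, 0], [1, -1, 0], [-1, 1, 0],
    [1, 0, 1], [-1, 0, -1], [1, 0, -1], [-1, 0, 1],
    [0, 1, 1], [0, -1, -1], [0, 1, -1], [0, -1, 1],
]

D3Q19 = Lattice(
    name="D3Q19",
    dim=3,
    q=19,
    c=np.array([[0, 0, 0]] + _D3_AXIS + _D3_DIAG),
    w=np.array([1 / 3] + [1 / 18] * 6 + [1 / 36] * 12),
)

_LATTICES = {"D2Q9": D2Q9, "D3Q19": D3Q19}


def get_lattice(name: str) -> Lattice:
    try:
        return _LATTICES[name]
    except KeyError:
        raise ValueError(f"unknown lattice {name!r}; choose from {sorted(_LATTICES)}")


class StabilityError(RuntimeError):
    """Raised when a configuration violates the LB stability guards."""


@dataclass(frozen=True)
class UnitSystem:
    """SI <-> lattice unit conversion.

    Parameters
    ----------
    dx : lattice spacing (m)
    dt : LB time step (s)
    nu : physical kinematic viscosity (m^2/s)
    rho0 : physical reference density (kg/m^3); lattice density 1 maps to rho0.
    cs2 : lattice speed-of-sound squared (stencil property).
    """

    dx: float
    dt: float
    nu: float
    rho0: float = 1000.0
    cs2: float = 1.0 / 3.0

    def __post_init__(self) -> None:
        if min(self.dx, self.dt, self.nu, self.rho0) <= 0:
            raise ValueError("dx, dt, nu, rho0 must be positive")
        if not 0.5 < self.tau <= 2.0:
            raise StabilityError(
                f"tau={self.tau:.4f} outside the stable window (0.5, 2]; "
                f"adjust dt or dx (nu_lat = nu*dt/dx^2 = {self.nu_lat:.4g})"
            )

    @property
    def nu_lat(self) -> float:
        return self.nu * self.dt / self.dx**2

    @property
    def tau(self) -> float:
        return self.nu_lat / self.cs2 + 0.5

    @property
    def u_scale(self) -> float:
        """Velocity conversion: u_phys = u_lat * u_scale (m/s)."""
        return self.dx / self.dt

    @property
    def p_scale(self) -> float:
        """Pressure conversion: p_phys = p_lat * p_scale (Pa)."""
        return self.rho0 * self.u_scale**2

    def velocity_to_si(self, u_lat: np.ndarray) -> np.ndarray:
        return np.asarray(u_lat) * self.u_scale

    def pressure_drop_to_lat(self, dP: float) -> float:
        return dP / self.p_scale
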