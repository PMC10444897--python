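"""Fused numba kernels for the 2D solver hot loops.

These are performance twins of the pure-numpy reference implementations in
:mod:`fibroflow.lb` and :mod:`fibroflow.transport`; the test suite asserts
bitwise-close equivalence.  Direction tables match ``lattice.D2Q9`` with
velocity component 0 mapped to array axis 0 (y) and component 1 to axis 1 (x).
"""

from __future__ import annotations

import numpy as np
from numba import njit

# D2Q9 displacement tables: (dy, dx) per direction, same order as lattice.D2Q9.
_CY = np.array([0, 1, 0, -1, 0, 1, -1, -1, 1], dtype=np.int64)
_CX = np.array([0, 0, 1, 0, -1, 1, 1, -1, -1], dtype=np.int64)
_W = np.array([4 / 9] + [1 / 9] * 4 + [1 / 36] * 4, dtype=np.float64)
_OPP = np.array([0, 3, 4, 1, 2, 7, 8, 5, 6], dtype=np.int64)


@njit(cache=True, fastmath=False)
def d2q9_step(f, ftmp, fnew, gamma, tau, ay, ax, use_force, rho_in, rho_out,
              use_pressure):
    """One BGK collide + partial-bounce-back stream step, in place into fnew.

    Two phases: collide+PBB-blend into ftmp (sequential writes), then a
    gather-form periodic streaming into fnew.  Walls are gamma=1 nodes.  When
    use_pressure, fixed-density boundaries are applied on the first/last
    x-columns by non-equilibrium extrapolation from the adjacent column
    (non-wall rows).
    """
    q, ny, nx = f.shape
    omega = 1.0 / tau
    w0 = 4.0 / 9.0
    ws = 1.0 / 9.0
    wd = 1.0 / 36.0
    for y in range(ny):
        for x in range(nx):
            f0 = f[0, y, x]
            f1 = f[1, y, x]
            f2 = f[2, y, x]
            f3 = f[3, y, x]
            f4 = f[4, y, x]
            f5 = f[5, y, x]
            f6 = f[6, y, x]
            f7 = f[7, y, x]
            f8 = f[8, y, x]
            rho = f0 + f1 + f2 + f3 + f4 + f5 + f6 + f7 + f8
            jy = f1 - f3 + f5 - f6 - f7 + f8
            jx = f2 - f4 + f5 + f6 - f7 - f8
            uy = jy / rho
            ux = jx / rho
            usq = 1.5 * (ux * ux + uy * uy)
            g = gamma[y, x]
            tg = 1.0 - g
            cu = uy
            e1 = ws * rho * (1.0 + 3.0 * cu + 4.5 * cu * cu - usq)
            cu = -uy
            e3 = ws * rho * (1.0 + 3.0 * cu + 4.5 * cu * cu - usq)
            cu = ux
            e2 = ws * rho * (1.0 + 3.0 * cu + 4.5 * cu * cu - usq)
            cu = -ux
            e4 = ws * rho * (1.0 + 3.0 * cu + 4.5 * cu * cu - usq)
            cu = uy + ux
            e5 = wd * rho * (1.0 + 3.0 * cu + 4.5 * cu * cu - usq)
            cu = -uy + ux
            e6 = wd * rho * (1.0 + 3.0 * cu + 4.5 * cu * cu - usq)
            cu = -uy - ux
            e7 = wd * rho * (1.0 + 3.0 * cu + 4.5 * cu * cu - usq)
            cu = uy - ux
            e8 = wd * rho * (1.0 + 3.0 * cu + 4.5 * cu * cu - usq)
            e0 = w0 * rho * (1.0 - usq)
            s0 = f0 - omega * (f0 - e0)
            s1 = f1 - omega * (f1 - e1)
            s2 = f2 - omega * (f2 - e2)
            s3 = f3 - omega * (f3 - e3)
            s4 = f4 - omega * (f4 - e4)
            s5 = f5 - omega * (f5 - e5)
            s6 = f6 - omega * (f6 - e6)
            s7 = f7 - omega * (f7 - e7)
            s8 = f8 - omega * (f8 - e8)
            if use_force:
                fy = rho * 3.0 * ay
                fx = rho * 3.0 * ax
                s1 += ws * fy
                s3 -= ws * fy
                s2 += ws * fx
                s4 -= ws * fx
                s5 += wd * (fy + fx)
                s6 += wd * (-fy + fx)
                s7 += wd * (-fy - fx)
                s8 += wd * (fy - fx)
            ftmp[0, y, x] = tg * s0 + g * f0
            ftmp[1, y, x] = tg * s1 + g * f3
            ftmp[2, y, x] = tg * s2 + g * f4
            ftmp[3, y, x] = tg * s3 + g * f1
            ftmp[4, y, x] = tg * s4 + g * f2
            ftmp[5, y, x] = tg * s5 + g * f7
            ftmp[6, y, x] = tg * s6 + g * f8
            ftmp[7, y, x] = tg * s7 + g * f5
            ftmp[8, y, x] = tg * s8 + g * f6
    for i in range(q):
        cy = _CY[i]
        cx = _CX[i]
        for y in range(ny):
            ys = y - cy
            if ys < 0:
                ys += ny
            elif ys >= ny:
                ys -= ny
            for x in range(nx):
                xs = x - cx
                if xs < 0:
                    xs += nx
                elif xs >= nx:
                    xs -= nx
                fnew[i, y, x] = ftmp[i, ys, xs]
    if use_pressure:
        for y in range(ny):
            for side in range(2):
                if side == 0:
                    xb, xn, rho_bc = 0, 1, rho_in
                else:
                    xb, xn, rho_bc = nx - 1, nx - 2, rho_out
                if gamma[y, xb] >= 1.0:
                    continue
                rho_n = 0.0
                jy = 0.0
                jx = 0.0
                for i in range(q):
                    fi = fnew[i, y, xn]
                    rho_n += fi
                    jy += _CY[i] * fi
                    jx += _CX[i] * fi
                uy = jy / rho_n
                ux = jx / rho_n
                usq = ux * ux + uy * uy
                for i in range(q):
                    cu = _CY[i] * uy + _CX[i] * ux
                    poly = 1.0 + 3.0 * cu + 4.5 * cu * cu - 1.5 * usq
                    feq_bc = _W[i] * rho_bc * poly
                    feq_n = _W[i] * rho_n * poly
                    fnew[i, y, xb] = feq_bc + (fnew[i, y, xn] - feq_n)


@njit(cache=True, fastmath=False)
def transport_react_2d(
    fbar, fibrin, blocked, wall, ux, uy, dx, dt, diff, k1,
    inlet_mask, inlet_value, outlet_col,
):
    """One explicit conservative advection-diffusion step plus the
    second-order lysis reaction, in place.

    Upwind-biased advection with a minmod-limited second-order (MUSCL)
    donor reconstruction on cell faces (arithmetic-mean face velocity);
    faces whose donor stencil touches a wall or blocked cell fall back to
    first-order upwind.  Central diffusion.  On blocked cells every
    outgoing flux component is suppressed (incoming fluxes deposit).  Wall
    cells exchange no flux.  Returns (influx, outflux) mass bookkeeping in
    concentration*cell units.
    """
    ny, nx = fbar.shape
    dtdx = dt / dx
    dcoef = diff / dx
    influx = 0.0
    outflux = 0.0
    dfbar = np.zeros((ny, nx))
    # x-faces between (y,x) and (y,x+1)
    for y in range(ny):
        for x in range(nx - 1):
            if wall[y, x] or wall[y, x + 1]:
                continue
            vf = 0.5 * (ux[y, x] + ux[y, x + 1])
            up = fbar[y, x] if vf > 0.0 else fbar[y, x + 1]
            donor = up
            if 1 <= x <= nx - 3:
                clean = not (
                    wall[y, x - 1] or blocked[y, x - 1]
                    or blocked[y, x] or blocked[y, x + 1]
                    or wall[y, x + 2] or blocked[y, x + 2]
                )
                if clean:
                    d_ce = fbar[y, x + 1] - fbar[y, x]
                    if vf > 0.0:
                        d_up = fbar[y, x] - fbar[y, x - 1]
                    else:
                        d_up = fbar[y, x + 2] - fbar[y, x + 1]
                    if d_up * d_ce > 0.0:
                        mag = min(abs(d_up), abs(d_ce))
                        slope = mag if d_ce > 0.0 else -mag
                        courant = abs(vf) * dtdx
                        donor = up + 0.5 * (1.0 - courant) * slope
            adv = vf * donor
            dif = -dcoef * (fbar[y, x + 1] - fbar[y, x])
            if blocked[y, x]:
                if adv > 0.0:
                    adv = 0.0
                if dif > 0.0:
                    dif = 0.0
            if blocked[y, x + 1]:
                if adv < 0.0:
                    adv = 0.0
                if dif < 0.0:
                    dif = 0.0
            flx = adv + dif
            dfbar[y, x] -= flx
            dfbar[y, x + 1] += flx
    # y-faces between (y,x) and (y+1,x)
    for y in range(ny - 1):
        for x in range(nx):
            if wall[y, x] or wall[y + 1, x]:
                continue
            vf = 0.5 * (uy[y, x] + uy[y + 1, x])
            up = fbar[y, x] if vf > 0.0 else fbar[y + 1, x]
            donor = up
            if 1 <= y <= ny - 3:
                clean = not (
                    wall[y - 1, x] or blocked[y - 1, x]
                    or blocked[y, x] or blocked[y + 1, x]
                    or wall[y + 2, x] or blocked[y + 2, x]
                )
                if clean:
                    d_ce = fbar[y + 1, x] - fbar[y, x]
                    if vf > 0.0:
                        d_up = fbar[y, x] - fbar[y - 1, x]
                    else:
                        d_up = fbar[y + 2, x] - fbar[y + 1, x]
                    if d_up * d_ce > 0.0:
                        mag = min(abs(d_up), abs(d_ce))
                        slope = mag if d_ce > 0.0 else -mag
                        courant = abs(vf) * dtdx
                        donor = up + 0.5 * (1.0 - courant) * slope
            adv = vf * donor
            dif = -dcoef * (fbar[y + 1, x] - fbar[y, x])
            if blocked[y, x]:
                if adv > 0.0:
                    adv = 0.0
                if dif > 0.0:
                    dif = 0.0
            if blocked[y + 1, x]:
                if adv < 0.0:
                    adv = 0.0
                if dif < 0.0:
                    dif = 0.0
            flx = adv + dif
            dfbar[y, x] -= flx
            dfbar[y + 1, x] += flx
    # outlet: free advective outflow from the last column
    for y in range(ny):
        x = outlet_col
        if wall[y, x] or blocked[y, x]:
            continue
        if ux[y, x] > 0.0:
            flx = ux[y, x] * fbar[y, x]
            dfbar[y, x] -= flx
            outflux += flx * dtdx
    for y in range(ny):
        for x in range(nx):
            if wall[y, x]:
                continue
            new = fbar[y, x] + dtdx * dfbar[y, x]
            if new < 0.0:
                new = 0.0
            if inlet_mask[y, x]:
                influx += inlet_value - new
                new = inlet_value
            fbar[y, x] = new
            # second-order lysis reaction, explicit Euler, clamped at zero
            fib = fibrin[y, x]
            if fib > 0.0:
                fib -= k1 * fib * fbar[y, x] * dt
                if fib < 0.0:
                    fib = 0.0
                fibrin[y, x] = fib
    return influx, outflux
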