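"""Anti-FA transport, reaction, clot-state update, and the coupled loop."""

import numpy as np
import pytest

import fibroflow._kernels as kernels
from fibroflow.clot import ClotField, calibrate_clot
from fibroflow.lattice import StabilityError, UnitSystem
from fibroflow.transport import (
    AntiFAField,
    react,
    run_lysis,
    transport_antifa,
    update_clot_state,
)

from conftest import mini_config


def column_setup(nx=30, u=5e-6, fbar0=1e-5, D=3.3e-11, clot_from=10):
    """A 1D (3-row) column: pre-filled lumen, blocked clot from clot_from."""
    ny = 3
    wall = np.zeros((ny, nx), bool)
    wall[0] = wall[-1] = True
    blocked = np.zeros((ny, nx), bool)
    blocked[1, clot_from:] = True
    fbar = np.zeros((ny, nx))
    fbar[1, :clot_from] = fbar0
    inlet = np.zeros((ny, nx), bool)
    inlet[1, 0] = True
    field = AntiFAField(Fbar=fbar, blocked=blocked, wall=wall, D=D,
                        inlet_mask=inlet, inlet_value=fbar0)
    vel = np.zeros((2, ny, nx))
    vel[1] = u
    return field, vel


class TestTransport:
    def test_quiescent_field_unchanged(self):
        field, _ = column_setup()
        field.blocked[:] = False
        before = field.Fbar.copy()
        u = np.zeros((2, 3, 30))
        field.D = 0.0
        transport_antifa(field, u, dx=1e-4, dt=1.0)
        # only the inlet Dirichlet is reasserted; everything else untouched
        assert np.allclose(field.Fbar, before)

    def test_front_accumulation_matches_linear_law(self):
        """The blocked front voxel accumulates at rate Fbar0 * u / dx once
        past the diffusive transient (the 1D front-feeding law)."""
        fbar0, u, dx = 1e-5, 5e-6, 1e-4
        field, vel = column_setup(u=u, fbar0=fbar0)
        dt = 2.0
        t, ts, vals = 0.0, [], []
        for _ in range(4000):
            transport_antifa(field, vel, dx, dt)
            t += dt
            ts.append(t)
            vals.append(field.Fbar[1, 10])
        ts, vals = np.array(ts), np.array(vals)
        grown = vals > 2 * fbar0  # past the transient
        slope = np.polyfit(ts[grown], vals[grown], 1)[0]
        assert slope == pytest.approx(fbar0 * u / dx, rel=0.02)

    def test_mass_bookkeeping_no_reaction(self):
        """With no sink, the global agent mass changes only by the boundary
        fluxes the step reports."""
        rng = np.random.default_rng(0)
        ny, nx = 6, 15
        wall = np.zeros((ny, nx), bool)
        wall[0] = wall[-1] = True
        blocked = np.zeros((ny, nx), bool)
        blocked[2:4, 8:12] = True
        fbar = rng.uniform(0, 1e-5, (ny, nx))
        fbar[wall] = 0.0
        inlet = np.zeros((ny, nx), bool)
        inlet[1:-1, 0] = True
        field = AntiFAField(Fbar=fbar, blocked=blocked, wall=wall, D=3e-11,
                            inlet_mask=inlet, inlet_value=1e-5)
        vel = np.zeros((2, ny, nx))
        vel[1] = rng.uniform(0, 4e-6, (ny, nx))
        for _ in range(50):
            before = field.Fbar.sum()
            influx, outflux = transport_antifa(field, vel, 1e-4, 2.0)
            after = field.Fbar.sum()
            assert after - before == pytest.approx(influx - outflux, abs=1e-18)

    def test_cfl_breach_raises(self):
        field, vel = column_setup(u=5e-6)
        with pytest.raises(StabilityError):
            transport_antifa(field, vel, dx=1e-4, dt=1e5)

    def test_numba_kernel_matches_reference(self):
        rng = np.random.default_rng(7)
        ny, nx = 6, 20
        fbar = rng.uniform(0, 1e-5, (ny, nx))
        F = rng.uniform(0, 3, (ny, nx))
        wall = np.zeros((ny, nx), bool)
        wall[0] = wall[-1] = True
        F[wall] = 0.0
        blocked = (rng.random((ny, nx)) < 0.3) & ~wall
        ux = rng.uniform(-1e-6, 5e-6, (ny, nx))
        uy = rng.uniform(-1e-6, 1e-6, (ny, nx))
        inlet = np.zeros((ny, nx), bool)
        inlet[1:-1, 0] = True
        inlet &= ~blocked
        dx, dt, D, k1 = 2e-5, 1.0, 1e-13, 100.0

        ref = AntiFAField(Fbar=fbar.copy(), blocked=blocked, wall=wall, D=D,
                          inlet_mask=inlet, inlet_value=2e-5)
        transport_antifa(ref, np.stack([uy, ux]), dx, dt)
        F_ref = react(F.copy(), ref.Fbar, k1, dt)

        fb2, F2 = fbar.copy(), F.copy()
        kernels.transport_react_2d(fb2, F2, blocked, wall, ux, uy, dx, dt,
                                  D, k1, inlet, 2e-5, nx - 1)
        assert np.array_equal(ref.Fbar, fb2)
        assert np.allclose(F_ref, F2, rtol=0, atol=1e-15)


class TestReact:
    def test_no_agent_no_reaction(self):
        F = np.array([[1.0, 2.0]])
        assert np.array_equal(react(F, np.zeros_like(F), 100.0, 1.0), F)

    def test_complete_consumption_at_unit_product(self):
        F = np.array([[2.0]])
        fbar = np.array([[1e-3]])
        out = react(F, fbar, k1=999.9, dt=1.0 / 0.9999)
        assert out[0, 0] == pytest.approx(0.0, abs=1e-10)

    def test_converges_to_exponential_decay(self):
        """Iterated explicit steps approach F0 exp(-k1 Fbar t), first order
        in dt."""
        k1, fbar, T = 100.0, np.array([[2e-4]]), 50.0
        errs = []
        for n in (500, 5000):
            F = np.array([[2.0]])
            dt = T / n
            for _ in range(n):
                F = react(F, fbar, k1, dt)
            errs.append(abs(F[0, 0] - 2.0 * np.exp(-k1 * fbar[0, 0] * T)))
        assert errs[1] < errs[0] / 5  # first-order convergence

    def test_positivity_guard(self):
        with pytest.raises(StabilityError):
            react(np.array([[1.0]]), np.array([[1.0]]), k1=10.0, dt=1.0)


class TestUpdateClotState:
    def setup_method(self):
        self.units = UnitSystem(dx=2e-5, dt=2e-4, nu=1e-6)
        cal = calibrate_clot(2.0, 1.4e-7, k0=1e-13)
        F = np.full((5, 8), 2.0)
        mask = np.ones((5, 8), bool)
        self.clot = ClotField(F=F, mask=mask, calibration=cal)

    def test_idempotent_without_reaction(self):
        g1, b1 = update_clot_state(self.clot, self.units, 0.2)
        g2, b2 = update_clot_state(self.clot, self.units, 0.2)
        assert np.array_equal(g1, g2) and np.array_equal(b1, b2)

    def test_gamma_strictly_decreases_with_fibrin(self):
        g1, _ = update_clot_state(self.clot, self.units, 0.2)
        self.clot.F[2, 3] *= 0.5
        g2, _ = update_clot_state(self.clot, self.units, 0.2)
        assert g2[2, 3] < g1[2, 3]
        mask_other = np.ones((5, 8), bool)
        mask_other[2, 3] = False
        assert np.array_equal(g1[mask_other], g2[mask_other])

    def test_threshold_crossing_unblocks_exactly_once(self):
        _, b1 = update_clot_state(self.clot, self.units, 0.2)
        assert b1.all()
        self.clot.F[1, 1] = 0.19
        _, b2 = update_clot_state(self.clot, self.units, 0.2)
        assert not b2[1, 1] and b2.sum() == b1.sum() - 1


class TestCoupledRun:
    def test_zero_reaction_rate_preserves_mass(self):
        cfg = mini_config()
        cfg.physical.k1 = 1e-12  # effectively inert agent
        cfg.stop.t_max_s = 200.0
        rec = run_lysis(cfg, seed_override=1)
        assert np.allclose(rec.mass_frac, 1.0, atol=1e-6)

    def test_same_seed_reproduces_record_exactly(self):
        a = run_lysis(mini_config(), seed_override=5)
        b = run_lysis(mini_config(), seed_override=5)
        assert np.array_equal(a.times, b.times)
        assert np.array_equal(a.mass_frac, b.mass_frac)
        assert np.array_equal(a.throughput, b.throughput)
        assert np.array_equal(a.slice_times, b.slice_times)

    def test_record_invariants(self, mini_run):
        rec = mini_run
        assert np.all(np.diff(rec.times) > 0)
        assert np.all(np.diff(rec.mass_frac) <= 1e-12)
        assert np.all(np.diff(rec.front_m) >= 0)
        assert rec.meta["termination"] == "lysed"

    def test_slices_lyse_in_order_for_homogeneous_clot(self, mini_run):
        """Strict inlet-to-outlet ordering through the front-propagation
        phase; the final slices overlap with the breakthrough regime where
        the mean-based slice clock can tie."""
        st = mini_run.slice_times
        assert not np.any(np.isnan(st))
        assert np.all(np.diff(st[:-2]) > 0)

    def test_throughput_effectively_nondecreasing(self, mini_run):
        """Permeability only rises during lysis, so flow through the clot
        rises too (tiny dips from quasi-steady re-solves are numerical)."""
        q = mini_run.throughput
        drops = np.diff(q) / q.max()
        assert np.all(drops > -0.02)

    def test_quasi_steady_cadence_convergence(self):
        """Halving the re-solve cadence interval barely changes the total
        lysis time."""
        base = mini_config()
        rec_a = run_lysis(base, seed_override=3)
        tight = mini_config()
        tight.numerics.resistance_retrigger = base.numerics.resistance_retrigger / 2
        tight.numerics.max_steps_between_solves = base.numerics.max_steps_between_solves // 2
        rec_b = run_lysis(tight, seed_override=3)
        assert rec_b.times[-1] == pytest.approx(rec_a.times[-1], rel=0.02)
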