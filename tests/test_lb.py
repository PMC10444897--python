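"""LB solver: operator contracts, conservation, and hydrodynamic oracles."""

import numpy as np
import pytest

from fibroflow import lb
from fibroflow.lattice import D2Q9, D3Q19, StabilityError, UnitSystem


def random_state(units, ny=8, nx=12, seed=0, walls=True, gamma_kind="random"):
    rng = np.random.default_rng(seed)
    if gamma_kind == "random":
        gamma = rng.uniform(0.0, 1.0, (ny, nx))
    else:
        gamma = np.zeros((ny, nx))
    if walls:
        gamma[0] = 1.0
        gamma[-1] = 1.0
    state = lb.FluidState.at_rest(D2Q9, units, gamma)
    state.f *= rng.uniform(0.9, 1.1, state.f.shape)
    return state


class TestEquilibrium:
    @pytest.mark.parametrize("lat", [D2Q9, D3Q19], ids=lambda l: l.name)
    def test_rest_state_is_weights(self, lat):
        rho = np.ones((3, 4) if lat.dim == 2 else (3, 4, 2))
        u = np.zeros((lat.dim,) + rho.shape)
        feq = lb.equilibrium(lat, rho, u)
        for i in range(lat.q):
            assert np.allclose(feq[i], lat.w[i])

    @pytest.mark.parametrize("lat", [D2Q9, D3Q19], ids=lambda l: l.name)
    def test_moments_reproduced(self, lat):
        rng = np.random.default_rng(1)
        shape = (5, 6) if lat.dim == 2 else (3, 4, 5)
        rho = rng.uniform(0.8, 1.2, shape)
        u = rng.uniform(-0.05, 0.05, (lat.dim,) + shape)
        feq = lb.equilibrium(lat, rho, u)
        assert np.allclose(feq.sum(axis=0), rho)
        mom = np.tensordot(lat.c.astype(float).T, feq, axes=(1, 0))
        assert np.allclose(mom, rho * u)

    def test_rest_population_hand_value(self):
        # D2Q9, rho=1, u=(0.1, 0): w0 * (1 - 1.5 * 0.01)
        rho = np.array([[1.0]])
        u = np.zeros((2, 1, 1))
        u[1] = 0.1  # axial component
        feq = lb.equilibrium(D2Q9, rho, u)
        assert feq[0, 0, 0] == pytest.approx((4 / 9) * (1 - 0.015), rel=1e-12)


class TestCollision:
    def test_equilibrium_is_fixed_point(self):
        rng = np.random.default_rng(2)
        rho = rng.uniform(0.9, 1.1, (4, 5))
        u = rng.uniform(-0.05, 0.05, (2, 4, 5))
        feq = lb.equilibrium(D2Q9, rho, u)
        assert np.allclose(lb.collide_bgk(feq, feq, tau=1.7), feq)

    def test_full_relaxation_at_tau_one(self):
        rng = np.random.default_rng(3)
        f = rng.uniform(0.05, 0.2, (9, 4, 5))
        rho, u = lb.macroscopic(D2Q9, f)
        feq = lb.equilibrium(D2Q9, rho, u)
        assert np.allclose(lb.collide_bgk(f, feq, tau=1.0), feq)

    def test_mass_and_momentum_invariant(self):
        rng = np.random.default_rng(4)
        f = rng.uniform(0.05, 0.2, (9, 4, 5))
        rho, u = lb.macroscopic(D2Q9, f)
        fs = lb.collide_bgk(f, lb.equilibrium(D2Q9, rho, u), tau=0.8)
        assert np.allclose(fs.sum(0), f.sum(0))
        mom_a = np.tensordot(D2Q9.c.astype(float).T, f, axes=(1, 0))
        mom_b = np.tensordot(D2Q9.c.astype(float).T, fs, axes=(1, 0))
        assert np.allclose(mom_a, mom_b)

    def test_subcritical_tau_rejected(self):
        f = np.full((9, 2, 2), 0.1)
        with pytest.raises(StabilityError):
            lb.collide_bgk(f, f, tau=0.5)


class TestStreaming:
    def test_single_population_travels_one_node(self):
        f = np.zeros((9, 5, 5))
        f[1, 2, 2] = 1.0  # direction (dy, dx) = (1, 0)
        out = lb.stream(D2Q9, f)
        assert out[1, 3, 2] == 1.0 and out.sum() == 1.0

    def test_uniform_field_is_invariant(self):
        f = np.tile(D2Q9.w.reshape(-1, 1, 1), (1, 4, 6))
        assert np.allclose(lb.stream(D2Q9, f), f)

    def test_periodic_mass_conservation_long_run(self, units):
        rng = np.random.default_rng(5)
        f = rng.uniform(0.05, 0.2, (9, 6, 8))
        total = f.sum()
        for _ in range(1000):
            f = lb.stream(D2Q9, f)
        assert f.sum() == pytest.approx(total, rel=1e-12)


class TestPartialBounceBack:
    def test_gamma_zero_reduces_to_streaming(self, units):
        rng = np.random.default_rng(6)
        f = rng.uniform(0.05, 0.2, (9, 5, 7))
        fs = rng.uniform(0.05, 0.2, (9, 5, 7))
        out = lb.pbb_stream(D2Q9, fs, f, np.zeros((5, 7)))
        assert np.allclose(out, lb.stream(D2Q9, fs))

    def test_gamma_one_reduces_to_bounce_back(self, units):
        rng = np.random.default_rng(7)
        f = rng.uniform(0.05, 0.2, (9, 5, 7))
        fs = rng.uniform(0.05, 0.2, (9, 5, 7))
        out = lb.pbb_stream(D2Q9, fs, f, np.ones((5, 7)))
        expect = lb.stream(D2Q9, f[D2Q9.opp])
        assert np.allclose(out, expect)

    def test_half_gamma_splits_single_population(self):
        """One incoming population on a gamma=1/2 node: half transmitted
        forward, half reflected backward (hand-checked 1D three-node case)."""
        f = np.zeros((9, 1, 3))
        fs = np.zeros((9, 1, 3))
        fs[2, 0, 1] = 1.0  # direction +x on the middle node
        f[2, 0, 1] = 1.0
        gamma = np.array([[0.0, 0.5, 0.0]])
        out = lb.pbb_stream(D2Q9, fs, f, gamma)
        assert out[2, 0, 2] == pytest.approx(0.5)  # transmitted to the right
        assert out[4, 0, 0] == pytest.approx(0.5)  # reflected to the left
        assert out.sum() == pytest.approx(1.0)

    def test_gamma_out_of_range_rejected(self):
        f = np.full((9, 2, 2), 0.1)
        with pytest.raises(ValueError):
            lb.pbb_stream(D2Q9, f, f, np.full((2, 2), 1.5))

    def test_closed_box_mass_constant(self, units):
        rng = np.random.default_rng(8)
        gamma = np.zeros((6, 6))
        gamma[[0, -1], :] = 1.0
        gamma[:, [0, -1]] = 1.0
        f = rng.uniform(0.05, 0.2, (9, 6, 6))
        total = f.sum()
        for _ in range(200):
            rho, u = lb.macroscopic(D2Q9, f)
            fs = lb.collide_bgk(f, lb.equilibrium(D2Q9, rho, u), units.tau)
            f = lb.pbb_stream(D2Q9, fs, f, gamma)
        assert f.sum() == pytest.approx(total, rel=1e-12)


class TestMacroscopic:
    def test_rest_moments(self):
        f = np.tile(D2Q9.w.reshape(-1, 1, 1), (1, 3, 3))
        rho, u = lb.macroscopic(D2Q9, f)
        assert np.allclose(rho, 1.0) and np.allclose(u, 0.0)

    def test_solid_node_velocity_zero(self):
        rng = np.random.default_rng(9)
        f = rng.uniform(0.05, 0.2, (9, 3, 3))
        _, u = lb.macroscopic(D2Q9, f, gamma=np.ones((3, 3)))
        assert np.allclose(u, 0.0)

    def test_half_gamma_halves_velocity(self):
        rng = np.random.default_rng(10)
        f = rng.uniform(0.05, 0.2, (9, 3, 3))
        _, u_bare = lb.macroscopic(D2Q9, f)
        _, u_half = lb.macroscopic(D2Q9, f, gamma=np.full((3, 3), 0.5))
        assert np.allclose(u_half, 0.5 * u_bare)


class TestNumbaEquivalence:
    @pytest.mark.parametrize("mode", ["pressure", "force", "none"])
    def test_fused_kernel_matches_reference(self, units, mode):
        s_np = random_state(units, seed=11)
        if mode == "pressure":
            lb.apply_pressure_drop(s_np, 300.0)
        elif mode == "force":
            lb.apply_body_force(s_np, 300.0)
        s_nb = s_np.copy()
        ftmp = np.empty_like(s_nb.f)
        fnew = np.empty_like(s_nb.f)
        for _ in range(40):
            lb.step(s_np)
            lb._step_numba(s_nb, ftmp, fnew)
            s_nb.f, fnew = fnew, s_nb.f
        assert np.allclose(s_np.f, s_nb.f, rtol=0, atol=1e-14)


class TestPressureDriving:
    def test_zero_gradient_stays_at_rest(self, units):
        state = lb.make_channel_2d(10, 16, units)
        lb.apply_pressure_drop(state, 0.0)
        rep = lb.run_to_steady(state, tol=1e-6, max_steps=2000)
        assert rep.converged
        assert np.abs(state.velocity_si()).max() < 1e-14

    def test_stokes_linearity_in_pressure_drop(self, units):
        flows = []
        for grad in (150.0, 300.0):
            state = lb.make_channel_2d(12, 20, units)
            lb.apply_pressure_drop(state, grad)
            lb.run_to_steady(state, tol=1e-8, max_steps=100_000)
            u = state.velocity_si()
            flows.append(u[1][1:-1, 10].sum())
        assert flows[1] == pytest.approx(2 * flows[0], rel=0.01)

    def test_compressibility_guard(self, units):
        state = lb.make_channel_2d(10, 16, units)
        with pytest.raises(StabilityError):
            lb.apply_pressure_drop(state, 5e6)


class TestRunToSteady:
    def test_rest_state_converges_immediately(self, units):
        state = lb.make_channel_2d(8, 10, units)
        rep = lb.run_to_steady(state, tol=1e-6, max_steps=500, check_every=50)
        assert rep.converged and rep.steps == 50

    def test_divergence_reported_as_instability(self, units):
        state = lb.make_channel_2d(8, 10, units)
        state.f[:, 3, 3] = np.nan
        with pytest.raises(StabilityError):
            lb.run_to_steady(state, tol=1e-6, max_steps=200)


class TestHydrodynamicOracles:
    def test_shear_wave_viscosity_identity(self, units):
        """The decay rate of a transverse shear wave measures the kinematic
        viscosity: nu_lat = cs2 (tau - 1/2)."""
        ny, nx = 64, 4  # long wavelength keeps discrete-k corrections small
        gamma = np.zeros((ny, nx))
        state = lb.FluidState.at_rest(D2Q9, units, gamma)
        k = 2 * np.pi / ny
        amp = 1e-4
        u = np.zeros((2, ny, nx))
        u[1] = amp * np.sin(k * np.arange(ny))[:, None]
        state.f = lb.equilibrium(D2Q9, np.ones((ny, nx)), u)
        ftmp, fnew = np.empty_like(state.f), np.empty_like(state.f)
        n_steps = 600
        for _ in range(n_steps):
            lb._step_numba(state, ftmp, fnew)
            state.f, fnew = fnew, state.f
        _, u_end = state.macroscopic()
        ratio = np.abs(u_end[1]).max() / amp
        nu_measured = -np.log(ratio) / (k**2 * n_steps)
        assert nu_measured == pytest.approx(units.nu_lat, rel=0.02)

    def test_checkpoint_restart_is_deterministic(self, units, tmp_path):
        from fibroflow.io import load_checkpoint, save_checkpoint

        state = random_state(units, seed=12)
        lb.apply_pressure_drop(state, 200.0)
        save_checkpoint(tmp_path / "chk.npz", state)
        lb.run_to_steady(state, tol=1e-7, max_steps=3000)
        resumed = lb.FluidState.at_rest(D2Q9, units, state.gamma.copy())
        load_checkpoint(tmp_path / "chk.npz", resumed)
        lb.run_to_steady(resumed, tol=1e-7, max_steps=3000)
        assert np.array_equal(state.f, resumed.f)
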