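"""Solver core: stencil identities, moments, collision, streaming, BCs."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from spongeflow.lbm import (
    SimParams,
    Simulation,
    StabilityError,
    collide_bgk,
    equilibrium,
    macro_moments,
    nu_from_tau,
    run_to_steady,
    stream_periodic,
)
from spongeflow.stencil import C, CS2, MIRROR_Z, OPP, W


class TestStencil:
    def test_weight_and_velocity_moments(self):
        assert W.sum() == pytest.approx(1.0, abs=1e-15)
        assert np.allclose(W @ C.astype(float), 0.0, atol=1e-15)
        second = np.einsum("i,ia,ib->ab", W, C.astype(float), C.astype(float))
        assert np.allclose(second, CS2 * np.eye(3), atol=1e-15)

    def test_every_velocity_has_opposite(self):
        assert (C[OPP] == -C).all()
        assert (C[MIRROR_Z] == C * np.array([1, 1, -1])).all()


random_f = arrays(
    np.float64, (19, 3, 3, 3),
    elements=st.floats(0.01, 2.0, allow_nan=False),
)


class TestCollision:
    def test_rest_state_equilibrium_is_weights(self):
        feq = equilibrium(np.float64(1.0), np.zeros(3))
        assert np.allclose(feq, W, atol=1e-15)

    @settings(deadline=None, max_examples=30)
    @given(f=random_f, tau=st.floats(0.51, 3.0))
    def test_mass_momentum_conserved_nodewise(self, f, tau):
        fc = collide_bgk(f, tau)
        assert np.allclose(fc.sum(axis=0), f.sum(axis=0), rtol=1e-13)
        for a in range(3):
            pre = np.tensordot(C[:, a].astype(float), f, axes=(0, 0))
            post = np.tensordot(C[:, a].astype(float), fc, axes=(0, 0))
            assert np.allclose(pre, post, atol=1e-13)

    @settings(deadline=None, max_examples=20)
    @given(
        rho=st.floats(0.5, 2.0),
        ux=st.floats(-0.1, 0.1), uy=st.floats(-0.1, 0.1), uz=st.floats(-0.1, 0.1),
    )
    def test_equilibrium_recovers_moments(self, rho, ux, uy, uz):
        u = np.array([ux, uy, uz])
        feq = equilibrium(np.float64(rho), u)
        assert feq.sum() == pytest.approx(rho, rel=1e-13)
        assert np.allclose(
            np.tensordot(C.astype(float), feq, axes=(0, 0)), rho * u, atol=1e-14
        )

    def test_equilibrium_second_moment(self):
        # brute-force sum over the 19 populations against cs2*rho + rho*u^2
        u = np.array([0.05, 0.0, 0.0])
        feq = equilibrium(np.float64(1.0), u)
        assert (feq * C[:, 0] ** 2).sum() == pytest.approx(
            CS2 + 0.05**2, rel=1e-13
        )

    def test_equilibrium_is_collision_fixed_point(self):
        feq = equilibrium(np.float64(1.2), np.array([0.03, -0.02, 0.01]))
        assert np.allclose(collide_bgk(feq, tau_f=0.9), feq, atol=1e-15)

    def test_full_relaxation_at_tau_equals_dt(self):
        rng = np.random.default_rng(3)
        f = rng.uniform(0.1, 1.0, size=(19, 2, 2, 2))
        rho, u = macro_moments(f)
        assert np.allclose(collide_bgk(f, tau_f=1.0), equilibrium(rho, u))

    def test_subviscous_tau_rejected(self):
        with pytest.raises(ValueError):
            collide_bgk(np.ones((19, 1, 1, 1)), tau_f=0.5)
        with pytest.raises(ValueError):
            SimParams(tau_f=0.5)


class TestStreaming:
    def test_single_population_translates_along_link(self):
        f = np.zeros((19, 5, 5, 5))
        f[7, 2, 2, 2] = 1.0  # c = (1, 1, 0)
        fs = stream_periodic(f)
        assert fs[7, 3, 3, 2] == 1.0
        assert fs.sum() == 1.0
        fs2 = stream_periodic(fs)
        assert fs2[7, 4, 4, 2] == 1.0  # two steps displace by 2c

    def test_periodic_box_conserves_mass(self):
        rng = np.random.default_rng(0)
        f = rng.uniform(0.1, 1.0, size=(19, 4, 5, 6))
        assert stream_periodic(f).sum() == pytest.approx(f.sum(), rel=1e-14)


class TestSimulationStep:
    def test_numba_and_numpy_paths_agree(self):
        occ = np.zeros((12, 10, 11), dtype=bool)
        occ[5:8, 4:7, 3:6] = True
        p = SimParams(tau_f=0.8, u_in_lattice=(0.05, 0.0, 0.0), n_steps=1)
        s1 = Simulation(occ, p, backend="numba")
        s2 = Simulation(occ, p, backend="numpy")
        for _ in range(15):
            s1.step()
            s2.step()
        fluid = ~s1.solid
        assert np.abs(s1.f - s2.f)[:, fluid].max() < 1e-13

    def test_closed_periodic_box_conserves_mass_over_time(self):
        occ = np.zeros((6, 6, 6), dtype=bool)
        p = SimParams(tau_f=0.7, n_steps=1)
        sim = Simulation(occ, p, open_x=False, bottom_wall=False,
                         top_freeslip=False)
        rng = np.random.default_rng(1)
        sim.f[...] = rng.uniform(0.1, 1.0, size=sim.f.shape)
        m0 = sim.f.sum()
        for _ in range(25):
            sim.step()
        assert sim.f.sum() == pytest.approx(m0, rel=1e-13)

    def test_uniform_flow_is_transparent_to_all_boundaries(self):
        # inlet/outlet + periodic sides + free-slip top/bottom-free channel
        occ = np.zeros((24, 8, 10), dtype=bool)
        u = 0.06
        p = SimParams(tau_f=0.8, u_in_lattice=(u, 0.0, 0.0), n_steps=1)
        sim = Simulation(occ, p, bottom_wall=False, top_freeslip=True)
        for _ in range(200):
            sim.step()
        m = sim.macro()
        assert np.abs(m.u[0] - u).max() < 1e-6
        assert np.abs(m.u[1:]).max() < 1e-6

    def test_quiescent_fluid_with_obstacle_stays_at_rest(self):
        occ = np.zeros((10, 10, 12), dtype=bool)
        occ[4:7, 4:7, 4:8] = True
        p = SimParams(tau_f=0.9, n_steps=1)
        sim = Simulation(occ, p, open_x=False, bottom_wall=True,
                         top_freeslip=True)
        for _ in range(60):
            sim.step()
        m = sim.macro()
        assert np.abs(m.u).max() < 1e-14
        assert np.abs(m.rho[~sim.solid] - 1.0).max() < 1e-14

    def test_blowup_raises_stability_error(self):
        occ = np.zeros((8, 4, 4), dtype=bool)
        p = SimParams(tau_f=0.6, n_steps=1)
        sim = Simulation(occ, p, open_x=False, bottom_wall=False,
                         top_freeslip=False)
        sim.f[0, 2, 2, 2] = np.nan
        sim.step()
        with pytest.raises(StabilityError):
            sim.check_stability()


class TestPhysicsBenchmarks:
    def test_poiseuille_profile_32_nodes(self):
        """Body-force channel matches the parabolic profile within 2%."""
        nzc = 32
        occ = np.zeros((4, 4, nzc + 2), dtype=bool)
        occ[:, :, 0] = True
        occ[:, :, -1] = True
        tau, g = 0.8, 1e-6
        p = SimParams(tau_f=tau, body_force=(g, 0.0, 0.0), n_steps=1)
        sim = Simulation(occ, p, open_x=False, bottom_wall=False,
                         top_freeslip=False)
        for _ in range(30000):
            sim.step()
        ux = sim.macro().u[0, 0, 0, 1:-1]
        z = np.arange(1, nzc + 1) - 0.5   # walls sit half a voxel outside
        ana = g / (2 * nu_from_tau(tau)) * z * (nzc - z)
        assert (np.abs(ux - ana) / ana.max()).max() < 0.02

    @pytest.mark.parametrize("tau", [0.6, 0.8, 1.5])
    def test_viscous_decay_rate_matches_nu(self, tau):
        """A sinusoidal shear mode decays as exp(-nu k^2 t) within 2%."""
        n = 32
        occ = np.zeros((4, 4, n), dtype=bool)
        p = SimParams(tau_f=tau, n_steps=1)
        sim = Simulation(occ, p, open_x=False, bottom_wall=False,
                         top_freeslip=False)
        k = 2 * np.pi / n
        u0 = np.zeros((3, 4, 4, n))
        u0[0] = 0.01 * np.sin(k * np.arange(n))
        sim.init_state(u=u0)

        def amplitude():
            return abs(np.fft.rfft(sim.macro().u[0, 0, 0])[1]) * 2 / n

        for _ in range(200):
            sim.step()
        a1 = amplitude()
        for _ in range(400):
            sim.step()
        a2 = amplitude()
        nu_meas = np.log(a1 / a2) / (k**2 * 400)
        assert nu_meas == pytest.approx(nu_from_tau(tau), rel=0.02)

    def test_empty_domain_run_to_steady_reaches_uniform_inflow(self):
        from spongeflow.geometry import CavityCylinder, VoxelGeometry

        occ = np.zeros((30, 8, 10), dtype=bool)
        geom = VoxelGeometry(
            occupancy=occ, spacing=1.0, origin=np.zeros(3),
            labels=occ.astype(np.uint8), cavities=[], cavity_masks=[],
        )
        u = 0.05
        p = SimParams(tau_f=0.8, u_in_lattice=(u, 0.0, 0.0), n_steps=2000,
                      steady_window=200, check_every=50)
        res = run_to_steady(geom, p, bottom_wall=False, top_freeslip=True)
        assert np.abs(res.macro.u[0] - u).max() < 1e-6
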