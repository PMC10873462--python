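"""Integrator behavior: free-space limits, contact handling, determinism,
event logging, and the mirrored-noise harness."""

import math

import numpy as np
import pytest

from capsim.engine import SimConfig, mirror_pair, simulate, wall_projected_velocity
from capsim.lattice import build_lattice
from capsim.model import CAPParams, FlowField


def cfg(**kw):
    base = dict(dt=1e-3, t_total=100.0, n_particles=2, seed=1,
                record_stride=100)
    base.update(kw)
    return SimConfig(**base)


class TestWallProjectedVelocity:
    def test_head_on_single_contact_cancels(self):
        v = wall_projected_velocity([-1.0, 0.0], [[1.0, 0.0]])
        assert np.allclose(v, 0.0)

    def test_tangential_motion_untouched(self):
        v = wall_projected_velocity([0.0, 1.0], [[1.0, 0.0]])
        assert np.allclose(v, [0.0, 1.0])

    def test_outward_motion_untouched(self):
        v = wall_projected_velocity([0.6, 0.8], [[1.0, 0.0]])
        assert np.allclose(v, [0.6, 0.8])

    def test_drift_included_in_projection(self):
        v = wall_projected_velocity([0.0, 1.0], [[1.0, 0.0]],
                                    v_drift=[-2.0, 0.0])
        assert np.allclose(v, [0.0, 1.0])

    def test_corner_projection_never_gains_speed(self):
        normals = [[1.0, 0.0], [0.0, 1.0]]
        v = wall_projected_velocity([-0.7, -0.714], normals)
        assert np.linalg.norm(v) <= 1.0 + 1e-12

    def test_non_unit_normals_rejected(self):
        with pytest.raises(ValueError, match="unit"):
            wall_projected_velocity([1.0, 0.0], [[2.0, 0.0]])


class TestFreeSpace:
    def test_noise_free_circle(self):
        # Dr=0, omega0=1: radius-1 circle retraced with period 2 pi
        p = CAPParams(v0=1, omega0=1, Dr=0)
        traj, _ = simulate(
            p, None,
            cfg(t_total=2 * math.pi, record_stride=10, burn_in=0.0),
            init=np.array([[0, 0, 0], [0, 0, 0]], dtype=float),
        )
        radius = np.hypot(traj.xu[0], traj.yu[0] - 1.0)
        assert np.abs(radius - 1.0).max() < 2e-3  # O(dt)
        closure = math.hypot(traj.xu[0, -1], traj.yu[0, -1])
        assert closure < 5e-3

    def test_pure_drift_advances_exactly(self):
        p = CAPParams(v0=1, omega0=0, Dr=0)
        traj, _ = simulate(
            p, None, cfg(t_total=5.0, burn_in=0.0, record_stride=50),
            flow=FlowField(v_g=1.0, psi=0.0),
            init=np.array([[0, 0, math.pi / 2], [0, 0, math.pi / 2]]),
        )
        # heading +y plus drift +x: both coordinates advance at unit rate
        assert traj.xu[0, -1] == pytest.approx(5.0, rel=1e-12)
        assert traj.yu[0, -1] == pytest.approx(5.0, rel=1e-12)

    def test_angular_increment_statistics(self):
        p = CAPParams(v0=1, omega0=0.7, Dr=0.3)
        traj, _ = simulate(p, None, cfg(t_total=400.0, n_particles=16,
                                        burn_in=0.0))
        T = traj.times[-1]
        dtheta = traj.theta[:, -1] - traj.theta[:, 0]
        mean, var = dtheta.mean(), dtheta.var(ddof=1)
        se_mean = math.sqrt(2 * p.Dr * T / 16)
        assert mean == pytest.approx(p.omega0 * T, abs=3 * se_mean)
        se_var = 2 * p.Dr * T * math.sqrt(2 / 15)
        assert var == pytest.approx(2 * p.Dr * T, abs=3 * se_var)

    def test_determinism_bitwise(self):
        p = CAPParams(v0=1, omega0=1, Dr=0.1)
        a, _ = simulate(p, None, cfg(n_particles=3))
        b, _ = simulate(p, None, cfg(n_particles=3))
        assert np.array_equal(a.xu, b.xu)
        assert np.array_equal(a.theta, b.theta)

    def test_dt_bound_enforced(self):
        p = CAPParams(v0=1, omega0=1, Dr=0.1)
        with pytest.raises(ValueError, match="dt"):
            simulate(p, None, cfg(dt=0.05))


class TestLatticeDynamics:
    def test_speed_bound_with_contacts(self, square_07):
        p = CAPParams.from_reduced(1.0, 10.0)
        traj, _ = simulate(p, square_07, cfg(t_total=200.0, burn_in=0.0),
                           flow=FlowField(v_g=1.0, psi=0.3))
        # per-sample displacement cannot exceed (v0+v_g) * sample interval
        dt_s = traj.times[1] - traj.times[0]
        step = np.hypot(np.diff(traj.xu, axis=1), np.diff(traj.yu, axis=1))
        assert step.max() <= 2.0 * dt_s * (1 + 1e-6)

    def test_no_penetration_at_samples(self, square_07):
        p = CAPParams.from_reduced(1.5, 50.0)
        traj, _ = simulate(p, square_07, cfg(t_total=300.0))
        f = np.stack([traj.xw, traj.yw], axis=-1) @ square_07.box_inv.T
        f -= np.round(f)
        g = f @ square_07.box.T
        dist = np.hypot(g[..., 0], g[..., 1])
        assert dist.min() >= square_07.R * (1 - 1e-9)

    def test_contact_time_consistency(self, square_07):
        p = CAPParams.from_reduced(1.0, 10.0)
        traj, log = simulate(p, square_07, cfg(t_total=150.0))
        assert log.t_slide + log.t_hop == log.t_total
        assert log.t_slide == log.dt * log.contact_steps.sum()
        # interval list covers the same sliding time
        for p_idx in range(log.n_particles):
            iv = log.intervals[p_idx]
            covered = float(np.sum(iv[:, 1] - iv[:, 0])) if len(iv) else 0.0
            assert covered == pytest.approx(
                log.dt * log.contact_steps[p_idx], rel=1e-9
            )

    def test_free_space_has_no_events(self):
        p = CAPParams.from_reduced(1.0, 10.0)
        _, log = simulate(p, None, cfg(t_total=100.0))
        assert log.t_slide == 0.0
        assert log.N == 0

    def test_initial_positions_outside_obstacles(self, triangular_07):
        p = CAPParams.from_reduced(1.0, 10.0)
        traj, _ = simulate(p, triangular_07,
                           cfg(t_total=10.0, n_particles=32, burn_in=0.0))
        f = np.stack([traj.xw[:, 0], traj.yw[:, 0]], axis=-1) @ triangular_07.box_inv.T
        f -= np.round(f)
        g = f @ triangular_07.box.T
        assert np.hypot(g[:, 0], g[:, 1]).min() >= triangular_07.R


class TestJitteredLattice:
    def test_positional_disorder_shifts_diffusivity(self):
        """Gaussian jitter of the obstacle positions (sigma = 0.05 d)
        breaks the orbital resonance with the perfect lattice: D_eff
        deviates beyond the joint standard error."""
        import warnings

        from capsim.lattice import jitter_lattice
        from capsim.observables import measure_diffusivity

        perfect = build_lattice("square", 0.7, n_cells=4)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # overlapping disks expected
            noisy = jitter_lattice(perfect, 0.05, seed=17)
        p = CAPParams.from_reduced(2.0, 100.0)
        fits = []
        for lat in (perfect, noisy):
            config = SimConfig(dt=2e-3, t_total=6000.0, n_particles=6,
                               seed=91, record_stride=500)
            traj, _ = simulate(p, lat, config)
            fits.append(measure_diffusivity(traj))
        a, b = fits
        z = abs(a.D_eff - b.D_eff) / math.hypot(a.D_se, b.D_se)
        assert z > 2.0


class TestMirrorHarness:
    def test_pathwise_mirror_equivalence(self):
        lat = build_lattice("parallelogram", 0.7, delta=0.3)
        p = CAPParams.from_reduced(1.5, 100.0, handedness=-1)
        config = SimConfig(dt=1e-3, t_total=30.0, n_particles=2, seed=3,
                           record_stride=10, burn_in=0.0)
        a, b = mirror_pair(p, lat, config)
        dev = max(np.abs(b.xu + a.xu).max(), np.abs(b.yu - a.yu).max())
        n_steps = 30_000
        assert dev < 1e-10 * n_steps

    def test_mirror_with_flow(self):
        lat = build_lattice("parallelogram", 0.7, delta=0.2)
        p = CAPParams.from_reduced(1.0, 50.0, handedness=1)
        config = SimConfig(dt=1e-3, t_total=20.0, n_particles=1, seed=9,
                           record_stride=10, burn_in=0.0)
        a, b = mirror_pair(p, lat, config, flow=FlowField(1.0, math.radians(30)))
        dev = max(np.abs(b.xu + a.xu).max(), np.abs(b.yu - a.yu).max())
        assert dev < 1e-9

    def test_abp_mirror_equivalence(self):
        # an achiral particle cannot tell a lattice from its mirror image:
        # with mirrored noise the reflected paths coincide (short horizon,
        # before roundoff is amplified by successive obstacle scatterings)
        lat = build_lattice("parallelogram", 0.7, delta=0.3)
        p = CAPParams.from_reduced(None, 10.0)
        config = SimConfig(dt=2e-3, t_total=100.0, n_particles=4, seed=4,
                           record_stride=100, burn_in=0.0)
        a, b = mirror_pair(p, lat, config)
        n_steps = int(100.0 / 2e-3)
        assert np.abs(b.xu + a.xu).max() < 1e-10 * n_steps


class TestDtConvergence:
    def test_halving_dt_preserves_free_space_diffusivity(self):
        from capsim.observables import measure_diffusivity

        p = CAPParams.from_reduced(1.0, 1.0)
        results = []
        for dt in (2e-3, 1e-3):
            config = SimConfig(dt=dt, t_total=4000.0, n_particles=16, seed=8,
                               record_stride=int(round(0.1 / dt)))
            traj, _ = simulate(p, None, config)
            results.append(measure_diffusivity(traj))
        a, b = results
        joint_se = math.hypot(a.D_se, b.D_se)
        assert abs(a.D_eff - b.D_eff) < 2 * joint_se
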