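"""MSD, diffusivity fits, Dr estimation, contact statistics, and locking
measures, validated on synthetic and closed-form oracles."""

import math

import numpy as np
import pytest

from capsim.engine import SimConfig, Trajectory, simulate
from capsim.model import CAPParams, free_space_diffusivity
from capsim.observables import (
    LockingCurve,
    MSDCurve,
    contact_statistics,
    effective_diffusivity,
    locking_plateaus,
    locking_strength,
    measure_diffusivity,
    migration_angle,
    msd,
    rotational_diffusion_estimate,
)


def make_trajectory(xu, yu, times, params=None, theta=None):
    xu = np.atleast_2d(xu)
    yu = np.atleast_2d(yu)
    if theta is None:
        theta = np.zeros_like(xu)
    if params is None:
        params = CAPParams(v0=1, omega0=1, Dr=1)
    z = np.zeros_like(xu)
    return Trajectory(
        times=times, xu=xu, yu=yu, xw=xu, yw=yu, theta=theta,
        contact=np.zeros(xu.shape, dtype=bool), dt=times[1] - times[0],
        params=params,
    )


class TestMsd:
    def test_ballistic_particle_exact(self):
        t = np.linspace(0.0, 100.0, 1001)
        traj = make_trajectory(t.copy(), np.zeros_like(t), t)
        curve = msd(traj)
        assert np.allclose(curve.values, curve.lags**2, rtol=1e-12)

    def test_closed_orbit_bounded(self):
        t = np.linspace(0.0, 200.0, 4001)
        r = 1.3
        traj = make_trajectory(r * np.cos(t), r * np.sin(t), t)
        curve = msd(traj)
        assert curve.values.max() <= (2 * r) ** 2 + 1e-9

    def test_excessive_lags_rejected(self):
        t = np.linspace(0.0, 10.0, 101)
        traj = make_trajectory(t.copy(), t.copy(), t)
        with pytest.raises(ValueError, match="t_total/2"):
            msd(traj, lag_grid=np.array([8.0]))

    def test_free_space_long_time_slope_is_diffusive(self):
        # high-persistence circle swimmer: MSD ~ t at t >> tau_p
        p = CAPParams.from_reduced(1.0, 100.0)
        cfg = SimConfig(dt=2e-3, t_total=2e4, n_particles=8, seed=31,
                        record_stride=500)
        traj, _ = simulate(p, None, cfg)
        curve = msd(traj)
        mask = curve.lags >= curve.lags[-1] / 10.0
        slope = np.polyfit(np.log(curve.lags[mask]),
                           np.log(curve.values[mask]), 1)[0]
        assert 0.9 <= slope <= 1.1


class TestEffectiveDiffusivity:
    def test_recovers_brownian_oracle(self, rng):
        # independent oracle: a plain Gaussian random walk of known D
        D_true = 0.35
        n_p, n, dt_s = 64, 2000, 0.5
        steps = rng.normal(0.0, math.sqrt(2 * D_true * dt_s), (2, n_p, n))
        xu = np.concatenate(
            [np.zeros((n_p, 1)), np.cumsum(steps[0], axis=1)], axis=1
        )
        yu = np.concatenate(
            [np.zeros((n_p, 1)), np.cumsum(steps[1], axis=1)], axis=1
        )
        t = np.arange(n + 1) * dt_s
        params = CAPParams(v0=1, omega0=0, Dr=0.5)  # D_free = 1
        traj = make_trajectory(xu, yu, t, params=params)
        res = effective_diffusivity(msd(traj), params)
        assert res.D_eff == pytest.approx(D_true, abs=3 * res.D_se)
        # unbiased at this replication level: bias below one s.e.
        assert abs(res.D_eff - D_true) < max(res.D_se, 0.05 * D_true)

    def test_free_space_cap_matches_closed_form(self):
        p = CAPParams.from_reduced(1.0, 100.0)
        cfg = SimConfig(dt=2e-3, t_total=2e4, n_particles=16, seed=13,
                        record_stride=500)
        traj, _ = simulate(p, None, cfg)
        res = measure_diffusivity(traj)
        assert res.D_eff == pytest.approx(res.D_free, abs=3 * res.D_se)
        assert res.D_free == free_space_diffusivity(p)

    def test_window_shorter_than_decade_rejected(self):
        t = np.linspace(0.0, 100.0, 1001)
        traj = make_trajectory(t.copy(), t.copy(), t)
        with pytest.raises(ValueError, match="decade"):
            effective_diffusivity(msd(traj), traj.params,
                                  fit_window=(20.0, 50.0))

    def test_psi_sign_classifies(self):
        # synthetic diffusive path slower than free space: Psi < 0
        t = np.linspace(0, 1000.0, 2001)
        xu = np.sqrt(4 * 0.01 * t)  # MSD = 4*0.01*t exactly along x
        params = CAPParams(v0=1, omega0=1, Dr=1)  # D_free = 0.25
        traj = make_trajectory(xu, np.zeros_like(t), t, params=params)
        res = effective_diffusivity(msd(traj), params)
        assert res.Psi < 0


class TestRotationalDiffusion:
    def test_zero_noise_gives_zero(self):
        t = np.linspace(0, 100, 2001)
        theta = 6.3 * t  # pure drift
        Dr, _ = rotational_diffusion_estimate(theta, t, omega0=6.3)
        assert Dr == pytest.approx(0.0, abs=1e-15)

    def test_recovery_of_measured_seed_parameters(self, rng):
        # seed-2 values omega0 = 6.3 /s, Dr = 2.7 /s
        omega0, Dr_true = 6.3, 2.7
        n_p, n, dt_s = 24, 20000, 5e-3
        inc = omega0 * dt_s + rng.normal(
            0.0, math.sqrt(2 * Dr_true * dt_s), (n_p, n)
        )
        theta = np.concatenate(
            [np.zeros((n_p, 1)), np.cumsum(inc, axis=1)], axis=1
        )
        t = np.arange(n + 1) * dt_s
        est, se = rotational_diffusion_estimate(theta, t, omega0=omega0)
        assert est == pytest.approx(Dr_true, abs=3 * se)
        # estimator must not need omega0 if it can fit the drift itself
        est2, se2 = rotational_diffusion_estimate(theta, t)
        assert est2 == pytest.approx(Dr_true, abs=3 * se2)

    def test_invariant_to_drift_when_subtracted(self, rng):
        n, dt_s = 5000, 1e-2
        noise = np.cumsum(rng.normal(0, math.sqrt(2 * 0.8 * dt_s), n))
        theta0 = np.concatenate([[0.0], noise])
        t = np.arange(n + 1) * dt_s
        a, _ = rotational_diffusion_estimate(theta0, t, omega0=0.0)
        b, _ = rotational_diffusion_estimate(theta0 + 12.0 * t, t, omega0=12.0)
        assert a == pytest.approx(b, rel=1e-9)


class TestContactStatistics:
    def test_free_space_zeroes(self):
        p = CAPParams.from_reduced(1.0, 10.0)
        cfg = SimConfig(dt=1e-3, t_total=50.0, n_particles=2, seed=2,
                        record_stride=50)
        _, log = simulate(p, None, cfg)
        st = contact_statistics(log)
        assert st["mu"] == 0.0
        assert st["N"] == 0

    def test_smaller_orbit_shortens_sliding_intervals(self, square_07):
        # larger omega0 (smaller r_bar) crosses the surface normal sooner,
        # so individual sliding intervals are shorter
        means = {}
        for r_bar in (0.5, 2.0):
            p = CAPParams.from_reduced(r_bar, 100.0)
            cfg = SimConfig(dt=2e-3, t_total=2000.0, n_particles=4, seed=6,
                            record_stride=100)
            _, log = simulate(p, square_07, cfg)
            lengths = np.concatenate(
                [iv[:, 1] - iv[:, 0] for iv in log.intervals]
            )
            means[r_bar] = lengths.mean()
        assert means[0.5] < means[2.0]


class TestMigrationAngle:
    def test_pure_drift_gives_flow_angle(self):
        p = CAPParams(v0=1, omega0=0, Dr=0)
        from capsim.model import FlowField

        cfg = SimConfig(dt=1e-3, t_total=50.0, n_particles=2, seed=1,
                        record_stride=100, burn_in=0.0)
        psi = math.radians(30.0)
        traj, _ = simulate(
            p, None, cfg, flow=FlowField(v_g=10.0, psi=psi),
            init=np.array([[0, 0, psi], [0, 0, psi]]),
        )
        alpha, _ = migration_angle(traj)
        assert alpha == pytest.approx(psi, abs=1e-9)

    def test_zero_velocity_flagged(self):
        t = np.linspace(0, 100, 1001)
        traj = make_trajectory(np.zeros_like(t), np.zeros_like(t), t)
        with pytest.raises(ValueError, match="undefined|~0"):
            migration_angle(traj)


class TestAlphaEquivariance:
    def test_square_lattice_quarter_turn(self, square_07):
        # the square lattice maps onto itself under a 90-degree rotation,
        # so rotating the drive by 90 degrees rotates the migration angle
        from capsim.model import FlowField

        p = CAPParams.from_reduced(1.0, 10.0)
        alphas = {}
        for psi_deg in (30.0, 120.0):
            cfg = SimConfig(dt=2e-3, t_total=1500.0, n_particles=6, seed=55,
                            record_stride=100)
            traj, _ = simulate(p, square_07, cfg,
                               flow=FlowField(1.0, math.radians(psi_deg)))
            alphas[psi_deg], se = migration_angle(traj)
        diff = math.degrees(alphas[120.0] - alphas[30.0])
        assert diff == pytest.approx(90.0, abs=3.0)


class TestLockingStrength:
    def test_perfect_following_gives_zero(self):
        psi = np.radians(np.arange(0.0, 91.0))
        curve = LockingCurve(psi=psi, alpha=psi.copy())
        assert locking_strength(curve) == 0.0

    def test_constant_45deg_closed_form(self):
        # integral of (pi/4 - psi)^2 over [0, pi/2] = pi^3/96
        psi = np.radians(np.linspace(0.0, 90.0, 901))
        curve = LockingCurve(psi=psi, alpha=np.full_like(psi, math.pi / 4))
        assert locking_strength(curve) == pytest.approx(
            math.pi**3 / 96, rel=1e-5
        )

    def test_orientation_reversal_invariance(self):
        psi = np.radians(np.arange(0.0, 91.0, 3.0))
        alpha = np.radians(45.0) * np.ones_like(psi)
        fwd = locking_strength(LockingCurve(psi=psi, alpha=alpha))
        rev = locking_strength(LockingCurve(psi=psi[::-1], alpha=alpha[::-1]))
        assert fwd == pytest.approx(rev)

    def test_unsorted_grid_rejected(self):
        psi = np.array([0.0, 0.5, 0.3, 1.0])
        with pytest.raises(ValueError, match="sorted"):
            locking_strength(LockingCurve(psi=psi, alpha=psi.copy()))


class TestLockingPlateaus:
    def test_perfect_following_has_no_plateau(self):
        psi = np.radians(np.arange(0.0, 91.0))
        curve = LockingCurve(psi=psi, alpha=psi.copy())
        assert locking_plateaus(curve, tol_deg=0.5) == []

    def test_single_step_curve(self):
        psi_deg = np.arange(0.0, 91.0)
        alpha_deg = np.where(psi_deg < 45, 20.0, 70.0)
        curve = LockingCurve(psi=np.radians(psi_deg),
                             alpha=np.radians(alpha_deg))
        plats = locking_plateaus(curve)
        assert len(plats) == 2
        widest = plats[0]
        assert widest["width"] == pytest.approx(45.0)
        assert widest["alpha"] == pytest.approx(70.0)

    def test_widest_wins_with_tilt_tiebreak(self):
        psi_deg = np.arange(0.0, 21.0)
        alpha_deg = np.concatenate([np.full(10, 5.0), np.full(11, 18.0)])
        curve = LockingCurve(psi=np.radians(psi_deg),
                             alpha=np.radians(alpha_deg))
        plats = locking_plateaus(curve)
        assert plats[0]["alpha"] == pytest.approx(18.0)
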