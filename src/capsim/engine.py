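"""Stochastic time integration with hard-wall contact handling.

Euler--Maruyama integration of the overdamped equations of motion

    dr/dt     = v0 p_hat + v_g e_hat + F_wall
    dtheta/dt = omega0 + sqrt(2 Dr) xi(t)

where the wall force cancels the component of the total velocity that
would drive the particle into an obstacle, and nothing else: orientation
dynamics are unaffected by contacts and there is no translational noise.
The heavy per-step work lives in :mod:`capsim._kernels`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .lattice import ObstacleLattice
from .model import CAPParams, FlowField

__all__ = [
    "SimConfig",
    "Trajectory",
    "EventLog",
    "wall_projected_velocity",
    "simulate",
    "mirror_pair",
]

_EMPTY = np.empty(0)


@dataclass(frozen=True)
class SimConfig:
    """Run controls for :func:`simulate`.

    ``burn_in`` (time units) is discarded before statistics; ``None``
    selects ``min(10 * max(tau_p, tau_omega), 0.1 * t_total)``, enough to
    forget the initial placement without eating into the sampled window.
    ``record_stride`` is the number of integration steps between stored
    samples.  ``interval_cap`` bounds the per-particle contact-interval
    list (counts and sliding times stay exact beyond it).
    """

    dt: float
    t_total: float
    n_particles: int
    seed: int
    record_stride: int = 100
    burn_in: float | None = None
    max_sweeps: int = 10
    interval_cap: int = 200_000
    wall_rule: str = "inward"

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.t_total <= 0:
            raise ValueError("dt and t_total must be positive")
        if self.n_particles < 1:
            raise ValueError("n_particles must be >= 1")
        if self.record_stride < 1:
            raise ValueError("record_stride must be >= 1")
        if self.wall_rule not in ("inward", "both"):
            raise ValueError("wall_rule must be 'inward' or 'both'")

    def resolve_burn_in(self, params: CAPParams) -> float:
        if self.burn_in is not None:
            return self.burn_in
        scales = [t for t in (params.tau_p, params.tau_omega) if math.isfinite(t)]
        if not scales:
            return 0.0
        return min(10.0 * max(scales), 0.1 * self.t_total)


@dataclass
class Trajectory:
    """Recorded ensemble of trajectories.

    Arrays are shaped ``(n_particles, n_samples)``; ``times`` is shared.
    ``xu, yu`` are unwrapped coordinates (true accumulated displacement),
    ``xw, yw`` the wrapped in-box positions, ``theta`` the unwrapped
    orientation, and ``contact`` a per-sample in-contact flag.
    """

    times: np.ndarray
    xu: np.ndarray
    yu: np.ndarray
    xw: np.ndarray
    yw: np.ndarray
    theta: np.ndarray
    contact: np.ndarray
    dt: float
    params: CAPParams
    flow: FlowField | None = None

    @property
    def n_particles(self) -> int:
        return self.xu.shape[0]

    @property
    def t_total(self) -> float:
        return float(self.times[-1])

    def to_dataframe(self):
        import pandas as pd

        frames = []
        for p in range(self.n_particles):
            frames.append(
                pd.DataFrame(
                    {
                        "particle": p,
                        "t": self.times,
                        "x_unwrapped": self.xu[p],
                        "y_unwrapped": self.yu[p],
                        "theta": self.theta[p],
                        "in_contact": self.contact[p],
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


@dataclass
class EventLog:
    """Contact bookkeeping accumulated during a run.

    ``t_slide`` is the cumulative in-contact time, ``t_hop`` its
    complement (``t_slide + t_hop == n_particles * t_total`` exactly, both
    being dt times integer step counts), and ``N`` the total number of
    tangential-velocity sign reversals during contact.  ``intervals`` holds
    per-particle ``(t_start, t_end, obstacle_id)`` triples.
    """

    contact_steps: np.ndarray  # (n_particles,) int
    reversals: np.ndarray      # (n_particles,) int
    intervals: list            # per particle: ndarray (k, 3)
    dt: float
    n_steps: int
    truncated: bool = False

    @property
    def n_particles(self) -> int:
        return len(self.contact_steps)

    @property
    def t_total(self) -> float:
        return self.dt * self.n_steps * self.n_particles

    @property
    def t_slide(self) -> float:
        return self.dt * int(self.contact_steps.sum())

    @property
    def t_hop(self) -> float:
        return self.t_total - self.t_slide

    @property
    def N(self) -> int:
        return int(self.reversals.sum())

    def summary(self) -> dict:
        return {
            "t_slide": self.t_slide,
            "t_hop": self.t_hop,
            "N": self.N,
            "t_total": self.t_total,
        }


def wall_projected_velocity(
    p_hat: np.ndarray,
    contact_normals: np.ndarray,
    v_drift: np.ndarray | None = None,
    v0: float = 1.0,
    max_sweeps: int = 10,
) -> np.ndarray:
    """Remove inward normal components of the total velocity at hard walls.

    ``contact_normals`` is an ``(k, 2)`` array of outward unit normals.
    Components of ``v = v0 p_hat + v_drift`` directed into a wall
    (``v . N < 0``) are cancelled; outward motion is untouched, so a
    particle whose orientation has rotated past the tangent leaves the
    surface.  With several simultaneous contacts the projection is
    iterated until no inward component remains.
    """
    normals = np.atleast_2d(np.asarray(contact_normals, dtype=float))
    if normals.size:
        norms = np.linalg.norm(normals, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("contact normals must be unit vectors")
    v = v0 * np.asarray(p_hat, dtype=float)
    if v_drift is not None:
        v = v + np.asarray(v_drift, dtype=float)
    for _ in range(max_sweeps):
        changed = False
        for n in normals:
            vn = float(v @ n)
            if vn < 0.0:
                v = v - vn * n
                changed = True
        if not changed:
            break
    return v


def _lattice_arrays(lattice: ObstacleLattice | None):
    if lattice is None or lattice.n_obstacles == 0:
        eye = np.eye(2)
        return _EMPTY, _EMPTY, eye, eye, 0.0
    box = lattice.box
    return (
        np.ascontiguousarray(lattice.centers[:, 0]),
        np.ascontiguousarray(lattice.centers[:, 1]),
        box,
        lattice.box_inv,
        float(lattice.R),
    )


def sample_initial_conditions(
    lattice: ObstacleLattice | None,
    n_particles: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Positions uniform over the obstacle-free area, headings uniform.

    Returns an ``(n, 3)`` array of ``(x, y, theta)``.
    """
    out = np.empty((n_particles, 3))
    out[:, 2] = rng.uniform(0.0, 2.0 * math.pi, n_particles)
    if lattice is None or lattice.n_obstacles == 0:
        out[:, :2] = 0.0
        return out
    box, box_inv = lattice.box, lattice.box_inv
    R2 = lattice.R**2
    c = lattice.centers
    filled = 0
    while filled < n_particles:
        f = rng.random((4 * n_particles, 2))
        pts = f @ box.T
        free = np.ones(len(pts), dtype=bool)
        for cc in c:
            dvec = pts - cc
            ff = dvec @ box_inv.T
            ff -= np.round(ff)
            for ix in (-1, 0, 1):
                for iy in (-1, 0, 1):
                    g = (ff + np.array([ix, iy])) @ box.T
                    free &= (g[:, 0] ** 2 + g[:, 1] ** 2) > R2
        good = pts[free]
        take = min(len(good), n_particles - filled)
        out[filled : filled + take, :2] = good[:take]
        filled += take
    return out


def simulate(
    params: CAPParams,
    lattice: ObstacleLattice | None,
    config: SimConfig,
    flow: FlowField | None = None,
    init: np.ndarray | None = None,
    noise_sign: float = 1.0,
    collect_intervals: bool = True,
) -> tuple[Trajectory, EventLog]:
    """Integrate ``n_particles`` independent trajectories.

    Deterministic given ``config.seed``: per-particle noise streams are
    derived from a single :class:`numpy.random.SeedSequence` root, and the
    initial conditions (uniform over the free area and over orientation,
    unless ``init`` provides explicit ``(x, y, theta)`` rows) come from a
    separate child stream.  ``lattice=None`` simulates free space.
    """
    vg = flow.v_g if flow is not None else 0.0
    psi = flow.psi if flow is not None else 0.0
    R = lattice.R if lattice is not None else 1.0
    step = (params.v0 + vg) * config.dt
    if params.v0 * config.dt > 0.01 * R or step > 0.02 * R:
        raise ValueError(
            f"dt={config.dt} too large: v0*dt must not exceed 0.01*R "
            f"(and (v0+v_g)*dt must stay below 0.02*R)"
        )
    n_steps = int(round(config.t_total / config.dt))
    # keep a whole number of recording intervals
    n_steps -= n_steps % config.record_stride
    if n_steps == 0:
        raise ValueError("t_total shorter than one recording interval")
    burn = config.resolve_burn_in(params)
    n_burn = int(round(burn / config.dt))
    n_rec = n_steps // config.record_stride + 1

    ss = np.random.SeedSequence(config.seed)
    ss_init, ss_noise = ss.spawn(2)
    seeds = ss_noise.generate_state(config.n_particles)
    if init is None:
        init = sample_initial_conditions(
            lattice, config.n_particles, np.random.default_rng(ss_init)
        )
    init = np.asarray(init, dtype=float)
    if init.shape != (config.n_particles, 3):
        raise ValueError("init must have shape (n_particles, 3)")

    cx, cy, box, box_inv, Rk = _lattice_arrays(lattice)
    np_ = config.n_particles
    xu = np.empty((np_, n_rec))
    yu = np.empty((np_, n_rec))
    xw = np.empty((np_, n_rec))
    yw = np.empty((np_, n_rec))
    th = np.empty((np_, n_rec))
    ct = np.empty((np_, n_rec), dtype=bool)
    contact_steps = np.zeros(np_, dtype=np.int64)
    reversals = np.zeros(np_, dtype=np.int64)
    intervals: list = []
    cap = config.interval_cap if collect_intervals else 0
    truncated = False

    for p in range(np_):
        iv_s = np.empty(cap, dtype=np.int64)
        iv_e = np.empty(cap, dtype=np.int64)
        iv_o = np.empty(cap, dtype=np.int64)
        out = _kernels.run_particle(
            np.int64(seeds[p]),
            float(noise_sign),
            n_burn,
            n_steps,
            config.dt,
            params.v0,
            params.omega0,
            params.Dr,
            vg,
            psi,
            cx,
            cy,
            box[0, 0],
            box[0, 1],
            box[1, 0],
            box[1, 1],
            box_inv[0, 0],
            box_inv[0, 1],
            box_inv[1, 0],
            box_inv[1, 1],
            Rk,
            config.max_sweeps,
            config.wall_rule == "both",
            init[p, 0],
            init[p, 1],
            init[p, 2],
            config.record_stride,
            xu[p],
            yu[p],
            xw[p],
            yw[p],
            th[p],
            ct[p],
            iv_s,
            iv_e,
            iv_o,
        )
        status, ncs, nrev, niv, trunc = out[0], out[1], out[2], out[3], out[4]
        if status == _kernels.STATUS_PENETRATION:
            raise RuntimeError(
                f"particle {p}: unresolved obstacle penetration after "
                f"{config.max_sweeps} sweeps; dt={config.dt} is too large "
                f"for this lattice density"
            )
        contact_steps[p] = ncs
        reversals[p] = nrev
        truncated = truncated or trunc
        iv = np.column_stack(
            [iv_s[:niv] * config.dt, iv_e[:niv] * config.dt, iv_o[:niv]]
        )
        intervals.append(iv)

    times = np.arange(n_rec) * (config.dt * config.record_stride)
    traj = Trajectory(
        times=times, xu=xu, yu=yu, xw=xw, yw=yw, theta=th, contact=ct,
        dt=config.dt, params=params, flow=flow,
    )
    log = EventLog(
        contact_steps=contact_steps,
        reversals=reversals,
        intervals=intervals,
        dt=config.dt,
        n_steps=n_steps,
        truncated=truncated,
    )
    return traj, log


def mirror_pair(
    params: CAPParams,
    lattice: ObstacleLattice,
    config: SimConfig,
    flow: FlowField | None = None,
) -> tuple[Trajectory, Trajectory]:
    """Run a trajectory and its exact mirror image.

    Run A uses ``(omega0, delta, xi)``; run B uses ``(-omega0, 1 - delta,
    -xi)`` with mirrored initial conditions ``(x, y, theta) -> (-x, y,
    pi - theta)`` and the same seed, so every Gaussian increment of B is
    the negation of A's.  Reflecting B about the vertical axis through the
    origin then reproduces A step by step, up to floating-point roundoff.
    """
    from .lattice import build_lattice

    if lattice.kind not in ("parallelogram", "square"):
        raise ValueError("mirror_pair requires a square/parallelogram lattice")
    mirror_delta = (1.0 - lattice.delta) % 1.0
    lattice_b = build_lattice(
        "parallelogram" if lattice.kind == "parallelogram" else "square",
        phi=lattice.phi,
        R=lattice.R,
        delta=mirror_delta if lattice.kind == "parallelogram" else 0.0,
        n_cells=lattice.n_cells,
    )
    params_b = CAPParams(v0=params.v0, omega0=-params.omega0, Dr=params.Dr)
    flow_b = None
    if flow is not None:
        flow_b = FlowField(v_g=flow.v_g, psi=math.pi - flow.psi)

    ss = np.random.SeedSequence(config.seed)
    ss_init, _ = ss.spawn(2)
    init_a = sample_initial_conditions(
        lattice, config.n_particles, np.random.default_rng(ss_init)
    )
    init_b = init_a.copy()
    init_b[:, 0] = -init_b[:, 0]
    init_b[:, 2] = math.pi - init_b[:, 2]

    traj_a, _ = simulate(params, lattice, config, flow=flow, init=init_a)
    traj_b, _ = simulate(
        params_b, lattice_b, config, flow=flow_b, init=init_b, noise_sign=-1.0
    )
    return traj_a, traj_b
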