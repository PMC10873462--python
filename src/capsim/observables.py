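"""Trajectory statistics: MSD, effective diffusivity, rotational-diffusion
estimation, contact statistics, migration angles, and directional-locking
measures.

The central quantity is the long-time effective diffusivity
``D_eff = <|dr|^2> / (4 t)`` and its logarithmic ratio to the free-space
closed form, ``Psi = ln(D_eff / D)``: ``Psi > 0`` flags lattice-enhanced
diffusion, ``Psi < 0`` suppression.  Directional locking under a drift
field is quantified by the mean migration angle
``alpha = atan2(<v_y>, <v_x>)`` as a function of the drive angle ``psi``
and by the locking strength ``epsilon = int_0^{pi/2} (alpha - psi)^2 dpsi``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .engine import EventLog, Trajectory
from .model import CAPParams, free_space_diffusivity

__all__ = [
    "MSDCurve",
    "DiffusivityResult",
    "LockingCurve",
    "msd",
    "effective_diffusivity",
    "measure_diffusivity",
    "rotational_diffusion_estimate",
    "contact_statistics",
    "migration_angle",
    "locking_strength",
    "locking_plateaus",
]


@dataclass
class MSDCurve:
    """Multi-origin mean squared displacement.

    ``per_particle`` keeps the per-walker curves (n_particles, n_lags) so
    downstream estimates can quote between-particle standard errors.
    """

    lags: np.ndarray
    values: np.ndarray
    counts: np.ndarray
    per_particle: np.ndarray


@dataclass
class DiffusivityResult:
    D_eff: float
    D_se: float
    D_free: float
    Psi: float
    Psi_se: float
    fit_window: tuple[float, float]
    n_particles: int


@dataclass
class LockingCurve:
    """Migration direction alpha sampled over a grid of drive angles psi."""

    psi: np.ndarray    # rad
    alpha: np.ndarray  # rad
    alpha_se: np.ndarray | None = None

    @property
    def epsilon(self) -> float:
        return locking_strength(self)


def _lag_indices(times: np.ndarray, lag_grid: np.ndarray) -> np.ndarray:
    dt_s = times[1] - times[0]
    idx = np.unique(np.round(np.asarray(lag_grid) / dt_s).astype(int))
    return idx[(idx >= 1) & (idx < len(times))]


def msd(
    traj: Trajectory,
    lag_grid: np.ndarray | None = None,
    n_lags: int = 40,
) -> MSDCurve:
    """Multi-origin, multi-particle mean squared displacement.

    ``lag_grid`` defaults to log-spaced lags from the sampling interval up
    to half the run length; requested lags beyond ``t_total/2`` are
    rejected.
    """
    times = traj.times
    t_max = times[-1]
    if lag_grid is None:
        dt_s = times[1] - times[0]
        lag_grid = np.geomspace(dt_s, t_max / 2.0, n_lags)
    else:
        lag_grid = np.asarray(lag_grid, dtype=float)
        if np.any(lag_grid > t_max / 2.0 + 1e-12):
            raise ValueError("lags exceeding t_total/2 are rejected")
    idx = _lag_indices(times, lag_grid)
    xu, yu = traj.xu, traj.yu
    n_p = xu.shape[0]
    per = np.empty((n_p, len(idx)))
    counts = np.empty(len(idx), dtype=int)
    for k, ell in enumerate(idx):
        dx = xu[:, ell:] - xu[:, :-ell]
        dy = yu[:, ell:] - yu[:, :-ell]
        per[:, k] = np.mean(dx * dx + dy * dy, axis=1)
        counts[k] = dx.shape[1]
    lags = times[idx]
    return MSDCurve(lags=lags, values=per.mean(axis=0), counts=counts,
                    per_particle=per)


def default_fit_window(params: CAPParams, max_lag: float) -> tuple[float, float]:
    """Long-time fit window for the diffusive MSD slope.

    Starts at ``50 * max(tau_p, tau_omega)``, capped at ``max_lag / 10``
    so the window always spans at least a decade; ends at the largest lag.
    """
    scales = [t for t in (params.tau_p, params.tau_omega) if math.isfinite(t)]
    t_lo = min(50.0 * max(scales), max_lag / 10.0) if scales else max_lag / 10.0
    return (t_lo, max_lag)


def effective_diffusivity(
    curve: MSDCurve,
    params: CAPParams,
    fit_window: tuple[float, float] | None = None,
) -> DiffusivityResult:
    """Long-time diffusivity from the MSD: least-squares slope of MSD
    against 4t through the origin on the fit window.

    The standard error comes from between-particle variability of the
    per-walker slopes.  ``Psi = ln(D_eff / D)`` compares against the
    free-space closed form.
    """
    max_lag = float(curve.lags[-1])
    if fit_window is None:
        fit_window = default_fit_window(params, max_lag)
    t_lo, t_hi = fit_window
    if t_hi / t_lo < 10.0 - 1e-9:
        raise ValueError(
            f"fit window [{t_lo:g}, {t_hi:g}] spans less than one decade; "
            "increase t_total"
        )
    mask = (curve.lags >= t_lo) & (curve.lags <= t_hi)
    if mask.sum() < 2:
        raise ValueError("fewer than 2 MSD lags in the fit window")
    t = curve.lags[mask]
    denom = 4.0 * float(t @ t)
    D_p = (curve.per_particle[:, mask] @ t) / denom
    n_p = len(D_p)
    D = float(D_p.mean())
    D_se = float(D_p.std(ddof=1) / math.sqrt(n_p)) if n_p > 1 else math.nan
    D_free = free_space_diffusivity(params)
    if D > 0 and D_free > 0:
        Psi = math.log(D / D_free)
        Psi_se = D_se / D if D > 0 else math.nan
    else:
        Psi = math.nan
        Psi_se = math.nan
    return DiffusivityResult(
        D_eff=D, D_se=D_se, D_free=D_free, Psi=Psi, Psi_se=Psi_se,
        fit_window=(t_lo, t_hi), n_particles=n_p,
    )


def measure_diffusivity(
    traj: Trajectory,
    fit_window: tuple[float, float] | None = None,
    n_lags: int = 40,
) -> DiffusivityResult:
    """Convenience wrapper: MSD then long-time diffusivity fit."""
    return effective_diffusivity(msd(traj, n_lags=n_lags), traj.params,
                                 fit_window=fit_window)


def rotational_diffusion_estimate(
    theta: np.ndarray,
    times: np.ndarray,
    omega0: float | None = None,
    n_lags: int = 30,
) -> tuple[float, float]:
    """Estimate Dr from the drift-subtracted angular MSD.

    ``theta`` is ``(n_particles, n_samples)`` of unwrapped orientations.
    The deterministic rotation is removed, ``theta_tilde = theta -
    omega0 t`` (``omega0`` least-squares fitted per particle when not
    given), and Dr is the through-origin slope of the multi-origin angular
    MSD against ``2 t`` over the upper half of the lag range.  Returns
    ``(Dr_hat, se)`` with the s.e. from between-particle spread.
    """
    theta = np.atleast_2d(np.asarray(theta, dtype=float))
    times = np.asarray(times, dtype=float)
    n_p, n = theta.shape
    T = times[-1] - times[0]
    self_fitted = omega0 is None
    if self_fitted:
        # per-particle endpoint slope: the max-likelihood drift of a
        # Brownian path, whose leakage into the MSD is corrected below
        om = (theta[:, -1] - theta[:, 0]) / T
    else:
        om = np.full(n_p, float(omega0))
    tilde = theta - om[:, None] * times[None, :]
    dt_s = times[1] - times[0]
    max_ell = n // 2
    idx = np.unique(np.geomspace(1, max_ell, n_lags).astype(int))
    # long-lag window: upper half of the available lags (log scale)
    idx = idx[idx >= max(1, int(math.sqrt(max_ell)))]
    lags = idx * dt_s
    per = np.empty((n_p, len(idx)))
    for k, ell in enumerate(idx):
        d = tilde[:, ell:] - tilde[:, :-ell]
        per[:, k] = np.mean(d * d, axis=1)
    if self_fitted:
        # endpoint-drift subtraction turns the path into a bridge:
        # E[MSD(l)] = 2 Dr l (1 - l/T); undo the deflation exactly
        per = per / (1.0 - lags / T)[None, :]
    denom = 2.0 * float(lags @ lags)
    Dr_p = (per @ lags) / denom
    Dr_hat = float(Dr_p.mean())
    se = float(Dr_p.std(ddof=1) / math.sqrt(n_p)) if n_p > 1 else math.nan
    if Dr_hat > 0 and times[-1] < 10.0 / Dr_hat:
        import warnings

        warnings.warn(
            "series shorter than 10/Dr_hat; confidence interval is wide",
            stacklevel=2,
        )
    return Dr_hat, se


def contact_statistics(log: EventLog) -> dict:
    """Sliding/hopping decomposition: mu = t_slide/t_hop and reversal count.

    Also reports both per unit total simulated time.  ``t_hop = 0`` maps
    to an infinite mu sentinel.
    """
    t_slide = log.t_slide
    t_hop = log.t_hop
    mu = t_slide / t_hop if t_hop > 0 else math.inf
    return {
        "mu": mu,
        "N": log.N,
        "t_slide": t_slide,
        "t_hop": t_hop,
        "N_rate": log.N / log.t_total,
        "slide_fraction": t_slide / log.t_total,
    }


def migration_angle(
    traj: Trajectory,
    delta_t: float | None = None,
    n_boot: int = 200,
    boot_seed: int = 0,
) -> tuple[float, float]:
    """Mean migration direction alpha = atan2(<v_y>, <v_x>) under drift.

    Velocities are finite differences over windows ``delta_t`` (default
    ``10 tau_omega``, clipped to the recorded range), averaged over all
    windows and particles; the s.e. comes from a bootstrap over particles.
    Raises if the mean speed is indistinguishable from zero.
    """
    times = traj.times
    t_max = times[-1]
    if delta_t is None:
        tw = traj.params.tau_omega
        delta_t = 10.0 * tw if math.isfinite(tw) else t_max / 10.0
    delta_t = min(max(delta_t, times[1] - times[0]), t_max / 2.0)
    dt_s = times[1] - times[0]
    ell = max(1, int(round(delta_t / dt_s)))
    # non-overlapping windows
    n = traj.xu.shape[1]
    stops = np.arange(0, n, ell)
    vx = np.diff(traj.xu[:, stops], axis=1) / (ell * dt_s)
    vy = np.diff(traj.yu[:, stops], axis=1) / (ell * dt_s)
    mvx = vx.mean(axis=1)
    mvy = vy.mean(axis=1)
    Vx, Vy = float(mvx.mean()), float(mvy.mean())
    speed = math.hypot(Vx, Vy)
    if speed < 1e-12 * traj.params.v0:
        raise ValueError("mean migration speed is ~0; angle undefined")
    alpha = math.atan2(Vy, Vx)
    n_p = len(mvx)
    if n_p > 1 and n_boot > 0:
        rng = np.random.default_rng(boot_seed)
        samples = np.empty(n_boot)
        for b in range(n_boot):
            pick = rng.integers(0, n_p, n_p)
            a = math.atan2(mvy[pick].mean(), mvx[pick].mean())
            # keep bootstrap replicas on alpha's branch
            samples[b] = a - 2 * math.pi * round((a - alpha) / (2 * math.pi))
        se = float(samples.std(ddof=1))
    else:
        se = math.nan
    return alpha, se


def locking_strength(curve: LockingCurve) -> float:
    """epsilon = integral over [0, pi/2] of (alpha - psi)^2 dpsi (rad^3)."""
    psi = np.asarray(curve.psi, dtype=float)
    alpha = np.asarray(curve.alpha, dtype=float)
    if psi[0] > psi[-1]:  # orientation-reversed grid
        psi, alpha = psi[::-1], alpha[::-1]
    if np.any(np.diff(psi) <= 0):
        raise ValueError("psi grid must be sorted")
    return float(np.trapezoid((alpha - psi) ** 2, psi))


def locking_plateaus(
    curve: LockingCurve,
    tol_deg: float = 2.0,
) -> list[dict]:
    """Maximal runs of psi over which alpha varies by less than tol.

    Each plateau is reported with its psi interval, width, and mean alpha;
    the list is sorted widest-first with ties broken by smaller
    ``|alpha - psi_center|``.  Runs no wider than a single grid step are
    dropped.
    """
    psi = np.degrees(np.asarray(curve.psi, dtype=float))
    alpha = np.degrees(np.asarray(curve.alpha, dtype=float))
    n = len(psi)
    step = np.min(np.diff(psi)) if n > 1 else 0.0
    # greedy right-extension from every start; j(i) is nondecreasing, so a
    # run is maximal iff its end advances past the previous start's end
    plateaus = []
    prev_j = -1
    for i in range(n):
        lo = hi = alpha[i]
        j = i
        while j + 1 < n:
            lo2 = min(lo, alpha[j + 1])
            hi2 = max(hi, alpha[j + 1])
            if hi2 - lo2 < tol_deg:
                lo, hi = lo2, hi2
                j += 1
            else:
                break
        if j <= prev_j:
            continue
        prev_j = j
        width = psi[j] - psi[i]
        if j > i and width > step + 1e-9:
            center = 0.5 * (psi[i] + psi[j])
            mean_alpha = float(alpha[i : j + 1].mean())
            plateaus.append(
                {
                    "psi_start": float(psi[i]),
                    "psi_end": float(psi[j]),
                    "width": float(width),
                    "alpha": mean_alpha,
                    "tilt": abs(mean_alpha - center),
                }
            )
    plateaus.sort(key=lambda p: (-p["width"], p["tilt"]))
    return plateaus
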