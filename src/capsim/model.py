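"""Particle parameter types, unit conventions, and free-space analytics.

A chiral active particle (CAP) self-propels at speed ``v0`` along an
orientation that rotates deterministically at angular velocity ``omega0``
(counter-clockwise positive) and diffuses rotationally with coefficient
``Dr``.  In free space the particle traces noisy circles of orbital radius
``r = v0/|omega0|`` and decorrelates over the persistence length
``l_p = v0/Dr``.  The achiral active Brownian particle (ABP) is the
``omega0 = 0`` limit of the same model.

Simulations work in reduced units ``v0 = R = 1`` where ``R`` is the
effective contact radius of an obstacle; the model is then fully specified
by the two dimensionless numbers ``r_bar = r/R`` and ``l_p_bar = l_p/R``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

__all__ = [
    "CAPParams",
    "ReducedParams",
    "FlowField",
    "reduce_parameters",
    "free_space_diffusivity",
    "free_space_argmax_Omega",
]


@dataclass(frozen=True)
class CAPParams:
    """Kinetic parameters of a single chiral active particle.

    Parameters
    ----------
    v0 : float
        Self-propulsion speed (length/time), strictly positive.
    omega0 : float
        Signed intrinsic angular velocity (rad/time).  Positive is
        counter-clockwise (CCW), negative clockwise (CW), zero is the
        achiral ABP limit.
    Dr : float
        Rotational diffusion coefficient (rad^2/time), non-negative.
    """

    v0: float
    omega0: float
    Dr: float

    def __post_init__(self) -> None:
        if not self.v0 > 0:
            raise ValueError(f"v0 must be > 0, got {self.v0}")
        if self.Dr < 0:
            raise ValueError(f"Dr must be >= 0, got {self.Dr}")

    @property
    def is_chiral(self) -> bool:
        return self.omega0 != 0.0

    @property
    def r(self) -> float:
        """Orbital radius v0/|omega0| (inf for an ABP)."""
        return self.v0 / abs(self.omega0) if self.omega0 != 0 else math.inf

    @property
    def l_p(self) -> float:
        """Persistence length v0/Dr (inf for zero rotational noise)."""
        return self.v0 / self.Dr if self.Dr > 0 else math.inf

    @property
    def tau_p(self) -> float:
        """Persistence time 1/Dr."""
        return 1.0 / self.Dr if self.Dr > 0 else math.inf

    @property
    def tau_omega(self) -> float:
        """Revolution time 1/|omega0|."""
        return 1.0 / abs(self.omega0) if self.omega0 != 0 else math.inf

    @property
    def Omega(self) -> float:
        """Dimensionless Dr/|omega0| = r/l_p = tau_omega/tau_p."""
        if self.omega0 == 0:
            return math.inf
        return self.Dr / abs(self.omega0)

    @property
    def handedness(self) -> int:
        """+1 for CCW, -1 for CW, 0 for an ABP."""
        return int(np.sign(self.omega0))

    @classmethod
    def from_reduced(
        cls,
        r_bar: float | None,
        l_p_bar: float,
        handedness: int = 1,
        v0: float = 1.0,
        R: float = 1.0,
    ) -> "CAPParams":
        """Build parameters from the reduced pair (r_bar, l_p_bar).

        ``r_bar=None`` (or ``inf``) gives the ABP limit ``omega0 = 0``;
        ``handedness`` selects the orbit sense (+1 CCW, -1 CW).
        """
        if r_bar is None or math.isinf(r_bar):
            omega0 = 0.0
        else:
            if r_bar <= 0:
                raise ValueError("r_bar must be positive")
            if handedness not in (-1, 1):
                raise ValueError("handedness must be +1 (CCW) or -1 (CW)")
            omega0 = handedness * v0 / (r_bar * R)
        Dr = v0 / (l_p_bar * R) if math.isfinite(l_p_bar) else 0.0
        return cls(v0=v0, omega0=omega0, Dr=Dr)


@dataclass(frozen=True)
class ReducedParams:
    """Dimensionless parameter set in units v0 = R = 1.

    ``r_bar`` and ``l_p_bar`` are the orbital radius and persistence
    length in units of the contact radius ``R``; ``omega0_bar = 1/r_bar``
    and ``Dr_bar = 1/l_p_bar``.  Infinite sentinels flag the ABP
    (``r_bar = inf``) and noise-free (``l_p_bar = inf``) limits.
    """

    r_bar: float
    l_p_bar: float
    omega0_bar: float
    Dr_bar: float
    R: float
    handedness: int = 1

    @property
    def is_abp(self) -> bool:
        return math.isinf(self.r_bar)

    def to_params(self, v0: float = 1.0) -> CAPParams:
        """Inverse map back to dimensional parameters at the stored R."""
        return CAPParams.from_reduced(
            None if self.is_abp else self.r_bar,
            self.l_p_bar,
            handedness=self.handedness if not self.is_abp else 1,
            v0=v0,
            R=self.R,
        )


@dataclass(frozen=True)
class FlowField:
    """Uniform drift of speed ``v_g`` along angle ``psi`` from the x-axis."""

    v_g: float
    psi: float

    def __post_init__(self) -> None:
        if self.v_g < 0:
            raise ValueError(f"v_g must be >= 0, got {self.v_g}")

    @property
    def e_hat(self) -> np.ndarray:
        return np.array([math.cos(self.psi), math.sin(self.psi)])


def reduce_parameters(params: CAPParams, R: float) -> ReducedParams:
    """Nondimensionalize particle parameters by the contact radius R.

    Returns the four reduced quantities; the ABP limit is reported with an
    infinite ``r_bar`` sentinel, zero rotational noise with infinite
    ``l_p_bar``.  Round-trips with :meth:`ReducedParams.to_params`.
    """
    if not R > 0:
        raise ValueError(f"R must be > 0, got {R}")
    r_bar = params.r / R
    l_p_bar = params.l_p / R
    omega0_bar = 0.0 if math.isinf(r_bar) else 1.0 / r_bar
    Dr_bar = 0.0 if math.isinf(l_p_bar) else 1.0 / l_p_bar
    return ReducedParams(
        r_bar=r_bar,
        l_p_bar=l_p_bar,
        omega0_bar=omega0_bar,
        Dr_bar=Dr_bar,
        R=R,
        handedness=params.handedness if params.is_chiral else 1,
    )


def free_space_diffusivity(params: CAPParams) -> float:
    """Closed-form long-time diffusivity of a CAP in free space.

    For a chiral particle, ``D = v0^2/(2 omega0) * Omega/(1 + Omega^2)``
    with ``Omega = Dr/omega0``; the expression is invariant under the sign
    of ``omega0``.  The ABP limit (``omega0 = 0``) is ``v0^2/(2 Dr)``, the
    continuous limit of the chiral form.  A noise-free chiral particle
    (``Dr = 0``) retraces a closed circle and has ``D = 0``.
    """
    v0, omega0, Dr = params.v0, params.omega0, params.Dr
    if omega0 == 0.0:
        if Dr == 0.0:
            raise ValueError("ballistic particle (omega0 = Dr = 0) has no "
                             "finite free-space diffusivity")
        return v0 * v0 / (2.0 * Dr)
    Omega = Dr / omega0
    return v0 * v0 / (2.0 * omega0) * Omega / (1.0 + Omega * Omega)


def free_space_argmax_Omega(
    v0: float,
    omega0: float,
    Dr_grid: np.ndarray,
    tol: float = 1e-9,
) -> float:
    """Locate the Omega maximizing the free-space diffusivity.

    Evaluates the closed form on ``Dr_grid`` (which must bracket the
    maximum, i.e. span Omega values on both sides of it) and refines the
    grid argmax with bounded scalar minimization to ``|Omega* - 1| <<
    1e-6``.  The location is independent of ``v0`` and ``omega0`` because
    the closed form factorizes into a prefactor and a function of Omega
    alone.
    """
    Dr_grid = np.asarray(Dr_grid, dtype=float)
    if Dr_grid.size < 3:
        raise ValueError("Dr_grid needs at least 3 points")
    Omegas = np.sort(Dr_grid / abs(omega0))
    D = Omegas / (1.0 + Omegas**2)  # prefactor irrelevant to the argmax
    k = int(np.argmax(D))
    if k == 0 or k == Omegas.size - 1:
        raise ValueError(
            "Dr_grid does not bracket the diffusivity maximum; extend the "
            "grid so Omega spans both sides of the peak"
        )
    lo, hi = Omegas[k - 1], Omegas[k + 1]
    res = minimize_scalar(
        lambda Om: -Om / (1.0 + Om * Om),
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": tol},
    )
    return float(res.x)
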