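"""Periodic obstacle lattices: construction, packing fraction, contact queries.

Obstacles are disks of effective radius ``R`` (obstacle radius plus
particle radius; the simulated particle itself is a point).  Three lattice
types are supported:

* ``square`` — primitive vectors (d, 0), (0, d); phi = pi R^2 / d^2.
* ``triangular`` — (d, 0), (d/2, sqrt(3) d/2); phi = 2 pi R^2 / (sqrt(3) d^2).
* ``parallelogram`` — a square lattice with each successive row shifted
  horizontally by ``delta * d``; primitive vectors (d, 0), (delta d, d).
  ``delta = 0`` reproduces the square lattice exactly; ``delta`` and
  ``1 - delta`` lattices are mirror images of each other about a vertical
  axis, and only ``delta in {0, 0.5, 1}`` preserve mirror symmetry.

Periodicity uses skewed box vectors (integer multiples of the primitive
vectors) so the cell closes exactly for every ``delta``; minimum-image
arithmetic is done in fractional coordinates.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "LatticeKind",
    "ObstacleLattice",
    "Contact",
    "lattice_constant",
    "packing_bound",
    "build_lattice",
    "jitter_lattice",
    "contacts",
    "contacts_bruteforce",
]

_KINDS = ("square", "triangular", "parallelogram")

LatticeKind = str  # one of _KINDS


def packing_bound(kind: str) -> float:
    """Largest effective area fraction before disks overlap."""
    if kind in ("square", "parallelogram"):
        return math.pi / 4.0
    if kind == "triangular":
        return math.pi / (2.0 * math.sqrt(3.0))
    raise ValueError(f"unknown lattice kind {kind!r}")


# margin below the geometric bound at which construction is refused
_BOUND_MARGIN = 1e-6


def lattice_constant(kind: str, phi: float, R: float) -> float:
    """Invert the packing-fraction definition for the lattice constant d."""
    if kind not in _KINDS:
        raise ValueError(f"unknown lattice kind {kind!r}")
    bound = packing_bound(kind)
    if not 0.0 < phi <= bound - _BOUND_MARGIN:
        raise ValueError(
            f"phi={phi} outside (0, {bound - _BOUND_MARGIN:.6f}] for "
            f"{kind} lattice (non-overlap bound {bound:.6f})"
        )
    if kind == "triangular":
        return R * math.sqrt(2.0 * math.pi / (math.sqrt(3.0) * phi))
    return R * math.sqrt(math.pi / phi)


@dataclass(frozen=True)
class ObstacleLattice:
    """A periodic array of effective-radius disks.

    ``centers`` lists obstacle positions inside the periodic supercell
    spanned by box vectors ``box = n_cells[0]*a1, n_cells[1]*a2`` (stored
    as matrix columns).  A perfect lattice keeps ``n_cells=(1, 1)`` with a
    single obstacle at the origin; jittered lattices tile a larger
    supercell so displacements can differ between sites.
    """

    kind: str
    d: float
    R: float
    phi: float
    delta: float
    a1: np.ndarray
    a2: np.ndarray
    n_cells: tuple[int, int]
    centers: np.ndarray  # (N, 2)

    @property
    def box(self) -> np.ndarray:
        """2x2 matrix with the supercell vectors as columns."""
        return np.column_stack([self.n_cells[0] * self.a1,
                                self.n_cells[1] * self.a2])

    @property
    def box_inv(self) -> np.ndarray:
        return np.linalg.inv(self.box)

    @property
    def cell_area(self) -> float:
        return abs(float(self.a1[0] * self.a2[1] - self.a1[1] * self.a2[0]))

    @property
    def n_obstacles(self) -> int:
        return len(self.centers)

    def wrap(self, pos: np.ndarray) -> np.ndarray:
        """Wrap positions into the primary supercell (fractional [0, 1))."""
        pos = np.atleast_2d(pos)
        f = pos @ self.box_inv.T
        f -= np.floor(f)
        out = f @ self.box.T
        return out[0] if out.shape[0] == 1 and np.ndim(pos) else out

    def to_csv(self, path) -> None:
        """Export centers as CSV with a JSON header line of lattice metadata."""
        meta = {
            "kind": self.kind,
            "d": self.d,
            "R": self.R,
            "phi": self.phi,
            "delta": self.delta,
            "a1": list(map(float, self.a1)),
            "a2": list(map(float, self.a2)),
            "n_cells": list(self.n_cells),
        }
        with open(path, "w") as fh:
            fh.write("# " + json.dumps(meta) + "\n")
            fh.write("id,x,y\n")
            for i, (x, y) in enumerate(self.centers):
                fh.write(f"{i},{float(x)!r},{float(y)!r}\n")

    @classmethod
    def from_csv(cls, path) -> "ObstacleLattice":
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("# "):
                raise ValueError("missing JSON metadata header")
            meta = json.loads(header[2:])
            rows = np.loadtxt(fh, delimiter=",", skiprows=1, ndmin=2)
        centers = rows[:, 1:3] if rows.size else np.empty((0, 2))
        return cls(
            kind=meta["kind"],
            d=meta["d"],
            R=meta["R"],
            phi=meta["phi"],
            delta=meta["delta"],
            a1=np.array(meta["a1"]),
            a2=np.array(meta["a2"]),
            n_cells=tuple(meta["n_cells"]),
            centers=centers,
        )


def build_lattice(
    kind: str,
    phi: float,
    R: float = 1.0,
    delta: float = 0.0,
    n_cells: int | tuple[int, int] = 1,
) -> ObstacleLattice:
    """Build a periodic obstacle lattice at packing fraction ``phi``.

    ``delta`` applies only to ``parallelogram`` (``delta=0`` is identical
    to ``square``).  ``n_cells`` repeats the primitive cell along each
    lattice vector; one obstacle per primitive cell.
    """
    if kind not in _KINDS:
        raise ValueError(f"unknown lattice kind {kind!r}")
    if kind != "parallelogram" and delta != 0.0:
        raise ValueError("delta is only meaningful for parallelogram lattices")
    if not 0.0 <= delta < 1.0:
        raise ValueError(f"delta must be in [0, 1), got {delta}")
    d = lattice_constant(kind, phi, R)
    if kind == "triangular":
        a1 = np.array([d, 0.0])
        a2 = np.array([d / 2.0, d * math.sqrt(3.0) / 2.0])
    else:
        a1 = np.array([d, 0.0])
        a2 = np.array([delta * d, d])
    if isinstance(n_cells, int):
        n_cells = (n_cells, n_cells)
    n1, n2 = n_cells
    if n1 < 1 or n2 < 1:
        raise ValueError("n_cells must be >= 1 per axis")
    ii, jj = np.meshgrid(np.arange(n1), np.arange(n2), indexing="ij")
    centers = ii.reshape(-1, 1) * a1 + jj.reshape(-1, 1) * a2
    return ObstacleLattice(
        kind=kind, d=d, R=R, phi=phi, delta=delta,
        a1=a1, a2=a2, n_cells=(n1, n2), centers=centers,
    )


def jitter_lattice(
    lattice: ObstacleLattice,
    sigma: float,
    seed: int,
    overlap_tol: float = 0.0,
) -> ObstacleLattice:
    """Displace each obstacle by isotropic Gaussian noise of s.d. sigma*d.

    Displaced centers are wrapped back into the periodic supercell.
    ``sigma=0`` returns the lattice unchanged.  Pairs of effective disks
    brought closer than ``2R - overlap_tol`` trigger a warning (overlapping
    obstacles are physically ill-defined but not refused).
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0.0:
        return lattice
    rng = np.random.default_rng(seed)
    disp = rng.normal(0.0, sigma * lattice.d, size=lattice.centers.shape)
    centers = lattice.centers + disp
    # wrap into the supercell
    f = centers @ lattice.box_inv.T
    f -= np.floor(f)
    centers = f @ lattice.box.T
    new = replace(lattice, centers=centers)
    if _min_pair_separation(new) < 2.0 * lattice.R - overlap_tol:
        warnings.warn(
            "jittered obstacles overlap (min separation below 2R)",
            stacklevel=2,
        )
    return new


def _min_pair_separation(lattice: ObstacleLattice) -> float:
    c = lattice.centers
    n = len(c)
    if n < 2:
        # single site: nearest periodic image of itself
        lengths = [np.linalg.norm(lattice.box @ v)
                   for v in ([1, 0], [0, 1], [1, 1], [1, -1])]
        return min(lengths)
    box, box_inv = lattice.box, lattice.box_inv
    dmin = math.inf
    for i in range(n):
        dvec = c[i + 1:] - c[i]
        f = dvec @ box_inv.T
        f -= np.round(f)
        dd = np.linalg.norm(f @ box.T, axis=1)
        if dd.size:
            dmin = min(dmin, float(dd.min()))
    # also nearest self-image via the shorter box translation
    for v in ([1, 0], [0, 1], [1, 1], [1, -1]):
        dmin = min(dmin, float(np.linalg.norm(box @ v)))
    return dmin


@dataclass(frozen=True)
class Contact:
    """One particle-obstacle contact: index, outward unit normal, overlap."""

    index: int
    normal: np.ndarray  # unit vector from obstacle center toward particle
    depth: float        # R - distance (>= 0 when touching/penetrating)


def contacts(
    pos: np.ndarray,
    lattice: ObstacleLattice,
    tol: float = 0.0,
) -> list[Contact]:
    """All obstacles whose effective disk contains ``pos`` (dist <= R + tol).

    Uses minimum-image search over the 3x3 block of periodic images around
    the fractional rounding of each center; exact for contact radii smaller
    than the supercell extent.  Normals point from obstacle center to the
    particle.  Sorted by descending overlap depth.
    """
    pos = np.asarray(pos, dtype=float)
    box, box_inv = lattice.box, lattice.box_inv
    R = lattice.R
    found: list[Contact] = []
    for j, c in enumerate(lattice.centers):
        dvec = pos - c
        f = box_inv @ dvec
        f0 = f - np.round(f)
        best = None
        for ix in (-1, 0, 1):
            for iy in (-1, 0, 1):
                g = box @ (f0 + np.array([ix, iy], dtype=float))
                dist = float(np.hypot(g[0], g[1]))
                if dist <= R + tol and (best is None or dist < best[0]):
                    best = (dist, g)
        if best is not None:
            dist, g = best
            if dist == 0.0:
                normal = np.array([1.0, 0.0])  # degenerate: at the center
            else:
                normal = g / dist
            found.append(Contact(index=j, normal=normal, depth=R - dist))
    found.sort(key=lambda c: -c.depth)
    return found


def contacts_bruteforce(
    pos: np.ndarray,
    lattice: ObstacleLattice,
    tol: float = 0.0,
    n_images: int = 2,
) -> list[Contact]:
    """O(N * images) reference contact query tiling explicit periodic images.

    Independent oracle for :func:`contacts`: enumerates every obstacle
    center translated by all supercell images within ``n_images`` and tests
    the distance directly.
    """
    pos = np.asarray(pos, dtype=float)
    box = lattice.box
    R = lattice.R
    found: list[Contact] = []
    rng = range(-n_images, n_images + 1)
    for j, c in enumerate(lattice.centers):
        best = None
        for ix in rng:
            for iy in rng:
                cc = c + box @ np.array([ix, iy], dtype=float)
                g = pos - cc
                dist = float(np.hypot(g[0], g[1]))
                if dist <= R + tol and (best is None or dist < best[0]):
                    best = (dist, g)
        if best is not None:
            dist, g = best
            normal = g / dist if dist > 0 else np.array([1.0, 0.0])
            found.append(Contact(index=j, normal=normal, depth=R - dist))
    found.sort(key=lambda c: -c.depth)
    return found


def measured_area_fraction(
    lattice: ObstacleLattice, n_points: int = 10**6, seed: int = 0
) -> tuple[float, float]:
    """Monte-Carlo estimate of the covered area fraction, with its s.e."""
    rng = np.random.default_rng(seed)
    f = rng.random((n_points, 2))
    pts = f @ lattice.box.T
    box, box_inv = lattice.box, lattice.box_inv
    covered = np.zeros(n_points, dtype=bool)
    for c in lattice.centers:
        dvec = pts - c
        ff = dvec @ box_inv.T
        ff -= np.round(ff)
        for ix in (-1, 0, 1):
            for iy in (-1, 0, 1):
                g = (ff + np.array([ix, iy])) @ box.T
                covered |= (g[:, 0] ** 2 + g[:, 1] ** 2) <= lattice.R**2
    p = covered.mean()
    # the supercell holds n1*n2 disks; the covered fraction estimates phi
    se = math.sqrt(p * (1 - p) / n_points)
    return float(p), se
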