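"""Geometric degree-of-asymmetry score for sheared parallelogram lattices.

A parallelogram lattice (shear ``delta``) has a handedness for
``delta`` outside {0, 0.5}: its unit cell cannot be superimposed on its
mirror image.  The score works on the triangle obtained by cutting the
unit cell along its diagonal — vertices ``(0,0), (d,0), (delta d, d)`` —
and measures how well that triangle overlaps its own mirror image:

* reflect the triangle about an axis at 45 degrees or 90 degrees,
* translate the mirror image rigidly to maximize the intersection area,
* normalize by the triangle area, giving ``A45`` and ``A90`` in [0, 1].

``A_max(delta) = max(A45, A90)`` equals 1 exactly when the triangle has a
mirror axis at one of the two orientations (``delta`` in {0, 0.5}, plus
``delta -> 1 - delta`` by the mirror identity) and dips below 1 otherwise;
its interior minimum marks the most chiral lattice.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from shapely.geometry import Polygon

__all__ = [
    "CellTriangle",
    "AsymmetryResult",
    "unit_cell_triangle",
    "mirror_overlap",
    "degree_of_asymmetry",
    "asymmetry_sweep",
]


@dataclass(frozen=True)
class CellTriangle:
    """Half of the parallelogram unit cell, vertices in CCW order."""

    vertices: np.ndarray  # (3, 2)

    def __post_init__(self) -> None:
        if self.area <= 0:
            raise ValueError("triangle is degenerate or not CCW-ordered")

    @property
    def area(self) -> float:
        v = self.vertices
        return 0.5 * float(
            (v[1, 0] - v[0, 0]) * (v[2, 1] - v[0, 1])
            - (v[2, 0] - v[0, 0]) * (v[1, 1] - v[0, 1])
        )

    @property
    def polygon(self) -> Polygon:
        return Polygon(self.vertices)


@dataclass(frozen=True)
class AsymmetryResult:
    delta: float
    A45: float
    A90: float

    @property
    def A_max(self) -> float:
        return max(self.A45, self.A90)


def unit_cell_triangle(delta: float, d: float = 1.0) -> CellTriangle:
    """Triangle (0,0), (d,0), (delta*d, d): the sheared cell cut along its
    diagonal.  Area is d^2/2 for every delta (shear preserves area)."""
    if d <= 0:
        raise ValueError("d must be positive")
    verts = np.array([[0.0, 0.0], [d, 0.0], [delta * d, d]])
    return CellTriangle(vertices=verts)


def _reflection_matrix(axis_angle: float) -> np.ndarray:
    c, s = math.cos(2.0 * axis_angle), math.sin(2.0 * axis_angle)
    return np.array([[c, s], [s, -c]])


def mirror_overlap(
    triangle: CellTriangle,
    axis_angle: float,
    grid: int = 21,
    refine_tol: float = 1e-10,
) -> float:
    """Best overlap fraction with the mirror image across an axis direction.

    The triangle is reflected about a line of orientation ``axis_angle``
    (radians) through the origin; composing with translation covers every
    mirror line of that orientation, so the intersection area is maximized
    over rigid translation of the image: a coarse grid around the
    centroid-aligned offset, refined by Nelder--Mead.  Intersection areas
    use exact polygon clipping.  Returns area fraction in [0, 1].
    """
    P = triangle.polygon
    area = triangle.area
    M = _reflection_matrix(axis_angle)
    refl = triangle.vertices @ M.T
    Q0 = Polygon(refl)
    # translation aligning the centroids is the natural starting point
    c0 = np.asarray(P.centroid.coords[0]) - np.asarray(Q0.centroid.coords[0])
    scale = math.sqrt(area)

    def overlap(t: np.ndarray) -> float:
        Q = Polygon(refl + t)
        return P.intersection(Q).area

    best_t = c0
    best = overlap(c0)
    span = np.linspace(-scale, scale, grid)
    for ox, oy in itertools.product(span, span):
        t = c0 + np.array([ox, oy])
        a = overlap(t)
        if a > best:
            best, best_t = a, t
    res = minimize(
        lambda t: -overlap(t),
        best_t,
        method="Nelder-Mead",
        options={"xatol": 1e-9 * scale, "fatol": refine_tol * area,
                 "maxiter": 500},
    )
    if not (res.success or -res.fun >= best - refine_tol * area):
        raise RuntimeError(f"mirror-overlap refinement failed: {res.message}")
    best = max(best, -res.fun)
    return min(best / area, 1.0)


def degree_of_asymmetry(delta: float, d: float = 1.0) -> AsymmetryResult:
    """A_max(delta) = max(A45, A90) for the unit-cell triangle.

    ``delta > 0.5`` is folded to ``1 - delta`` (mirror-image lattices have
    equal asymmetry scores by construction).  Scale-invariant in ``d``.
    """
    if not 0.0 <= delta < 1.0:
        raise ValueError("delta must be in [0, 1)")
    folded = min(delta, 1.0 - delta) if delta > 0 else delta
    tri = unit_cell_triangle(folded, d)
    A45 = mirror_overlap(tri, math.pi / 4.0)
    A90 = mirror_overlap(tri, math.pi / 2.0)
    return AsymmetryResult(delta=delta, A45=A45, A90=A90)


def asymmetry_sweep(deltas: np.ndarray, d: float = 1.0):
    """A_max over a delta grid, as a pandas DataFrame."""
    import pandas as pd

    rows = []
    for delta in np.asarray(deltas, dtype=float):
        res = degree_of_asymmetry(float(delta), d)
        rows.append(
            {"delta": res.delta, "A45": res.A45, "A90": res.A90,
             "A_max": res.A_max}
        )
    return pd.DataFrame(rows)
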