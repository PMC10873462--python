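"""Config-driven sweep pipelines reproducing the simulator's headline
computations at desk scale: the (l_p_bar, r_bar) diffusivity map, the
packing-fraction sweep, directional-locking curves, and the chirality
sorting sweep over sheared lattices.

Every sweep is exactly reproducible from its spec: cell seeds derive from
the root seed and the cell index through a SeedSequence, so cells can be
re-run independently.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .asymmetry import degree_of_asymmetry
from .engine import SimConfig, simulate
from .lattice import ObstacleLattice, build_lattice
from .model import CAPParams, FlowField
from .observables import (
    LockingCurve,
    contact_statistics,
    locking_plateaus,
    locking_strength,
    measure_diffusivity,
    migration_angle,
)

__all__ = [
    "SweepSpec",
    "cell_seed",
    "measure_lattice_diffusivity",
    "run_diffusivity_map",
    "run_packing_sweep",
    "run_locking_curve",
    "run_locking_sweep",
    "run_sorting_sweep",
]

# default replicate budget for diffusivity cells: 32 walkers over 2e4 time
# units, integrated at dt = 2e-3 (well inside the v0*dt <= 0.01 R bound)
DEFAULT_BUDGET = {
    "n_particles": 32,
    "t_total": 2.0e4,
    "dt": 2.0e-3,
    "record_stride": 500,
}

# drift (locking) runs need less time per cell: the migration velocity is
# O(v0) and self-averages quickly
DEFAULT_DRIFT_BUDGET = {
    "n_particles": 8,
    "t_total": 3.0e3,
    "dt": 2.0e-3,
    "record_stride": 50,
}


@dataclass(frozen=True)
class SweepSpec:
    """Cartesian sweep definition.

    ``axes`` maps parameter names to value lists; cells enumerate the
    product in a deterministic (row-major, insertion-ordered) order.
    ``fixed`` holds the constant parameters, ``budget`` overrides the
    default replicate budget.
    """

    axes: dict
    fixed: dict = field(default_factory=dict)
    seed: int = 0
    budget: dict = field(default_factory=dict)

    def cells(self):
        names = list(self.axes)
        for idx, values in enumerate(itertools.product(*self.axes.values())):
            params = dict(self.fixed)
            params.update(dict(zip(names, values)))
            yield idx, params

    def n_cells(self) -> int:
        out = 1
        for v in self.axes.values():
            out *= len(v)
        return out


def cell_seed(root: int, index: int) -> int:
    """Reproducible per-cell engine seed below 2^31."""
    return int(
        np.random.SeedSequence([root, index]).generate_state(1)[0] & 0x7FFFFFFF
    )


def _budget(spec_budget: dict, default: dict) -> dict:
    out = dict(default)
    out.update(spec_budget)
    return out


def measure_lattice_diffusivity(
    r_bar: float | None,
    l_p_bar: float,
    lattice: ObstacleLattice | None,
    seed: int,
    handedness: int = 1,
    n_particles: int = 32,
    t_total: float = 2.0e4,
    dt: float = 2.0e-3,
    record_stride: int = 500,
    with_contacts: bool = False,
):
    """One diffusivity cell: simulate and fit the long-time MSD slope."""
    params = CAPParams.from_reduced(r_bar, l_p_bar, handedness=handedness)
    cfg = SimConfig(
        dt=dt,
        t_total=t_total,
        n_particles=n_particles,
        seed=seed,
        record_stride=record_stride,
    )
    traj, log = simulate(params, lattice, cfg, collect_intervals=False)
    res = measure_diffusivity(traj)
    if with_contacts:
        return res, contact_statistics(log)
    return res


def run_diffusivity_map(spec: SweepSpec) -> pd.DataFrame:
    """Psi = ln(D_eff/D) over a (l_p_bar, r_bar, lattice kind) grid at
    fixed packing fraction.

    Cells whose MSD fit fails (window too short) are flagged with NaN
    rather than aborting the sweep.
    """
    budget = _budget(spec.budget, DEFAULT_BUDGET)
    phi = spec.fixed.get("phi", 0.7)
    handedness = spec.fixed.get("handedness", 1)
    rows = []
    lattices: dict = {}
    for idx, cell in spec.cells():
        kind = cell["lattice"]
        if kind not in lattices:
            lattices[kind] = None if kind == "free" else build_lattice(kind, phi)
        try:
            res, cst = measure_lattice_diffusivity(
                cell["r_bar"],
                cell["l_p_bar"],
                lattices[kind],
                cell_seed(spec.seed, idx),
                handedness=handedness,
                with_contacts=True,
                **budget,
            )
            rows.append(
                {
                    "lattice": kind,
                    "l_p_bar": cell["l_p_bar"],
                    "r_bar": cell["r_bar"],
                    "D_eff": res.D_eff,
                    "D_se": res.D_se,
                    "D_free": res.D_free,
                    "Psi": res.Psi,
                    "Psi_se": res.Psi_se,
                    "mu": cst["mu"],
                    "N": cst["N"],
                    "N_rate": cst["N_rate"],
                    "ok": True,
                }
            )
        except ValueError:
            rows.append(
                {
                    "lattice": kind,
                    "l_p_bar": cell["l_p_bar"],
                    "r_bar": cell["r_bar"],
                    "D_eff": math.nan,
                    "Psi": math.nan,
                    "ok": False,
                }
            )
    return pd.DataFrame(rows)


def run_packing_sweep(spec: SweepSpec) -> pd.DataFrame:
    """D_eff as a function of packing fraction phi.

    ``axes`` must provide ``phi``; ``fixed`` picks the particle
    (``r_bar`` may be None for an ABP), the lattice kind, and l_p_bar.
    """
    budget = _budget(spec.budget, DEFAULT_BUDGET)
    kind = spec.fixed.get("lattice", "square")
    l_p_bar = spec.fixed.get("l_p_bar", 100.0)
    r_bar = spec.fixed.get("r_bar", 1.0)
    handedness = spec.fixed.get("handedness", 1)
    rows = []
    for idx, cell in spec.cells():
        phi = cell["phi"]
        lattice = build_lattice(kind, phi)
        res = measure_lattice_diffusivity(
            r_bar,
            l_p_bar,
            lattice,
            cell_seed(spec.seed, idx),
            handedness=handedness,
            **budget,
        )
        rows.append(
            {
                "lattice": kind,
                "phi": phi,
                "r_bar": math.inf if r_bar is None else r_bar,
                "l_p_bar": l_p_bar,
                "D_eff": res.D_eff,
                "D_se": res.D_se,
                "Psi": res.Psi,
            }
        )
    return pd.DataFrame(rows)


def run_locking_curve(
    r_bar: float | None,
    l_p_bar: float,
    lattice: ObstacleLattice,
    psi_deg: np.ndarray,
    seed: int,
    v_g: float = 1.0,
    handedness: int = 1,
    n_particles: int = 8,
    t_total: float = 3.0e3,
    dt: float = 2.0e-3,
    record_stride: int = 50,
) -> LockingCurve:
    """Migration direction alpha(psi) over a grid of drive angles."""
    params = CAPParams.from_reduced(r_bar, l_p_bar, handedness=handedness)
    psi_rad = np.radians(np.asarray(psi_deg, dtype=float))
    alphas = np.empty_like(psi_rad)
    ses = np.empty_like(psi_rad)
    for k, psi in enumerate(psi_rad):
        cfg = SimConfig(
            dt=dt,
            t_total=t_total,
            n_particles=n_particles,
            seed=cell_seed(seed, k),
            record_stride=record_stride,
        )
        traj, _ = simulate(
            params,
            lattice,
            cfg,
            flow=FlowField(v_g=v_g, psi=float(psi)),
            collect_intervals=False,
        )
        alphas[k], ses[k] = migration_angle(traj)
    return LockingCurve(psi=psi_rad, alpha=alphas, alpha_se=ses)


def run_locking_sweep(spec: SweepSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Locking curves and strengths over particle types and lattices.

    ``axes``: ``lattice`` in {square, triangular}, ``l_p_bar`` values,
    ``particle`` in {"cap", "abp"}.  Returns (curve table, epsilon table);
    the epsilon table also reports the widest plateau per cell.
    """
    budget = _budget(spec.budget, DEFAULT_DRIFT_BUDGET)
    phi = spec.fixed.get("phi", 0.7)
    r_bar = spec.fixed.get("r_bar", 1.0)
    handedness = spec.fixed.get("handedness", 1)
    v_g = spec.fixed.get("v_g", 1.0)
    psi_deg = np.asarray(
        spec.fixed.get("psi_deg", np.arange(0.0, 91.0, 1.0)), dtype=float
    )
    lattices: dict = {}
    curve_rows = []
    eps_rows = []
    for idx, cell in spec.cells():
        kind = cell["lattice"]
        if kind not in lattices:
            lattices[kind] = build_lattice(kind, phi)
        rb = r_bar if cell["particle"] == "cap" else None
        curve = run_locking_curve(
            rb,
            cell["l_p_bar"],
            lattices[kind],
            psi_deg,
            cell_seed(spec.seed, idx),
            v_g=v_g,
            handedness=handedness,
            **budget,
        )
        for p, a, se in zip(psi_deg, np.degrees(curve.alpha), np.degrees(curve.alpha_se)):
            curve_rows.append(
                {
                    "lattice": kind,
                    "particle": cell["particle"],
                    "l_p_bar": cell["l_p_bar"],
                    "psi_deg": p,
                    "alpha_deg": a,
                    "alpha_se_deg": se,
                }
            )
        plats = locking_plateaus(curve)
        widest = plats[0] if plats else None
        eps_rows.append(
            {
                "lattice": kind,
                "particle": cell["particle"],
                "l_p_bar": cell["l_p_bar"],
                "epsilon": locking_strength(curve),
                "plateau_alpha_deg": widest["alpha"] if widest else math.nan,
                "plateau_width_deg": widest["width"] if widest else math.nan,
            }
        )
    return pd.DataFrame(curve_rows), pd.DataFrame(eps_rows)


def run_sorting_sweep(spec: SweepSpec) -> pd.DataFrame:
    """CW-vs-CCW effective diffusivity over the shear parameter delta.

    Simulates clockwise particles only; counter-clockwise values follow
    from the exact mirror identity ``D_CCW(delta) = D_CW(1 - delta)``
    (mirror-image lattices swap particle handedness), so every
    ``delta`` in the axes is simulated together with ``1 - delta``.
    Reports ``DeltaD = D_CW - D_CCW`` and joins the geometric asymmetry
    score A_max.
    """
    budget = _budget(spec.budget, DEFAULT_BUDGET)
    phi = spec.fixed.get("phi", 0.7)
    r_bar = spec.fixed.get("r_bar", 1.5)
    l_p_bar = spec.fixed.get("l_p_bar", 100.0)
    deltas = sorted(set(float(d) for d in spec.axes["delta"]))
    # simulate CW in every delta and its mirror partner
    need = sorted(set(deltas) | {round(1.0 - d, 12) % 1.0 for d in deltas})
    d_cw: dict[float, tuple[float, float]] = {}
    for idx, delta in enumerate(need):
        lattice = build_lattice("parallelogram", phi, delta=delta)
        res = measure_lattice_diffusivity(
            r_bar,
            l_p_bar,
            lattice,
            cell_seed(spec.seed, idx),
            handedness=-1,
            **budget,
        )
        d_cw[round(delta, 12)] = (res.D_eff, res.D_se)
    rows = []
    for delta in deltas:
        key = round(delta, 12)
        mirror = round((1.0 - delta) % 1.0, 12)
        D_cw, se_cw = d_cw[key]
        D_ccw, se_ccw = d_cw[mirror]
        rows.append(
            {
                "delta": delta,
                "D_CW": D_cw,
                "D_CW_se": se_cw,
                "D_CCW": D_ccw,
                "D_CCW_se": se_ccw,
                "DeltaD": D_cw - D_ccw,
                "DeltaD_se": math.hypot(se_cw, se_ccw),
                "A_max": degree_of_asymmetry(delta).A_max,
            }
        )
    return pd.DataFrame(rows)
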