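"""Configuration files, canonical fixtures, and run manifests.

Configs are flat key-value YAML.  All lengths are in units of the contact
radius R and times in R/v0 (the simulation units); the optional ``si_*``
keys carry dimensional values for reproducing measured particle
parameters and are informational only.

Schema (defaults in parentheses):

    particle   r_bar (1.0; null = ABP), l_p_bar (100.0),
               handedness (1: CCW, -1: CW)
    lattice    lattice (square | triangular | parallelogram | free),
               phi (0.7), delta (0.0), n_cells (1)
    flow       v_g (0.0), psi_deg (0.0)
    run        dt (0.002), t_total (20000.0), n_particles (32),
               record_stride (500), seed (0), burn_in (null = auto)
    extra      label (""), si_v0 (null), si_omega0 (null), si_Dr (null),
               si_R (null)

Unknown keys are rejected so typos cannot silently change a run.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .engine import SimConfig
from .lattice import ObstacleLattice, build_lattice, packing_bound
from .model import CAPParams, FlowField

__all__ = [
    "CONFIG_SCHEMA",
    "RunBundle",
    "RunManifest",
    "load_config",
    "save_config",
    "generate_fixtures",
]

_NULLABLE_FLOAT = ("nullable_float",)

# key -> (type, default, validator or None); validators raise ValueError
CONFIG_SCHEMA: dict = {
    "r_bar": ("nullable_float", 1.0, lambda v: v is None or v > 0),
    "l_p_bar": ("float", 100.0, lambda v: v > 0),
    "handedness": ("int", 1, lambda v: v in (-1, 1)),
    "lattice": (
        "str",
        "square",
        lambda v: v in ("square", "triangular", "parallelogram", "free"),
    ),
    "phi": ("float", 0.7, lambda v: 0 < v),
    "delta": ("float", 0.0, lambda v: 0 <= v < 1),
    "n_cells": ("int", 1, lambda v: v >= 1),
    "v_g": ("float", 0.0, lambda v: v >= 0),
    "psi_deg": ("float", 0.0, None),
    "dt": ("float", 2e-3, lambda v: v > 0),
    "t_total": ("float", 2e4, lambda v: v > 0),
    "n_particles": ("int", 32, lambda v: v >= 1),
    "record_stride": ("int", 500, lambda v: v >= 1),
    "seed": ("int", 0, lambda v: v >= 0),
    "burn_in": ("nullable_float", None, lambda v: v is None or v >= 0),
    "label": ("str", "", None),
    "si_v0": ("nullable_float", None, None),
    "si_omega0": ("nullable_float", None, None),
    "si_Dr": ("nullable_float", None, None),
    "si_R": ("nullable_float", None, None),
}


@dataclass(frozen=True)
class RunBundle:
    """A validated configuration resolved into domain objects."""

    config: dict
    params: CAPParams
    lattice: ObstacleLattice | None
    flow: FlowField | None
    sim: SimConfig

    @property
    def label(self) -> str:
        return self.config["label"]


def _coerce(key: str, value):
    kind, _default, validator = CONFIG_SCHEMA[key]
    if kind == "float":
        if value is None or isinstance(value, bool):
            raise ValueError(f"config key {key!r}: expected a number")
        value = float(value)
    elif kind == "nullable_float":
        if value is not None:
            value = float(value)
    elif kind == "int":
        if isinstance(value, bool) or value is None:
            raise ValueError(f"config key {key!r}: expected an integer")
        if int(value) != value:
            raise ValueError(f"config key {key!r}: expected an integer")
        value = int(value)
    elif kind == "str":
        value = str(value)
    if validator is not None and not validator(value):
        raise ValueError(f"config key {key!r}: invalid value {value!r}")
    return value


def validate_config(raw: dict) -> dict:
    """Fill defaults, coerce types, and cross-validate a raw mapping."""
    unknown = set(raw) - set(CONFIG_SCHEMA)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    cfg = {k: spec[1] for k, spec in CONFIG_SCHEMA.items()}
    for k, v in raw.items():
        cfg[k] = _coerce(k, v)
    # cross-field checks
    if cfg["lattice"] != "free":
        bound = packing_bound(
            "parallelogram" if cfg["lattice"] == "parallelogram" else cfg["lattice"]
        )
        if cfg["phi"] >= bound - 1e-6:
            raise ValueError(
                f"config key 'phi': {cfg['phi']} at or above the "
                f"non-overlap bound {bound:.6f} for {cfg['lattice']} lattice"
            )
    if cfg["delta"] != 0.0 and cfg["lattice"] != "parallelogram":
        raise ValueError("config key 'delta': nonzero delta requires a "
                         "parallelogram lattice")
    if cfg["dt"] > 0.01:
        raise ValueError("config key 'dt': v0*dt must not exceed 0.01 R "
                         "(simulation units v0 = R = 1)")
    return cfg


def resolve(cfg: dict) -> RunBundle:
    """Turn a validated config dict into domain objects."""
    params = CAPParams.from_reduced(
        cfg["r_bar"], cfg["l_p_bar"], handedness=cfg["handedness"]
    )
    if cfg["lattice"] == "free":
        lattice = None
    else:
        lattice = build_lattice(
            cfg["lattice"], cfg["phi"], delta=cfg["delta"], n_cells=cfg["n_cells"]
        )
    flow = None
    if cfg["v_g"] > 0:
        flow = FlowField(v_g=cfg["v_g"], psi=math.radians(cfg["psi_deg"]))
    sim = SimConfig(
        dt=cfg["dt"],
        t_total=cfg["t_total"],
        n_particles=cfg["n_particles"],
        seed=cfg["seed"],
        record_stride=cfg["record_stride"],
        burn_in=cfg["burn_in"],
    )
    return RunBundle(config=cfg, params=params, lattice=lattice, flow=flow, sim=sim)


def load_config(path) -> RunBundle:
    """Load, validate, and resolve a YAML config file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a flat key-value mapping")
    try:
        cfg = validate_config(raw)
    except ValueError as err:
        raise ValueError(f"{path}: {err}") from None
    return resolve(cfg)


def _format_value(v) -> str:
    if v is None:
        return "null"
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, float):
        return repr(v)  # shortest round-tripping decimal (17 sig digits max)
    return str(v)


def save_config(cfg: dict, path) -> None:
    """Write a validated config as sorted flat YAML (byte-reproducible)."""
    cfg = validate_config(cfg)
    lines = []
    for k in sorted(cfg):
        v = cfg[k]
        if isinstance(v, str):
            lines.append(f"{k}: {json.dumps(v)}")
        else:
            lines.append(f"{k}: {_format_value(v)}")
    Path(path).write_text("\n".join(lines) + "\n")


def config_hash(cfg: dict) -> str:
    """Stable SHA-256 of the canonical config serialization."""
    canon = json.dumps(validate_config(cfg), sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()


@dataclass
class RunManifest:
    """Provenance record for a run: config hash, seed, output checksums."""

    config_hash: str
    seed: int
    code_version: str
    outputs: dict = field(default_factory=dict)

    @classmethod
    def for_run(cls, cfg: dict, outputs: dict[str, Path] | None = None):
        from . import __version__

        man = cls(
            config_hash=config_hash(cfg),
            seed=validate_config(cfg)["seed"],
            code_version=__version__,
        )
        for name, path in (outputs or {}).items():
            man.add_output(name, path)
        return man

    def add_output(self, name: str, path) -> None:
        digest = hashlib.sha256(Path(path).read_bytes()).hexdigest()
        self.outputs[name] = digest

    def to_json(self, path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "config_hash": self.config_hash,
                    "seed": self.seed,
                    "code_version": self.code_version,
                    "outputs": self.outputs,
                },
                indent=2,
                sort_keys=True,
            )
            + "\n"
        )


# ---------------------------------------------------------------------------
# canonical fixtures

# measured grass-seed parameters in reduced units (seed 1 orbits clockwise,
# seed 2 counter-clockwise), plus the SI measurements they summarize
_SEED_FIXTURES = {
    "seed1_free": {
        "label": "seed 1 free space (CW, r_bar=1.7, l_p_bar=3.2)",
        "r_bar": 1.7,
        "l_p_bar": 3.2,
        "handedness": -1,
        "lattice": "free",
        "si_v0": 39.0,
        "si_omega0": -2.6,
        "si_Dr": 1.6,
        "si_R": 7.0,
    },
    "seed2_free": {
        "label": "seed 2 free space (CCW, r_bar=0.2, l_p_bar=0.5)",
        "r_bar": 0.2,
        "l_p_bar": 0.5,
        "handedness": 1,
        "lattice": "free",
        "si_v0": 9.7,
        "si_omega0": 6.3,
        "si_Dr": 2.7,
        "si_R": 7.0,
    },
}


def generate_fixtures(out_dir) -> list[Path]:
    """Write the canonical config set to ``out_dir``.

    Covers: the two measured seed particles in free space; the four
    caging/enhancement conditions (square/triangular at r_bar 1 and
    2, l_p_bar = 100, phi = 0.7); the directional-locking baseline
    (v_g/v0 = 1, r_bar = 1); and the chirality-sorting pair (r_bar = 1.5,
    l_p_bar = 100, delta = 0.3 and 0.7).  Deterministic: same names and
    bytes on every call.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fixtures: dict[str, dict] = {}
    fixtures.update(_SEED_FIXTURES)
    for kind in ("square", "triangular"):
        for r_bar in (1.0, 2.0):
            fixtures[f"lattice_{kind}_r{r_bar:g}"] = {
                "label": f"{kind} lattice phi=0.7, r_bar={r_bar:g}, l_p_bar=100",
                "r_bar": r_bar,
                "l_p_bar": 100.0,
                "lattice": kind,
                "phi": 0.7,
            }
    for l_p_bar in (0.1, 1.0, 100.0):
        fixtures[f"locking_square_lp{l_p_bar:g}"] = {
            "label": f"directional locking, square, l_p_bar={l_p_bar:g}",
            "r_bar": 1.0,
            "l_p_bar": l_p_bar,
            "lattice": "square",
            "phi": 0.7,
            "v_g": 1.0,
            "psi_deg": 45.0,
            "t_total": 3000.0,
        }
    for delta in (0.3, 0.7):
        fixtures[f"sorting_delta{delta:g}"] = {
            "label": f"chirality sorting, parallelogram delta={delta:g}",
            "r_bar": 1.5,
            "l_p_bar": 100.0,
            "handedness": -1,
            "lattice": "parallelogram",
            "phi": 0.7,
            "delta": delta,
        }
    paths = []
    for name in sorted(fixtures):
        path = out / f"{name}.yaml"
        save_config(fixtures[name], path)
        paths.append(path)
    return paths
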