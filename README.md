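# capsim

Brownian-dynamics simulation and analysis of **chiral active particles
(CAPs)** — circle-swimming microparticles — moving through periodic
lattices of disk obstacles.  The package is aimed at active-matter
researchers studying how environmental geometry (lattice type, density,
and mirror symmetry) shapes the transport of circle swimmers, and at
anyone designing passive obstacle arrays that sort particles by activity
or by handedness.

## Model

A CAP is an overdamped point particle self-propelled at speed `v0` along
an orientation θ that rotates at a constant signed angular velocity `ω0`
(counter-clockwise positive) and diffuses rotationally with coefficient
`Dr`:

    dr/dt = v0 p̂ + v_g ê + F_wall,      p̂ = (cos θ, sin θ)
    dθ/dt = ω0 + √(2 Dr) ξ(t)

Hard disk obstacles of effective radius `R` cancel the inward normal
component of the velocity, so particles slide along obstacle surfaces and
leave tangentially.  In free space the particle orbits at radius
`r = v0/|ω0|` and its long-time diffusivity is

    D = v0²/(2 ω0) · Ω/(1 + Ω²),   Ω = Dr/ω0 = r/l_p,

maximal at Ω = 1 (`l_p = v0/Dr` is the persistence length; `ω0 = 0`
recovers the achiral active Brownian particle with `D = v0²/2Dr`).
Everything is computed in reduced units `v0 = R = 1`, leaving two
dimensionless knobs: orbital radius `r̄ = r/R` and persistence length
`l̄_p = l_p/R`.

The analysis suite measures, on simulated trajectory ensembles:

* long-time effective diffusivity `D_eff` from the MSD and the relative
  diffusivity `Ψ = ln(D_eff/D)` (enhancement vs suppression by the
  lattice);
* sliding/hopping decomposition (`μ = t_slide/t_hop`) and surface
  reversal counts `N`;
* directional locking under a uniform drift: migration angle
  `α(ψ) = atan2(⟨v_y⟩, ⟨v_x⟩)`, plateau detection, and locking strength
  `ε = ∫₀^{π/2} (α−ψ)² dψ`;
* chirality sorting in sheared ("parallelogram") lattices whose rows are
  shifted by `δ·d`, including the purely geometric lattice-asymmetry
  score `A_max(δ)` (best mirror-overlap of the unit-cell triangle across
  45° and 90° axes).

## Worked example

Clockwise and counter-clockwise swimmers in a mirror-symmetry-broken
lattice (shear δ = 0.3, packing fraction φ = 0.7):

```python
import numpy as np
from capsim import CAPParams, SimConfig, build_lattice, simulate
from capsim.observables import measure_diffusivity

lattice = build_lattice("parallelogram", phi=0.7, delta=0.3)
cfg = SimConfig(dt=2e-3, t_total=2e4, n_particles=24, seed=42,
                record_stride=500)

for hand, name in [(-1, "CW "), (1, "CCW")]:
    params = CAPParams.from_reduced(r_bar=1.5, l_p_bar=100, handedness=hand)
    traj, events = simulate(params, lattice, cfg)
    res = measure_diffusivity(traj)
    print(f"{name}: D_eff = {res.D_eff:.4f} ± {res.D_se:.4f}  "
          f"(free-space D = {res.D_free:.4f}, Psi = {res.Psi:+.2f})")
```

```
CW : D_eff = 0.0171 ± 0.0013  (free-space D = 0.0112, Psi = +0.42)
CCW: D_eff = 0.0357 ± 0.0054  (free-space D = 0.0112, Psi = +1.16)
```

The two handednesses differ only in the sign of `ω0`, yet the CCW
particle diffuses about twice as fast in this δ = 0.3 lattice — the lattice
itself is chiral, and its handedness couples to the particle's.  A
mirror-image lattice (δ = 0.7) exactly swaps the two numbers, which is
the basis for sorting mixed CW/CCW populations by letting them spread at
different rates.

The command-line interface exposes the sweep pipelines
(`capsim diffmap`, `capsim packing`, `capsim locking`, `capsim sorting`,
`capsim asymmetry`, `capsim fixtures`, `capsim simulate`); each writes a
tidy CSV plus a JSON metadata sidecar with seed provenance.

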