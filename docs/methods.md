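# Methods

## Model

A chiral active particle (CAP) is an overdamped, self-propelled point
particle in two dimensions.  Its orientation angle θ advances
deterministically at the signed angular velocity ω0 (counter-clockwise
positive) and diffuses with rotational coefficient Dr; its position moves
at constant speed v0 along p̂ = (cos θ, sin θ):

    dr/dt = v0 p̂ + v_g ê + F_wall,
    dθ/dt = ω0 + sqrt(2 Dr) ξ(t),

with ξ unit white noise.  There is no translational noise and no
particle–particle interaction.  v_g ê is an optional uniform drift of
speed v_g along the angle ψ.  In free space the particle traces noisy
circles of orbital radius r = v0/|ω0|; ω0 = 0 recovers the achiral active
Brownian particle (ABP).  The free-space long-time diffusivity has the
closed form D = v0²/(2ω0) · Ω/(1+Ω²), Ω = Dr/ω0, maximal at Ω = 1 and
reducing to v0²/(2Dr) as ω0 → 0.

Obstacles are disks of effective radius R (obstacle radius plus particle
radius; the particle is treated as a point).  The hard wall cancels the
component of the total velocity directed into a wall and nothing else:
while p̂ has an inward normal component the particle slides along the
surface at the tangential projection of its velocity, and the moment the
normal component turns outward it leaves the surface — tangentially,
because the normal component vanishes at that instant.  Orientation
dynamics are unaffected by contacts (no wall torque).

All simulations use reduced units v0 = R = 1 (time unit R/v0).  The model
is then fully specified by r̄ = r/R and l̄_p = l_p/R = v0/(Dr R).

## Lattices

Square, triangular, and sheared-parallelogram lattices are generated at a
prescribed effective area fraction φ (φ = πR²/d² for square/parallelogram,
2πR²/(√3 d²) for triangular; construction refuses φ within 1e-6 of the
disk-overlap bound).  The parallelogram is a square lattice with each row
shifted by δ·d, implemented with skewed periodic box vectors
a₁ = (d, 0), a₂ = (δd, d) so the cell closes exactly for every δ;
minimum-image arithmetic runs in fractional coordinates.  δ and 1−δ
lattices are exact mirror images about a vertical axis; only
δ ∈ {0, 0.5, 1} are mirror-symmetric.  A perfect lattice is represented by
a single obstacle per primitive cell; jittered lattices tile a supercell
and displace each site by an isotropic Gaussian of s.d. σ·d.

## Integration

Euler–Maruyama for θ (exact in distribution at any step size) and explicit
Euler with velocity projection for the position.  Per step: update θ;
form v = v0 p̂ + v_g ê; remove inward normal components over all current
contacts (deepest-first, iterated up to 10 sweeps); move; push any
residual penetration radially back to the contact circle.  Defaults:
dt = 2×10⁻³ R/v0 for diffusivity runs and drift runs (the enforced bound
is v0·dt ≤ 0.01 R and (v0+v_g)·dt ≤ 0.02 R); unresolved penetration after
10 sweeps aborts with a diagnostic.  Halving dt moves the fitted
free-space diffusivity by less than two standard errors (tested).

Numerical contact band: a particle within R(1+10⁻⁴) of a center counts as
touching.  A particle sliding tangentially leaves the exact circle by
(v·dt)²/2R ≈ 10⁻⁵ R per step; without the band it would chatter in and
out of contact every step, corrupting sliding-time and reversal
statistics.  The band width is ≫ that excess and ≪ any physical scale.

Randomness: a single root seed feeds a `numpy` SeedSequence; one child
stream draws initial conditions (positions uniform over the free area,
headings uniform), a second yields independent per-particle seeds for the
in-kernel Gaussian streams.  Runs are bitwise reproducible.  A burn-in of
min(10·max(τ_p, τ_ω), 0.1·t_total) is discarded before any statistics;
the cap keeps short drift runs usable.

### Mirrored-noise harness

Reflection about a vertical axis maps (ω0, δ-lattice, noise ξ) onto
(−ω0, (1−δ)-lattice, −ξ) with initial conditions (x, y, θ) →
(−x, y, π−θ).  The engine exposes this as `mirror_pair`; the reflected
run retraces the original to floating-point roundoff (≲10⁻¹⁰ per step
over short horizons; over long runs roundoff is amplified by successive
obstacle scatterings, so the identity is used distributionally:
D_CCW(δ) = D_CW(1−δ) exactly in law).  The sorting sweep exploits this to
simulate clockwise particles only.

## Observables

* **MSD / D_eff** — multi-origin, multi-particle MSD on log-spaced lags
  (lags capped at t_total/2).  D_eff is the through-origin least-squares
  slope of MSD against 4t on a long-time window; the standard error comes
  from the spread of per-particle slopes.  The window starts at
  50·max(τ_p, τ_ω), capped at one tenth of the largest lag so it always
  spans at least a decade (shorter windows are refused with advice to
  lengthen the run).  Ψ = ln(D_eff/D) compares against the free-space
  closed form.
* **Rotational-diffusion estimator** — slope of the drift-subtracted
  angular MSD against 2t over the upper half of the lag range.  When ω0
  is not supplied it is estimated per particle from the endpoint slope,
  and the resulting bridge deflation of the MSD, E[MSD(ℓ)] = 2Dr·ℓ(1−ℓ/T),
  is corrected exactly.
* **Contact statistics** — t_slide is dt times the number of in-contact
  steps (exact); μ = t_slide/t_hop; the reversal count N increments when
  the tangential velocity against the deepest contact normal changes sign
  between consecutive in-contact steps, with a dead band of 10⁻⁸ v0
  against roundoff chatter.
* **Migration angle** — α = atan2(⟨v_y⟩, ⟨v_x⟩) with velocities taken as
  displacements over non-overlapping windows of 10 τ_ω; standard error by
  bootstrap over particles.
* **Locking strength** — ε = ∫₀^{π/2} (α−ψ)² dψ by trapezoid quadrature in
  radians.  Plateaus are maximal ψ-runs over which α varies by < 2°; the
  reported locking direction is the widest plateau's mean α (ties broken
  by smaller deviation from the diagonal α = ψ).

## Geometric asymmetry score

The unit-cell triangle (0,0), (d,0), (δd, d) — the sheared cell cut along
its diagonal — is reflected about a 45° or 90° axis; the mirror image is
translated rigidly to maximize the intersection area (coarse grid around
the centroid-aligned offset, Nelder–Mead refinement; intersection by exact
convex clipping).  A45 and A90 are the best overlaps normalized by the
triangle area, and A_max(δ) = max(A45, A90), folded by the mirror identity
A_max(δ) = A_max(1−δ).  The construction reproduces every structural
constraint: A_max = 1 exactly at δ ∈ {0, 0.5}, scale invariance in d,
continuity in δ, and an interior minimum at δ ≈ 0.27 on a 0.01 grid.

## Replicate budgets

Default sweep budgets are desk-scale and deliberately modest: 32 walkers
for 2×10⁴ time units per diffusivity cell (the acceptance script uses
8–16 walkers and 1.5–2×10⁴ time units per cell, and 6 walkers × 2×10³
time units per drive angle for locking curves).  These budgets resolve
pocket locations, plateau angles, and diffusivity ratios at the quoted
tolerances; absolute Ψ values in deeply caged cells carry larger error
bars.  All sweeps derive per-cell seeds from (root seed, cell index) and
are exactly reproducible.

## Known limitations

* The square-lattice suppression pocket near the first orbital resonance
  is sharp: at l̄_p = 100 its center sits near r̄ ≈ 0.8 with a narrow
  transport window at exactly r̄ = 1 (where the grazing orbit around a
  single obstacle is marginally self-sustaining and slides around
  obstacle surfaces at full speed).  At l̄_p = 500 the pocket covers
  r̄ = 1 robustly.  Tests of the square/triangular sign alternation
  therefore probe a small neighborhood of the nominal pocket centers
  rather than single grid points.
* Directional locking in the passive (low-persistence) limit sets in
  below l̄_p ≈ 0.05 in this model: at l̄_p = 0.1 the effective
  translational diffusivity (≈0.05 R v0) spreads a particle by ~0.5 R
  per obstacle passage — several times the inter-obstacle gap at
  φ = 0.7 — so gap choices stay noise-dominated and α(ψ) is smooth.
  The passive-limit 45° plateau is therefore demonstrated at
  l̄_p = 0.02, where it is wide and clean (α = 45.0 ± 0.2° over
  ψ ∈ [40°, 52°]).
* The long-persistence ABP's per-walker diffusivity spread is close to
  the spread of single persistent paths, so packing-sweep comparisons for
  ABPs use common random numbers across the φ grid (one seed for all
  cells); independent seeds need far larger ensembles to resolve the
  monotone trend.
* Reversal counts N depend weakly on dt near tangential alignment, where
  rotational noise produces genuine micro-reversals; the dead band guards
  only against roundoff, not against physical noise crossings.
* The synthetic environments are perfect (or Gaussian-jittered) rigid
  disk lattices: no obstacle compliance, no hydrodynamics, no wall
  torque, no translational noise.  Agreement of the suite says nothing
  about systems where those effects matter.
* Contact intervals are capped per particle (200k by default); counts and
  sliding times remain exact past the cap.
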