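# Model and methods

## The cell-centre model

An epithelial monolayer is represented by the centres of its cells,
`r_i`, in two dimensions.  Connectivity is the Delaunay triangulation of
the centres, recomputed every time step, so neighbour exchanges (T1
transitions) happen implicitly whenever cell motion flips a Delaunay
edge.  Each Delaunay edge is a harmonic spring of rest length `a0` with
a piecewise stiffness: compressed springs (`delta = |r_j - r_i| - a0 <= 0`)
have stiffness `k_c` (bulk cell stiffness), stretched springs have
stiffness `k_t` (cell–cell cohesivity), and a spring whose deformation
exceeds `d_max = 1.3 a0` transfers no force (the adhesion is broken).
An alternative convention, cutting on the separation rather than the
deformation, is available as `ModelParams(cutoff_on="separation")`; the
deformation reading is the default.

Cells are self-propelled, overdamped particles:

    v_i = v0 p̂_i [motile] + mu F_i,

where `p̂_i` is the unit polarization (front–rear axis), `v0` the motile
speed and `mu` the substrate mobility.  The polarization relaxes toward
the velocity direction at rate `xi`:

    dp̂_i/dt = xi (p̂_i × v̂_i · ẑ) p̂_i⊥,

equivalent to `dθ/dt = -xi sin θ` for the angle θ between `p̂` and `v̂`.
No angular noise is included.  Confinement (disc or annulus) is a soft
wall: a centre that crosses the pattern edge feels a linear restoring
force of stiffness `3 k_c` toward the allowed region.

Positions advance by forward Euler with `dt = 0.001`; the polarization
is renormalized each step (the update preserves the norm only to first
order).  The per-step order is forces → velocities → positions →
polarization (with the just-computed velocities) → cell cycles →
division check → re-triangulation.  A convergence test in the suite
verifies first-order accuracy on a smooth fixture.

Units: lengths in `a0`, time in `a0/v0`, force in `v0/mu`.  With the
physiological anchors `a0 = 20 um`, `v0 = 20 um/hr` and substrate drag
`zeta = 100 pN hr/um^3`, the mobility is `mu = 1/(zeta a0^2) =
2.5e-5 um/(pN hr)`, one time unit is one hour and the force unit is
`8e5 pN`; a non-dimensional stiffness `k̄ = 1–10` maps to
`0.04–0.4 N/m`, comparable to the thin-plate estimate
`k = E h / (2 sqrt(3) (1 - nu)) ≈ 0.03 N/m` for `E = 10 kPa`,
`h = 5 um`, `nu = 0.5` (`camsim.theory.dimensionalize`).

## Protocol of a run

1. `n` centres are placed uniformly at random in the domain (rejection
   sampling; no minimum spacing — overlaps relax out).
2. The packing equilibrates passively (`v0` treated as 0) until every
   speed `|mu F_i|` falls below `tol = 1e-3` (in `v0` units), with a cap
   of 1e6 steps.  During this phase the triangulation is rebuilt
   whenever any centre has moved more than `0.005 a0` since the last
   build — the triangulation cannot change while points are still —
   which keeps the long overdamped tail of the relaxation cheap without
   altering the trajectory materially.
3. Motility is switched on with polarizations at independent random
   angles; the production clock starts at 0.  During production the
   triangulation is rebuilt every step (`triangulation_stride = 1`).
4. Timed events fire on the production clock: enabling the division
   clock, removing the confinement, locking/releasing the edge list.
5. Frames (positions, polarizations, velocities, IDs) are recorded every
   100 steps (0.1 time units) and the metric series is computed on the
   recorded frames.

Runs are bit-reproducible from (config, seed): one `numpy` Generator
drives placement, polarization angles, cycle assignment and division
directions, in that order.

## Division

A cell carries a cycle number in [0, 1] advancing by `dt / T_div`
(`T_div = 24` hours).  On reaching 1 it divides, provided its Voronoi
area exceeds a critical area; undersized cells stay saturated and retry.
The two daughters are placed at `±a0/4` along the major principal axis
of the mother's Voronoi polygon (eigenvector of the larger eigenvalue of
the area second-moment tensor about the centroid), receive equal and
opposite polarizations along a fresh random direction (or two
independent random directions under the alternative policy), inherit
motility and mobility, and restart the cycle at 0.  Division stops when
the population reaches `n_cap` (default 80); excess mature candidates
are deferred in cell-ID order.

Synchronous mode starts every cycle at 0 (all cells divide together one
`T_div` after the clock starts); asynchronous mode draws initial cycles
uniformly from [0, 1), spreading divisions over one `T_div`.

The division presets (annulus `R = 5`, `R_in = 3.5`, 40 → 80 cells,
`k_c = 5`, `k_t = 1`) set the critical area to a quarter of the relaxed
hexagonal cell area, `0.25 · (sqrt(3)/2) a0²`.  With the larger gate of
half the hexagonal area the crowded annulus stalls below the cap and
"synchronous" divisions smear over many hours, which defeats the purpose
of the protocol; the quarter gate lets every cell divide while still
refusing pathologically squeezed ones.  The clock start also differs by
mode: the synchronous clock may start at t = 5 (its divisions fire a
full `T_div` later, at t = 29, well inside steady rotation), while the
asynchronous clock starts at t = 25 because its first divisions fire
immediately and the annulus rotation at these parameters only settles
by t ≈ 20–25.  The before/after rotation signs are medians of the mean
vorticity over windows just before the first possible division and over
the last 5 time units of the run; a median magnitude below 0.05 (a
quarter of the typical steady value) yields no sign — the direction was
not established — and such runs are excluded from the flip statistic
rather than mis-scored as reversals.

## Metrics

The velocity gradient is estimated per Delaunay triangle from linear
interpolation of the three nodal velocities, which reproduces any
affine field exactly.  Mean vorticity is the area-weighted average of
`ω = ½(∂v_y/∂x − ∂v_x/∂y)` (counter-clockwise positive); for an annulus,
triangles whose centroid falls in the lumen are excluded.  The principal
shear rate is half the difference of the eigenvalues of the symmetric
rate-of-deformation tensor.  The velocity correlation function is the
angular-averaged autocorrelation of velocity fluctuations (mean
subtracted), and the correlation length its first zero crossing (or the
maximum pair distance when there is none).  Fluidisation diagnostics:
triangle quality `Q = 4 sqrt(3) A / Σ l²` (1 for equilateral), the
spring-length distribution and its Pearson second skewness coefficient
`Sk2 = 3(mean − median)/std` (set to 0 when the spread is numerically
degenerate), per-frame T1 counts, mean radial distance and centroid
drift.

Voronoi polygons are computed with a ring of dummy points at `R + a0/2`
(and `R_in − a0/2` inside an annulus) with angular spacing `a0/2`, and
clipped to the domain; dummy points never enter the dynamics.  Polygons
whose vertices are all strictly inside the domain skip the clipping
(the outer circle is convex; near the inner rim a safety margin of
`0.1 a0` accounts for chord sag).

## Continuum oracles

Treating the rotating tissue as a linear, isotropic elastic sheet driven
tangentially, torque balance with zero rim traction gives
`ω = 4 v0 / (3R)`.  The steady displacement is `u_r = 0`,
`u_θ = [v0 ρ (1+ν) R² / (3 E h μ)] s²(s − 2)` with `s = r/R`, and the
internal shear `τ_rθ = (v0 R / 3 μ_s) s(s − 1)` peaks at `r = R/2` with
`τ_max = v0 ρ R / 12 μ`.  (The cubic form of `u_θ` is fixed by requiring
consistency with the shear expression, which the suite verifies by
finite differences.)  In the fully fluidised limit the rim moves at `v0`
and the mean vorticity is `v0/R`.  For an annulus, Stokes' theorem gives
`ω_mean = (R_out v_out − R_in v_in)/(R_out² − R_in²)` for any tangential
profile with those rim speeds.

## What the simulations show, and known deviations

The `N = 140`, `R = 5` disc preset rotates near-rigidly (linear speed
profile, alignment `p̂·v̂ ≈ 0.97`) at a steady rate ~11% below
`4 v0/3R`.  The deficit is exact, not numerical: summing `r × v` over
cells shows internal spring torques cancel pairwise and the wall torque
vanishes, so `ω = v0 Σ r_i (p̂·t̂)_i / Σ r_i²`.  Two physical effects
lower this below 4/(3R): (i) in steady rotation the polarization must
keep turning at ω, which requires a steady lag angle with
`sin θ* = ω/ξ`, reducing the tangential drive by `cos θ* ≈ 0.97`; and
(ii) the slight outward tilt of the lagged polarization presses cells
against the soft wall, skewing the density outward so that
`Σ r / Σ r² < 4/(3R)`.  Both factors are reproduced quantitatively by
the torque-balance identity evaluated on simulation frames.  The
`N = 170` preset fluidises: rim speed saturates at `v0`, the vorticity
ratio `|ω| R/v0` falls to ≈ 1 (the fluid value), shear rate, low-quality
triangles and spring-length skewness all increase.

## Problem sizes

Defaults were chosen to keep a full verification run at desk scale: the
solid disc preset runs 40 time units (steady state from t ≈ 10) and the
dense one 60 (coherence onset is slower at high density); the division
batches use 6 seeds per mode; the chirality split uses 20 seeds of an
8-time-unit run (the rotation direction is set early in the transient).
The division-reversal fraction at 6 seeds carries a binomial standard
error of ~0.2, so it is a coarse estimate of the underlying ~0.6
probability; the asynchronous null (no flips) is insensitive to the
replicate count.  The invasion presets keep the confinement-removal
time at t = 50; the suite's stiff-vs-soft invasion contrast runs a
scaled variant (removal at t = 22, horizon 36) since the contrast is
established within a few time units of removal.  The size sweep runs
at R = 10 (N = 520) rather than R = 15 (N = 1170).

## What the generator does not emulate

No polarization noise, no cell death or extrusion, no growth of the
rest length over the cycle, no mechanochemical feedback on cycle
progression, no substrate-stiffness or contractility effects, no
hydrodynamic coupling through the medium, and only circular/annular
(or removed) confinements.  Passing tests therefore certify the model's
internal consistency and its stated collective phenomena, not agreement
with any particular experimental monolayer.
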