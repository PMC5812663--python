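# Methods

## The model

`mtcortex` simulates the collective self-organization of plant cortical
microtubules (MTs) on the inner surface of a cell, represented as a closed
triangulated 2-manifold embedded in 3D.  MTs are inextensible polymer lines
confined to the surface.  Each MT has a plus end that switches stochastically
between growth (speed `v_plus`) and shrinkage (`v_minus`) — dynamic
instability, with spontaneous catastrophe rate `r_c` and rescue rate `r_r` —
and a minus end that retracts steadily at the treadmilling speed `v_tm`.
New MTs nucleate at rate `r_n` per unit area, at positions uniform over the
surface and directions uniform in angle.  MTs that shrink to zero length are
removed.

MT–MT interactions follow the "survival of the aligned" collision rules.
When a growing plus end meets another MT at an in-plane angle θ (taken acute):

* θ < `theta_zip` (default 40°): *zippering* — the tip bends and continues
  parallel to the obstacle, choosing the sign that minimizes turning;
* θ ≥ `theta_zip`: with probability `p_ic` an *induced catastrophe* (the tip
  switches to shrinkage), otherwise a *crossover* (the tip passes over
  unchanged).

The 40° threshold is the classic observational boundary between the shallow
and steep collision regimes.  The steep-angle split is not uniquely fixed by
observation; the default `p_ic = 0.5` follows the convention of the
event-driven cortical-array modelling framework this simulator builds on.
Zippering is strict (`θ < theta_zip`); the boundary angle itself goes to the
steep branch.

### Geometry: charts, transitions, geodesics

Each triangle is mapped isometrically to the x–y plane by a rotation
(stored as a quaternion) taking its outward normal to +z, plus a
z-translation.  Charts are mutually disjoint; all inter-triangle geometry is
carried by per-edge transition maps.  The transition for the ordered pair
(source, target) translates a point on the source chart's image of the
shared edge to the same barycentric position on the target chart's image and
rotates directions by the signed angle θ_R between the two edge images.
Because both charts are positively oriented, continuing a ray straight
through this map realizes the geodesic (locally straightest) continuation:
the lifted 3D polyline makes equal angles with the shared edge on both
sides.  This is verified against a brute-force planar-unfolding oracle in
the test suite (deviation < 1e-8 rad over random 10-triangle chains).

Only the magnitude of θ_R is fixed by the edge-vector inner product; its
sign is determined by the signed 2D angle, which the equal-angle test pins
to the geodesic continuation.

MTs are stored as chains of straight 2D segments, one per triangle.
Lifting applies the inverse chart rotation; segments of one MT meeting at a
shared edge reconnect exactly in 3D.

### Event-driven scheduling

The simulation is exact event-driven (no time stepping):

* **Stochastic events** (nucleation, spontaneous catastrophe, rescue) form a
  Poisson process with total rate R = r_n·A + Σ_growing r_c(face) +
  n_shrinking·r_r.  The next stochastic time is drawn fresh from Exp(R)
  after every state change, which is statistically exact by memorylessness.
  Catastrophes are attributed to growing tips proportionally to their
  face-specific r_c.
* **Deterministic events** — collisions, triangle-edge crossings, a
  shrinking tip reaching a segment junction, the minus end exhausting the
  oldest segment, disappearance, and measurements — are predicted exactly
  from the piecewise-linear motion and kept in two priority queues.

All growing tips share the same effective growth speed, so tip-growth events
are queued against the common growth-distance coordinate
W(t) = ∫ v_plus_eff dt rather than in real time; all other events are queued
in real time.  Scheduled growth events remain exact when v_plus_eff changes
(finite tubulin pool), at O(1) cost per change.  Events carry per-MT epoch
counters; any state change of an MT bumps its epoch and invalidates its
pending events, which are skipped lazily when popped.

Collision candidates are intersections of the growing tip's ray with the
trajectory lines of the segments resident in the *same triangle* (the
locality that makes the method fast on fine meshes).  Candidates are pruned
by two safe bounds — a frozen segment's final extent, and a reachability
bound exploiting that no frontier can outrun the shared growth speed — and
re-validated against the obstacle's occupied extent when they come due, so
false collisions are impossible and none are missed.  When a new segment is
created in a triangle, candidates are issued for the growing tips already
resident there.  Exactly parallel (bundled) trajectories never produce
candidates; bundles have zero thickness.

### Edge-catastrophes and face stability

Cell edges (tagged shared edges with a dihedral angle) can kill growing tips
that cross them:

* `constant_per_class`: catastrophe with a fixed probability per edge class
  (e.g. P_transverse / P_longitudinal for the cube's edge groups);
* `bending_angle`: catastrophe with probability
  min(1, E_cat · θ_b / (π/2)), where θ_b is the 3D bending angle between
  the incoming and outgoing lifted directions at the crossing.  θ_b depends
  on both the local dihedral and the incidence angle; it vanishes on flat
  edges, so triangulation edges inside a flat face never trigger
  catastrophes.  The linear-in-θ_b law is the simplest form that is zero on
  flat edges and increases monotonically with local bending; the constant
  per-class model is used where explicit probabilities are prescribed.

Untagged edges never trigger catastrophes, and minus ends never do — the
rule concerns growing plus ends only.

Face-specific MT stability is expressed as per-face-tag overrides of `r_c`;
a growing tip adopts the local rate the moment it crosses into a triangle
with a different face tag.

### Finite tubulin pool

With a finite pool density `rho_tub` (µm of polymer per µm² of surface), the
growth speed is homeostatically reduced: v_plus_eff = v_plus × free/(rho_tub·A),
recomputed at every event (piecewise-constant between events).  Polymer and
free pool are bookkept analytically from per-MT offsets, so conservation
polymer + free = rho_tub·A holds to floating-point accuracy at all times;
tests assert it to 1e-6 µm.  The linear law is the simplest homeostatic
feedback with the required qualitative effect (faster relaxation to steady
state, effective control parameter shifted to more negative values).
Nucleation attempts with an exhausted pool are no-ops.  `v_minus` and `v_tm`
are not modulated by the pool.

### Numerical choices

* Geometric tolerance 1e-9 µm throughout; degenerate triangles
  (area < 1e-12 µm²) are rejected at load.
* A tip whose edge-crossing point falls within tolerance of a mesh vertex is
  routed deterministically through the same edge with the crossing point
  clamped at least one tolerance inside the edge interior (counted in
  `counters["vertex_clamp"]`).  This moves the crossing by ≤ 1e-9 µm and
  avoids the undefined vertex transition.
* Nucleation selects the triangle with probability proportional to its
  *area* (spatially uniform nucleation).  Selecting triangles uniformly
  regardless of area would bias nucleation density on irregular meshes; a
  `nucleation_weighting="triangle"` mode is retained for comparison.
* Meshes are re-wound to consistent outward orientation on construction, so
  every chart has positive 2D winding and collision angles are unambiguous.
* Identical (surface, parameters, seed) reproduce the identical event
  sequence bit-for-bit; ensemble realization *i* uses seed base_seed + i.

## Order metrics

The global order tensor is Q = 3⟨û ûᵀ⟩_L − I with the length-weighted
average over the 3D unit directions of all MT segments at measurement time
(nematic: û ≡ −û).  The scalar order parameter Q⁽²⁾ is the absolute value
of the smallest eigenvalue; the director Ω̂ is the corresponding unit
eigenvector.  This normalization is the unique traceless form with
Q⁽²⁾ = 0 for isotropic 3D directions and Q⁽²⁾ = 1 for any perfectly planar
arrangement, with Ω̂ normal to the array plane.  Ω̂ is sign-canonicalized
(first nonzero component positive) for serialization only.

For the cube, C⁽²⁾ = Ω_z² − (Ω_x² + Ω_y²)/2 = (3Ω_z² − 1)/2 scores the
orientation: +1 transverse (array wrapping the top–bottom axis), −1/2
longitudinal.  Outcomes are classified with thresholds at the midpoints
between the anchors: transverse if C⁽²⁾ > 0.5, longitudinal if C⁽²⁾ < −0.25,
otherwise "other".

The control parameter of interaction-driven ordering is

    G = −l_0 / l_avg,
    l_0   = (2 (v₊−v_tm)(v₋+v_tm) / (r_n (v₊+v₋)))^{1/3},
    1/l_avg = r_c/(v₊−v_tm) − r_r/(v₋+v_tm),

the ratio of the MT–MT interaction length to the interaction-free mean MT
length; G < 0 is the bounded-growth regime.  Scenario presets set r_c
through the target l_avg (the `rc_for_mean_length` inverse) rather than as a
raw rate.

## Study conditions (scenario presets)

Shared single-MT dynamics: v₊ = 0.08, v₋ = 0.16, v_tm = 0.01 µm/s,
r_r = 0.007 s⁻¹, r_n = 0.01 s⁻¹µm⁻² — the standard values of the
event-driven cortical-array framework with the nucleation rate raised to
give sufficiently many MTs on embryonic-cell-sized surfaces.

* **Sphere working point**: radius 6 µm (icosphere, T = 1280 by default),
  l_avg = 417.5 µm (r_c ≈ 0.00305 s⁻¹, giving l_0 ≈ 2.15 µm and
  G ≈ −0.005), tubulin pool rho_tub = 10 µm⁻¹.  Under these conditions the
  array orders robustly; the steady plateau of Q⁽²⁾ is ≈ 0.70, reached after
  roughly 2–4 h of biological time.  Because Q⁽²⁾ fluctuates by a few
  hundredths in steady state, the steady-state estimate is the time average
  over the final third of a run.
* **Cube**: side 15 µm, 24 triangles (each face split into 4 by its
  diagonals), infinite pool, constant per-class edge-catastrophe
  probabilities on the 12 cube edges (8 transverse bordering top/bottom,
  4 longitudinal on the sides).  At P_⊥ = P_∥ = 0.26 the final C⁽²⁾
  distribution is bimodal (≈1 and ≈−1/2), the two longitudinal orientations
  together being favoured ≈2:1 over the transverse one; scanning P_⊥
  downward at fixed P_∥ = 0.26 switches the array from transverse lock-in to
  exclusively longitudinal outcomes.
* **Rounded cuboid**: 13 × 7.5 × 5 µm, edge rounding 1 µm, T ≈ 1280,
  rho_tub = 10 µm⁻¹, default dynamics as the sphere.  The simulated mean MT
  length settles at l̄ ≈ 4.5 µm, making MTs sensitive to both edge and shape
  effects.  Variants: bending-angle edge-catastrophes on the rounded strips
  (E_cat = 0.5), and face stabilization ("protected" a×c faces: r_c raised
  on all other face tags to the value implied by l_avg = 40 µm, lowering l̄
  there to ≈ 3.5 µm).

## What the generators emulate — and what they do not

The mesh generators (sphere by four independent triangulations, cube,
rounded cuboid, sinusoidally lobed flat cell) produce idealized, tagged
closed surfaces standing in for segmented confocal reconstructions of real
cells.  The lobed-cell generator is explicitly synthetic: it mimics the
semi-2D, multi-lobed outline of leaf pavement cells but not their irregular
lobe shapes, thickness variation, or measured cell-edge angles.  Passing
tests on these geometries validates the geometric and stochastic machinery
and reproduces shape-effect phenomenology on idealized shapes; it does not
by itself establish quantitative agreement with microscopy of real cells.

## Problem sizes

Production-style runs use 10 h of biological time (36 000 s) and ensembles
of hundreds of realizations.  The bundled test suite uses reduced study
sizes chosen so the full suite runs on a single CPU in well under half an
hour: ensembles of 5–12 realizations, durations of 1.5–5 h of biological
time (past the ordering transient of each geometry), and Wilson 95%
intervals for all outcome-fraction comparisons.  The bundled acceptance script runs
the sphere working point for 43 200 s (12 h) with 5 seeds, so that even the
slowest realizations are past the ordering transient, and estimates the
steady state as the time average over the final third of each run.
Micro-scenario equivalence against the brute-force fixed-timestep reference
simulator uses 10× scaled speeds so that the same geometry unfolds in an
8 s window at Δt = 1e-4 s.

## Known limitations

* Nucleation is unbound and isotropic: no MT-bound (branched) nucleation,
  no katanin severing, no plus-end pausing, no cell-cycle parameter
  schedules, no mechanical-stress coupling.
* The surface is a static template; growing cells are out of scope.
* The bending-angle edge-catastrophe law and the linear finite-pool
  feedback are the simplest forms consistent with the qualitative behaviour
  they implement; their exact functional forms are model choices.
* A segment that is shrunk back past a zippering junction and then regrows
  can extend beyond its previously frozen extent; collision candidates of
  *other* tips against that segment are not re-issued at that moment.  The
  configuration is rare and the effect is a missed collision opportunity,
  not a spurious event.
* With a finite pool, v_plus_eff is piecewise-constant between events
  rather than continuous; with event spacing of milliseconds-to-seconds the
  discretization of the pool feedback is far below statistical noise.
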