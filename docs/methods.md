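# Methods

## Model

The package simulates disorganized actomyosin structures with three coarse
elements, each built from cylindrical segments:

* **F-actin** — serially connected 140-nm segments with polarity (vertex 0
  is the barbed end).  Segments keep a harmonic rest length
  (`U_s = ½κ_s(r−r₀)²`), adjacent segments a harmonic straightening angle
  (`U_b = ½κ_b θ²`, θ measured from the straight configuration), and
  overlapping actin segment pairs repel harmonically below a 7-nm cutoff.
  The joint bending stiffness is not free: `κ_b,A = Lp·kBT/r₀` encodes the
  9-µm persistence length.  Each segment carries 20 discrete binding sites
  spaced 7 nm apart.
* **Cross-linkers (ACPs)** — a center vertex with two 23.5-nm arms.  An arm
  binds a site as a spring from the center to a material point of the
  segment (reaction shared between the segment endpoints by the site's
  axial fraction); a soft hinge straightens the two arms.  Links are
  permanent: once both arms are engaged they never release.
* **Bipolar motors** — a backbone of 42-nm segments with a central
  arm-free bare zone; every arm-bearing endpoint carries two arms, each arm
  lumping `N_h = 8` myosin heads.  Three architecture families are
  supported: more arms (`N_a`↑ at 42-nm spacing), a longer bare zone
  (`L_bz`↑, extra arm-free 42-nm segments in the middle), and wider arm
  spacing (`L_sp`↑, all segments lengthened).  The total length obeys
  `L_M = 2·L_sp·(N_a/4 − 1) + L_bz` exactly.

A bound arm is a two-spring element: a transverse spring restores the
anchor-to-site distance to 13.5 nm, and a longitudinal spring (rest
offset 0, "right angle") penalizes the axial slip of the attachment
relative to the foot of the anchor's perpendicular on the filament axis.
Both gradients are implemented exactly, including the axis-rotation couple
of the longitudinal term, so every force path passes a finite-difference
check against its potential at relative tolerance 1e-5.

## Dynamics

Vertices follow overdamped Langevin dynamics integrated with explicit
Euler at `dt = 1.15e-5 s`: `r(t+dt) = r(t) + (F + F^T)·dt/ζ`.  Drags come
from the approximate cylinder formula `ζ = 3πμ·r_c·(3 + 2r₀/r_c)/5`;
thermal forces have per-component variance `2kBT·ζ/dt`
(fluctuation–dissipation), drawn as Gaussians per step.  Periodic axes use
the minimum-image convention everywhere — forces, binding searches and
force measurement; non-periodic axes carry harmonic repulsive walls.
Clamped vertices (the barbed ends in the two-filament assay) never move.
A per-step displacement above half an actin segment aborts the run as an
instability signal.

### Drag and stiffness scaling

With the time step fixed, explicit Euler is stable only for
`κ·dt/ζ ≲ 2`, while the wall-clock cost of reaching mechanical steady
state scales as `1/ζ` (the elastic take-up a motor must walk through is
`F/κ_s`, and the admissible `κ_s` is proportional to `ζ`).  The defaults
therefore use an elevated effective medium drag, `μ = 8.6 Pa·s`, with
proportionally stiff springs (`κ_s,A = 0.12 N/m`, backbone and linker arms
0.06 N/m, arm springs 0.01 N/m, repulsion/walls 0.02 N/m) — the same
stability ratios as at physiological drag, uniformly scaled.  Steady-state
forces, η, and every equilibrium observable (persistence length, thermal
variances, the form of the Einstein relation) are drag-independent;
filament sliding stays walking-limited (the drag-limited sliding speed,
~0.5 µm/s at typical force imbalances, is well above the 140 nm/s walking
speed), so the transients reported are motor-limited as intended.  Under
stall-level loads segments strain by a few percent at these stiffnesses.

## Motor mechanochemistry

Arms bind free sites within a capture radius `r₀,M2 + 2·(site spacing)
= 27.5 nm` of their anchor at rate `40·N_h = 320 s⁻¹`, with two
constraints: polarity alignment (the arm's walking direction — from its
anchor toward its backbone end — must have positive overlap with the
filament's barbed-end direction) and sibling exclusion (the two arms of
one anchor never bind the same filament).  Together these cap the arms
bound per filament at `N_a/4`.

Bound arms walk toward the barbed end in 7-nm site steps with the linear
force–velocity law `k_w(F) = (v₀/7 nm)·max(0, 1 − F/F_stall)`, where the
load `F` is the spring-force component opposing walking and
`F_stall = F_st·N_h = 45.6 pN` per arm; unloaded this gives 140 nm/s and
stalls at exactly 5.7 pN per head.  Unbinding is a catch bond,
`k_u(F) = max(k_u₀·e^(−F/F_cat), 10⁻³·k_u₀)` with `k_u₀ = 350 s⁻¹` and
`F_cat = 6 pN`.  This triple is pinned by three observables: the unloaded
duty ratio of an arm parked at a filament, `320/(320+350) = 0.48 < 0.5`
(myosin II is a low-duty-ratio motor); monotone load-stabilized release;
and a near-stall release rate of ~0.35 s⁻¹ so force-bearing arms hold for
seconds rather than churning.  The rate laws are a pluggable strategy
(`MotorKinetics`); the engine implements this default family and the
single-event reference path accepts arbitrary rate functions.

Event ordering within a step is binding → walking → unbinding, each with
its own exponential probability; at the default `dt` all per-tick
probabilities are ≪ 1 so the ordering is second-order.  Long production
runs evaluate kinetics every 4th step over `4·dt` (rates ≤ 350 s⁻¹, so
waiting times are vastly longer than the tick) — a pure performance
choice with no measurable effect on event statistics.

## Systems and initialization

* **Two-filament assay**: an antiparallel pair clamped by their barbed
  ends to the opposing z walls, 27 nm apart in x so a motor centered
  between them sits at both arms' 13.5-nm equilibrium.  Motors and
  cross-linkers are placed at uniform random z in the antiparallel
  overlap.
* **Bundle**: an `N_F × N_F` grid of lanes at 27-nm pitch (hence
  `2·N_F²` filaments, two per lane at random z offsets with random ±z
  polarity) in a fully periodic box.  The random offsets are conditioned
  on the bundle spanning the box (every z covered by at least two
  filaments, redrawn otherwise): a cross-section tension measurement
  presupposes a percolating structure, tension can only hand over between
  filaments where two coexist for a cross-linker to bridge, and short
  filaments at unlucky offsets would otherwise leave a gap instead of a
  bundle.  Motors run along z at random interior cell centers of the lane
  grid — 19.1 nm (diagonal) from the four surrounding lanes, all inside
  the arms' capture radius, so every motor can reach several filaments of
  each polarity; localized placement draws centers from a window of
  length `f·L_z` centered at the bundle midpoint, optionally conditioned
  on a minimum gap between motor spans (the sparse, non-overlapping
  regime of the 1/N_M efficiency law).
* **Network**: a thin quasi-2D sheet.  Filaments are grown by a
  nucleation/elongation process (constant nucleation rate; each barbed
  end elongates at `k_p`; growth stops at a target actin amount) with the
  rate ratio calibrated analytically so the mean final length is the
  requested one (`mean segments = sqrt(target·k_p/2k_n)`); they are laid
  out at their nucleation points with uniform in-plane orientations.

Cross-linkers are placed directly (distributionally equivalent to the
frozen-actin binding transient): random free site pairs on distinct
filaments whose separation is within 0.7–1.1 of the 47-nm rest span, the
center at the midpoint.  Every run then starts with a settling phase
(6×10³ steps with actin frozen — ample, as binding at 320 s⁻¹ saturates
within ~2×10³ steps) in which motor arms attach to the stationary
scaffold, before everything is released.

## Force measurement

Planes normal to the bundle axis every 200 nm (networks: 20 planes each
along x and y) collect the axial components of the *extensional* spring
forces of every crossing element — actin segments, linker arms, motor arms,
motor backbones — signed + for tension, with minimum-image-aware crossing
detection.  `F_tot` is the mean of the plane totals over planes and
steady-state frames.  The maximal motor force is
`F_M^max = ½·Σᵢ F_{M,z}ⁱ` (bundles; `¼·Σᵢ(F_{M,x}ⁱ + F_{M,y}ⁱ)` for
networks) with `F_{M,z}ⁱ` the summed |z components| of motor i's arm
spring forces; the efficiency is `η = F_tot / F_M^max`.  Bending forces
are excluded from the sums — at steady state the time-averaged plane
totals are nearly z-independent (a few percent relative spread for
cooperative two-filament seeds; up to ~20% where buckled inter-motor
regions reroute force through the motor backbones), confirming spring
forces carry the load.

Steady state is the earliest trailing window of ≥ 20 frames whose linear
trend, normalized by the window mean, changes by less than 1% over the
window; without one, the trailing 20 frames are used and flagged.

## Overlap theory

`L_c = 2·L_sp·(N_a/4 − 1)` is twice the arm-bearing length per side: two
motors overlapping by at least `L_c` present interleaved arm regions that
no cross-linker can separate, so their forces add.  The pair weight is 1
above `L_c`, `L_ov/L_c` for partial overlap, 0 for none.
`Ξ = max over motors i and sides j of (1 + Σ_k ξ_ik^j)`; the side rule —
only neighbors centered at-or-left (at-or-right) of motor i's bare-zone
center count for side L (R), neighbors spanning that center count for
both — is a package choice validated against an independent brute-force
enumeration.  For networks, motors pair only when their (sign-free) axes
differ by < 30°, with overlap measured along the pair's mean axis.  The
force prediction is `F_est = F_st·N_h·N_a·Ξ/2`.

## Desk-scale study conditions

The published experiments ran at cluster scale (19-µm filaments, bundles
to 98 filaments, motor counts to ~10³, tens of simulated seconds).  The
package's validation suite reproduces the mechanistic claims at desk
scale, with these stated sizes:

* Two-filament assay: 6-µm filaments in a 5×5×6 µm box (the pair overlaps
  over the whole box, keeping the motors' footprint a small fraction of
  the overlap, as at full scale) with 5 cross-linkers — the full-scale
  linear density of 16 per 18 µm of overlap.  20 seeds, 6 s each.
* Thin-bundle efficiency: N_F = 2 (8 filaments), 6-µm filaments in a
  14-µm periodic box, 4 motors anywhere (f = 1) conditioned on sparse
  placement (all circular gaps between motor spans ≥ 280 nm, so motors
  never overlap and every inter-motor gap holds cross-linkers), 100
  cross-linkers.  5 seeds, 5.5-9 s each.
* Persistence length: an ensemble of twenty 9-µm filaments initialized
  from the worm-like-chain equilibrium distribution (the dynamics must
  maintain it), > 2×10⁶ integrated vertex-steps in total, tangent
  correlation fit for s ≤ 0.7 µm — the range whose bending modes fully
  re-thermalize within the run at the elevated drag.
* Gliding velocity: ten walkers on one long filament, springs released
  (zero load) and unbinding disabled, 10 s.

The cluster-scale sweeps (N_F = 7 bundles, N_M to 1045, the network
N_M^0.65 scaling and the η ≈ 0.08 plateau) are *not* reproduced
numerically; their mechanisms are covered qualitatively by the overlap
theory's ensemble trends (localization, architecture comparison at fixed
length, near-linear large-N_M force growth), which the test suite checks
at theory level.

## What the synthetic systems do and do not show

The generators emulate the geometry and kinetics of reconstituted
actomyosin: discrete binding sites, bipolar motor architecture, permanent
cross-links, thermal bending.  They omit actin turnover, cross-linker
unbinding (slip or catch), motor self-assembly dynamics, hydrodynamic
coupling and excluded volume for non-actin elements — so passing tests
validate the force-generation mechanism under those idealizations, not
quantitative agreement with any particular in-vitro system.  Desk-scale
η values carry seed-to-seed spreads of a few hundredths; the two-filament
dichotomy sharpens as the overlap grows relative to the motor length.

## Numerical choices

* Bending gradient: exact analytic form with a series branch for
  near-straight joints (error < 2e-6 at the branch point) and the torque
  prefactor capped at its θ = π/2 value for folded joints.
* Segment–segment repulsion: exact closest-point algorithm on a Verlet
  list (cutoff + 15-nm skin) rebuilt whenever any vertex may have crossed
  half the skin; candidates are binned along the longest box axis.
  Coincident axes get a deterministic perpendicular tie-break.
* Segment rounding: `round(length/r₀)` segments at exactly the 140-nm
  rest length (9 µm → 64 segments, 19 µm → 136).
* One seeded generator per run; chunked execution derives independent
  sub-seeds per chunk, so identical seeds give bit-identical trajectories.
* Bare-zone realization: `ceil(L_bz/L_sp)` equal arm-free segments when
  the bare zone is enlarged; a single segment otherwise.
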