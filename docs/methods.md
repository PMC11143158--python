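# Methods

## Model overview

The package simulates single grid-cell firing as a coordinate
transformation.  Self-motion (speed, heading) is integrated in a place-cell
local frame; the resulting position is mapped into the cell's lattice space
by the inverse basis matrix and shifted by the cell's phase; the firing rate
is a decreasing sigmoid of the distance to the nearest integer lattice
point.  Nothing is learned: spacing, orientation and phase are parameters,
and the hexagonal pattern is a geometric consequence of the two basis
vectors being 60° apart.

Assumptions worth making explicit:

- Place frames are rigid (rotation + translation); no scaling or shear, and
  all geometry is 2D.
- One frame per compartment, anchored to that compartment's cues; the
  reference compartment's frame is identical to the global frame.
- Path integration is noiseless.  The model addresses where fields sit, not
  the accumulation of odometric error.
- The mechanism by which an animal detects that compartments are connected
  is not modelled; only the consequent frame adjustment is.

## Firing-rate function

The printed form of the rate in the source model is an unnormalised arctan
that is negative near field centers and does not lie in the stated [0, 1]
range, so this package uses the monotone-decreasing normalised form

    rate = clip(1/2 − arctan(κ (d/s − ζ))/π, 0, 1),

which preserves every stated property: range [0, 1], maxima exactly at the
preferred (integer-lattice) positions, ζ acting as the half-maximum
threshold, κ as the sharpness.  The lattice residual is likewise printed as
a squared norm but described as a distance; the Euclidean norm is used, with
`squared=True` available to reproduce the literal formula.  Rounding ties
(components at exactly .5) round away from zero, fixed for determinism.
Note that d is measured in lattice units and divided by s again, so the
relative bump size grows with spacing: at s = 1.5 the rate never falls
below ≈ 0.56 and the pattern is low-contrast, which is why map analysis
smooths before peak detection (below).

Component-wise rounding in the oblique basis can pick a lattice point that
is not the Euclidean-nearest in world space; this affects only far-from-
center positions where the rate is already near its floor, and the literal
rounding rule is kept.

## Frames and their adjustment

A `FrameTransform` stores (φ, ϖ) with the fixed convention
`apply(T, p) = Rot(φ)·p + ϖ`; matrix inverses that appear in the source
equations are absorbed as sign conventions on φ.  Frame differences wrap the
angle to (−π, π], which makes the angular decay well defined.

Adjustment: while the animal is inside a non-reference compartment, that
compartment's counter N_t increments by one per trajectory sample and its
frame takes one step `current − γ·(current − target)` in both angle and
translation, with γ = α/(β + e^{−ξ(N_t−M)}).  Both differences therefore
shrink by the factor (1 − γ) per step — monotone contraction, geometric
convergence once N_t ≫ M.  The difference is recomputed from the current
frames each step rather than frozen at its initial value.  In the
four-compartment arena each non-reference compartment has its own schedule
and counter, so compartments converge at different times depending on when
they were explored.  Convergence tolerances default to 10⁻³ rad and 10⁻³ m,
below the rate-map bin size.

Default schedules: two-compartment α = 0.5, β = 1.0, ξ = 0.1, M = 100 000
with cell G = [1.5, π/4, 0, 0]; four-compartment α = 0.8, β = 1.0, ξ = 0.2,
M = 100 000 with G = [1.0, π/4, 0, 0]; ζ = 0.4 and κ = 3.0 throughout.

## Environments

- `square`: 5 m × 5 m, frame origin at the (0, 0) corner.
- `circle`: radius 2 m, centred on the origin.
- `two_compartment`: two 5 × 4 m rooms separated by a 0.1 m wall, joined by
  an open 1 m corridor strip running along the top of both; both place
  frames share orientation 0 with origins at each room's left-bottom
  corner, so the frames differ by a pure translation.
- `four_compartment`: a 2 × 2 grid of 3 × 3 m rooms (0.1 m walls) joined by
  2 m doorways; frame origins at each room's corner with orientations 0°,
  90°, 180°, 270°, so both the rotation and the translation paths of the
  adjustment are exercised.

Corridor and doorway samples carry no frame of their own; they are handled
in the reference frame and excluded from rate-map comparisons.  Points on a
shared region edge are assigned deterministically to the lowest-indexed
region (compartments before corridors).

## Random-walk generator

The walk emulates rodent foraging: nominal speed 0.3 m/s with 20%
multiplicative Gaussian jitter (clipped at zero), dt = 0.1 s, heading
evolving as a wrapped Gaussian random walk with s.d. 0.15 rad per step, and
wall encounters resolved by following the wall at full speed along the
tangent closest to the heading (thigmotaxis), with a random heading re-draw
only when cornered.  The heading persistence and wall-following matter in
the multi-compartment arenas: a more diffusive walk mixes between
compartments so slowly that compartment occupancy over a bounded run is
extremely seed-dependent.  All draws come from one `numpy` generator seeded
per run; a trajectory is a pure function of (environment, parameters,
seed).

What the generator does **not** emulate: home-base behaviour, rearing and
pausing, speed–turning coupling, odometric noise, or any goal-directed
structure.  Passing tests therefore show that the model behaves as designed
under an ergodic, roughly uniform exploration pattern — not that it would
under the occupancy biases of real rodent data.

## Rate maps and estimation

Maps are occupancy-normalised means over half-open 0.1 m bins (≥ 10 bins
per spacing at the smallest spacing used).  The correlation of global fit is
the Pearson r between the map produced under the current (possibly
mid-adjustment) frames and the map of the same samples with every
compartment expressed in the reference frame, over jointly visited,
non-corridor bins.  It is ≈ 0-ish while patterns are locally replicated and
exactly 1 at convergence.

Peak detection smooths the map with an occupancy-weighted Gaussian (σ = 1.5
bins; numerator and denominator smoothed separately so unvisited bins do not
leak), takes 8-connected local maxima above a threshold (fixed 0.5, or the
smoothed map's mid-range for low-contrast fields), and refines each peak by
a 3 × 3 centre of mass.  Maxima within an `edge_margin` of the map boundary
can be dropped: bumps whose true centers lie outside the mapped region are
clipped at the edge and would otherwise masquerade as interior centers.

Lattice parameters are estimated from a center set in two stages: an
initial estimate (spacing = median nearest-neighbour distance; orientation
= circular mean of neighbour directions folded by the 6-fold symmetry;
phase = per-component circular mean of fractional lattice coordinates),
then two rounds of integer-index assignment and joint least-squares refit
of the basis and offset.  The refit removes the drift that a percent-level
spacing error accumulates across an arena and brings binned-map recovery
well inside one bin for spacings in [0.5, 2] m.

## Problem sizes and numerical choices

- Analytic checks (lattice geometry, hexagonality, frame identities) run at
  full precision with tolerances 10⁻⁶–10⁻¹²; ties and wrapping rules are
  fixed as described above.
- Single-cell and recovery analyses use 2–2.5 × 10⁵-step walks; recovery
  tests use an 8 m × 8 m arena so that even s = 2 m cells leave at least
  seven interior field centers after edge-margin filtering.
- Connected-environment experiments default to the full-length runs
  (770 000 / 833 000 steps, M = 100 000).  The `scaled()` preset divides
  step counts and M by 50 and multiplies ξ by 50, preserving the sigmoid's
  shape relative to the run; the convergence result depends only on that
  shape, not on absolute counts.  The test suite runs the scaled presets.
  The adjustment-off replication comparison uses a 10⁵-step walk so per-bin
  occupancy makes the aligned-map correlation stable.
- The experience-schedule exponent is clipped at 700 before `exp` to avoid
  overflow for naive (N_t ≪ M) states.

## Known limitations

- A single cell (or an independent list of cells) is simulated; there is no
  population coupling and no module structure along the dorsoventral axis.
- The model does not provide a metric readout (decoding position from
  rates); it generates patterns only.
- Corridor geometry in the connected arenas is plausible rather than
  prescribed; only the connection topology matters to the model, and the
  dimensions are configurable.
- The correlation-of-global-fit curve is step-like under the default
  schedules because the experience sigmoid is sharp relative to the run
  length (1/ξ ≪ M at either scale); a gentler ξ produces a gradual curve.
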