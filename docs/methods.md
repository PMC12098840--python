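# Methods

## Magnetostatic model

All circular-coil fields derive from the exact solution for a filamentary
circular loop in terms of the complete elliptic integrals K(m) and E(m)
(Smythe's form; `magstim/fieldsim/loops.py` states the expressions).  A
thick coil of rectangular cross-section is replaced by an `n_r x n_z` grid
of filaments at the cell centers, each carrying `turns*current/(n_r*n_z)`.
This mirrors the uniform-current-density assumption that 2D axisymmetric
FEM solvers make for stranded windings; the only approximation left is the
winding subdivision.  With the default 20 x 20 subdivision, refining to
40 x 40 moves the reported region homogeneities by less than 0.01
percentage points (a tested invariant), so discretization error is
negligible at the 1 mm sampling used throughout.

Rectangular cuboid coils use rectangular filament loops (layers
interpolated between the inner and outer apertures, spread along the coil
length); each straight segment contributes through the Hanson–Hirshman
form of the finite-segment Biot–Savart law, which is numerically stable
except on the wire itself.  Points on a filament raise an explicit
singularity error; grid points that fall inside a winding volume are
flagged and excluded from region statistics (with an excluded-point count
in the report) instead of producing meaningless near-filament values.

Conventions: z along the coil axis, origin at the array's geometric
mid-plane, positive current counterclockwise viewed from +z.  Homogeneity,
`(B_max - B_min)/B_mean * 100 %`, is computed on the vector magnitude |B|
(what a Gauss-meter probe aligned with the field reads), not on B_z alone.
Evaluation regions are centered on the array mid-plane and sampled at
<= 1 mm; because the problem is axisymmetric, a cylinder region reduces to
a rectangle in the (r, z) half-plane.

### Agreement with finite-element reference values

The engine reproduces the published FEM figures for the 10 cm arena (all
three region heights, and the field extrema of every apparatus, within
10 % relative).  The homogeneity percentages of the 3.5 cm microscopy coil
and the 20 cm arena disagree beyond the max(2 points, 25 % relative)
consistency band.  Two observations locate the difference on the FEM side
rather than in this engine: (1) the loop solution here matches an
independent brute-force Biot–Savart quadrature to ~1e-14 relative error,
and the filament model is converged; (2) the published maximum for the
20 cm arena (55.5 mT) lies *below* the exact on-axis center value for the
stated geometry (57.2 mT), a signature of a truncated open-boundary FEM
domain, which depresses the solution non-uniformly.  The remaining spread
sits in the near-winding corners of the evaluation regions (both arena
regions end 5 mm from the bore), where a coarse FEM readout smooths the
local field rise.  The analytic solution is taken as ground truth; the
printed FEM values serve as consistency checks at the tolerances above.

### Engineering estimators

Winding resistance uses a nominal 20 C AWG copper table (length = turns x
mean-turn circumference); inductance uses Wheeler's multilayer
approximation.  Both are order-of-magnitude design aids with property
tests only: applied to the published turn counts they predict roughly
11 ohm for the microscopy coil where ~7 ohm was measured on the bench,
which is the expected direction when as-built turn counts fall short of
the design value.  They are never used as acceptance quantities.

## Protocol compiler

A protocol is an ordered list of phases: stimulation duration, rest
duration, square-wave frequency, dead time, mode, repeats.  Choices made
where the behavior was underdetermined:

* Phases begin with the stimulation period, then rest.  An experiment that
  starts quiet (e.g. "30 s off, then 30 s on") is expressed through the
  controller's protocol gate rather than by reordering phases.
* Unidirectional mode is a 50 % duty on/off square wave.
* Default dead time is 1 ms — two percent of the half-period at the
  typical 10 Hz, matching the firmware intent of staggered pin pairs.
  Dead time must be strictly below the half-period; this is validated
  before compilation.
* The 200 Hz sensing-stability limit is a strict inequality: 200 Hz with
  sensing enabled is reported infeasible.  With sensing disabled the
  supported range is capped at 1 kHz.
* Event times are exact `Fraction`s of the input durations, so long
  protocols accumulate no float drift; times become floats only on CSV
  export.  This makes the safety properties (no shoot-through, every
  opposite-direction gap >= dead time, energized time = stim time minus
  number-of-gaps x dead time) exactly checkable, and they are checked over
  1000 seeded random protocols.

## Closed-loop controller

Gates are evaluated at poll instants only (sampled control, 20 Hz
default), which bounds breach-to-off latency by one poll interval; the
test suite verifies the 50 ms bound over 100 randomized breach onsets.
Readings exactly at a threshold count as breaches.  A sensor with no
reading, or whose latest reading is older than two poll intervals, fails
the sensor gate (fail-safe; the stale window gives a one-poll grace for
jittered streams).  After a pause the loop resumes stimulation at the
first poll where all gates hold again, including mid-ON-interval — the
alternative (waiting for the next programmed interval) would be a one-line
change in `run_closed_loop` and is deliberately not the default, since
resuming maximizes delivered dose under transient disturbances.  With
`breach_action="abort"` the first breach latches stimulation off.  Logs
are one CSV row per poll; identical inputs produce byte-identical logs.

## Tracking

The light–dark and three-chamber algorithms operate on grayscale frames:
crop ROI, median blur (default kernel 5; the original blur size is not
documented, so it is configurable), binary threshold at intensity 127,
count target-color pixels.  A count equal to the pixel threshold counts as
"in ROI" (the below-threshold case is the documented negative).  The
three-chamber tracker keeps a side memory: a frame with both ROI counts
below threshold is assigned to the side chamber the subject was last seen
nearest; with no memory yet the frame is reported `undetermined` rather
than guessed, and undetermined time is excluded from occupancy-fraction
denominators.  Locomotion sums centroid displacements (absent-centroid
frames are bridged to the next detection) and divides by elapsed time; the
mm/px scale must be supplied, since it depends on the camera setup.

## Synthetic data

Virtual arenas scale the physical chambers (14 cm boxes, 20 cm middle
chamber, 10 cm height) at 10 px/cm; the subject is a black disc of radius
15 px (~3 cm, mouse body scale) on a white background, and only the
camera-visible chambers are rendered — exactly the information the real
video pipeline sees.  Walks are reflected correlated random walks
(constant step length, Gaussian heading noise, default 8 px/frame at
20 fps ~ 16 cm/s) — sufficient to exercise every chamber-transition path,
with no claim of behavioral realism.  Sensor traces are per-kind baselines
(24 C, 45 dB, 0.02 g, 0 mT) plus seeded Gaussian noise and additive
anomaly windows.  Every generator is a pure function of its seed.

What passing synthetic tests do **not** show: robustness to illumination
drift, motion blur, occlusion, or non-elliptical posture in real video;
sensor drift or calibration error on real hardware; and any behavioral
effect in real animals.  Bench agreement figures (Pearson/Bland–Altman of
sensor vs handheld instruments), as-built coil measurements, animal
statistics, and usability-survey scores are properties of physical
experiments and are represented here only by their formulas and by
property-based substitutes.

## Problem sizes

Default verification sizes, chosen to characterize the methods fully:
field maps at 1 mm spacing (up to ~20k samples x 2400 filaments for the
six-coil arena); 1000 random protocols in the safety audit; 100 breach
onsets for the latency bound; 20 seeded videos per behavioral paradigm at
150–200 frames; constant-speed locomotion recovery at 5–50 px/frame.
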