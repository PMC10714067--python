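# Methods

This note documents the models and procedures the package implements, the
parameters that matter, what the synthetic-data generator does and does
not emulate, and the numerical choices made where the design was open.

## Sensor model and conventions

Depth is positive down with the surface at 0 m; raw negative readings are
clamped before segmentation. The world frame is north/east/up; heading is
in (−180°, 180°] with 0 at magnetic north and negative values a leftward
rotation; pitch is positive nose-up, roll positive right-side-down. At
rest the accelerometer reads `g·(sin θ, cos θ sin φ, cos θ cos φ)` with
g = 9.81 m/s², so pitch = asin(aₓ/g) and roll = atan2(a_y, a_z); heading
comes from the tilt-compensated magnetic field with a configurable
declination correction (0° by default — the generator and estimator share
one convention). Calibration is per-axis affine (offset, gain) with an
optional fixed mounting rotation; device axes are taken as animal axes.

Magnetometry and depth are analyzed at 5 Hz after anti-aliased decimation
(block means); acceleration keeps its native 200/250 Hz for jerk work and
is decimated to 25 Hz for stroke filtering (the 0.4–2.5 Hz stroke band
needs headroom below Nyquist) and to 5 Hz for orientation.

## Dive segmentation and labelling

A dive is a maximal run of 5 Hz depth samples strictly deeper than 5 m;
runs in (0, 5] m are kept separately as shallow under-ice activity, so
every sample belongs to exactly one of surface/shallow/dive. No minimum
dive duration is imposed. Each dive carries its day period at the dive
start — day (solar elevation > 0°), twilight ([−12°, 0°], closed
interval) or night — computed by a self-contained NOAA-style solar
ephemeris (geometric elevation, accurate to well under 0.1°), and a 40 m
maximum-depth bin `[k·40, (k+1)·40)`.

## Capture-attempt detection

The jerk is the norm of the first-differenced triaxial acceleration
scaled by the sampling rate (a central-difference variant is available).
The detection statistic is a centered sliding RMS with a 0.2 s window and
one-sample hop; the window length is not critical between ~0.1–0.5 s and
is exposed in `DetectorConfig`. Events are maximal excursions above
150 m/s³. Merging happens **before** the minimum-duration rule: bursts
separated by gaps < 5 s are consolidated (a long capture made of several
peaks counts once), then merged events shorter than 5 s are discarded.
Events are tied to the dive containing their start and to the 5 Hz depth
at that instant; events outside dives (≤ 5 m) are flagged excluded.

The survival curve S(Δ) of inter-event gaps reports a suggested merge
threshold at the knee — the grid point furthest below the chord from
(0, S(0)) to (max, S(max)). A maximum-discrete-curvature rule was tried
first and discarded: on an empirical survival step function the second
difference is dominated by within-mode sampling steps and never found the
between-mode knee on constructed bimodal mixtures, while the chord knee
separates the modes reliably. The suggestion is report-only; the default
merge gap stays 5 s.

Two detector properties worth noting. Raising the threshold always
shrinks the total supra-threshold *time*, but can *increase* the raw run
count (one tall excursion splits); the count is monotone only for
single-excursion events, which is what the capture signal model produces.
Merging can only extend covered time before the duration filter.

## Echogram analysis

Echograms are ENR images (echo minus background noise in dB, floored at
0) over ±5 s around each PrCA, 25 pings/s, 0–7 m range at 1 cm/bin by
default so acoustic sizes in cm equal pixel counts. The pixel-inclusion
threshold is 9 dB; all trace and size results are reported with the
threshold used.

*Seafloor*: per ping, the deepest contiguous supra-threshold run of at
least 2 bins (isolated single-pixel noise exceedances deeper than the
ridge would otherwise hijack the search); pings are kept when the run
center stays within 3 bins of the local 9-ping median, and the floor is
declared present at ≥ 30 % ping coverage. A window with a detected floor
marks the PrCA — and thereby its dive — benthic.

*Traces*: 8-connected supra-threshold components after masking the ridge
plus a 2-bin guard band above it, kept at ≥ 6 pixels spanning ≥ 3 pings.
Components sharing ≥ 3 ping columns are labelled "several" (a school).

*Reaction*: from the per-ping range polyline (the component's column
centers, lightly smoothed). *Leave-seafloor* requires a first point
within 10 cm of the floor and a linear slope below −3 cm/s; *escape*
requires the whole trace > 10 cm clear of the floor and an upward-opening
quadratic with an interior minimum plus a genuine dip (≥ 4 cm down and
up). Either class also requires a total range sweep > 6 cm — stationary
blobs with jitter otherwise occasionally satisfy the quadratic test.
When both fire, the departure origin wins (leave-seafloor). The onset is
the first ping whose smoothed range rate exceeds 5 cm/s; for
leave-seafloor the onset is refined by extrapolating the fitted line back
to its intersection with the floor (the trace only becomes visible after
clearing the ridge and guard band, ~6 cm, which would otherwise bias the
onset ~0.5 s late at typical departure speeds), and the onset *range* is
the seafloor range there — the departure origin — rather than the first
unmasked pixel. Onset times before the PrCA start are negative.

*Acoustic size*: median over ping columns of the longest contiguous
supra-threshold pixel run, × bin width; only defined for isolated traces.

## Dive-shape clustering

Profiles are centered and reduced per dive: time rescaled to [0, 1] and
resampled to 101 uniform points, depth z-scored with the dive's own mean
and SD, so clustering sees shape rather than magnitude — a much shallower
W-dive still separates by shape. Curves are projected by least squares
onto 15 cubic B-splines (uniform interior knots); the eigenproblem of the
coefficient covariance under the basis Gram matrix (L2 inner product,
computed by trapezoidal quadrature on a 1001-point grid) gives
orthonormal eigenfunctions, scores and explained-variance fractions. The
leading 3 components are kept. Both 101 and 15 are config-exposed; results
are insensitive to moderate changes.

Scores are clustered with Gaussian mixtures over four covariance
families (spherical, tied, diag, full), K = 1…9, EM with 5 restarts,
tolerance 1e-6, max 500 iterations, fixed seed; the lowest BIC wins and
the full selection trace is kept on the model. Dives are assigned to the
argmax cluster only when that posterior is ≥ 0.8, else unclassified;
raising the threshold never increases the assigned count.

On generator output the five archetypes separate into five clusters in
the modal case over seeds, but the shape variation concentrates in two
between-archetype modes (~57 % and ~33 % of variance), with sinuosity
spread thinly over the remaining components (~5 % each). Field data with
richer within-type variability can distribute variance more evenly; the
variance spectrum is a property of the data, not of the method.

## Orientation, tracks and approach behavior

Static acceleration is isolated by a 0.5 Hz zero-phase low-pass; samples
whose static magnitude departs from g by > 30 % are flagged unreliable.
Dead-reckoning steps `s·Δt·(cos θ cos ψ, cos θ sin ψ, −sin θ)` with speed
`|depth rate|/|sin θ|` when |pitch| > 20° (clamped to [0.2, 3] m/s), else
a 1 m/s fallback — no speed sensor is assumed.

Lateral acceleration is split into a stroke component (0.4–2.5 Hz
zero-phase band-pass, bracketing phocid stroke frequencies), a slow
gravity/posture trend (0.05 Hz low-pass) and a residual attributed to
other lateral movements such as head turns. Strokes are counted as peaks
with ≥ 0.3 m/s² prominence and ≥ 0.3 s spacing; when the residual channel
is supplied, peaks whose local (±0.6 s) stroke-band RMS does not exceed
1.5× the residual RMS are rejected. This implements the desynchronization
idea — broadband transients (capture lunges, filter edge-ringing) leak a
little energy into the stroke band but are incoherent with it, while
genuine stroking dominates the residual by an order of magnitude; without
the gate, stroke presence in approach windows overlapping a capture burst
is over-reported by ~8 points.

Approach windows span 10 s before to 5 s after each reactive-prey PrCA.
Reaction timing is classified before/during/after from the estimated
onset versus the event interval; "chasing" before/during is stroke count
> 0 in the 5 s before the reaction and during the event respectively; the
head turn is the net wrapped heading change over ±1 s around the
reaction, called left/right at |Δψ| ≥ 10° (the angular threshold is a
package choice; heading differences make the call invariant to any
constant offset and to the ±180° wrap).

## The synthetic-data generator

The generator is the package's study-conditions statement. Defaults: 3
individuals at 250/250/200 Hz acceleration; five dive archetypes with
weights from the observed cluster proportions; non-foraging maximum
depths log-normal with mean 36 m and SD 44 m (W-dives scaled shallower,
floored at 16 m so the mid-dive rise clears the 5 m threshold with a free
level); capture depths truncated-normal 88 ± 30 m on [6, 320] m; capture
events 5.5–10 s long, ≥ 7 s apart, ~38 % with visible prey, 56 % of those
reactive, 70 % of reactions leaving the seafloor, 1.6 % schools; reaction
distances truncated-normal 51 ± 18 cm on [16, 121] cm; acoustic sizes
5 ± 1 cm on [3, 13] cm; reaction timing scheduled 34/59/7 %
before/during/after with onset times drawn from N(9, 7) s truncated to
the category interval; strokes before/continuing 74/79 %; head turns
43/27/30 % left/right/none at 25° over 1.4 s on a 6°-amplitude, 12 s
scanning baseline; 98 % of windows benthic; RMS-jerk regimes ~30 m/s³
(noise) and ~400 m/s³ (capture, log-normal spread) around the 150 m/s³
threshold; GPS fixes ~30/day with 0.2 km steps reflected inside a 3 km
radius around the colony (66.67° S, 140.01° E, November).

Two structural choices matter for recovery statistics. First, all capture
depths are drawn i.i.d. and sorted-partitioned into foraging dives — a
seal working a narrow seafloor band within one dive — with the dive's
bottom phase following a relief line through each event's scheduled
depth; the pooled event-depth mean therefore carries full-sample (not
per-dive-clustered) sampling variance. Second, within-archetype shape
variability is Gaussian keypoint jitter plus fixed-frequency sinusoidal
wiggles with Gaussian coefficients, so each archetype forms a coherent,
near-Gaussian cloud in score space — the regime in which mixture-model
selection is meaningful.

Default deployments are scaled (~107 dives, 42 PrCAs, ~4 h of data) so a
full simulate-and-analyze cycle runs in seconds;
`SimulationConfig.study_scale()` reproduces the study's event totals (331
PrCAs in 78 foraging dives, 308/2/21 and 61/2/15 per individual) with
non-foraging dives reduced, since only foraging dives carry tested
signal. Runs are bit-reproducible under a fixed seed with independent
per-individual sub-seeds; echograms are synthesized on demand per PrCA
(deterministically from the seed) rather than stored.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: sonar beam geometry and time-varying gain,
prey-echo fading as targets leave the beam, pressure-sensor drift and
tides, multi-animal acoustic interference, pup behavior, haul-out
periods, and the judgment of a human echogram reader. The reaction
classes are painted with clean geometries; the ≥ 90 % classification
agreement measured here is an upper bound on what hand-read field
echograms would give.

## Degenerate inputs and tie-breaks

Constant-depth profiles cannot be normalized (error); traces of < 4 pings
classify as "none"; non-isolated traces have undefined acoustic size
(NaN, flagged); an empty gap list yields an empty survival curve; zero
scheduled dives yield empty streams and empty truth; degenerate mixture
fits are skipped with the BIC trace recording only successful candidates;
events at exactly the 5 m boundary count as shallow (strict >); the
twilight interval is closed at both ends.

## Known limitations

The seafloor tracker assumes the ridge is the deepest persistent feature
and can mislabel a window pelagic when the sonar points away from the
floor (the same limitation the tag design has). Dead-reckoned tracks are
not fused with GPS and drift accordingly. The approach-behavior
estimators were validated against scripted behavior; field-data stroke
amplitudes and head-turn magnitudes vary more than the schedule does.
Table-style outputs reproduce counts and ratios exactly only insofar as
the upstream stages are correct on the given data — the printed-ratio
identities are arithmetic checks, not biological ones.
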