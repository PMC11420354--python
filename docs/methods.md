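# Methods

This note records the models, conventions and numerical choices behind
`glidekymo`, and what the synthetic benchmarks do and do not demonstrate.

## Coordinates and conventions

Image arrays are indexed `[row, col]`; positions are reported as
`(x = col, y = row)` with y increasing downward. All angles exposed to the
user are degrees, counter-clockwise positive in the mathematical (y-up)
sense, wrapped to the half-open interval (−90°, 90°] where they describe an
undirected axis. In a kymograph (rows = time increasing downward, columns =
space), a trace at angle α from the space axis, measured in the (col, row)
plane, converts to velocity as `v = (pixel_size/frame_interval)·cot α`;
α = 90° is stationary and α < 90° moves toward +x as time advances.

Default calibrations follow the instruments being emulated: 0.13 µm/px
(0.086 µm/px at the higher magnification) and 0.1 s/frame for the
single-cell channel data; 0.91 µm/px and 1 s/frame for the population assay.

## Synthetic movies

The generator is the package's substitute for raw microscopy data; it
renders exactly the structure the analysis assumes and nothing more.

* **Cell kinematics.** A piecewise-constant-velocity trajectory
  `(t0, t1, v, heading)` is integrated analytically, so ground-truth centres
  are exact to machine precision and finite-difference speeds equal the
  segment speeds away from boundaries. Speeds are capped at 4 µm/s (cell)
  and 12 µm/s (cell-frame spots), the ranges the assay is built for.
* **Structural axis vs heading.** The rendered cell body is oriented by the
  heading modulo 180°: a directional reversal flips the velocity, not the
  frustule. Spot positions live on this structural axis, so after a
  reversal the spot population genuinely reverses in the lab frame, which is
  what the kymograph slope test must detect.
* **Channels.** The autofluorescence channel holds two isotropic Gaussian
  blobs whose FWHM equals the stated chloroplast diameter (defaults 4.5 and
  6.0 µm, offsets ±10 µm from the centre). The GFP channel holds a dim
  anisotropic Gaussian ridge along the axis (σ_long = cell_length/4,
  σ_short = 0.3 µm — the raphe line) plus Gaussian spots (σ = 0.25 µm,
  amplitude 200) whose along-axis positions integrate their cell-frame
  velocity. Everything is evaluated analytically at pixel centres (no
  supersampling); with zero noise the per-frame summed blob intensity is
  conserved to < 1e-3 relative, the tolerance set by sub-pixel sampling.
* **Noise and artefacts.** Additive Gaussian noise (default sd 20 against
  spot amplitude 200, i.e. spot SNR 10; Poisson noise available behind a
  flag). Stripe events add a constant offset to whole rows of given frames,
  mimicking interference patterns and abrupt z-shifts. The evanescent-field
  depth profile is *not* modelled — no stage of the analysis uses z.
* **Default geometry.** Cell length 40 µm, width 5 µm; the organism's cells
  are tens of µm ("about one cell length" ≈ 50 µm is the only anchor the
  assay itself provides), and all dimensions are configurable.
* **Population movies.** Dark anisotropic-Gaussian cells (contrast 500 on a
  background of 1000, noise sd 10 ≈ 1% of background — bright-field-like)
  on gently curved constant-speed paths headed roughly toward the field
  centre; initial placements are rejected until non-overlapping (error
  after 100 attempts per cell).
* **Determinism.** All randomness flows from `numpy.random.default_rng`
  seeded from the scenario, and noise is drawn frame by frame in a fixed
  order, so equal seeds give bit-identical movies.

Passing on these movies shows the estimators are correct under the model's
assumptions (rigid motion, Gaussian-blob landmarks, straight constant-speed
traces, additive noise). It does not exercise photobleaching, landmark
deformation, defocus, uneven illumination, or trace curvature; on real data
those effects degrade the inputs before they reach this code path.

## Cell tracking

Detection is a single-scale Laplacian-of-Gaussian response at the fixed
bounding-circle diameter (accepted range 4–8 µm), thresholded at 3× a
median-absolute-deviation noise estimate, followed by intensity-weighted
centroid refinement inside the bounding circle with the local boundary
minimum subtracted. The two strongest non-overlapping responses per frame
are kept; frames with fewer detections become gaps, closed by linear
interpolation up to `max_gap` (default 5) consecutive frames and flagged.
Frame-to-frame assignment minimizes the summed distance to the tracks' last
known positions; a tie within tolerance raises an error naming the frame
rather than silently risking an identity swap.

The cell centre is the coordinate midpoint of the two chloroplast centres —
the arithmetic mean of x and y (a literal geometric mean of signed
coordinates is not well defined). The axis angle is the angle of the
connecting vector. Leading/trailing labels are assigned by projecting each
track's mean position onto the net displacement vector; below 1 px of net
displacement the labels fall back to image order (+x first).

Instantaneous speed is `‖c[i+1] − c[i]‖·px/Δt`, the final value repeated so
the trace is frame-aligned. Smoothing is a centred uniform moving average
with **mirror (half-sample symmetric) padding**; this choice, rather than
edge-shrinking windows, makes the smoother exactly mean-conserving (every
sample contributes total weight 1), which keeps windowed mean speeds
consistent between raw and smoothed traces. Even window widths are rounded
down to the next odd value, so the default window of 20 samples runs as an
effective span of 19 (2 s at 10 fps) — the same convention MATLAB's `smooth`
applies.

## Registration

The reference frame minimizes `|angle|/90 + dist(centre, FOV centre)/(diag/2)`
over valid frames (ties → earliest). Every frame is translated so its cell
centre lands on the reference centre, then rotated about the reference
centre by the angle difference — the order is fixed and verified by the
motion-cancellation invariant (re-tracked centres constant to < 0.5 px),
which any self-consistent choice must satisfy. Resampling is bilinear;
pixels pulled from outside the canvas are zero, and content leaving the
canvas is lost (the canvas equals the input FOV). Frames with an invalid
pose are emitted blank and flagged.

## Kymographs and stripe removal

`K[t, x] = max over y in the row band of I[t, y, x]` (band default: full
height). The maximum projection across the cell width keeps traces visible
when the labelled structure wanders off any single row.

Full-width horizontal stripes live entirely in the zero-spatial-frequency
column of the 2D spectrum. The filter zeroes a `mask_width` (default 2)
column strip there across all temporal frequencies, with two deliberate
deviations from the naive mask:

* **DC is preserved**, so the mean brightness of the kymograph is unchanged
  (and a spatially uniform image passes through untouched).
* **The mirrored partner columns are zeroed too.** A real image has a
  conjugate-symmetric spectrum; a one-sided mask would leak back into the
  "masked" columns when the real part is taken on inverse transform. Masking
  ±frequency pairs is also what painting a strip on a Hartley-transform
  display does. For even widths the strip covers centred columns {0, −1},
  so with mirroring the effective mask is {−1, 0, +1}.

With this geometry, a pure-stripe image (each row constant) collapses
exactly to its global mean, the filter is linear, and re-transforming the
output shows zero energy at every masked frequency.

## Velocimetry

**Orientation histogram (batch method).** The ROI (minimum 16×16 px) is
mean-subtracted, apodized with a 2D Hann window, zero-padded to a square
power of two (≥ 64), and its power spectrum integrated over the annulus
0.1–0.9 of Nyquist into 90 bins of 2° — the Fourier-components method of
the Fiji *Directionality* plugin, with its default granularity. Spectral
angles are rotated by 90° so bins report structure orientation. A
Gaussian-plus-baseline fit around the circularly unwrapped peak supplies
`(µ, σ, A, b, r²)`.

**Estimation hierarchy.** ROIs must span 5–15 s (drawn over windows of
smooth sustained gliding: smoothed speed > 0.5 µm/s for ≥ 5 s, found by
`select_gliding_windows`). Before estimation the per-column temporal mean is
subtracted — the stationary raphe ridge otherwise dominates the spectrum
with a vertical mode; the manual workflow implicitly makes the same
selection by drawing ROIs over the moving traces. The strongest mode more
than 6° from vertical is located on a lightly smoothed histogram (3-bin
circular window — a genuine trace mode is several bins wide, so this
suppresses single-bin noise flukes); if no such mode exceeds 1.5× the
uniform level the ROI has no moving traces and an error is raised. The
Gaussian fit around that mode gives the orientation when r² ≥ 0.5
(method `gaussian-peak`); otherwise the raw local maximum is used
(`local-max`). Orientations within 2° of horizontal are rejected as too
fast to resolve. The third tier, `measure_segment`, converts a hand-drawn
straight segment's slope directly and exactly agrees with
`orientation_to_velocity` on the same geometry.

**Pairing.** Each measurement is paired with the mean *smoothed* cell speed
over its time window; the summary reports mean ± SD of |myosin| and cell
speeds per cell half. In the reference conditions (cell +2 µm/s, spots
−6 µm/s in the cell frame) the recovered myosin sign is negative — opposite
to cell motion — as the force-coupling picture requires.

**Reversal localization.** A 5 s window slides down the kymograph in 0.5 s
steps; each window yields a signed velocity from its dominant off-vertical
orientation, and the reversal time is the linear zero crossing between the
last window of one sign and the first of the other. With the spot
population reversing in place, the estimate lands within ~0.2 s of the
true event; the cell's own velocity trace localizes it independently via
its minimum.

## Population motility

Cells are segmented per frame from the smoothed inverted image at the
larger of Otsu's threshold and 6× the robust (MAD) noise scale — Otsu alone
mis-splits the noise mode when cells cover a tiny fraction of the field.
Centroids are weighted by contrast *above* the threshold, which removes the
baseline-noise contribution to localization; at the default noise this
keeps the stationary-cell apparent speed below 0.05 µm/s at 1 fps. Linking
is nearest-neighbour with a 15 µm/frame step budget; an unmatched cell ends
its trace. Mean velocity is cumulative path length over duration — "distance
moved" is taken as path length, not net displacement (the one-cell-length
remark behind the 50 µm cut suggests a path-like distance). Filters are
strict inequalities: duration > 30 s AND path length > 50 µm. No smoothing
is applied before path summation; at 1 fps the jitter bias this induces is
quantified by the stationary-cell test (< 0.05 µm/s). Quartiles use linear
interpolation between order statistics (numpy default), so boxplot numbers
are bit-reproducible.

## Drag bound

At these scales Re ≈ 1e-6, so drag is Stokes-regime. The cell body — a
hemispherically-capped cylinder — has no exact closed form, so its drag is
approximated by axial translation of the prolate spheroid with equal
diameter and length (Oberbeck):

    F = 16πη a e³ v / [(1+e²) ln((1+e)/(1−e)) − 2e],   e = √(1 − b²/a²)

with a series expansion of the denominator below e = 1e-3 to avoid
cancellation; the formula reduces to `6πηrv` in the sphere limit (relative
difference < 1e-6 at length = diameter·(1+1e-8)). The assay leaves length
and viscosity open, so the bound is reported as the maximum over lengths
6–50 µm at η = 1.0 mPa·s (water, 20 °C): 0.536 pN at 50 µm for d = 6 µm and
v = 4 µm/s — below 1 pN everywhere in the sweep. The prolate surrogate is
standard and accurate to a few percent for moderate aspect ratios, and is
conservative here because the true capsule at equal volume is slightly less
elongated.

## Problem sizes and defaults

The benchmark movies are 25 s (steady glide) and 20 s (reversal) at 10 fps
with a 96×(640–768) px field — long enough for ~15–20 spot transits and
stable statistics, small enough that the full pipeline (generation,
tracking, registration, kymograph, velocimetry) completes in well under a
minute per movie. The population assay simulates 12 cells for 5 min at
1 fps on a 640² px field. All thresholds named above (spot diameter range
4–8 µm, smoothing window 20, ROI span 5–15 s, gliding cut 0.5 µm/s / 5 s,
stripe mask width 2, 90 histogram bins, r² ≥ 0.5, trace filters 30 s /
50 µm) are collected in `glidekymo.config.PipelineConfig`, validated on
construction, and hashed into the results manifest for reproducibility.

## Known limitations

* The rigid-pose model assumes the two landmarks move with the cell body;
  chloroplast deformation or independent motion would corrupt registration.
* The batch estimator reports one dominant velocity per ROI; mixtures of
  velocities (e.g. the bidirectional slow-myosin regime) need the manual
  segment tier or multiple ROIs.
* Orientations within 2° of horizontal (|v| ≳ 37 µm/s at default
  calibration) are declared unresolvable rather than estimated.
* The stripe filter removes genuine image content at near-zero spatial
  frequency; on narrow kymographs (≲ 100 px) this measurably attenuates
  broad features, which is why kymographs are built at full FOV width.
* Population linking has no gap closing; a detection dropout splits a trace
  (the duration filter then discards fragments, biasing toward steadily
  visible cells — the same bias the real assay's filters impose).
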