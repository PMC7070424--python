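# Methods

`irsring` is a software model of a tube-mounted infrared light gate used
for automated arthropod monitoring, together with the statistical analysis
that characterises its sensitivity. This note records the model, its
assumptions, the tunable parameters, and the design choices made where the
hardware description left the design open.

## Optical model

The instrument is a ring on the cross-section of a trap tube: two
vertically stacked IR LEDs face 16 photodiodes arranged along the opposite
semicircle in two vertically offset rows, the rows' angular grids staggered
by half the combined pitch. Two variants share the frame: a wide sensing
field (35 mm aperture, `IRSR1`) for macroarthropods and a narrow one
(10 mm, `IRSR2`) for soil microarthropods.

The model is deliberately two-dimensional. Each photodiode row is an
independent "sensed sheet" inside the 15 mm ring height; within a sheet,
light transport is a fan of straight rays from the LED point to stratified
sample points across each photodiode's aperture arc. The stacked LEDs share
one in-plane position and enter as two Gaussian angular-intensity lobes
(half-width at half maximum = `half_beam_angle`) whose axes are rotated
against each other by `led_beam_shift`; their weights are summed per ray.
Occlusion of a channel by an object is the intensity-weighted fraction of
its ray bundle that intersects the object's projected outline (a disk, or a
rotated ellipse for elongated bodies), scaled by the object's opacity.
Channel occlusion is therefore deterministic, bounded in [0, 1], linear in
opacity, and mirror-symmetric about the LED axis.

Choices worth recording:

* **Ring radius.** The radius of the circle carrying emitters and
  detectors is not part of the published description. It is set to 1.4x
  the aperture radius for both variants, which (a) guarantees that every
  LED-to-photodiode ray crosses the sensing aperture, so a centered object
  as large as the aperture blocks every channel completely, and (b)
  reproduces the stated origin of the narrow ring's higher sensitivity:
  the same object subtends a much larger angle when everything sits
  closer together.
* **Photodiode apertures** tile the semicircle without gaps (angular
  half-width = half the combined pitch), so any ray into the far
  semicircle lands on exactly one channel.
* **Beam angle.** The LED beam width is not published. The default
  half-beam angle is 60 degrees, typical of a lensless wide-angle IR LED;
  it keeps the unobstructed illumination of the 16 channels homogeneous to
  within a factor of two, which is the stated purpose of the two shifted
  LEDs. (A narrow 10 degree beam leaves most of the wide ring's aperture
  effectively unlit, caps large-grain detectability far below 95% and
  makes the noise calibration below infeasible; it remains configurable
  for sensitivity studies.)
* **Ray count.** 4096 stratified rays per channel; the stratified midpoint
  pattern makes occlusion reproducible and accurate to ~2.5e-4, verified
  against a closed-form chord-blocking integral for a centred disk.

## Fall and front-end simulation

Objects enter the tube with the speed of a free fall from `drop_height`
(default 38 mm, the glass tube above the ring) and cross the two sheets at
constant acceleration; air drag and tumbling dynamics are out of scope.
Each sheet contributes a Gaussian vertical envelope whose 1/e full width is
`beam_vertical_extent` (default 4.9 mm), broadened by the object's own
size. The default was set so that the simulated dip of a small object at
the default drop has a 1/e duration of 5 ms, the instrument's reported
fall time constant. Flutter — springtails bending appendages mid-fall —
is modelled as a sinusoidal modulation of the outline scale within
`[1 - flutter_amplitude, 1]`: deformation only ever shrinks the projected
outline, which encodes the observation that living springtails are harder
to detect than grains of the same size.

The analog chain per channel is: stage-1 gain 15x with the one-pole
low-pass implied by the amplifier's 100 kHz gain-bandwidth product
(~6.7 kHz), a 5 Hz one-pole high-pass, stage-2 gain 30x, additive white
Gaussian noise, plain subsampling from the internally oversampled rate
(10 x 3.2 kHz by default) to the 3.2 kHz ADC rate, and a 10-bit ADC
(offset 512, clamped, rounded). There is deliberately no anti-aliasing
filter: the hardware accepts aliasing above the ADC Nyquist rate, and the
emulation reproduces that behaviour. The internal grid is phase-locked to
the ADC clock and the filters use first-order-hold discretisation, so the
digitised output is insensitive to the oversampling factor (verified to
<= 1 LSB between factors 8 and 16 at zero noise).

Two numbers map physics to counts, and both are calibrations rather than
derivations because the hardware's ADC reference and photocurrent scaling
are unpublished:

* `light_scale` (default 760 counts): the mid-band amplitude of a full
  occlusion of a fully lit channel. The default was chosen once so that
  the zero-noise grain experiment of the wide ring at ST = 100 yields a
  95%-detectability size just above 0.9 mm, leaving the noise calibration
  (below) a well-posed bracket.
* `noise_sigma` (default 8 counts): the single free noise parameter; the
  default is the value the reference calibration returns (~7.5, rounded).

## Detection algorithm

The detector is a bit-faithful integer re-implementation of the embedded
algorithm, per channel at 3.2 kHz:

* **Baseline.** A 32-sample moving average in fixed point with 5
  fractional bits. Default mode is the recursive form
  `fp += (sample*32 - fp) >> 5` (most recent samples weighted highest); a
  true 32-sample sliding mean is provided as `"sma"` since the hardware
  description reads both ways. Both have a constant input as an exact
  fixed point. The 32-sample window spans exactly 10 ms.
* **Events.** A detection opens when `sample - baseline > ST`; while
  open, every above-threshold deviation is added to `raw_sum`; it closes
  after `holdoff_samples` (default 8, i.e. 2.5 ms — the firmware states
  only "a specific length of time") consecutive at-or-below-threshold
  samples. The baseline is frozen while a channel's event is open
  (default on) so long occlusions are not absorbed into the baseline.
* **Normalisation.** `raw_sum` is divided by the power of two nearest to
  the number of contributing samples, ties rounding down, implemented as a
  shift. Ties-down makes the documented worst-case error of 50% exactly
  attainable (n = 6 -> divisor 4).
* **Merging.** Whether one falling animal produces one record or several
  (it usually shades several diodes) is unspecified; per-channel events
  overlapping in time are merged into one record with the union channel
  mask and the dominant channel's amplitude statistics, so the
  normalisation invariant keeps holding for the record. A consequence is
  that the "higher threshold, fewer events" monotonicity is guaranteed
  per channel but not for merged counts (a low threshold can merge
  overlapping detections into fewer records).
* ST presets: 100 (robust, field) and 40 (sensitive, laboratory).

## Storage

Records are fixed-width 32-byte little-endian structs (timestamp, variant,
threshold, channel mask, sample counts, amplitudes; 6 reserved bytes) —
the layout itself is this package's choice. The 8 MiB store (8 MB is read
as 8 MiB) is written strictly cyclically: 262,144 slots, no address reused
before all have been written in the cycle, which keeps per-slot write
counts exactly uniform and sustains more than 500 detections/day for 183
days (1432/day) before any overwrite.

## Detectability analysis

A drop experiment draws, per trial, an entry position uniform over the
aperture disk (the drop positioning procedure is unspecified) and an
independent noise stream, all by counter-based child seeding from one
master seed. `detected` means at least one event in the trial window.

Detection is modelled per group as a binomial GLM with logit link,
`logit P = beta0 + beta1 * size`, fitted by the package's own IRLS
(tolerance 1e-8 on the coefficient step, max 100 iterations), covariance
from the inverse Fisher information. The two-step phrasing sometimes used
for such curves (fit a GLM, then a logistic to its predictions) collapses
to a single fit because logit-GLM predictions already lie on a logistic
curve. D95 = (logit(0.95) - beta0)/beta1, with a delta-method standard
error; the same delta construction provides the plotted confidence band.
Perfect separation is flagged (warning, non-regular fit) and D95 reported
as the midpoint between the largest undetected and smallest detected size;
a sample with only one outcome is an error. Per-group fits are independent
by default; a pooled model with shared slope and per-group intercepts is
available. The estimator (`DetectabilityGLM`) follows scikit-learn
conventions and composes with its tooling.

The grain protocol nominally uses "six 0.2 mm categories between 0.2 and
1.8 mm", which is arithmetically inconsistent (that span holds eight such
bins); the package uses eight 0.2 mm bins over 0.2-1.8 mm.

## Noise calibration and what the simulation can claim

The physical D95 values (0.9 mm grains on the wide ring, 0.6 mm on the
narrow one, species values 1.1/0.9/0.5 mm) are empirical properties of one
hardware build and are not predicted here. Instead, one explicit
calibration bridges simulator and instrument: `calibrate_noise` bisects
`noise_sigma` until the simulated wide-ring grain experiment at ST = 100
returns D95 = 0.9 mm (common random numbers across evaluations; 60 drops
per bin). With a fixed threshold and additive noise, noise can only help a
sub-threshold dip cross ST, so D95 *decreases* with sigma: the bracket
runs from the zero-noise D95 (just above target, by the `light_scale`
choice) down to the heavy-noise regime. After calibration the simulation
reproduces the instrument's qualitative findings, checked over 20 seed
replicates at 500 trials per curve:

* variant ordering — D95(narrow) <= D95(wide) at equal noise and ST;
* threshold ordering — D95(ST=40) <= D95(ST=100) on the narrow ring;
* flutter ordering — fluttering objects are never more detectable than
  rigid ones of the same size.

What passing these tests does *not* show: the synthetic populations are
spheres/ellipsoids with uniform opacity and sinusoidal deformation, noise
is white and Gaussian, entries are uniform and vertical, and there is no
environmental light, dust, or tube-wall interaction — so agreement with
the orderings validates the mechanism, not field performance.

## Numerical choices and degenerate inputs

* Occlusion: stratified midpoint ray sampling; deterministic; tolerance
  against the analytic oracle 1e-3.
* Filters: first-order-hold discretisation (exact for piecewise-linear
  input), so oversampling is a fidelity knob, not a result knob.
* Detector arithmetic: Python integers only; arithmetic right shifts
  (floor) mirror firmware behaviour, including on negative deviations.
* Degenerate GLM inputs: single outcome -> error; perfect separation ->
  warning + midpoint bound; slope <= 0 -> D95 non-identifiable error.
* Calibration: bisection direction inferred from the bracket endpoints;
  unbracketed targets raise rather than extrapolate.
* Problem sizes: unit tests use hundreds of trials; the ordering study
  uses 20 replicates x 500 trials per curve and the calibration 480
  trials per evaluation, sizes at which the D95 sampling error (~0.05 mm)
  is small against the effects being ordered.

## Known limitations

* The count mapping (`light_scale`) and beam geometry defaults are
  calibrated/assumed, not derived from the hardware; absolute simulated
  D95 values for the narrow ring land well below the physical 0.6 mm.
* No air drag: terminal-velocity effects for very small animals are
  ignored, so dip durations for <0.3 mm objects are optimistic.
* The ST = 40 setting with heavy noise produces trial-window false
  positives, consistent with the instrument's documented noisiness at
  high sensitivity; detectability floors at small sizes reflect this.
* Interrupt timing, A/D multiplexing and bus behaviour are not modelled;
  the shift-based normalisation is honoured in spirit (integer shifts),
  not benchmarked.
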