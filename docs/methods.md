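# Methods

This note records the models, parameter choices, and numerical
decisions behind `optofret`, in the spirit of a methods supplement: it
explains *why* the code does what it does. No empirical claim here goes
beyond what the test suite and `scripts/acceptance.py` themselves
compute.

## Image formation model

The sensor is a membrane-anchored FRET pair read out on two cameras.
Per pixel, with sensor density `S` (photons/frame), activity
`A ∈ [0, 1]`, and baseline ratio `R0`:

```
R = R0 · (1 + amp · A)
E[donor]    = S · L_d / (1 + R)
E[acceptor] = S · L_a · R / (1 + R)
```

`L_d`, `L_a` are per-camera illumination/sensitivity fields. This form
redistributes emission between the channels without creating photons
(donor + acceptor is invariant to `A` when `L_d = L_a`), which is the
defining property of a FRET readout; it is a phenomenological
parameterization, not a photophysical model. The dynamic range `amp`
defaults to 0.11, the scale of a red-shifted tandem-dimer sensor pair.

The camera chain is: Poisson shot noise on expected photons → gain
(counts/photon, default 2) → dark offset (100 counts) → Gaussian read
noise (SD 3 counts) → clipping at the 16-bit ceiling (never rescaling).
The donor channel is resampled through the true inter-camera map before
the camera chain, because misalignment is an optical effect upstream of
the sensor. Empty regions carry a smooth nonzero background
(~650 photons/px ≈ 1400 counts), so background estimation is a real
task, not a no-op.

Artifacts available in the optics model: per-camera quadratic
vignetting, a multiplicative sensitivity step on the bottom half of one
chip, and a Gaussian dust dim spot on one camera. Their defaults (12%
corner falloff, 3% step, 20% spot) are chosen so the uncorrected
flat-field error is clearly visible against shot noise.

## Activity kinetics

Per cell (per pixel for focal stimuli):

```
dA/dt  = k_in (u0 + u(t)) g(x) − (k_off + k1 F1 + k2 F2) A
dFi/dt = ai A − di Fi          i = 1 (fast), 2 (slow)
g(x)   = exp(−d(x, target)² / 2ℓ²)   focal;   g ≡ 1   global
```

The two feedback pools are a minimal phenomenological stand-in for
multi-layered negative regulation; no mechanistic identification with
specific GAPs/kinases is intended. A small constant drive `u0`
maintains a resting activity so that post-stimulus *undershoot* below
baseline is possible (a system starting at zero activity has nothing to
undershoot).

Default rates (`k_in = 12.5`, `k_off = 0.04`, `a1 = 0.03`,
`d1 = 0.05`, `k1 = 1.0`, `a2 = 0.01`, `d2 = 0.015`, `k2 = 0.8`,
`u0 = 5·10⁻⁴`, all 1/s except the dimensionless drive) were tuned once
to reproduce the qualitative response shape of the assay: a
near-immediate peak after a brief saturating pulse, attenuation over
tens of seconds, a shallow undershoot around half a minute, and
recovery on the two-minute scale. No rate constants are claimed to be
physiological; they define reproducible study conditions.

Integration is classical RK4 on a grid with breakpoints at every pulse
edge and frame time and substeps capped at 50 ms, so the
piecewise-constant drive is exact within each step; the unit test
bounds the error against a 1000× finer independent Euler solve at
rel. 10⁻³. Activity is clipped to [0, 1] on output (a saturating
sensor); default parameters keep the clip inactive except under
deliberately saturating pulses.

## Cell geometry and motion

Cells are deformable disks: boundary radius
`r(θ) = r0(1 + Σk ak cos(kθ + φk))`, harmonics 2–5 with SD 0.08 —
enough irregularity to exercise masks, protrusions and edge targeting
without modelling real morphology. Motion is a persistent random walk:
the heading follows an Ornstein–Uhlenbeck process (relaxation 180 s,
stationary spread 0.5 rad) about the cell's initial direction, with
reflective walls keeping every mask inside the field. Neutrophil-like
defaults: radius 6 µm, speed 10 µm/min, 5% dead cells with a constant
ratio of 0.6 and zero activity. For leading-edge profile studies the
generator offers a `front` activity mode: a linear ramp from 0 at the
rear to 1 at the front along the instantaneous heading.

All randomness descends from one seed through spawned per-cell
substreams, so per-cell streams are order-independent and scenes are
bit-reproducible.

## Corrections: interpretation decisions

* **Dust correction.** The calibration text is ambiguous about whether
  the dust field multiplies or divides. Implemented as a
  *multiplicative restore-to-clean-field*: pixels ≥ 2% dimmer than the
  σ = 30 smoothed dye image are flagged; a clean-field estimate is
  built by σ = 10 normalized convolution of the *unflagged* pixels (so
  the spot does not bias its own reference); flagged pixels are blended
  toward `clean/dye` with a feathered weight, non-flagged pixels map to
  exactly 1. The flagged-area guard (> 10% of the chip) rejects bad
  calibration images.
* **Dust after half-chip.** The dust builder expects the half-chip
  step already corrected; otherwise the step contaminates the broad
  smooth reference near the midline.
* **Ratio correction normalization.** Rescaled to mean 1 over the
  field so absolute FRET levels are preserved; neutrality is asserted
  to < 0.1% in the tests. Border blocks use partial-block medians;
  empty blocks are filled from nearest neighbours.
* **Half-chip rows.** "Two rows above and below the middle" is read as
  rows `mid−2..mid−1` vs `mid..mid+1` with `mid = rows // 2`.
* Gaussian filters use reflective boundaries throughout, avoiding edge
  darkening in correction fields. A consequence: the σ = 5 block-level
  smoothing of the ratio correction flattens gradients within ~5 blocks
  of the border, so gradient-removal accuracy is specified at chip
  scale (≥ ~40 blocks), not on tiny test images.

## Registration

Coordinates are normalized to [−1, 1] per axis before fitting so the
second-order coefficients are well-scaled. The model maps output
(acceptor) coordinates to donor sampling positions; fitting therefore
recovers the *inverse* of the transform used to synthesize a misaligned
donor, and recovery tests measure the round-trip mapping error
`|G(M(q)) − q|`. The optimizer is Nelder–Mead with one restart per
stage (tolerances 10⁻⁶ on parameters, 10⁻⁸ on the objective), preceded
by a coarse translation grid on 4×4-binned feature images; feature
images are background-subtracted, normalized, σ = 2 smoothed gradient
magnitudes. Correlations are evaluated on the interior (≈ 8% margin)
to suppress boundary resampling effects. Invertibility is checked as a
positive Jacobian determinant at the four corners and centre.
Out-of-field samples become NaN and are excluded downstream, never
extrapolated.

## Segmentation and tracking

Otsu on the unsharp-masked (σ = 2 smooth minus σ = 25 blur) sum image,
8-connected components, hard area limits (default 80–2000 px² at 20×).
One safeguard beyond the classical recipe: a frame whose Otsu
*separability* (between-class variance over total variance) falls
below 0.75 yields no objects — a pure-noise frame is unimodal
(separability ≈ 0.64 for a Gaussian) and would otherwise be thresholded
into large speckle. Masks are invariant to positive intensity scaling.

Tracking links mutually-nearest centroids within 10 µm/frame; exact
distance ties break reciprocity conservatively (no link). Tracks not
spanning every frame are flagged incomplete and excluded from
single-cell kinetics, mirroring the assay's practice.

Background estimation has two modes: *dense* (dimmest 1.5-percentile
pixels of the minimum projection locate background; the level or
empty-well-profile scale is estimated from the temporal median at those
pixels, because the min-projection itself is biased low by noise) and
*sparse/TIRF* (conservative background pixels feed a 24-px block-local
median surface, smoothed and upsampled — a block-local approximation
chosen over a literal 65-px rolling disk median for tractability).

## Ratio QC and kinetics

Pixel filters: dim (< 2% of the bit-depth range), near-saturating
(> 98%), low ratio (< 0.8; dying cells show donor-dominant
autofluorescence). Zero/negative donor pixels are invalidated as dim,
never returned as infinities. Well series use the *ratio of channel
means* — more robust than averaging per-pixel ratios — normalized so
the pre-stimulus window averages to exactly 1, with time reported
relative to the last pre-stimulus frame. Single-cell analysis uses
closed five-frame windows (C1 = −13.5…−7.5 s, C2 = −6…0 s,
P = 4.5…10.5 s at the 1.5-s cadence); the five-frame definition is
taken as authoritative where window-width wordings disagree. Cells are
excluded for baseline < 0.95 (first ten frames), any saturated pixel,
or missing window frames, each with a recorded reason; QC counts must
reconcile (included + excluded = complete tracks).

Two-pulse analysis defines amplitudes as the baseline-subtracted
maximum within 15 s after each pulse (the first window clipped at the
second pulse) and declares the second peak *unresolvable* unless the
trace dips between the peaks by at least 20% of the smaller amplitude —
a prominence criterion; a plain "local maximum exists" test is
satisfied by sampling noise on overlapping responses.

## Photobleached-pool correction

The printed diffusion coefficient "0.5 µm/s" is dimensionally
inconsistent for diffusion and is interpreted as 0.5 µm²/s. The
initial bleach pattern is assumed Gaussian (fit by least squares to
post/pre intensity), spreading in free space:
`σ²(t) = σ0² + 2Dt`, amplitude `b0σ0²/σ²(t)`, which conserves the
bleached amount; a finite-difference PDE oracle bounds the closed form
to < 0.5%. Amplitudes scale linearly from the 37-µW calibration power
to the experimental power. The ratio bias is modelled as
`(1 − α·b)` with channel asymmetry `α` (α = 0: both fluorophores
bleach equally, no bias); in the renderer the donor is scaled by
`(1 − b)` and the acceptor by `(1 − b)(1 − α·b)`. Multiple pulses sum
and clip at the physical bound `b ≤ 1`; a correction factor ≤ 0
signals a mis-scaled model and is an error.

## Spatial profiling

Protrusions are the largest 8-connected component of
`mask(t) \ mask(t−1)`; pixels farther than one dilation from either
neighbouring frame's protrusion are trimmed (an all-or-nothing reading
would also reject genuine protrusions advancing > 1 px/frame), and a
one-frame transient with no neighbours is rejected outright. Geodesic
distances are quasi-Euclidean (steps 1 and √2) within the mask,
computed by a minimum-cost-path front and verified exactly against
Dijkstra on the pixel graph. Edge profiles pool valid pixels across
frames and cells into distance bins and are normalized to 1 at the
leading-edge bin.

Radial profiles use half-open 1-µm annuli `[k−1, k)` by pixel-centre
distance (bin 1 nearest); the ratio correction divides the acceptor
before binning; per-bin ratio is the ratio of means; fold change
divides by the same bin of the last pre-stimulus frame. Bins with
fewer than 5 valid pixels are reported missing, and every bin carries
an annulus coverage fraction because distal annuli extend past the
cell in some directions (partial annuli are included, flagged, not
dropped). Frames are first registered with recorded stage offsets.
Screening rejects cells whose stimulation pixel misses the mask, lies
within 4 px of the edge (Euclidean distance transform), or whose
centroid moves > 4 µm after the stimulus.

Edge targets use mathematical angles (counter-clockwise from +x,
image y-axis up); ties between equally-matching perimeter pixels go to
the larger centroid distance. In place of manual curation of
"consistently moving" frames, profile studies gate tracks
automatically on centroid speed — a documented deviation from the
manual practice.

## Migration statistics

MSD is displacement-from-start (`|r(t0+lag) − r(t0)|²`, t0 = track
start), not time-averaged over sliding origins — matching per-cell
trajectories from a common start; this reading of an ambiguous
definition is deliberate. Inclusion: net displacement ≥ 5 µm (MSD), or
first 30-s step ≥ 5 µm (persistence cosine, so the reference direction
is well determined). Zero-length steps contribute no cosine term.
Means and SEMs are computed across experiment groups at each lag. The
Welch test on per-experiment fractions uses the Welch–Satterthwaite
degrees of freedom and a 95% CI on the difference of means; zero
variance with equal means returns t = 0, p = 1.

## What the generator does and does not emulate

Emulated: membrane-sensor photon statistics, two-camera misalignment
and sensitivity artifacts, dense- and sparse-field backgrounds,
dead cells, stimulus-driven kinetics with adaptation, the diffusing
photobleached pool, persistent migration, and front-polarized activity.
Not emulated: real cell morphology and morphodynamics (blebs, tethers,
touching-cell clusters beyond occasional overlap), 3-D optics/PSF and
TIRF evanescent-field physics (TIRF vs. epi differ only by background
level), receptor photocycle dynamics, and advection of the activity
field in moving cells (focal-stimulation activity lives on the lab
grid; the screened assays involve nearly stationary cells). Passing
recovery tests therefore demonstrates correctness of the *analysis*
under known ground truth, not robustness to every property of real
movies.

## Problem sizes

Tests run at desk scale by design: 96–320 px fields, 1–20 cells,
6–50 frames, 20-replicate recovery studies; the acceptance script fits
20 replicates of a 21-frame 64×64 recovery series. These sizes were
chosen so each study completes in seconds while leaving the measured
effects far above their estimation noise.
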