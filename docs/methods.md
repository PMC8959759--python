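# Methods

This note documents the models behind `respiradar`, the defaults and why
they were chosen, what the simulator does and does not emulate, and the
numerical choices that matter.

## Sensing model and geometry

The package assumes the observation geometry of a room-scale multi-radar
monitoring rig: IR-UWB radars on the walls producing slow-time × fast-time
amplitude matrices, and one depth camera on a pole reporting skeleton
joints at 1 fps. Constants are fixed by that hardware class:

| quantity | value | meaning |
|---|---|---|
| slow-time rate | 17 Hz | common rate all streams are resampled to |
| range resolution | 5.22 cm | distance per fast-time column (range bin) |
| recorded range | 9.4 m → 180 bins | columns of every radar matrix |
| beam half-angle | 30° | radar coverage cone (60° beam) |
| detection range | 5 m | beyond this a subject is not assigned |
| camera tilt *A* | −30° | x-axis rotation between camera frames |
| window / overlap | 15 s / 12 s | analysis chunking (255 samples, 3-s stride) |

Coordinates follow the depth camera: x right, y down, z forward, origin at
the focal point. All beam and orientation geometry is evaluated on the
horizontal (xz) plane, which matches wall-mounted radars at chest height.

## Simulator

The simulator is the package's data source and defines the conditions the
tests run under.

**Waveforms.** Chest displacement per pattern:

- *eupnea*: sinusoid whose cycle lengths are jittered per breath
  (SD 3% of the period), plus white noise (SD 0.02 of amplitude).
- *Kussmaul*: the same generator at a higher rate and amplitude — the
  clinical picture of deep, rapid breathing.
- *apnea*: breathing runs alternating with flat gaps (raised-cosine edges,
  gap cycle ≈ 12 s, `apnea_fraction` of it flat).
- *CSR*: a sin² (raised-cosine) amplitude envelope over the active part of
  each cycle and zero during the apnea gap, multiplying a fixed-rate
  carrier; the cycle exceeds 15 s so any single chunk shows the crescendo
  or decrescendo phase.
- *non-stationary*: a random walk with occasional step discontinuities —
  movement artifacts uncorrelated with breathing.

**Radar echo.** An additive model per slow-time sample: constant per-bin
clutter (SD 1.0) + white noise (SD 0.05) + the subject's displacement at
the chest's range bin with triangular spillover (weights 0.5/1/0.5 over
±1 bin), scaled by an orientation gain — the cosine of the angle between
the facing direction and the subject→radar direction, clipped at zero and
zeroed outside the beam. This is the minimal model that reproduces the
pipeline's working assumption: the chest bin has maximal slow-time
variance. No multipath, antenna patterns or electromagnetic propagation.

**Skeletons.** Ground-truth joints are emitted in the *rotated* camera
frame (inverse of the reference transform) plus isotropic noise, so the
localization stage is exercised, not bypassed.

**Training database.** 5 classes × 50 chunks of 15 s by default, with
per-chunk parameters drawn once per chunk: eupnea 14–20 breaths/min,
Kussmaul 24–34, apnea fraction 0.6–0.85, CSR period 36–60 s with carrier
18–26 breaths/min, amplitudes in class-typical ranges. CSR chunks are cut
from inside the active phase (5% margin from the envelope's near-zero
edges), mirroring how crescendo/decrescendo exemplar chunks present the
phase. The eupnea range reflects seated adults breathing normally
(reference belt rates in this setting are ≈ 15–16 breaths/min) and the
quality gate's intrinsic floor discussed below.

## Signal quality index and its detectability floor

A chunk passes the SQI iff, after a kernel-5 median filter and min-max
normalisation, it has ≥ 3 valid breath intervals (consecutive peaks of
prominence > 0.15 enclosing a trough) whose SD/mean < 0.25. Three
intervals require four peaks, i.e. ≥ ~14 breaths/min in a 15-s chunk:
**slower breathing cannot pass the gate** and is relabelled
non-stationary by design. At exactly 15 breaths/min (3.75 cycles per
window) the outcome depends on window phase, which is why some windows of
a 15-breaths/min subject carry no RR. This is a property of the
15-s/3-interval rule, not of the simulator.

Apnea bypasses the SQI gate in the discriminator: a genuine apnea chunk
can never show 3 breaths, yet apnea is a label the system must emit. A
literal reading of the gate would relabel every apnea chunk
non-stationary; the bypass resolves that contradiction in favour of
reporting apnea.

The min-max normalisation makes the SQI (and the whole discriminator)
invariant to positive affine transforms of the chunk. Its flip side: a
flat-plus-noise chunk is amplified to full scale and shows many spurious
prominent peaks, so such chunks fail via interval irregularity rather than
via a zero breath count.

## Preprocessing order

`svd_clutter_removal` subtracts the top singular triplet(s); static
clutter — constant along slow time across all bins — dominates the leading
component of a **raw** matrix by orders of magnitude. `preprocess_matrix`
therefore applies SVD first and subtracts residual per-bin means second.
Subtracting an accurate background estimate *first* would leave the
breathing signal as the dominant component, and the SVD step would then
delete exactly the signal of interest. Both operations are also exposed
individually with the conventional contracts. SVD is applied per analysis
window, not per recording.

## Classification

Features (13): peak-amplitude SD/mean/max and peak count, measured on the
mean-subtracted chunk at peaks found by the shared prominence detector
(run without the median filter, on the chunk as extracted);
instantaneous-frequency SD/mean/max/min/range from the derivative of the
unwrapped Hilbert phase, with 0.5 s discarded at each end against edge
artifacts; and SD/max/min/range of the energies of the three
non-overlapping 5-s segments. "Variability" is the standard deviation
throughout. A zero-range chunk takes the degenerate path: zero peak and
IF features.

The classifier is a 100-tree random forest (scikit-learn defaults
otherwise, fixed seed). On the default synthetic database it reaches
~0.98 ten-fold CV accuracy and ~0.97 held-out accuracy after
discrimination; these numbers are recomputed by the test suite, not
stored.

The CSR morphology test takes the maximum-amplitude peak as the boundary
and requires strictly increasing amplitudes before it and strictly
decreasing after. Near-equal peak amplitudes can satisfy strict
monotonicity by chance, so the test is only consulted for chunks the
classifier already labelled CSR.

## Radar selection details

Candidates are covering radars sorted by |∠RMD − 90°| with ties broken by
lower radar id. Conflicts (shared radar, chest distances closer than
6 bins ≈ 30 cm) demote the subject with the worse angle to its next-best
candidate, iterating until conflict-free; a subject with no viable
candidate left is reported uncovered rather than given a corrupted-bin
signal. The result is independent of subject iteration order.

Because ∠RMD uses only the shoulder axis, it cannot distinguish facing a
radar from facing directly away from it; with radars on opposite walls a
subject can be assigned the radar behind their back (which then sees no
chest echo and the window degrades to apnea/non-stationary). This
front/back ambiguity is a known limitation of the orientation criterion.

## What passing tests do and do not show

The simulator's clean geometry, additive echo model and noise-free subject
identity mean that passing tests demonstrate the *algorithmic* correctness
of each stage and of their composition — bin arithmetic, selection logic,
gating, recovery of scripted parameters — under the stated statistical
structure. They do not demonstrate performance on real radar data, where
multipath, body-motion harmonics, skeleton-tracking dropouts and
inter-person variability dominate the error budget.

## Numerical choices

- Resampling: linear interpolation; the breathing band (< 0.5 Hz) is far
  below Nyquist at 17 Hz.
- Band-pass: 3rd-order Butterworth 0.1–0.5 Hz applied forward-backward
  (zero phase) so peak times are not shifted; with the 0.1 Hz corner the
  impulse response spans seconds, so stop-band attenuation on a 15-s chunk
  is partly masked by edge transients.
- RR estimation reuses the SQI's breath detector (median filter,
  normalisation, prominence 0.15), making the estimate invariant to
  amplitude scaling; RR = 60 / mean peak interval.
- Degenerate inputs: single skeleton sample → stationary; zero-range chunk
  → SQI fail with zero breaths; subject beyond recorded range contributes
  nothing to a matrix (logged).
- Test problem sizes: 15–60 s scenes, 20 seeds per rate for RR recovery,
  250-chunk training database with 150 held-out chunks — small enough to
  run the whole suite in well under a minute per module while keeping the
  stochastic checks stable across seeds.
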