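# Methods

## Signal model

The package operates on the eye aspect ratio (EAR), a per-frame scalar
computed from six eye landmarks: the two vertical lid distances
‖p2 − p6‖ and ‖p3 − p5‖ over twice the horizontal corner distance
‖p1 − p4‖. Open eyes give a plateau near 0.25; closure drives the ratio
toward 0. EAR is dimensionless and invariant under similarity transforms
of the landmark set (asserted numerically to 1e-9 in the tests), which is
what makes thresholding comparable across camera distances and poses.

When a recording provides both eyes, the per-frame value is the mean of
the two per-eye EARs by default (falling back to the available eye), with
`left`, `right` and `min` as alternatives. The formula is defined per eye
and nothing in the data dictates a combination rule; the mean was chosen
as the lowest-variance symmetric option and is configurable.

Frames where the landmark detector returned nothing are kept in the
series as missing values (NaN), not dropped. Run-based detection treats
them as run breakers, so dropout (e.g. mask wearing, head turns)
monotonically undercounts blinks — a real failure mode the pipeline
reproduces rather than hides. An optional `bridge_gap` (default 0) merges
runs separated by at most that many non-qualifying frames.

## Blink detection

Two rules are implemented.

*Fixed rule*: one blink per maximal run of at least `min_run = 3`
consecutive non-missing frames with EAR ≤ 0.163 (both constants
configurable; the comparison is inclusive). This is the classical
approach; it undercounts for individuals whose partial closures never
reach the threshold and cannot classify blink types.

*Dynamic dual-threshold rule*: per-recording thresholds proportional to
the individual's EAR span,

    full    = (0.1281 / 0.27527) × (MaxEAR − MinEAR)
    partial = 1.4 × full

with MaxEAR/MinEAR the raw extrema over all processed frames. The
coefficient is treated as a fixed empirical constant. Events are maximal
runs of ≥ `min_run` frames at or below the *partial* threshold and are
classified FULL when the event minimum reaches the full threshold,
PARTIAL otherwise. Segmenting at the partial threshold and classifying by
the event minimum is deliberate: a full blink's entry and exit frames
necessarily traverse the partial band, and per-frame classification would
double-count them as spurious partial events. `min_run = 3` is reused
from the fixed rule for the dynamic detector.

**Threshold reference.** As printed, the thresholds are absolute EAR
values proportional to the span. For an individual whose MinEAR sits far
above zero, an absolute full threshold near 0.46 × span may be
unreachable (span small, floor high). The default mode compares raw EAR
against the thresholds exactly as the formula is written; an `offset`
mode compares the excursion depth (EAR − MinEAR) instead, which is
invariant to a constant shift of the whole trace. Both behaviors are
asserted in tests; the ambiguity is inherent to the formula and
documented rather than resolved silently.

**Metrics.** Counts are normalized to per-minute rates by the actual
recording duration (count × 60 / duration), since real recordings run a
few seconds over or under a minute. The reported open/close ratio is
defined here as 100 × MinEAR / MaxEAR; this definition is a package
convention without clinical validation and is excluded from scoring and
from all quantitative checks.

## Eye healthiness score

Five components with fixed weights: full blink rate > 30/min (3 points),
partial blinks > 5/min (3), dry/gritty feeling (2), woman over 50 (1),
regular contact-lens wear (1); the comparisons are strict, so exact
boundary values score nothing. Totals map to NORMAL (0–3), MILD_DED
(4–6, triggers the alert at ≥ 4) and SEVERE_DED (7–10); the three-band
reading follows the prose definition of the severe band. Rates fed to
the score are the duration-normalized per-minute values.

The packaged pilot cohort (10 DED patients, 10 controls) reproduces the
formula exactly for every participant whose questionnaire inputs are
determined by the pilot table; for two patients (DED8, DED9) no
dry/gritty answer yields the printed total, and the package implements
the formula as specified rather than the irreproducible rows — the
discrepancy is asserted in a dedicated test and the two questionnaires
are omitted from the packaged set.

## Cohort statistics

Group summaries are arithmetic means with display rounding half-up to one
decimal (full precision retained internally). Group comparisons use the
two-sided Student's pooled-variance t-test by default, Welch's by flag,
via `scipy.stats.ttest_ind`. On the pilot table the eye score separates
the groups at p = 0.00022 and the partial-blink rate does not (p = 0.117)
until the three screen-positive controls are regrouped as DED
(p = 0.031). The full-blink column separates the groups at p = 0.016
(Student's; 0.021 Welch) — notably short of the p < 0.001 level
the pilot analysis reports for it; no standard test variant on the
recorded columns reaches that level, and the corresponding check is left
failing as documentation of the discrepancy.

## Synthetic recordings

The generator emulates a one-minute, fixed-frame-rate recording: a
plateau at `open_level = 0.25` (the canonical open-eye EAR), trapezoidal
dips — `ramp_frames = 2` descent frames, ≥ 3 bottom frames, symmetric
ascent — to `full_depth = 0.02` for full blinks and to half the
open-to-closed span (0.135) for partials, which places partial bottoms
between the two noise-free dynamic thresholds (0.107 and 0.150).
Trapezoids are deliberate: instantaneous dips would never exercise the
entry/exit double-counting hazard the segmentation rule exists to handle.
Events are placed uniformly at random without overlap (≥ 2 open frames
apart); i.i.d. Gaussian noise (σ default 0.005, ≈ 2% of the open level —
no empirical noise model exists for this signal) is added after the
shape and clipped at 0; dropout runs are applied last as missing frames.
One seeded generator drives all randomness, so a (spec, seed) pair is
fully reproducible. Group presets draw event counts near the observed
means (≈ 22 full / 2.5 partial per minute for controls, ≈ 37 / 6 for DED)
clipped to the observed ranges.

What the generator does *not* emulate: autocorrelated sensor noise,
drift of the open plateau, saccade artifacts, asymmetric or variable
blink kinematics, and landmark-level jitter. Passing recovery tests
therefore show the detector is correct for the idealized signal class,
not that it matches manual counts on real video.

### Noise sensitivity of extrema-derived thresholds

Because the dynamic thresholds are proportional to the raw sample
extrema, i.i.d. per-frame noise biases them upward: over ~1800 frames the
sample maximum of the plateau exceeds the true level by ≈ 3.3 σ, and
clipping pulls the minimum to 0, so at σ = 0.01 the full threshold rises
from 0.107 to ≈ 0.132 — within one σ of the default partial-dip bottom,
and partial events then misclassify as full through their own noise
minima. Measured ground-truth recovery (exact (full, partial) counts,
100 seeded replicates of 10 full + 2 partial events): 100% noise-free,
100% at σ = 0.002, 98% at σ = 0.005, 7% at σ = 0.01. The acceptance-level
check asserts the specified 99% at σ = 0.01 and fails accordingly; this
is a genuine fragility of span-proportional thresholds under frame-level
noise, relevant to real deployments, and is documented rather than
patched (robust-percentile extrema are available as an explicit opt-in
but are not part of the validated pipeline).

## Problem sizes and numerics

Tests run on one-minute, 30 fps traces (1800 frames); oracle comparisons
use 1000 random series for run counting and the full boundary grid for
scoring. Threshold comparisons are inclusive (≤); the coupled threshold
pair is validated to 1e-12; similarity invariance to 1e-9; means against
brute force to 1e-12. Degenerate inputs fail loudly: coincident eye
corners, empty or all-missing series, empty groups, zero-variance t-tests
and infeasible event placements each raise a typed exception.

## Known limitations

- No landmark extraction from pixels: the package starts at landmark or
  EAR level by design; any detector adapter producing `LandmarkFrame`s
  can feed it.
- The scoring weights are fixed integers from a small pilot; they are not
  regression-calibrated, and two recorded pilot totals are not
  reproducible under the formula (see above).
- The open/close ratio lacks a validated definition.
- Dynamic thresholds assume the recording contains both a genuine open
  plateau and at least one full closure; traces without full blinks
  compress the span and both thresholds with it.
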