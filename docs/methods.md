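# Methods

## Event detection model

The detector treats the console overlay as a deterministic signal: each
console function (cut and coagulation pedals per arm, clutch, third-arm
swap, camera) drives one on-screen indicator whose appearance differs
between the *inactive*, *hover* (foot above the pedal, not pressing) and
*active* (pressed) states. Detection is per-frame template matching inside
a fixed region of interest, followed by discretization of the per-frame
state sequence into events.

**Matching metric.** The score is the normalized correlation coefficient
(Pearson correlation over the ROI pixels, all channels flattened). This
choice fixes the scale of the thresholds: a pixel-identical match scores
exactly 1, uncorrelated noise scores ≈ 0 ± 1/√N for N pixels, and the
operating thresholds (0.95 for cut/coagulation/clutch, 0.90 for camera and
third-arm swap) sit far above the noise floor. Flat (zero-variance)
patches are handled explicitly: a flat crop matches a flat template only
when pixel-identical, since the correlation is otherwise undefined — this
prevents a blank ROI from spuriously "matching" a blank template of a
different shade. The cut channels default to the coagulation threshold
(0.95): both are pedal indicators with the same on-screen footprint, and
no separate operating value is established for cut.

**Resolution binding.** Template matching does not generalize across
resolutions: templates recorded at one frame size never match footage at
another, which silently yields zero events. `validate_templates` therefore
reports a per-indicator OK/MISMATCH verdict and `scan_video` refuses to run
on any mismatch, making the failure loud and named rather than a plausible
all-zero result.

**Event semantics.** One event is one maximal run of active frames (a
rising edge of the active state): counts are meant to match how a human
rater counts pedal presses or clutch uses, not how long a pedal was held.
Hover frames are recorded in the state sequence for audit but are never
events, and a hover frame inside an active run splits it — the pedal was
demonstrably released. Debouncing is available but off by default
(`min_gap_frames=1`, `min_duration_frames=1`, i.e. raw maximal runs),
because no debouncing rule is established for console footage; both knobs
are monotone (raising either never increases the count), which the tests
check, so they can only merge or drop events, never invent them.

**Laterality.** The side suffix of a channel (`CUT_L`, `COAG_R`, …)
reflects which side of the picture the indicator refers to; each side has
its own ROI and is counted independently. Clutch differs by generation:
the Si console clutches both hand controllers conjointly (one `CLUTCH`
channel), the Xi per arm (`CLUTCH_L`/`CLUTCH_R`). Profile validation
enforces the generation-consistent channel set.

## Hand-path kinematics

Landmark detection is deliberately a *contract*, not a bundled model: any
callable that maps a frame to `(hand, landmark, x, y, confidence)` tuples
plugs in, and pre-computed streams load from CSV. This keeps the
kinematics testable without a pretrained network and decouples the metric
from any particular tracking library. Observations below a confidence
threshold (default 0.5; no principled value exists, 0.5 is the customary
binary-classifier midpoint) or outside the frame are invalid and create
gaps.

Path length is the sum of Euclidean distances between consecutive valid
observations, in pixels — the motion camera has no metric calibration, so
only relative comparisons between surgeons filmed with the same setup are
meaningful. Two gap policies are reported:

* **bridge** (default): a straight segment spans each tracking dropout.
  This reproduces what a naive dot-to-dot trail overlay measures,
  including its known artifact — long straight jumps when a hand leaves
  the field of view.
* **split**: gaps break the path; by the triangle inequality split ≤
  bridge for every track. This is the robust variant and the recommended
  one when dropouts are frequent.

Both are cheap; reporting both makes the dropout sensitivity of a
recording visible as their difference.

The overlay renderer draws a dot per observation and a persistent trail
(left hand blue, right green) by dense line sampling; segments are drawn
per observation pair without resampling.

## Annotation handling

The TSV dialect requires a header with Time/Behavior/Status columns
(case-insensitive); extra exporter columns are ignored, times are decimal
seconds. START/STOP pairing uses one LIFO stack per behavior: a STOP
closes the most recent open START of the same behavior. Nesting of the
same behavior never occurs in practice but is permitted by default (the
permissive reading); `strict=True` rejects it. Unmatched STOPs and
dangling STARTs are hard errors naming the behavior — silent dropping
would bias counts.

Clip boundaries are `[round(start_s·fps), round(stop_s·fps))`, half-open,
so clip frame counts are bit-reproducible. Aggregation counts *paired
intervals* (equivalently STARTs of well-formed files) per subcategory;
category totals are sums of their subcategories by construction and the
invariant is enforced in `CountTable`.

## Cohort summaries

The novice/experienced boundary is 100 prior RAS procedures, following
the customary learning-curve grouping; the boundary value 100 itself is
assigned to the experienced group ("under 100" defines the novices, so
100 is not under it). Spread is the sample standard deviation (n−1); with
one session the SD is reported as NA rather than 0. Durations are stored
in seconds and additionally formatted as `mm.ss` strings for report
parity. Because session durations vary widely, tables are emitted both as
raw per-session counts and as per-minute rates (`count / (duration/60)`).

## Synthetic data: what it emulates, what it does not

The simulator renders the *indicator semantics* of a console feed: a
seeded pseudo-random background (fixed per video) with each scripted span
painting the channel's active or hover template into its ROI on the frame
grid (`[round(start·fps), round(end·fps))`). The detection templates are
crops of the same renderer, so profile and footage agree by construction —
the point is to exercise the full scan → match → discretize → count
pipeline against exact ground truth, not to imitate surgical imagery.

Toy profiles (320×180, 15 fps, striped 28×22 glyphs, distinct color pairs
and stripe orientations per channel and state) keep the closed loop fast.
Timelines generated by `random_timeline` leave at least two inactive
frames between spans of a channel so every scripted span is one maximal
run, and may precede a press with a hover span, which must *not* be
counted.

**Noise robustness.** With additive Gaussian pixel noise of standard
deviation σ on an 8-bit scale, the expected correlation of a noisy ROI
against its template is ≈ 1/√(1 + σ²/σ_t²) where σ_t ≈ 60 is the
template's own pixel SD. The pinned amplitude `MAX_EXACT_NOISE_SIGMA = 8`
keeps scores near 0.99 — comfortably above the 0.95 threshold — and the
suite asserts exact count recovery at that amplitude. This documents a
margin, not a cliff; real capture noise is far below σ = 8.

What the simulator does **not** emulate: compression artifacts, camera
shake, partial occlusion of indicators, brightness drift, interlacing, or
any anatomy. Passing closed-loop tests therefore demonstrates the
correctness of the pipeline's logic and geometry, not the adequacy of any
particular threshold on real footage — thresholds remain per-installation
calibration, which is why they live in the profile.

Label packing lays requested interval counts on an even grid over the
duration (each interval 80 % of its slot, ≥ 1 ms) and shuffles behaviors
with the seed, guaranteeing a well-formed file whose aggregation equals
the request; infeasible packings raise instead of truncating.

## Video I/O and synchronization

Multi-page TIFF is the native container: lossless (pixel-exact round
trips are assertable, and the stereo-crop reconstruction invariant is
tested exactly), dependency-free, with the frame rate stored in the TIFF
description. MP4/AVI are supported through imageio's ffmpeg plugin when
present; production users will typically transcode to TIFF for analysis
or install the plugin.

Stereo side-by-side frames split at the exact midline (odd widths are a
hard error rather than a rounded guess). Two-stream synchronization uses
a shared physical marker (e.g. a clap visible in both the console feed
and the motion camera): given the marker's frame index in each stream,
`offset_s = f_a/fps_a − f_b/fps_b`, and `apply_offset` shifts timestamps
by −offset onto the common clock, clamping at zero with a per-record flag.
Finding the marker frame is deliberately manual input: automatic clap
detection is out of scope.

## Problem sizes

The default suite renders ~20 s clips at 320×180/15 fps; the acceptance
script uses 20 timelines per generation, 2¹² + 10,000 state sequences for
the oracle comparison, 1,000-step landmark walks, and the full ~4,400
interval annotation campaign. These sizes were chosen so the whole
closed loop stays well under a minute on one core while every check is
exact rather than statistical.

## Known limitations

* No automatic discovery of indicator positions: profiles are calibration
  artifacts produced per installation.
* Per-file threshold overrides exist, but no preset is shipped for
  low-resolution captures, which in practice need bespoke templates.
* 3D (depth-camera) path length is out of scope; outputs are 2D pixels.
* The landmark CSV format carries one observation per (frame, hand,
  landmark); multi-detection fusion is the detector's job.
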