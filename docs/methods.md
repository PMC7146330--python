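# Methods

This note documents the models and procedures `jellyquant` implements, the
parameters that matter, the numerical conventions, and what the synthetic
validation does and does not demonstrate.

## Coordinate and box conventions

Boxes are axis-aligned rectangles in continuous pixel coordinates with the
origin at the image's top-left corner, under a **half-open** convention: a
box covers `[xmin, xmax) × [ymin, ymax)`, so `area = (xmax−xmin)·(ymax−ymin)`
exactly and edge-touching boxes have zero intersection. PASCAL VOC XML (the
LabelImg dialect) stores 1-based *inclusive* integer coordinates; the readers
convert with `xmin_internal = xmin_voc − 1`, `xmax_internal = xmax_voc`
(likewise for y), and the writers invert this and round to the nearest
integer, as LabelImg itself writes integers. The conversion is its own
inverse for integer-aligned boxes. Degenerate (zero-area) boxes are rejected
at construction, so IoU — intersection area over union area — is always
well-defined, in `[0, 1]`, and equal to 1 only for identical boxes.

Confidences are stored as fractions in `[0, 1]` and rendered as percentages
in reports and thresholds (C<sub>thr1</sub>, C<sub>thr2</sub>); a detection
*survives* a threshold t% iff `confidence ≥ t/100` (instances *lower than*
the cutoff are deleted).

## Non-maxima suppression

Greedy, by descending confidence: each kept detection suppresses every
remaining detection whose overlap with it exceeds the threshold (default
0.40 — restrictive, because jellyfish rarely appear superimposed). Ties in
confidence break by input order, then lower `xmin`, making the result
deterministic; the procedure is idempotent. Suppression is
**class-agnostic**: overlap between boxes is a geometric signal independent
of species. The overlap measure is pluggable — IoU (default) or
intersection-over-min-area, the latter reading an "intersection area"
threshold as a fraction of the smaller box so that a small box swallowed by
a large one is always suppressed. NMS runs on both the prediction branch
and (by default, switchable off) the quantification branch.

## Detection evaluation

Matching follows the PASCAL VOC protocol. Within each frame and class,
predictions in descending-confidence order claim the unmatched ground-truth
box of highest IoU, provided IoU ≥ thr_iou (default 0.5); a claimed box
cannot be matched again, so duplicate detections of one animal are false
positives, as are wrong-class detections regardless of overlap. Unclaimed
ground-truth boxes are false negatives. The `≥` comparison is used
uniformly. Invariants: `TP + FP = #predictions` and, per class,
`TP + FN = #ground truths`.

Precision `TP/(TP+FP)` and recall `TP/(TP+FN)` are defined as 0 when their
denominator is 0; F1 is their harmonic mean (0 when both vanish). Per-class
AP ranks all detections of the class across frames by confidence, computes
the cumulative precision–recall staircase with the same greedy matching,
and integrates the **monotone (non-increasing) precision envelope** over
recall in `[0, 1]` — the all-point interpolation; the older 11-point rule
(mean of the envelope at recall 0, 0.1, …, 1.0) is available by flag. mAP
is the unweighted mean of per-class APs and is an error, not a silent skip,
when a requested class has no ground truth (the CLI narrows to classes
present and logs the omission).

The operating threshold C<sub>thr1</sub> is found by sweeping the cutoff
over 0–100% in 1% steps; at each step predictions below the cutoff are
removed and the matching is recomputed in full, so removed true positives
re-appear as false negatives. The reported optimum maximises F1, ties going
to the **lowest** cutoff (retaining more detections); the full curves are
kept in the report so the choice is auditable.

The 10-fold splitter shuffles item ids deterministically by seed, cuts them
into folds of near-equal size, and gives run *i* the folds *i* and
*(i+1) mod k* as its test set (20% of the data for k = 10). Which two folds
form a test pair is a free choice; consecutive pairs keep every item in
exactly two test sets.

## Quantification

Each analysed frame becomes an information point: the per-species count of
detections surviving C<sub>thr2</sub>, timestamped `frame_id / fps` where
`fps` is the *analysis* rate (a property of the detector, carried in the
stream header, never measured here). Windows of `Wsize` consecutive points
advance by `stride = Wsize·(1−Wover)` points; non-integer strides are
rejected at configuration time rather than rounded (the standard grid
Wsize ∈ {4, 8, 12} × Wover ∈ {25%, 50%, 75%} gives strides 1, 2, 3, 6, 9).

The resulting count is the **mode per species independently**, not of the
joint count vector — per-species count traces are the monitoring product —
with ties broken toward the previous resulting value for that species
(temporal continuity) and then toward the lower count (conservatism against
false alarms); a joint-vector reduction was considered and rejected because
it discards per-species majorities whenever another species flickers.
Resulting points are stamped at the window's **final** contributing frame:
causal, real-time semantics — at the moment the window closes, its smoothed
count refers to "now". Consequently the gap between consecutive resulting
points is exactly `stride` frames, i.e. `Wsize·(1−Wover)/fps` seconds, and
inverting that formula transfers a cadence to a detector of different speed
(the inversion insists on an integer window, reporting neighbours
otherwise).

Similarity compares each resulting point against the manual timeline **at
that same final frame** (not against a windowed reduction of the truth): a
point is correct iff its full count vector matches, and Similarity is
100·correct/total. This choice has a structural consequence: around every
true count transition the modal window lags by up to about half a window,
so even a perfect detector scores below 100% on a scene with transitions
whenever `Wsize > 1`. The no-smoothing limit (`Wsize = 1`,
C<sub>thr2</sub> = 0, NMS off) reproduces the raw per-frame counts exactly
and is the configuration under which a perfect detector scores Similarity
100%. The C<sub>thr2</sub> sweep mirrors the C<sub>thr1</sub> sweep: 101
cutoffs, per windowing combination the best-Similarity cutoff, ties to the
lowest.

## Synthetic scenes and the detector model

The generator emulates a fixed camera watching slow-moving animals: per
species, arrivals are Poisson in time and dwell times exponential, so the
per-frame count is a birth–death process with mean simultaneous count
`arrival_rate · dwell_mean` per species; each individual's box performs a
reflected Gaussian random walk inside the image with fixed size. Defaults —
600 s at 1.6 fps, three species, arrival rate 0.0015 s⁻¹ and mean dwell
150 s per species, 1280×720 px images, boxes 60–200 px, 4 px/frame motion —
describe a sparse scene whose counts change a handful of times over ten
minutes, the regime the windowing is designed for. Denser scenes (for
evaluation-style tests) simply raise the arrival rate.

The detector model applies, per true box per frame: a miss with probability
`p_miss` (default 0.1), Gaussian jitter of each box edge (sd 3 px), a
species swap with probability 0.01, and a confidence drawn from
Beta(14, 2.5) (mean ≈ 0.85); spurious detections arrive as
Poisson(`fp_rate` = 0.05) per frame with random boxes and Beta(1.5, 8)
confidences (mean ≈ 0.16). The two Beta laws are deliberately
well-separated: true detections are mostly high-confidence, spurious ones
mostly low-confidence, which is what makes a low C<sub>thr2</sub> optimal
once windowing absorbs the spurious minority. All draws flow from one
seeded generator in a documented order (scene: species, then individuals;
detector: frame by frame, true boxes before false positives), so fixture
bundles are byte-stable given a seed.

**What the synthetic validation shows — and does not.** Passing the
20-seed, ten-minute pipeline check (mean Similarity ≥ 95% with the default
error rates and (12, 25%) windowing) demonstrates that the sweep + windowed
mode recovers slowly varying counts from sporadically corrupted streams. It
does not demonstrate detector quality on real imagery: the simulator has no
turbidity, lighting, occlusion structure or correlated failure bursts —
misses and false positives are independent across frames, the friendliest
case for a modal filter. Real correlated dropouts (a jellyfish fading into
backlight for many consecutive frames) defeat a window shorter than the
dropout, and nothing here measures that.

## Numerical and degenerate-input choices

* Published cadence tables truncate (not round) seconds to two decimals;
  the acceptance script reproduces that display convention
  (5.625 → 5.62, 1.875 → 1.87). Library functions always return exact
  values.
* Sweeps are exhaustive over the 101 integer percentages — no early exit,
  so tie-breaking is exact.
* Fewer information points than `Wsize` yields an empty result with a
  warning (not an error): short streams are expected at start-up.
* An empty prediction list makes Similarity and AP undefined (raised), not
  zero: silently scoring 0 would be indistinguishable from a genuinely bad
  run.
* `kfold_split` requires at least `k` items; fold sizes differ by at most
  one.
* Detection streams serialise with an explicit frame-id list in the header
  so frames where nothing was detected survive the round trip — they carry
  real information (count zero) for quantification.

## Problem sizes used in the checks

The bundled validation runs at sizes a laptop handles in seconds: 500
random frames for the NMS oracle, instances of ≤ 10 detections for the AP
staircase, 20 seeds × 960 frames for the pipeline analogue, 200 replicates
of 120-point streams for the window-size stability property. These sizes
give the statistical assertions (3-sigma Monte-Carlo bands, mean-Similarity
bounds) comfortable margins; nothing in the implementation depends on them.

## Known limitations

* No tracking or re-identification: counts, not individuals.
* Similarity is all-or-nothing per point; a one-animal miscount in a
  three-species vector scores the same as a total failure. A graded metric
  (e.g. per-species absolute error) would complement it for dense scenes.
* Class-agnostic NMS will merge two genuinely superimposed animals of
  different species — accepted because superimposition is rare in this
  application; use the per-measure flag and a higher threshold otherwise.
* The windowed mode reacts to true count changes with a lag of up to
  roughly `Wsize/(2·fps)` seconds; cadence and responsiveness trade off
  directly through `Wsize` and `Wover`.
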