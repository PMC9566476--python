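# Methods

This note records the models implemented in `depthact`, the parameter
choices that matter, and the places where the design was genuinely open.

## Depth codec

Depth is encoded through disparity (`disp = 1/d`) because disparity is the
quantity a stereo depth camera measures linearly; equal steps in disparity
give finer depth resolution near the camera, where the person is.  The
normalized disparity

    d_normal = (disp − disp_min) / (disp_max − disp_min) · 1529

is rounded half-up and clamped to the integer ranks 0…1528.  Rank 1529
would land on the same color as rank 0 (the hue circle closes), so the top
rank is clamped rather than wrapped; "1529 discrete ranks" therefore means
levels 0–1528.

The six-segment wheel is laid out as

| levels        | (r, g, b)        |
|---------------|------------------|
| [0, 255]      | (255, v, 0)      |
| (255, 510]    | (510 − v, 255, 0)|
| (510, 765]    | (0, 255, v − 510)|
| (765, 1020]   | (0, 1020 − v, 255)|
| (1020, 1275)  | (v − 1020, 0, 255)|
| [1275, 1528]  | (255, 0, 1529 − v)|

and decoded by the four-branch channel-dominance rule (red-dominant with
g ≥ b → `g − b`; red-dominant with g < b → `g − b + 1529`; green-dominant →
`b − r + 510`; blue-dominant → `r − g + 1020`, evaluated in that order).
One subtlety fixes the segment boundaries: pure magenta (255, 0, 255) is
claimed by the *red-dominant* decoder branch and would alias level 1274, so
the wheel places level 1275 in the last segment — (255, 0, 254) — and never
emits magenta.  With this layout decode∘encode is the identity on all 1529
levels, verified by exhaustive enumeration in the test suite.

Depth 0 is reserved as the "no sensor return" sentinel, encoded as black
(0, 0, 0) — a color the wheel cannot produce — and decoded back to 0.
Out-of-range depths clamp to [d_min, d_max].  The default range 0.5–5.0 m
is an indoor room scale; the bounds are configurable and are persisted in a
`range.json` sidecar next to encoded frames because decoding with a
different range silently rescales depth.  Colorized frames must be stored
in a lossless format (PNG); any lossy codec perturbs channel values and
breaks the dominance decoding, so the readers reject non-PNG content.

The round-trip depth error at depth `d` is bounded by the local
quantization step `d²·(disp_max − disp_min)/1529` (the full step, not the
half step, because of the clamp at the top rank).  For the 0.5–5.0 m range
that is at most 2.9 cm at 5 m, and the measured average MSE over 100
seeded smooth 120×160 maps is ≈ 1·10⁻⁵ m².

## Person detection

The pipeline only consumes one bounding box per frame.  The `Detector`
protocol abstracts any detector over colorized frames; the repository
ships a deterministic oracle for synthetic scenes that thresholds
`background − frame > min_delta` (default 0.15 m, i.e. a person must stand
at least 15 cm in front of the wall/floor plane), labels 8-connected
components, discards regions under `min_area` = 200 px², and returns tight
boxes sorted by area.  `select_primary_box` enforces the one-resident
assumption: largest area, ties to higher confidence, then the smaller
(y0, x0) corner.  Frames with no detection propagate a no-person marker
that the decoder and the scorer both skip.  Adapters for trained
object-detection models can implement the same protocol; none is required
for any test.

## Window features

Crops are resized to 128×128 *in color space* and then decoded to depth,
keeping the crop geometry fixed before any depth statistic is taken.  The
crop size is forced by the published descriptor length: with 8×8-pixel
cells, 2×2-cell blocks at one-cell stride and 9 bins, only a 128×128 map
yields 15·15·4·9 = 8100 entries (non-overlapping blocks would give 2304,
contradicting the stated dimensionality).

The two maps summarize a five-frame window:

* **DMA** — per-pixel mean of the five depth crops, min–max scaled to
  [0, 255] and quantized to integer gray levels; a constant window maps to
  all zeros.
* **DMH** — recency-coded motion history: for each consecutive pair
  t−1→t (t = 2…5), pixels whose depth changed by more than ε receive
  intensity 255·(t−1)/4 (64, 128, 191, 255), later motion overwriting
  earlier.  ε defaults to 0.05 m — above the synthetic sensor noise,
  below any real postural motion.

Both maps are described with unsigned-gradient HOG (scikit-image), L2
block normalization, concatenated DMA-first.  The exact DMA/DMH formulas
are not uniquely determined by their published description; the
definitions above implement the stated intent (overall shape; temporal
depth motion) and are isolated behind the `FeatureMap.kind` tag so
alternative definitions can be swapped without touching the HOG stage.
Whether HOG should see raw meters or 8-bit-scaled maps was also open;
8-bit scaling was chosen so both maps share one intensity convention.

## HMM recognizer

Five states (the actions) and five symbols, one per state template.
π is fixed uniform (0.2 each) and is *not* updated by Baum-Welch: it is an
assumption of the deployment (any action may start a recording), and
training it on per-state sequences would destroy that neutrality.

* **A** comes from co-occurrence counts over a long per-frame label
  sequence, Laplace-smoothed with α = 10⁻³ so Baum-Welch never starts from
  a structural zero.
* **B** row j is estimated by assigning a symbol to each held-out state-j
  descriptor and normalizing: each descriptor contributes a unit-mass
  Gaussian kernel placed at its L2 magnitude (bandwidth = per-row sample
  std of magnitudes, floored at 10⁻⁶); summing same-label kernels and
  dividing by total mass reduces exactly to per-label relative frequency
  because every kernel integrates to one.  The kernels, magnitudes and
  bandwidths are retained on the returned estimate object so a
  point-evaluated (non-unit-mass) reading could be substituted; relative
  frequency is the only reading that yields a proper row-stochastic B, so
  it is the default.
* **Symbol assigners**: mean-template (squared-Euclidean argmin over the
  per-state mean descriptors, ties to the smaller index), k-NN (k = 5,
  Euclidean, majority vote, vote ties broken by smaller mean neighbor
  distance), and linear SVM (one-vs-rest, C = 1, seeded).  k and the SVM
  kernel were open choices; k = 5 matches the window length and a linear
  kernel is the standard default for 16,200-dim HOG features.
* **Baum-Welch** runs scaled forward–backward over the held-out set's
  duplicated symbol streams (one sequence per state, length 5·n).  How the
  held-out descriptors become training sequences was an open design point;
  grouping per state mirrors how the emission rows are estimated and keeps
  the streams class-pure.  Probabilities are floored at 10⁻⁸ and
  renormalized each iteration; convergence at 10⁻⁴ log-likelihood change
  or 100 iterations.  The log-likelihood trace is monotone non-decreasing
  (EM guarantee; asserted per iteration in the tests).
* **Viterbi** decodes in log space, ties toward the smaller state index.
  It is cross-checked in the tests against exhaustive path enumeration
  (all 5⁸ paths at T = 8) and against hmmlearn's reference decoder.

### Inference protocol

One symbol per five-frame window, duplicated five times, keeps the
observation stream frame-aligned; a trailing remainder shorter than five
frames inherits the last window's symbol so predictions always cover every
frame.  Each 60-frame minute is decoded independently — no state is
carried across chunk boundaries — and chunks with fewer than five detected
frames are emitted as no-person markers with a warning.

### Evaluation

Frame accuracy is 100·correct/evaluated, rounded half-up to two decimals,
with marker frames excluded from both sides.  Confusion matrices count
frames (rows = actual); per-action accuracy is the diagonal over the row
sum, with empty rows reported as absent; the overall accuracy derived from
a confusion table can be rounded to the integer convention used when such
tables are printed.  Room-level aggregation is the unweighted mean of
per-room accuracies, two decimals.

## Synthetic scenes

The generator emulates the *structure* of a care-room depth recording at
1 fps: a static planar background (2.5 m at the top row to 4.5 m at the
bottom, inside the 0.5–5.0 m codec range), one person as an elliptical
blob `depth_offset` meters in front of the background, Gaussian depth
noise (default σ = 0.01 m, typical of stereo depth at room range), and a
scripted action timeline.  Posture geometry: standing tall/narrow
(18×70 px half-axes, 1.2 m offset), sitting 30×40 at 1.0 m, lying 75×20 at
0.8 m, seated 26×34 at 1.1 m plus a wheelchair block under the torso.
Transition segments linearly interpolate every pose parameter between the
neighboring postures, which also produces the inter-frame motion DMH keys
on; static-action training sequences hold a slightly jittered pose.
Script durations default to multiples of the five-frame window so segment
boundaries align with feature windows, as they do when features fire every
five frames from the start of a recording.

What the generator does **not** emulate: articulated human silhouettes,
occlusion by furniture, depth shadows/holes beyond the sentinel mechanism,
multiple people, camera motion, and the appearance ambiguity between
visually similar postures that dominates errors on real recordings.
Passing the end-to-end synthetic bar (≥ 90% frame accuracy with the SVM
assigner) therefore demonstrates that the stages compose correctly and
that the protocol's bookkeeping (windowing, duplication, chunking,
marker handling) is sound — not that comparable accuracy would be reached
on real depth video.

## Problem sizes and numerical choices

Full-scale datasets are 900 training and 100 emission sequences per state;
tests and examples run the same code at 12/6 per state and a 320×240
scene, sizes chosen so the whole suite stays at desk scale while every
state and code path is exercised.  The codec audit uses 100 maps of
120×160.  Degenerate inputs fail loudly: zero-area boxes, ragged CSV rows,
non-PNG images, empty descriptor classes, zero-probability sequences under
the current model (reported with the sequence index), and empty
observation streams all raise with specific messages.  All randomness
flows through `numpy.random.Generator` seeds; dataset generation spawns
disjoint seed streams for the training and emission sets so they never
share a rendered frame.

## Known limitations

* The emission model is discrete with five symbols; a continuous-emission
  HMM over descriptor space is out of scope.
* The oracle detector requires a known empty-scene background and is not a
  substitute for a trained detector on real footage.
* Accuracy on real recordings depends on detector quality and posture
  ambiguity that the synthetic generator deliberately does not model.
* `estimate_transitions` treats the label sequence as one continuous stay;
  concatenating unrelated recordings inflates cross-action counts at the
  seams.
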