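# Methods

`wildtrack` detects and tracks large, poorly textured animals (the design
target is elephants) in unconstrained wildlife video. No assumptions are
made about camera motion, background, pose, or the number of animals.
Because shape (occlusion, pose variety), fine skin texture (invisible at
distance), and motion (animals often rest) are all unreliable cues, the
method uses color as the *initial* cue — deliberately permissive — and then
prunes the resulting false positives with spatiotemporal consistency
analysis.

## Pipeline

1. **Preprocessing.** Frames are downscaled by `scale` (default 0.25 for
   full-HD input) with area averaging and converted to CIE L\*u\*v\*
   (sRGB/D65, L in [0, 100]), where Euclidean distance approximates
   perceptual color distance.
2. **Color segmentation.** Joint spatial+range mean-shift filtering with
   flat kernels (pixel positions fixed, range estimate iterated to a local
   color mode, ≤5 iterations), then 4-connected labeling of pixels whose
   filtered colors are within the range bandwidth, then merging of regions
   smaller than `min_segment_size` into the most similar-color 4-connected
   neighbor (ties: lower id). Each segment carries the mean of the original
   LUV pixel colors.
3. **Color model.** Per annotated training image, the foreground and the
   background side are segmented independently (the other side blanked);
   each segment contributes its mean color with its side's label. An
   RBF-SVM is trained on these lists. The foreground class gets
   misclassification weight `cost_ratio × n_bg/n_fg`: the cost asymmetry
   the method requires (missing an animal is worse than a false alarm),
   applied on top of inverse-class-frequency balancing because the
   background list is always much longer. Gamma is chosen from a
   logarithmic grid as the *sparsest* model (fewest support vectors, ties
   to smaller gamma) among those whose balanced five-fold CV accuracy is
   within 0.02 of the grid's best — sparsity is only meaningful among
   models that separate both classes; judged unconditionally it selects a
   degenerate boundary that ignores the minority class.
4. **Luminance filter.** Near-black/near-white colors carry unreliable
   class evidence. Foreground training samples with L below `lower_pct` or
   above `upper_pct` of the theoretical L range [0, 100] are dropped before
   training (the theoretical range keeps the cut stable across training
   sets). (0, 100) disables the filter; (10, 90) and (20, 80) are the
   medium and strong settings.
5. **Classification.** One-stage classifies a segment's mean color;
   two-stage (default) classifies every pixel and accepts iff the positive
   fraction is strictly above the vote threshold (default 2/3 — the strict
   "above" is load-bearing and boundary-tested). Two-stage is more robust
   because a mean color can look animal-like while the pixel distribution
   does not.
6. **Tracking.** Each candidate mask is traced ±`w` frames by dense
   optical flow (iterative warp; nearest-neighbor forward splatting plus
   one closing pass, on a padded grid so border-clipped masks are not
   eroded). In every window frame the trace is intersected with the
   candidates there; a link is kept iff the Jaccard confidence
   c = |T∩S|/|T∪S| is strictly above `C`. Links spanning up to `w` frames
   bridge detection gaps. The undirected graph over candidates (duplicate
   links collapse to max confidence) is decomposed into connected
   components; per component and frame, member masks are unioned. This
   handles splits and merges without one-to-one matching.
7. **Spatiotemporal features.** Per track: duration (span, last−first+1),
   instability (gap fraction of the lifetime), shape change
   (max−min)/max of per-frame areas, and two texture summaries built on a
   5-bin oriented edge histogram (2×2 blocks of the masked region scored by
   the five MPEG-7 edge filters; a block is an edge block iff the max
   response ≥ `edge_threshold`): edge density (mean summed histogram) and
   texture variation (mean per-bin range over time). Only observed,
   non-interpolated frames contribute, since validation runs before gap
   filling.
8. **Validation.** One threshold per feature, calibrated to a *safe* value
   on labeled tracks: on a constant-step grid (step = observed range/100)
   the threshold keeps every true detection while the kept subset is
   minimal; decisions combine by logical AND, so thresholds stay mutually
   independent. Orientations: long duration is good (reject below); high
   instability, shape change, edge density, texture variation are bad
   (reject above). Ties at the threshold pass, so calibration extrema are
   accepted. If a calibration sequence contains no true track, every track
   is rejected (the minimal safe subset is empty). An SVM over the
   5-feature space is available as an alternative validator.
9. **Gap filling.** Gaps inside validated tracks (≤ `w` by construction)
   are closed by flow-propagating the temporally nearer flanking mask
   (ties: earlier flank). Interpolated frames are flagged and excluded from
   any later feature computation.
10. **Evaluation.** Detection rate = ground-truth region instances hit /
    all region instances (a region hit twice counts once); false-positive
    rate = detections coinciding with no region / all detections. Counting
    is per frame-level region instance. A detection that touches a region
    and background counts as a hit by default (`mixed_policy` switches
    this). The spatial coincidence criterion is `min_overlap` on
    overlap/detection-area, default any positive overlap.

## Parameters

| name | default | meaning |
| --- | --- | --- |
| `scale` | 0.25 | downscale factor (1.0 for already-small synthetic frames) |
| `spatial_bandwidth` | 8 px | mean-shift spatial kernel radius |
| `range_bandwidth` | 8 LUV | mean-shift range kernel radius |
| `min_segment_size` | 150 px | minimum surviving segment (near-distance); 20 px for far-distance work |
| `cost_ratio` | 2.0 | extra foreground misclassification cost (on top of class balancing) |
| `luminance_limits` | (0, 100) | foreground L percentile cuts |
| `vote_threshold` | 2/3 | two-stage pixel-vote acceptance fraction (strict >) |
| `w` | 5 frames | temporal analysis window each direction |
| `C` | 0.5 | trace-intersection confidence threshold (strict >) |
| `edge_threshold` | 11 | edge-block threshold on a 0–255 intensity scale |
| `min_overlap` | 0 | spatial coincidence criterion for evaluation |

`w`, `C`, the bandwidths, the cost ratio, and the gamma grid are tunables
with no single canonical value; the defaults above are the package's
fixed study conditions. Raising `C` strictly sparsifies the connectivity
graph (edge sets are nested in `C`); raising `w` lets tracks bridge longer
gaps.

## Synthetic scenes

The generator renders what the method assumes about real footage, not how
it looks: elliptical gray-brown low-texture blobs (palette defined in LUV:
low chroma, mid luminance) over a textured green background with clutter
patches; a configurable fraction of clutter is drawn from the *foreground*
palette (default 0.3) so that color alone cannot reject it — these
confusable patches carry high-amplitude luminance texture, which is exactly
what the texture features key on. The whole background pans (default 2
px/frame), blobs ride the pan plus small own motion, and a schedule hides
blobs for a few frames while the ground truth stays continuous (flagged
occluded). Optional near-black/near-white low-texture confusers, together
with shaded/highlighted blob parts in the training images, exercise the
luminance filter: with the filter off those patches become validated false
positives; the (10, 90) filter removes the extreme foreground training
colors and with them the false positives, at ≤2 points detection loss.
Exact dense flow fields are emitted alongside the frames and can be
injected into the tracker, which separates tracking correctness from flow
estimation quality.

What the generator does **not** emulate: perspective, shading gradients on
curved bodies, partial (as opposed to scheduled whole-blob) occlusion
boundaries, motion blur, zoom, and photometric drift. Passing tests
therefore demonstrate the correctness and the qualitative behaviour of the
machinery — not field-footage performance figures.

Standard synthetic conditions: 320×180 frames, 24 frames per sequence,
3 blobs, 12 clutter patches, noise σ=2 (8-bit). At this working resolution
the pipeline config uses `spatial_bandwidth=4` and `min_segment_size=40`
(blobs are tens of pixels across). Training uses 16 generated annotated
images — within the 10–20 image regime the method is designed for.

## Numerical choices and edge cases

- Jaccard confidence of two empty masks is an error, not 0; it cannot arise
  from real candidates.
- Mask warping re-binarizes at any positive splat occupancy; the closing
  pass runs on a 2-pixel padded grid to avoid border erosion.
- Undersized-region merging processes regions smallest-first
  (deterministic); color-distance ties break to the lower region id.
- `duration` exposes both readings of lifetime — `span` (default, keeps
  duration consistent with the gap-fraction definition of instability) and
  `present` (frames actually detected) — behind `duration_mode`.
- The edge histogram uses the L channel rescaled to 0–255 so the default
  edge threshold 11 retains its reference meaning; blocks are 2×2 pixels
  over the merged track mask (one 5-bin histogram per track per frame, not
  the 80-bin whole-image descriptor).
- Safe-threshold grids are anchored at the minimum observed value over both
  classes; floating-point grid indices are guarded with a relative epsilon.
- Exact mid-gap interpolation ties propagate from the earlier flank.
- Track labeling for calibration: a track is a true detection when more
  than half of its observed frames coincide with a ground-truth region.

## Limitations

- Re-identification across absences longer than `w` is out of scope; such
  tracks legitimately remain separate.
- The estimated-flow backend (pyramidal iterative Lucas-Kanade on L) is
  adequate for the dominant-translation scenes tested; large non-rigid
  motion would need a stronger flow method behind the same provider
  interface.
- Validation calibrated on a sequence with no true detections rejects
  everything; calibrate on sequences known to contain the target animal.
- Quantitative performance on real wildlife footage depends on the corpus
  at hand; the synthetic results here characterize the machinery and its
  qualitative behaviour, not field performance.
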