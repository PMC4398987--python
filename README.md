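# wildtrack

Detection and tracking of large, poorly textured animals — elephants being
the design target — in unconstrained wildlife video: handheld cameras,
pans, clutter, occlusions, no staging. Biologists collect hundreds of
hours of such footage and need to know *where* and *when* animals appear
without scrubbing through it linearly.

Animals like elephants defeat the usual cues: their shape varies wildly
with pose and occlusion, their skin texture is too fine to resolve at
distance, and they often stand still. Color is the one usable initial cue
— and it is weak, because sandy ground and rocks share the gray-brown
band. `wildtrack` therefore runs a deliberately permissive color detector
first and cleans up afterwards with spatiotemporal reasoning:

1. **Color segmentation** — frames are downscaled, converted to CIE
   L\*u\*v\*, and partitioned into coherent color segments by mean-shift
   filtering.
2. **Trainable color model** — an RBF-SVM over segment mean colors,
   learned from 10–20 annotated images, with higher misclassification cost
   on the foreground class. Segments are accepted per pixel-vote: a
   segment is a candidate iff strictly more than 2/3 of its pixels
   classify as foreground.
3. **Trace-intersection tracking** — each candidate mask is propagated
   ±w frames by dense optical flow; a temporal link is kept iff the
   Jaccard overlap with a candidate there satisfies c = |T∩S|/|T∪S| > C.
   Connected components of the resulting graph are the tracks; this
   absorbs the splits and merges that frame-wise segmentation produces and
   bridges detection gaps up to w frames.
4. **Spatiotemporal validation** — per track, five features (duration,
   instability, shape change (max−min)/max of areas, edge density,
   texture variation from 5-bin oriented edge histograms) are each cut at
   a *safe* threshold calibrated so that no true detection is lost, and
   combined by logical AND.
5. **Postprocessing** — gaps inside validated tracks are closed by
   flow-interpolating the nearer flanking mask.

Scoring follows the detection (not segmentation) view:
detection rate = GT regions hit / GT regions, false-positive rate =
false detections / detections.

A deterministic synthetic-scene generator (`wildtrack.synthetic`) renders
the statistical structure this method assumes — low-texture gray-brown
blobs, textured clutter whose colors partially overlap the foreground
palette, camera pan, scheduled occlusions — together with exact ground
truth and exact dense flow fields, so every stage is testable without
field footage.

## Worked example

```python
from wildtrack import (PipelineConfig, SceneSpec, generate_sequence,
                       generate_training_images, run_pipeline,
                       train_model_from_images)

spec = SceneSpec()                      # 320x180, 3 blobs, clutter, pan, occlusion
cfg = PipelineConfig(scale=1.0, spatial_bandwidth=4.0, min_segment_size=40)

pairs = generate_training_images(spec, seed=11)        # 16 annotated images
model = train_model_from_images(pairs, cfg, seed=0)

seq = generate_sequence(spec, seed=1)
result = run_pipeline(seq.frames, model, cfg,
                      flow_provider=seq.flow_provider(), gt=seq.gt)
print(result.report)
```

prints (abridged):

```
n_segments 242, n_candidates 165, n_links 708, n_tracks 7, n_validated_tracks 3
detection_rate_unvalidated 0.958   false_positive_rate_unvalidated 0.582
detection_rate 1.000               false_positive_rate 0.000
```

Reading: color classification alone tracks the three blobs *and* four
panning clutter patches whose colors sit inside the foreground palette —
58% of detections are false, which is what a color-only detector buys you.
The texture features separate them cleanly (edge density ≈ 0.99 for the
textured confusers vs ≈ 0.27 for the smooth blobs), validation rejects all
four, and gap filling recovers the frames where one blob was occluded,
lifting the detection rate from 0.96 to 1.00.

The same stages are scriptable from the shell:

```bash
wildtrack synth --seed 3 --out scene/ --training-images 16
wildtrack train --images scene/training/images --masks scene/training/masks --out model.json
wildtrack detect --frames scene/frames --model model.json --gt scene/gt \
                 --tracks tracks.json --report report.json
wildtrack evaluate --tracks tracks.json --gt scene/gt
wildtrack sweep --param C --values 0.3,0.5,0.7 --seed 1 --out sweep.csv
```

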