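# Methods

## Network model

The segmentation network is an anchor-free, single-class (weed) YOLO-family
instance segmenter. The backbone is a CSP ladder (stem stride 4, then four
stages at strides 8/16/32 with an SPPF and a partial-stage attention block
at the deepest level); a PAN neck fuses three scales; the head is decoupled
per scale into box (4 × 16 distribution-focal logits), class (1 logit) and
mask-coefficient (32) branches, with a shared 32-prototype bank at stride 4.

Two scales are provided: `n` (width ×0.25) and `s` (width ×0.50, channel
cap 768). The cap is a one-time width calibration so the all-modules
s-scale network lands near 8.5 M parameters / 24–25 GFLOPs at 480×480 —
the regime the architecture is designed for — while remaining a
YOLO11-seg-shaped graph. Parameter counts: baseline n 2.96 M, all-modules
s 8.56 M.

### Block conventions

The four replacement blocks follow their published designs with these
concrete choices where the sources are silent:

- Normalization is per-channel batch norm (eps 1e-5, momentum 0.03);
  activation SiLU throughout.
- **RepConv** sums three normalized branches (3×3, 1×1, identity when
  shapes permit). Fusion folds running statistics into one 3×3 kernel +
  bias; equivalence to the branched form therefore holds in inference
  (eval) mode, which is where fusion is used. Measured whole-model
  disagreement is ~1e-10 in float64, asserted < 1e-4.
- **RCSOSA**: shuffle group count 2 (matching the two-way channel split);
  each RCS unit preserves its channel count; the `n_repeats` unit outputs
  are concatenated once and projected by a 1×1 convolution.
- **SEAM**: channel gate `exp(z)` (sigmoid selectable). The second FC layer
  is zero-initialized and the gate logit clipped to ±4: an unbounded
  exponential gate is a positive feedback loop that we measured driving
  pre-norm activation variance over 1e30 within 20 SGD iterations; the
  clip bounds the re-weighting to [e⁻⁴, e⁴] without touching the gate's
  form at initialization (exp(0) = 1).
- **iRMB**: expansion 2.0, 4 heads, 7×7 attention windows with pad-and-crop
  for non-divisible maps. The stride lives in the depthwise convolution; a
  residual applies when stride 1 and channels match.
- **ADown**: 2×2 stride-1 average pool (no padding) → channel split → 3×3
  stride-2 pad-1 conv ‖ 3×3 stride-2 pad-1 max pool + 1×1 conv → concat.
- **ADown cost model** counts multiply-accumulates only; pooling,
  normalization and activations are excluded. Under that convention the
  plain conv / ADown ratio is exactly 18/5 = 3.6 for both parameters
  ((9c²)/((5/2)c²)) and MACs (((9/4)c²hw)/((5/8)c²hw)), independent of
  c, h, w.
- Module placement for the toggles: RCSOSA occupies every C3k2 position
  (backbone and neck); SEAM sits after the attention operator inside the
  deep attention block's residual branch; one iRMB precedes the prototype
  branch; ADown replaces the three backbone stage-transition downsamples
  and the two neck top-down-return downsamples (the stride-4 stem remains
  plain convolution). Toggling any single module never changes output map
  shapes.

### Autograd engine

All blocks run on a small reverse-mode autograd engine over numpy
(`fieldseg.nn`): elementwise ops with broadcasting, batched matmul, grouped
2-D convolution lowered to BLAS matmuls via strided im2col, max pooling,
nearest upsampling. Gradients are verified against central differences in
the test suite. FLOP counting instruments the conv/matmul primitives at
forward time (1 MAC = 2 FLOPs). Everything is float32 by default; fusion
equivalence tests run in float64. All initialization is driven by an
explicit `numpy.random.Generator`, so training is bit-deterministic per
seed.

## Training (smoke scale)

The loss is the standard YOLO-seg composite: IoU loss on boxes decoded as
the expectation of the per-side distribution-focal softmax, cross-entropy
on the two neighbouring DFL bins, BCE on the class map (normalized by the
positive count), and prototype-mask BCE restricted to the (one-cell-padded)
ground-truth box and normalized by its area. Weights 7.5 / 1.5 / 0.5 / 2.5.
Assignment is center-based: an instance claims the anchors of its
size-matched level that fall inside its box within 2.5 cells of its
center; conflicts go to the nearest instance; sub-stride instances snap to
the single nearest anchor. This simple assigner (rather than a
task-aligned one) is sufficient at overfit scale and keeps the loss free
of non-differentiable machinery.

Optimization is SGD (momentum 0.9, initial learning rate 0.01 — the
full-scale convention) with 20 warm-up iterations. The smoke harness
deliberately overfits ≤ 16 tiles for ≤ 200 iterations to demonstrate that
the assembled network trains and can segment its own training tiles; it is
not a statement about generalization. Problem sizes used by the tests:
n-scale model, 96 px tiles, batch 4 — at those sizes 200 iterations take a
few minutes on one CPU and reach mask mAP@0.5 of 1.0 on the training
tiles. Field-scale training (480 px, batch 16, 300 epochs, pretrained
initialization) is out of scope on this engine.

## Evaluation conventions

Matching is greedy in descending score order (ties by input order); each
prediction claims the highest-IoU unclaimed ground truth at IoU ≥ 0.5.
AP uses 101-point interpolation of the precision envelope (COCO
convention); the box and mask tracks are computed independently. The
single precision/recall figures use a fixed 0.25 confidence threshold;
AP uses all predictions. mAP@[0.5:0.95] and size-stratified AP are
deliberately not implemented.

## Georeferencing

Flat ground at constant height above ground is assumed (nadir low-altitude
flight); no lens distortion, no terrain model, no bundle adjustment.
Conventions: pixel origin top-left; +u → +east and +v → −north at zero
yaw; rotation order Z(yaw)·Y(pitch)·X(roll) in an ENU frame. The
Gauss–Krüger projection uses the WGS-84 ellipsoid with the fourth-order
Krüger series (scale factor 1.0, 3° zones, false easting 500 000 m):
round-trip displacement is ~1e-7 m, and the northing of a
central-meridian point matches numerically integrated meridian arc length
to < 1e-4 m. Out-of-zone input falls back to the nearest zone with a
warning. Instance centroids are georeferenced; per-tile detections are
first merged across shared tile edges in scene pixel space so an instance
split by the tile grid is counted once.

## Synthetic fields

The generator emulates the statistical structure the chain depends on, not
photorealism: brown soil with two-scale Gaussian texture, regularly spaced
rows of green crop seedlings (unlabeled background), weeds as irregular
star-shaped polygons with a distinct yellow-green tint, a multiplicative
illumination gradient and soft elliptical shadows. Weed count is Poisson
with mean density × imaged area (default 2 weeds/m²); default scene
geometry matches the acquisition (5280×3956 px frames, 12 m altitude,
≈3.24 mm ground sample distance from a 3700 px focal length). Overlapping
weeds overwrite in the label map; instance records are rebuilt from the
final map so ground truth is exact by construction.

What this does not capture: real leaf morphology and texture,
crop–weed visual similarity, perspective and mosaicking artefacts,
multi-temporal variation. Passing tests therefore demonstrate the
correctness of the pipeline machinery (tiling, labels, training dynamics,
geodesy, gridding) — not field-scale recognition accuracy, which requires
real imagery.

Dataset construction: non-overlapping 480 px tiles by default (stride
configurable), weed-free tiles removed, training tiles augmented ×4
(right-angle rotations, flips, per-channel gain ±20 %, brightness ±15,
Gaussian noise σ∈[2,8]; geometric ops applied jointly to image and label
map — right-angle-only rotation keeps masks lossless). The ×4 multiplicity
makes 1010 originals expand to exactly 5050 samples. The spatial split
assigns whole regions (blocks of 2×2 tiles) to train/val/test by a
largest-deficit greedy targeting 8:1:1; regions never span splits.

Label IO traces exact pixel boundaries (union of unit pixel squares) so a
LabelMe/YOLO-seg write–read round trip reproduces masks pixel-for-pixel;
interior holes, which polygon formats cannot express, are dropped (they do
not occur for the generator's star-shaped blobs in practice).

## Prescription mapping

Cells are axis-aligned 12 m squares (the sprayer working width) anchored
to the projected-coordinate grid; boundary-crossing cells are flagged
partial and classified like full cells (no area normalization by default;
an option provides it). Point-in-cell assignment is by floor indexing with
a left/bottom-inclusive tie rule, so shared-edge points land in exactly
one cell and counts are conserved. The shipped classifier is the fixed
five-tier table (1–24, 25–48, 49–72, 73–96, ≥97); an exact Fisher–Jenks
dynamic program (O(k·n²), ties toward earlier breaks) can recompute
data-driven breaks from the non-zero counts instead. Zero-weed cells get
tier 0 and rate 0 — the tier table starts at count 1 and a no-spray
convention is the agronomically sensible completion. Rates decrease from
the 120 L/hm² baseline by 5 % of baseline per tier: 120, 114, 108, 102,
96 L/hm² for tiers 5…1.

Exports: GeoJSON (WGS-84 when a projected→geodetic converter is supplied),
CSV, and a single-band rate raster as GeoTIFF (tifffile with
pixel-scale/tiepoint tags; no CRS geokeys) or ESRI ASCII grid.

## Pipeline

`run_end_to_end` chains generation → tiling/filter/split/augment →
detection (ground-truth passthrough by default, optional smoke-trained
model) → evaluation → georeferencing → gridding → export, writing a
manifest with per-stage timings, counts and artifact SHA-256 checksums.
All stages derive their randomness from the single run seed; two runs with
the same configuration produce identical checksums. With ground-truth
masks as detections the per-cell counts equal the generator's planted
component counts exactly (see the end-to-end test); this validates the
decision chain independently of any trained model.

## Known limitations

- The autograd engine is CPU-only and slow at field scale; the package
  demonstrates architecture and chain correctness, not training throughput.
- Exact placement of the attention module inside the deep attention block
  and the set of downsamples replaced by ADown are documented choices; the
  source designs leave both open.
- The printed ablation table and comparative accuracy of the original
  study require the (unreleased) field dataset and GPU-scale training and
  are explicitly not reproduced; `ablation_report` reproduces the
  structural compositions and cost columns only.
- Georeferencing ignores lens distortion and terrain relief; at 12 m over
  flat fields both are sub-cell effects, but the projection chain should
  not be reused for oblique or mountainous imagery.
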