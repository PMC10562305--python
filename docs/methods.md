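# Methods

`mapchange` reconstructs land-use/land-cover (LULC) time series from
scanned, georeferenced historical map sheets and quantifies change between
epochs. This note documents the models and procedures each stage
implements, the defaults that matter, what the synthetic data generator
does and does not emulate, and the numerical choices made where the design
was genuinely open.

## Problem setting

Printed topographic map series (here modeled on the Finnish 1:20 000 basic
map, scanned at ~1.7 m/px) encode five extractable LULC classes:

| code | class | symbology |
|---|---|---|
| 1 | fields | uniform light fill |
| 2 | mires | horizontal hatch lines inside a dotted outline |
| 3 | roads (>3 m) | wide red line |
| 4 | watercourses | thin blue line |
| 5 | water bodies | blue fill |

Background (0) is everything else, including lettering and contour lines,
which act as decoys for any automatic extraction. The pipeline is:
pre-process → segment per pixel → clean per class → vectorize → aggregate
to a regular grid → difference between epochs.

## Synthetic sheets

Real archive sheets cannot be redistributed, so `mapchange.synthmap`
fabricates scenes with exact vector ground truth. Default densities follow
the magnitudes of a southern-boreal study area: fields 11% and mires 9% of
area, water bodies 19%, roads 0.4 km/km², watercourses 1.3 km/km² in the
first epoch. Field parcels are rotated rectangles (radius 120–320 m), mires
and lakes are smoothed star polygons, roads cross the sheet border to
border, brooks are low-curvature random walks. Areal classes are kept
mutually disjoint (30 m separation); linear classes may cross anything, as
printed maps do.

Epoch evolution applies three documented change processes: removal of whole
field parcels to a target area fraction (granularity is therefore one
parcel — on small scenes the realized fraction deviates accordingly);
straight parallel drainage ditches (60 m spacing, random orientation per
mire) clipped to mire interiors until a target added length, matching the
historical concentration of ditching in peatlands; and added road links.
The final ditch is trimmed so the configured length is hit almost exactly.

Rendering burns labels by a pixel-center coverage rule, areal classes
first, then watercourses, then roads, so thin features are never erased by
fills. Line widths are symbology widths: roads 5 px (~8.5 m) and
watercourses 3 px (~5 m, the printed exaggeration of a ~0.3 mm blue line at
1:20 000 — and the minimum width that survives the 5×5 majority filter of
the cleanup chain, see below). Mire hatching is drawn every 6 px with a
dotted outline (pitch 5 px); both are visual approximations, as the map
legend does not quantify them. Degradation is a per-band multiplicative
color cast (yellowed/reddish paper) plus Gaussian noise (σ = 2.5 DN).
Decoys — lettering from a fixed glyph set and contour-like wiggly curves,
both near-black — appear only in the RGB rendering, never in the labels.

What the generator does *not* emulate: paper texture and fold damage,
halftone printing patterns, misregistration between color plates,
paludified-area hatching variants, and the full basic-map symbology
(buildings, elevation figures, municipal borders). Passing tests on
synthetic sheets therefore demonstrate correctness of the pipeline
machinery and learnability of clean symbology, not performance on real
scans.

## Pre-processing

White balance follows the luminance-preserving per-band scaling: with
reference patch means (R_ref, G_ref, B_ref) and luminance L = (R_ref +
G_ref + B_ref)/3, each band is multiplied by L/band_ref, clipped to
[0, 255] and truncated to unsigned 8-bit. Truncation (rather than
round-half-even) matches "convert to unsigned integer" semantics; the two
differ by at most 1 DN. A gray reference leaves the image unchanged; one
pass makes the reference patch neutral, so the operation is idempotent up
to ±1 DN. `find_white_patch` automates the manual step of picking the
unprinted margin: border windows are scored by mean brightness minus 4×
mean band standard deviation.

Georeferencing dislocation is summarized as RMSE = √(1/n Σ (x_i² + y_i²))
over 2-D control-point residuals; the implementation accepts precomputed
residual pairs (CSV with x_map, y_map, x_ref, y_ref) so the formula is
testable without a GIS digitizing session.

All rasters are north-up with square pixels; world units are meters and a
pixel's coordinate refers to its center.

## Tiling and splitting

Training uses non-overlapping 256 px tiles (64 px at desk scale);
inference uses overlapping tiles (stride = tile/2) and keeps only the
central 3/4 window of each prediction (256/128/192 at full scale), because
edge predictions are least reliable. Border tiles keep their outer margin
so the mosaic covers the sheet; overlaps resolve to the last tile in
row-major order (hard labels are de-mosaicked, not logits — probability
averaging would be a possible extension). `keep ≥ stride` guarantees
gap-free coverage, verified against a brute-force accumulator.

The train/val/test split assigns whole square blocks of tiles (default
4×4) so each subset occupies contiguous geography and no evaluation tile
overlaps a training tile. Targets are floor((1−0.75)·n) test tiles and
floor(0.25·n_remaining) validation tiles, rounded up to whole blocks; the
assignment depends only on tile origins and the seed, so every epoch of the
same sheet splits identically.

## Segmentation model

The segmentation network is a three-level U-Net implemented directly on
NumPy (im2col + GEMM convolutions with hand-written backprop), with
backbone strings `unet8`/`unet16`/`unet32` selecting the base width.
`unet16` (~100k parameters, receptive field of several tens of pixels —
enough to read mire hatching and to separate blue lines from blue fills)
trains on one CPU in about two minutes at desk scale. Training follows
fine-tuning practice: one epoch with the encoder frozen, then all weights,
each phase under its own one-cycle cosine schedule with Adam. The paper-
scale default `max_lr = 1e-4` suits fine-tuning a pretrained encoder;
`desk_scale_config()` uses 5e-3 (training from scratch), 1+5 epochs, and
focal alpha weights (1, 1, 1, 3, 6, 1) that lift the two linear classes,
whose pixels are outnumbered roughly 50:1.

The loss is focal loss, mean over pixels of −α_t (1−p_t)^γ log p_t with
γ = 2 (the original default; the choice is not constrained further) and the
exact softmax gradient

    dL/dz_k = α_t ((1−p_t)^γ − γ p_t (1−p_t)^{γ−1} log p_t) (p_k − δ_tk),

which reduces to the cross-entropy gradient at γ = 0 (asserted to 1e-12).

Augmentation: random horizontal flips and rotations within ±5° (applied to
image and label identically; larger rotations are implausible because the
symbology is orientation-sensitive), photometric brightness/contrast/
saturation jitter and random erasing (image only).

Evaluation computes per-class precision, recall, F1 (Dice) and IoU
(Jaccard) from pixel counts, background excluded, macro-averaged over the
five classes. F1 and IoU obey f1 = 2·iou/(1+iou) exactly. A class absent
from both prediction and target scores 1.0 — deliberately, so synthetic
sheets lacking a class do not zero the macro average; this convention
matters mostly for small synthetic scenes.

## Morphological cleanup

Each class has its own chain (structuring elements are flat; sizes are
pixels; "low-pass" is a box-majority filter — box mean thresholded at 0.5 —
since a linear filter alone would not return a binary mask):

* water bodies: opening 11×11 rectangle, then 7×7 majority;
* roads, watercourses: closing 7×7 rectangle, then 5×5 majority;
* fields, mires: union with watercourses (so ditches do not split
  parcels), erosion with an 11×11 cross, dilation with an 11×11 rectangle,
  7×7 majority, then subtraction of the processed roads and water bodies
  (set subtraction, so the clip order is immaterial). The final watercourse
  band is not subtracted from the areal bands.

Single erosions/dilations treat outside-of-raster as background (zero
padding). Openings and closings are composed on a padded copy so the
intermediate dilation is not clipped at the raster edge; this keeps opening
anti-extensive and closing extensive everywhere, and every configuration is
tested against a per-pixel brute-force neighborhood oracle.

## Vectorization

Areal masks are traced to polygons along exact pixel edges: the boundary
"crack" segments between foreground and background pixels are polygonized
and faces lying on foreground are kept, holes preserved. Polygon area
therefore equals pixel count × pixel area exactly for any boundary
orientation (marching-squares contours were rejected because they bevel
diagonal staircases, biasing areas low by several percent on small
regions). Regions under `min_area_m2` (default 1000 m² ≈ 346 px, a
vectorization-speck threshold, configurable) are dropped.

Linear masks become centerlines: skeletonize to one pixel width →
polygonize skeleton pixels (pixel squares) → buffer 10 m → dissolve →
negative-buffer 10 m → Voronoi medial axis per polygon. Features closer
than 20 m merge — a documented artifact of the 10 m merge radius. The
medial axis uses Voronoi edges of boundary points densified at half a
pixel (sampling coarser than the ~1-pixel sliver width fragments the
axis), on a polygon first simplified by half a pixel and with interior
rings smaller than (2·buffer)² removed — both suppress spurious branches
and cycles. Leaf branches shorter than 2× the buffer radius are pruned in
at most two passes; unbounded pruning would cascade along chains whose
junction spacing is below the threshold and consume real centerline.
Recovered length is within ~5% of truth for straight or gently curving
networks and within the 15% skeleton-path bound on all tested inputs.

## Change accounting

Per-epoch layers are aggregated into a regular 500×500 m grid (origin
snapped to 500 m multiples, so grids from different epochs align even when
layer extents jitter): per cell, summed polygon-intersection area or
clipped line length. Cell sums conserve layer totals to 1e-6 relative.
Between consecutive epochs, per-cell deltas give gain = Σ max(Δ, 0),
loss = Σ max(−Δ, 0), change = gain − loss (exact at full precision;
rounding happens only at output). Working per cell rather than by geometric
overlay deliberately absorbs small georeferencing offsets between epochs;
per-cell gain is a lower bound on overlay gain. Watercourse length inside
fields and mires (an indicator separating drainage ditching from other
change) is the length of the line/polygon-union intersection. `extreme_cells`
ranks cells by |Δ| with row-major index as the deterministic tie-break.

## Run modes and reproducibility

The pipeline has two modes. `"oracle"` feeds rendered ground-truth labels
straight into cleanup/vectorization/change accounting — a closed loop that
isolates the geometry stages from model quality: on a 5×5 km two-epoch
scene it recovers the configured field-loss fraction to within a few
percent relative and the configured ditch-length gain to within ~5%
(centerline shortening biases both epochs similarly, so the difference is
accurate). `"full"` trains the network on first-epoch tiles and predicts
all epochs. Every stochastic component (scene generation, evolution,
augmentation, weight init, batch order, rendering noise) draws from
generators derived from explicit seeds; CPU runs are bit-reproducible.

Desk-scale problem sizes used by the test suite and the acceptance script:
3.3×3.3 km sheets tiled at 64 px (≈900 tiles, ≈500 training tiles) for
training runs, and 5×5 km two-epoch scenes for geometry recovery.

## Known limitations

* GeoTIFF tags are limited to pixel scale and tiepoint plus a JSON sidecar
  CRS label; no projection WKT is written. Vector output is GeoJSON, one
  layer per class and epoch.
* The pretrained very deep backbones used at full scale on real archives
  are out of scope; backbone strings select NumPy U-Net widths.
* Watercourses thinner than 3 px cannot survive the published cleanup
  chain (a 2-px line loses the 5×5 majority vote); the renderer's line
  width respects that bound.
* Centerline length is biased low by a few percent at junctions and line
  ends; parallel lines within 20 m merge.
* Gain/loss are per-cell quantities; sub-cell relocation within one cell
  cancels out.
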