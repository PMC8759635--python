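# flowseg

Label-free single-cell segmentation from time-lapse microscopy, driven by
dense optical flow.

Most segmentation methods classify pixels by what they look like in a
single image — intensity, contrast, texture. That breaks down exactly where
live-cell imaging is hardest: label-free modalities (phase contrast, DIC,
transmitted light, IRM) where cell and background intensities overlap, and
structured in-vitro environments (etched grooves, printed patterns) whose
static features look just like cells. `flowseg` instead classifies pixels
by how they *move*: living cells are never truly still between frames —
membranes ruffle and intracellular intensity churns even when the centroid
does not budge — while the background holds still. The displacement field
between consecutive frames therefore separates cell from background with a
single threshold, regardless of the optical modality.

## Method

For consecutive frames the brightness-constancy relation

```
I(x, y, t) ≈ I(x + uΔt, y + vΔt, t + Δt)
```

is solved densely for the displacement field (u, v) with the Farnebäck
algorithm, implemented here from scratch: each frame is approximated
per pixel by a local quadratic model `f(x) = xᵀA x + bᵀx + c` fitted by
Gaussian-weighted least squares over a small window (default 5×5), and the
displacement relating the two frames' models,

```
d = argmin Σ w ‖ G d − Δb ‖²,   G = (A₁ + A₂)/2,   Δb = −½ (b₂ − b₁),
```

is solved per pixel from spatially averaged normal equations, iterated
with warping, and propagated coarse-to-fine over a 2×2-averaging resolution
pyramid so large displacements are caught at low resolution and refined at
full resolution.

Segmentation is then three intuitive operations:

1. **Th** — threshold on the flow magnitude `√(u² + v²)` (pixels/frame):
   pixels moving faster than Th are cell. This is the one parameter that
   typically needs tuning per data set.
2. **smoothing disk** — morphological closing (default radius 1 px) plus
   hole filling of the binary mask.
3. **size filter** — connected components smaller than a minimum area
   (default 1000 px) are discarded as debris.

Surviving components are labeled and measured (area, perimeter, centroid,
bounding box). Evaluation against ground truth reports the object-level
detection F-score `F1 = TP / (TP + ½(FN + FP))` (greedy one-to-one IoU
matching, threshold 0.5) and the pixel-level Jaccard index
`J(T, S) = |T ∩ S| / |T ∪ S|`.

Because real ground truth is expensive, the package ships a synthetic
scene generator: textured, deformable cells (star-convex boundaries with
time-varying Fourier ripples) translating — or merely churning internally —
over static flat-speckled or groove-striped backgrounds, with fresh sensor
noise per frame and exact rasterized ground-truth masks.

## Worked example

```python
from flowseg import (PRESET_TH, FlowParams, SegmentationParams,
                     evaluate_dataset, preset_scenes, render_scene,
                     regions_table, segment_sequence)

spec = preset_scenes()["single_migrating"]          # one cell, 6 frames
seq, truths = render_scene(spec)                    # frames + ground truth
masks = segment_sequence(
    seq, FlowParams(),
    SegmentationParams(th=PRESET_TH["single_migrating"]),
)
print(evaluate_dataset(masks, truths[:-1]).summary())
print(regions_table(masks).head(3).to_string(index=False))
```

prints

```
TP=5 FP=0 FN=0  F1=1.0000  Jaccard=0.8833  (IoU match >= 0.5)
 frame  label  area_px  perimeter_px  centroid_row  centroid_col  bbox_min_row  bbox_min_col  bbox_max_row  bbox_max_col
     0      1     3082    228.693434     63.450681     52.364698            31            21            98            85
     1      1     3044    225.036580     65.608739     54.636991            34            23            99            89
     2      1     3031    218.651804     67.316397     56.500495            37            25            99            90
```

All five frame pairs detect exactly the one simulated cell (perfect F1,
no spurious objects), and the predicted masks overlap the exact ground
truth at Jaccard 0.88 — the residual being a thin halo where flow support
extends past the moving boundary. The region table tracks the programmed
(1.5, 2.0) px/frame trajectory.

The same pipeline from the shell:

```
flowseg synth --preset grooves --outdir scene/
flowseg run  --input scene/sequence.tif --outdir out/ --th 1.2
flowseg eval --pred out/ --truth scene/truth_labels.tif
```

Only `--th` is needed beyond the defaults.

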