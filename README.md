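# embgan

Adversarial nucleus detection for label-free DIC microscopy, with the
downstream machinery for lineage tracing at desk scale: synthetic
pseudo-embryo generation, detection and tracking, error accounting, and
lineage-tree comparison statistics.

## The problem

Automated cell lineage tracing in developing embryos (the *C. elegans*
embryo being the canonical system) normally relies on fluorescent nuclear
reporters: nuclei appear as bright blobs that standard
detection-and-tracking pipelines handle well. Label-free differential
interference contrast (DIC) imaging avoids transgenesis and staining, but
nuclei in DIC appear as textured relief patterns with directional shadows,
not blobs — classic detectors fail on them.

This package implements an adversarial solution: a **segmentor** network S
(a U-Net with residual blocks) converts each DIC slice `x` into an unbounded
nucleus-score image, and a **critic** network C extracts hierarchical
features from nucleus-masked images. Both are trained on the min/max
objective

```
min_S max_C  L(θ_S, θ_C) = (1/N) Σₙ ℓ_mae( f_C(xₙ ∘ S(xₙ)), f_C(xₙ ∘ yₙ) )

ℓ_mae(f, f′) = (1/L) Σᵢ₌₁..L ‖ f_Cⁱ − f_C′ⁱ ‖₁
```

where `∘` is the elementwise mask product, `yₙ` are imperfect binary labels
(as produced by a generic pretrained 2D fluorescence segmenter), and
`f_Cⁱ` is the critic's feature map at scale `i` of `L`. Because the loss
compares *masked images* through learned multiscale features rather than
pixels, the segmentor learns object-focused detections that tolerate
imperfect labels. No manual annotation enters training.

Around the networks the package provides, in one consistent coordinate
convention (0-based `(z, y, x)` voxels, physical anisotropy carried as
spacing):

| module | what it does |
| --- | --- |
| `synthetic_embryo` | paired pseudo-DIC + fluorescence volumes, corrupted training masks, ground-truth lineage and track graph |
| `imgproc` | autocontrast to 8-bit with a bounded saturation budget, slice split/reassembly, clip-shift postprocessing |
| `network`, `adversarial_loss`, `training` | segmentor, critic, multiscale masked L1 loss, alternating Adam optimization |
| `detection_tracking` | difference-of-Gaussians nucleus detection, greedy nearest-neighbor track linking with divisions |
| `evaluation` | detection/tracking FP-FN accounting (identity swaps count all erroneous edges), per-time and per-depth performance series |
| `lineage_metrics` | branch distance (L2 over matched cell-cycle vectors), global clock ratio (PC1 slope), intra-strain variability rank-sum comparison |
| `io_formats` | multi-page TIFF volumes and the zip-of-delimited-text nuclei archive dialect of the established lineaging ecosystem |

## Worked example

```python
import numpy as np
import embgan as eg

# 1. simulate a pseudo-embryo and render one timepoint
cfg = eg.SimulationConfig(rng_seed=0, n_generations=3)
tree = eg.simulate_lineage(cfg)
nuclei = eg.place_nuclei(tree, cfg, timepoint=45)
dic = eg.render_dic(nuclei, cfg)
print(f"{len(tree)} cells in the lineage, {len(nuclei)} nuclei alive at t=45")
print(f"DIC volume {dic.shape}, spacing {dic.spacing_um} um")

# 2. count tracking errors for an identity swap
from embgan.trackgraph import Detection, TrackGraph
truth, pred = TrackGraph(), TrackGraph()
for g in (truth, pred):
    for t in range(2):
        g.add_detection(Detection(0, t, (1.0, 10.0, 10.0)))
        g.add_detection(Detection(1, t, (1.0, 40.0, 10.0)))
truth.add_edge((0, 0), (1, 0)); truth.add_edge((0, 1), (1, 1))
pred.add_edge((0, 0), (1, 1)); pred.add_edge((0, 1), (1, 0))
tally = eg.count_tracking_errors(pred, truth, radius=2.0)
print(f"identity swap: {tally.trk_fp} FP + {tally.trk_fn} FN "
      f"= {tally.trk_total_errors} tracking errors")

# 3. compare two lineage trees
cfg_b = eg.SimulationConfig(rng_seed=3, cycle_cv=0.05)
tree_b = eg.simulate_lineage(cfg_b)
res = eg.branch_distance(tree, tree_b)
ratio = eg.global_clock_ratio(tree, tree_b)
print(f"branch distance {res.value:.2f} min over {res.n_matched_cells} shared cells; "
      f"clock ratio {ratio:.3f}")
```

prints

```
15 cells in the lineage, 4 nuclei alive at t=45
DIC volume (20, 48, 64), spacing (0.75, 0.5, 0.5) um
identity swap: 2 FP + 2 FN = 4 tracking errors
branch distance 4.31 min over 7 shared cells; clock ratio 0.905
```

The identity-swap line shows the edge-level error convention: when two
tracks exchange cells between frames, both missing correct edges are
false negatives and both crossing edges are false positives — 4 errors for
one swap. The branch distance is the L2 norm over the 7 cells whose
completed cell cycles exist in both trees; the clock ratio says embryo B
develops ~10% faster than embryo A (durations ~0.9x as long).

A `click` CLI wraps the same functionality:
`embgan simulate | preprocess | postprocess | train | infer | detect |
track | evaluate | lineage-compare` (see `embgan --help`).

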