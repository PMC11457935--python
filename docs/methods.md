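# Methods

This note documents the models, conventions, and numerical choices behind
the package, in the spirit of a methods supplement: what each component
assumes, which knobs matter, and what the synthetic benchmark does and does
not demonstrate.

## Coordinate and unit conventions

All volumes are numpy arrays indexed `(z, y, x)` with 0-based voxel
coordinates; z is the slice axis of the multi-page TIFF on disk. Physical
spacing is carried per volume as `(dz, dy, dx)` in micrometres — default
`(0.75, 0.5, 0.5)`, i.e. the 750 nm axial step of typical lineaging
acquisitions and a 1.5x axial anisotropy. Distances used for track linking
and detection matching are always computed in physical units. Nuclei
archives on disk use 1-based indices and `x, y, z` column order; the
conversion is confined to `io_formats`.

## Synthetic pseudo-embryo

The simulator exists so the full pipeline — training included — runs and is
testable without external data. It emulates, at desk scale, the structure
of a label-free lineaging acquisition:

* **Lineage.** A binary tree rooted at a founder cell ("AB"), daughters
  appending `a`/`p` to the parent's name (Sulston-style). Cell-cycle
  durations are lognormal, parameterized by a per-generation mean vector
  (default 16–32 min, lengthening with generation) and a coefficient of
  variation (default 0.05); lognormal guarantees positive durations and
  reduces to the exact mean at CV 0. Cells of the final generation never
  divide and persist to a common movie end (one final-generation mean cycle
  past the last division), so nuclei do not vanish mid-movie. Frames are
  1 min apart by default.
* **Placement.** Nuclei live inside an ellipsoid (half-axes in voxels,
  default (8, 18, 26)). Per frame each nucleus takes a small random drift
  (capped at 0.25 radii — frame-to-frame movement well below a nuclear
  radius, as in real embryos), daughters start on opposite sides of the
  parent's last position along a name-derived division axis, and capped
  iterative pairwise repulsion enforces center separations of at least
  0.8x the radius sum, with a soft clamp into the ellipsoid. Everything is
  a pure function of the config seed.
* **DIC rendering.** A refractive-index phantom (Gaussian bumps per
  nucleus, an eggshell step at the embryo boundary, smoothed cytoplasmic
  texture) is differentiated along a configurable 2D shear direction and
  placed on a mid-gray offset with a linear illumination gradient and
  Gaussian noise. Nuclei therefore appear as paired bright/dark shadows —
  the defining property of DIC that makes blob detectors fail. During the
  last ~2 min before division a nucleus renders as a two-lobed dumbbell,
  reproducing the division-time appearance that is the hardest case for
  detection.
* **Fluorescence rendering.** Anisotropic Gaussian blobs plus Poisson
  counting noise (`fluor_photons` sets the rate; 0 disables noise).
* **Training masks.** Per-slice analytic sphere cross-sections corrupted to
  emulate a generic pretrained 2D fluorescence segmenter: whole-nucleus
  omissions (default 5%), per-slice center/radius jitter (default 1 voxel),
  and occasional inflation that can merge adjacent nuclei (default 2%).
  The defaults are deliberately conservative; the error modes, not their
  exact rates, are the point.

**What the simulator does not emulate:** optics (no polarization or
Wollaston-prism model), cell membranes and shapes, depth-dependent signal
attenuation, embryo rotation/compression, or the full ~550-cell density of
late embryogenesis. Passing the desk-scale tests therefore demonstrates
that the algorithms are implemented correctly and that the training
procedure converges on DIC-like structure — not that the small networks
would match the reported performance of a full-scale model on real data.

## Networks

The **segmentor** is a U-Net: per level a stride-2 3x3 convolution +
batchnorm + ReLU followed by a bottleneck residual block (1x1, 3x3, 1x1
convolutions; a 1x1 projection on the identity path where channel counts
change). The decoder mirrors with bilinear 2x upsampling + convolution +
batchnorm + ReLU, concatenation of the matching encoder output (the raw
input image at full resolution), and a residual block. The head is a linear
1x1 convolution: the output is an unbounded score image, consistent with a
postprocessing step that clips at −4 — a sigmoid would make that step
meaningless. Channel widths double per level from `base_channels`
(default 32, 4 levels; the desk-scale experiments use 8, 2 levels).

The **critic** mirrors the encoder without residual blocks. Each level is a
stride-2 convolution + batchnorm + ReLU, and emits a feature map through a
*global convolution* factorized as a kx1 followed by a 1xk convolution
(default k=11; desk scale 7) — the factorization yields a large receptive
field at a fraction of the parameters of a full kxk kernel. The L per-level
maps, finest first, are the multiscale features of the loss.

Batch normalization in the critic is a deliberate choice (the closest
precedent architectures leave it open): a maximizing critic with
unconstrained activations can grow its features — and hence the loss —
without bound, which at desk scale degrades the gradient signal reaching
the segmentor. Normalizing each level bounds the feature scale and keeps
the min/max game balanced. Because batch statistics must be identical for
the two branches being compared, the objective runs both masked batches
through the critic as one concatenated forward pass.

All weights are He-initialized from a per-network seed; construction and
forward passes are bit-reproducible. The underlying autodiff engine is
float64 throughout, which makes training deterministic at the bit level and
finite-difference gradient checks sharp.

## Loss and training

The objective is the multiscale masked L1 feature loss shown in the README.
`‖·‖₁` is the entrywise *sum* of absolute feature differences (per sample,
averaged over the batch); a per-element-mean variant sits behind
`per_element_mean` for callers who want magnitudes independent of image
size, but the sum is the default reading of the norm. Labels may be soft;
nothing in the loss requires binarity.

Training alternates per batch: (1) segmentor frozen (parameters and
batchnorm running statistics), one full forward/backward pass, one Adam
*ascent* step on the critic; (2) critic frozen likewise, one Adam *descent*
step on the segmentor. "Epoch" means one pass of alternating steps over all
batches of the shuffled dataset. Adam uses learning rate 2e-4 and the
conventional betas (0.9, 0.999), eps 1e-8, recorded in checkpoints. The
loop aborts with a diagnostic if the objective goes non-finite. Data order,
initialization and hence the entire loss history are functions of the
config seed. Full-scale settings (10,000 epochs, batch 36) remain
expressible; the desk defaults are 50 epochs, batch 8.

Inference (`infer_volume`) applies the exact processing chain: per-volume
autocontrast to 8-bit, scale to [0, 1], slice-wise segmentor forward
(reflect-padded to divisibility and cropped back), reassembly into a stack,
then `clip_shift` (add 4, clamp negatives to zero).

## Image processing rules

Autocontrast picks low/high cutoffs from order statistics so the number of
clipped pixels is maximal subject to the saturation budget (default 0.35%
of pixels), split equally between the two tails — the budget's tail
split is not standardized anywhere, so half/half is used and documented.
Values between the cutoffs map linearly into [1, 254]; only clipped pixels
reach 0 or 255, so the saturated count is exactly the clipped count.
A constant volume returns mid-gray 128 instead of raising, so batch jobs
survive blank frames. The transform is invariant to affine rescaling of
the input up to one quantization level.

## Detection and tracking stand-in

Detection is a difference-of-Gaussians band-pass (sigmas in physical
units, scaled per axis by the voxel spacing) followed by local-maximum
extraction above an intensity threshold, greedy non-maximum suppression at
the minimum diameter (score order), and a diameter estimate from the
half-max support of the response (equivalent-sphere diameter, filtered by
the configured limits). Peaks within one voxel of the volume faces are
excluded by default: the band-pass response at the filter boundary reflects
the padding rule rather than the image, and faint spurious maxima
accumulate in corners. Linking is greedy: candidate pairs between
consecutive frames within `max_displacement` (physical units) are accepted
in order of increasing distance — ties broken by the lower (timepoint, id)
pair — one-to-one first; a second pass attaches remaining detections to the
nearest already-linked parent with spare out-degree, creating division
edges (out-degree capped at 2, in-degree at 1). This is a minimal
implementation of the operator class used by established lineaging
pipelines, sufficient to exercise the evaluation machinery; it makes no
claim of equivalence to any production tracker's division scoring.

## Error accounting

Detections are matched per timepoint by minimum-cost one-to-one assignment
(Hungarian algorithm) under a physical distance cutoff; unmatched
predictions are detection FPs, unmatched references FNs. Tracking errors
are edge-level: a reference edge absent from the prediction is one FN,
subtyped *missing-detection* if either endpoint is unmatched and
*missed-link* otherwise; a predicted edge whose endpoints do not map to a
connected reference pair is one FP. Edges incident to FP detections count
as tracking FPs by default (`include_fp_detection_edges=False` restricts
to mislinked true detections); the default keeps the FP/FN accounting
symmetric under exchanging prediction and reference. All erroneous edges
are counted, so one two-cell identity swap costs exactly 2 FN + 2 FP = 4.

"Accuracy" is TP/(TP+FP+FN) — the standard choice when no true-negative
class exists. Performance over time uses a centered moving average
(default 10 frames) with shrinking edge windows; frames with undefined
rates (0/0) stay missing and do not poison their neighbors' windows. Depth
series aggregate detection tallies per z bin without smoothing.

## Lineage statistics

* **Branch distance**: L2 norm between vectors of cell-cycle durations over
  the cells with *completed* cycles present in both trees (optionally
  restricted to a named sublineage). The shared cells are taken in
  lexicographic name order — any fixed common order gives the same L2.
  Cells still alive at movie end are excluded. An empty intersection is an
  error, never distance 0.
* **Global clock ratio**: matched durations are paired as 2D points; the
  first principal component of the *centered, unstandardized* scatter
  (standardizing would destroy the slope interpretation) gives a
  nonparametric slope; the ratio of its loadings, sign-normalized positive,
  is the fold-difference in developmental rate. By construction
  ratio(A,B)·ratio(B,A) = 1.
* **Variability comparison**: all intra-group pairwise branch distances are
  pooled per group (pooling, rather than per-embryo summaries, keeps the
  test simple and is documented as the choice); groups are compared by
  median and a two-sided Wilcoxon rank-sum test.

## Desk-scale experiment sizes

The end-to-end acceptance experiment trains on 200 slices (10 timepoints x
20 z-slices of one simulated embryo, masks uncorrupted) with a 2-level,
8-channel segmentor and a 3-level, 8-channel critic for 50 epochs at batch
8, then evaluates detection on 4 held-out volumes of a different embryo
(different seed) and exact track recovery over a well-separated 2-cell
window. These sizes were chosen as the smallest configuration at which the
adversarial pair visibly converges; they are not tuned per seed.

## Known limitations

* The networks are 2D slice-wise by design; no 3D context is used.
* The critic's batchnorm couples samples within a batch; per-pair
  decompositions of the objective hold exactly in evaluation mode
  (running statistics), which is how the oracle tests verify them.
* The greedy linker has no motion model and no division classifier; on
  adversarial ties its output depends on the documented tie-break.
* The simulator's corruption rates for training masks are free parameters;
  no attempt is made to calibrate them against a real 2D segmenter's error
  statistics.
* |x| and ReLU make the objective piecewise-smooth; finite-difference
  checks use small steps (1e-7) to keep kink crossings improbable.
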