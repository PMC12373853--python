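# Methods

`neopose` implements multimodal (RGB, depth, infra-red) fusion pose
estimation for the four neonatal torso key-points — left/right shoulder
and left/right hip — together with the evaluation protocol, frame
sampler, synthetic scene generator and experiment harness needed to
exercise every stage without access to clinical recordings.

## Problem setting and assumptions

Each frame is an aligned triplet of images on one pixel grid: RGB (8-bit,
3 channels), depth (millimetres, 16-bit) and IR (active-illumination
intensity, 16-bit). Exactly one infant appears per frame, so detection
identity coincides with frame identity and a top-down heatmap detector
needs no person-detection stage; the person box is the full frame.
Key-point visibility distinguishes *visible* (clearly visible **or**
under a blanket — the position is still annotatable), *occluded*
(covered by another object such as a nurse's hand) and *not visible*.
Scene labels record lying position (prone / supine / side), blanket
covering (none / half / three-quarter / full) and whether a care
intervention is in progress.

## Fusion architectures

Every backbone is organised as `stem → four stages → key-point head` and
can be split at a stage boundary X ∈ {1..4} into a modality-specific
*Part 1* (stem + stages 1..X) and a shared *Part 2* (stages X+1..4 +
head). Inter-stage transition layers are grouped with the stage they feed
(for the plain ViT this is the stated rule — the patch embedding belongs
to the first stage; stages are quarters of the transformer blocks). Both
parts reference the same layer objects, so composing them reproduces the
unpartitioned forward pass bit-for-bit.

* **single** — one backbone on one image type.
* **EIF** (early): images concatenated on the channel axis (3 + 1 + 1
  channels for RGB-D-IR); the first convolution is widened.
* **IIF-X** (intermediate): one Part 1 per image type; the multi-
  resolution feature maps are summed element-wise and fed to a single
  shared Part 2. For X = 4 the summation happens right before the head.
* **LIF-X** (late): one Part 1 per image type; the *same* shared Part 2
  runs once per branch and the per-branch heatmaps are summed after the
  head, so the total heatmap is identically the branch sum.

Weight adaptation for transfer from RGB-shaped weights follows channel
linearity: a single-channel modality receives the first-layer kernel
summed over its input-channel axis (exact for replicated-channel input);
EIF keeps the RGB kernels bit-for-bit and fills each single-channel slot
with the channel-summed kernel scaled by 1/(number of modalities), so no
extra channel dominates the stacked response. A 17-channel COCO key-point
head is reduced to the torso by keeping output channels 5, 6, 11, 12.
Per-modality branches are initialised as identical copies of one base
backbone (asserted bit-equal at construction).

Backbone catalogue: HRNet-W32/W48 (four native multi-resolution stages,
4 basic blocks per branch per module, module counts 1/4/3 for stages
2–4), HRFormer-S/B (the same layout with two local-window attention
blocks per branch per module, window 7, depth-wise-conv FFNs, separable
fusion convs, module counts 1/4/2), a plain ViT-S/B with a two-deconv
heatmap decoder, and a reduced norm-free convolutional backbone (`tiny`,
width 24) with full backward support. With a 17-key-point head and
3-channel input the catalogue reproduces the published reference
parameter counts (HRNet-W32 28.54 M, W48 63.60 M, HRFormer-S 7.75 M,
HRFormer-B 43.21 M), which is the strongest available check that the
reconstructions are faithful.

The numpy module system implements forward and backward passes for the
convolutional layers and forward passes for the transformer primitives;
training therefore runs on the norm-free convolutional family, while the
large backbones support forward evaluation, stage partitioning and
complexity analysis. Batch norm runs in inference mode (running
statistics), which keeps the partition identity exact.

## Complexity accounting

`complexity(spec)` counts trainable parameters exactly (from the
instantiated arrays, shared modules counted once — hence
params(IIF-X) = params(LIF-X) for every X) and forward-pass FLOPs by
symbolic per-layer accounting at the spec's input size. The convention,
fixed once and applied everywhere: one multiply-accumulate = one FLOP
for convolutions, linear layers and the two attention matrix products;
one FLOP per output element for bias addition, normalisation,
activations, element-wise sums, softmax and upsampling. Complexity tools
in the model-zoo ecosystem differ by several percent in exactly these
choices; the convention here is deliberately complete and documented
rather than tuned to any published figure.

## Evaluation metrics

Frame k receives the object key-point similarity

    OKS_k = Σ_i δ_ik exp(−d_ik² / (2 κ_i² s_k²)) / Σ_i δ_ik

with detection error d_ik (pixels), per-key-point difficulty κ_i and
frame scale s_k. κ defaults to twice the COCO annotation sigmas for
shoulders (0.079) and hips (0.107), matching the reference evaluator's
Gaussian; neonate-specific constants are an open research question, so κ
is configurable. δ_ik = 1 for visibility ≥ occluded by default (COCO
v ≥ 1); a strict visible-only mode is a flag.

Without a segmented body outline the scale comes from the visible
key-points, with factors calibrated against the COCO person-area
convention: s² = 3.28 × torso-box area when 3–4 key-points (or one
shoulder plus the contralateral hip — the only pairs spanning the box
diagonal) are visible; 2.0 × torso height² for a single body side;
6.16 × shoulder width² for shoulders only; 13.64 × hip width² for hips
only; frames with ≤ 1 visible key-point are excluded, as are degenerate
zero-extent configurations. Widths and heights are Euclidean distances
(the choice matters only for rotated torsos and is documented rather
than prescribed).

With one detection per frame, AP at threshold t reduces to the fraction
of evaluated frames with OKS ≥ t, averaged over t = 0.50:0.05:0.95;
AP50/AP75 are the single-threshold values. The test suite cross-checks
this against an independent implementation of the COCO matching protocol
(score-ranked matching, 101-point interpolated precision); the two agree
up to the protocol's own 1/101 recall quantisation. Stratified reports
give per-stratum mean OKS, AP, quartiles and 5/95 percentiles. Group
comparisons use a two-sided Mann–Whitney U test (the permutation
alternative resamples the group-mean difference with a fixed seed).
Cross-dataset RMSE rescales errors anisotropically to a 128 × 96
reference image (dx by 128/W, dy by 96/H).

## Frame selection

Annotation frames are chosen per fifteen-minute window, evenly spaced in
cumulative depth activity, where activity is the mean absolute
difference between consecutive depth frames over valid (non-zero)
pixels. Targets sit at k·(total/n), k = 1..n; each target takes the
first frame whose cumulative activity reaches it and duplicates advance
to the next unused frame, which keeps the selection strictly increasing
and deterministic. Zero-activity windows fall back to even spacing in
time. A stride option subsamples the sequence before differencing.

## Synthetic scenes: what they emulate — and what they do not

Rendering is procedural 2-D compositing: ellipsoidal torso/head/legs,
smooth-noise textures, a blanket drawn from the feet up to a quantile of
the body's axial extent (0 / 0.5 / 0.75 / 0.97 for the four covering
levels), optional hand-shaped intervention occluders. Key-points under
an occluder are labelled occluded; under only the blanket they remain
visible, mirroring the annotation convention.

Modality physics:

* **depth** — mattress plane at 400 mm with a smooth raised body (relief
  30–80 mm, head highest), per-pixel time-of-flight noise (8 mm),
  speckle dropout (1 % of pixels → 0) and, in 25 % of frames, large
  invalid patches from specular reflection or motion. The blanket drapes
  (smooths) over the body but does not erase the bump.
* **RGB** — scene reflectance times the lighting parameter (0 = covered
  incubator, 1 = bright) plus sensor noise; at lighting 0 only the noise
  floor remains.
* **IR** — the camera's own illumination: same scene structure,
  *invariant to lighting*, with radial emitter falloff and occasional
  specular glare patches (30 % of frames).

The modality balance is deliberate: no single image type suffices (depth
fails on invalid-patch frames, RGB in darkness and under blankets, IR
under glare and blankets), which reproduces the clinical finding that
fusion outperforms single-image models and that dark scenes are only
recoverable from IR. The body lies roughly along the cot axis (±20°
jitter) with the head end larger and more elevated — without such cues a
2-D scene contains no information to tell shoulders from hips. Subjects
differ in body scale, relief and skin tone so subject-wise folds are
meaningful.

What the generator does **not** emulate: photorealistic appearance,
limbs and face as separate key-points, motion blur, camera calibration
artefacts, real blanket geometry, or the clinical composition
percentages (the default scenario mix only follows them qualitatively —
side most common, about half of frames at least three-quarters covered).
Passing tests on these scenes demonstrate that the pipeline's machinery
(fusion, training, evaluation, ablation) behaves correctly; they say
nothing quantitative about accuracy on real neonatal recordings. One
knowing divergence: synthetically IR is the easiest single modality,
whereas the clinical study found depth the best single-image model.

## Training protocol

The clinical protocol surface (`TrainConfig`) defaults to the study's
settings: up to 50 epochs, Adam with decoupled weight decay (0.01,
unstated in the protocol and therefore configurable), learning rate
5e-4, batch size 16, best-held-out-AP checkpointing (final-epoch mode is
available). Five-fold subject-wise cross-validation assigns whole
subjects to folds (balanced to ±1, seeded); subject disjointness of each
split is asserted at run time.

The desk-scale experiments train the reduced backbone from scratch,
which needs different optimisation than fine-tuning pretrained weights:
learning rate 2e-3 (5e-3 in the acceptance experiment), two-epoch warmup
with cosine decay, and a positive-weighted heatmap MSE (weight
1 + 10·target) masked by key-point visibility — plain MSE on sparse
Gaussian targets otherwise collapses to the all-background solution at
this model scale. Targets are Gaussians with σ = 2 heatmap pixels at
stride 4. Inputs are z-scored per modality with training-set statistics;
invalid depth pixels are imputed with the frame's median valid depth,
and a frame with no valid depth at all (a missing sensor) with the
training-set mean — a neutral input. Decoding takes the per-map argmax
(ties to the lower linear index), shifts a quarter pixel toward the
higher neighbour per axis, maps to input pixels by the stride, and clips
the peak value to [0, 1] as the confidence; a constant map decodes to
the map centre.

Missing-modality ablation zero-fills the unavailable *raw* images before
the standard preprocessing, so a missing depth sensor manifests as an
all-invalid depth map (imputed neutral) while missing RGB resembles a
dark frame — both consistent with how those sensors actually fail.

## Numerical and reproducibility notes

All randomness flows through `numpy.random.default_rng` with explicit
seeds; scene generation is bit-reproducible given the config (IR draws
come from a separate stream so the lighting parameter cannot perturb
them). Training is deterministic per platform (single-threaded BLAS may
still reorder reductions across platforms). Heatmap tensors are float32.
The `freeze` flag (`none` / `half` / `mhsa`) exposes the stage-freezing
configurations; `half` freezes the modality-specific early layers,
`mhsa` is meaningful only for attention backbones and is otherwise a
no-op.

## Problem sizes used in the shipped experiments

The acceptance experiment trains three models (single-depth, IIF-2,
LIF-3 on RGB-D-IR) for 20 epochs on 500 synthetic frames (64 × 64, ten
subjects) and evaluates on 100 frames from two held-out subjects, plus
60 dark-lighting frames and 2 × 50 covering-stratified frames. These
sizes were chosen so the full study runs comfortably on a single CPU
core while leaving clear margins on its accuracy floors.

## Known limitations

* Transformer backbones are forward-only; training them would require
  attention/normalisation backward passes that the engine does not
  implement (the study's transformer results relied on GPU fine-tuning
  of zoo weights, which is out of scope here).
* Batch norm never updates running statistics, so training is restricted
  to the norm-free reduced family.
* FLOP figures follow this package's stated convention; other counting
  tools differ by up to ~10 % on transformer architectures (they
  disagree with each other by at least as much).
* From-scratch training of the reduced models at desk scale carries
  substantial run-to-run variance (on the order of ±0.1 AP across seeds).
  The robust findings across seeds are the accuracy floors, the
  dark-scene IR/RGB asymmetry and the covering ordering; the relative
  ranking of fusion versus the single-image model at a fixed 20-epoch
  budget can flip with the seed, and the fusion advantage itself is
  established by the clinical-scale experiments, not by this testbed.
* The synthetic scenes are a testbed, not a benchmark: absolute AP/OKS
  values on them have no clinical meaning.
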