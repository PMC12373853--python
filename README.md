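# neopose

Multimodal fusion pose estimation for pre-term neonates in intensive
care: locating the four torso key-points (left/right shoulder,
left/right hip) from time-synchronized RGB, depth and infra-red video of
an infant in an incubator, in the *unaltered* clinical scene — blankets,
darkness, nurses' hands and all. The package is aimed at researchers
building camera-based neonatal monitoring (position compliance, motion
and vital-sign reference points) who need the full experimental
apparatus: fusion architectures, a torso-adapted evaluation protocol,
activity-driven annotation sampling, subject-wise cross-validation,
missing-sensor ablation, and a synthetic scene generator that makes
every stage testable without access to identifiable clinical data.

## The models

A top-down heatmap detector is built from a stage-partitioned backbone
(HRNet-W32/W48, HRFormer-S/B, plain ViT-S/B, or a reduced trainable
family), split at stage X into an image-type-specific **Part 1** and a
shared **Part 2**, and combined across image types by one of

* **EIF** — early fusion: channel-stacked input (5 channels for
  RGB-D-IR) with a widened first convolution;
* **IIF-X** — intermediate fusion: per-modality Part 1, element-wise sum
  of feature maps, shared Part 2;
* **LIF-X** — late fusion: shared Part 2 evaluated per branch, heatmaps
  summed after the key-point head.

Transfer-learning weight adaptation (first-kernel channel summation for
grayscale-like inputs, kernel stacking for EIF, torso subsetting of a
17-channel COCO head — indices 5, 6, 11, 12) is provided as exact
array-level operations.

## The metric

Each frame k is scored by the object key-point similarity

    OKS_k = Σ_i δ_ik exp(−d_ik² / (2 κ_i² s_k²)) / Σ_i δ_ik

with per-key-point difficulty constants κ_i and a frame scale s_k²
derived from the *visible* key-points: 3.28 × torso-box area (3–4
visible, or two opposing corners), 2.0 × torso height² (one body side),
6.16 × shoulder width² (shoulders only), 13.64 × hip width² (hips only);
frames with ≤ 1 visible key-point are excluded. With one infant per
frame, AP at a threshold is the fraction of frames at or above it,
averaged over thresholds 0.50:0.05:0.95. Reports stratify by position,
covering and intervention.

## Worked example

```python
from neopose import (FusionPoseEstimator, FusionSpec, complexity,
                     generate_samples, score_frames,
                     average_precision, stratified_report)

# complexity of a published configuration
rep = complexity(FusionSpec(backbone="hrformer_s", strategy="iif",
                            modalities=("rgb", "depth", "ir"), split_x=2))
print(f"{rep.label}: {rep.mparams:.2f} M params, {rep.gflops:.2f} GFLOPS")

# desk-scale training on synthetic NICU scenes, subject-wise split
samples = generate_samples(n_subjects=12, frames_per_subject=50, seed=1)
train = [s for s in samples if s.frame.subject_id < "s010"]
test = [s for s in samples if s.frame.subject_id >= "s010"]
est = FusionPoseEstimator(backbone="tiny", strategy="single",
                          modalities=("depth",), epochs=20, lr=5e-3, seed=1)
est.fit([s.frame for s in train], [s.annotation for s in train])
dets = est.predict([s.frame for s in test])
scored = score_frames(dets, [s.annotation for s in test])
print("held-out AP:", {k: round(v, 3)
                       for k, v in average_precision(scored).items()})
rep = stratified_report(scored)
print(rep[rep.stratum == "covering"][["value", "n", "mean_oks", "AP"]]
      .to_string(index=False))
```

prints (a couple of minutes on one CPU core):

```
hrformer_s-iif-2-rgb+depth+ir: 8.84 M params, 16.32 GFLOPS
held-out AP: {'AP': 0.519, 'AP50': 0.91, 'AP75': 0.52}
        value  n  mean_oks       AP
         full 24  0.743725 0.541667
         half 20  0.752356 0.570000
         none 23  0.741775 0.530435
three_quarter 33  0.706109 0.463636
```

The first line says the three-branch HRFormer-S intermediate-fusion
model costs 8.84 M trainable parameters and 16.3 GFLOPS per forward pass
at 384 × 384 — the economy that makes it a cot-side candidate. The rest
is a depth-only reduced model trained from scratch on 500 synthetic
frames and evaluated on two held-out subjects: AP 0.519 means 51.9 % of
frames clear the OKS threshold ladder on average (91 % clear 0.5), and
the per-covering rows show the depth modality is comparatively
insensitive to blanket covering — the physical reason depth imaging
helps when the infant is covered.

A `neopose` CLI wraps the same library: `neopose simulate`,
`neopose select-frames`, `neopose complexity`, `neopose evaluate`.

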