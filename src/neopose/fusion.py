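"""Fusion architectures over stage-partitioned backbones.

Four model categories process the aligned image types:

* **single** — one backbone on one modality (reference models);
* **EIF** — early image fusion: the images are concatenated along the
  channel dimension (3 channels per RGB plus 1 per depth/IR) and the first
  convolution is widened to match;
* **IIF-X** — intermediate fusion: one image-type-specific Part 1 (stem +
  stages 1..X) per modality, feature maps summed element-wise, then a
  single shared Part 2; for X = 4 the summation happens right before the
  key-point head;
* **LIF-X** — late fusion: per-modality Part 1, the *same* shared Part 2
  is evaluated once per branch, and the per-branch heatmaps are summed
  after the key-point head.

Transfer-learning weight adaptation follows the channel-arithmetic rules
used when porting RGB-pretrained weights: single-channel modalities sum
the first convolution kernel along its input-channel axis (exact by
linearity for replicated-channel inputs), and EIF stacks kernels along the
channel dimension. Per-modality branches are initialised as identical
copies of the same base weights.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from . import nn
from .backbones import BACKBONES, StagePartitionedBackbone, build_backbone
from .nn import Module, Sequential, tree_sum
from .types import COCO_TORSO_INDICES, Detection, MODALITY_CHANNELS, MODALITIES

STRATEGIES = ("single", "eif", "iif", "lif")


@dataclass(frozen=True)
class FusionSpec:
    """Declarative description of a pose model."""

    backbone: str = "tiny"
    strategy: str = "single"
    modalities: Tuple[str, ...] = ("rgb",)
    split_x: Optional[int] = None
    input_size: Optional[Tuple[int, int]] = None  # (H, W); backbone default if None
    num_keypoints: int = 4
    freeze: str = "none"  # none | half | mhsa (training-time flag)

    def __post_init__(self):
        if self.backbone not in BACKBONES:
            raise ValueError(f"unknown backbone {self.backbone!r}")
        if self.strategy not in STRATEGIES:
            raise ValueError(f"unknown strategy {self.strategy!r}")
        mods = tuple(m for m in MODALITIES if m in self.modalities)
        if len(mods) != len(self.modalities) or not mods:
            raise ValueError(
                f"modalities must be a non-empty subset of {MODALITIES}"
            )
        object.__setattr__(self, "modalities", mods)
        if self.strategy == "single" and len(mods) != 1:
            raise ValueError("single-image models take exactly one modality")
        if self.strategy == "eif":
            if len(mods) < 2:
                raise ValueError("EIF needs at least two modalities")
            if self.split_x is not None:
                raise ValueError("EIF has no split point X")
        if self.strategy in ("iif", "lif"):
            if self.split_x is None or not 1 <= self.split_x <= 4:
                raise ValueError("IIF/LIF need a split point X in 1..4")
        if self.freeze not in ("none", "half", "mhsa"):
            raise ValueError("freeze must be none, half or mhsa")

    @property
    def resolved_input_size(self) -> Tuple[int, int]:
        return self.input_size or BACKBONES[self.backbone][1]

    def label(self) -> str:
        if self.strategy == "single":
            return f"{self.backbone}-{self.modalities[0]}"
        x = f"-{self.split_x}" if self.split_x else ""
        return f"{self.backbone}-{self.strategy}{x}-" + "+".join(self.modalities)


# ---------------------------------------------------------------------------
# weight adaptation

def adapt_first_layer_sum(weights: np.ndarray) -> np.ndarray:
    """Collapse a 3-channel first-convolution kernel to one input channel.

    By linearity, convolving the summed kernel with a single-channel image
    equals convolving the original kernel with that image replicated to
    three channels; the bias is untouched.
    """
    w = np.asarray(weights)
    if w.ndim != 4 or w.shape[1] != 3:
        raise ValueError(f"expected (out, 3, kh, kw) weights, got {w.shape}")
    return w.sum(axis=1, keepdims=True)


def adapt_first_layer_stack(
    weights: np.ndarray, modalities: Sequence[str]
) -> np.ndarray:
    """Widen a 3-channel first convolution for channel-stacked (EIF) input.

    The RGB slot keeps the original kernels bit-for-bit; every
    single-channel modality slot receives the channel-summed kernel scaled
    by 1 / (number of modalities), so no single extra channel dominates the
    stacked response.
    """
    mods = tuple(m for m in MODALITIES if m in modalities)
    if len(mods) < 2:
        raise ValueError("EIF stacking needs at least two modalities")
    w = np.asarray(weights)
    if w.ndim != 4 or w.shape[1] != 3:
        raise ValueError(f"expected (out, 3, kh, kw) weights, got {w.shape}")
    summed = w.sum(axis=1, keepdims=True) / len(mods)
    blocks = [w if m == "rgb" else summed for m in mods]
    return np.concatenate(blocks, axis=1)


def subset_keypoint_head(
    weights: np.ndarray,
    bias: Optional[np.ndarray] = None,
    indices: Sequence[int] = COCO_TORSO_INDICES,
):
    """Keep only the torso heatmap channels of a full-skeleton head.

    ``weights`` has output channels first (e.g. a (17, C, 1, 1) conv
    kernel); the retained output channels are COCO indices 5, 6, 11, 12 in
    that order, so the new head's heatmap ``c`` equals the old head's
    heatmap ``indices[c]`` on any input.
    """
    w = np.asarray(weights)
    if w.shape[0] <= max(indices):
        raise ValueError(
            f"head with {w.shape[0]} outputs cannot be subset to indices "
            f"{tuple(indices)}"
        )
    w4 = w[list(indices)]
    if bias is None:
        return w4
    return w4, np.asarray(bias)[list(indices)]


def _copy_adapted(dst: StagePartitionedBackbone, base: StagePartitionedBackbone,
                  mode: str, modalities: Sequence[str] = ()) -> None:
    """Copy base weights into ``dst``, adapting the first convolution."""
    pd_, ps = dst.full().parameters(), base.full().parameters()
    assert len(pd_) == len(ps)
    mismatches = 0
    for a, b in zip(pd_, ps):
        if a.value.shape == b.value.shape:
            a.value[...] = b.value
        else:
            mismatches += 1
            if mode == "sum":
                a.value[...] = adapt_first_layer_sum(b.value)
            elif mode == "stack":
                a.value[...] = adapt_first_layer_stack(b.value, modalities)
            else:
                raise AssertionError("unexpected shape mismatch")
    if mode in ("sum", "stack") and mismatches != 1:
        raise AssertionError("first-layer adaptation did not trigger exactly once")


# ---------------------------------------------------------------------------
# pose models

class PoseModel(Module):
    """Common surface: forward a dict of modality images to heatmaps."""

    spec: FusionSpec

    @property
    def heatmap_stride(self) -> int:
        return self._stride

    def expected_channels(self) -> Dict[str, int]:
        return {m: MODALITY_CHANNELS[m] for m in self.spec.modalities}

    def _check_inputs(self, inputs: Dict[str, np.ndarray]) -> Dict[str, np.ndarray]:
        out = {}
        shape = None
        for m in self.spec.modalities:
            if m not in inputs:
                raise ValueError(f"missing input for modality {m!r}")
            x = np.asarray(inputs[m], dtype=np.float32)
            if x.ndim == 3:
                x = x[:, None]
            if x.shape[1] != MODALITY_CHANNELS[m]:
                raise ValueError(
                    f"{m} input must have {MODALITY_CHANNELS[m]} channels"
                )
            if shape is None:
                shape = x.shape[2:]
            elif x.shape[2:] != shape:
                raise ValueError("modalities must share the same image size")
            out[m] = x
        return out


class SinglePoseNet(PoseModel):
    def __init__(self, spec, backbone):
        self.spec = spec
        self.backbone = backbone
        self.net = backbone.full()
        self._stride = backbone.heatmap_stride

    def forward(self, inputs, train=False):
        x = self._check_inputs(inputs)[self.spec.modalities[0]]
        return self.net.forward(x, train)

    def backward(self, gout, cache):
        return self.net.backward(gout, cache)

    def flops(self, input_size=None):
        h, w = input_size or self.spec.resolved_input_size
        c = MODALITY_CHANNELS[self.spec.modalities[0]]
        f, _ = self.net.complexity((c, h, w))
        return {"model": f}


class EIFPoseNet(PoseModel):
    def __init__(self, spec, backbone):
        self.spec = spec
        self.backbone = backbone
        self.net = backbone.full()
        self._stride = backbone.heatmap_stride

    def forward(self, inputs, train=False):
        xs = self._check_inputs(inputs)
        x = np.concatenate([xs[m] for m in self.spec.modalities], axis=1)
        return self.net.forward(x, train)

    def backward(self, gout, cache):
        return self.net.backward(gout, cache)

    def flops(self, input_size=None):
        h, w = input_size or self.spec.resolved_input_size
        c = sum(MODALITY_CHANNELS[m] for m in self.spec.modalities)
        f, _ = self.net.complexity((c, h, w))
        return {"model": f}


def _numel(shapes) -> int:
    if isinstance(shapes, list):
        return sum(int(np.prod(s)) for s in shapes)
    return int(np.prod(shapes))


class IIFPoseNet(PoseModel):
    """Per-modality Part 1, element-wise feature summation, shared Part 2."""

    def __init__(self, spec, part1s: Dict[str, Sequential], part2: Sequential,
                 stride: int):
        self.spec = spec
        self.part1s = part1s
        self.part2 = part2
        self._stride = stride
        self._branches = [part1s[m] for m in spec.modalities]  # for traversal

    def children(self):
        return self._branches + [self.part2]

    def forward(self, inputs, train=False):
        xs = self._check_inputs(inputs)
        feats, caches = [], []
        for m in self.spec.modalities:
            f, c = self.part1s[m].forward(xs[m], train)
            feats.append(f)
            caches.append(c)
        summed = tree_sum(feats)
        out, c2 = self.part2.forward(summed, train)
        return out, (caches, c2)

    def backward(self, gout, cache):
        caches, c2 = cache
        g = self.part2.backward(gout, c2)
        if isinstance(g, list) and not isinstance(g, np.ndarray):
            raise NotImplementedError("backward through multi-branch features")
        gins = {}
        for m, c in zip(self.spec.modalities, caches):
            gins[m] = self.part1s[m].backward(g, c)
        return gins

    def flops(self, input_size=None):
        h, w = input_size or self.spec.resolved_input_size
        out = {}
        feat_shape = None
        for m in self.spec.modalities:
            f, shape = self.part1s[m].complexity((MODALITY_CHANNELS[m], h, w))
            out[f"part1[{m}]"] = f
            feat_shape = shape
        out["fusion_sum"] = (len(self.spec.modalities) - 1) * _numel(feat_shape)
        f2, _ = self.part2.complexity(feat_shape)
        out["part2"] = f2
        return out


class LIFPoseNet(PoseModel):
    """Per-modality Part 1, shared Part 2 evaluated per branch, heatmap sum."""

    def __init__(self, spec, part1s: Dict[str, Sequential], part2: Sequential,
                 stride: int):
        self.spec = spec
        self.part1s = part1s
        self.part2 = part2
        self._stride = stride
        self._branches = [part1s[m] for m in spec.modalities]

    def children(self):
        return self._branches + [self.part2]

    def branch_heatmaps(self, inputs) -> Dict[str, np.ndarray]:
        """Per-modality heatmaps before summation (diagnostic view)."""
        xs = self._check_inputs(inputs)
        out = {}
        for m in self.spec.modalities:
            f, _ = self.part1s[m].forward(xs[m])
            out[m], _ = self.part2.forward(f)
        return out

    def forward(self, inputs, train=False):
        xs = self._check_inputs(inputs)
        maps, caches = [], []
        for m in self.spec.modalities:
            f, c1 = self.part1s[m].forward(xs[m], train)
            hmap, c2 = self.part2.forward(f, train)
            maps.append(hmap)
            caches.append((c1, c2))
        return tree_sum(maps), caches

    def backward(self, gout, cache):
        gins = {}
        for m, (c1, c2) in zip(self.spec.modalities, cache):
            g = self.part2.backward(gout, c2)  # shared grads accumulate
            gins[m] = self.part1s[m].backward(g, c1)
        return gins

    def flops(self, input_size=None):
        h, w = input_size or self.spec.resolved_input_size
        out = {}
        hm_shape = None
        for m in self.spec.modalities:
            f1, feat = self.part1s[m].complexity((MODALITY_CHANNELS[m], h, w))
            out[f"part1[{m}]"] = f1
            f2, hm_shape = self.part2.complexity(feat)
            out[f"part2[{m}]"] = f2
        out["fusion_sum"] = (len(self.spec.modalities) - 1) * _numel(hm_shape)
        return out


# ---------------------------------------------------------------------------
# model construction

def build_model(spec: FusionSpec, seed: int = 0) -> PoseModel:
    """Assemble a pose model from its specification.

    All branches start from the same base weights (identical copies), with
    the first convolution adapted to each modality's channel count.
    """
    size = spec.resolved_input_size
    base = build_backbone(spec.backbone, 3, spec.num_keypoints, size, seed)

    def adapted(in_ch: int, mode: str) -> StagePartitionedBackbone:
        bb = build_backbone(spec.backbone, in_ch, spec.num_keypoints, size, seed)
        if mode != "none":
            _copy_adapted(bb, base, mode, spec.modalities)
        return bb

    if spec.strategy == "single":
        m = spec.modalities[0]
        if m == "rgb":
            return SinglePoseNet(spec, base)
        return SinglePoseNet(spec, adapted(1, "sum"))

    if spec.strategy == "eif":
        total = sum(MODALITY_CHANNELS[m] for m in spec.modalities)
        return EIFPoseNet(spec, adapted(total, "stack"))

    x = spec.split_x
    part1s = {}
    for m in spec.modalities:
        if m == "rgb":
            bb = build_backbone(spec.backbone, 3, spec.num_keypoints, size, seed)
            _copy_adapted(bb, base, "copy")
        else:
            bb = adapted(1, "sum")
        part1s[m] = bb.part1(x)
    part2 = base.part2(x)
    cls = IIFPoseNet if spec.strategy == "iif" else LIFPoseNet
    return cls(spec, part1s, part2, base.heatmap_stride)


def zero_fill(
    inputs: Dict[str, np.ndarray], available: Iterable[str]
) -> Dict[str, np.ndarray]:
    """Replace unavailable modality images with all-zero images.

    Emulates evaluating a fusion model when only a subset of image types is
    provided; available images pass through unchanged.
    """
    avail = set(available)
    if not avail:
        raise ValueError("at least one modality must remain available")
    unknown = avail - set(inputs)
    if unknown:
        raise ValueError(f"available modalities {sorted(unknown)} not in inputs")
    return {
        m: (x if m in avail else np.zeros_like(np.asarray(x, dtype=np.float32)))
        for m, x in inputs.items()
    }


# ---------------------------------------------------------------------------
# heatmap decoding

def decode_heatmaps(
    heatmaps: np.ndarray, stride: int = 4, frame_id: str = ""
) -> Detection:
    """Decode per-key-point heatmaps to pixel coordinates and confidences.

    The peak (ties broken toward the lower linear index) is refined by a
    quarter-pixel shift toward the higher of the two neighbours along each
    axis, then mapped to input pixels by the heatmap stride; the score is
    the peak value clipped to [0, 1]. A constant map decodes to the map
    centre with its value as the score.
    """
    hm = np.asarray(heatmaps, dtype=float)
    if hm.ndim != 3:
        raise ValueError("expected (K, H, W) heatmaps")
    k, h, w = hm.shape
    pts, scores = [], []
    for c in range(k):
        m = hm[c]
        if np.ptp(m) == 0.0:
            pts.append(((w - 1) / 2.0 * stride, (h - 1) / 2.0 * stride))
            scores.append(float(np.clip(m.flat[0], 0.0, 1.0)))
            continue
        flat = int(np.argmax(m))
        y, x = divmod(flat, w)
        fx, fy = float(x), float(y)
        if 0 < x < w - 1:
            fx += 0.25 * np.sign(m[y, x + 1] - m[y, x - 1])
        if 0 < y < h - 1:
            fy += 0.25 * np.sign(m[y + 1, x] - m[y - 1, x])
        pts.append((fx * stride, fy * stride))
        scores.append(float(np.clip(m[y, x], 0.0, 1.0)))
    return Detection(frame_id=frame_id, keypoints=np.asarray(pts),
                     scores=np.asarray(scores))


# ---------------------------------------------------------------------------
# complexity accounting

@dataclass
class ComplexityReport:
    """Trainable parameters and forward FLOPs (1 MAC = 1 FLOP) per part."""

    label: str
    input_size: Tuple[int, int]
    params: int
    flops: int
    param_breakdown: Dict[str, int]
    flop_breakdown: Dict[str, int]

    @property
    def gflops(self) -> float:
        return self.flops / 1e9

    @property
    def mparams(self) -> float:
        return self.params / 1e6

    def to_frame(self) -> pd.DataFrame:
        parts = sorted(set(self.param_breakdown) | set(self.flop_breakdown))
        rows = [
            {
                "part": p,
                "params": self.param_breakdown.get(p, 0),
                "flops": self.flop_breakdown.get(p, 0),
            }
            for p in parts
        ]
        rows.append({"part": "total", "params": self.params, "flops": self.flops})
        return pd.DataFrame(rows)


def complexity(spec: FusionSpec, seed: int = 0) -> ComplexityReport:
    """Parameter count and symbolic forward-pass FLOPs for a model spec."""
    model = build_model(spec, seed)
    flop_breakdown = model.flops()
    flops = int(sum(flop_breakdown.values()))

    param_breakdown: Dict[str, int] = {}
    if isinstance(model, (IIFPoseNet, LIFPoseNet)):
        for m in spec.modalities:
            param_breakdown[f"part1[{m}]"] = model.part1s[m].num_params()
        param_breakdown["part2"] = model.part2.num_params()
    else:
        param_breakdown["model"] = model.net.num_params()
    params = int(sum(param_breakdown.values()))
    assert params == model.num_params()
    return ComplexityReport(
        label=spec.label(),
        input_size=spec.resolved_input_size,
        params=params,
        flops=flops,
        param_breakdown=param_breakdown,
        flop_breakdown=flop_breakdown,
    )
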