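"""Trainable pose estimator with a scikit-learn interface.

`FusionPoseEstimator` wraps model assembly, input normalisation, Gaussian
heatmap targets, masked-MSE training with AdamW and heatmap decoding into
a fit/predict estimator, so models compose with sklearn tooling (clone,
parameter grids). Training requires a backbone with backward support (the
reduced convolutional family); the large backbones remain available for
forward passes and complexity analysis.

X is a sequence of :class:`~neopose.types.MultimodalFrame` with image
arrays loaded; y the matching :class:`~neopose.types.TorsoAnnotation`.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from sklearn.base import BaseEstimator

from .fusion import FusionSpec, build_model, decode_heatmaps, zero_fill
from .metrics import MetricConfig, average_precision, score_frames
from .types import Detection, MultimodalFrame, TorsoAnnotation, Visibility


class AdamW:
    """Adam with decoupled weight decay."""

    def __init__(self, params, lr=5e-4, weight_decay=0.01, betas=(0.9, 0.999),
                 eps=1e-8):
        self.params = list(params)
        self.lr, self.wd = lr, weight_decay
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            if self.wd:
                p.value *= 1.0 - self.lr * self.wd
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def stack_modalities(
    frames: Sequence[MultimodalFrame], modalities: Sequence[str],
    fill_invalid_depth: bool = True,
) -> Dict[str, np.ndarray]:
    """Stack per-frame images into (N, C, H, W) float arrays per modality.

    Depth pixels at 0 are time-of-flight dropout; they are filled with the
    frame's median valid depth so they do not become extreme outliers after
    standardisation.
    """
    out = {}
    for m in modalities:
        imgs = []
        for f in frames:
            img = getattr(f, m)
            if img is None:
                raise ValueError(f"frame {f.frame_id!r} has no {m} image loaded")
            arr = np.asarray(img, dtype=np.float32)
            if arr.ndim == 2:
                arr = arr[None]
            else:
                arr = arr.transpose(2, 0, 1)
            if m == "depth" and fill_invalid_depth:
                arr = arr.copy()
                valid = arr > 0
                if valid.any() and not valid.all():
                    arr[~valid] = np.median(arr[valid])
            imgs.append(arr)
        out[m] = np.stack(imgs)
    return out


def gaussian_targets(
    annotations: Sequence[TorsoAnnotation],
    heatmap_size: Tuple[int, int],
    stride: int,
    sigma: float,
    min_visibility: Visibility = Visibility.OCCLUDED,
) -> Tuple[np.ndarray, np.ndarray]:
    """Per-key-point Gaussian heatmap targets and visibility masks."""
    h, w = heatmap_size
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float32)
    n, k = len(annotations), 4
    targets = np.zeros((n, k, h, w), dtype=np.float32)
    mask = np.zeros((n, k), dtype=np.float32)
    for i, ann in enumerate(annotations):
        for c, ((x, y), v) in enumerate(zip(ann.keypoints, ann.visibility)):
            if int(v) < int(min_visibility):
                continue
            mask[i, c] = 1.0
            cx, cy = x / stride, y / stride
            targets[i, c] = np.exp(
                -((xx - cx) ** 2 + (yy - cy) ** 2) / (2.0 * sigma**2)
            )
    return targets, mask


class FusionPoseEstimator(BaseEstimator):
    """Top-down heatmap pose estimator over a fusion architecture.

    Parameters mirror the training protocol of the clinical experiments:
    AdamW with learning rate 5e-4 and weight decay, a fixed epoch budget,
    MSE on Gaussian heatmaps masked by key-point visibility, and optional
    best-validation-AP checkpointing. Inputs are z-scored per modality
    with statistics estimated from the training set.
    """

    def __init__(self, backbone="tiny", strategy="single", modalities=("rgb",),
                 split_x=None, input_size=None, epochs=20, lr=2e-3,
                 weight_decay=0.01, batch_size=16, sigma=2.0, pos_weight=10.0,
                 seed=0, freeze="none", checkpoint="best"):
        self.backbone = backbone
        self.strategy = strategy
        self.modalities = modalities
        self.split_x = split_x
        self.input_size = input_size
        self.epochs = epochs
        self.lr = lr
        self.weight_decay = weight_decay
        self.batch_size = batch_size
        self.sigma = sigma
        self.pos_weight = pos_weight
        self.seed = seed
        self.freeze = freeze
        self.checkpoint = checkpoint

    # -- plumbing ------------------------------------------------------------
    def _spec(self) -> FusionSpec:
        return FusionSpec(
            backbone=self.backbone, strategy=self.strategy,
            modalities=tuple(self.modalities), split_x=self.split_x,
            input_size=self.input_size, freeze=self.freeze,
        )

    def _fill_depth(self, raw: Dict[str, np.ndarray]) -> Dict[str, np.ndarray]:
        """Impute invalid (zero) depth pixels with the frame's median valid
        depth; a frame with no valid depth at all (e.g. a missing sensor)
        is imputed with the training-set mean, i.e. a neutral input."""
        if "depth" not in raw:
            return raw
        d = raw["depth"].copy()
        for i in range(d.shape[0]):
            valid = d[i] > 0
            if valid.all():
                continue
            if valid.any():
                d[i][~valid] = np.median(d[i][valid])
            else:
                fallback = self.stats_["depth"][0] if hasattr(self, "stats_") else 0.0
                d[i][...] = fallback
        return {**raw, "depth": d}

    def _normalize(self, raw: Dict[str, np.ndarray]) -> Dict[str, np.ndarray]:
        out = {}
        for m, x in raw.items():
            mean, std = self.stats_[m]
            out[m] = (x - mean) / std
        return out

    def _fit_stats(self, raw: Dict[str, np.ndarray]) -> None:
        self.stats_ = {}
        for m, x in raw.items():
            std = float(x.std())
            self.stats_[m] = (float(x.mean()), std if std > 0 else 1.0)

    def _trainable_params(self):
        params = self.model_.parameters()
        if self.freeze == "none":
            return params
        if self.freeze == "half":
            frozen = set()
            for part in getattr(self.model_, "part1s", {}).values():
                frozen.update(id(p) for p in part.parameters())
            if not frozen and hasattr(self.model_, "backbone"):
                bb = self.model_.backbone
                for mod in [bb.stem, *bb.stages[:2]]:
                    frozen.update(id(p) for p in mod.parameters())
            return [p for p in params if id(p) not in frozen]
        # 'mhsa': freeze everything except attention modules (transformer
        # backbones); for conv families this equals 'none'
        return params

    # -- estimator API --------------------------------------------------------
    def fit(self, X, y, X_val=None, y_val=None):
        spec = self._spec()
        self.model_ = build_model(spec, seed=self.seed)
        raw = self._fill_depth(stack_modalities(X, spec.modalities,
                                                fill_invalid_depth=False))
        self._fit_stats(raw)
        inputs = self._normalize(raw)
        n = len(X)
        h, w = next(iter(inputs.values())).shape[2:]
        stride = self.model_.heatmap_stride
        targets, mask = gaussian_targets(
            y, (h // stride, w // stride), stride, self.sigma
        )

        opt = AdamW(self._trainable_params(), lr=self.lr,
                    weight_decay=self.weight_decay)
        rng = np.random.default_rng([self.seed, 7])
        self.history_ = []
        best_ap, best_state = -np.inf, None
        warmup = min(2, max(0, self.epochs - 1))
        for epoch in range(self.epochs):
            # linear warmup then cosine decay to a tenth of the base rate
            if epoch < warmup:
                opt.lr = self.lr * (epoch + 1) / (warmup + 1)
            else:
                frac = (epoch - warmup) / max(1, self.epochs - 1 - warmup)
                opt.lr = self.lr * (0.1 + 0.9 * 0.5 * (1 + np.cos(np.pi * frac)))
            order = rng.permutation(n)
            losses = []
            for lo in range(0, n, self.batch_size):
                idx = order[lo : lo + self.batch_size]
                batch = {m: x[idx] for m, x in inputs.items()}
                pred, cache = self.model_.forward(batch, train=True)
                tgt = targets[idx]
                diff = (pred - tgt) * mask[idx][:, :, None, None]
                # up-weight the Gaussian peaks so the loss cannot be
                # satisfied by an all-background prediction
                wgt = 1.0 + self.pos_weight * tgt
                denom = max(mask[idx].sum(), 1.0) * pred.shape[2] * pred.shape[3]
                loss = float((wgt * diff**2).sum() / denom)
                self.model_.zero_grad()
                self.model_.backward(2.0 * wgt * diff / denom, cache)
                opt.step()
                losses.append(loss)
            entry = {"epoch": epoch, "loss": float(np.mean(losses))}
            if X_val is not None:
                entry["val_AP"] = self.score(X_val, y_val)
                if self.checkpoint == "best" and entry["val_AP"] >= best_ap:
                    best_ap = entry["val_AP"]
                    best_state = [p.value.copy() for p in self.model_.parameters()]
                    self.best_epoch_ = epoch
            self.history_.append(entry)
        if best_state is not None:
            for p, v in zip(self.model_.parameters(), best_state):
                p.value[...] = v
        return self

    def _predict_heatmaps(self, X, keep=None) -> np.ndarray:
        raw = stack_modalities(X, self._spec().modalities,
                               fill_invalid_depth=False)
        if keep is not None:
            raw = zero_fill(raw, keep)
        inputs = self._normalize(self._fill_depth(raw))
        outs = []
        bs = max(1, self.batch_size)
        for lo in range(0, len(X), bs):
            batch = {m: x[lo : lo + bs] for m, x in inputs.items()}
            pred, _ = self.model_.forward(batch)
            outs.append(pred)
        return np.concatenate(outs)

    def predict(self, X, keep=None) -> List[Detection]:
        """Decode detections; ``keep`` restricts the available modalities
        (the rest are zero-filled), emulating missing sensors."""
        heatmaps = self._predict_heatmaps(X, keep)
        stride = self.model_.heatmap_stride
        return [
            decode_heatmaps(hm, stride, frame_id=f.frame_id)
            for hm, f in zip(heatmaps, X)
        ]

    def score(self, X, y, keep=None) -> float:
        """Mean AP over the OKS threshold ladder on (X, y)."""
        dets = self.predict(X, keep=keep)
        scored = score_frames(dets, y, MetricConfig())
        if not scored:
            return float("nan")
        return average_precision(scored)["AP"]
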