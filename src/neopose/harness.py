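"""Experiment harness: subject-wise cross-validation, training runs and
missing-modality ablation.

Subject-wise folds keep every frame of an infant in the same fold, so each
model is tested on entirely unseen babies — the split that matters for
clinical generalisation claims. The harness runs desk-scale experiments on
synthetic scenes with the reduced trainable backbone; the same code paths
apply to any dataset readable by :mod:`neopose.io`.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .estimator import FusionPoseEstimator
from .fusion import FusionSpec
from .metrics import MetricConfig, average_precision, score_frames
from .scenes import SceneSample
from .types import MultimodalFrame, TorsoAnnotation


@dataclass
class TrainConfig:
    """Training protocol: AdamW with weight decay, lr 5e-4, a fixed epoch
    budget with best-validation-AP checkpointing."""

    spec: FusionSpec = field(default_factory=FusionSpec)
    epochs: int = 50
    lr: float = 5e-4
    weight_decay: float = 0.01
    batch_size: int = 16
    sigma: float = 2.0
    seed: int = 0
    checkpoint: str = "best"  # or 'final'

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.lr < 0:
            raise ValueError("learning rate must be non-negative")

    def make_estimator(self) -> FusionPoseEstimator:
        s = self.spec
        return FusionPoseEstimator(
            backbone=s.backbone, strategy=s.strategy, modalities=s.modalities,
            split_x=s.split_x, input_size=s.input_size, epochs=self.epochs,
            lr=self.lr, weight_decay=self.weight_decay,
            batch_size=self.batch_size, sigma=self.sigma, seed=self.seed,
            freeze=s.freeze, checkpoint=self.checkpoint,
        )


@dataclass
class FoldAssignment:
    """Mapping subject id -> fold index, balanced to within one subject."""

    folds: Dict[str, int]
    k: int

    def subjects_in(self, fold: int) -> List[str]:
        return sorted(s for s, f in self.folds.items() if f == fold)

    def validate(self):
        sizes = np.bincount(list(self.folds.values()), minlength=self.k)
        if sizes.max() - sizes.min() > 1:
            raise ValueError("fold sizes differ by more than one subject")
        return self


def make_folds(subject_ids: Iterable[str], k: int = 5, seed: int = 0) -> FoldAssignment:
    """Seeded, balanced assignment of whole subjects to ``k`` folds."""
    subjects = sorted(set(subject_ids))
    if len(subjects) < k:
        raise ValueError(f"need at least {k} subjects, got {len(subjects)}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(subjects))
    folds = {subjects[j]: i % k for i, j in enumerate(order)}
    return FoldAssignment(folds, k).validate()


def _split(samples: Sequence[SceneSample], folds: FoldAssignment, test_fold: int):
    train, test = [], []
    for s in samples:
        (test if folds.folds[s.frame.subject_id] == test_fold else train).append(s)
    train_subj = {s.frame.subject_id for s in train}
    test_subj = {s.frame.subject_id for s in test}
    assert not train_subj & test_subj, "subject leakage across the split"
    return train, test


def _xy(samples: Sequence[SceneSample]):
    return [s.frame for s in samples], [s.annotation for s in samples]


def train(
    samples: Sequence[SceneSample],
    config: TrainConfig,
    folds: FoldAssignment,
    test_fold: int,
) -> Tuple[FusionPoseEstimator, pd.DataFrame]:
    """Train on all folds but ``test_fold``; returns model + training curve
    (per-epoch loss and held-out AP)."""
    train_set, test_set = _split(samples, folds, test_fold)
    if not train_set:
        raise ValueError("training fold is empty")
    est = config.make_estimator()
    est.fit(*_xy(train_set), *(_xy(test_set) if test_set else (None, None)))
    return est, pd.DataFrame(est.history_)


def cross_validate(
    samples: Sequence[SceneSample], config: TrainConfig
) -> pd.DataFrame:
    """Five-fold subject-wise cross-validation.

    Returns one row per fold (AP on the held-out fold) plus a summary row
    with the mean and sample standard deviation across folds.
    """
    folds = make_folds([s.frame.subject_id for s in samples], seed=config.seed)
    rows = []
    for fold in range(folds.k):
        est, _ = train(samples, config, folds, fold)
        _, test_set = _split(samples, folds, fold)
        ap = est.score(*_xy(test_set)) if test_set else float("nan")
        rows.append({"fold": fold, "AP": ap, "n_test": len(test_set)})
    df = pd.DataFrame(rows)
    aps = df["AP"].to_numpy(dtype=float)
    df.loc[len(df)] = {
        "fold": "mean±sd",
        "AP": float(np.mean(aps)),
        "n_test": float(np.std(aps, ddof=1)) if len(aps) > 1 else 0.0,
    }
    return df


def ablate_missing(
    est: FusionPoseEstimator,
    samples: Sequence[SceneSample],
    keep_subsets: Optional[Sequence[Tuple[str, ...]]] = None,
    cfg: Optional[MetricConfig] = None,
) -> pd.DataFrame:
    """AP when only a subset of image types is provided.

    Unavailable modalities are replaced by all-zero images before the
    standard preprocessing. The default subsets follow the missing-image
    protocol: all images, each leave-one-out pair, and each single image.
    """
    cfg = cfg or MetricConfig()
    mods = tuple(est._spec().modalities)
    if keep_subsets is None:
        keep_subsets = [mods]
        if len(mods) > 1:
            keep_subsets += [
                tuple(m for m in mods if m != drop) for drop in mods
            ] + [(m,) for m in mods]
    frames, annos = _xy(samples)
    rows = []
    for keep in keep_subsets:
        if not set(keep) <= set(mods):
            raise ValueError(f"subset {keep} not within model modalities {mods}")
        dets = est.predict(frames, keep=keep)
        scored = score_frames(dets, annos, cfg)
        ap = average_precision(scored, cfg)["AP"] if scored else float("nan")
        rows.append({"kept": "+".join(keep), "AP": ap, "n": len(scored)})
    return pd.DataFrame(rows)
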