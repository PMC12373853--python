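"""Torso-adapted OKS and AP evaluation.

With only four annotated key-points and no segmented body outline, the
standard COCO object key-point similarity needs two adaptations:

* the per-frame scale ``s_k`` is derived from the *visible* torso
  key-points, with a visibility-dependent multiplicative factor calibrated
  so that the expected value matches the COCO person-area convention
  (3.28 x torso box area when the box is two-dimensional; 2.0 x torso
  height squared for a single body side; 6.16 x shoulder width squared;
  13.64 x hip width squared); frames with at most one visible key-point are
  excluded from evaluation, and
* each frame holds exactly one infant, so the AP at a threshold reduces to
  the fraction of evaluated frames whose OKS reaches the threshold.

OKS for frame ``k`` is

    OKS_k = sum_i delta_ik exp(-d_ik^2 / (2 kappa_i^2 s_k^2)) / sum_i delta_ik

where ``d_ik`` is the detection error of key-point ``i`` in pixels,
``kappa_i`` a per-key-point difficulty constant and ``delta_ik`` the
visibility indicator.
"""
from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .types import Detection, TorsoAnnotation, Visibility

#: COCO per-key-point sigma for (L shoulder, R shoulder, L hip, R hip);
#: the OKS Gaussian uses kappa = 2 * sigma, as in the reference evaluator.
COCO_SIGMAS = (0.079, 0.079, 0.107, 0.107)
DEFAULT_KAPPAS = tuple(2.0 * s for s in COCO_SIGMAS)

DEFAULT_THRESHOLDS = tuple(np.round(np.arange(0.50, 0.951, 0.05), 2))


@dataclass
class MetricConfig:
    """Evaluation constants.

    ``delta_min_visibility`` controls which visibility states count as
    delta = 1: with the default (OCCLUDED) both clearly-visible and
    object-occluded key-points are evaluated (COCO ``v >= 1`` convention);
    set to VISIBLE for strict mode.
    """

    kappas: Tuple[float, ...] = DEFAULT_KAPPAS
    thresholds: Tuple[float, ...] = DEFAULT_THRESHOLDS
    delta_min_visibility: Visibility = Visibility.OCCLUDED

    def __post_init__(self):
        if any(k <= 0 for k in self.kappas):
            raise ValueError("kappas must be positive")
        t = np.asarray(self.thresholds)
        if not (np.all(np.diff(t) > 0) and np.all((t > 0) & (t < 1))):
            raise ValueError("thresholds must be strictly increasing in (0, 1)")

    def delta(self, annotation: TorsoAnnotation) -> np.ndarray:
        return np.array(
            [int(v) >= int(self.delta_min_visibility) for v in annotation.visibility]
        )


class ScaleCase(enum.Enum):
    TORSO_BOX = "torso_box"  # 3-4 visible, or two opposing corners
    SIDE_PAIR = "side_pair"  # only-left or only-right shoulder+hip
    SHOULDERS = "shoulders"  # only the two shoulders
    HIPS = "hips"  # only the two hips
    EXCLUDED = "excluded"  # <= 1 visible, or zero spatial extent


#: multiplicative factors mapping the visible-key-point geometry to s^2,
#: calibrated against the COCO person-area convention
SCALE_FACTORS = {
    ScaleCase.TORSO_BOX: 3.28,
    ScaleCase.SIDE_PAIR: 2.0,
    ScaleCase.SHOULDERS: 6.16,
    ScaleCase.HIPS: 13.64,
}


@dataclass
class ScaleResult:
    s2: float
    case: ScaleCase
    excluded: bool


@dataclass
class FrameScore:
    frame_id: str
    oks: float
    case: ScaleCase
    position: str = "unknown"
    covering: str = "unknown"
    intervention: Optional[bool] = None


def compute_scale(
    annotation: TorsoAnnotation, cfg: Optional[MetricConfig] = None
) -> ScaleResult:
    """Visibility-dependent scale parameter for one frame.

    Key-point order is (L shoulder, R shoulder, L hip, R hip). "Two opposing
    corners" means one shoulder plus the contralateral hip — the only pairs
    spanning the torso box diagonal. Widths/heights are Euclidean distances
    between the respective key-points. Frames whose visible key-points have
    no spatial extent (coincident points) are excluded as degenerate.
    """
    cfg = cfg or MetricConfig()
    vis = cfg.delta(annotation)
    pts = annotation.keypoints
    idx = np.flatnonzero(vis)
    n = len(idx)

    def result(case, value):
        if value <= 0:
            return ScaleResult(0.0, ScaleCase.EXCLUDED, True)
        return ScaleResult(SCALE_FACTORS[case] * value, case, False)

    if n <= 1:
        return ScaleResult(0.0, ScaleCase.EXCLUDED, True)
    if n >= 3:
        sel = pts[idx]
        area = np.ptp(sel[:, 0]) * np.ptp(sel[:, 1])
        return result(ScaleCase.TORSO_BOX, area)
    pair = frozenset(idx)
    if pair in ({0, 3}, {1, 2}):  # shoulder + contralateral hip
        sel = pts[idx]
        area = np.ptp(sel[:, 0]) * np.ptp(sel[:, 1])
        return result(ScaleCase.TORSO_BOX, area)
    if pair in ({0, 2}, {1, 3}):  # same-side shoulder + hip
        height = np.linalg.norm(pts[idx[0]] - pts[idx[1]])
        return result(ScaleCase.SIDE_PAIR, height**2)
    if pair == {0, 1}:
        width = np.linalg.norm(pts[0] - pts[1])
        return result(ScaleCase.SHOULDERS, width**2)
    # only hips remain
    width = np.linalg.norm(pts[2] - pts[3])
    return result(ScaleCase.HIPS, width**2)


def oks(
    detection: Detection,
    annotation: TorsoAnnotation,
    scale: Optional[ScaleResult] = None,
    cfg: Optional[MetricConfig] = None,
) -> FrameScore:
    """Object key-point similarity of one detection against ground truth."""
    cfg = cfg or MetricConfig()
    if scale is None:
        scale = compute_scale(annotation, cfg)
    if scale.excluded:
        raise ValueError(
            f"frame {annotation.frame_id!r} has no usable scale and is not "
            "evaluated"
        )
    delta = cfg.delta(annotation).astype(float)
    if delta.sum() < 1:
        raise ValueError("OKS needs at least one key-point with delta = 1")
    d2 = np.sum((detection.keypoints - annotation.keypoints) ** 2, axis=1)
    kap = np.asarray(cfg.kappas, dtype=float)
    sim = np.exp(-d2 / (2.0 * kap**2 * scale.s2))
    value = float(np.sum(delta * sim) / np.sum(delta))
    return FrameScore(
        frame_id=annotation.frame_id,
        oks=value,
        case=scale.case,
        position=annotation.position.value,
        covering=annotation.covering.value,
        intervention=annotation.intervention,
    )


def score_frames(
    detections: Sequence[Detection],
    annotations: Sequence[TorsoAnnotation],
    cfg: Optional[MetricConfig] = None,
) -> List[FrameScore]:
    """Score matching detection/annotation lists, skipping excluded frames."""
    cfg = cfg or MetricConfig()
    by_id = {d.frame_id: d for d in detections}
    out = []
    for ann in annotations:
        det = by_id.get(ann.frame_id)
        if det is None:
            continue
        scale = compute_scale(ann, cfg)
        if scale.excluded or cfg.delta(ann).sum() < 1:
            continue
        out.append(oks(det, ann, scale, cfg))
    return out


def average_precision(
    frame_scores: Sequence[FrameScore], cfg: Optional[MetricConfig] = None
) -> Dict[str, float]:
    """AP over the OKS threshold ladder (plus AP50/AP75).

    With exactly one detection per frame the COCO matching step is trivial
    and the AP at threshold ``t`` is the fraction of evaluated frames whose
    OKS is at least ``t``.
    """
    cfg = cfg or MetricConfig()
    if len(frame_scores) == 0:
        raise ValueError("average_precision needs at least one scored frame")
    vals = np.array([f.oks for f in frame_scores])
    per_thr = {t: float(np.mean(vals >= t)) for t in cfg.thresholds}
    ap = float(np.mean(list(per_thr.values())))
    return {
        "AP": ap,
        "AP50": per_thr.get(0.5, np.nan),
        "AP75": per_thr.get(0.75, np.nan),
    }


def stratified_report(
    frame_scores: Sequence[FrameScore], cfg: Optional[MetricConfig] = None
) -> pd.DataFrame:
    """Per-stratum OKS/AP summary across position, covering and intervention.

    One row per (stratum kind, stratum value) with the mean OKS, AP, the
    quartiles and the 5th/95th percentiles. Strata with no frames are
    omitted; 'unknown' labels are not reported.
    """
    cfg = cfg or MetricConfig()
    df = pd.DataFrame(
        {
            "oks": [f.oks for f in frame_scores],
            "position": [f.position for f in frame_scores],
            "covering": [f.covering for f in frame_scores],
            "intervention": [
                "unknown" if f.intervention is None
                else ("intervention" if f.intervention else "no_intervention")
                for f in frame_scores
            ],
        }
    )
    rows = []
    for kind in ("position", "covering", "intervention"):
        for value, grp in df.groupby(kind):
            if value == "unknown":
                continue
            sub = [frame_scores[i] for i in grp.index]
            q = np.percentile(grp["oks"], [5, 25, 50, 75, 95])
            rows.append(
                {
                    "stratum": kind,
                    "value": value,
                    "n": len(grp),
                    "mean_oks": float(grp["oks"].mean()),
                    "AP": average_precision(sub, cfg)["AP"],
                    "p5": q[0],
                    "q25": q[1],
                    "median": q[2],
                    "q75": q[3],
                    "p95": q[4],
                }
            )
    return pd.DataFrame(rows)


def compare_groups(
    scores_a: Sequence[float],
    scores_b: Sequence[float],
    method: str = "mannwhitney",
    n_resamples: int = 10_000,
    seed: int = 0,
) -> float:
    """Two-sided p-value for a difference between two OKS score groups.

    ``mannwhitney`` uses the Mann-Whitney U test; ``permutation`` resamples
    the difference in group means with a fixed seed.
    """
    a = np.asarray(list(scores_a), dtype=float)
    b = np.asarray(list(scores_b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if method == "mannwhitney":
        return float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
    if method == "permutation":
        res = stats.permutation_test(
            (a, b),
            lambda x, y: np.mean(x) - np.mean(y),
            permutation_type="independent",
            alternative="two-sided",
            n_resamples=n_resamples,
            rng=np.random.default_rng(seed),
        )
        return float(res.pvalue)
    raise ValueError(f"unknown method {method!r}")


def rescale_rmse(
    errors: np.ndarray,
    source_size: Tuple[int, int],
    reference_size: Tuple[int, int] = (128, 96),
) -> float:
    """Root-mean-square key-point error rescaled to a reference image size.

    ``errors`` is an (n, 2) array of per-key-point (dx, dy) in pixels of a
    ``(W, H)`` source image; dx is scaled by ``128 / W`` and dy by
    ``96 / H`` before the RMS is taken over key-points and frames, making
    errors comparable across datasets with different resolutions.
    """
    err = np.asarray(errors, dtype=float).reshape(-1, 2)
    w, h = source_size
    if w <= 0 or h <= 0:
        raise ValueError("source size must be positive")
    rw, rh = reference_size
    scaled = err * np.array([rw / w, rh / h])
    if scaled.size == 0:
        return 0.0
    return float(np.sqrt(np.mean(np.sum(scaled**2, axis=1))))
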