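"""Core domain types.

A recording session yields time-synchronized triplets of RGB, depth and IR
frames of a single neonate, annotated with the four torso key-points
(left/right shoulder, left/right hip) plus scene labels describing the
clinical context (lying position, level of blanket covering, and whether a
care intervention is in progress).
"""
from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

KEYPOINT_NAMES = ("left_shoulder", "right_shoulder", "left_hip", "right_hip")
NUM_KEYPOINTS = 4

#: 0-based indices of the torso key-points inside the 17-point COCO skeleton.
COCO_TORSO_INDICES = (5, 6, 11, 12)

MODALITIES = ("rgb", "depth", "ir")
#: channel count contributed by each modality when images are stacked
MODALITY_CHANNELS = {"rgb": 3, "depth": 1, "ir": 1}


class Visibility(enum.IntEnum):
    """Per-key-point visibility, numerically equal to the COCO v-flag.

    ``VISIBLE`` covers key-points that are clearly visible *or* under a
    blanket (their position can still be annotated); ``OCCLUDED`` means
    covered by another object such as a nurse's hand.
    """

    NOT_VISIBLE = 0
    OCCLUDED = 1
    VISIBLE = 2


class Position(enum.Enum):
    PRONE = "prone"
    SUPINE = "supine"
    SIDE = "side"
    UNKNOWN = "unknown"


class Covering(enum.Enum):
    NONE = "none"
    HALF = "half"
    THREE_QUARTER = "three_quarter"
    FULL = "full"
    UNKNOWN = "unknown"


@dataclass
class MultimodalFrame:
    """One aligned RGB/depth/IR triplet.

    Images may be held in memory (arrays) or referenced by path; the three
    images always share the same pixel grid (depth/IR are aligned to RGB).
    Depth is in millimetres.
    """

    frame_id: str
    subject_id: str
    timestamp: float
    width: int
    height: int
    rgb: Optional[np.ndarray] = None
    depth: Optional[np.ndarray] = None
    ir: Optional[np.ndarray] = None
    rgb_path: Optional[str] = None
    depth_path: Optional[str] = None
    ir_path: Optional[str] = None

    def validate(self) -> "MultimodalFrame":
        for name in MODALITIES:
            img = getattr(self, name)
            if img is None:
                continue
            if img.shape[:2] != (self.height, self.width):
                raise ValueError(
                    f"{name} image of frame {self.frame_id!r} has shape "
                    f"{img.shape[:2]}, expected {(self.height, self.width)}"
                )
        if self.rgb is not None and (self.rgb.ndim != 3 or self.rgb.shape[2] != 3):
            raise ValueError("rgb must be H x W x 3")
        if self.depth is not None and np.any(np.asarray(self.depth) < 0):
            raise ValueError("depth values must be non-negative (millimetres)")
        return self


@dataclass
class TorsoAnnotation:
    """Ground-truth torso key-points plus scene labels for one frame."""

    frame_id: str
    keypoints: np.ndarray  # (4, 2) float, pixel coordinates (x right, y down)
    visibility: tuple  # 4 x Visibility
    position: Position = Position.UNKNOWN
    covering: Covering = Covering.UNKNOWN
    intervention: Optional[bool] = None

    def __post_init__(self):
        self.keypoints = np.asarray(self.keypoints, dtype=float).reshape(
            NUM_KEYPOINTS, 2
        )
        self.visibility = tuple(Visibility(v) for v in self.visibility)
        if len(self.visibility) != NUM_KEYPOINTS:
            raise ValueError("need exactly four visibility flags")

    def validate(self, width: Optional[int] = None, height: Optional[int] = None):
        if width is not None and height is not None:
            for (x, y), v in zip(self.keypoints, self.visibility):
                if v != Visibility.NOT_VISIBLE and not (
                    0 <= x < width and 0 <= y < height
                ):
                    raise ValueError(
                        f"key-point ({x}, {y}) of frame {self.frame_id!r} lies "
                        f"outside the {width}x{height} image"
                    )
        return self


@dataclass
class Detection:
    """Predicted key-points with per-key-point confidences for one frame.

    There is exactly one detection per frame (one infant per incubator), so
    detection identity coincides with frame identity.
    """

    frame_id: str
    keypoints: np.ndarray  # (4, 2) float pixels
    scores: np.ndarray  # (4,) float in [0, 1]

    def __post_init__(self):
        self.keypoints = np.asarray(self.keypoints, dtype=float).reshape(
            NUM_KEYPOINTS, 2
        )
        self.scores = np.asarray(self.scores, dtype=float).reshape(NUM_KEYPOINTS)


@dataclass
class DatasetRecord:
    """One (frame, annotation) pair as stored on disk."""

    frame: MultimodalFrame
    annotation: TorsoAnnotation

    def __iter__(self):
        return iter((self.frame, self.annotation))
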