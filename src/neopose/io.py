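"""COCO-keypoint JSON reading/writing with scene-label extensions.

The on-disk format is a standard COCO key-point file (``images``,
``annotations``, ``categories``) whose single category declares the four
torso key-points. Scene labels (``position``, ``covering``,
``intervention``) are stored as extra keys on each annotation object so the
files stay readable by stock COCO tooling; absent labels read back as
*unknown*. Image files are referenced by path and are not loaded by
:func:`read_dataset`; use :func:`load_images` when pixel data is needed.
"""
from __future__ import annotations

import json
import os
from typing import Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd
from PIL import Image

from .types import (
    COCO_TORSO_INDICES,
    KEYPOINT_NAMES,
    NUM_KEYPOINTS,
    Covering,
    DatasetRecord,
    MultimodalFrame,
    Position,
    TorsoAnnotation,
    Visibility,
)


class DatasetFormatError(ValueError):
    """Raised when a dataset file violates the expected COCO structure."""


def _category() -> dict:
    return {
        "id": 1,
        "name": "neonate",
        "supercategory": "person",
        "keypoints": list(KEYPOINT_NAMES),
        "skeleton": [[1, 2], [1, 3], [2, 4], [3, 4]],
    }


def read_dataset(path: str) -> List[DatasetRecord]:
    """Read a COCO key-point JSON file with scene-label extensions.

    Returns one :class:`DatasetRecord` per image; exactly one annotation per
    image is required (one infant per frame). Image pixels are *not*
    loaded — the frame carries file paths relative to the JSON's directory.
    """
    try:
        with open(path) as fh:
            data = json.load(fh)
    except json.JSONDecodeError as exc:
        raise DatasetFormatError(f"malformed JSON in {path}: {exc}") from exc

    for section in ("images", "annotations", "categories"):
        if section not in data:
            raise DatasetFormatError(f"missing required section {section!r}")
    cats = data["categories"]
    if len(cats) != 1 or len(cats[0].get("keypoints", [])) != NUM_KEYPOINTS:
        raise DatasetFormatError(
            "categories must declare exactly one category with "
            f"{NUM_KEYPOINTS} key-points"
        )

    base = os.path.dirname(os.path.abspath(path))

    def _resolve(p):
        return None if p is None else os.path.join(base, p)

    frames = {}
    for im in data["images"]:
        frames[im["id"]] = MultimodalFrame(
            frame_id=str(im["id"]),
            subject_id=str(im.get("subject_id", "unknown")),
            timestamp=float(im.get("timestamp", 0.0)),
            width=int(im["width"]),
            height=int(im["height"]),
            rgb_path=_resolve(im.get("file_name")),
            depth_path=_resolve(im.get("depth_file_name")),
            ir_path=_resolve(im.get("ir_file_name")),
        )

    seen = set()
    records = []
    for ann in data["annotations"]:
        img_id = ann["image_id"]
        if img_id not in frames:
            raise DatasetFormatError(
                f"annotation {ann.get('id')} refers to unknown image {img_id}"
            )
        if img_id in seen:
            raise DatasetFormatError(
                f"image {img_id} has more than one annotation; the dataset "
                "must contain exactly one infant per frame"
            )
        seen.add(img_id)
        kps = np.asarray(ann["keypoints"], dtype=float).reshape(NUM_KEYPOINTS, 3)
        annotation = TorsoAnnotation(
            frame_id=str(img_id),
            keypoints=kps[:, :2],
            visibility=tuple(Visibility(int(v)) for v in kps[:, 2]),
            position=Position(ann.get("position", "unknown")),
            covering=Covering(ann.get("covering", "unknown")),
            intervention=ann.get("intervention", None),
        )
        records.append(DatasetRecord(frames[img_id], annotation))

    missing = set(frames) - seen
    if missing:
        raise DatasetFormatError(f"images without annotations: {sorted(missing)}")
    records.sort(key=lambda r: r.frame.frame_id)
    return records


def write_dataset(records: Sequence[DatasetRecord], path: str) -> None:
    """Write records as COCO key-point JSON (deterministic byte output).

    Visibility is encoded with the COCO v-flag convention (0 = not visible,
    1 = occluded, 2 = visible); coordinates of not-visible key-points are
    preserved verbatim.
    """
    base = os.path.dirname(os.path.abspath(path))

    def _relative(p):
        if p is None:
            return None
        try:
            return os.path.relpath(p, base)
        except ValueError:
            return p

    images, annotations = [], []
    for i, rec in enumerate(records):
        frame, ann = rec.frame, rec.annotation
        frame.validate()
        ann.validate(frame.width, frame.height)
        img = {
            "id": frame.frame_id,
            "width": frame.width,
            "height": frame.height,
            "subject_id": frame.subject_id,
            "timestamp": frame.timestamp,
        }
        for key, p in (
            ("file_name", frame.rgb_path),
            ("depth_file_name", frame.depth_path),
            ("ir_file_name", frame.ir_path),
        ):
            rel = _relative(p)
            if rel is not None:
                img[key] = rel
        images.append(img)
        kps = []
        for (x, y), v in zip(ann.keypoints, ann.visibility):
            kps.extend([float(x), float(y), int(v)])
        entry = {
            "id": i + 1,
            "image_id": frame.frame_id,
            "category_id": 1,
            "keypoints": kps,
            "num_keypoints": sum(1 for v in ann.visibility if v > 0),
            "iscrowd": 0,
            "position": ann.position.value,
            "covering": ann.covering.value,
        }
        if ann.intervention is not None:
            entry["intervention"] = bool(ann.intervention)
        annotations.append(entry)

    data = {"images": images, "annotations": annotations, "categories": [_category()]}
    with open(path, "w") as fh:
        json.dump(data, fh, indent=1, sort_keys=True)


def subset_to_torso(keypoints, frame_id: str = "", **scene_labels) -> TorsoAnnotation:
    """Reduce a full-skeleton COCO annotation to the four torso key-points.

    ``keypoints`` is the flat COCO triplet list (or an (N, 3) array) of a
    skeleton in COCO order with at least 13 key-points; the retained entries
    are indices 5, 6, 11 and 12 (left/right shoulder, left/right hip), with
    visibility flags carried over.
    """
    kps = np.asarray(keypoints, dtype=float).reshape(-1, 3)
    if kps.shape[0] <= max(COCO_TORSO_INDICES):
        raise ValueError(
            f"need at least {max(COCO_TORSO_INDICES) + 1} key-points in COCO "
            f"order, got {kps.shape[0]}"
        )
    sel = kps[list(COCO_TORSO_INDICES)]
    return TorsoAnnotation(
        frame_id=frame_id,
        keypoints=sel[:, :2],
        visibility=tuple(Visibility(int(v)) for v in sel[:, 2]),
        **scene_labels,
    )


def expand_from_torso(ann: TorsoAnnotation, n: int = 17) -> np.ndarray:
    """Place a torso annotation back into an ``n``-slot COCO skeleton."""
    out = np.zeros((n, 3), dtype=float)
    for row, idx in enumerate(COCO_TORSO_INDICES):
        out[idx, :2] = ann.keypoints[row]
        out[idx, 2] = int(ann.visibility[row])
    return out


def composition_report(annotations: Iterable[TorsoAnnotation]) -> pd.DataFrame:
    """Tabulate percentage of frames per (position x covering) stratum.

    Intervention frames form their own stratum (row ``intervention``), as in
    clinical-scene composition summaries; frames whose position *and*
    covering are both unknown (and that are not interventions) are excluded
    from the denominator. All cells sum to 100.
    """
    annotations = list(annotations)
    rows = []
    for ann in annotations:
        if ann.intervention:
            rows.append(("intervention", "intervention"))
        elif (
            ann.position is not Position.UNKNOWN
            or ann.covering is not Covering.UNKNOWN
        ):
            rows.append((ann.position.value, ann.covering.value))
    if not rows:
        raise ValueError(
            "composition_report: no annotations with known scene labels"
        )
    df = pd.DataFrame(rows, columns=["position", "covering"])
    table = (
        df.value_counts(["position", "covering"]).unstack(fill_value=0).astype(float)
    )
    table = table / len(rows) * 100.0
    table.index.name = "position"
    return table


# --------------------------------------------------------------------------
# image I/O helpers

def _read_image(path: str) -> np.ndarray:
    with Image.open(path) as im:
        arr = np.asarray(im)
    return arr


def load_images(frame: MultimodalFrame) -> MultimodalFrame:
    """Load the referenced RGB/depth/IR files into the frame (in place)."""
    if frame.rgb is None and frame.rgb_path:
        frame.rgb = _read_image(frame.rgb_path)
    if frame.depth is None and frame.depth_path:
        frame.depth = _read_image(frame.depth_path).astype(np.uint16)
    if frame.ir is None and frame.ir_path:
        frame.ir = _read_image(frame.ir_path).astype(np.uint16)
    return frame.validate()


def save_image(path: str, array: np.ndarray) -> None:
    """Write 8-bit RGB or 16-bit single-channel PNG (depth in mm, IR counts)."""
    arr = np.asarray(array)
    if arr.ndim == 3:
        Image.fromarray(arr.astype(np.uint8), mode="RGB").save(path)
    else:
        Image.fromarray(arr.astype(np.uint16)).save(path)
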