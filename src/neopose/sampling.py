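"""Activity-driven annotation frame selection.

Long recordings contain stretches where the infant barely moves;
annotating uniformly in time would oversample those. Instead, each
fifteen-minute window is summarized by a depth-activity trace (mean
absolute difference between consecutive depth frames) and a fixed number
of frames per window is picked evenly spaced in *cumulative* activity, so
that busy spans contribute proportionally more annotation frames.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence

import numpy as np


@dataclass
class ActivityTrace:
    """Per-frame activity within one window.

    ``activity[t]`` is the mean absolute depth difference (mm) between
    frames ``t`` and ``t - 1`` (0 for the first frame); ``cumulative`` is
    its running sum.
    """

    window_id: str
    frame_indices: np.ndarray
    activity: np.ndarray
    cumulative: np.ndarray

    def __post_init__(self):
        self.frame_indices = np.asarray(self.frame_indices)
        self.activity = np.asarray(self.activity, dtype=float)
        self.cumulative = np.asarray(self.cumulative, dtype=float)
        if np.any(np.diff(self.cumulative) < 0):
            raise ValueError("cumulative activity must be non-decreasing")


def depth_activity(
    depth_frames: Sequence[np.ndarray],
    window_id: str = "",
    stride: int = 1,
    invalid_value: int = 0,
) -> ActivityTrace:
    """Mean absolute inter-frame depth difference per frame.

    Pixels at ``invalid_value`` (time-of-flight dropout) in either frame of
    a pair are excluded from the mean; a pair with no valid pixels scores 0.
    ``stride`` optionally subsamples the sequence in time before
    differencing.
    """
    frames = list(depth_frames)[:: max(1, int(stride))]
    if len(frames) < 2:
        raise ValueError("need at least two depth frames")
    shape = np.asarray(frames[0]).shape
    act = [0.0]
    prev = np.asarray(frames[0], dtype=float)
    for arr in frames[1:]:
        cur = np.asarray(arr, dtype=float)
        if cur.shape != shape:
            raise ValueError(
                f"depth frame shape {cur.shape} does not match {shape}"
            )
        valid = (prev != invalid_value) & (cur != invalid_value)
        act.append(float(np.abs(cur - prev)[valid].mean()) if valid.any() else 0.0)
        prev = cur
    activity = np.asarray(act)
    return ActivityTrace(
        window_id=window_id,
        frame_indices=np.arange(len(frames)) * max(1, int(stride)),
        activity=activity,
        cumulative=np.cumsum(activity),
    )


def select_frames(trace: ActivityTrace, n: int = 30) -> np.ndarray:
    """Select ``n`` frame indices evenly spaced in cumulative activity.

    Targets sit at ``k * total / n`` for ``k = 1..n``; each target is
    matched to the first frame whose cumulative activity reaches it, and a
    frame already taken advances to the next unused frame so the result is
    strictly increasing. A window with zero total activity falls back to
    indices evenly spaced in time.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    m = len(trace.cumulative)
    if m == 0:
        raise ValueError("empty trace")
    if n > m:
        raise ValueError(f"cannot select {n} frames from a {m}-frame window")
    total = trace.cumulative[-1]
    if total <= 0:
        pos = np.round(np.linspace(0, m - 1, n)).astype(int)
    else:
        pos = []
        used = -1
        eps = 1e-9 * total  # tolerance so pure rescaling cannot flip a tie
        for k in range(1, n + 1):
            target = k * total / n
            j = int(np.searchsorted(trace.cumulative, target - eps, side="left"))
            j = min(j, m - 1)
            j = max(j, used + 1)  # duplicates advance to the next unused frame
            pos.append(j)
            used = j
        pos = np.asarray(pos)
        # if advancing ran off the end, pull back from the tail
        overflow = pos > m - 1
        if overflow.any():
            pos = np.minimum(pos, m - 1)
    pos = _make_strictly_increasing(pos, m)
    return np.asarray(trace.frame_indices)[pos]


def _make_strictly_increasing(pos: np.ndarray, m: int) -> np.ndarray:
    """Resolve duplicate selections deterministically (forward, then back)."""
    out = list(pos)
    for i in range(1, len(out)):
        if out[i] <= out[i - 1]:
            out[i] = out[i - 1] + 1
    # ran past the end: shift the tail back while keeping strict monotonicity
    for i in range(len(out) - 1, -1, -1):
        cap = m - (len(out) - i)
        if out[i] > cap:
            out[i] = cap
    if out and (out[0] < 0 or out[-1] > m - 1):
        raise ValueError("cannot produce a strictly increasing selection")
    return np.asarray(out, dtype=int)


def select_from_recording(
    depth_frames: Sequence[np.ndarray],
    fps: float = 30.0,
    window_minutes: float = 15.0,
    per_window: int = 30,
    stride: int = 1,
) -> List[np.ndarray]:
    """Split a recording into fixed windows and select frames per window."""
    frames = list(depth_frames)
    per = int(round(window_minutes * 60.0 * fps))
    out = []
    for w0 in range(0, len(frames), per):
        chunk = frames[w0 : w0 + per]
        if len(chunk) < 2:
            continue
        trace = depth_activity(chunk, window_id=str(w0 // per), stride=stride)
        out.append(select_frames(trace, min(per_window, len(trace.cumulative))) + w0)
    return out
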