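import numpy as np
import pytest

from neopose.scenes import generate_samples
from neopose.types import (
    Covering,
    DatasetRecord,
    MultimodalFrame,
    Position,
    TorsoAnnotation,
    Visibility,
)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_record(i, subject="s0", position=Position.SUPINE,
                covering=Covering.NONE, intervention=False, size=64):
    rng = np.random.default_rng(100 + i)
    kps = rng.uniform(10, size - 10, (4, 2))
    frame = MultimodalFrame(
        frame_id=f"f{i:03d}", subject_id=subject, timestamp=float(i),
        width=size, height=size,
    )
    ann = TorsoAnnotation(
        frame_id=f"f{i:03d}", keypoints=kps,
        visibility=(Visibility.VISIBLE,) * 4,
        position=position, covering=covering, intervention=intervention,
    )
    return DatasetRecord(frame, ann)


@pytest.fixture
def records():
    return [make_record(i) for i in range(4)]


@pytest.fixture(scope="session")
def scene_bank():
    """Small shared bank of synthetic scenes (3 subjects x 8 frames)."""
    return generate_samples(3, 8, seed=42)
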