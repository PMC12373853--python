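"""Synthetic NICU scene generator.

Produces aligned RGB/depth/IR triplets of a procedurally rendered infant
with exactly known torso key-points, spanning the clinical scene taxonomy
(prone/supine/side position, four blanket-covering levels, optional
care-intervention occluders, lighting from covered-incubator darkness to
bright daylight). Rendering is deliberately 2-D compositing — ellipsoidal
body parts, smooth-noise textures — which is enough to exercise fusion,
training and evaluation logic deterministically at desk scale.

Modality physics emulated:

* **depth** (millimetres): a mattress plane around 400 mm from the camera
  with a smooth raised body region (30-80 mm relief). A blanket drapes
  over the body — it smooths but does not erase the body bump.
* **RGB** (8-bit): reflectance of mattress/skin/blanket multiplied by the
  scene lighting, plus sensor noise; at lighting 0 only the noise floor
  remains.
* **IR** (16-bit counts): the camera's own active illumination, so the
  image shares the RGB scene structure but is invariant to the lighting
  parameter.
"""
from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

from .io import DatasetRecord, save_image, write_dataset
from .types import (
    Covering,
    MultimodalFrame,
    Position,
    TorsoAnnotation,
    Visibility,
)

MATTRESS_MM = 400.0

#: fraction of the body (measured along the body axis, feet upward) hidden
#: under the blanket at each covering level
COVER_FRACTION = {
    Covering.NONE: 0.0,
    Covering.HALF: 0.5,
    Covering.THREE_QUARTER: 0.75,
    Covering.FULL: 0.97,
}


@dataclass
class SceneConfig:
    """Parameters of one synthetic scene. Identical configs (including the
    seed) render identical output."""

    position: Position = Position.SUPINE
    covering: Covering = Covering.NONE
    intervention: bool = False
    lighting: float = 1.0  # 0 = covered incubator darkness, 1 = bright
    image_size: int = 64  # square frame, pixels
    body_scale: float = 20.0  # torso length (shoulder-to-hip), pixels
    pose_jitter: float = 0.15  # spread of key-point placement, dimensionless
    rgb_noise: float = 6.0  # additive Gaussian sigma, 8-bit counts
    ir_noise: float = 12.0  # additive Gaussian sigma, 16-bit counts
    #: probability of specular glare patches from the active IR emitter
    #: reflecting off the incubator perspex
    ir_glare_prob: float = 0.3
    depth_noise: float = 8.0  # per-pixel time-of-flight noise sigma, mm
    depth_dropout: float = 0.01  # speckle dropout probability per pixel
    #: probability that a frame suffers large invalid-depth patches
    #: (reflections off the incubator wall, motion artefacts)
    depth_fail_prob: float = 0.25
    relief_mm: float = 55.0  # body elevation above the mattress
    skin_tone: float = 0.75  # skin reflectance in [0, 1]
    seed: int = 0

    def validate(self) -> "SceneConfig":
        if not 0.0 <= self.lighting <= 1.0:
            raise ValueError("lighting must lie in [0, 1]")
        if not 30.0 <= self.relief_mm <= 80.0:
            raise ValueError("body relief must lie in [30, 80] mm")
        # torso plus head and jitter must fit inside the frame
        if self.body_scale * 2.75 > self.image_size:
            raise ValueError(
                f"body scale {self.body_scale} px does not fit a "
                f"{self.image_size} px frame"
            )
        return self


@dataclass
class SceneSample:
    frame: MultimodalFrame
    annotation: TorsoAnnotation
    body_mask: np.ndarray
    blanket_mask: np.ndarray
    occluder_mask: np.ndarray


def _smooth_noise(rng, shape, sigma, amplitude=1.0):
    return gaussian_filter(rng.standard_normal(shape), sigma) * amplitude


def _ellipse_mask(xx, yy, center, axis_u, semi_len, semi_wid):
    dx, dy = xx - center[0], yy - center[1]
    t = dx * axis_u[0] + dy * axis_u[1]
    s = -dx * axis_u[1] + dy * axis_u[0]
    return (t / semi_len) ** 2 + (s / semi_wid) ** 2 <= 1.0


def generate_scene(config: SceneConfig) -> SceneSample:
    """Render one scene triplet with ground-truth key-points and masks."""
    config.validate()
    n = config.image_size
    rng_layout = np.random.default_rng([config.seed, 1])
    rng_rgb = np.random.default_rng([config.seed, 2])
    rng_ir = np.random.default_rng([config.seed, 3])
    rng_depth = np.random.default_rng([config.seed, 4])

    yy, xx = np.mgrid[0:n, 0:n].astype(float)

    # ---- body geometry -----------------------------------------------------
    # the cot constrains the infant roughly along the mattress axis; the
    # head end is larger and more elevated than the legs, which is what
    # lets a detector tell shoulders from hips
    L = config.body_scale  # shoulder-to-hip distance
    center = np.array([n / 2.0, n / 2.0]) + rng_layout.uniform(-3, 3, 2)
    theta = rng_layout.uniform(-0.35, 0.35)
    u = np.array([np.cos(theta), np.sin(theta)])  # body axis, feet -> head
    v = np.array([-u[1], u[0]])  # lateral

    lateral = 1.0
    if config.position is Position.SIDE:
        lateral = 0.38  # projected hip-shoulder separation compresses
    shoulder_w = 0.62 * L * lateral
    hip_w = 0.52 * L * lateral

    jit = config.pose_jitter * L
    kp = np.empty((4, 2))
    kp[0] = center + u * (L / 2) + v * (shoulder_w / 2)  # left shoulder
    kp[1] = center + u * (L / 2) - v * (shoulder_w / 2)  # right shoulder
    kp[2] = center - u * (L / 2) + v * (hip_w / 2)  # left hip
    kp[3] = center - u * (L / 2) - v * (hip_w / 2)  # right hip
    kp += rng_layout.normal(0.0, 0.18 * jit, size=(4, 2))

    torso = _ellipse_mask(xx, yy, center, u, 0.72 * L, 0.48 * L * max(lateral, 0.55))
    head = _ellipse_mask(
        xx, yy, center + u * (0.95 * L), u, 0.45 * L, 0.42 * L
    )
    legs = _ellipse_mask(
        xx, yy, center - u * (0.85 * L), u, 0.40 * L, 0.24 * L * max(lateral, 0.55)
    )
    body = torso | head | legs
    # key-points must lie on the body mask: widen the torso locally if jitter
    # pushed one off (rare at default jitter)
    for x, y in kp:
        xi, yi = int(round(x)), int(round(y))
        body[max(0, yi - 1) : yi + 2, max(0, xi - 1) : xi + 2] = True

    # ---- blanket ------------------------------------------------------------
    # the edge is ragged and the coverage jittered per frame (a real blanket
    # is not tucked at an exact body fraction); both perturbations are drawn
    # unconditionally so covering levels of one seed stay nested
    frac = COVER_FRACTION[config.covering]
    edge_jitter = float(rng_layout.normal(0.0, 0.03))
    edge_wave = _smooth_noise(rng_layout, (n, n), 5.0, 0.2 * L)
    # how much the blanket flattens the body relief varies with its weight
    drape_scale = float(rng_layout.uniform(0.55, 0.8))
    blanket = np.zeros((n, n), dtype=bool)
    if frac > 0:
        t_axis = (xx - center[0]) * u[0] + (yy - center[1]) * u[1]
        body_t = t_axis[body]
        frac_eff = float(np.clip(frac + edge_jitter, 0.05, 0.99))
        tau = np.quantile(body_t, frac_eff)
        blanket = t_axis + edge_wave <= tau

    # ---- intervention occluders --------------------------------------------
    occluder = np.zeros((n, n), dtype=bool)
    if config.intervention:
        n_occ = 1 + int(rng_layout.uniform() < 0.4)
        body_px = np.argwhere(body)
        for _ in range(n_occ):
            cy, cx = body_px[rng_layout.integers(len(body_px))]
            ang = rng_layout.uniform(0, 2 * np.pi)
            hand_u = np.array([np.cos(ang), np.sin(ang)])
            occluder |= _ellipse_mask(
                xx, yy, np.array([cx, cy], dtype=float), hand_u, 0.34 * L, 0.20 * L
            )

    # ---- depth --------------------------------------------------------------
    mattress = MATTRESS_MM + _smooth_noise(rng_depth, (n, n), 6.0, 1.5)
    relief = body.astype(float)
    relief[head] = 1.35  # the head rises furthest from the mattress
    elevation = gaussian_filter(relief, 1.8) * config.relief_mm
    if frac > 0:
        # the blanket drapes over the union of body and mattress: smoother
        # and flatter, but the body bump persists underneath
        drape = gaussian_filter(elevation, 5.0) * drape_scale + 6.0
        elevation = np.where(blanket, np.maximum(drape, 0.55 * elevation),
                             elevation)
    if config.intervention:
        elevation = np.where(occluder, elevation + 40.0, elevation)
    depth = mattress - elevation
    depth += rng_depth.normal(0.0, config.depth_noise, size=(n, n))
    dropout = rng_depth.uniform(size=(n, n)) < config.depth_dropout
    depth[dropout] = 0.0
    if rng_depth.uniform() < config.depth_fail_prob:
        # large invalid patches over the scene (specular reflection / motion)
        body_px = np.argwhere(body)
        for _ in range(int(rng_depth.integers(3, 7))):
            cy, cx = body_px[rng_depth.integers(len(body_px))]
            ang = rng_depth.uniform(0, 2 * np.pi)
            patch_u = np.array([np.cos(ang), np.sin(ang)])
            patch = _ellipse_mask(
                xx, yy, np.array([cx, cy], dtype=float), patch_u,
                rng_depth.uniform(0.35, 0.6) * L, rng_depth.uniform(0.25, 0.45) * L,
            )
            depth[patch] = 0.0
    depth = np.clip(depth, 0, 65535).astype(np.uint16)

    # ---- reflectance composite (shared RGB/IR structure) --------------------
    reflect = 0.22 + _smooth_noise(rng_rgb, (n, n), 4.0, 0.03)  # mattress
    skin = config.skin_tone + _smooth_noise(rng_rgb, (n, n), 2.0, 0.05)
    reflect = np.where(body, skin, reflect)
    if frac > 0:
        stripes = 0.55 + 0.18 * np.sin(
            2 * np.pi * (xx * 0.11 + yy * 0.07) + config.seed % 7
        )
        # drape shading: the blanket brightens faintly where it rides over
        # the body
        shade = 0.9 + 0.15 * elevation / max(float(elevation.max()), 1.0)
        reflect = np.where(blanket, stripes * shade, reflect)
    if config.intervention:
        reflect = np.where(occluder, 0.9, reflect)
    reflect = np.clip(reflect, 0.0, 1.0)

    illum = 0.03 + 0.97 * config.lighting
    rgb = np.empty((n, n, 3))
    tint = np.array([1.0, 0.86, 0.78])  # warm skin tint
    for c in range(3):
        rgb[..., c] = reflect * tint[c] * illum * 255.0
    rgb += rng_rgb.normal(0.0, config.rgb_noise, size=rgb.shape)
    rgb = np.clip(rgb, 0, 255).astype(np.uint8)

    # IR: active illumination from the camera, independent of scene lighting,
    # with radial emitter falloff and occasional specular glare
    rr = ((xx - n / 2) ** 2 + (yy - n / 2) ** 2) / (n / 2) ** 2
    ir = (reflect * 900.0 + 60.0) * (1.0 - 0.35 * rr)
    if rng_ir.uniform() < config.ir_glare_prob:
        body_px = np.argwhere(body)
        for _ in range(int(rng_ir.integers(1, 4))):
            cy, cx = body_px[rng_ir.integers(len(body_px))]
            ang = rng_ir.uniform(0, 2 * np.pi)
            g_u = np.array([np.cos(ang), np.sin(ang)])
            glare = _ellipse_mask(
                xx, yy, np.array([cx, cy], dtype=float), g_u,
                rng_ir.uniform(0.3, 0.55) * L, rng_ir.uniform(0.2, 0.4) * L,
            )
            ir[glare] = 1000.0
    ir += rng_ir.normal(0.0, config.ir_noise, size=ir.shape)
    ir = np.clip(ir, 0, 65535).astype(np.uint16)

    # ---- visibility ---------------------------------------------------------
    vis = []
    for x, y in kp:
        xi = int(np.clip(round(x), 0, n - 1))
        yi = int(np.clip(round(y), 0, n - 1))
        vis.append(
            Visibility.OCCLUDED if occluder[yi, xi] else Visibility.VISIBLE
        )

    frame = MultimodalFrame(
        frame_id="scene",
        subject_id="synthetic",
        timestamp=0.0,
        width=n,
        height=n,
        rgb=rgb,
        depth=depth,
        ir=ir,
    ).validate()
    annotation = TorsoAnnotation(
        frame_id="scene",
        keypoints=np.clip(kp, 0, n - 1),
        visibility=tuple(vis),
        position=config.position,
        covering=config.covering,
        intervention=config.intervention,
    )
    return SceneSample(frame, annotation, body, blanket, occluder)


# ---------------------------------------------------------------------------
# dataset-level generation

@dataclass
class ScenarioMix:
    """Sampling distribution over scene strata.

    The defaults follow the qualitative composition of a 24-hour NICU
    recording: lying on the side is the most common position, roughly half
    of the time the infant is at least three-quarters covered, and care
    interventions occupy a modest fraction of frames. Lighting is drawn
    uniformly between near-darkness and bright.
    """

    position_probs: Dict[Position, float] = field(
        default_factory=lambda: {
            Position.SIDE: 0.44,
            Position.SUPINE: 0.31,
            Position.PRONE: 0.25,
        }
    )
    covering_probs: Dict[Covering, float] = field(
        default_factory=lambda: {
            Covering.NONE: 0.20,
            Covering.HALF: 0.28,
            Covering.THREE_QUARTER: 0.28,
            Covering.FULL: 0.24,
        }
    )
    intervention_prob: float = 0.12
    lighting_range: tuple = (0.02, 1.0)

    def draw(self, rng: np.random.Generator, base: SceneConfig) -> SceneConfig:
        positions, p_pos = zip(*self.position_probs.items())
        coverings, p_cov = zip(*self.covering_probs.items())
        return replace(
            base,
            position=positions[rng.choice(len(positions), p=np.asarray(p_pos))],
            covering=coverings[rng.choice(len(coverings), p=np.asarray(p_cov))],
            intervention=bool(rng.uniform() < self.intervention_prob),
            lighting=float(rng.uniform(*self.lighting_range)),
        )


def _subject_base(rng: np.random.Generator, template: SceneConfig) -> SceneConfig:
    """Subject-specific appearance so subject-wise folds are meaningful."""
    return replace(
        template,
        body_scale=float(template.body_scale * rng.uniform(0.85, 1.15)),
        relief_mm=float(rng.uniform(35.0, 75.0)),
        skin_tone=float(rng.uniform(0.6, 0.9)),
    )


def generate_samples(
    n_subjects: int,
    frames_per_subject: int,
    mix: Optional[ScenarioMix] = None,
    seed: int = 0,
    template: Optional[SceneConfig] = None,
) -> List[SceneSample]:
    """Generate an in-memory dataset of scene samples.

    Subjects receive disjoint appearance parameters (body scale, relief,
    skin tone); each frame draws its scenario from ``mix``.
    """
    if n_subjects < 1:
        raise ValueError("need at least one subject")
    if frames_per_subject < 1:
        raise ValueError("need at least one frame per subject")
    mix = mix or ScenarioMix()
    template = template or SceneConfig()
    samples = []
    for s in range(n_subjects):
        rng = np.random.default_rng([seed, 100 + s])
        base = _subject_base(rng, template)
        for f in range(frames_per_subject):
            cfg = mix.draw(rng, base)
            cfg = replace(cfg, seed=int(rng.integers(2**31 - 1)))
            sample = generate_scene(cfg)
            sample.frame.frame_id = f"s{s:03d}_f{f:04d}"
            sample.frame.subject_id = f"s{s:03d}"
            sample.frame.timestamp = 30.0 * f
            sample.annotation.frame_id = sample.frame.frame_id
            samples.append(sample)
    return samples


def generate_dataset(
    n_subjects: int,
    frames_per_subject: int,
    out_dir: str,
    mix: Optional[ScenarioMix] = None,
    seed: int = 0,
    template: Optional[SceneConfig] = None,
) -> str:
    """Write a synthetic dataset (PNG images + COCO JSON) to ``out_dir``.

    Returns the path of the annotation JSON; the output is readable by
    :func:`neopose.io.read_dataset`.
    """
    samples = generate_samples(n_subjects, frames_per_subject, mix, seed, template)
    img_dir = os.path.join(out_dir, "images")
    os.makedirs(img_dir, exist_ok=True)
    records = []
    for sample in samples:
        frame = sample.frame
        fid = frame.frame_id
        frame.rgb_path = os.path.join(img_dir, f"{fid}_rgb.png")
        frame.depth_path = os.path.join(img_dir, f"{fid}_depth.png")
        frame.ir_path = os.path.join(img_dir, f"{fid}_ir.png")
        save_image(frame.rgb_path, frame.rgb)
        save_image(frame.depth_path, frame.depth)
        save_image(frame.ir_path, frame.ir)
        records.append(DatasetRecord(frame, sample.annotation))
    json_path = os.path.join(out_dir, "annotations.json")
    write_dataset(records, json_path)
    return json_path
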