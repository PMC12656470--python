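"""Ground-truthed synthetic visible/infrared-like image pairs.

The generator emulates the acquisition regime of a co-mounted visible +
thermal camera (FLIR C2 class): a 640x480 visible frame and an 80x60 infrared
frame of the same scene.  The scene is a set of smooth closed "body"
silhouettes (Fourier-perturbed ellipses with at least four curvature maxima)
on a weakly textured background.  The infrared rendering differs from the
visible one by

* a planted similarity transform (scale, rotation, translation) on top of the
  8x resolution ratio,
* a reversed monotone nonlinear intensity map (hot-on-cold vs dark-on-light),
* heavy blur followed by downsampling to the infrared grid, and
* independent sensor noise,

while the visible rendering passes through one of four illumination schedules
(#1 darkest ... #4 brightest, the bright end pushed toward saturation).  All
randomness flows from the single spec seed.  Ground truth carries the exact
composite coordinate map and control points on the silhouette outlines, so
every pipeline stage and metric can be scored without real data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.draw import polygon
from skimage.transform import SimilarityTransform, warp

from .exceptions import ParameterError
from .matching import Transform

__all__ = ["ScenePairSpec", "GroundTruth", "generate_pair", "illumination_schedule"]


@dataclass
class ScenePairSpec:
    seed: int = 0
    scene_size: tuple = (640, 480)  # visible (width, height)
    ir_size: tuple = (80, 60)       # infrared (width, height)
    # similarity between frames beyond the resolution ratio
    planted_scale: float = 1.05
    planted_rotation: float = 0.04  # radians
    planted_translation: tuple = (6.0, -4.0)  # px, visible frame
    illumination_level: int = 2
    blob_count: int = 3
    texture_amp: float = 0.06
    noise_sigma: float = 0.01
    ir_blur_sigma: float = 4.0      # px in the visible frame before downsampling
    reverse_intensity: bool = True
    n_control_points: int = 40

    def validate(self) -> "ScenePairSpec":
        if min(self.scene_size) <= 0 or min(self.ir_size) <= 0:
            raise ParameterError("frame sizes must be positive")
        if self.planted_scale <= 0:
            raise ParameterError("planted scale must be > 0")
        if self.illumination_level not in (1, 2, 3, 4):
            raise ParameterError("illumination level must be in {1, 2, 3, 4}")
        if self.blob_count < 1:
            raise ParameterError("blob_count must be >= 1")
        return self


@dataclass
class GroundTruth:
    """Exact geometry of the generated pair.

    transform maps native-IR coordinates into the visible frame (composite:
    resolution ratio then planted similarity).  control_points is (n, 4):
    columns (ir_x, ir_y, vis_x, vis_y).  keypoint_truth holds the true
    curvature-maximum locations of the silhouettes in the visible frame.
    """

    transform: Transform
    control_points: np.ndarray
    keypoint_truth: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))

    def map_ir_to_vis(self, points) -> np.ndarray:
        return self.transform.apply(points)


def illumination_schedule(level: int) -> dict:
    """Map an illumination group (#1 darkest ... #4 brightest) to a
    (gain, offset, gamma) photometric schedule; #4 uses gamma < 1 so bright
    regions push into saturation."""
    table = {
        1: {"gain": 0.45, "offset": 0.02, "gamma": 1.40},
        2: {"gain": 0.70, "offset": 0.05, "gamma": 1.10},
        3: {"gain": 1.00, "offset": 0.00, "gamma": 1.00},  # identity (reference level)
        4: {"gain": 1.25, "offset": 0.18, "gamma": 0.55},
    }
    if level not in table:
        raise ParameterError(f"illumination level must be in 1..4, got {level}")
    return table[level]


def _blob_outline(rng: np.random.Generator, center, base_radius, n_theta=720):
    """Closed Fourier-perturbed ellipse outline; returns (points, curvature)."""
    theta = np.linspace(0.0, 2.0 * math.pi, n_theta, endpoint=False)
    aspect = rng.uniform(0.65, 0.95)
    r = np.ones_like(theta)
    for m in rng.choice([4, 5, 6, 7, 8, 9], size=2, replace=False):
        c = rng.uniform(0.10, 0.20)
        phase = rng.uniform(0, 2 * math.pi)
        r += c * np.cos(m * theta + phase)
    x = center[0] + base_radius * r * np.cos(theta)
    y = center[1] + base_radius * aspect * r * np.sin(theta)

    # curvature of the parametric outline (for keypoint ground truth)
    dx = np.gradient(x, theta)
    dy = np.gradient(y, theta)
    ddx = np.gradient(dx, theta)
    ddy = np.gradient(dy, theta)
    kappa = np.abs(dx * ddy - dy * ddx) / np.maximum((dx**2 + dy**2) ** 1.5, 1e-12)
    return np.column_stack([x, y]), kappa


def _render_world(spec: ScenePairSpec, rng: np.random.Generator):
    w, h = spec.scene_size
    world = np.full((h, w), 0.35)
    if spec.texture_amp > 0:
        noise = rng.standard_normal((h, w))
        tex = gaussian_filter(noise, 6.0)
        tex /= max(np.abs(tex).max(), 1e-9)
        world += spec.texture_amp * tex

    # jittered grid placement keeps silhouettes separated
    cols = int(math.ceil(math.sqrt(spec.blob_count)))
    rows = int(math.ceil(spec.blob_count / cols))
    outlines = []
    corner_truth = []
    k = 0
    for gy in range(rows):
        for gx in range(cols):
            if k >= spec.blob_count:
                break
            cx = (gx + 0.5) / cols * w + rng.uniform(-0.06, 0.06) * w
            cy = (gy + 0.5) / rows * h + rng.uniform(-0.06, 0.06) * h
            base = rng.uniform(0.55, 0.8) * min(w / cols, h / rows) / 2.0
            pts, kappa = _blob_outline(rng, (cx, cy), base)
            level = rng.uniform(0.62, 0.85) if rng.random() < 0.7 else rng.uniform(0.05, 0.18)
            rr, cc = polygon(pts[:, 1], pts[:, 0], shape=(h, w))
            world[rr, cc] = level
            outlines.append(pts)
            # curvature maxima of the true outline
            n = len(kappa)
            is_max = (kappa >= np.roll(kappa, 1)) & (kappa > np.roll(kappa, -1))
            for i in np.nonzero(is_max & (kappa > np.percentile(kappa, 80)))[0]:
                corner_truth.append(pts[i])
            k += 1
    return world, outlines, np.array(corner_truth).reshape(-1, 2)


def _apply_illumination(world: np.ndarray, level: int) -> np.ndarray:
    p = illumination_schedule(level)
    v = np.clip(p["gain"] * world + p["offset"], 0.0, 1.0)
    return v ** p["gamma"]


def generate_pair(spec: ScenePairSpec) -> tuple[np.ndarray, np.ndarray, GroundTruth]:
    """Render (visible, infrared, GroundTruth); deterministic given the seed."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    w, h = spec.scene_size
    iw, ih = spec.ir_size
    ratio = w / iw

    world, outlines, corner_truth = _render_world(spec, rng)

    visible = _apply_illumination(world, spec.illumination_level)
    if spec.noise_sigma > 0:
        visible = visible + spec.noise_sigma * rng.standard_normal(visible.shape)
    visible = np.clip(visible, 0.0, 1.0)

    # planted similarity A: IR-fullres coords -> world coords
    A = SimilarityTransform(
        scale=spec.planted_scale,
        rotation=spec.planted_rotation,
        translation=spec.planted_translation,
    )
    identity_geometry = (
        spec.planted_scale == 1.0
        and spec.planted_rotation == 0.0
        and tuple(spec.planted_translation) == (0.0, 0.0)
        and (iw, ih) == (w, h)
    )
    ir_full = world if identity_geometry else warp(world, A, output_shape=(h, w), mode="reflect", order=3)

    ir = ir_full
    if spec.reverse_intensity:
        ir = (1.0 - np.clip(ir, 0.0, 1.0)) ** 1.2
    if spec.ir_blur_sigma > 0:
        ir = gaussian_filter(ir, spec.ir_blur_sigma)
    if (iw, ih) != (w, h):
        down = SimilarityTransform(scale=ratio)
        ir = warp(ir, down, output_shape=(ih, iw), mode="reflect", order=3)
    if spec.noise_sigma > 0:
        ir = ir + spec.noise_sigma * rng.standard_normal(ir.shape)
    ir = np.clip(ir, 0.0, 1.0)

    # composite ground-truth map: native IR u -> vis q = A(ratio * u)
    planted = Transform(
        spec.planted_scale, spec.planted_rotation,
        float(spec.planted_translation[0]), float(spec.planted_translation[1]),
    )
    composite = planted.compose(Transform(ratio, 0.0, 0.0, 0.0))

    # control points on silhouette outlines, visible in both frames
    all_pts = np.vstack(outlines)
    rng.shuffle(all_pts)
    inv = composite.inverse()
    control = []
    for q in all_pts:
        u = inv.apply(q)[0]
        if 2 <= u[0] <= iw - 3 and 2 <= u[1] <= ih - 3 and 2 <= q[0] <= w - 3 and 2 <= q[1] <= h - 3:
            control.append((u[0], u[1], q[0], q[1]))
        if len(control) >= spec.n_control_points:
            break
    control = np.array(control).reshape(-1, 4)

    truth = GroundTruth(transform=composite, control_points=control, keypoint_truth=corner_truth)
    return visible, ir, truth
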