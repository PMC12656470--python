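"""Bilateral matching, RANSAC rough registration, fine refinement, and the
end-to-end visible/infrared registration driver.

Rough-to-fine scheme: mutual-nearest-neighbor descriptor matches (with a
nearest/second-nearest ratio test) are filtered by a seeded RANSAC similarity
fit; the surviving inlier pairs (P_ri on the infrared side, P_rv on the
visible side) are then refined positionally by searching a small window around
each visible location for the best zero-normalized cross-correlation between
the transform-warped infrared feature-map patch and the visible feature map.
A refinement is kept only if it improves the correlation, and the whole fine
stage is reverted if it fails to reduce the mean reprojection error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from skimage.transform import SimilarityTransform

from .config import PipelineConfig
from .contours import detect_and_orient
from .descriptors import Descriptor, describe_all
from .exceptions import ParameterError, RegistrationError
from .filters import FeatureMap, default_gabor_bank, gabor_feature_map, normalize_map, ordinal_feature_map
from .filters import OrdinalParams

__all__ = [
    "Match",
    "Transform",
    "RegistrationResult",
    "bilateral_match",
    "ransac_similarity",
    "refine_matches",
    "register_pair",
    "feature_pipeline",
    "orient_compare",
]


@dataclass
class Match:
    ir_point: tuple
    vis_point: tuple
    distance: float
    stage: str = "bilateral"  # bilateral | rough | fine
    inlier: bool = False
    ir_index: int = -1
    vis_index: int = -1
    ir_orientation: float = float("nan")
    vis_orientation: float = float("nan")


@dataclass
class Transform:
    """Similarity transform p' = s * R(phi) p + t on (x, y) coordinates."""

    scale: float
    rotation: float
    tx: float
    ty: float

    def __post_init__(self):
        if self.scale <= 0:
            raise ParameterError(f"similarity scale must be > 0, got {self.scale}")

    @property
    def translation(self) -> tuple:
        return (self.tx, self.ty)

    def apply(self, points) -> np.ndarray:
        p = np.asarray(points, dtype=float).reshape(-1, 2)
        c, s = math.cos(self.rotation), math.sin(self.rotation)
        R = np.array([[c, -s], [s, c]])
        return (self.scale * (R @ p.T)).T + np.array([self.tx, self.ty])

    def inverse(self) -> "Transform":
        c, s = math.cos(-self.rotation), math.sin(-self.rotation)
        tx = -(c * self.tx - s * self.ty) / self.scale
        ty = -(s * self.tx + c * self.ty) / self.scale
        return Transform(1.0 / self.scale, -self.rotation, tx, ty)

    def compose(self, inner: "Transform") -> "Transform":
        """self o inner: apply ``inner`` first."""
        c, s = math.cos(self.rotation), math.sin(self.rotation)
        R = np.array([[c, -s], [s, c]])
        t_in = np.array([inner.tx, inner.ty])
        t = self.scale * (R @ t_in) + np.array([self.tx, self.ty])
        return Transform(self.scale * inner.scale, self.rotation + inner.rotation, t[0], t[1])

    @classmethod
    def from_skimage(cls, t: SimilarityTransform) -> "Transform":
        return cls(float(t.scale), float(t.rotation), float(t.translation[0]), float(t.translation[1]))

    def as_dict(self) -> dict:
        return {"kind": "similarity", "scale": self.scale, "rotation": self.rotation,
                "tx": self.tx, "ty": self.ty}


@dataclass
class RegistrationResult:
    transform: Transform            # upsampled-IR frame -> visible frame
    composite_transform: Transform  # native-IR frame -> visible frame
    resolution_ratio: float
    matches: list = field(default_factory=list)  # all stages
    refined: bool = False
    log: dict = field(default_factory=dict)
    keypoints_ir: list = field(default_factory=list)
    keypoints_vis: list = field(default_factory=list)
    maps: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# bilateral matching


def bilateral_match(desc_ir: list[Descriptor], desc_vis: list[Descriptor], ratio: float = 0.7) -> list[Match]:
    """Mutual-nearest-neighbor matches with an IR->visible ratio test.

    A pair survives iff each descriptor is the other's nearest neighbor and
    the nearest/second-nearest distance ratio on the IR side is <= ratio.
    When the visible side carries several scales per keypoint, only the best
    (smallest-distance) match per keypoint pair is kept, and each keypoint
    appears in at most one final match.  Equal distances break toward the
    lower index (np.argmin), so matching is deterministic.
    """
    if not desc_ir or not desc_vis:
        return []
    A = np.stack([d.vector for d in desc_ir])
    B = np.stack([d.vector for d in desc_vis])
    D = cdist(A, B)
    nn_ab = np.argmin(D, axis=1)
    nn_ba = np.argmin(D, axis=0)

    cands = []
    for i, j in enumerate(nn_ab):
        if nn_ba[j] != i:
            continue
        best = D[i, j]
        if D.shape[1] > 1:
            second = np.partition(D[i], 1)[1]
            if second <= 0 or best > ratio * second:
                continue
        elif ratio <= 0:
            continue
        cands.append((best, i, int(j)))

    # one match per keypoint (best scale wins)
    cands.sort(key=lambda t: (t[0], t[1], t[2]))
    used_ir, used_vis, out = set(), set(), []
    for dist, i, j in cands:
        ki = id(desc_ir[i].keypoint)
        kj = id(desc_vis[j].keypoint)
        if ki in used_ir or kj in used_vis:
            continue
        used_ir.add(ki)
        used_vis.add(kj)
        out.append(
            Match(
                ir_point=tuple(desc_ir[i].keypoint.location),
                vis_point=tuple(desc_vis[j].keypoint.location),
                distance=float(dist),
                stage="bilateral",
                ir_index=i,
                vis_index=j,
                ir_orientation=desc_ir[i].keypoint.orientation,
                vis_orientation=desc_vis[j].keypoint.orientation,
            )
        )
    return out


# ---------------------------------------------------------------------------
# RANSAC


def _fit_two_point(src: np.ndarray, dst: np.ndarray) -> Transform | None:
    """Closed-form similarity from two correspondences via complex ratio."""
    s0 = complex(src[0, 0], src[0, 1])
    s1 = complex(src[1, 0], src[1, 1])
    d0 = complex(dst[0, 0], dst[0, 1])
    d1 = complex(dst[1, 0], dst[1, 1])
    if s0 == s1:
        return None
    a = (d1 - d0) / (s1 - s0)
    if abs(a) <= 0:
        return None
    b = d0 - a * s0
    return Transform(abs(a), math.atan2(a.imag, a.real), b.real, b.imag)


def fit_similarity(src, dst) -> Transform:
    """Least-squares similarity fit (Umeyama) on >= 2 correspondences."""
    src = np.asarray(src, float)
    dst = np.asarray(dst, float)
    if hasattr(SimilarityTransform, "from_estimate"):
        t = SimilarityTransform.from_estimate(src, dst)
        if not t:
            raise RegistrationError("similarity estimation failed (degenerate points)")
    else:
        t = SimilarityTransform()
        if not t.estimate(src, dst):
            raise RegistrationError("similarity estimation failed (degenerate points)")
    return Transform.from_skimage(t)


def ransac_similarity(
    matches: list[Match],
    inlier_tol: float = 5.0,
    iterations: int = 2000,
    seed: int = 0,
    min_inliers: int = 4,
) -> tuple[Transform, list[Match]]:
    """Seeded RANSAC over 2-point similarity hypotheses.

    Returns the least-squares refit on the best consensus set, and the inlier
    matches restaged as "rough".  Raises RegistrationError on fewer than two
    matches or a consensus smaller than ``min_inliers``.
    """
    if len(matches) < 2:
        raise RegistrationError(
            "RANSAC needs at least 2 matches", {"n_matches": len(matches)}
        )
    src = np.array([m.ir_point for m in matches], dtype=float)
    dst = np.array([m.vis_point for m in matches], dtype=float)
    n = len(matches)
    rng = np.random.default_rng(seed)

    best_mask = None
    best_count = 0
    best_err = np.inf
    for _ in range(iterations):
        i, j = rng.choice(n, size=2, replace=False)
        t = _fit_two_point(src[[i, j]], dst[[i, j]])
        if t is None:
            continue
        err = np.linalg.norm(t.apply(src) - dst, axis=1)
        mask = err <= inlier_tol
        count = int(mask.sum())
        total = float(err[mask].sum())
        if count > best_count or (count == best_count and total < best_err):
            best_count = count
            best_err = total
            best_mask = mask
    if best_mask is None or best_count < max(2, min_inliers):
        raise RegistrationError(
            f"RANSAC consensus too small ({best_count} inliers)",
            {"n_matches": n, "n_inliers": best_count},
        )
    # local optimization: refit on the consensus, re-evaluate membership, and
    # iterate until the inlier set stabilizes
    transform = fit_similarity(src[best_mask], dst[best_mask])
    for _ in range(5):
        err = np.linalg.norm(transform.apply(src) - dst, axis=1)
        mask = err <= inlier_tol
        if mask.sum() < 2 or np.array_equal(mask, best_mask):
            break
        best_mask = mask
        transform = fit_similarity(src[best_mask], dst[best_mask])
    inliers = []
    for k in np.nonzero(best_mask)[0]:
        m = matches[int(k)]
        inliers.append(
            Match(m.ir_point, m.vis_point, m.distance, "rough", True,
                  m.ir_index, m.vis_index, m.ir_orientation, m.vis_orientation)
        )
    return transform, inliers


# ---------------------------------------------------------------------------
# fine refinement


def _zncc(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    na = np.linalg.norm(a)
    nb = np.linalg.norm(b)
    if na <= 1e-12 or nb <= 1e-12:
        return -np.inf
    return float((a * b).sum() / (na * nb))


def refine_matches(
    rough: list[Match],
    transform: Transform,
    map_ir: FeatureMap,
    map_vis: FeatureMap,
    window: int = 10,
    patch_radius: int = 16,
    smooth_sigma: float = 4.0,
    iterations: int = 2,
    max_residual: float = 5.0,
) -> tuple[list[Match], Transform, bool]:
    """Iterative windowed |ZNCC| refinement of the visible-side locations.

    For each inlier the infrared feature-map patch is warped through the
    current transform and compared against visible patches at every integer
    shift within ``window``; the location moves to the best-correlating shift
    (it stays put unless a strictly better one exists).  The absolute
    correlation is used because a contrast-reversing modality flips the sign
    of its band-pass response wholesale.  The integer peak is polished with a
    parabolic sub-pixel fit.  After each sweep the transform is refit on the
    refined pairs and the sweep repeats, so residual local misalignment
    shrinks toward zero.  Featureless or border-clipped patches are left
    unrefined.

    Guard: the whole stage is reverted if the mean pair reprojection error
    ends up worse than both the rough stage's and ``max_residual`` (the
    inlier tolerance).  Pair residual alone is not required to decrease: the
    two contour detectors share a localization bias that cancels in the rough
    residual, so correcting the visible side can raise the pair residual even
    as the transform improves.  Returns (matches, transform, refined_flag).
    """
    from scipy.ndimage import gaussian_filter, map_coordinates

    if not rough:
        return rough, transform, False

    vis = map_vis.values
    ir_vals = map_ir.values
    if smooth_sigma > 0:
        vis = gaussian_filter(vis, smooth_sigma)
        ir_vals = gaussian_filter(ir_vals, smooth_sigma)
    h, w = vis.shape
    r = patch_radius
    uv = np.arange(-r, r + 1, dtype=float)
    gu, gv = np.meshgrid(uv, uv)

    src = np.array([m.ir_point for m in rough], dtype=float)
    dst = np.array([m.vis_point for m in rough], dtype=float)
    err_before = float(np.linalg.norm(transform.apply(src) - dst, axis=1).mean())

    new_transform = transform
    refined_dst = dst.copy()
    for _ in range(max(iterations, 1)):
        inv = new_transform.inverse()
        moved = False
        for k in range(len(rough)):
            vx, vy = refined_dst[k]
            grid = np.column_stack([(gu + vx).ravel(), (gv + vy).ravel()])
            ir_pts = inv.apply(grid)
            tmpl = map_coordinates(
                ir_vals, [ir_pts[:, 1], ir_pts[:, 0]], order=1, mode="nearest"
            ).reshape(gu.shape)
            if tmpl.std() <= 1e-9:
                continue  # featureless: leave unrefined
            ix, iy = int(round(vx)), int(round(vy))
            if (
                ix - r - window < 0
                or iy - r - window < 0
                or ix + r + window > w - 1
                or iy + r + window > h - 1
            ):
                continue  # window exits image: leave unrefined
            best = abs(_zncc(tmpl, vis[iy - r : iy + r + 1, ix - r : ix + r + 1]))
            best_shift = (0, 0)
            for dy in range(-window, window + 1):
                for dx in range(-window, window + 1):
                    if dx == 0 and dy == 0:
                        continue
                    c = abs(
                        _zncc(
                            tmpl,
                            vis[iy + dy - r : iy + dy + r + 1, ix + dx - r : ix + dx + r + 1],
                        )
                    )
                    if c > best:
                        best = c
                        best_shift = (dx, dy)
            if best_shift != (0, 0):
                # parabolic sub-pixel polish along each axis
                bx, by = best_shift

                def _corr(dx, dy):
                    return abs(_zncc(
                        tmpl,
                        vis[iy + dy - r : iy + dy + r + 1, ix + dx - r : ix + dx + r + 1],
                    ))

                sub = [0.0, 0.0]
                if abs(bx) < window:
                    c0, c1, c2 = _corr(bx - 1, by), best, _corr(bx + 1, by)
                    den = c0 - 2 * c1 + c2
                    if abs(den) > 1e-12:
                        sub[0] = float(np.clip(0.5 * (c0 - c2) / den, -0.5, 0.5))
                if abs(by) < window:
                    c0, c1, c2 = _corr(bx, by - 1), best, _corr(bx, by + 1)
                    den = c0 - 2 * c1 + c2
                    if abs(den) > 1e-12:
                        sub[1] = float(np.clip(0.5 * (c0 - c2) / den, -0.5, 0.5))
                refined_dst[k] = (vx + bx + sub[0], vy + by + sub[1])
                moved = True
        new_transform = fit_similarity(src, refined_dst)
        if not moved:
            break

    err_after = float(np.linalg.norm(new_transform.apply(src) - refined_dst, axis=1).mean())
    if err_after > max(err_before, max_residual):
        return rough, transform, False  # revert: refinement must never make it worse

    fine = [
        Match(m.ir_point, (float(refined_dst[k, 0]), float(refined_dst[k, 1])),
              m.distance, "fine", True, m.ir_index, m.vis_index,
              m.ir_orientation, m.vis_orientation)
        for k, m in enumerate(rough)
    ]
    return fine, new_transform, True


# ---------------------------------------------------------------------------
# end-to-end


def _upsample(image: np.ndarray, shape: tuple, ratio: float) -> np.ndarray:
    """Bicubic upsampling under the pure coordinate-scaling convention
    out(p) = image(p / ratio), the same convention the composite transform
    assumes when it folds the resolution ratio back in."""
    from skimage.transform import SimilarityTransform, warp

    return warp(image, SimilarityTransform(scale=1.0 / ratio), output_shape=shape,
                mode="edge", order=3)


def feature_pipeline(
    image: np.ndarray,
    config: PipelineConfig | None = None,
    sigmas: tuple | None = None,
) -> tuple[FeatureMap, FeatureMap]:
    """Image -> (Gabor map F, Gabor-ordinal map S), normalized.

    ``sigmas`` overrides the bank scales; the infrared side of a pair is
    analysed with coarser scales matched to its native resolution.
    """
    config = config or PipelineConfig()
    bank = default_gabor_bank(
        config.gabor.n_orientations, sigmas or config.gabor.sigmas, config.gabor.gamma
    )
    F = gabor_feature_map(image, bank)
    params = OrdinalParams(
        positive_lobes=((0.0, config.ordinal.sigma_p),),
        negative_lobes=((-config.ordinal.omega, config.ordinal.sigma_n),
                        (config.ordinal.omega, config.ordinal.sigma_n)),
    )
    S = ordinal_feature_map(F, params)
    if config.normalize_maps:
        F = normalize_map(F)
        S = normalize_map(S)
    return F, S


def _detect(S: FeatureMap, config: PipelineConfig):
    c = config.contours
    return detect_and_orient(
        S,
        threshold_rule=c.threshold_rule,
        min_length=c.min_length,
        percentile=c.percentile,
        sigmas=c.css_sigmas,
        curvature_threshold=c.curvature_threshold,
        nms_separation=c.nms_separation,
        arm_length=c.arm_length,
    )


def register_pair(
    visible: np.ndarray,
    infrared: np.ndarray,
    config: PipelineConfig | None = None,
    seed: int | None = None,
) -> RegistrationResult:
    """Full rough-to-fine registration of a visible/infrared pair.

    The infrared image is bicubically upsampled to the visible grid first (its
    native resolution is too coarse for contour arms); the resolution ratio is
    composed into the reported composite transform, so native-IR coordinates
    map directly into the visible frame.  Raises RegistrationError (with stage
    counts) when any stage leaves too little to continue.
    """
    config = config or PipelineConfig()
    if seed is None:
        seed = config.ransac.seed
    visible = np.asarray(visible, dtype=float)
    infrared = np.asarray(infrared, dtype=float)
    if visible.ndim != 2 or infrared.ndim != 2:
        raise ParameterError("register_pair expects single-channel 2-D images")

    ratio = visible.shape[1] / infrared.shape[1]
    ir_up = _upsample(infrared, visible.shape, ratio)

    _, S_vis = feature_pipeline(visible, config)
    _, S_ir = feature_pipeline(ir_up, config, sigmas=config.gabor.ir_sigmas)

    kps_vis = _detect(S_vis, config)
    kps_ir = _detect(S_ir, config)
    log = {"keypoints_vis": len(kps_vis), "keypoints_ir": len(kps_ir)}
    if not kps_vis or not kps_ir:
        raise RegistrationError("no keypoints detected", log)

    desc_vis = describe_all(S_vis, kps_vis, config.descriptors.vis_radii,
                            config.descriptors.smooth_sigma)
    desc_ir = describe_all(S_ir, kps_ir, (config.descriptors.ir_radius,),
                           config.descriptors.smooth_sigma)
    log.update(descriptors_vis=len(desc_vis), descriptors_ir=len(desc_ir))
    if not desc_vis or not desc_ir:
        raise RegistrationError("no descriptors computed", log)

    bilateral = bilateral_match(desc_ir, desc_vis, config.descriptors.ratio)
    log["matches_bilateral"] = len(bilateral)
    if len(bilateral) < 2:
        raise RegistrationError("too few bilateral matches", log)

    transform, rough = ransac_similarity(
        bilateral, config.ransac.tol, config.ransac.iterations, seed,
        config.ransac.min_inliers,
    )
    log["matches_rough"] = len(rough)

    fine, transform, refined = refine_matches(
        rough, transform, S_ir, S_vis, config.refine.window,
        config.refine.patch_radius, config.refine.smooth_sigma,
        config.refine.iterations, config.ransac.tol,
    )
    log["matches_fine"] = len(fine)
    log["refined"] = refined

    upscale = Transform(ratio, 0.0, 0.0, 0.0)
    composite = transform.compose(upscale)

    return RegistrationResult(
        transform=transform,
        composite_transform=composite,
        resolution_ratio=ratio,
        matches=bilateral + rough + fine,
        refined=refined,
        log=log,
        keypoints_ir=kps_ir,
        keypoints_vis=kps_vis,
        maps={"S_vis": S_vis, "S_ir": S_ir},
    )


# ---------------------------------------------------------------------------
# Gabor-ordinal vs raw-contour comparison


def orient_compare(
    visible: np.ndarray,
    infrared: np.ndarray,
    true_map,
    config: PipelineConfig | None = None,
    radius: float = 5.0,
    tol_deg: float = 5.0,
    expected_rotation: float = 0.0,
) -> dict:
    """Compare keypoint counts and cross-modal orientation agreement between
    the Gabor-ordinal representation and plain raw-image contours.

    The baseline extracts contours from the raw images with a Canny edge
    detector and runs the identical CSS / bisector-orientation machinery on
    them, isolating the contribution of the Gabor-ordinal feature maps.
    ``true_map`` maps native-IR coordinates into the visible frame (ground
    truth); the agreement count is the number of corresponding keypoint pairs
    whose main orientations differ by less than ``tol_deg`` degrees after
    removing ``expected_rotation`` (radians), the rotation the ground-truth
    transform itself imposes between the frames.
    """
    from skimage.feature import canny

    from .contours import contours_from_mask, orient_keypoints_on_contours

    config = config or PipelineConfig()
    visible = np.asarray(visible, dtype=float)
    infrared = np.asarray(infrared, dtype=float)
    ratio = visible.shape[1] / infrared.shape[1]
    ir_up = _upsample(infrared, visible.shape, ratio)

    c = config.contours

    def raw_keypoints(img):
        contours = contours_from_mask(canny(img, sigma=1.0), c.min_length)
        return orient_keypoints_on_contours(
            contours, c.css_sigmas, c.curvature_threshold, c.nms_separation, c.arm_length
        )

    S_vis = feature_pipeline(visible, config)[1]
    S_ir = feature_pipeline(ir_up, config, sigmas=config.gabor.ir_sigmas)[1]
    variants = {
        "gabor_ordinal": (_detect(S_vis, config), _detect(S_ir, config)),
        "raw_contour": (raw_keypoints(visible), raw_keypoints(ir_up)),
    }

    from scipy.spatial import cKDTree

    results = {}
    for name, (kv, ki) in variants.items():
        agree = 0
        if kv and ki:
            pv = np.array([kp.location for kp in kv], dtype=float)
            pi = np.array([kp.location for kp in ki], dtype=float)
            # upsampled-IR frame -> native IR -> visible via ground truth
            mapped = np.asarray(true_map(pi / ratio), dtype=float).reshape(-1, 2)
            tree = cKDTree(pv)
            d, idx = tree.query(mapped)
            for k in range(len(ki)):
                if d[k] <= radius:
                    da = math.degrees(
                        abs(ki[k].orientation + expected_rotation - kv[idx[k]].orientation)
                    )
                    da = da % 360.0
                    da = min(da, 360.0 - da)
                    if da < tol_deg:
                        agree += 1
        results[name] = {
            "keypoints_vis": len(kv),
            "keypoints_ir": len(ki),
            "orientation_agreement": agree,
        }
    return results
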