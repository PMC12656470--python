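"""Modified-SIFT (MSIFT) descriptors on the Gabor-ordinal feature maps.

Two modality-robust modifications of the classical SIFT descriptor:

* gradient orientations are folded modulo pi, merging opposite gradient
  directions — this converts the usual 16-direction histogram into 8 bins and
  makes the descriptor invariant to the contrast reversal between visible and
  infrared renderings of the same contour;
* gradient magnitudes are normalized (per patch, 99th percentile, clamped)
  so the very different dynamic ranges of the two spectra do not dominate.

Each descriptor is the standard 4x4 spatial grid x 8 orientation bins = 128
values, accumulated in the keypoint's main-orientation frame with trilinear
interpolation, clamped at 0.2 and renormalized to unit L2 norm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter, map_coordinates

from .contours import KeyPoint
from .filters import FeatureMap

__all__ = ["Descriptor", "folded_gradients", "describe", "describe_all"]

N_CELLS = 4
N_BINS = 8  # over [0, pi)


@dataclass
class Descriptor:
    """128-vector (4x4 cells x 8 folded-orientation bins), unit L2 norm."""

    vector: np.ndarray
    keypoint: KeyPoint
    scale: float  # patch radius, px


def folded_gradients(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Central-difference gradients as (magnitude, angle folded into [0, pi)).

    Magnitudes are divided by their 99th percentile and clamped to 1.
    """
    values = np.asarray(values, dtype=float)
    gy, gx = np.gradient(values)
    mag = np.hypot(gx, gy)
    ang = np.arctan2(gy, gx) % math.pi
    p99 = np.percentile(mag, 99)
    if p99 > 0:
        mag = np.minimum(mag / p99, 1.0)
    return mag, ang


def _gradient_fields(values: np.ndarray, smooth_sigma: float = 0.0) -> tuple[np.ndarray, np.ndarray]:
    v = np.asarray(values, dtype=float)
    if smooth_sigma > 0:
        v = gaussian_filter(v, smooth_sigma)
    gy, gx = np.gradient(v)
    return gx, gy


def describe(
    map_or_values,
    keypoint: KeyPoint,
    patch_radius: float,
    smooth_sigma: float = 8.0,
    _grads: tuple[np.ndarray, np.ndarray] | None = None,
) -> Descriptor | None:
    """One MSIFT descriptor at a keypoint, or None if the rotated patch exits
    the image or the patch is flat (zero histogram).

    The patch is sampled on a (2r)^2 grid rotated so the keypoint's main
    orientation maps onto +x; sample angles are taken relative to that
    orientation and folded modulo pi.  Gradients are taken on the map smoothed
    by ``smooth_sigma`` so that both spectra are described at a common
    effective resolution (the fine-scale content of the sharper modality has
    no counterpart in the other and would only add noise to the histograms).
    """
    values = map_or_values.values if isinstance(map_or_values, FeatureMap) else np.asarray(map_or_values, float)
    h, w = values.shape
    r = float(patch_radius)
    cx, cy = keypoint.location
    o = keypoint.orientation
    if not np.isfinite(o):
        return None
    co, so = math.cos(o), math.sin(o)

    # rotated sample grid (u along the main orientation)
    n = int(round(2 * r))
    uv = (np.arange(n) + 0.5) / n * 2 * r - r
    u, v = np.meshgrid(uv, uv)
    xs = cx + u * co - v * so
    ys = cy + u * so + v * co
    if xs.min() < 0 or ys.min() < 0 or xs.max() > w - 1 or ys.max() > h - 1:
        return None

    gx, gy = _grads if _grads is not None else _gradient_fields(values, smooth_sigma)
    sgx = map_coordinates(gx, [ys.ravel(), xs.ravel()], order=1, mode="nearest")
    sgy = map_coordinates(gy, [ys.ravel(), xs.ravel()], order=1, mode="nearest")
    mag = np.hypot(sgx, sgy)
    p99 = np.percentile(mag, 99)
    if p99 <= 0:
        return None
    mag = np.minimum(mag / p99, 1.0)
    ang = (np.arctan2(sgy, sgx) - o) % math.pi

    # Gaussian spatial window
    weight = np.exp(-(u.ravel() ** 2 + v.ravel() ** 2) / (2.0 * r**2))
    wmag = mag * weight

    # fractional cell / bin coordinates for trilinear accumulation
    ci = (u.ravel() + r) / (2 * r) * N_CELLS - 0.5
    cj = (v.ravel() + r) / (2 * r) * N_CELLS - 0.5
    cb = ang / math.pi * N_BINS - 0.5

    hist = np.zeros((N_CELLS, N_CELLS, N_BINS))
    i0 = np.floor(ci).astype(int)
    j0 = np.floor(cj).astype(int)
    b0 = np.floor(cb).astype(int)
    fi = ci - i0
    fj = cj - j0
    fb = cb - b0
    for di in (0, 1):
        wi = np.where(di == 0, 1 - fi, fi)
        ii = i0 + di
        oki = (ii >= 0) & (ii < N_CELLS)
        for dj in (0, 1):
            wj = np.where(dj == 0, 1 - fj, fj)
            jj = j0 + dj
            okj = oki & (jj >= 0) & (jj < N_CELLS)
            for db in (0, 1):
                wb = np.where(db == 0, 1 - fb, fb)
                bb = (b0 + db) % N_BINS  # orientation wraps
                contrib = wmag * wi * wj * wb
                sel = okj & (contrib > 0)
                np.add.at(hist, (ii[sel], jj[sel], bb[sel]), contrib[sel])

    vec = hist.ravel()
    norm = np.linalg.norm(vec)
    if norm < 1e-9:
        return None
    vec = np.minimum(vec / norm, 0.2)
    vec /= np.linalg.norm(vec)
    return Descriptor(vector=vec, keypoint=keypoint, scale=r)


def describe_all(
    fmap: FeatureMap, keypoints: list[KeyPoint], scales: tuple = (32.0,),
    smooth_sigma: float = 8.0,
) -> list[Descriptor]:
    """One descriptor per (keypoint, scale); flat or out-of-bounds patches are
    skipped.  The visible side typically passes several radii (its scale
    information is richer); the infrared side a single base radius."""
    grads = _gradient_fields(fmap.values, smooth_sigma)
    out = []
    for kp in keypoints:
        for r in scales:
            d = describe(fmap, kp, r, smooth_sigma, _grads=grads)
            if d is not None:
                out.append(d)
    return out
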