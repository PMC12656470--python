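"""Contour extraction, curvature-scale-space corners, and main orientations.

A contour is an ordered 8-connected pixel chain traced from the Gabor-ordinal
map ``S``.  Corners are curvature-scale-space (CSS) feature points: local
maxima of the absolute curvature of the Gaussian-smoothed chain that persist
across smoothing scales.  Each corner's main orientation is the direction of
the angular bisector of its two contour arms,

    v = min(|L|, |R|) * (L/|L| + R/|R|),

mapped to an angle O in [0, 2*pi) measured counter-clockwise from +x with +y
pointing down image rows (x = column, y = row, origin top-left, 0-based).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter, gaussian_filter1d
from skimage.morphology import skeletonize

from .exceptions import ParameterError
from .filters import FeatureMap

__all__ = [
    "Contour",
    "KeyPoint",
    "extract_contours",
    "contours_from_mask",
    "orient_keypoints_on_contours",
    "css_feature_points",
    "arm_vectors",
    "bisector",
    "orientation_from_bisector",
    "detect_and_orient",
]

TWO_PI = 2.0 * math.pi


@dataclass
class Contour:
    """Ordered pixel chain (x = column, y = row); consecutive points are
    8-connected neighbors."""

    id: int
    points: np.ndarray  # (n, 2) float, columns (x, y)
    closed: bool

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 2)

    def __len__(self):
        return len(self.points)


@dataclass
class KeyPoint:
    """A CSS corner on a contour with its bisector main orientation."""

    location: tuple  # (x, y)
    contour_id: int
    contour_index: int
    arm_left: tuple = (0.0, 0.0)
    arm_right: tuple = (0.0, 0.0)
    orientation: float = float("nan")  # radians in [0, 2*pi), NaN while unset
    css_scale: float = 0.0
    curvature: float = 0.0
    extras: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# contour extraction


def _binarize(values: np.ndarray, percentile: float) -> np.ndarray:
    mag = np.abs(values)
    thr = np.percentile(mag, percentile)
    return mag >= thr if thr > 0 else np.zeros_like(mag, dtype=bool)


def _resample_chain(points: np.ndarray, closed: bool, spacing: float = 1.0) -> np.ndarray:
    """Resample a polyline to uniform arc-length spacing (px)."""
    if closed:
        points = np.vstack([points, points[:1]])
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if total < spacing:
        return points[:-1] if closed else points
    n = max(int(round(total / spacing)), 3)
    t = np.linspace(0.0, total, n, endpoint=not closed)
    x = np.interp(t, s, points[:, 0])
    y = np.interp(t, s, points[:, 1])
    return np.column_stack([x, y])


_NBR = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def _trace_component(pixels: set) -> tuple[list, bool]:
    """Order one 8-connected simple component (path or loop) into a chain."""
    nbrs = {
        p: [q for dy, dx in _NBR if (q := (p[0] + dy, p[1] + dx)) in pixels]
        for p in pixels
    }
    endpoints = [p for p, ns in nbrs.items() if len(ns) <= 1]
    start = min(endpoints) if endpoints else min(pixels)
    chain = [start]
    visited = {start}
    cur = start
    while True:
        nxt = [q for q in nbrs[cur] if q not in visited]
        if not nxt:
            break
        # prefer 4-connected steps to avoid zig-zag corner cutting
        nxt.sort(key=lambda q: (abs(q[0] - cur[0]) + abs(q[1] - cur[1]), q))
        cur = nxt[0]
        chain.append(cur)
        visited.add(cur)
    closed = not endpoints and len(chain) >= 3 and chain[0] in nbrs[chain[-1]]
    return chain, closed


def _contours_zero_crossing(
    values: np.ndarray, percentile: float, rel_strength: float = 0.35
) -> list[tuple]:
    """Ordered subpixel chains along the zero crossings of the signed map,
    gated by gradient energy (Marr-Hildreth style edge localization).

    Zero crossings of a band-pass (zero-sum) response sit on the contour
    itself regardless of blur level, which is what makes the two modalities
    agree on contour position.  Besides the percentile gate, a curve must
    reach ``rel_strength`` of the strongest curve's mean energy: that drops
    the weak sidelobe rings that flank every principal crossing.
    """
    from skimage.measure import find_contours

    sm = gaussian_filter(values, 1.0)
    gy, gx = np.gradient(sm)
    energy = np.hypot(gx, gy)
    high = np.percentile(energy, percentile)
    if high <= 0:
        return []
    low = 0.4 * high
    out = []
    for rc in find_contours(sm, 0.0):
        closed = bool(np.allclose(rc[0], rc[-1]))
        pts = rc[:-1] if closed and len(rc) > 1 else rc
        if len(pts) < 3:
            continue
        rows = np.clip(np.round(pts[:, 0]).astype(int), 0, values.shape[0] - 1)
        cols = np.clip(np.round(pts[:, 1]).astype(int), 0, values.shape[1] - 1)
        e = energy[rows, cols]
        # hysteresis along the chain: keep maximal runs of e >= low that
        # contain at least one e >= high point.  A level-0 iso-contour bounds
        # a signed-response region, so it carries both the true edge crossing
        # and a weak sidelobe return path; the split keeps only the former.
        ok = e >= low
        if closed and ok.all():
            if e.max() >= high:
                out.append((np.column_stack([pts[:, 1], pts[:, 0]]), True))
            continue
        if closed:
            # rotate so the chain starts at a weak point; runs never wrap
            start = int(np.argmin(ok))
            pts = np.roll(pts, -start, axis=0)
            e = np.roll(e, -start)
            ok = np.roll(ok, -start)
        edges = np.flatnonzero(np.diff(ok.astype(int)))
        starts = [i + 1 for i in edges if not ok[i]]
        ends = [i + 1 for i in edges if ok[i]]
        if ok[0]:
            starts = [0] + starts
        if ok[-1]:
            ends = ends + [len(ok)]
        for a, b in zip(starts, ends):
            if b - a >= 3 and e[a:b].max() >= high:
                out.append((np.column_stack([pts[a:b, 1], pts[a:b, 0]]), False))

    def mean_energy(chain):
        rows = np.clip(np.round(chain[:, 1]).astype(int), 0, values.shape[0] - 1)
        cols = np.clip(np.round(chain[:, 0]).astype(int), 0, values.shape[1] - 1)
        return float(np.mean(energy[rows, cols]))

    if out:
        strengths = [mean_energy(chain) for chain, _ in out]
        floor = rel_strength * max(strengths)
        out = [item for item, s_ in zip(out, strengths) if s_ >= floor]
    return out


def chains_from_mask(mask: np.ndarray) -> list[tuple]:
    """Thin a binary mask to a 1-px skeleton and trace 8-connected chains;
    junction pixels (more than two skeleton neighbors) are removed first so
    every component is a simple path or loop.  Returns [(points_xy, closed)]."""
    if not mask.any():
        return []
    sk = skeletonize(mask)
    # neighbor counts in 8-connectivity
    nb = np.zeros(sk.shape, dtype=int)
    for dy, dx in _NBR:
        shifted = np.zeros_like(sk)
        ys = slice(max(dy, 0), sk.shape[0] + min(dy, 0))
        xs = slice(max(dx, 0), sk.shape[1] + min(dx, 0))
        yd = slice(max(-dy, 0), sk.shape[0] + min(-dy, 0))
        xd = slice(max(-dx, 0), sk.shape[1] + min(-dx, 0))
        shifted[yd, xd] = sk[ys, xs]
        nb += shifted & sk
    simple = sk & (nb <= 2)

    from skimage.measure import label

    labels = label(simple, connectivity=2)
    out = []
    for lab in range(1, labels.max() + 1):
        ys, xs = np.nonzero(labels == lab)
        if len(ys) < 3:
            continue
        chain, closed = _trace_component(set(zip(ys.tolist(), xs.tolist())))
        pts = np.array([(x, y) for y, x in chain], dtype=float)
        out.append((pts, closed))
    return out


def _contours_magnitude(values: np.ndarray, percentile: float) -> list[tuple]:
    """Binarize |S| at a percentile and chain-trace the skeleton."""
    return chains_from_mask(_binarize(values, percentile))


def contours_from_mask(mask: np.ndarray, min_length: int = 40) -> list[Contour]:
    """Ordered, resampled contours from any binary edge mask (e.g. Canny)."""
    contours = []
    for pts, closed in chains_from_mask(np.asarray(mask, dtype=bool)):
        pts = _resample_chain(pts, closed)
        if len(pts) < min_length:
            continue
        contours.append(Contour(id=0, points=pts, closed=closed))
    contours.sort(key=lambda c: -len(c))
    for j, c in enumerate(contours, start=1):
        c.id = j
    return contours


def orient_keypoints_on_contours(
    contours: list[Contour],
    sigmas: tuple = (2.0, 4.0, 6.0),
    curvature_threshold: float = 0.05,
    nms_separation: int = 5,
    arm_length: int = 20,
) -> list[KeyPoint]:
    """CSS corners + bisector orientations for pre-extracted contours."""
    base_sigma = min(sigmas)
    keypoints: list[KeyPoint] = []
    for contour in contours:
        kps = css_feature_points(contour, sigmas, curvature_threshold, nms_separation)
        if not kps:
            continue
        mode = "wrap" if contour.closed else "reflect"
        xs = gaussian_filter1d(contour.points[:, 0], base_sigma, mode=mode)
        ys = gaussian_filter1d(contour.points[:, 1], base_sigma, mode=mode)
        smooth = np.column_stack([xs, ys])
        for kp in kps:
            arms = arm_vectors(smooth, kp.contour_index, arm_length, contour.closed)
            if arms is None:
                continue
            v = bisector(*arms)
            if math.hypot(*v) < 1e-9:
                continue
            kp.arm_left = (float(arms[0][0]), float(arms[0][1]))
            kp.arm_right = (float(arms[1][0]), float(arms[1][1]))
            kp.orientation = orientation_from_bisector(*v)
            keypoints.append(kp)
    return keypoints


def extract_contours(
    S: FeatureMap,
    threshold_rule: str = "zero-crossing",
    min_length: int = 10,
    percentile: float = 90.0,
) -> list[Contour]:
    """Extract ordered contour chains from the Gabor-ordinal map S.

    The default rule traces the zero crossings of the signed response gated by
    gradient energy; the "magnitude" rule binarizes |S| at the percentile and
    skeleton-traces instead.  Chains are resampled to ~1 px arc-length spacing,
    those shorter than ``min_length`` points are discarded, and the result is
    ordered by descending length.  An all-zero map yields an empty list.
    """
    if threshold_rule == "zero-crossing":
        raw = _contours_zero_crossing(S.values, percentile)
    elif threshold_rule == "magnitude":
        raw = _contours_magnitude(S.values, percentile)
    else:
        raise ParameterError(f"unknown threshold rule {threshold_rule!r}")
    contours = []
    for pts, closed in raw:
        pts = _resample_chain(pts, closed)
        if len(pts) < min_length:
            continue
        contours.append(Contour(id=0, points=pts, closed=closed))
    contours.sort(key=lambda c: -len(c))

    # symmetric scenes can produce the same crossing twice (a zero plateau has
    # two boundaries); keep only the longer of two nearly coincident chains
    from scipy.spatial import cKDTree

    kept: list[Contour] = []
    for c in contours:
        duplicate = False
        for k in kept:
            d, _ = cKDTree(k.points).query(c.points)
            if np.median(d) < 2.0:
                duplicate = True
                break
        if not duplicate:
            kept.append(c)
    for j, c in enumerate(kept, start=1):
        c.id = j
    return kept


# ---------------------------------------------------------------------------
# CSS feature points


def _chain_curvature(x: np.ndarray, y: np.ndarray, sigma: float, mode: str) -> np.ndarray:
    x1 = gaussian_filter1d(x, sigma, order=1, mode=mode)
    y1 = gaussian_filter1d(y, sigma, order=1, mode=mode)
    x2 = gaussian_filter1d(x, sigma, order=2, mode=mode)
    y2 = gaussian_filter1d(y, sigma, order=2, mode=mode)
    denom = (x1**2 + y1**2) ** 1.5
    return (x1 * y2 - y1 * x2) / np.maximum(denom, 1e-12)


def _local_maxima_circular(v: np.ndarray, closed: bool) -> np.ndarray:
    n = len(v)
    if closed:
        prev = np.roll(v, 1)
        nxt = np.roll(v, -1)
        return np.nonzero((v >= prev) & (v > nxt))[0]
    idx = np.nonzero((v[1:-1] >= v[:-2]) & (v[1:-1] > v[2:]))[0] + 1
    return idx


def css_feature_points(
    contour: Contour,
    sigmas: tuple = (2.0, 4.0, 6.0),
    curvature_threshold: float = 0.05,
    nms_separation: int = 5,
    persistence_window: int = 3,
) -> list[KeyPoint]:
    """Curvature-scale-space corners of one contour (orientation unset).

    Curvature kappa = (x'y'' - y'x'') / (x'^2 + y'^2)^(3/2) is evaluated on the
    chain smoothed at each scale; candidates are |kappa| local maxima above the
    threshold at the finest scale that keep |kappa| >= threshold (within a
    small index window) at every coarser scale, then thinned by non-maximum
    suppression along the chain.
    """
    sigmas = sorted(sigmas)
    n = len(contour)
    if n < 4 * max(2, int(sigmas[0])):
        return []
    x = contour.points[:, 0]
    y = contour.points[:, 1]
    mode = "wrap" if contour.closed else "reflect"
    kappas = [np.abs(_chain_curvature(x, y, s, mode)) for s in sigmas]

    base = kappas[0]
    cand = [i for i in _local_maxima_circular(base, contour.closed) if base[i] >= curvature_threshold]
    w = persistence_window
    kept = []
    for i in cand:
        ok = True
        for k in kappas[1:]:
            if contour.closed:
                window = k[(np.arange(i - w, i + w + 1)) % n]
            else:
                window = k[max(0, i - w) : min(n, i + w + 1)]
            if window.max() < curvature_threshold:
                ok = False
                break
        if ok:
            kept.append(i)

    # non-maximum suppression with minimum chain separation
    kept.sort(key=lambda i: -base[i])
    selected = []
    for i in kept:
        far = True
        for j in selected:
            d = abs(i - j)
            if contour.closed:
                d = min(d, n - d)
            if d <= nms_separation:
                far = False
                break
        if far:
            selected.append(i)
    selected.sort()

    # sub-step localization: parabolic fit of |kappa| around the peak reduces
    # the along-chain position error, which otherwise rotates the bisector by
    # kappa * delta_s radians
    xs = gaussian_filter1d(x, sigmas[0], mode=mode)
    ys = gaussian_filter1d(y, sigmas[0], mode=mode)
    out = []
    for i in selected:
        im = (i - 1) % n if contour.closed else max(i - 1, 0)
        ip = (i + 1) % n if contour.closed else min(i + 1, n - 1)
        denom = base[im] - 2 * base[i] + base[ip]
        delta = 0.5 * (base[im] - base[ip]) / denom if abs(denom) > 1e-12 else 0.0
        delta = float(np.clip(delta, -0.5, 0.5))
        j = ip if delta > 0 else im
        frac = abs(delta)
        loc = ((1 - frac) * xs[i] + frac * xs[j], (1 - frac) * ys[i] + frac * ys[j])
        out.append(
            KeyPoint(
                location=(float(loc[0]), float(loc[1])),
                contour_id=contour.id,
                contour_index=int(i),
                css_scale=float(sigmas[0]),
                curvature=float(base[i]),
            )
        )
    return out


# ---------------------------------------------------------------------------
# arms, bisector, orientation


def arm_vectors(
    points: np.ndarray, index: int, arm_length: int, closed: bool
) -> tuple[np.ndarray, np.ndarray] | None:
    """Chain-step arm vectors L = P[i-a] - P[i], R = P[i+a] - P[i].

    Indices wrap for closed contours; for open contours a point too close to
    an end (or a degenerate zero arm) returns None and the keypoint is dropped.
    """
    if arm_length < 1:
        raise ParameterError("arm_length must be >= 1")
    points = np.asarray(points, dtype=float)
    n = len(points)
    if closed:
        il = (index - arm_length) % n
        ir = (index + arm_length) % n
    else:
        il = index - arm_length
        ir = index + arm_length
        if il < 0 or ir >= n:
            return None
    left = points[il] - points[index]
    right = points[ir] - points[index]
    if np.allclose(left, 0) or np.allclose(right, 0):
        return None
    return left, right


def bisector(arm_left, arm_right) -> tuple[float, float]:
    """Angular-bisector vector v = min(|L|,|R|) * (L/|L| + R/|R|).

    Exactly anti-parallel arms give (0, 0): the degenerate straight-line case,
    which callers must drop.
    """
    L = np.asarray(arm_left, dtype=float)
    R = np.asarray(arm_right, dtype=float)
    nl = np.linalg.norm(L)
    nr = np.linalg.norm(R)
    if nl == 0 or nr == 0:
        raise ParameterError("arm vectors must be non-zero")
    v = min(nl, nr) * (L / nl + R / nr)
    return (float(v[0]), float(v[1]))


def orientation_from_bisector(x_im: float, y_im: float) -> float:
    """Map a bisector vector to its angle O in [0, 2*pi).

    Piecewise arctangent: atan(y/x) in the first quadrant, +pi for x < 0,
    +2*pi for the fourth quadrant; the x = 0 boundary goes to pi/2 or 3*pi/2
    by continuity.  Equivalent to atan2(y, x) mod 2*pi.
    """
    if x_im == 0.0 and y_im == 0.0:
        raise ParameterError("zero bisector vector has no orientation")
    if x_im == 0.0:
        return math.pi / 2.0 if y_im > 0 else 3.0 * math.pi / 2.0
    t = math.atan(y_im / x_im)
    if y_im >= 0 and x_im > 0:
        o = t
    elif x_im < 0:
        o = t + math.pi
    else:  # y < 0, x > 0
        o = t + TWO_PI
    return o % TWO_PI


# ---------------------------------------------------------------------------
# composition


def detect_and_orient(
    S: FeatureMap,
    threshold_rule: str = "zero-crossing",
    min_length: int = 40,
    percentile: float = 98.0,
    sigmas: tuple = (2.0, 4.0, 6.0),
    curvature_threshold: float = 0.05,
    nms_separation: int = 5,
    arm_length: int = 20,
) -> list[KeyPoint]:
    """Full keypoint stage: contours -> CSS corners -> bisector orientations.

    Arms are measured on the chain smoothed at the CSS base scale; raw pixel
    quantization would alone contribute several degrees of orientation noise.
    Degenerate (straight-line) corners are dropped, so every returned keypoint
    carries a valid orientation in [0, 2*pi).
    """
    contours = extract_contours(S, threshold_rule, min_length, percentile)
    return orient_keypoints_on_contours(
        contours, sigmas, curvature_threshold, nms_separation, arm_length
    )
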