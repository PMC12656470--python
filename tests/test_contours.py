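"""Contour extraction, CSS corners, bisector main orientations."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from gocao.contours import (
    Contour,
    arm_vectors,
    bisector,
    css_feature_points,
    detect_and_orient,
    extract_contours,
    orientation_from_bisector,
)
from gocao.exceptions import ParameterError
from gocao.filters import FeatureMap
from gocao.matching import feature_pipeline


def circ_diff_deg(a, b):
    d = abs(math.degrees(a - b)) % 360.0
    return min(d, 360.0 - d)


class TestExtractContours:
    def test_filled_disk_single_contour_on_circle(self, disk_image):
        _, S = feature_pipeline(disk_image)
        contours = extract_contours(S)
        assert len(contours) == 1
        d = np.hypot(contours[0].points[:, 0] - 80, contours[0].points[:, 1] - 80)
        assert np.all(np.abs(d - 45) <= 2.0)
        assert contours[0].closed

    def test_blank_map_no_contours(self):
        S = FeatureMap(np.zeros((64, 64)), "ordinal-S")
        assert extract_contours(S) == []

    def test_two_separated_rectangles_two_contours(self):
        img = np.full((200, 360), 0.3)
        img[40:110, 40:140] = 0.9
        img[90:160, 220:320] = 0.9
        _, S = feature_pipeline(img)
        contours = extract_contours(S)
        assert len(contours) == 2
        # one contour per rectangle: split by mean x
        means = sorted(c.points[:, 0].mean() for c in contours)
        assert means[0] < 180 < means[1]

    def test_ordered_by_descending_length(self, synthetic_pair):
        vis, _, _ = synthetic_pair
        _, S = feature_pipeline(vis)
        contours = extract_contours(S)
        lengths = [len(c) for c in contours]
        assert lengths == sorted(lengths, reverse=True)

    def test_unknown_rule_rejected(self):
        S = FeatureMap(np.zeros((16, 16)), "ordinal-S")
        with pytest.raises(ParameterError):
            extract_contours(S, threshold_rule="nope")


class TestCssFeaturePoints:
    @staticmethod
    def _chain(points):
        return Contour(id=1, points=np.asarray(points, dtype=float), closed=False)

    def test_right_angle_corner_detected_at_apex(self):
        n = 60
        pts = [(i, 0.0) for i in range(n)] + [(n - 1, float(j)) for j in range(1, n)]
        kps = css_feature_points(self._chain(pts))
        assert len(kps) == 1
        assert abs(kps[0].contour_index - (n - 1)) <= 2

    def test_straight_line_no_corners(self):
        pts = [(float(i), 2.0 * i) for i in range(80)]
        assert css_feature_points(self._chain(pts)) == []

    def test_square_contour_four_corners(self):
        side = 40
        pts = (
            [(i, 0) for i in range(side)]
            + [(side, i) for i in range(side)]
            + [(side - i, side) for i in range(side)]
            + [(0, side - i) for i in range(side)]
        )
        contour = Contour(id=1, points=np.asarray(pts, dtype=float), closed=True)
        kps = css_feature_points(contour)
        assert len(kps) == 4

    def test_short_contour_empty(self):
        assert css_feature_points(self._chain([(0, 0), (1, 1), (2, 2)])) == []


class TestArmVectors:
    def test_corner_arms_along_segments(self):
        pts = np.array([(i, 0.0) for i in range(6)] + [(5.0, j) for j in range(1, 6)])
        arms = arm_vectors(pts, 5, 4, closed=False)
        assert arms is not None
        left, right = arms
        assert np.allclose(left, (-4, 0))
        assert np.allclose(right, (0, 4))

    def test_straight_chain_arms_antiparallel(self):
        pts = np.array([(float(i), float(i)) for i in range(20)])
        left, right = arm_vectors(pts, 10, 5, closed=False)
        assert np.allclose(left, -right)

    def test_closed_square_corner_arms_on_sides(self):
        side = 10
        pts = np.array(
            [(i, 0) for i in range(side)]
            + [(side, i) for i in range(side)]
            + [(side - i, side) for i in range(side)]
            + [(0, side - i) for i in range(side)],
            dtype=float,
        )
        left, right = arm_vectors(pts, 0, 3, closed=True)
        assert np.allclose(left, (0, 3))   # wraps onto the left vertical side
        assert np.allclose(right, (3, 0))  # along the top side

    def test_open_chain_end_returns_none(self):
        pts = np.array([(float(i), 0.0) for i in range(10)])
        assert arm_vectors(pts, 1, 5, closed=False) is None


class TestBisector:
    def test_unit_arms(self):
        assert bisector((1, 0), (0, 1)) == pytest.approx((1.0, 1.0))

    def test_unequal_arms_scaled_by_shorter(self):
        # min(2,1) * ((1,0) + (0,1)) per the bisector definition
        assert bisector((2, 0), (0, 1)) == pytest.approx((1.0, 1.0))

    def test_antiparallel_degenerate_zero(self):
        v = bisector((1, 0), (-1, 0))
        assert math.hypot(*v) < 1e-12

    def test_zero_arm_rejected(self):
        with pytest.raises(ParameterError):
            bisector((0, 0), (1, 0))


class TestOrientationFromBisector:
    @pytest.mark.parametrize("vec,expected", [
        ((1, 1), math.pi / 4),          # first quadrant: atan(y/x)
        ((-1, 0), math.pi),             # x < 0: atan + pi
        ((1, -1), 7 * math.pi / 4),     # fourth quadrant: atan + 2 pi
        ((0, 1), math.pi / 2),          # boundary by continuity
        ((0, -1), 3 * math.pi / 2),
    ])
    def test_piecewise_cases(self, vec, expected):
        assert orientation_from_bisector(*vec) == pytest.approx(expected)

    def test_zero_vector_rejected(self):
        with pytest.raises(ParameterError):
            orientation_from_bisector(0.0, 0.0)

    @given(st.floats(-10, 10), st.floats(-10, 10))
    def test_equals_atan2_mod_2pi(self, x, y):
        if x == 0 and y == 0:
            return
        expected = math.atan2(y, x) % (2 * math.pi)
        assert circ_diff_deg(orientation_from_bisector(x, y), expected) < 1e-9

    def test_oracle_equivalence_on_random_grid(self):
        rng = np.random.default_rng(0)
        pts = rng.uniform(-5, 5, size=(1000, 2))
        pts = pts[np.linalg.norm(pts, axis=1) > 1e-3]
        for x, y in pts:
            o = orientation_from_bisector(x, y)
            assert 0 <= o < 2 * math.pi
            assert abs(o - math.atan2(y, x) % (2 * math.pi)) < 1e-9


class TestDetectAndOrient:
    def test_square_orientations_along_diagonals(self, square_maps):
        _, S = square_maps
        kps = detect_and_orient(S)
        corner_kps = [k for k in kps if k.curvature > 0.1]
        assert len(corner_kps) >= 4
        for kp in corner_kps:
            err = min(
                circ_diff_deg(kp.orientation, math.pi / 4 + k * math.pi / 2)
                for k in range(4)
            )
            assert err < 5.0

    def test_rotation_shifts_orientations(self, square_image):
        from scipy.ndimage import rotate
        from scipy.spatial import cKDTree

        deg = 30.0
        th = math.radians(deg)
        rotated = rotate(square_image, deg, reshape=True, order=3,
                         mode="constant", cval=0.35)
        k1 = detect_and_orient(feature_pipeline(square_image)[1])
        k2 = detect_and_orient(feature_pipeline(rotated)[1])
        h, w = square_image.shape
        h2, w2 = rotated.shape
        R = np.array([[math.cos(th), math.sin(th)], [-math.sin(th), math.cos(th)]])
        p1 = np.array([k.location for k in k1]) - [(w - 1) / 2, (h - 1) / 2]
        mapped = (R @ p1.T).T + [(w2 - 1) / 2, (h2 - 1) / 2]
        p2 = np.array([k.location for k in k2])
        d, idx = cKDTree(p2).query(mapped)
        matched = [(k1[a], k2[idx[a]]) for a in np.nonzero(d <= 3)[0]]
        assert len(matched) >= 4
        errs = [circ_diff_deg(a.orientation - th, b.orientation) for a, b in matched]
        assert np.mean(np.array(errs) < 5.0) >= 0.9

    def test_blank_image_empty(self):
        S = FeatureMap(np.zeros((64, 64)), "ordinal-S")
        assert detect_and_orient(S) == []

    def test_scale_robustness_of_keypoint_count(self, synthetic_pair):
        vis, _, _ = synthetic_pair
        half = vis[::2, ::2]
        n_full = len(detect_and_orient(feature_pipeline(vis)[1]))
        n_half = len(detect_and_orient(feature_pipeline(half)[1]))
        assert n_full > 0 and n_half > 0
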