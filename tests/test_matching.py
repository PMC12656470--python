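"""Bilateral matching, RANSAC similarity recovery, fine refinement."""

import math

import numpy as np
import pytest

from gocao.contours import KeyPoint
from gocao.descriptors import Descriptor
from gocao.exceptions import ParameterError, RegistrationError
from gocao.filters import FeatureMap
from gocao.matching import (
    Match,
    Transform,
    bilateral_match,
    fit_similarity,
    ransac_similarity,
    refine_matches,
    register_pair,
)


def _desc(vec, x=0.0, y=0.0):
    vec = np.asarray(vec, dtype=float)
    vec = vec / np.linalg.norm(vec)
    kp = KeyPoint(location=(x, y), contour_id=1, contour_index=0, orientation=0.0)
    return Descriptor(vector=vec, keypoint=kp, scale=8.0)


def _rand_descs(rng, n, dim=16):
    return [_desc(rng.random(dim), x=i, y=i) for i in range(n)]


class TestTransform:
    def test_apply_inverse_roundtrip(self):
        t = Transform(2.0, 0.5, 10.0, -5.0)
        pts = np.array([[1.0, 2.0], [-3.0, 4.0], [0.0, 0.0]])
        assert np.allclose(t.inverse().apply(t.apply(pts)), pts, atol=1e-12)

    def test_compose_matches_sequential_application(self):
        a = Transform(1.5, 0.3, 2.0, 3.0)
        b = Transform(0.8, -0.2, -1.0, 4.0)
        pts = np.array([[1.0, 1.0], [5.0, -2.0]])
        assert np.allclose(a.compose(b).apply(pts), a.apply(b.apply(pts)), atol=1e-12)

    def test_nonpositive_scale_rejected(self):
        with pytest.raises(ParameterError):
            Transform(0.0, 0.0, 0.0, 0.0)


class TestBilateralMatch:
    def test_identical_sets_identity_matching(self):
        rng = np.random.default_rng(0)
        descs = _rand_descs(rng, 8)
        matches = bilateral_match(descs, descs, ratio=1.0)
        assert len(matches) == 8
        assert all(m.distance == pytest.approx(0.0) for m in matches)
        assert all(m.ir_point == m.vis_point for m in matches)

    def test_mutuality_stricter_than_one_directional(self):
        # brute-force oracle: mutual pairs are a subset of IR->vis nearest pairs
        rng = np.random.default_rng(1)
        a = _rand_descs(rng, 10)
        b = _rand_descs(rng, 10)
        D = np.array([[np.linalg.norm(x.vector - y.vector) for y in b] for x in a])
        one_dir = {(i, int(np.argmin(D[i]))) for i in range(10)}
        mutual = {(i, j) for i, j in one_dir if int(np.argmin(D[:, j])) == i}
        matches = bilateral_match(a, b, ratio=1.0)
        got = {(m.ir_index, m.vis_index) for m in matches}
        assert got == mutual
        assert len(mutual) <= len(one_dir)

    def test_zero_ratio_empty(self):
        rng = np.random.default_rng(2)
        assert bilateral_match(_rand_descs(rng, 5), _rand_descs(rng, 5), ratio=0.0) == []

    def test_empty_input_empty_output(self):
        rng = np.random.default_rng(3)
        assert bilateral_match([], _rand_descs(rng, 3)) == []

    def test_one_match_per_keypoint_best_scale_wins(self):
        rng = np.random.default_rng(4)
        kp_v = KeyPoint(location=(5, 5), contour_id=1, contour_index=0, orientation=0.0)
        base = rng.random(16)
        # two visible descriptors of the same keypoint at different scales
        dv = [Descriptor(base / np.linalg.norm(base), kp_v, 8.0),
              Descriptor((base + 0.01) / np.linalg.norm(base + 0.01), kp_v, 16.0)]
        di = [_desc(base)]
        matches = bilateral_match(di, dv, ratio=1.0)
        assert len(matches) == 1


def _planted_matches(rng, n, transform, noise=0.0, n_outliers=0):
    src = rng.uniform(0, 100, size=(n, 2))
    dst = transform.apply(src)
    if noise:
        dst = dst + rng.normal(0, noise, size=dst.shape)
    matches = [Match(tuple(s), tuple(d), 0.1) for s, d in zip(src, dst)]
    for _ in range(n_outliers):
        matches.append(Match(tuple(rng.uniform(0, 100, 2)), tuple(rng.uniform(0, 300, 2)), 0.1))
    return matches


class TestRansacSimilarity:
    def test_exact_recovery_without_outliers(self):
        rng = np.random.default_rng(5)
        true = Transform(2.0, math.radians(30), 10.0, -5.0)
        matches = _planted_matches(rng, 20, true)
        t, inliers = ransac_similarity(matches, inlier_tol=3.0, iterations=500, seed=0)
        assert t.scale == pytest.approx(true.scale, abs=1e-6)
        assert t.rotation == pytest.approx(true.rotation, abs=1e-6)
        assert t.tx == pytest.approx(true.tx, abs=1e-6)
        assert t.ty == pytest.approx(true.ty, abs=1e-6)
        assert len(inliers) == 20
        assert all(m.stage == "rough" and m.inlier for m in inliers)

    def test_recovery_with_forty_percent_outliers(self):
        rng = np.random.default_rng(6)
        true = Transform(2.0, math.radians(30), 10.0, -5.0)
        matches = _planted_matches(rng, 20, true, n_outliers=13)  # ~40%
        t, inliers = ransac_similarity(matches, inlier_tol=3.0, iterations=2000, seed=1)
        assert len([m for m in inliers]) >= 20
        assert t.scale == pytest.approx(true.scale, rel=0.01)
        assert abs(math.degrees(t.rotation - true.rotation)) < 0.5
        assert abs(t.tx - true.tx) < 0.5 and abs(t.ty - true.ty) < 0.5

    def test_identity_correspondences_identity_transform(self):
        rng = np.random.default_rng(7)
        matches = _planted_matches(rng, 10, Transform(1.0, 0.0, 0.0, 0.0))
        t, _ = ransac_similarity(matches, inlier_tol=1.0, iterations=100, seed=0)
        assert t.scale == pytest.approx(1.0, abs=1e-9)
        assert abs(t.rotation) < 1e-9
        assert abs(t.tx) < 1e-9 and abs(t.ty) < 1e-9

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(8)
        true = Transform(1.5, 0.2, 3.0, 4.0)
        matches = _planted_matches(rng, 15, true, noise=0.5, n_outliers=5)
        r1 = ransac_similarity(matches, 3.0, 500, seed=42)
        r2 = ransac_similarity(matches, 3.0, 500, seed=42)
        assert r1[0].as_dict() == r2[0].as_dict()
        assert [(m.ir_point, m.vis_point) for m in r1[1]] == \
               [(m.ir_point, m.vis_point) for m in r2[1]]

    def test_too_few_matches_raises(self):
        with pytest.raises(RegistrationError):
            ransac_similarity([Match((0, 0), (0, 0), 0.0)], 3.0, 10, 0)

    def test_small_consensus_flagged_as_failure(self):
        rng = np.random.default_rng(9)
        # pure noise: no similarity explains 4+ of these
        matches = [Match(tuple(rng.uniform(0, 100, 2)), tuple(rng.uniform(0, 1000, 2)), 0.1)
                   for _ in range(8)]
        with pytest.raises(RegistrationError):
            ransac_similarity(matches, inlier_tol=0.05, iterations=200, seed=0)


class TestRefineMatches:
    @staticmethod
    def _warped_pair(rng, transform, shape=(200, 200)):
        """A textured map and its exact warp under ``transform``."""
        from scipy.ndimage import gaussian_filter, map_coordinates

        base = gaussian_filter(rng.standard_normal(shape), 3.0)
        yy, xx = np.mgrid[: shape[0], : shape[1]].astype(float)
        pts = transform.inverse().apply(np.column_stack([xx.ravel(), yy.ravel()]))
        warped = map_coordinates(base, [pts[:, 1], pts[:, 0]], order=1, mode="nearest")
        return (FeatureMap(base, "ordinal-S"),
                FeatureMap(warped.reshape(shape), "ordinal-S"))

    def test_exact_rough_locations_stay_put(self):
        rng = np.random.default_rng(10)
        t = Transform(1.0, 0.0, 0.0, 0.0)
        m_ir, m_vis = self._warped_pair(rng, t)
        pts = rng.uniform(60, 140, size=(6, 2))
        rough = [Match(tuple(p), tuple(p), 0.1, "rough", True) for p in pts]
        fine, t2, refined = refine_matches(rough, t, m_ir, m_vis, smooth_sigma=0)
        moved = np.array([np.hypot(f.vis_point[0] - r.vis_point[0],
                                   f.vis_point[1] - r.vis_point[1])
                          for f, r in zip(fine, rough)])
        assert np.all(moved <= 1.0)

    def test_planted_perturbation_reduced(self):
        # rough visible locations perturbed by up to +-3 px on an exactly
        # warped pair; the transform is fit from the perturbed pairs as in the
        # rough stage.  Refinement must not worsen the point RMSE to ground
        # truth and must strictly improve the recovered transform.
        rng = np.random.default_rng(11)
        t = Transform(1.0, 0.0, 5.0, -3.0)
        m_ir, m_vis = self._warped_pair(rng, t)
        src = rng.uniform(60, 140, size=(8, 2))
        true_dst = t.apply(src)
        perturbed = true_dst + rng.uniform(-3, 3, size=true_dst.shape)
        rough = [Match(tuple(s), tuple(d), 0.1, "rough", True)
                 for s, d in zip(src, perturbed)]
        t_fit = fit_similarity(src, perturbed)
        fine, t_ref, refined = refine_matches(rough, t_fit, m_ir, m_vis, smooth_sigma=0)
        assert refined
        before = np.linalg.norm(perturbed - true_dst, axis=1).mean()
        after = np.linalg.norm(np.array([m.vis_point for m in fine]) - true_dst, axis=1).mean()
        assert after <= before
        grid = rng.uniform(60, 140, size=(50, 2))
        err_fit = np.linalg.norm(t_fit.apply(grid) - t.apply(grid), axis=1).mean()
        err_ref = np.linalg.norm(t_ref.apply(grid) - t.apply(grid), axis=1).mean()
        assert err_ref < err_fit

    def test_flat_maps_left_unrefined(self):
        flat = FeatureMap(np.zeros((100, 100)), "ordinal-S")
        t = Transform(1.0, 0.0, 0.0, 0.0)
        rough = [Match((50, 50), (52, 50), 0.1, "rough", True),
                 Match((30, 60), (30, 62), 0.1, "rough", True)]
        fine, _, _ = refine_matches(rough, t, flat, flat, smooth_sigma=0)
        assert [m.vis_point for m in fine] == [m.vis_point for m in rough]

    def test_residual_never_exceeds_tolerance_bound(self, registered_pair):
        # the enforced guard: the fine stage's mean pair residual stays within
        # max(rough residual, RANSAC inlier tolerance)
        result, _ = registered_pair
        rough = [m for m in result.matches if m.stage == "rough"]
        fine = [m for m in result.matches if m.stage == "fine"]
        src = np.array([m.ir_point for m in rough])
        dst = np.array([m.vis_point for m in rough])
        fdst = np.array([m.vis_point for m in fine])
        # recompute the rough-stage transform for the bound
        rough_t = fit_similarity(src, dst)
        err_rough = np.linalg.norm(rough_t.apply(src) - dst, axis=1).mean()
        err_fine = np.linalg.norm(result.transform.apply(src) - fdst, axis=1).mean()
        assert err_fine <= max(err_rough, 5.0) + 1e-9


class TestRegisterPair:
    def test_self_registration_is_identity(self, synthetic_pair):
        vis, _, _ = synthetic_pair
        result = register_pair(vis, vis, seed=0)
        t = result.composite_transform
        assert t.scale == pytest.approx(1.0, abs=0.02)
        assert abs(math.degrees(t.rotation)) < 1.0
        assert math.hypot(t.tx, t.ty) < 2.0

    def test_blank_pair_fails_cleanly(self):
        blank = np.full((120, 160), 0.5)
        with pytest.raises(RegistrationError):
            register_pair(blank, np.full((60, 80), 0.5), seed=0)

    def test_recovers_planted_composite_scale(self, registered_pair):
        result, truth = registered_pair
        assert result.composite_transform.scale == pytest.approx(
            truth.transform.scale, rel=0.05
        )

    def test_log_reports_every_stage(self, registered_pair):
        result, _ = registered_pair
        for key in ("keypoints_vis", "keypoints_ir", "descriptors_vis",
                    "descriptors_ir", "matches_bilateral", "matches_rough",
                    "matches_fine"):
            assert key in result.log

    def test_forward_backward_scales_are_inverse(self, synthetic_pair):
        # modality-style symmetry on same-size frames: a contrast-reversed,
        # blurred, similarity-warped copy registered both ways
        from scipy.ndimage import gaussian_filter, map_coordinates

        vis, _, _ = synthetic_pair
        t = Transform(1.08, 0.05, 8.0, -6.0)
        h, w = vis.shape
        yy, xx = np.mgrid[:h, :w].astype(float)
        pts = t.apply(np.column_stack([xx.ravel(), yy.ravel()]))
        other = map_coordinates(vis, [pts[:, 1], pts[:, 0]], order=1, mode="nearest")
        other = gaussian_filter(1.0 - other.reshape(h, w), 3.0)
        fwd = register_pair(vis, other, seed=0)
        bwd = register_pair(other, vis, seed=0)
        assert fwd.composite_transform.scale * bwd.composite_transform.scale == \
            pytest.approx(1.0, abs=0.02)
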