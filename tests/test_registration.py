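import math

import numpy as np
import pytest
from skimage.transform import ProjectiveTransform

from retinareg.registration import (
    RegistrationConfig,
    RegistrationStatus,
    compute_descriptors,
    estimate_homography,
    extract_keypoints,
    match_descriptors,
    register_pair,
    transform_point,
    transform_points,
    warp_image,
)
from retinareg.synthetic import (
    VascularTreeParams,
    generate_pair,
    generate_vascular_tree,
    render_fundus,
)
from retinareg.types import FundusImage, Homography, JunctionPoint

from conftest import control_point_error


def _textured_image(seed=0, n=128):
    rng = np.random.default_rng(seed)
    from scipy import ndimage

    img = ndimage.gaussian_filter(rng.normal(0, 1, (n, n)), 2.0)
    img = (img - img.min()) / np.ptp(img)
    return img


class TestKeypoints:
    def test_no_junctions_no_keypoints(self, fundus):
        assert extract_keypoints([], fundus) == []

    def test_radius_zero_one_keypoint_per_interior_junction(self, fundus):
        pts = [JunctionPoint(100, 100), JunctionPoint(140, 120)]
        kps = extract_keypoints(pts, fundus, radius=0)
        assert len(kps) == 2

    def test_border_junction_skipped(self, fundus):
        kps = extract_keypoints([JunctionPoint(2, 2)], fundus)
        assert kps == []

    def test_rotation_rotates_dominant_orientation(self):
        """Rotating the patch by 90 degrees shifts each keypoint's
        orientation by 90 degrees up to the histogram bin width."""
        img = _textured_image(3)
        rot = np.rot90(img)  # CCW in array sense
        n = img.shape[0]
        r, c = 60, 70
        (kp,) = extract_keypoints([JunctionPoint(r, c)], img, radius=0)
        (kp_rot,) = extract_keypoints(
            [JunctionPoint(n - 1 - c, r)], rot, radius=0
        )
        bin_w = 2 * math.pi / 36
        delta = (kp_rot.orientation - kp.orientation) % (2 * math.pi)
        # array-sense CCW rotation is a -90 degree rotation of (x, y) axes
        assert min(abs(delta - 3 * math.pi / 2), abs(delta - 3 * math.pi / 2 - 2 * math.pi),
                   abs(delta + math.pi / 2)) <= bin_w + 1e-6


class TestDescriptors:
    def test_unit_norm_and_determinism(self):
        img = _textured_image(1)
        kps = extract_keypoints([JunctionPoint(60, 60), JunctionPoint(70, 50)], img)
        d1, k1 = compute_descriptors(img, kps)
        d2, _ = compute_descriptors(img, kps)
        assert d1.shape[1] == 128
        np.testing.assert_allclose(np.linalg.norm(d1, axis=1), 1.0, atol=1e-6)
        np.testing.assert_array_equal(d1, d2)

    def test_flat_patch_dropped(self):
        img = np.full((128, 128), 0.5)
        kps = extract_keypoints([JunctionPoint(64, 64)], img, radius=0)
        descs, kept = compute_descriptors(img, kps)
        assert len(descs) == 0 and kept == []

    def test_rotation_invariance_within_tolerance(self):
        """The same patch rotated by 90 degrees yields a descriptor within
        0.2 Euclidean distance (orientation-relative binning)."""
        img = _textured_image(5)
        n = img.shape[0]
        r, c = 64, 64
        rot = np.rot90(img)
        kps_a = extract_keypoints([JunctionPoint(r, c)], img, radius=0)
        kps_b = extract_keypoints([JunctionPoint(n - 1 - c, r)], rot, radius=0)
        da, _ = compute_descriptors(img, kps_a)
        db, _ = compute_descriptors(rot, kps_b)
        assert np.linalg.norm(da[0] - db[0]) <= 0.2


class TestMatching:
    def _descs(self, rows):
        return np.asarray(rows, dtype=float)

    def test_clear_accept(self):
        ref = self._descs([[0.0, 0.0]])
        sen = self._descs([[0.5, 0.0], [1.0, 0.0]])
        (m,) = match_descriptors(ref, sen)
        assert m.ratio == pytest.approx(0.5)

    def test_clear_reject(self):
        ref = self._descs([[0.0, 0.0]])
        sen = self._descs([[0.9, 0.0], [1.0, 0.0]])
        assert match_descriptors(ref, sen) == []

    def test_tie_rejected(self):
        ref = self._descs([[0.0, 0.0]])
        sen = self._descs([[1.0, 0.0], [1.0, 0.0]])
        assert match_descriptors(ref, sen) == []

    def test_one_to_one(self):
        ref = self._descs([[0.1, 0.0], [0.2, 0.0], [5.0, 5.0]])
        sen = self._descs([[0.0, 0.0], [10.0, 10.0], [20.0, 0.0]])
        matches = match_descriptors(ref, sen, ratio_threshold=0.9)
        sensed = [m.sensed_index for m in matches]
        assert len(sensed) == len(set(sensed))

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(0)
        ref = rng.normal(0, 1, (20, 8))
        sen = rng.normal(0, 1, (25, 8))
        tight = {(m.ref_index, m.sensed_index) for m in match_descriptors(ref, sen, 0.6)}
        loose = {(m.ref_index, m.sensed_index) for m in match_descriptors(ref, sen, 0.9)}
        assert tight <= loose

    def test_too_few_sensed_rejected(self):
        with pytest.raises(ValueError):
            match_descriptors(np.zeros((1, 8)), np.zeros((1, 8)))


class TestHomographyOps:
    def test_identity(self):
        h = Homography.identity()
        assert transform_point(h, (3.0, 4.0)) == pytest.approx((3.0, 4.0))

    def test_translation(self):
        m = np.eye(3)
        m[0, 2], m[1, 2] = 10.0, -5.0
        assert transform_point(Homography(m), (3, 4)) == pytest.approx((13.0, -1.0))

    def test_perspective_hand_case(self):
        m = np.eye(3)
        m[2, 0] = 0.001
        a, b = transform_point(Homography(m), (100.0, 0.0))
        assert a == pytest.approx(100.0 / 1.1, abs=1e-9)
        assert b == pytest.approx(0.0, abs=1e-12)

    def test_horizon_point_raises(self):
        m = np.eye(3)
        m[2, 0] = -0.01
        with pytest.raises(ZeroDivisionError):
            transform_point(Homography(m), (100.0, 0.0))

    def test_round_trip_through_inverse(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            m = np.eye(3) + rng.normal(0, 0.1, (3, 3)) * np.array(
                [[1, 1, 10], [1, 1, 10], [1e-4, 1e-4, 0]]
            )
            h = Homography(m)
            pts = rng.uniform(0, 200, (10, 2))
            back = transform_points(h.inverse(), transform_points(h, pts))
            np.testing.assert_allclose(back, pts, atol=1e-9)


class TestEstimateHomography:
    def test_four_exact_points_recovered_exactly(self):
        h_true = np.array([[1.02, 0.05, 12.0], [-0.03, 0.98, -7.0], [1e-5, -2e-5, 1.0]])
        sensed = np.array([[10.0, 10], [200, 15], [30, 180], [190, 210]])
        ref = transform_points(Homography(h_true), sensed)
        h, inl, status = estimate_homography(ref, sensed)
        assert status is RegistrationStatus.OK
        np.testing.assert_allclose(
            transform_points(h, sensed), ref, atol=1e-6
        )

    @pytest.mark.parametrize("seed", range(5))
    def test_robust_to_forty_percent_outliers(self, seed):
        rng = np.random.default_rng(seed)
        h_true = Homography(
            np.array([[1.01, 0.03, 8.0], [-0.02, 0.99, -4.0], [1e-5, 1e-5, 1.0]])
        )
        sensed = rng.uniform(20, 230, (60, 2))
        ref = transform_points(h_true, sensed)
        n_out = 24
        ref[:n_out] += rng.uniform(30, 80, (n_out, 2)) * rng.choice([-1, 1], (n_out, 2))
        h, inliers, status = estimate_homography(ref, sensed, seed=seed)
        assert status is RegistrationStatus.OK
        true_in = np.arange(60) >= n_out
        err = np.hypot(*(transform_points(h, sensed[true_in]) - ref[true_in]).T)
        assert err.mean() <= 1.0

    def test_collinear_points_degenerate(self):
        sensed = np.stack([np.arange(10.0), np.arange(10.0)], axis=1)
        ref = sensed + 5.0
        h, _, status = estimate_homography(ref, sensed)
        assert status is RegistrationStatus.DEGENERATE

    def test_too_few_matches(self):
        h, _, status = estimate_homography(np.zeros((3, 2)), np.zeros((3, 2)))
        assert status is RegistrationStatus.INSUFFICIENT_MATCHES


class TestWarp:
    def test_identity_warp(self, fundus):
        out = warp_image(Homography.identity(), fundus)
        np.testing.assert_array_equal(out.pixels, fundus.pixels)

    def test_translation_shifts_columns(self, fundus):
        m = np.eye(3)
        m[0, 2] = 10.0  # sensed x + 10 = reference x
        out = warp_image(Homography(m), fundus)
        np.testing.assert_array_equal(
            out.pixels[:, 50:200], fundus.pixels[:, 40:190]
        )

    def test_warp_with_true_homography_aligns_pair(self, pair):
        """Warping the sensed frame by the true homography reproduces the
        reference up to rendering noise inside the shared footprint."""
        warped = warp_image(pair.true_H, pair.sensed_image, pair.ref_image.pixels.shape)
        both = (warped.pixels > 0) & (pair.ref_image.pixels > 0)
        diff = np.abs(
            warped.pixels.astype(float) - pair.ref_image.pixels.astype(float)
        )[both]
        # bounded by the independent texture/noise of the two renderings
        assert diff.mean() < 25.0
        # geometric check free of texture: the warped sensed mask must
        # coincide with the reference mask almost everywhere
        warped_mask = warp_image(
            pair.true_H,
            FundusImage(pair.true_mask_sensed.mask.astype(np.float64)),
            pair.ref_image.pixels.shape,
        )
        a = warped_mask.pixels > 0.5
        b = pair.true_mask_ref.mask == 1
        dice = 2 * (a & b).sum() / (a.sum() + b.sum())
        assert dice >= 0.8


class TestRegisterPair:
    def test_self_registration_is_near_identity(self, tree, fundus):
        mask, _ = tree
        res = register_pair(fundus, fundus, ref_mask=mask, sensed_mask=mask)
        assert res.status is RegistrationStatus.OK
        pts = np.array([[50.0, 50], [200, 60], [60, 200], [180, 190]])
        err = np.hypot(*(transform_points(res.homography, pts) - pts).T)
        assert err.mean() <= 0.5

    def test_synthetic_pair_registers_accurately(self, pair):
        res = register_pair(
            pair.ref_image, pair.sensed_image,
            ref_mask=pair.true_mask_ref, sensed_mask=pair.true_mask_sensed,
        )
        assert res.status is RegistrationStatus.OK
        assert control_point_error(pair, res.homography) <= 2.0

    def test_unrelated_phantoms_do_not_silently_succeed(self):
        a = generate_pair(VascularTreeParams(seed=21), seed=21)
        b = generate_pair(VascularTreeParams(seed=77), seed=77)
        res = register_pair(
            a.ref_image, b.ref_image,
            ref_mask=a.true_mask_ref, sensed_mask=b.true_mask_ref,
        )
        if res.status is RegistrationStatus.OK:
            # wildly wrong geometry must show up as a large error
            pts = np.array([[60.0, 60], [200, 60], [60, 200], [190, 190]])
            err = np.hypot(*(transform_points(res.homography, pts) - pts).T)
            assert err.mean() >= 25.0

    def test_registration_against_external_projective_oracle(self, pair):
        """Cross-check: our recovered matrix agrees with scikit-image's
        independent projective mapping of the matched inlier points."""
        res = register_pair(
            pair.ref_image, pair.sensed_image,
            ref_mask=pair.true_mask_ref, sensed_mask=pair.true_mask_sensed,
        )
        assert res.status is RegistrationStatus.OK
        tf = ProjectiveTransform(matrix=res.homography.matrix)
        pts = np.array([[60.0, 60], [180, 70], [70, 180]])
        np.testing.assert_allclose(tf(pts), transform_points(res.homography, pts), atol=1e-9)
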