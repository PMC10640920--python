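"""Eye-region geometry, iris segmentation, and centroid estimation."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from gave.eye_image import (
    EyeRegion,
    FaceLandmarks,
    InvalidLandmarksError,
    IrisSegParams,
    PupilNotFoundError,
    SegmentationError,
    extract_eye_regions,
    pupil_center,
    segment_iris,
)
from gave.synthetic import EyeImageSpec, generate_eye_image


def region_for_image(img, lm6):
    """EyeRegion over a whole single-eye image, refs from the 6 landmarks."""
    return EyeRegion(
        crop=img,
        origin=(0, 0),
        corner_x_min=float(lm6[0, 0]),
        corner_x_max=float(lm6[3, 0]),
        eyelid_y_min=float((lm6[1, 1] + lm6[2, 1]) / 2),
        eyelid_y_max=float((lm6[4, 1] + lm6[5, 1]) / 2),
    )


class TestFaceLandmarks:
    def test_requires_68_points(self):
        with pytest.raises(InvalidLandmarksError):
            FaceLandmarks(points=np.zeros((67, 2)))

    def test_degenerate_eye_hull_rejected(self, landmarks68):
        pts = landmarks68.copy()
        pts[36:42, 1] = 125.0  # collinear left-eye landmarks
        with pytest.raises(InvalidLandmarksError):
            FaceLandmarks(points=pts)


class TestExtractEyeRegions:
    def test_reference_coordinates(self, landmarks68):
        img = np.full((300, 320), 150, dtype=np.uint8)
        left, right = extract_eye_regions(img, FaceLandmarks(landmarks68))
        assert left.corner_x_min == 100 and left.corner_x_max == 140
        # eyelid refs are the midpoints of the two lid landmarks per lid
        assert left.eyelid_y_min == pytest.approx(119.0)
        assert left.eyelid_y_max == pytest.approx(131.0)
        assert right.corner_x_min == 180 and right.corner_x_max == 220

    def test_crop_clamped_to_frame(self, landmarks68):
        pts = landmarks68 - [58, 116]  # push the left eye to the frame edge
        pts = np.clip(pts, 0, None)
        img = np.full((120, 250), 150, dtype=np.uint8)
        left, _ = extract_eye_regions(img, FaceLandmarks(pts), margin=10)
        x0, y0 = left.origin
        assert x0 >= 0 and y0 >= 0
        assert left.crop.shape[0] <= img.shape[0] and left.crop.shape[1] <= img.shape[1]

    def test_out_of_frame_landmarks_rejected(self, landmarks68):
        img = np.full((100, 100), 150, dtype=np.uint8)
        with pytest.raises(InvalidLandmarksError):
            extract_eye_regions(img, FaceLandmarks(landmarks68))


class TestSegmentIris:
    def test_synthetic_disc_matches_threshold_classification(self):
        spec = EyeImageSpec(noise_sd=0.0)
        img, gt = generate_eye_image(spec)
        region = region_for_image(img, gt.landmarks)
        mask = segment_iris(region, IrisSegParams(binary_threshold=128))
        # oracle: exhaustive pixel classification at the threshold; the
        # filter chain may only move the boundary by the erosion margin
        oracle = img < 128
        grown = np.zeros_like(oracle)
        margin = 3 * 1 + 5  # erosion growth + bilateral window reach
        ys, xs = np.nonzero(oracle)
        y0, y1 = ys.min() - margin, ys.max() + margin
        x0, x1 = xs.min() - margin, xs.max() + margin
        grown[max(0, y0):y1 + 1, max(0, x0):x1 + 1] = True
        assert mask[oracle].mean() > 0.95       # oracle iris mostly kept
        assert not mask[~grown].any()           # nothing far from the iris

    def test_uniform_crop_fails(self):
        region = EyeRegion(
            crop=np.full((20, 40), 150, dtype=np.uint8),
            origin=(0, 0), corner_x_min=0, corner_x_max=39,
            eyelid_y_min=0, eyelid_y_max=19,
        )
        with pytest.raises(SegmentationError):
            segment_iris(region)

    def test_auto_threshold_equals_any_fixed_between_modes(self):
        img, gt = generate_eye_image(EyeImageSpec(noise_sd=0.0))
        region = region_for_image(img, gt.landmarks)
        auto = segment_iris(region, IrisSegParams(binary_threshold="auto"))
        # any threshold between the iris level (40) and the next-darkest
        # gray level present in the crop (background 150) is equivalent
        for thr in (100, 128, 145):
            fixed = segment_iris(region, IrisSegParams(binary_threshold=thr))
            assert np.array_equal(auto, fixed)

    def test_auto_threshold_invariant_to_gray_offset(self):
        img, gt = generate_eye_image(EyeImageSpec(noise_sd=0.0))
        region = region_for_image(img, gt.landmarks)
        shifted = region_for_image(
            np.clip(img.astype(int) + 20, 0, 255).astype(np.uint8), gt.landmarks
        )
        assert np.array_equal(segment_iris(region), segment_iris(shifted))


class TestPupilCenter:
    def test_disc_centroid_with_origin(self):
        mask = np.zeros((60, 60), dtype=bool)
        yy, xx = np.mgrid[:60, :60]
        mask[(xx - 25) ** 2 + (yy - 30) ** 2 <= 100] = True
        assert pupil_center(mask, origin=(100, 50)) == pytest.approx((125, 80))

    def test_two_equal_discs_average(self):
        mask = np.zeros((30, 50), dtype=bool)
        yy, xx = np.mgrid[:30, :50]
        mask |= (xx - 10) ** 2 + (yy - 10) ** 2 <= 16
        mask |= (xx - 30) ** 2 + (yy - 10) ** 2 <= 16
        cx, cy = pupil_center(mask)
        assert (cx, cy) == pytest.approx((20.0, 10.0))

    def test_single_pixel(self):
        mask = np.zeros((10, 10), dtype=bool)
        mask[3, 7] = True
        assert pupil_center(mask, origin=(2, 5)) == (9.0, 8.0)

    def test_empty_mask_raises(self):
        with pytest.raises(PupilNotFoundError):
            pupil_center(np.zeros((5, 5), dtype=bool))

    @given(arrays(bool, (12, 17), elements=st.booleans()))
    def test_centroid_equals_bruteforce_mean(self, mask):
        """Image-moment centroid == mean of foreground coordinates."""
        if not mask.any():
            return
        cx, cy = pupil_center(mask)
        coords = np.argwhere(mask)  # (y, x)
        assert cx == pytest.approx(coords[:, 1].mean())
        assert cy == pytest.approx(coords[:, 0].mean())


class TestEndToEndRecovery:
    def test_noise_free_recovery_and_noise_degradation(self):
        """Detected centers track ground truth within 1.5 px noise-free and
        degrade monotonically (on average) as pixel noise grows."""
        rng = np.random.default_rng(42)
        mean_err = {}
        for noise_sd in (0.0, 25.0, 60.0):
            errs = []
            for k in range(25):
                cx = rng.uniform(22, 42)
                cy = rng.uniform(20, 28)
                spec = EyeImageSpec(iris_center=(cx, cy), noise_sd=noise_sd, seed=k)
                img, gt = generate_eye_image(spec)
                region = region_for_image(img, gt.landmarks)
                px, py = pupil_center(segment_iris(region), region.origin)
                errs.append(np.hypot(px - cx, py - cy))
            mean_err[noise_sd] = np.mean(errs)
            if noise_sd == 0.0:
                assert max(errs) <= 1.5
        assert mean_err[0.0] <= mean_err[25.0] <= mean_err[60.0]
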