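"""Algorithmic localizers: oracle equivalence, symmetry and equivariance."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from crloc.localizers import (
    NoCRFoundError,
    best_achievable_error,
    intensity_centroid,
    radial_symmetry_center,
    radial_symmetry_objective,
    threshold_centroid,
)
from crloc.synthcr import BackgroundSpec, CRSpec, make_patch


def gaussian_image(shape, x_c, y_c, sigma=2.0, amp=0.9):
    y, x = np.mgrid[0 : shape[0], 0 : shape[1]]
    return amp * np.exp(-(((x - x_c) ** 2 + (y - y_c) ** 2) / (2 * sigma**2)))


class TestThresholdCentroid:
    def test_single_pixel_blob(self):
        img = np.zeros((8, 8))
        img[4, 3] = 1.0  # row y=4, column x=3
        res = threshold_centroid(img, threshold=0.5)
        assert (res.x, res.y) == (3.0, 4.0)

    def test_two_pixel_row_blob(self):
        img = np.zeros((8, 8))
        img[5, 2:4] = 1.0
        res = threshold_centroid(img, threshold=0.5)
        assert res.x == 2.5 and res.y == 5.0

    def test_symmetric_cr_at_integer_center(self):
        patch = make_patch(
            CRSpec(90.0, 90.0, 10.0, 10000.0),
            BackgroundSpec(dark_level=10, light_level=None),
        )
        res = threshold_centroid(patch)
        assert (res.x, res.y) == (90.0, 90.0)

    def test_no_pixel_above_threshold(self):
        with pytest.raises(NoCRFoundError):
            threshold_centroid(np.zeros((8, 8)), threshold=0.5)

    def test_hole_filling_recenters_annulus(self):
        """A bright ring with a dark core centroids at the ring center
        once the enclosed hole is filled."""
        y, x = np.mgrid[0:21, 0:21]
        d = np.hypot(x - 10, y - 13)
        img = np.where((d > 2) & (d < 6), 1.0, 0.0)
        res = threshold_centroid(img, threshold=0.5)
        assert res.x == pytest.approx(10.0, abs=1e-9)
        assert res.y == pytest.approx(13.0, abs=1e-9)

    def test_area_criteria_select_in_range_blob(self):
        img = np.zeros((40, 40))
        img[2:20, 2:20] = 1.0  # large square, area 324
        img[30:33, 30:33] = 1.0  # small square, area 9
        res = threshold_centroid(img, threshold=0.5, max_area=50)
        assert (res.x, res.y) == (31.0, 31.0)
        res = threshold_centroid(img, threshold=0.5)  # default: largest
        assert (res.x, res.y) == (10.5, 10.5)

    def test_integer_translation_equivariance(self):
        img = np.zeros((30, 30))
        img[8:12, 5:10] = 1.0
        shifted = np.zeros((30, 30))
        shifted[11:15, 7:12] = 1.0  # +2 in x, +3 in y
        a = threshold_centroid(img, threshold=0.5)
        b = threshold_centroid(shifted, threshold=0.5)
        assert (b.x - a.x, b.y - a.y) == (2.0, 3.0)


class TestIntensityCentroid:
    def test_hand_worked_examples(self):
        assert intensity_centroid(np.array([[1.0, 3.0]])).x == pytest.approx(0.75)
        assert intensity_centroid(np.array([[1.0, 2.0, 1.0]])).x == pytest.approx(1.0)
        res = intensity_centroid(np.ones((11, 21)))
        assert (res.x, res.y) == (10.0, 5.0)  # geometric lattice center

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            intensity_centroid(np.zeros((5, 5)))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10**6))
    def test_matches_double_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        img = rng.uniform(0.01, 1.0, size=(6, 7))
        sx = sy = w = 0.0
        for i in range(6):  # independent brute-force accumulation
            for j in range(7):
                w += img[i, j]
                sx += img[i, j] * j
                sy += img[i, j] * i
        res = intensity_centroid(img)
        assert res.x == pytest.approx(sx / w, abs=1e-12)
        assert res.y == pytest.approx(sy / w, abs=1e-12)

    def test_integer_translation_equivariance(self):
        img = np.zeros((40, 40))
        img[10:14, 6:11] = np.arange(20).reshape(4, 5) + 1.0
        shifted = np.zeros((40, 40))
        shifted[13:17, 8:13] = np.arange(20).reshape(4, 5) + 1.0  # +2 x, +3 y
        a = intensity_centroid(img)
        b = intensity_centroid(shifted)
        assert b.x - a.x == pytest.approx(2.0, abs=1e-12)
        assert b.y - a.y == pytest.approx(3.0, abs=1e-12)


def brute_force_radial_symmetry(img, lo=-3.0, hi=11.0):
    """Two-stage grid search of the explicit weighted line-distance
    objective; final grid spacing 0.001 px."""
    best = None
    for step in (0.05, 0.001):
        if best is None:
            x0, x1, y0, y1 = lo, hi, lo, hi
        else:
            x0, x1 = best[0] - 0.06, best[0] + 0.06
            y0, y1 = best[1] - 0.06, best[1] + 0.06
        xs = np.arange(x0, x1 + step / 2, step)
        ys = np.arange(y0, y1 + step / 2, step)
        gx, gy = np.meshgrid(xs, ys)
        q = np.column_stack([gx.ravel(), gy.ravel()])
        vals = radial_symmetry_objective(img, q)
        best = q[np.argmin(vals)]
    return best


class TestRadialSymmetry:
    def test_exact_center_of_unsaturated_gaussian(self):
        img = gaussian_image((81, 81), 40.0, 40.0, sigma=6.0)
        res = radial_symmetry_center(img)
        assert res.x == pytest.approx(40.0, abs=1e-6)
        assert res.y == pytest.approx(40.0, abs=1e-6)

    def test_subpixel_center_recovery(self):
        img = gaussian_image((81, 81), 40.3, 39.6, sigma=6.0)
        res = radial_symmetry_center(img)
        assert res.x == pytest.approx(40.3, abs=1e-6)
        assert res.y == pytest.approx(39.6, abs=1e-6)

    def test_closed_form_equals_brute_force_minimizer(self):
        """The 2x2 linear solve lands on the brute-force argmin of the
        weighted objective for 100 random 9x9 blob images."""
        for seed in range(100):
            rng = np.random.default_rng(seed)
            img = gaussian_image(
                (9, 9),
                rng.uniform(2.0, 6.0),
                rng.uniform(2.0, 6.0),
                sigma=rng.uniform(0.8, 2.0),
                amp=rng.uniform(0.3, 1.0),
            )
            img = np.clip(img + rng.normal(0, 0.02, img.shape), 0, 1)
            res = radial_symmetry_center(img)
            ref = brute_force_radial_symmetry(img)
            assert abs(res.x - ref[0]) <= 2e-3
            assert abs(res.y - ref[1]) <= 2e-3

    def test_integer_translation_equivariance(self):
        a = radial_symmetry_center(gaussian_image((60, 60), 25.4, 27.1, sigma=3.0))
        b = radial_symmetry_center(gaussian_image((60, 60), 27.4, 30.1, sigma=3.0))
        assert b.x - a.x == pytest.approx(2.0, abs=1e-9)
        assert b.y - a.y == pytest.approx(3.0, abs=1e-9)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            radial_symmetry_center(np.full((9, 9), 0.5))  # no gradient
        ramp = np.tile(np.linspace(0, 1, 9), (9, 1))
        with pytest.raises(ValueError):
            radial_symmetry_center(ramp)  # all lines parallel
        with pytest.raises(ValueError):
            radial_symmetry_center(np.ones((2, 2)))


class TestAllMethodsAgreeOnSymmetricCR:
    def test_true_center_on_pixel_center(self):
        """On a patch symmetric about the CR (odd size, uniform dark
        background, no noise) all three estimators hit the center."""
        patch = make_patch(
            CRSpec(90.0, 90.0, 10.0, 1000.0),
            BackgroundSpec(dark_level=10, light_level=None),
            size=181,
        )
        for fn in (threshold_centroid, intensity_centroid, radial_symmetry_center):
            res = fn(patch)
            assert res.x == pytest.approx(90.0, abs=1e-3)
            assert res.y == pytest.approx(90.0, abs=1e-3)


class TestBestAchievableError:
    def test_continuous_centroid_is_unbiased(self):
        """Without quantization the centroid of a symmetric Gaussian has
        no error; the floor comes entirely from discretization."""
        img = gaussian_image((120, 120), 60.37, 60.0, sigma=4.0)
        res = intensity_centroid(img)
        assert res.x == pytest.approx(60.37, abs=1e-6)

    def test_small_cr_worse_than_large(self):
        small = best_achievable_error(r=2, A=10000).mean()
        large = best_achievable_error(r=18, A=10000).mean()
        assert small > large

    def test_error_grows_with_amplitude_at_small_radius(self):
        """Narrower tails (larger A) leave less sub-pixel information."""
        lo = best_achievable_error(r=2, A=10).mean()
        hi = best_achievable_error(r=2, A=10000).mean()
        assert hi >= lo
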