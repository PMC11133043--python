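"""Frame-wise eye pipeline: detection, cutouts, downsampling, fixtures."""

import numpy as np
import pytest

from crloc.eyepipe import (
    EyeFrameParams,
    PipelineConfig,
    detect_pupil_cr,
    downsample_frame,
    extract_patch,
    process_video,
    refine_centers,
    synth_eye_frame,
)
from crloc.localizers import intensity_centroid
from crloc.synthcr import CRSpec


@pytest.fixture
def clean_frame():
    return synth_eye_frame(EyeFrameParams(sigma_n=0.0))


class TestDetect:
    def test_fixture_truth_recovered_within_1px(self, rng):
        frame, truth = synth_eye_frame(EyeFrameParams(sigma_n=2.0), rng)
        pupil, cr = detect_pupil_cr(frame, PipelineConfig())
        assert pupil is not None and cr is not None
        assert np.hypot(*(np.subtract(pupil, truth["pupil"]))) < 1.0
        assert np.hypot(*(np.subtract(cr, truth["cr"]))) < 1.0

    def test_missing_cr_flagged_invalid(self):
        frame = np.full((100, 100), 0.4)  # nothing above the CR threshold
        pupil, cr = detect_pupil_cr(frame, PipelineConfig(pupil_area=(50, 1e6)))
        assert cr is None

    def test_area_criteria_reject_out_of_range_blob(self):
        frame = np.full((200, 200), 0.3)
        frame[20:120, 20:120] = 0.95  # huge bright square, outside cr_area
        y, x = np.mgrid[0:200, 0:200]
        frame[np.hypot(x - 160, y - 160) <= 5] = 1.0  # in-range CR disk
        _, cr = detect_pupil_cr(frame, PipelineConfig())
        assert cr is not None
        assert np.hypot(cr[0] - 160, cr[1] - 160) < 1.0

    def test_cr_on_pupil_iris_border_still_found(self, rng):
        params = EyeFrameParams(
            cr=CRSpec(x_c=508.0, y_c=300.0, r=12.0, A=10000.0),  # on ellipse edge
            sigma_n=2.0,
        )
        frame, truth = synth_eye_frame(params, rng)
        _, cr = detect_pupil_cr(frame, PipelineConfig())
        assert cr is not None
        assert np.hypot(cr[0] - truth["cr"][0], cr[1] - truth["cr"][1]) < 1.0

    def test_roi_restricts_search(self, clean_frame):
        frame, truth = clean_frame
        cfg = PipelineConfig(roi=(300, 150, 650, 450))
        _, cr = detect_pupil_cr(frame, cfg)
        assert np.hypot(cr[0] - truth["cr"][0], cr[1] - truth["cr"][1]) < 1.0
        with pytest.raises(ValueError):
            detect_pupil_cr(frame, PipelineConfig(roi=(0, 0, 10_000, 10)))


class TestExtractPatch:
    def test_mask_radius_boundary(self, clean_frame):
        frame, _ = clean_frame
        patch, origin, padded = extract_patch(frame, (470, 280), PipelineConfig())
        assert patch.pixels.shape == (180, 180)
        assert not padded
        assert patch.pixels[90, 90 + 47] == frame[280, 470 + 47]  # distance 47 kept
        assert patch.pixels[90, 90 + 49] == 0.0  # distance 49 masked
        assert origin == (470 - 90, 280 - 90)

    def test_corner_cutout_is_zero_padded(self, clean_frame):
        frame, _ = clean_frame
        patch, origin, padded = extract_patch(frame, (3, 2), PipelineConfig())
        assert patch.pixels.shape == (180, 180)
        assert padded
        assert origin == (-87, -88)

    def test_masking_is_idempotent(self, clean_frame):
        frame, _ = clean_frame
        cfg = PipelineConfig()
        once, origin, _ = extract_patch(frame, (470, 280), cfg)
        twice, _, _ = extract_patch(once.pixels, (90, 90), cfg)
        assert np.array_equal(once.pixels, twice.pixels)


class TestRefine:
    def test_round_trip_to_frame_coordinates(self, clean_frame, small_model):
        frame, truth = clean_frame
        cfg = PipelineConfig()
        _, cr_coarse = detect_pupil_cr(frame, cfg)
        patch, origin, _ = extract_patch(frame, cr_coarse, cfg)
        refined = refine_centers(
            patch, origin, methods=("radial_symmetry", "cnn"), model=small_model
        )
        res = refined["cnn"]
        assert res is not None
        assert np.hypot(res.x - truth["cr"][0], res.y - truth["cr"][1]) < 1.0
        # radial symmetry is biased by the pupil edge crossing the masked
        # cutout (non-uniform background), so it only gets a loose bound
        res = refined["radial_symmetry"]
        assert res is not None
        assert np.hypot(res.x - truth["cr"][0], res.y - truth["cr"][1]) < 3.0

    def test_failure_yields_none(self):
        from crloc.synthcr import ImagePatch

        flat = ImagePatch(np.zeros((180, 180)))
        out = refine_centers(flat, (0, 0), methods=("radial_symmetry",))
        assert out["radial_symmetry"] is None


class TestDownsample:
    def test_constant_and_checkerboard(self):
        assert np.all(downsample_frame(np.full((10, 12), 0.25)) == 0.25)
        board = np.indices((8, 8)).sum(axis=0) % 2
        assert np.all(downsample_frame(board.astype(float)) == 0.5)

    def test_odd_edges_cropped(self):
        assert downsample_frame(np.zeros((9, 11))).shape == (4, 5)

    def test_coordinate_mapping(self):
        """A feature at x maps to (x - 0.5) / 2 under 2x2 block-mean
        downsampling, verified with an off-center Gaussian blob."""
        y, x = np.mgrid[0:120, 0:120]
        img = 0.8 * np.exp(-((x - 63.0) ** 2 + (y - 48.5) ** 2) / (2 * 16.0))
        res = intensity_centroid(downsample_frame(img))
        assert res.x == pytest.approx((63.0 - 0.5) / 2, abs=0.02)
        assert res.y == pytest.approx((48.5 - 0.5) / 2, abs=0.02)

    def test_half_resolution_config(self):
        cfg = PipelineConfig().at_half_resolution()
        assert cfg.downsample == 2 and cfg.mask_radius == 24.0


class TestProcessVideo:
    def _drift_frames(self, n=6, sigma_n=0.0):
        frames, truths = [], []
        for k in range(n):
            params = EyeFrameParams(
                cr=CRSpec(x_c=470.0 + 0.7 * k, y_c=280.0 - 0.3 * k, r=12.0, A=1e4),
                sigma_n=sigma_n,
            )
            frame, truth = synth_eye_frame(params, np.random.default_rng(k))
            frames.append(frame)
            truths.append(truth)
        return frames, truths

    def test_drifting_cr_tracked_subpixel(self, small_model):
        frames, truths = self._drift_frames()
        results = process_video(
            frames, PipelineConfig(), methods=("radial_symmetry", "cnn"),
            model=small_model,
        )
        for res, truth in zip(results, truths):
            assert res.cr_valid["threshold"]
            est = res.cr["cnn"]
            assert np.hypot(est[0] - truth["cr"][0], est[1] - truth["cr"][1]) < 1.0
            est = res.cr["radial_symmetry"]  # biased by the pupil edge
            assert np.hypot(est[0] - truth["cr"][0], est[1] - truth["cr"][1]) < 3.0

    def test_frame_order_invariance(self):
        """Frames are processed independently: permuting the input only
        permutes the outputs."""
        frames, _ = self._drift_frames(n=5, sigma_n=2.0)
        order = [3, 0, 4, 2, 1]
        direct = process_video(frames, PipelineConfig())
        permuted = process_video([frames[i] for i in order], PipelineConfig())
        for new_idx, old_idx in enumerate(order):
            assert permuted[new_idx].cr == direct[old_idx].cr
            assert permuted[new_idx].pupil == direct[old_idx].pupil

    def test_empty_video(self):
        assert process_video([], PipelineConfig()) == []

    def test_half_resolution_pipeline_on_fixture(self, small_model):
        """The 2x-downsampled pipeline still yields valid sub-pixel CR
        estimates (in half-res pixel units) on a clean fixture."""
        frames, truths = self._drift_frames(n=3)
        cfg = PipelineConfig().at_half_resolution()
        results = process_video(frames, cfg, methods=("radial_symmetry",))
        for res, truth in zip(results, truths):
            assert res.cr_valid["radial_symmetry"]
            tx, ty = truth["cr"]
            tx, ty = (tx - 0.5) / 2, (ty - 0.5) / 2  # half-res coordinates
            est = res.cr["radial_symmetry"]
            assert np.hypot(est[0] - tx, est[1] - ty) < 1.0


class TestSynthFrame:
    def test_seeded_frames_identical(self):
        a, _ = synth_eye_frame(EyeFrameParams(), np.random.default_rng(4))
        b, _ = synth_eye_frame(EyeFrameParams(), np.random.default_rng(4))
        assert np.array_equal(a, b)

    def test_cr_outside_frame_rejected(self):
        with pytest.raises(ValueError):
            synth_eye_frame(
                EyeFrameParams(cr=CRSpec(x_c=5000.0, y_c=10.0, r=5.0, A=100.0))
            )
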