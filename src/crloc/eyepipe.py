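"""Frame-wise eye-image processing.

Each frame is processed independently (no temporal state): a coarse
threshold stage finds the dark pupil blob and the bright CR blob inside a
region of interest, a 180x180 cutout centered on the rounded coarse CR
center is extracted and masked with a black circle of radius 48 px, and
the masked patch is fed to the refinement methods (radial symmetry and/or
the CNN), whose patch-coordinate estimates are mapped back to frame
coordinates.  A half-resolution variant downsamples frames by 2x2 block
averaging and halves the mask radius.

``synth_eye_frame`` generates synthetic eye frames (dark pupil ellipse on
a lighter iris with one saturated CR) with known ground-truth centers, so
the whole pipeline can be exercised and verified without real recordings.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .localizers import (
    LocalizationResult,
    Method,
    radial_symmetry_center,
)
from .synthcr import CRSpec, ImagePatch, NoiseSpec, render_cr

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "FrameResult",
    "detect_pupil_cr",
    "extract_patch",
    "refine_centers",
    "downsample_frame",
    "synth_eye_frame",
    "process_video",
    "load_frames",
]


@dataclass(frozen=True)
class PipelineConfig:
    """Per-video processing parameters (fixed for a whole recording)."""

    roi: Optional[Tuple[int, int, int, int]] = None  # (x0, y0, x1, y1), px
    pupil_threshold: float = 0.25  # pixels below -> pupil candidate
    cr_threshold: float = 0.7  # pixels above -> CR candidate
    pupil_area: Tuple[float, float] = (200.0, 1e6)  # px^2 bounds
    cr_area: Tuple[float, float] = (4.0, 5000.0)
    min_circularity: float = 0.6  # 4*pi*A/P^2 of accepted blobs
    cutout_size: int = 180
    mask_radius: float = 48.0
    downsample: int = 1  # 1 = full resolution, 2 = half

    def __post_init__(self) -> None:
        if not (0.0 < self.pupil_threshold < 1.0 and 0.0 < self.cr_threshold < 1.0):
            raise ValueError("thresholds must lie in (0, 1)")
        if self.mask_radius >= self.cutout_size / 2:
            raise ValueError("mask_radius must be below cutout_size / 2")
        if self.downsample not in (1, 2):
            raise ValueError("downsample factor must be 1 or 2")

    def at_half_resolution(self) -> "PipelineConfig":
        """The half-resolution variant: 2x downsampling, halved mask."""
        return replace(
            self,
            downsample=2,
            mask_radius=self.mask_radius / 2,
            roi=None if self.roi is None else tuple(v // 2 for v in self.roi),
            pupil_area=tuple(a / 4 for a in self.pupil_area),
            cr_area=tuple(a / 4 for a in self.cr_area),
        )


@dataclass
class FrameResult:
    """Per-frame feature centers, all in frame coordinates (px)."""

    frame_index: int
    pupil: Optional[Tuple[float, float]] = None
    cr: Dict[str, Tuple[float, float]] = field(default_factory=dict)
    pupil_valid: bool = False
    cr_valid: Dict[str, bool] = field(default_factory=dict)
    at_border: bool = False  # cutout needed zero padding


def _as_gray(frame) -> np.ndarray:
    f = np.asarray(frame, dtype=float)
    if f.ndim == 3:  # collapse an accidental color axis
        f = f.mean(axis=2)
    if f.max() > 1.0:  # accept 8-bit input
        f = f / 255.0
    return f


def _select_blob(
    mask: np.ndarray,
    area_bounds: Tuple[float, float],
    min_circularity: float,
) -> Optional[Tuple[float, float]]:
    from .localizers import _circularity

    mask = ndimage.binary_fill_holes(mask)
    labels, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    best = None
    for lab in range(1, n + 1):
        blob = labels == lab
        area = float(blob.sum())
        if not (area_bounds[0] <= area <= area_bounds[1]):
            continue
        if _circularity(blob, area) < min_circularity:
            continue
        if best is None or area > best[0]:
            rows, cols = np.nonzero(blob)
            best = (area, float(cols.mean()), float(rows.mean()))
    if best is None:
        return None
    return best[1], best[2]


def detect_pupil_cr(
    frame, cfg: PipelineConfig
) -> Tuple[Optional[Tuple[float, float]], Optional[Tuple[float, float]]]:
    """Coarse detection: pupil (dark blob) and CR (bright blob) centroids.

    Returns ``(pupil_center, cr_center)`` in frame coordinates; either may
    be ``None`` when no qualifying blob exists.
    """
    f = _as_gray(frame)
    x0 = y0 = 0
    if cfg.roi is not None:
        x0, y0, x1, y1 = cfg.roi
        if not (0 <= x0 < x1 <= f.shape[1] and 0 <= y0 < y1 <= f.shape[0]):
            raise ValueError(f"ROI {cfg.roi} outside frame {f.shape}")
        f = f[y0:y1, x0:x1]

    pupil = _select_blob(f < cfg.pupil_threshold, cfg.pupil_area, cfg.min_circularity)
    cr = _select_blob(f > cfg.cr_threshold, cfg.cr_area, cfg.min_circularity)
    offset = np.array([x0, y0], dtype=float)
    pupil = None if pupil is None else tuple(np.asarray(pupil) + offset)
    cr = None if cr is None else tuple(np.asarray(cr) + offset)
    return pupil, cr


def extract_patch(
    frame, center: Tuple[float, float], cfg: PipelineConfig
) -> Tuple[ImagePatch, Tuple[int, int], bool]:
    """Masked cutout centered on the rounded coarse center.

    Returns ``(patch, origin, padded)`` where ``origin`` is the frame
    coordinate of patch pixel (0, 0) and ``padded`` flags cutouts that ran
    over the frame border (zero-padded).  Pixels farther than
    ``mask_radius`` from the patch center are set to 0.
    """
    f = _as_gray(frame)
    size = cfg.cutout_size
    half = size // 2
    cx, cy = int(round(center[0])), int(round(center[1]))
    ox, oy = cx - half, cy - half

    patch = np.zeros((size, size))
    sy0, sy1 = max(0, oy), min(f.shape[0], oy + size)
    sx0, sx1 = max(0, ox), min(f.shape[1], ox + size)
    padded = (sy1 - sy0 < size) or (sx1 - sx0 < size)
    if sy1 > sy0 and sx1 > sx0:
        patch[sy0 - oy : sy1 - oy, sx0 - ox : sx1 - ox] = f[sy0:sy1, sx0:sx1]

    y, x = np.mgrid[0:size, 0:size]
    patch[(x - half) ** 2 + (y - half) ** 2 > cfg.mask_radius**2] = 0.0
    return ImagePatch(patch), (ox, oy), padded


def refine_centers(
    patch: ImagePatch,
    origin: Tuple[int, int],
    methods: Sequence[str] = ("radial_symmetry",),
    model=None,
) -> Dict[str, Optional[LocalizationResult]]:
    """Run refinement methods on a masked patch; map back to frame coords."""
    out: Dict[str, Optional[LocalizationResult]] = {}
    for method in methods:
        try:
            if method == "radial_symmetry":
                res = radial_symmetry_center(patch)
            elif method == "cnn":
                if model is None:
                    raise ValueError("cnn refinement requires a model")
                from .crnet import predict_center

                res = predict_center(model, patch)
            else:
                raise ValueError(f"unknown refinement method {method!r}")
            out[method] = LocalizationResult(
                x=res.x + origin[0], y=res.y + origin[1], method=res.method
            )
        except Exception as exc:
            logger.debug("refinement %s failed: %s", method, exc)
            out[method] = None
    return out


def downsample_frame(frame) -> np.ndarray:
    """Half-resolution frame via 2x2 block mean (odd edges cropped).

    A feature at full-resolution coordinate ``x`` maps to ``(x - 0.5) / 2``
    in the downsampled frame, because the new pixel centered at index ``i``
    averages old pixels ``2i`` and ``2i + 1`` (center ``2i + 0.5``).
    """
    f = _as_gray(frame)
    h2, w2 = f.shape[0] // 2, f.shape[1] // 2
    return f[: 2 * h2, : 2 * w2].reshape(h2, 2, w2, 2).mean(axis=(1, 3))


# --------------------------------------------------------------------------
# synthetic fixture frames


@dataclass(frozen=True)
class EyeFrameParams:
    """Parameters of one synthetic eye frame (all px / image levels)."""

    shape: Tuple[int, int] = (600, 896)  # (height, width)
    pupil_center: Tuple[float, float] = (448.0, 300.0)  # (x, y)
    pupil_axes: Tuple[float, float] = (60.0, 50.0)  # semi-axes (x, y)
    pupil_level: float = 20.0
    iris_level: float = 120.0
    cr: CRSpec = CRSpec(x_c=470.0, y_c=280.0, r=12.0, A=10000.0)
    sigma_n: float = 2.0


def synth_eye_frame(
    params: EyeFrameParams = EyeFrameParams(), rng: Optional[np.random.Generator] = None
) -> Tuple[np.ndarray, Dict[str, Tuple[float, float]]]:
    """Synthetic eye frame plus ground truth.

    The frame is an iris-level background with a dark pupil ellipse and one
    saturated CR composed on top (same max-compose / noise / quantization
    chain as the synthetic patches).  Returns ``(frame, truth)`` with
    ``truth = {"pupil": (x, y), "cr": (x, y)}``.  The frame is float in
    [0, 1] on the k/255 lattice.
    """
    h, w = params.shape
    cr = params.cr
    if not (0 <= cr.x_c < w and 0 <= cr.y_c < h):
        raise ValueError("CR center outside the frame")
    y, x = np.mgrid[0:h, 0:w]
    bg = np.full((h, w), float(params.iris_level))
    px, py = params.pupil_center
    ax, ay = params.pupil_axes
    inside = ((x - px) / ax) ** 2 + ((y - py) / ay) ** 2 <= 1.0
    bg[inside] = params.pupil_level

    cr_field = render_cr(cr, (h, w))
    levels = np.maximum(cr_field * 255.0, bg)
    if params.sigma_n > 0:
        rng = rng if rng is not None else np.random.default_rng()
        levels = levels + rng.normal(0.0, params.sigma_n, size=levels.shape)
    frame = np.rint(np.clip(levels, 0.0, 255.0)) / 255.0
    truth = {"pupil": (px, py), "cr": (cr.x_c, cr.y_c)}
    return frame, truth


# --------------------------------------------------------------------------
# video processing


def process_frame(
    index: int, frame, cfg: PipelineConfig, methods: Sequence[str], model=None
) -> FrameResult:
    """Process a single frame through coarse detection and refinement."""
    if cfg.downsample == 2:
        frame = downsample_frame(frame)
    result = FrameResult(frame_index=index)
    try:
        pupil, cr_coarse = detect_pupil_cr(frame, cfg)
    except Exception as exc:
        logger.warning("frame %d unreadable: %s", index, exc)
        return result
    if pupil is not None:
        result.pupil = pupil
        result.pupil_valid = True
    if cr_coarse is None:
        result.cr_valid = {m: False for m in ("threshold", *methods)}
        return result

    result.cr["threshold"] = cr_coarse
    result.cr_valid["threshold"] = True
    patch, origin, padded = extract_patch(frame, cr_coarse, cfg)
    result.at_border = padded
    for method, res in refine_centers(patch, origin, methods, model).items():
        if res is None:
            result.cr_valid[method] = False
        else:
            result.cr[method] = (res.x, res.y)
            result.cr_valid[method] = True
    return result


def process_video(
    frames: Iterable,
    cfg: PipelineConfig,
    methods: Sequence[str] = ("radial_symmetry",),
    model=None,
) -> List[FrameResult]:
    """Process an iterable of frames; every frame is handled independently."""
    return [
        process_frame(i, frame, cfg, methods, model) for i, frame in enumerate(frames)
    ]


def load_frames(path) -> Iterable[np.ndarray]:
    """Frames from a directory of PNGs (sorted) or a video file.

    Video decode requires an imageio ffmpeg backend; grayscale PNG frame
    directories need none.
    """
    import imageio.v3 as iio

    path = Path(path)
    if path.is_dir():
        for p in sorted(path.glob("*.png")):
            yield iio.imread(p)
    else:
        try:
            for frame in iio.imiter(path):
                yield frame
        except Exception as exc:  # pragma: no cover - depends on ffmpeg
            raise RuntimeError(
                f"cannot decode {path}; video input needs an imageio ffmpeg "
                "backend — use a directory of PNG frames instead"
            ) from exc
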