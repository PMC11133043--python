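"""Algorithmic sub-pixel center estimators for the corneal reflection.

Three estimators are provided:

``threshold_centroid``
    Binarize above a fixed level, fill holes, select a blob and return the
    unweighted centroid of its pixels — the classic eye-tracker approach.

``intensity_centroid``
    Intensity-weighted center of mass of the whole image.  Also drives
    :func:`best_achievable_error`, which measures the localization floor
    imposed by pixelation and 8-bit quantization alone.

``radial_symmetry_center``
    The radial-symmetry estimator from particle tracking: every
    inter-pixel midpoint defines a line along its local gradient
    direction; for a radially symmetric spot all such lines pass through
    the center, so the center is recovered as the weighted least-squares
    point minimizing the summed squared perpendicular distance to the
    lines.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Optional, Tuple, Union

import numpy as np
from scipy import ndimage, signal

from .synthcr import CRSpec, ImagePatch, NoiseSpec, compose_image, render_cr

__all__ = [
    "Method",
    "LocalizationResult",
    "NoCRFoundError",
    "threshold_centroid",
    "intensity_centroid",
    "radial_symmetry_center",
    "best_achievable_error",
]

ImageLike = Union[ImagePatch, np.ndarray]

#: Default binarization threshold for synthetic evaluation sweeps, on the
#: [0, 1] intensity scale.  Chosen above the maximum light-background level
#: (153/255 = 0.6) and below saturation (1.0) so that only the CR blob is
#: segmented across the whole evaluation grid; configurable per run.
DEFAULT_THRESHOLD = 0.7


class Method(str, enum.Enum):
    THRESHOLD = "threshold"
    CENTROID = "centroid"
    RADIAL_SYMMETRY = "radial_symmetry"
    CNN = "cnn"


class NoCRFoundError(RuntimeError):
    """Raised when no qualifying CR blob exists in the image."""


@dataclass(frozen=True)
class LocalizationResult:
    """Sub-pixel (x, y) center estimate from one method."""

    x: float
    y: float
    method: Method

    def __iter__(self):
        yield self.x
        yield self.y


def _pixels(img: ImageLike) -> np.ndarray:
    if isinstance(img, ImagePatch):
        return img.pixels
    return np.asarray(img, dtype=float)


def threshold_centroid(
    img: ImageLike,
    threshold: float = DEFAULT_THRESHOLD,
    min_area: Optional[float] = None,
    max_area: Optional[float] = None,
    min_circularity: Optional[float] = None,
) -> LocalizationResult:
    """Binarize, fill holes and return the selected blob's pixel centroid.

    Pixels strictly above ``threshold`` are kept, enclosed holes are filled
    (4-connectivity) and connected bright blobs are extracted
    (8-connectivity).  Optional area bounds (px^2) and a minimum
    circularity ``4*pi*area / perimeter**2`` filter the candidates; the
    largest qualifying blob is selected.

    Raises
    ------
    NoCRFoundError
        If no pixel exceeds the threshold or no blob passes the criteria.
    """
    p = _pixels(img)
    mask = p > threshold
    if not mask.any():
        raise NoCRFoundError("no pixel above threshold")
    mask = ndimage.binary_fill_holes(mask)
    labels, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        raise NoCRFoundError("no blob found")

    areas = ndimage.sum_labels(np.ones_like(labels), labels, index=range(1, n + 1))
    candidates = []
    for lab, area in zip(range(1, n + 1), areas):
        if min_area is not None and area < min_area:
            continue
        if max_area is not None and area > max_area:
            continue
        if min_circularity is not None:
            circ = _circularity(labels == lab, area)
            if circ < min_circularity:
                continue
        candidates.append((area, lab))
    if not candidates:
        raise NoCRFoundError("no blob passes the size/shape criteria")

    _, lab = max(candidates)
    rows, cols = np.nonzero(labels == lab)
    return LocalizationResult(
        x=float(cols.mean()), y=float(rows.mean()), method=Method.THRESHOLD
    )


def _circularity(blob: np.ndarray, area: float) -> float:
    from skimage.measure import perimeter

    per = perimeter(blob, neighborhood=4)
    if per == 0:  # single pixel
        return 1.0
    return float(4.0 * np.pi * area / per**2)


def intensity_centroid(img: ImageLike) -> LocalizationResult:
    """Intensity-weighted center of mass of all pixels."""
    p = _pixels(img)
    total = p.sum()
    if total <= 0:
        raise ValueError("image has zero total intensity")
    y, x = np.mgrid[0 : p.shape[0], 0 : p.shape[1]]
    return LocalizationResult(
        x=float((p * x).sum() / total),
        y=float((p * y).sum() / total),
        method=Method.CENTROID,
    )


# --------------------------------------------------------------------------
# radial symmetry


def _gradient_lines(
    img: ImageLike,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Midpoint gradient lines feeding the radial-symmetry solve.

    For every 2x2 pixel cell, the two diagonal intensity derivatives are
    computed on the half-pixel midpoint lattice (midpoints offset +0.5 from
    pixel indices), smoothed with a 3x3 boxcar, and converted to a gradient
    vector in (x, y).  Each midpoint then carries a line through it along
    its gradient direction, with weight

        w_k = |grad I|^2_k / d_k

    where d_k is the distance from the midpoint to the gradient-magnitude-
    weighted centroid of all midpoints.

    Returns ``(points, normals, weights, mag2)``: midpoint coordinates
    (K, 2), unit line normals (K, 2), line weights (K,), and the smoothed
    squared gradient magnitudes (K,).  Zero-gradient midpoints get zero
    weight and an arbitrary zero normal.
    """
    p = _pixels(img)
    if p.shape[0] < 3 or p.shape[1] < 3:
        raise ValueError("image must be at least 3x3")
    # diagonal derivatives of each 2x2 cell; du along (+x,-y), dv along (-x,-y)
    du = p[:-1, 1:] - p[1:, :-1]
    dv = p[:-1, :-1] - p[1:, 1:]
    box = np.full((3, 3), 1.0 / 9.0)
    fdu = signal.convolve2d(du, box, mode="same")
    fdv = signal.convolve2d(dv, box, mode="same")
    gx = fdu - fdv
    gy = -fdu - fdv
    mag2 = fdu**2 + fdv**2
    if not mag2.any():
        raise ValueError("zero gradient everywhere; no radial-symmetry center")

    h, w = du.shape
    ym, xm = np.mgrid[0:h, 0:w]
    xm = xm + 0.5
    ym = ym + 0.5

    tot = mag2.sum()
    xc_w = (mag2 * xm).sum() / tot
    yc_w = (mag2 * ym).sum() / tot
    d = np.sqrt((xm - xc_w) ** 2 + (ym - yc_w) ** 2)
    d = np.maximum(d, 1e-9)
    weights = mag2 / d

    norm = np.sqrt(gx**2 + gy**2)
    ok = norm > 0
    # unit normal perpendicular to the gradient direction
    nx = np.where(ok, -gy / np.where(ok, norm, 1.0), 0.0)
    ny = np.where(ok, gx / np.where(ok, norm, 1.0), 0.0)
    weights = np.where(ok, weights, 0.0)

    points = np.stack([xm.ravel(), ym.ravel()], axis=1)
    normals = np.stack([nx.ravel(), ny.ravel()], axis=1)
    return points, normals, weights.ravel(), mag2.ravel()


def radial_symmetry_center(img: ImageLike) -> LocalizationResult:
    """Radial-symmetry center: weighted least squares over gradient lines.

    Solves ``argmin_q sum_k w_k (n_k . (q - p_k))^2`` in closed form as a
    2x2 linear system, where line k passes through midpoint ``p_k`` with
    unit normal ``n_k`` (perpendicular to the local gradient).  The
    direction-vector parameterization has no slope singularities, so
    vertical gradients need no special casing.
    """
    points, normals, w, _ = _gradient_lines(img)
    nx, ny = normals[:, 0], normals[:, 1]
    c = nx * points[:, 0] + ny * points[:, 1]  # n . p per line
    a11 = (w * nx * nx).sum()
    a12 = (w * nx * ny).sum()
    a22 = (w * ny * ny).sum()
    b1 = (w * nx * c).sum()
    b2 = (w * ny * c).sum()
    A = np.array([[a11, a12], [a12, a22]])
    det = a11 * a22 - a12 * a12
    if not np.isfinite(det) or abs(det) <= 1e-12 * max(a11 * a22, 1e-300):
        raise ValueError("degenerate gradient field; center is not identifiable")
    x, y = np.linalg.solve(A, np.array([b1, b2]))
    return LocalizationResult(x=float(x), y=float(y), method=Method.RADIAL_SYMMETRY)


def radial_symmetry_objective(img: ImageLike, q: np.ndarray) -> np.ndarray:
    """Evaluate the radial-symmetry objective at candidate points ``q``.

    ``q`` is (M, 2); returns the weighted sum of squared perpendicular
    distances for each candidate.  Exposed so the closed-form solve can be
    checked against a brute-force minimizer of the same objective.
    """
    points, normals, w, _ = _gradient_lines(img)
    q = np.atleast_2d(np.asarray(q, dtype=float))
    # perpendicular distance of q to each line: n . (q - p)
    dist = q @ normals.T - (normals * points).sum(axis=1)
    return (w * dist**2).sum(axis=1)


def best_achievable_error(
    r: float,
    A: float,
    n_steps: int = 100,
    step: float = 0.01,
    size: int = 180,
) -> np.ndarray:
    """Localization floor from pixelation and 8-bit quantization.

    The CR is rendered on a completely black background so that only
    CR-related intensity enters the estimate, quantized to 256 levels, and
    its center estimated with the intensity centroid while the true
    horizontal center steps across one pixel in ``n_steps`` increments of
    ``step`` px.  Returns the per-step absolute horizontal error (px).
    """
    c = size / 2.0
    errors = np.empty(n_steps)
    black = np.zeros((size, size))
    for k in range(n_steps):
        x_c = c + k * step
        cr = CRSpec(x_c=x_c, y_c=c, r=r, A=A)
        patch = compose_image(render_cr(cr, size), black, NoiseSpec())
        est = intensity_centroid(patch)
        errors[k] = abs(est.x - x_c)
    return errors
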