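"""P-CR gaze construction, polynomial calibration and data-quality metrics.

Gaze is derived with the standard pupil-minus-CR (P-CR) principle: the CR
center is subtracted from the pupil center per sample, and the resulting
vector is mapped to gaze in degrees with a second-order polynomial per
axis, including the first-order interaction::

    p_gaze = a + b*x + c*y + d*x^2 + e*y^2 + f*x*y

fitted by least squares on the calibration fixations (one median P-CR
point per fixation target).

Data-quality metrics follow eye-tracking convention, computed in moving
200-ms windows that advance one sample at a time, with the median over
windows reported per trial:

* RMS-S2S precision: RMS of Euclidean sample-to-sample displacements.
* STD precision: ``sqrt(var(x) + var(y))`` (population variances).
* Accuracy: Euclidean offset between the per-axis median gaze during a
  fixation and the target location, averaged over repetitions and targets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "GazeSeries",
    "CalibModel",
    "CALIBRATION_GRID_3X3",
    "ACCURACY_GRID_5X3",
    "pcr_vector",
    "fit_calibration",
    "apply_calibration",
    "rms_s2s",
    "std_precision",
    "accuracy",
]

#: 3x3 calibration fixation grid, degrees: h in {-7, 0, 7}, v in {-5, 0, 5}.
CALIBRATION_GRID_3X3: Tuple[Tuple[float, float], ...] = tuple(
    (h, v) for v in (-5.0, 0.0, 5.0) for h in (-7.0, 0.0, 7.0)
)

#: 5x3 accuracy/validation grid, degrees.
ACCURACY_GRID_5X3: Tuple[Tuple[float, float], ...] = tuple(
    (h, v) for v in (-5.0, 0.0, 5.0) for h in (-7.0, -3.5, 0.0, 3.5, 7.0)
)


@dataclass
class GazeSeries:
    """Uniformly sampled 2-D signal: raw feature centers (px) or gaze (deg)."""

    t: np.ndarray  # seconds, strictly increasing
    x: np.ndarray
    y: np.ndarray
    sampling_rate: float  # Hz
    valid: Optional[np.ndarray] = None  # per-sample validity; None = all valid

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (self.t.shape == self.x.shape == self.y.shape):
            raise ValueError("t, x, y must have identical shapes")
        if len(self.t) > 1 and not np.all(np.diff(self.t) > 0):
            raise ValueError("timestamps must be strictly increasing")
        if self.valid is None:
            self.valid = np.ones(len(self.t), dtype=bool)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)

    def __len__(self) -> int:
        return len(self.t)


@dataclass(frozen=True)
class CalibModel:
    """Per-axis polynomial calibration coefficients (a, b, c, d, e, f)."""

    coef_x: np.ndarray  # horizontal gaze coefficients
    coef_y: np.ndarray  # vertical gaze coefficients

    def __post_init__(self) -> None:
        for c in (self.coef_x, self.coef_y):
            if np.asarray(c).shape != (6,):
                raise ValueError("each axis needs exactly 6 coefficients")


def _design(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    return np.column_stack(
        [np.ones_like(x), x, y, x**2, y**2, x * y]
    )


def pcr_vector(pupil: GazeSeries, cr: GazeSeries) -> GazeSeries:
    """Per-sample pupil-minus-CR vector; invalid samples propagate."""
    if len(pupil) != len(cr) or not np.allclose(pupil.t, cr.t):
        raise ValueError("pupil and CR series must share timestamps")
    return GazeSeries(
        t=pupil.t.copy(),
        x=pupil.x - cr.x,
        y=pupil.y - cr.y,
        sampling_rate=pupil.sampling_rate,
        valid=pupil.valid & cr.valid,
    )


def fit_calibration(
    pcr_points: np.ndarray, targets: Sequence[Tuple[float, float]]
) -> Tuple[CalibModel, np.ndarray]:
    """Least-squares polynomial calibration from fixation medians.

    ``pcr_points`` is (N, 2): one (median) P-CR point per calibration
    fixation; ``targets`` the matching fixation locations in degrees,
    N >= 6.  Returns the fitted model and the (N, 2) residuals.
    """
    pts = np.asarray(pcr_points, dtype=float)
    tgt = np.asarray(targets, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape != tgt.shape:
        raise ValueError("need matching (N, 2) P-CR points and targets")
    if len(pts) < 6:
        raise ValueError("at least 6 calibration points are required")
    X = _design(pts[:, 0], pts[:, 1])
    if np.linalg.matrix_rank(X) < 6:
        raise ValueError("rank-deficient calibration design (degenerate points)")
    coef, *_ = np.linalg.lstsq(X, tgt, rcond=None)
    residuals = tgt - X @ coef
    return CalibModel(coef_x=coef[:, 0], coef_y=coef[:, 1]), residuals


def apply_calibration(model: CalibModel, pcr: GazeSeries) -> GazeSeries:
    """Map a P-CR series to gaze in degrees via the fitted polynomials."""
    X = _design(pcr.x, pcr.y)
    return GazeSeries(
        t=pcr.t.copy(),
        x=X @ model.coef_x,
        y=X @ model.coef_y,
        sampling_rate=pcr.sampling_rate,
        valid=pcr.valid.copy(),
    )


def _window_length(series: GazeSeries, window_ms: float) -> int:
    n = int(np.floor(window_ms / 1000.0 * series.sampling_rate))
    if n < 2:
        raise ValueError("window must contain at least 2 samples")
    if len(series) < n:
        raise ValueError(
            f"series of {len(series)} samples is shorter than one "
            f"{window_ms}-ms window ({n} samples)"
        )
    return n


def _sliding(a: np.ndarray, n: int) -> np.ndarray:
    return np.lib.stride_tricks.sliding_window_view(a, n)


def rms_s2s(series: GazeSeries, window_ms: float = 200.0) -> float:
    """RMS sample-to-sample precision: median over moving windows.

    Within each window of ``floor(window_ms * rate)`` samples the RMS of
    the Euclidean displacement between successive samples is computed; the
    windows advance one sample at a time and the median across windows is
    returned, in the units of the input signal.
    """
    n = _window_length(series, window_ms)
    d2 = np.diff(series.x) ** 2 + np.diff(series.y) ** 2
    per_window = np.sqrt(_sliding(d2, n - 1).mean(axis=1))
    return float(np.median(per_window))


def std_precision(series: GazeSeries, window_ms: float = 200.0) -> float:
    """STD precision ``sqrt(var(x) + var(y))``: median over moving windows.

    Population variances; captures slower wander than RMS-S2S.
    """
    n = _window_length(series, window_ms)
    wx = _sliding(series.x, n)
    wy = _sliding(series.y, n)
    per_window = np.sqrt(wx.var(axis=1) + wy.var(axis=1))
    return float(np.median(per_window))


def accuracy(
    gaze: GazeSeries,
    segments: Sequence[Tuple[int, int]],
    targets: Sequence[Tuple[float, float]],
) -> float:
    """Mean gaze offset (deg) over fixation targets.

    ``segments`` are (start, stop) sample index pairs, one per fixation,
    aligned with ``targets`` (repeated targets allowed).  Per fixation the
    offset is the Euclidean distance between the per-axis median gaze and
    the target; offsets are averaged over the repetitions of each target,
    then across targets.  Empty segments are excluded with a warning.
    """
    if len(segments) != len(targets):
        raise ValueError("one target per fixation segment required")
    per_target: Dict[Tuple[float, float], List[float]] = {}
    for (start, stop), target in zip(segments, targets):
        sel = slice(start, stop)
        ok = gaze.valid[sel]
        if stop <= start or not ok.any():
            warnings.warn(f"empty fixation segment ({start}, {stop}); excluded")
            continue
        mx = float(np.median(gaze.x[sel][ok]))
        my = float(np.median(gaze.y[sel][ok]))
        offset = float(np.hypot(mx - target[0], my - target[1]))
        per_target.setdefault(tuple(target), []).append(offset)
    if not per_target:
        raise ValueError("no usable fixation segments")
    return float(np.mean([np.mean(v) for v in per_target.values()]))
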