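"""Synthetic corneal-reflection (CR) image generator.

The CR in a video-based eye tracker image is modelled as a heavily
oversaturated 2-D Gaussian: an isotropic Gaussian of amplitude ``A`` (in
saturation units, where 1.0 corresponds to the 255-level ceiling of an
8-bit camera) is clipped at 1.0, leaving a flat saturated disk of radius
``r`` surrounded by shallow tails.  The Gaussian width is derived from the
requested saturated radius so that, whatever the amplitude, the rendered
intensity at distance ``r`` from the center equals exactly 1::

    sigma_w = r / sqrt(-2 * log(1 / A)),   A > 1

The CR is composed onto a two-section background (emulating the pupil-iris
border) via a per-pixel ``max``, Gaussian pixel noise is added, and the
result is clipped to [0, 255], scaled to [0, 1] and discretized to 256
levels, mimicking an 8-bit camera image.

Coordinate convention: 0-based, ``x`` is the column index, ``y`` the row
index; pixel centers sit at integer coordinates and the Gaussian is
point-sampled at pixel centers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np

__all__ = [
    "CRSpec",
    "BackgroundSpec",
    "NoiseSpec",
    "ImagePatch",
    "compute_sigma_w",
    "render_cr",
    "render_background",
    "evaluation_background",
    "compose_image",
    "make_patch",
    "sample_spec",
    "PATCH_SIZE",
    "PATCH_CENTER",
]

#: Default patch size (px) fed to the localizers and the CNN.
PATCH_SIZE = 180

#: "Center of the image" used for evaluation sweeps and stage-2 sampling;
#: chosen as 90.0 so that the stage-2 center range [89.25, 90.75] spans
#: exactly 1.5 px around it.
PATCH_CENTER = 90.0


def compute_sigma_w(r: float, A: float) -> float:
    """Gaussian width that puts the saturation boundary at radius ``r``.

    Parameters
    ----------
    r : float
        Radius of the saturated disk in pixels, ``> 0``.
    A : float
        Gaussian amplitude in saturation units, ``> 1`` (no saturated
        region exists otherwise).
    """
    if r <= 0:
        raise ValueError(f"saturated radius must be positive, got {r}")
    if A <= 1:
        raise ValueError(
            f"amplitude must exceed 1 for a saturation boundary to exist, got {A}"
        )
    return r / math.sqrt(2.0 * math.log(A))


@dataclass(frozen=True)
class CRSpec:
    """Parameters of one synthetic corneal reflection."""

    x_c: float  # horizontal center (px)
    y_c: float  # vertical center (px)
    r: float  # saturated-disk radius (px)
    A: float  # Gaussian amplitude (saturation units)

    def __post_init__(self) -> None:
        compute_sigma_w(self.r, self.A)  # validates r and A

    @property
    def sigma_w(self) -> float:
        """Derived Gaussian width (px)."""
        return compute_sigma_w(self.r, self.A)


@dataclass(frozen=True)
class BackgroundSpec:
    """Two-section background split by a smoothed straight edge.

    ``light_level=None`` renders a uniform background at ``dark_level``
    (the "no gray" evaluation condition).  Levels are 8-bit image levels
    (0..255).  The transition between the sections follows a raised-cosine
    profile over a band of ``smooth_width`` pixels centered on the line.
    """

    line_point: Tuple[float, float] = (0.0, 0.0)  # (x, y) on the line
    theta: float = 0.0  # line orientation, radians in [0, 2*pi)
    dark_level: float = 10.0
    light_level: Optional[float] = None
    smooth_width: float = 4.0

    def __post_init__(self) -> None:
        if self.dark_level < 1:
            raise ValueError("dark_level must be >= 1 (full black never occurs)")
        if self.light_level is not None and self.dark_level >= self.light_level:
            raise ValueError("dark_level must be below light_level")


@dataclass(frozen=True)
class NoiseSpec:
    """Additive i.i.d. Gaussian pixel noise, in image levels."""

    sigma_n: float = 0.0
    seed: object = None  # int or numpy SeedSequence; None -> fresh entropy

    def __post_init__(self) -> None:
        if self.sigma_n < 0:
            raise ValueError("sigma_n must be >= 0")


@dataclass(frozen=True)
class ImagePatch:
    """8-bit-quantized grayscale patch with values on the k/255 lattice."""

    pixels: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        p = np.asarray(self.pixels)
        if p.ndim != 2:
            raise ValueError("patch must be 2-D")
        object.__setattr__(self, "pixels", p)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


def _pixel_grid(size) -> Tuple[np.ndarray, np.ndarray]:
    if np.isscalar(size):
        h = w = int(size)
    else:
        h, w = size
    y, x = np.mgrid[0:h, 0:w]
    return x.astype(float), y.astype(float)


def render_cr(spec: CRSpec, size=PATCH_SIZE) -> np.ndarray:
    """Render the pre-clip CR intensity field in saturation units.

    The value at the center is ``A``, at distance ``r`` exactly 1, and at
    distance ``2r`` it is ``A ** -3``.
    """
    x, y = _pixel_grid(size)
    s2 = 2.0 * spec.sigma_w**2
    return spec.A * np.exp(-(((x - spec.x_c) ** 2 + (y - spec.y_c) ** 2) / s2))


def _dark_weight(d: np.ndarray, smooth_width: float) -> np.ndarray:
    """Raised-cosine blend: 1 on the dark side (d <= -w/2), 0 on the light
    side (d >= w/2), 0.5 on the line."""
    half = smooth_width / 2.0
    b = 0.5 * (1.0 + np.cos(np.pi * (d + half) / smooth_width))
    b = np.where(d <= -half, 1.0, b)
    b = np.where(d >= half, 0.0, b)
    return b


def render_background(bg: BackgroundSpec, size=PATCH_SIZE) -> np.ndarray:
    """Render the background field in image levels (0..255, continuous)."""
    x, y = _pixel_grid(size)
    if bg.light_level is None:
        return np.full(x.shape, float(bg.dark_level))
    # signed perpendicular distance; normal n = (-sin t, cos t); dark at d < 0
    px, py = bg.line_point
    d = -math.sin(bg.theta) * (x - px) + math.cos(bg.theta) * (y - py)
    b = _dark_weight(d, bg.smooth_width)
    return bg.dark_level * b + bg.light_level * (1.0 - b)


def evaluation_background(
    E: Optional[float],
    r: float,
    x_c: float = PATCH_CENTER,
    y_c: float = PATCH_CENTER,
    light_level: float = 128.0,
    dark_level: float = 10.0,
) -> BackgroundSpec:
    """Background used in the synthetic evaluation sweeps.

    A vertical edge is placed ``E`` CR radii from the CR center (``E=-1``
    puts it one radius to the *left*), with the lighter gray section on the
    left and the dark section on the right.  ``E=None`` is the "no gray"
    condition: a uniform dark background.
    """
    if E is None:
        return BackgroundSpec(dark_level=dark_level, light_level=None)
    # theta = pi/2 gives normal (-1, 0): d = -(x - x_line), dark at x > line
    return BackgroundSpec(
        line_point=(x_c + E * r, y_c),
        theta=math.pi / 2.0,
        dark_level=dark_level,
        light_level=light_level,
    )


def compose_image(
    cr_field: np.ndarray, bg_field: np.ndarray, noise: NoiseSpec = NoiseSpec()
) -> ImagePatch:
    """Combine CR and background, add pixel noise, clip and quantize.

    The CR field (saturation units) is scaled to image levels, combined with
    the background as ``max(CR, background)``, Gaussian noise of SD
    ``sigma_n`` levels is added per pixel, and the result is limited to
    [0, 255], quantized to 256 levels and scaled to [0, 1].
    """
    cr_field = np.asarray(cr_field, dtype=float)
    bg_field = np.asarray(bg_field, dtype=float)
    if cr_field.shape != bg_field.shape:
        raise ValueError(
            f"field shapes differ: {cr_field.shape} vs {bg_field.shape}"
        )
    levels = np.maximum(cr_field * 255.0, bg_field)
    if noise.sigma_n > 0:
        rng = np.random.default_rng(noise.seed)
        levels = levels + rng.normal(0.0, noise.sigma_n, size=levels.shape)
    levels = np.clip(levels, 0.0, 255.0)
    return ImagePatch(np.rint(levels) / 255.0)


def make_patch(
    cr: CRSpec,
    bg: BackgroundSpec,
    noise: NoiseSpec = NoiseSpec(),
    size=PATCH_SIZE,
) -> ImagePatch:
    """Render one complete synthetic CR patch."""
    return compose_image(render_cr(cr, size), render_background(bg, size), noise)


def sample_spec(
    stage: int, rng: np.random.Generator
) -> Tuple[CRSpec, BackgroundSpec, NoiseSpec]:
    """Draw one training-image parameter set for the given training stage.

    Stage 1 draws the CR center anywhere in the patch (margins of one
    radius); stage 2 restricts both center coordinates to [89.25, 90.75],
    i.e. 1.5 px around the patch center, matching the inference condition
    where a coarse detector has already centered the CR.  All other
    parameter distributions are identical between stages.
    """
    if stage not in (1, 2):
        raise ValueError(f"stage must be 1 or 2, got {stage}")
    r = rng.uniform(1.0, 30.0)
    if stage == 1:
        x_c = rng.uniform(r, PATCH_SIZE - r)
        y_c = rng.uniform(r, PATCH_SIZE - r)
    else:
        x_c = rng.uniform(89.25, 90.75)
        y_c = rng.uniform(89.25, 90.75)
    A = rng.uniform(2.0, 20000.0)
    cr = CRSpec(x_c=x_c, y_c=y_c, r=r, A=A)

    line_x = rng.normal(x_c, 1.5 * r)
    line_y = rng.normal(y_c, 1.5 * r)
    theta = rng.uniform(0.0, 2.0 * math.pi)
    light = rng.uniform(32.0, 153.0)
    # exponential dark level, offset 1; redrawn on the rare draws that would
    # not be darker than the light section
    while True:
        dark = 1.0 + rng.exponential(10.0)
        if dark < light:
            break
    bg = BackgroundSpec(
        line_point=(line_x, line_y),
        theta=theta,
        dark_level=dark,
        light_level=light,
    )
    noise = NoiseSpec(
        sigma_n=rng.uniform(0.0, 30.0),
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    return cr, bg, noise
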