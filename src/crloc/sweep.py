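"""Synthetic evaluation sweeps over the CR parameter grid.

A condition is one combination of CR radius ``r``, Gaussian amplitude
``A``, pixel noise ``sigma_n``, background-edge location ``E`` (in CR
radii; ``None`` = uniform dark, "no gray") and light-section intensity
``I``.  For each condition the true horizontal CR center is stepped in
100 increments of 0.01 px across one pixel, with the vertical center at
the patch center and the (vertical) background edge moving with the CR;
each image gets a fresh noise realization seeded by (base seed,
condition, step) so runs are reproducible yet noise is independent across
images.  Each requested localization method is run on every image and the
signed/absolute horizontal error recorded.

The full grid is the Cartesian product of the default sets — 36,000
conditions — so desk runs slice it with ``subset``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .localizers import (
    DEFAULT_THRESHOLD,
    radial_symmetry_center,
    threshold_centroid,
)
from .synthcr import (
    PATCH_CENTER,
    PATCH_SIZE,
    CRSpec,
    NoiseSpec,
    evaluation_background,
    make_patch,
)

__all__ = ["SweepGrid", "Condition", "run_condition", "run_grid", "summarize"]

NO_GRAY = None  # uniform dark background sentinel for E


@dataclass(frozen=True)
class SweepGrid:
    """Default evaluation grid (Cartesian product of all sets)."""

    r_set: Tuple[float, ...] = tuple(range(2, 19, 2))
    A_set: Tuple[float, ...] = (10, 50, 200, 1000, 10000)
    sigma_n_set: Tuple[float, ...] = tuple(range(0, 19, 2))
    E_set: Tuple[Optional[float], ...] = (NO_GRAY, -1.5, -1.0, -0.5, 0.0, 0.5, 1.0, 1.5)
    I_set: Tuple[float, ...] = (38, 51, 64, 77, 89, 102, 115, 128, 140, 153)
    n_steps: int = 100
    delta_x: float = 0.01

    @property
    def n_conditions(self) -> int:
        return (
            len(self.r_set)
            * len(self.A_set)
            * len(self.sigma_n_set)
            * len(self.E_set)
            * len(self.I_set)
        )

    def conditions(
        self, subset: Optional[Dict[str, Sequence]] = None
    ) -> List["Condition"]:
        """All grid conditions, optionally restricted per parameter.

        ``subset`` maps parameter names (``r``, ``A``, ``sigma_n``, ``E``,
        ``I``) to the values to keep.
        """
        sets = {
            "r": self.r_set,
            "A": self.A_set,
            "sigma_n": self.sigma_n_set,
            "E": self.E_set,
            "I": self.I_set,
        }
        if subset:
            for key, values in subset.items():
                if key not in sets:
                    raise KeyError(f"unknown sweep parameter {key!r}")
                wanted = values if isinstance(values, Iterable) and not isinstance(
                    values, str
                ) else [values]
                sets[key] = tuple(v for v in sets[key] if v in tuple(wanted))
        return [
            Condition(r=r, A=A, sigma_n=sn, E=E, I=I)
            for r, A, sn, E, I in itertools.product(
                sets["r"], sets["A"], sets["sigma_n"], sets["E"], sets["I"]
            )
        ]


@dataclass(frozen=True)
class Condition:
    r: float
    A: float
    sigma_n: float
    E: Optional[float]  # None = no gray background
    I: float

    def noise_key(self, step: int) -> Tuple[int, ...]:
        """Stable non-negative integer tuple identifying (condition, step)."""
        e_code = 99 if self.E is None else int(round(2 * self.E)) + 16
        return (
            int(self.r),
            int(self.A),
            int(round(10 * self.sigma_n)),
            e_code,
            int(self.I),
            step,
        )


def _run_methods(patch, methods, model, threshold):
    out = {}
    for method in methods:
        try:
            if method == "threshold":
                res = threshold_centroid(patch, threshold=threshold)
            elif method == "radial_symmetry":
                res = radial_symmetry_center(patch)
            elif method == "cnn":
                if model is None:
                    raise ValueError("cnn method requested but no model supplied")
                from .crnet import predict_center

                res = predict_center(model, patch)
            else:
                raise ValueError(f"unknown method {method!r}")
            out[method] = (res.x, res.y)
        except Exception:
            out[method] = (np.nan, np.nan)  # recorded as missing, not a crash
    return out


def run_condition(
    cond: Condition,
    methods: Sequence[str] = ("threshold", "radial_symmetry"),
    seed: int = 0,
    model=None,
    threshold: float = DEFAULT_THRESHOLD,
    n_steps: int = 100,
    delta_x: float = 0.01,
    size: int = PATCH_SIZE,
) -> pd.DataFrame:
    """Run one grid condition: ``n_steps`` sub-pixel shifts x all methods.

    Returns a tidy frame with one row per (step, method): the condition
    parameters, the true center, the estimate and the signed and absolute
    horizontal error (px).  Method failures yield NaN estimates.
    """
    rows = []
    y_c = size / 2.0
    for step in range(n_steps):
        x_c = size / 2.0 + step * delta_x
        cr = CRSpec(x_c=x_c, y_c=y_c, r=cond.r, A=cond.A)
        bg = evaluation_background(cond.E, cond.r, x_c, y_c, light_level=cond.I)
        noise = NoiseSpec(
            sigma_n=cond.sigma_n,
            seed=np.random.SeedSequence((seed,) + cond.noise_key(step)),
        )
        patch = make_patch(cr, bg, noise, size=size)
        estimates = _run_methods(patch, methods, model, threshold)
        for method, (ex, ey) in estimates.items():
            err = ex - x_c
            rows.append(
                {
                    "r": cond.r,
                    "A": cond.A,
                    "sigma_n": cond.sigma_n,
                    "E": np.nan if cond.E is None else cond.E,
                    "I": cond.I,
                    "step": step,
                    "x_true": x_c,
                    "method": method,
                    "x_est": ex,
                    "y_est": ey,
                    "error": err,
                    "abs_error": abs(err),
                }
            )
    return pd.DataFrame(rows)


def run_grid(
    grid: SweepGrid = SweepGrid(),
    methods: Sequence[str] = ("threshold", "radial_symmetry"),
    seed: int = 0,
    subset: Optional[Dict[str, Sequence]] = None,
    model=None,
    threshold: float = DEFAULT_THRESHOLD,
) -> pd.DataFrame:
    """Run all (or a subset of) grid conditions and concatenate records.

    Noise seeds derive from (seed, condition, step), never from iteration
    order, so a grid can be resumed or split by condition: re-running any
    subset yields records identical to the corresponding rows of a full
    run.
    """
    conditions = grid.conditions(subset)
    frames = [
        run_condition(
            cond,
            methods=methods,
            seed=seed,
            model=model,
            threshold=threshold,
            n_steps=grid.n_steps,
            delta_x=grid.delta_x,
        )
        for cond in conditions
    ]
    if not frames:
        return pd.DataFrame(
            columns=[
                "r", "A", "sigma_n", "E", "I", "step", "x_true",
                "method", "x_est", "y_est", "error", "abs_error",
            ]
        )
    return pd.concat(frames, ignore_index=True)


def summarize(records: pd.DataFrame) -> pd.DataFrame:
    """Per-condition, per-method mean absolute and mean signed error.

    NaN estimates (method failures) are excluded from the means but
    counted in ``n_missing``.
    """
    if records.empty:
        raise ValueError("no sweep records to summarize")
    keys = ["r", "A", "sigma_n", "E", "I", "method"]
    grouped = records.groupby(keys, dropna=False)
    out = grouped.agg(
        mean_abs_error=("abs_error", "mean"),
        mean_signed_error=("error", "mean"),
        n_steps=("step", "size"),
        n_missing=("x_est", lambda s: int(s.isna().sum())),
    ).reset_index()
    return out
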