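"""Near-wall volume statistics and the y+ limit correlation.

The wall-normal extent of the anisotropic near-wall turbulence damping
(the *y+ limit*) is predicted from a volume-averaged, wall-distance-based
cell Reynolds number::

    Re_i          = y_i |u_i| rho_i / mu_i          (per cell)
    Re_cell,Vavg  = sum(Re_i V_i) / sum(V_i)        over cells with y+ <= 100
    y+_lim        = max(0, 0.0122 Re_cell,Vavg - 1.4098)   (linear form)

A quadratic form is also available.  The correlation was calibrated over
Re_cell,Vavg in roughly [150, 400]; evaluation outside that range is
permitted but logged as extrapolation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ShellAverage",
    "RegionCalibration",
    "CorrelationFit",
    "volume_average",
    "cell_reynolds",
    "yplus_limit_from_correlation",
    "fit_yplus_correlation",
    "read_calibration_csv",
    "LINEAR_COEFFS",
    "QUADRATIC_COEFFS",
    "CALIBRATED_RANGE",
]

logger = logging.getLogger(__name__)

#: Linear correlation y+_lim = max(0, a*Re + b).
LINEAR_COEFFS = (0.0122, -1.4098)
#: Quadratic correlation y+_lim = max(0, a*Re^2 + b*Re + c).
QUADRATIC_COEFFS = (3.7964e-5, -8.7033e-3, 1.2801)
#: Re_cell,Vavg range covered by the calibration data.
CALIBRATED_RANGE = (150.0, 400.0)

#: Default shell upper bound: includes the viscous and buffer layers while
#: excluding the core flow.
DEFAULT_SHELL_YPLUS = 100.0


@dataclass(frozen=True)
class ShellAverage:
    """Volume average of a field over the shell of cells with y+ <= bound."""

    quantity: str
    yplus_upper: float
    value: float
    total_volume: float


@dataclass(frozen=True)
class RegionCalibration:
    """One calibration point: a region's Re_cell,Vavg and required y+ limit."""

    region: str
    recell_vavg: float
    yplus_limit: float

    def __post_init__(self) -> None:
        if self.yplus_limit < 0:
            raise ValueError("yplus_limit must be non-negative")


@dataclass(frozen=True)
class CorrelationFit:
    form: str
    coefficients: tuple
    r_squared: float

    def __call__(self, recell_vavg) -> np.ndarray:
        re = np.asarray(recell_vavg, dtype=float)
        return np.maximum(0.0, np.polyval(self.coefficients, re))


def volume_average(
    cells: Iterable,
    yplus_upper: float = DEFAULT_SHELL_YPLUS,
    quantity: str = "value",
) -> ShellAverage:
    """Volume-weighted mean of cell values over the shell y+ <= yplus_upper.

    ``cells`` is an iterable of ``(value, volume, yplus)`` triples (or a
    three-column array).  Raises if the shell is empty or a volume is not
    positive.
    """
    arr = np.asarray([tuple(c) for c in cells], dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 3:
        raise ValueError("cells must be (value, volume, yplus) triples")
    values, volumes, yplus = arr.T
    if np.any(volumes <= 0):
        raise ValueError("cell volumes must be positive")
    mask = yplus <= yplus_upper
    if not np.any(mask):
        raise ValueError(f"no cells found below y+ = {yplus_upper}")
    vtot = float(volumes[mask].sum())
    avg = float(np.sum(values[mask] * volumes[mask]) / vtot)
    return ShellAverage(quantity, yplus_upper, avg, vtot)


def cell_reynolds(sample) -> float:
    """Wall-distance cell Reynolds number y |u| rho / mu at a flow sample."""
    speed = float(np.linalg.norm(sample.mean_velocity))
    return (
        sample.wall_distance * speed * sample.fluid_density
        / sample.dynamic_viscosity
    )


def yplus_limit_from_correlation(
    recell_vavg: float, form: str = "linear"
) -> float:
    """y+ limit for the near-wall anisotropic damping from Re_cell,Vavg.

    Both forms are floored at zero (a negative y+ limit is meaningless).
    """
    re = float(recell_vavg)
    if re < 0:
        raise ValueError("Recell_Vavg must be non-negative")
    lo, hi = CALIBRATED_RANGE
    if not (lo <= re <= hi):
        logger.info(
            "Re_cell,Vavg=%.1f outside the calibrated range [%g, %g]; "
            "correlation extrapolated", re, lo, hi,
        )
    if form == "linear":
        a, b = LINEAR_COEFFS
        return max(0.0, a * re + b)
    if form == "quadratic":
        a, b, c = QUADRATIC_COEFFS
        return max(0.0, a * re**2 + b * re + c)
    raise ValueError(f"unknown correlation form {form!r}")


def fit_yplus_correlation(
    points: Sequence[RegionCalibration], form: str = "linear"
) -> CorrelationFit:
    """Least-squares fit of the y+ limit correlation to calibration points."""
    degree = {"linear": 1, "quadratic": 2}.get(form)
    if degree is None:
        raise ValueError(f"unknown correlation form {form!r}")
    if len(points) < degree + 1:
        raise ValueError(f"{form} fit needs at least {degree + 1} points")
    x = np.array([p.recell_vavg for p in points], dtype=float)
    y = np.array([p.yplus_limit for p in points], dtype=float)
    if np.ptp(x) == 0:
        raise np.linalg.LinAlgError(
            "calibration points share one Recell_Vavg (rank-deficient fit)"
        )
    coeffs = np.polyfit(x, y, degree)
    resid = y - np.polyval(coeffs, x)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return CorrelationFit(form, tuple(float(c) for c in coeffs), r2)


def read_calibration_csv(path: str) -> list[RegionCalibration]:
    """Read calibration points from CSV (region, Recell_Vavg, yplus_limit)."""
    frame = pd.read_csv(path)
    cols = {c.lower(): c for c in frame.columns}
    try:
        region = cols["region"]
        re_col = cols["recell_vavg"]
        yl_col = cols["yplus_limit"]
    except KeyError as exc:
        raise ValueError(
            "calibration CSV needs columns region, Recell_Vavg, yplus_limit"
        ) from exc
    return [
        RegionCalibration(str(r), float(re), float(yl))
        for r, re, yl in zip(frame[region], frame[re_col], frame[yl_col])
    ]
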