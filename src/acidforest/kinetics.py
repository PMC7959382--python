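"""Milk-acidification kinetics: hue→pH calibration and V_max extraction.

Microplate fermentations are followed by scanning the colour (hue) of a pH
indicator every 6 minutes.  A degree-4 polynomial calibration converts hue to
pH, and the phenotype of interest, the maximum hourly acidification rate
``V_max`` (pH·h⁻¹, negative for acidifying cultures), is the most negative
sliding-window slope of the pH curve.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from numpy.polynomial import polynomial as npoly

#: sampling interval of the plate scanner, in hours (6 minutes)
SAMPLE_STEP_H = 0.1

TEMPERATURES = (25, 30, 40)
VOLUMES = ("LW", "DW")
YEASTS = ("NY", "YE")


@dataclass(frozen=True, order=True)
class Condition:
    """One growth condition: temperature × plate volume × yeast extract."""

    temperature_C: int
    volume: Literal["LW", "DW"]
    yeast: Literal["NY", "YE"]

    def __post_init__(self) -> None:
        if self.temperature_C not in TEMPERATURES:
            raise ValueError(f"temperature must be one of {TEMPERATURES}")
        if self.volume not in VOLUMES:
            raise ValueError(f"volume must be one of {VOLUMES}")
        if self.yeast not in YEASTS:
            raise ValueError(f"yeast must be one of {YEASTS}")

    @property
    def label(self) -> str:
        """Column label, e.g. ``DW_YE_30``."""
        return f"{self.volume}_{self.yeast}_{self.temperature_C}"

    @classmethod
    def from_label(cls, label: str) -> "Condition":
        vol, yeast, temp = label.split("_")
        return cls(int(temp), vol, yeast)  # type: ignore[arg-type]


#: the 12 experimental conditions, in fixed column order
ALL_CONDITIONS: tuple[Condition, ...] = tuple(
    Condition(t, v, y) for v in VOLUMES for y in YEASTS for t in TEMPERATURES
)


@dataclass
class PhCurve:
    """A single strain × condition kinetic time series (pH or hue)."""

    strain_id: str
    condition: Condition
    times: np.ndarray  # hours, uniform spacing
    values: np.ndarray
    value_kind: Literal["pH", "hue"] = "pH"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have the same length")
        if len(self.times) >= 2:
            steps = np.diff(self.times)
            if np.any(steps <= 0):
                raise ValueError("times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times)


@dataclass
class CalibrationModel:
    """Degree-4 polynomial mapping hue to pH.

    ``coefficients`` are in increasing-power order (c0..c4).  The monotonicity
    of the fit over the fitted hue range is checked numerically at fit time;
    a non-monotone fit is flagged, not rejected, because indicator-dye curves
    can wiggle at the edges of their useful range.
    """

    coefficients: np.ndarray
    hue_range: tuple[float, float]
    ph_range: tuple[float, float]
    rmse: float = 0.0
    monotone: bool = True

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if self.coefficients.shape != (5,):
            raise ValueError("calibration requires exactly 5 coefficients")

    def __call__(self, hue: np.ndarray | float) -> np.ndarray | float:
        return npoly.polyval(hue, self.coefficients)

    def in_range(self, hue: np.ndarray | float) -> np.ndarray | bool:
        lo, hi = self.hue_range
        return (np.asarray(hue) >= lo) & (np.asarray(hue) <= hi)

    def invert(self, ph: float, tol: float = 1e-10) -> float:
        """Hue giving this pH, by bisection over the fitted (monotone) range."""
        from scipy.optimize import brentq

        lo, hi = self.hue_range
        f = lambda h: float(self(h)) - ph
        flo, fhi = f(lo), f(hi)
        if flo * fhi > 0:
            raise ValueError(f"pH {ph} outside the calibrated range")
        return float(brentq(f, lo, hi, xtol=tol))


def fit_hue_calibration(pairs: Iterable[tuple[float, float]]) -> CalibrationModel:
    """Least-squares degree-4 polynomial fit of pH against hue.

    Parameters
    ----------
    pairs
        ``(hue, pH)`` calibration measurements; at least 5 distinct hue
        values are required for the quartic to be identifiable.
    """
    arr = np.asarray(list(pairs), dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("pairs must be (hue, pH) tuples")
    hue, ph = arr[:, 0], arr[:, 1]
    if len(np.unique(hue)) < 5:
        raise ValueError("need at least 5 distinct hue values for a quartic fit")
    coeffs = npoly.polyfit(hue, ph, deg=4)
    resid = npoly.polyval(hue, coeffs) - ph
    rmse = float(np.sqrt(np.mean(resid**2)))
    hue_range = (float(hue.min()), float(hue.max()))
    # numeric monotonicity check on a dense grid over the fitted range
    grid = np.linspace(*hue_range, 512)
    deriv = npoly.polyval(grid, npoly.polyder(coeffs))
    tol = 1e-12 * max(1.0, float(np.abs(deriv).max()))
    monotone = bool(np.all(deriv >= -tol) or np.all(deriv <= tol))
    if not monotone:
        warnings.warn(
            "hue calibration polynomial is not monotone over the fitted range",
            stacklevel=2,
        )
    return CalibrationModel(
        coefficients=coeffs,
        hue_range=hue_range,
        ph_range=(float(ph.min()), float(ph.max())),
        rmse=rmse,
        monotone=monotone,
    )


def hue_to_ph(calib: CalibrationModel, curve: PhCurve) -> PhCurve:
    """Convert a hue curve to pH by evaluating the calibration polynomial.

    Hues outside the fitted range are converted anyway (polynomial
    extrapolation) but a warning is emitted, since a quartic is untrustworthy
    outside its calibration support.
    """
    if curve.value_kind != "hue":
        raise ValueError(f"expected a hue curve, got value_kind={curve.value_kind!r}")
    if len(curve) and not np.all(calib.in_range(curve.values)):
        warnings.warn(
            f"curve {curve.strain_id}/{curve.condition.label}: hue values outside "
            "the calibrated range were extrapolated",
            stacklevel=2,
        )
    return PhCurve(
        strain_id=curve.strain_id,
        condition=curve.condition,
        times=curve.times.copy(),
        values=np.asarray(calib(curve.values), dtype=float),
        value_kind="pH",
    )


def compute_vmax(
    curve: PhCurve,
    window_points: int = 10,
    slope_method: Literal["ols", "endpoint"] = "ols",
) -> float:
    """Maximum hourly acidification rate of a pH curve.

    Every contiguous window of ``window_points`` measurements (10 points at
    6-minute spacing, spanning ~1 h) is fitted and the most negative slope in
    pH·h⁻¹ is returned.  If no window slopes downward the curve did not
    acidify and 0 is returned.

    ``slope_method='ols'`` (default) takes the least-squares slope over the
    window, which is robust to single-point noise; ``'endpoint'`` takes the
    difference of the window endpoints over the elapsed time.
    """
    if curve.value_kind != "pH":
        raise ValueError("V_max is defined on pH curves; convert hue first")
    n = len(curve)
    if n < window_points:
        raise ValueError(f"need at least {window_points} points, got {n}")
    if window_points < 2:
        raise ValueError("window_points must be >= 2")
    steps = np.diff(curve.times)
    if not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-9):
        raise ValueError("curve time points must be uniformly spaced")

    t = curve.times
    y = curve.values
    w = window_points
    tw = np.lib.stride_tricks.sliding_window_view(t, w)
    yw = np.lib.stride_tricks.sliding_window_view(y, w)
    if slope_method == "ols":
        tc = tw - tw.mean(axis=1, keepdims=True)
        yc = yw - yw.mean(axis=1, keepdims=True)
        slopes = (tc * yc).sum(axis=1) / (tc * tc).sum(axis=1)
    elif slope_method == "endpoint":
        slopes = (yw[:, -1] - yw[:, 0]) / (tw[:, -1] - tw[:, 0])
    else:
        raise ValueError(f"unknown slope_method {slope_method!r}")
    vmax = float(slopes.min())
    return vmax if vmax < 0 else 0.0


@dataclass
class PhenotypeTable:
    """V_max (h⁻¹) per strain per condition, with a missingness mask.

    Backed by a pandas DataFrame with strains as rows and the 12 condition
    labels as columns; missing measurements are NaN.
    """

    values: pd.DataFrame

    def __post_init__(self) -> None:
        expected = [c.label for c in ALL_CONDITIONS]
        missing_cols = set(expected) - set(self.values.columns)
        if missing_cols:
            raise ValueError(f"phenotype table missing condition columns: {sorted(missing_cols)}")
        self.values = self.values[expected].astype(float)
        self.values.index = self.values.index.astype(str)
        self.values.index.name = "strain"
        if self.values.index.has_duplicates:
            raise ValueError("duplicate strain ids in phenotype table")

    @property
    def strain_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def n_observed(self) -> int:
        return int(self.values.notna().sum().sum())

    def vmax(self, strain_id: str, condition: Condition) -> float:
        return float(self.values.at[strain_id, condition.label])


def build_phenotype_table(curves: Sequence[PhCurve], window_points: int = 10) -> PhenotypeTable:
    """Apply :func:`compute_vmax` to each curve and tabulate strain × condition.

    Absent strain×condition combinations are left missing; a duplicate
    combination is an error.
    """
    seen: set[tuple[str, str]] = set()
    strains: list[str] = []
    for c in curves:
        key = (c.strain_id, c.condition.label)
        if key in seen:
            raise ValueError(f"duplicate curve for strain {c.strain_id}, condition {c.condition.label}")
        seen.add(key)
        if c.strain_id not in strains:
            strains.append(c.strain_id)
    table = pd.DataFrame(
        np.nan, index=sorted(strains), columns=[c.label for c in ALL_CONDITIONS]
    )
    for c in curves:
        table.at[c.strain_id, c.condition.label] = compute_vmax(c, window_points=window_points)
    table.index.name = "strain"
    return PhenotypeTable(table)
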