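"""Calibration curves, back-calculation and detection/quantification limits.

The calibration model is a straight line of detector response (peak-area
ratio of analyte to internal standard) on nominal concentration, fitted by
least squares — unweighted by default, with 1/x and 1/x² weighting available
because a 5–1000 ng/mL range spans 200-fold. Unknowns are back-calculated by
inverting the line and multiplying by the dilution factor applied at the
bench.

LOD is the lowest tested concentration whose signal-to-noise ratio reaches
3:1; LOQ is the lowest tested level determined with relative error < 20% and
RSD < 20%. Both are selected among the discrete tested levels, never
interpolated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .datatypes import DomainError

WEIGHTINGS = ("none", "1/x", "1/x2")

#: Levels with fewer points than this are fittable but flagged non-reportable.
MIN_REPORTABLE_LEVELS = 6


@dataclass(frozen=True)
class CalibrationResults:
    """Fitted calibration line and its quality metrics."""

    slope: float
    intercept: float
    r_squared: float
    weighting: str
    levels_used: tuple

    @property
    def n_levels(self) -> int:
        return len(self.levels_used)

    @property
    def reportable(self) -> bool:
        """True when enough distinct levels back the curve (>= 6 here)."""
        return self.n_levels >= MIN_REPORTABLE_LEVELS

    def back_calculate(self, response, dilution_factor: float = 1.0):
        """Invert the line: ((response − intercept) / slope) × dilution."""
        return back_calculate(self, response, dilution_factor)

    def predict(self, level):
        return self.slope * np.asarray(level, dtype=float) + self.intercept

    def summary(self) -> str:
        lines = [
            "Calibration curve (response = slope·conc + intercept)",
            f"  slope      {self.slope:.6g}  per ng/mL",
            f"  intercept  {self.intercept:.6g}",
            f"  r²         {self.r_squared:.6f}",
            f"  weighting  {self.weighting}",
            f"  levels     {self.n_levels} "
            f"({min(self.levels_used):g}–{max(self.levels_used):g} ng/mL)"
            + ("" if self.reportable else "  [below reportable minimum]"),
        ]
        return "\n".join(lines)


class CalibrationModel:
    """Least-squares calibration line of response ratio on concentration.

    Parameters
    ----------
    levels : array-like
        Nominal concentrations, ng/mL; at least 2 distinct values.
    responses : array-like
        Peak-area ratios, same length.
    weighting : {"none", "1/x", "1/x2"}
        Weighted least squares with weights 1, 1/x or 1/x². Equal weights
        reduce exactly to the ordinary fit.
    """

    def __init__(self, levels, responses, weighting: str = "none"):
        levels = np.asarray(levels, dtype=float)
        responses = np.asarray(responses, dtype=float)
        if levels.shape != responses.shape or levels.ndim != 1:
            raise ValueError("levels and responses must be 1-D and equal length")
        if np.unique(levels).size < 2:
            raise ValueError("calibration needs at least 2 distinct levels")
        if weighting not in WEIGHTINGS:
            raise ValueError(f"weighting must be one of {WEIGHTINGS}")
        if weighting != "none" and np.any(levels <= 0):
            raise ValueError("1/x weighting needs strictly positive levels")
        self.levels = levels
        self.responses = responses
        self.weighting = weighting

    def fit(self) -> CalibrationResults:
        x = self.levels
        if self.weighting == "none":
            w = np.ones_like(x)
        elif self.weighting == "1/x":
            w = 1.0 / x
        else:
            w = 1.0 / x**2
        model = sm.WLS(self.responses, sm.add_constant(x), weights=w)
        res = model.fit()
        intercept, slope = res.params
        with np.errstate(divide="ignore", invalid="ignore"):
            r2 = float(res.rsquared)
        if not np.isfinite(r2):  # constant responses: no explainable variance
            r2 = 0.0
        return CalibrationResults(
            slope=float(slope),
            intercept=float(intercept),
            r_squared=r2,
            weighting=self.weighting,
            levels_used=tuple(np.unique(x)),
        )


def fit_calibration(batch, weighting: str = "none") -> CalibrationResults:
    """Fit a calibration curve from a (level, response) table.

    ``batch`` may be a DataFrame with columns ``level_ng_per_ml`` and
    ``response`` (the simulator's format) or any two-column array-like of
    (level, response) pairs.
    """
    if isinstance(batch, pd.DataFrame):
        levels = batch["level_ng_per_ml"].to_numpy(dtype=float)
        responses = batch["response"].to_numpy(dtype=float)
    else:
        arr = np.asarray(batch, dtype=float)
        levels, responses = arr[:, 0], arr[:, 1]
    return CalibrationModel(levels, responses, weighting=weighting).fit()


def back_calculate(curve: CalibrationResults, response, dilution_factor: float = 1.0):
    """Concentration corresponding to a measured response ratio.

    Over-range samples assayed after bench dilution are rescaled by
    ``dilution_factor`` (>= 1). Negative back-calculated concentrations are
    non-physical (response below the fitted blank) and raise a warning.
    """
    if not curve.slope > 0:
        raise DomainError("calibration slope must be positive")
    if dilution_factor < 1:
        raise DomainError("dilution_factor must be >= 1")
    response = np.asarray(response, dtype=float)
    conc = (response - curve.intercept) / curve.slope * dilution_factor
    if np.any(conc < 0):
        warnings.warn(
            "back-calculated concentration below zero (non-physical)",
            RuntimeWarning,
            stacklevel=2,
        )
    return float(conc) if conc.ndim == 0 else conc


def lod_from_snr(series, ratio_threshold: float = 3.0):
    """Limit of detection: lowest tested level with signal/noise >= threshold.

    ``series`` is a DataFrame with columns ``level_ng_per_ml``, ``signal``,
    ``noise`` or an iterable of (level, signal, noise) triples. Returns the
    concentration in ng/mL, or ``None`` when no level qualifies.
    """
    if isinstance(series, pd.DataFrame):
        rows = series[["level_ng_per_ml", "signal", "noise"]].to_numpy(dtype=float)
    else:
        rows = np.asarray(list(series), dtype=float)
    if rows.size == 0:
        raise ValueError("S/N series is empty")
    if np.any(rows[:, 2] <= 0):
        raise DomainError("noise must be positive")
    if np.any(rows[:, 0] <= 0):
        raise DomainError("concentrations must be positive")
    qualifying = rows[rows[:, 1] / rows[:, 2] >= ratio_threshold]
    if qualifying.size == 0:
        return None
    return float(qualifying[:, 0].min())


def loq_from_criteria(rows, re_limit: float = 20.0, rsd_limit: float = 20.0):
    """Limit of quantification among tested levels.

    The LOQ is the lowest level measured accurately (relative error strictly
    below ``re_limit`` %) and precisely (RSD strictly below ``rsd_limit`` %).
    ``rows`` is a DataFrame with columns ``level_ng_per_ml``, ``re_pct``,
    ``rsd_pct`` (as produced by the validation tables) or an iterable of
    (level, re_pct, rsd_pct) triples. Returns ng/mL or ``None``.
    """
    if isinstance(rows, pd.DataFrame):
        arr = rows[["level_ng_per_ml", "re_pct", "rsd_pct"]].to_numpy(dtype=float)
    else:
        arr = np.asarray(list(rows), dtype=float)
    if arr.size == 0:
        raise ValueError("no accuracy/precision rows supplied")
    ok = arr[(arr[:, 1] < re_limit) & (arr[:, 2] < rsd_limit)]
    if ok.size == 0:
        return None
    return float(ok[:, 0].min())
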