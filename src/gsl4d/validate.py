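"""Calibration linearity, detection limits, and carry-over.

A calibration series plots the concentration ratio x (analyte/ISTD)
against the response ratio y (peak-area analyte/ISTD).  From the ordinary
least-squares fit with slope s and response standard deviation sigma, the
lower limits of detection and quantification follow the ICH convention

    LLOD = 3.3 sigma / s        LLOQ = 10 sigma / s

"Standard deviation of responses" is read as the residual standard error
of the regression by default; the standard error of the intercept or an
externally supplied blank-response SD are selectable alternatives.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

R2_DEFAULT_THRESHOLD = 0.95


@dataclass
class CalibrationFit:
    """OLS calibration result for one analyte/ISTD pair."""

    analyte: str
    istd: str
    x: np.ndarray
    y: np.ndarray
    slope: float
    intercept: float
    r_squared: float
    sigma: float
    llod: float
    lloq: float
    sigma_mode: str = "residual"
    flag: str = ""  # "nonpositive_slope" when limits are undefined

    def summary(self) -> str:
        lines = [
            f"Calibration: {self.analyte} / {self.istd}",
            f"  n points   {len(self.x)}",
            f"  slope      {self.slope:.5g}",
            f"  intercept  {self.intercept:.5g}",
            f"  R^2        {self.r_squared:.4f}",
            f"  sigma      {self.sigma:.5g} ({self.sigma_mode})",
            f"  LLOD       {self.llod:.5g}",
            f"  LLOQ       {self.lloq:.5g}",
        ]
        if self.flag:
            lines.append(f"  flag       {self.flag}")
        return "\n".join(lines)


def fit_calibration(points, analyte: str = "analyte", istd: str = "istd",
                    sigma_mode: str = "residual",
                    blank_sd: float | None = None) -> CalibrationFit:
    """Fit y = intercept + s*x and derive LLOD/LLOQ.

    ``points`` is an (n, 2) array-like of (x, y); n >= 3 distinct x values
    are required.  ``sigma_mode``: "residual" (residual standard error),
    "intercept" (standard error of the intercept), or "blank"
    (externally supplied ``blank_sd``).
    """
    pts = np.asarray(points, dtype=float)
    x, y = pts[:, 0], pts[:, 1]
    if len(np.unique(x)) < 3:
        raise ValueError("need >= 3 distinct concentration levels")
    fit = sps.linregress(x, y)
    n = len(x)
    resid = y - (fit.intercept + fit.slope * x)
    dof = max(n - 2, 1)
    if sigma_mode == "residual":
        sigma = float(np.sqrt(np.sum(resid ** 2) / dof))
    elif sigma_mode == "intercept":
        sigma = float(fit.intercept_stderr)
    elif sigma_mode == "blank":
        if blank_sd is None:
            raise ValueError("sigma_mode='blank' requires blank_sd")
        sigma = float(blank_sd)
    else:
        raise ValueError(f"unknown sigma_mode {sigma_mode!r}")
    r2 = float(fit.rvalue ** 2)
    if fit.slope > 0:
        llod = 3.3 * sigma / fit.slope
        lloq = 10.0 * sigma / fit.slope
        flag = ""
    else:
        llod = lloq = math.nan
        flag = "nonpositive_slope"
    return CalibrationFit(
        analyte=analyte, istd=istd, x=x, y=y,
        slope=float(fit.slope), intercept=float(fit.intercept),
        r_squared=r2, sigma=sigma, llod=llod, lloq=lloq,
        sigma_mode=sigma_mode, flag=flag,
    )


def r2_acceptance(fit: CalibrationFit,
                  threshold: float = R2_DEFAULT_THRESHOLD) -> bool:
    """Linearity acceptance: R^2 at or above the threshold."""
    return fit.r_squared >= threshold


def carryover_percent(blank_area: float, standard_area: float) -> float:
    """Analyte signal in a blank following a high standard, as % of the
    standard's area."""
    if standard_area <= 0:
        return math.nan
    return 100.0 * blank_area / standard_area


def carryover_summary(pairs) -> float:
    """Mean carry-over % across (blank, standard) analyte pairs."""
    vals = [carryover_percent(b, s) for b, s in pairs]
    vals = [v for v in vals if not math.isnan(v)]
    return float(np.mean(vals)) if vals else math.nan


def dilution_series(top: float = 5.0, n_points: int = 8,
                    fold: float = 2.0) -> np.ndarray:
    """Two-fold serial dilution design from ``top`` downwards (pmol/µL);
    the default 8-point series spans 5 down to 0.039."""
    return top / fold ** np.arange(n_points - 1, -1, -1)
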