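"""Half-life estimation from decay time courses and qPCR quantities.

Three estimators cover the calibration readouts:

* ``fit_log_linear_halflife`` — first-order fluorescence decay: ordinary
  least squares of ln(value) on time; half-life = ln 2 / (-slope).
* ``fit_linear_halflife`` — straight-line fit on the raw scale; the
  half-life is the time at which the fitted line reaches half its
  intercept.  Provided because published decay fits are sometimes done
  on the linear scale; on noise-free exponential data over a short
  window the two agree closely.
* ``fit_ct_halflife`` — qPCR Ct vs time after transcription blockade:
  one additional cycle corresponds to one template halving, so the
  half-life is 1 / slope (hours per cycle).

``relative_expression`` implements the usual delta-Ct fold change
against a housekeeping gene (2^-(Ct_target - Ct_reference)).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .kinetics import DecaySeries

__all__ = [
    "HalfLifeFit",
    "fit_log_linear_halflife",
    "fit_linear_halflife",
    "fit_ct_halflife",
    "relative_expression",
]


@dataclass(frozen=True)
class HalfLifeFit:
    """Fitted half-life with regression diagnostics.

    ``decaying`` is False when the series does not decay (slope has the
    wrong sign); the half-life is then reported as +inf.
    """

    halflife: float
    slope: float
    intercept: float
    pearson_r: float
    r_squared: float
    scale: str  # "log_linear" | "linear" | "ct"
    n: int
    decaying: bool

    def to_dict(self) -> dict:
        return {
            "halflife_h": float(self.halflife) if math.isfinite(self.halflife) else None,
            "slope": float(self.slope),
            "intercept": float(self.intercept),
            "pearson_r": float(self.pearson_r),
            "r_squared": float(self.r_squared),
            "scale": self.scale,
            "n": int(self.n),
            "decaying": bool(self.decaying),
        }


def _series_arrays(series: DecaySeries | tuple) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(series, DecaySeries):
        t, v = series.times, series.values
    else:
        t, v = series
    t = np.asarray(t, dtype=float)
    v = np.asarray(v, dtype=float)
    if t.shape != v.shape:
        raise ValueError("times and values must have matching shapes")
    if t.size < 3:
        raise ValueError("need at least 3 time points to fit a decay")
    if not np.all(np.isfinite(t)) or not np.all(np.isfinite(v)):
        raise ValueError("non-finite values in decay series")
    return t, v


def fit_log_linear_halflife(series: DecaySeries | tuple) -> HalfLifeFit:
    """OLS of ln(value) on time; half-life = ln2 / (-slope).

    Replicates at the same time point enter individually.  Values must be
    strictly positive.  A non-decaying series (slope >= 0) is flagged and
    the half-life reported as +inf.
    """
    t, v = _series_arrays(series)
    if np.any(v <= 0):
        raise ValueError("log-linear fit requires strictly positive values")
    res = stats.linregress(t, np.log(v))
    decaying = res.slope < 0
    hl = math.log(2.0) / -res.slope if decaying else math.inf
    return HalfLifeFit(
        halflife=hl,
        slope=res.slope,
        intercept=res.intercept,
        pearson_r=res.rvalue,
        r_squared=res.rvalue**2,
        scale="log_linear",
        n=t.size,
        decaying=decaying,
    )


def fit_linear_halflife(series: DecaySeries | tuple) -> HalfLifeFit:
    """Straight-line fit on the raw scale; half-life = time to half intercept.

    With fitted line v = intercept + slope * t, the half-life solves
    intercept + slope * t = intercept / 2, i.e. t = -intercept / (2 slope).
    """
    t, v = _series_arrays(series)
    res = stats.linregress(t, v)
    decaying = res.slope < 0 and res.intercept > 0
    hl = -res.intercept / (2.0 * res.slope) if decaying else math.inf
    return HalfLifeFit(
        halflife=hl,
        slope=res.slope,
        intercept=res.intercept,
        pearson_r=res.rvalue,
        r_squared=res.rvalue**2,
        scale="linear",
        n=t.size,
        decaying=decaying,
    )


def fit_ct_halflife(series: DecaySeries | tuple) -> HalfLifeFit:
    """OLS of Ct on time; half-life = 1 / slope (one cycle per halving).

    A slope <= 0 means the template is not decaying; the fit is flagged
    and the half-life reported as +inf.
    """
    t, ct = _series_arrays(series)
    res = stats.linregress(t, ct)
    decaying = res.slope > 0
    hl = 1.0 / res.slope if decaying else math.inf
    return HalfLifeFit(
        halflife=hl,
        slope=res.slope,
        intercept=res.intercept,
        pearson_r=res.rvalue,
        r_squared=res.rvalue**2,
        scale="ct",
        n=t.size,
        decaying=decaying,
    )


def relative_expression(ct_target: float, ct_reference: float) -> float:
    """Delta-Ct fold change relative to a housekeeping gene: 2^-(dCt)."""
    ct_target = float(ct_target)
    ct_reference = float(ct_reference)
    if not (math.isfinite(ct_target) and math.isfinite(ct_reference)):
        raise ValueError("Ct values must be finite")
    return 2.0 ** (-(ct_target - ct_reference))
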