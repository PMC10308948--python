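"""Growth-curve kinetics: extract r, K, and lag from plate-reader time series.

The estimation rules mirror standard plate-reader practice for batch growth:

* carrying capacity ``K`` is the maximum of the smoothed OD record;
* growth rate ``r`` comes from a log-linear fit of OD against time in the
  early-exponential window (readings above the detection floor and the
  pre-growth plateau, up to 30% of ``K``), with a first-order logistic
  curvature correction so the slope is unbiased even when the window brushes
  the bend of the curve;
* lag time is where that fit line extrapolates back to the inoculum density.

``GrowthKinetics`` wraps the three estimators into a model object whose
``fit()`` returns a results object with the fitted :class:`LogisticParams`,
per-stage diagnostics, ``summary()`` and ``plot()``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy import ndimage

from .params import FitError, LogisticParams, ParameterError

DETECTION_FLOOR = 0.001  # OD600; log of blank-corrected noise below this is meaningless


@dataclass
class GrowthCurve:
    """One well's time series: time (hours, strictly increasing), OD600, and
    an optional fluorescence channel, plus identifying metadata."""

    time: np.ndarray
    od: np.ndarray
    fluorescence: Optional[np.ndarray] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.od = np.asarray(self.od, dtype=float)
        if self.time.ndim != 1 or self.od.shape != self.time.shape:
            raise ParameterError("time and od must be 1-D vectors of equal length")
        if len(self.time) < 3:
            raise ParameterError("a growth curve needs at least 3 points")
        if np.any(np.diff(self.time) <= 0):
            raise ParameterError("time must be strictly increasing")
        if not np.all(np.isfinite(self.od)) or np.any(self.od < 0):
            raise ParameterError("od must be finite and >= 0")
        if self.fluorescence is not None:
            self.fluorescence = np.asarray(self.fluorescence, dtype=float)
            if self.fluorescence.shape != self.time.shape:
                raise ParameterError("fluorescence must match time in length")

    @property
    def label(self) -> str:
        m = self.meta
        return "/".join(str(m.get(k, "?")) for k in ("isolate", "context", "replicate"))


def smooth_series(values: np.ndarray, window: int) -> np.ndarray:
    """Centered moving-median then moving-mean; window=1 is the identity."""
    values = np.asarray(values, dtype=float)
    if window < 1 or window % 2 == 0:
        raise ParameterError(f"smoothing window must be odd and >= 1, got {window}")
    if window > len(values):
        raise ParameterError(
            f"smoothing window {window} exceeds series length {len(values)}"
        )
    if window == 1:
        return values.copy()
    med = ndimage.median_filter(values, size=window, mode="nearest")
    return ndimage.uniform_filter1d(med, size=window, mode="nearest")


def smooth_curve(curve: GrowthCurve, window: int) -> GrowthCurve:
    """Return a copy of the curve with the OD channel smoothed."""
    return GrowthCurve(time=curve.time, od=smooth_series(curve.od, window),
                       fluorescence=curve.fluorescence, meta=dict(curve.meta))


def subtract_blank(curve: GrowthCurve, blank=None) -> GrowthCurve:
    """Blank-correct a curve.

    ``blank`` may be a per-time vector (e.g. the median of dedicated blank
    wells) or a scalar; if None, the curve's own pre-growth minimum is used
    (note this also removes the inoculum density — prefer real blank wells).
    Corrected OD is clipped at 0.
    """
    if blank is None:
        blank = float(np.min(curve.od))
    od = np.maximum(curve.od - np.asarray(blank, dtype=float), 0.0)
    return GrowthCurve(time=curve.time, od=od, fluorescence=curve.fluorescence,
                       meta=dict(curve.meta))


@dataclass
class FitDiagnostics:
    window_start: float = float("nan")
    window_end: float = float("nan")
    n_points: int = 0
    r_squared: Optional[float] = None
    truncated_plateau: bool = False
    no_growth: bool = False
    widened: bool = False
    slope_raw: Optional[float] = None
    intercept: Optional[float] = None
    notes: list[str] = field(default_factory=list)


def estimate_carrying_capacity(curve: GrowthCurve, smooth_window: int = 5
                               ) -> tuple[float, FitDiagnostics]:
    """Carrying capacity as the maximum of the smoothed OD record.

    Flags ``no_growth`` when the record never rises meaningfully above its
    minimum, and ``truncated_plateau`` when the curve is still climbing at
    the end of the record (final smoothed value within 5% of the maximum
    while the last-quarter slope exceeds 2% of K per hour), i.e. the plateau
    was not reached and K is a lower bound.
    """
    window = min(smooth_window, len(curve.od) - (1 - len(curve.od) % 2))
    if window % 2 == 0:
        window -= 1
    sm = smooth_series(curve.od, max(window, 1))
    K = float(np.max(sm))
    diag = FitDiagnostics(window_start=float(curve.time[0]),
                          window_end=float(curve.time[-1]),
                          n_points=len(sm))
    rise = K - float(np.min(sm))
    if rise < max(0.005, 0.2 * float(np.min(sm))):
        diag.no_growth = True
        diag.notes.append("no growth: OD never rose above its baseline")
        return K, diag
    q = max(len(sm) // 4, 2)
    tail_t, tail_od = curve.time[-q:], sm[-q:]
    tail_slope = float(np.polyfit(tail_t, tail_od, 1)[0])
    if sm[-1] >= 0.95 * K and tail_slope > 0.02 * K:
        diag.truncated_plateau = True
        diag.notes.append("record ends while still climbing; K is a lower bound")
    return K, diag


def _exponential_window(curve: GrowthCurve, K: float, upper_fraction: float,
                        detection_floor: float,
                        relaxed: bool = False) -> np.ndarray:
    """Boolean mask of points in the early-exponential fitting window.

    The pre-growth plateau is located via the minimum of the lightly
    smoothed record; its level and scatter are summarized robustly (median
    and MAD of the readings up to that minimum). Usable points lie at/after
    the minimum, above the detection floor, at most ``upper_fraction * K``,
    and clearly above the plateau — twice its median and four robust sigmas
    over it — so lag-phase noise never leaks into the log fit. ``relaxed``
    drops the clearance to 1.2x the median for low-ceiling wells whose K
    sits too close to the inoculum to ever clear it.
    """
    od = curve.od
    w = min(5, len(od))
    if w % 2 == 0:
        w -= 1
    sm = smooth_series(od, max(w, 1))
    imin = int(np.argmin(sm))
    seg = od[: max(imin + 1, min(5, len(od)))]
    baseline = max(float(np.median(seg)), detection_floor)
    sigma = 1.4826 * float(np.median(np.abs(seg - np.median(seg))))
    if relaxed:
        lo = max(detection_floor, 1.2 * baseline)
    else:
        lo = max(detection_floor, 2.0 * baseline, baseline + 4.0 * sigma)
    idx = np.arange(len(od))
    return (idx >= imin) & (od > lo) & (od <= upper_fraction * K)


def estimate_growth_rate(curve: GrowthCurve, K: float,
                         upper_fraction: float = 0.3,
                         detection_floor: float = DETECTION_FLOOR,
                         curvature_correction: bool = True
                         ) -> tuple[float, FitDiagnostics]:
    """Growth rate from a log-linear fit in the early-exponential window.

    Ordinary least squares of ``ln(od)`` on time over the exponential window;
    if fewer than 4 points qualify the window widens once to 50% of ``K``
    (flagged). With ``curvature_correction`` (default) the OLS slope is
    divided by ``1 - mean(od_window)/K``, the first-order logistic correction
    — without it the slope is biased low by ~7-10% for typical inoculum/K
    ratios because ``d ln S / dt = r (1 - S/K)``, not ``r``, inside the window.
    The raw slope is kept in ``diagnostics.slope_raw``.
    """
    if K <= 0:
        raise ParameterError(f"carrying capacity must be > 0, got {K}")
    if not (0 < upper_fraction < 1):
        raise ParameterError(f"upper_fraction must be in (0, 1), got {upper_fraction}")
    mask = _exponential_window(curve, K, upper_fraction, detection_floor)
    widened = False
    if mask.sum() < 4:
        mask = _exponential_window(curve, K, 0.5, detection_floor)
        widened = True
    if mask.sum() < 4:
        # low-ceiling wells (K close to the inoculum) never clear twice the
        # baseline; admit anything clearly above it before giving up
        mask = _exponential_window(curve, K, 0.5, detection_floor, relaxed=True)
    if mask.sum() < 4:
        raise FitError(
            f"too few usable points ({int(mask.sum())}) for a log-linear growth "
            f"fit in well {curve.label}"
        )
    t, y = curve.time[mask], np.log(curve.od[mask])
    slope, intercept = np.polyfit(t, y, 1)
    resid = y - (slope * t + intercept)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    r = float(slope)
    if curvature_correction:
        denom = max(1.0 - float(np.mean(curve.od[mask])) / K, 0.5)
        r = float(slope) / denom
    diag = FitDiagnostics(window_start=float(t[0]), window_end=float(t[-1]),
                          n_points=int(mask.sum()), r_squared=max(min(r2, 1.0), 0.0),
                          widened=widened, slope_raw=float(slope),
                          intercept=float(intercept))
    if widened:
        diag.notes.append("window widened to 50% of K (fewer than 4 points below 30%)")
    return r, diag


def estimate_lag_time(curve: GrowthCurve, r: float, S0: float,
                      upper_fraction: float = 0.3,
                      detection_floor: float = DETECTION_FLOOR) -> float:
    """Lag time: where the log-linear fit line extrapolates back to ``ln(S0)``.

    The line has slope ``r`` and passes through the centroid of the
    exponential window; the crossing time is clipped at 0. Returns NaN when
    ``r <= 0`` (no growth, lag undefined).
    """
    if r <= 0:
        return float("nan")
    K_proxy = float(np.max(curve.od))
    mask = _exponential_window(curve, K_proxy, upper_fraction, detection_floor)
    if mask.sum() < 2:
        mask = _exponential_window(curve, K_proxy, 0.5, detection_floor)
    if mask.sum() < 2:
        return float("nan")
    t_bar = float(np.mean(curve.time[mask]))
    y_bar = float(np.mean(np.log(curve.od[mask])))
    lag = t_bar - (y_bar - np.log(S0)) / r
    return max(float(lag), 0.0)


class GrowthKinetics:
    """Model object: logistic growth kinetics of one well.

    Parameters
    ----------
    curve : GrowthCurve
        The (optionally blank-corrected) well time series.
    upper_fraction : float
        Upper edge of the exponential fitting window as a fraction of K.
    smooth_window : int
        Odd window for the median-then-mean smoother used for K.
    detection_floor : float
        OD below which readings are excluded from log fits.
    curvature_correction : bool
        Apply the first-order logistic correction to the OLS slope.
    """

    def __init__(self, curve: GrowthCurve, upper_fraction: float = 0.3,
                 smooth_window: int = 5,
                 detection_floor: float = DETECTION_FLOOR,
                 curvature_correction: bool = True):
        self.curve = curve
        self.upper_fraction = upper_fraction
        self.smooth_window = smooth_window
        self.detection_floor = detection_floor
        self.curvature_correction = curvature_correction

    def fit(self) -> "GrowthKineticsResults":
        curve = self.curve
        K, k_diag = estimate_carrying_capacity(curve, self.smooth_window)
        if k_diag.no_growth:
            S0 = float(np.median(curve.od))
            params = LogisticParams(r=0.0, K=max(K, self.detection_floor),
                                    S0=max(min(S0, K), 1e-12),
                                    lag=0.0, name=str(curve.meta.get("isolate", "")))
            return GrowthKineticsResults(self, params, k_diag,
                                         FitDiagnostics(no_growth=True), float("nan"))
        r, r_diag = estimate_growth_rate(
            curve, K, self.upper_fraction, self.detection_floor,
            self.curvature_correction)
        imin = int(np.argmin(curve.od))
        S0 = float(np.median(curve.od[: imin + 1]))
        S0 = min(max(S0, self.detection_floor / 2 or 1e-12), K)
        lag = estimate_lag_time(curve, r, S0, self.upper_fraction,
                                self.detection_floor)
        params = LogisticParams(r=max(r, 0.0), K=K, S0=S0,
                                lag=0.0 if np.isnan(lag) else lag,
                                name=str(curve.meta.get("isolate", "")))
        return GrowthKineticsResults(self, params, k_diag, r_diag, lag)


@dataclass
class GrowthKineticsResults:
    """Fitted kinetics of one well: ``params`` holds (r, K, S0, lag)."""

    model: GrowthKinetics
    params: LogisticParams
    capacity_diagnostics: FitDiagnostics
    rate_diagnostics: FitDiagnostics
    lag: float

    @property
    def r(self) -> float:
        return self.params.r

    @property
    def K(self) -> float:
        return self.params.K

    @property
    def no_growth(self) -> bool:
        return self.capacity_diagnostics.no_growth or self.rate_diagnostics.no_growth

    def summary(self) -> str:
        c, p = self.model.curve, self.params
        lines = [
            "Growth kinetics fit",
            "===================",
            f"well:            {c.label}",
            f"n observations:  {len(c.time)}",
            f"growth rate r:   {p.r:.4f} 1/h",
            f"capacity K:      {p.K:.4f} OD600",
            f"inoculum S0:     {p.S0:.5f} OD600",
            f"lag time:        {self.lag:.3f} h" if np.isfinite(self.lag)
            else "lag time:        undefined (no growth)",
            f"exp window:      [{self.rate_diagnostics.window_start:.2f}, "
            f"{self.rate_diagnostics.window_end:.2f}] h, "
            f"n={self.rate_diagnostics.n_points}, "
            f"R2={self.rate_diagnostics.r_squared if self.rate_diagnostics.r_squared is not None else float('nan'):.4f}",
        ]
        flags = []
        if self.capacity_diagnostics.truncated_plateau:
            flags.append("truncated-plateau")
        if self.no_growth:
            flags.append("no-growth")
        if self.rate_diagnostics.widened:
            flags.append("widened-window")
        lines.append(f"flags:           {', '.join(flags) if flags else 'none'}")
        return "\n".join(lines)

    def predicted(self, t=None) -> np.ndarray:
        """Fitted logistic curve evaluated on ``t`` (defaults to the data grid)."""
        from .lv import logistic_solution

        t = self.model.curve.time if t is None else np.asarray(t, float)
        return logistic_solution(self.params, t)

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        c = self.model.curve
        ax.semilogy(c.time, np.maximum(c.od, 1e-4), ".", ms=3, label="observed")
        ax.semilogy(c.time, np.maximum(self.predicted(), 1e-4), "-",
                    label="fitted logistic")
        ax.axvspan(self.rate_diagnostics.window_start,
                   self.rate_diagnostics.window_end, alpha=0.15,
                   label="exp window")
        ax.set_xlabel("time (h)")
        ax.set_ylabel("OD600")
        ax.set_title(c.label)
        ax.legend()
        return ax
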