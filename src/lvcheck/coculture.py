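"""Two-species coculture analysis.

A coculture is observed through two channels: total OD600 and the GFP
fluorescence of the tagged species. A piecewise calibration converts
fluorescence to the tagged species' OD; subtracting that from the total OD
yields the partner's density. From the deconvolved channels the module
infers the interaction coefficients two ways:

* an *empirical trace*: invert the focal species' growth equation pointwise
  over the exponential window to get a per-timepoint estimate of ``c_ij``;
* a *global fit*: least-squares adjustment of (c12, c21) so the simulated
  community dynamics match both deconvolved channels across all traces and
  inoculum ratios simultaneously (baseline kinetics stay fixed at their
  monoculture values).

Agreement (in sign and magnitude) between these and the spent-medium-derived
coefficients is the coculture-level check of the LV description.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import least_squares

from .kinetics import smooth_series
from .params import FitError, LogisticParams, LVSystem, ParameterError


@dataclass(frozen=True)
class GFPCalibration:
    """Piecewise GFP -> OD600 calibration for the tagged species.

    Below ``branch_threshold`` fluorescence units the conversion is linear,
    ``linear_scale * (F + linear_offset)``; above it the conversion is
    ``-a + sqrt(a^2 - b)`` with ``b = b_scale * (b_offset - F)``. Defaults
    are the constants of the sGFP S. aureus calibration. The two branches
    leave a small gap in OD (~0.0950-0.0977): ODs falling inside it have no
    exact preimage and are mapped to the threshold on inversion.
    """

    linear_scale: float = 2.97e-5
    linear_offset: float = 200.0
    branch_threshold: float = 3000.0
    a: float = 0.0283
    b_scale: float = 5.20e-6
    b_offset: float = 100.0

    def __post_init__(self) -> None:
        if self.linear_scale <= 0:
            raise ParameterError("linear_scale must be > 0")
        if self.branch_threshold <= self.b_offset:
            raise ParameterError("branch_threshold must exceed b_offset")

    @property
    def od_linear_max(self) -> float:
        """Supremum of the linear branch's OD range (at F -> threshold)."""
        return self.linear_scale * (self.branch_threshold + self.linear_offset)

    @property
    def od_sqrt_min(self) -> float:
        """OD at the threshold on the square-root branch."""
        b = self.b_scale * (self.b_offset - self.branch_threshold)
        return -self.a + float(np.sqrt(self.a**2 - b))


def gfp_to_od(F, cal: GFPCalibration = GFPCalibration()) -> np.ndarray:
    """Convert fluorescence to the tagged species' OD600 (vectorized).

    Accepts ``F >= -linear_offset`` (the linear branch extended to OD 0, so
    background-subtracted signals near zero remain convertible).
    """
    F = np.asarray(F, dtype=float)
    scalar = F.ndim == 0
    F = np.atleast_1d(F)
    if np.any(F < -cal.linear_offset):
        raise ParameterError(
            f"fluorescence below -{cal.linear_offset} maps to negative OD"
        )
    od = cal.linear_scale * (F + cal.linear_offset)
    hi = F >= cal.branch_threshold
    if np.any(hi):
        b = cal.b_scale * (cal.b_offset - F[hi])
        disc = cal.a**2 - b
        if np.any(disc < 0):
            raise ParameterError("calibration discriminant negative (a^2 - b < 0)")
        od[hi] = -cal.a + np.sqrt(disc)
    return od[0] if scalar else od


def invert_gfp_calibration(od, cal: GFPCalibration = GFPCalibration(),
                           extrapolate: bool = False,
                           return_gap_mask: bool = False):
    """Exact algebraic inverse of :func:`gfp_to_od`, branch by branch.

    ODs inside the calibration's discontinuity gap ``[od_linear_max,
    od_sqrt_min)`` have no preimage and are mapped to the branch threshold
    (flagged via ``return_gap_mask``). ODs below ``gfp_to_od(0)`` raise
    unless ``extrapolate`` is set, in which case the linear branch extends
    down to OD 0 (F = -linear_offset) — needed to synthesize fluorescence
    for inocula dimmer than the calibration's zero-signal OD.
    """
    od = np.asarray(od, dtype=float)
    scalar = od.ndim == 0
    od = np.atleast_1d(od)
    od0 = gfp_to_od(0.0, cal) if not extrapolate else 0.0
    if np.any(od < od0 - 1e-12):
        raise ParameterError(
            f"OD below the calibration range ({od.min():.5f} < {od0:.5f})"
        )
    F = od / cal.linear_scale - cal.linear_offset
    gap = (od >= cal.od_linear_max) & (od < cal.od_sqrt_min)
    F[gap] = cal.branch_threshold
    hi = od >= cal.od_sqrt_min
    if np.any(hi):
        # od = -a + sqrt(a^2 - b)  =>  b = a^2 - (od + a)^2
        b = cal.a**2 - (od[hi] + cal.a) ** 2
        F[hi] = cal.b_offset - b / cal.b_scale
    if scalar:
        F, gap = F[0], gap[0]
    return (F, gap) if return_gap_mask else F


@dataclass
class CocultureTrace:
    """Observed coculture channels plus (after deconvolution) the per-species
    densities. ``od1`` is the GFP-tagged species; ``od2`` the partner."""

    time: np.ndarray
    total_od: np.ndarray
    fluorescence: np.ndarray
    od1: Optional[np.ndarray] = None
    od2: Optional[np.ndarray] = None
    meta: dict = field(default_factory=dict)
    clamped: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.total_od = np.asarray(self.total_od, dtype=float)
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        if not (self.time.shape == self.total_od.shape == self.fluorescence.shape):
            raise ParameterError("coculture channels must have equal length")
        if np.any(np.diff(self.time) <= 0):
            raise ParameterError("time must be strictly increasing")

    @property
    def deconvolved(self) -> bool:
        return self.od1 is not None and self.od2 is not None

    @property
    def clamped_fraction(self) -> float:
        if self.clamped is None:
            return 0.0
        return float(np.mean(self.clamped))


def deconvolve_coculture(trace: CocultureTrace,
                         cal: GFPCalibration = GFPCalibration()) -> CocultureTrace:
    """Split the total-OD channel into the two species.

    ``od1 = gfp_to_od(F)``; ``od2 = max(0, total - od1)``. Points where the
    converted od1 exceeds the total are clamped (od2 = 0) and flagged; the
    flagged fraction is available as ``clamped_fraction``.
    """
    od1 = gfp_to_od(np.maximum(trace.fluorescence, -cal.linear_offset), cal)
    clamped = od1 > trace.total_od
    od2 = np.maximum(trace.total_od - od1, 0.0)
    return CocultureTrace(time=trace.time, total_od=trace.total_od,
                          fluorescence=trace.fluorescence, od1=od1, od2=od2,
                          meta=dict(trace.meta), clamped=clamped)


@dataclass
class InteractionTrace:
    """Per-timepoint empirical interaction-coefficient estimates.

    ``valid`` masks points inside the exponential window with the partner
    above the density threshold; ``c_hat`` is finite wherever valid."""

    time: np.ndarray
    c_hat: np.ndarray
    valid: np.ndarray
    focal: int

    @property
    def median(self) -> float:
        return float(np.median(self.c_hat[self.valid]))

    @property
    def sd(self) -> float:
        return float(np.std(self.c_hat[self.valid]))


def empirical_interaction_trace(trace: CocultureTrace,
                                baseline_i: LogisticParams,
                                baseline_j: LogisticParams,
                                focal: int = 1,
                                window: Optional[tuple[float, float]] = None,
                                window_hours: float = 4.5,
                                partner_floor: float = 0.005,
                                smooth_window: int = 1,
                                detection_floor: float = 1e-4) -> InteractionTrace:
    """Invert the focal species' growth equation pointwise.

    From ``dS_i/dt = r_i S_i (1 - (S_i - c_ij S_j)/K_i)``,

        ``c_hat_ij(t) = [S_i - K_i + K_i (d ln S_i/dt) / r_i] / S_j``

    evaluated on smoothed channels, restricted to the exponential window
    (default: lag_i to lag_i + 4.5 h, the first hours of growth) and to
    points where the partner density exceeds ``partner_floor`` (division
    guard). The derivative is a centered finite difference of the
    *log*-density — at low OD its truncation error is ~K/S_i-fold smaller
    than differentiating the density itself, which matters because the
    error is amplified by 1/S_j — and points whose difference stencil
    straddles the focal lag kink are excluded from the window.

    ``smooth_window`` defaults to 1 (identity): the pointwise estimates are
    exact on clean data, and under multiplicative noise the *median* over
    the window stays nearly unbiased unsmoothed, whereas pre-smoothing the
    channels biases it (a moving mean inflates a convex exponential). Set a
    wider odd window to trade bias for per-point variance on ragged data.
    """
    if not trace.deconvolved:
        raise ParameterError("trace must be deconvolved first")
    if focal not in (1, 2):
        raise ParameterError("focal must be 1 or 2")
    Si = trace.od1 if focal == 1 else trace.od2
    Sj = trace.od2 if focal == 1 else trace.od1
    base = baseline_i
    Si_s = smooth_series(Si, smooth_window)
    Sj_s = smooth_series(Sj, smooth_window)
    dt = float(np.median(np.diff(trace.time)))
    stencil = (max(smooth_window, 3) // 2 + 1) * dt
    if window is None:
        window = (base.lag + stencil, base.lag + window_hours)
    with np.errstate(divide="ignore", invalid="ignore"):
        dlnSi = np.gradient(np.log(np.maximum(Si_s, 1e-12)), trace.time)
        c_hat = (Si_s - base.K + base.K * dlnSi / base.r) / Sj_s
    valid = ((trace.time >= window[0]) & (trace.time <= window[1])
             & (Sj_s > partner_floor) & (Si_s > detection_floor)
             & np.isfinite(c_hat))
    if not np.any(valid):
        raise FitError(
            f"no valid points for the empirical interaction trace "
            f"(window {window}, partner floor {partner_floor})"
        )
    return InteractionTrace(time=trace.time, c_hat=c_hat, valid=valid, focal=focal)


def _trace_initials(trace: CocultureTrace, lags: np.ndarray,
                    floor: float = 1e-6) -> np.ndarray:
    """Initial densities from the pre-lag deconvolved readings (absorbs
    inoculation error); falls back to the first three points if no lag."""
    pre = trace.time < max(float(np.min(lags)), trace.time[min(3, len(trace.time) - 1)])
    s1 = float(np.mean(trace.od1[pre]))
    s2 = float(np.mean(trace.od2[pre]))
    return np.maximum([s1, s2], floor)


def simulate_pair(system: LVSystem, initial, t_grid) -> np.ndarray:
    from .lv import simulate_lv

    return simulate_lv(system, initial, t_grid)


class CocultureLV:
    """Model object: fit LV interaction coefficients to coculture dynamics.

    Parameters
    ----------
    traces : sequence of deconvolved CocultureTrace
        All replicates/inoculum ratios are fitted jointly.
    baselines : (LogisticParams, LogisticParams)
        Monoculture kinetics of the tagged species and the partner; these
        stay fixed — only the requested parameters are free.
    c0 : (float, float)
        Starting point for (c12, c21); use the spent-medium-derived values
        when available (they are the natural prior).
    free : sequence of str
        Subset of {"c12", "c21", "lag1", "lag2"} to optimise.
    bounds : (float, float)
        Box bounds applied to the interaction coefficients.
    """

    def __init__(self, traces: Sequence[CocultureTrace],
                 baselines: tuple[LogisticParams, LogisticParams],
                 c0: tuple[float, float] = (0.0, 0.0),
                 free: Sequence[str] = ("c12", "c21"),
                 bounds: tuple[float, float] = (-5.0, 5.0),
                 lag_bounds: tuple[float, float] = (0.0, 8.0)):
        traces = list(traces)
        if not traces:
            raise ParameterError("at least one coculture trace is required")
        for tr in traces:
            if not tr.deconvolved:
                raise ParameterError("traces must be deconvolved before fitting")
        bad = set(free) - {"c12", "c21", "lag1", "lag2"}
        if bad:
            raise ParameterError(f"unknown free parameters: {sorted(bad)}")
        self.traces = traces
        self.baselines = baselines
        self.c0 = tuple(c0)
        self.free = tuple(free)
        self.bounds = bounds
        self.lag_bounds = lag_bounds

    def _unpack(self, x: np.ndarray) -> tuple[float, float, float, float]:
        c12, c21 = self.c0
        lag1, lag2 = self.baselines[0].lag, self.baselines[1].lag
        vals = dict(zip(self.free, x))
        return (vals.get("c12", c12), vals.get("c21", c21),
                vals.get("lag1", lag1), vals.get("lag2", lag2))

    def _system(self, c12: float, c21: float, lag1: float, lag2: float) -> LVSystem:
        b1, b2 = self.baselines
        return LVSystem(
            isolates=[b1.with_(lag=lag1), b2.with_(lag=lag2)],
            c=np.array([[0.0, c12], [c21, 0.0]]),
        )

    def _residuals(self, x: np.ndarray) -> np.ndarray:
        c12, c21, lag1, lag2 = self._unpack(x)
        system = self._system(c12, c21, lag1, lag2)
        res = []
        for tr in self.traces:
            s0 = _trace_initials(tr, system.lag)
            sim = simulate_pair(system, s0, tr.time)
            res.append(sim[:, 0] - tr.od1)
            res.append(sim[:, 1] - tr.od2)
        return np.concatenate(res)

    def fit(self) -> "CocultureLVResults":
        x0, lo, hi = [], [], []
        for name in self.free:
            if name in ("c12", "c21"):
                x0.append(self.c0[0] if name == "c12" else self.c0[1])
                lo.append(self.bounds[0])
                hi.append(self.bounds[1])
            else:
                x0.append(self.baselines[0].lag if name == "lag1"
                          else self.baselines[1].lag)
                lo.append(self.lag_bounds[0])
                hi.append(self.lag_bounds[1])
        x0 = np.clip(np.asarray(x0, float), lo, hi)
        sol = least_squares(self._residuals, x0, bounds=(lo, hi),
                            xtol=1e-10, ftol=1e-10, gtol=1e-10)
        if not sol.success:
            raise FitError(f"LV coefficient fit did not converge: {sol.message}")
        c12, c21, lag1, lag2 = self._unpack(sol.x)
        system = self._system(c12, c21, lag1, lag2)
        return CocultureLVResults(self, system, c12, c21, sol)


@dataclass
class CocultureLVResults:
    model: CocultureLV
    system: LVSystem
    c12: float
    c21: float
    optimizer_result: object

    def rmse(self) -> dict:
        """Per-channel root-mean-square residual (OD600) across all traces."""
        r1, r2, n = 0.0, 0.0, 0
        for tr in self.model.traces:
            s0 = _trace_initials(tr, self.system.lag)
            sim = simulate_pair(self.system, s0, tr.time)
            r1 += float(np.sum((sim[:, 0] - tr.od1) ** 2))
            r2 += float(np.sum((sim[:, 1] - tr.od2) ** 2))
            n += len(tr.time)
        return {"od1": np.sqrt(r1 / n), "od2": np.sqrt(r2 / n)}

    def compare_cfsm(self, c12_cfsm: float, c21_cfsm: float) -> dict:
        """Fitted vs spent-medium-derived coefficients: absolute differences
        and sign agreement."""
        return {
            "c12_fit": self.c12, "c21_fit": self.c21,
            "c12_cfsm": c12_cfsm, "c21_cfsm": c21_cfsm,
            "abs_diff_c12": abs(self.c12 - c12_cfsm),
            "abs_diff_c21": abs(self.c21 - c21_cfsm),
            "sign_agree_c12": np.sign(self.c12) == np.sign(c12_cfsm),
            "sign_agree_c21": np.sign(self.c21) == np.sign(c21_cfsm),
        }

    def summary(self) -> str:
        rm = self.rmse()
        b1, b2 = self.model.baselines
        lines = [
            "Coculture LV fit",
            "================",
            f"traces fitted:     {len(self.model.traces)}",
            f"free parameters:   {', '.join(self.model.free)}",
            f"c12 (j=2 on i=1):  {self.c12:+.4f}",
            f"c21 (j=1 on i=2):  {self.c21:+.4f}",
            f"baseline 1:        r={b1.r:.3f}/h  K={b1.K:.3f}  lag={self.system.isolates[0].lag:.2f} h",
            f"baseline 2:        r={b2.r:.3f}/h  K={b2.K:.3f}  lag={self.system.isolates[1].lag:.2f} h",
            f"RMSE od1/od2:      {rm['od1']:.5f} / {rm['od2']:.5f} OD600",
        ]
        return "\n".join(lines)

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for tr in self.model.traces:
            ax.plot(tr.time, tr.od1, ".", color="tab:green", ms=2, alpha=0.5)
            ax.plot(tr.time, tr.od2, ".", color="tab:orange", ms=2, alpha=0.5)
            s0 = _trace_initials(tr, self.system.lag)
            sim = simulate_pair(self.system, s0, tr.time)
            ax.plot(tr.time, sim[:, 0], "-", color="tab:green", lw=1)
            ax.plot(tr.time, sim[:, 1], "-", color="tab:orange", lw=1)
        ax.set_xlabel("time (h)")
        ax.set_ylabel("OD600")
        ax.set_title("coculture data (dots) vs fitted LV (lines)")
        return ax


def fit_lv_to_coculture(traces: Sequence[CocultureTrace],
                        baselines: tuple[LogisticParams, LogisticParams],
                        c0: tuple[float, float] = (0.0, 0.0),
                        free: Sequence[str] = ("c12", "c21"),
                        bounds: tuple[float, float] = (-5.0, 5.0)
                        ) -> CocultureLVResults:
    """Functional wrapper over :class:`CocultureLV`."""
    return CocultureLV(traces, baselines, c0=c0, free=free, bounds=bounds).fit()


def compare_model_experiment(trace: CocultureTrace, system: LVSystem,
                             window_hours: float = 4.5,
                             partner_floor: float = 0.005) -> dict:
    """Simulate the given system from the trace's own initial densities and
    report per-channel RMSE plus sign agreement between the empirical
    interaction-coefficient medians and the system's c's."""
    if not trace.deconvolved:
        raise ParameterError("trace must be deconvolved first")
    s0 = _trace_initials(trace, system.lag)
    sim = simulate_pair(system, s0, trace.time)
    out = {
        "rmse_od1": float(np.sqrt(np.mean((sim[:, 0] - trace.od1) ** 2))),
        "rmse_od2": float(np.sqrt(np.mean((sim[:, 1] - trace.od2) ** 2))),
        "rmse_total": float(np.sqrt(np.mean((sim.sum(axis=1) - trace.total_od) ** 2))),
    }
    b1, b2 = system.isolates[0], system.isolates[1]
    for focal, (bi, bj) in ((1, (b1, b2)), (2, (b2, b1))):
        c_true = system.c[focal - 1, 2 - focal]
        try:
            tr = empirical_interaction_trace(trace, bi, bj, focal=focal,
                                             window_hours=window_hours,
                                             partner_floor=partner_floor)
            out[f"c_hat_{focal}"] = tr.median
            out[f"sign_agree_{focal}"] = np.sign(tr.median) == np.sign(c_true)
        except FitError:
            out[f"c_hat_{focal}"] = float("nan")
            out[f"sign_agree_{focal}"] = False
    return out
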