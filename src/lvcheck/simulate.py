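"""Synthetic plate-reader data with the statistical structure the analysis
assumes.

Generators cover the three experiment types the pipeline consumes:

* monoculture growth curves (lagged logistic + plate-reader noise),
* spent-medium (CFSM) panels in which the conditioned parameters either obey
  the LV relation ``r_ij / K_ij = r_i / K_i`` by construction or deliberately
  violate it (rate-yield tradeoff, shuffled capacities), and
* two-species cocultures observed through a total-OD channel plus a GFP
  channel synthesized through the inverse of the piecewise calibration.

Defaults follow the stated assay design: readings every 10 minutes, 48 h for
monocultures/CFSM and 24 h for cocultures, 4 replicates for panels and 6 for
cocultures. All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .coculture import CocultureTrace, GFPCalibration, invert_gfp_calibration
from .kinetics import GrowthCurve
from .lv import logistic_solution, predict_cfsm_params, simulate_lv
from .params import LogisticParams, LVSystem, NoiseModel, ParameterError

TEN_MINUTES = 1.0 / 6.0  # hours


def _time_grid(sampling_interval: float, duration: float) -> np.ndarray:
    if sampling_interval <= 0:
        raise ParameterError("sampling_interval must be > 0")
    if duration < sampling_interval:
        raise ParameterError("duration must be >= sampling_interval")
    n = int(round(duration / sampling_interval))
    return np.arange(n + 1) * sampling_interval


def simulate_monoculture_curve(params: LogisticParams,
                               noise: NoiseModel = NoiseModel(),
                               sampling_interval: float = TEN_MINUTES,
                               duration: float = 48.0,
                               seed: int = 0,
                               meta: Optional[dict] = None) -> GrowthCurve:
    """One well of lagged logistic growth observed through the noise model."""
    t = _time_grid(sampling_interval, duration)
    true = logistic_solution(params, t)
    rng = np.random.default_rng(seed)
    od = noise.apply(rng, true)
    m = {"isolate": params.name or "isolate", "context": "fresh", "replicate": 1}
    if meta:
        m.update(meta)
    return GrowthCurve(time=t, od=od, meta=m)


@dataclass
class PanelSpec:
    """Design of a synthetic spent-medium panel.

    ``violation_mode``:

    * ``"none"`` — conditioned parameters follow the LV relation exactly:
      ``K_ij = K_i + c_ij K_j``, ``r_ij = r_i K_ij / K_i``;
    * ``"rate_yield_tradeoff"`` — growth rate rises as capacity falls
      (``r_ij = r_i (1 + strength (1 - K_ij/K_i))``), producing a negative
      r-K slope;
    * ``"shuffled_K"`` — the LV capacities are permuted across contexts
      within each focal isolate, destroying the r-K coupling while keeping
      the marginal distributions.
    """

    isolates: list[LogisticParams]
    interactions: np.ndarray
    violation_mode: str = "none"
    sampling_interval: float = TEN_MINUTES
    duration: float = 48.0
    replicates: int = 4
    seed: int = 0
    tradeoff_strength: float = 1.0
    include_fresh: bool = True

    def __post_init__(self) -> None:
        self.interactions = np.asarray(self.interactions, dtype=float)
        n = len(self.isolates)
        if self.interactions.shape != (n, n):
            raise ParameterError(f"interactions must be {n}x{n}")
        if self.violation_mode not in ("none", "rate_yield_tradeoff", "shuffled_K"):
            raise ParameterError(f"unknown violation_mode {self.violation_mode!r}")
        if self.replicates < 1:
            raise ParameterError("replicates must be >= 1")
        if self.sampling_interval <= 0 or self.duration < self.sampling_interval:
            raise ParameterError("invalid sampling grid")


def conditioned_parameters(spec: PanelSpec) -> list[dict]:
    """True conditioned parameters (r_ij, K_ij) for every focal/context pair,
    before observation noise. Suppressed pairs (K_ij <= 0) carry r = K = 0."""
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0xC0FFEE]))
    out = []
    names = [p.name or f"isolate{i + 1}" for i, p in enumerate(spec.isolates)]
    for i, pi in enumerate(spec.isolates):
        rows = []
        for j, pj in enumerate(spec.isolates):
            rec = predict_cfsm_params(pi, spec.interactions[i, j], pj.K,
                                      context=names[j])
            rows.append({"focal": names[i], "context": names[j],
                         "r": rec.r, "K": rec.K, "suppressed": rec.suppressed})
        if spec.violation_mode == "rate_yield_tradeoff":
            for row in rows:
                if not row["suppressed"]:
                    row["r"] = pi.r * (1.0 + spec.tradeoff_strength
                                       * (1.0 - row["K"] / pi.K))
        elif spec.violation_mode == "shuffled_K":
            ks = [row["K"] for row in rows]
            perm = rng.permutation(len(rows))
            for row, p in zip(rows, perm):
                row["K"] = ks[p]
                row["suppressed"] = row["suppressed"] or row["K"] <= 0
        out.extend(rows)
    return out


def generate_cfsm_panel(spec: PanelSpec, noise: NoiseModel = NoiseModel()
                        ) -> tuple[list[GrowthCurve], dict]:
    """Synthesize a full spent-medium panel.

    Returns the curves (tagged focal isolate / context / replicate, plus a
    fresh-medium context per isolate when ``include_fresh``) and a truth
    sidecar dict with the generating parameters and seed, for recovery tests.
    """
    params = conditioned_parameters(spec)
    names = [p.name or f"isolate{i + 1}" for i, p in enumerate(spec.isolates)]
    by_focal = {n: {} for n in names}
    curves: list[GrowthCurve] = []
    ss = np.random.SeedSequence(spec.seed)
    n_fresh = len(spec.isolates) if spec.include_fresh else 0
    children = ss.spawn((len(params) + n_fresh) * spec.replicates)
    ci = 0
    floor = max(noise.detection_floor, 1e-4)

    def well_curves(p_true: Optional[LogisticParams], focal: str, context: str):
        nonlocal ci
        t = _time_grid(spec.sampling_interval, spec.duration)
        for rep in range(1, spec.replicates + 1):
            rng = np.random.default_rng(children[ci]); ci += 1
            true = (np.full_like(t, floor) if p_true is None
                    else logistic_solution(p_true, t))
            od = noise.apply(rng, true)
            od = np.maximum(od, min(floor, np.min(od)) if p_true is None else 0.0)
            curves.append(GrowthCurve(time=t, od=od, meta={
                "isolate": focal, "context": context, "replicate": rep}))

    if spec.include_fresh:
        for i, pi in enumerate(spec.isolates):
            well_curves(pi, names[i], "fresh")
    base = {n: p for n, p in zip(names, spec.isolates)}
    for row in params:
        pi = base[row["focal"]]
        if row["suppressed"] or row["K"] <= floor:
            row = dict(row, suppressed=True)
            well_curves(None, row["focal"], f"cfsm:{row['context']}")
        else:
            p_cond = LogisticParams(r=row["r"], K=row["K"], S0=min(pi.S0, row["K"]),
                                    lag=pi.lag, name=row["focal"])
            well_curves(p_cond, row["focal"], f"cfsm:{row['context']}")
    truth = {
        "seed": spec.seed,
        "violation_mode": spec.violation_mode,
        "isolates": [{"name": n, "r": p.r, "K": p.K, "S0": p.S0, "lag": p.lag}
                     for n, p in zip(names, spec.isolates)],
        "interactions": spec.interactions.tolist(),
        "conditioned": params,
        "noise": {"multiplicative_sd": noise.multiplicative_sd,
                  "additive_sd": noise.additive_sd,
                  "blank_offset": noise.blank_offset,
                  "detection_floor": noise.detection_floor},
    }
    return curves, truth


def simulate_coculture_trace(system: LVSystem, initial,
                             calibration: GFPCalibration = GFPCalibration(),
                             noise: NoiseModel = NoiseModel(),
                             sampling_interval: float = TEN_MINUTES,
                             duration: float = 24.0,
                             seed: int = 0,
                             meta: Optional[dict] = None) -> CocultureTrace:
    """Synthesize one coculture well: total OD = S1 + S2 (noisy, blanked),
    fluorescence = inverse-calibration of the (noisy) tagged-species density.

    Noise-free channels satisfy ``gfp_to_od(F) + S2 == total`` exactly.
    """
    if system.n != 2:
        raise ParameterError("coculture simulation requires a two-isolate system")
    initial = np.asarray(initial, dtype=float)
    if np.any(initial < 0):
        raise ParameterError("initial densities must be >= 0")
    t = _time_grid(sampling_interval, duration)
    S = simulate_lv(system, initial, t)
    rng = np.random.default_rng(seed)
    total = noise.apply(rng, S.sum(axis=1))
    s1 = S[:, 0]
    if noise.multiplicative_sd > 0:
        s1 = s1 * np.exp(rng.normal(0.0, noise.multiplicative_sd, s1.shape))
    F = invert_gfp_calibration(np.maximum(s1, 0.0), calibration, extrapolate=True)
    if noise.additive_sd > 0:
        F = F + rng.normal(0.0, noise.additive_sd / calibration.linear_scale,
                           F.shape)
    F = np.maximum(F, -calibration.linear_offset)
    m = {"pair": tuple(system.names), "initial": initial.tolist(), "replicate": 1}
    if meta:
        m.update(meta)
    return CocultureTrace(time=t, total_od=total, fluorescence=F, meta=m)


def simulate_saturating_coculture(system: LVSystem, initial,
                                  saturation_od: float = 0.05,
                                  calibration: GFPCalibration = GFPCalibration(),
                                  noise: NoiseModel = NoiseModel(),
                                  sampling_interval: float = TEN_MINUTES,
                                  duration: float = 24.0,
                                  seed: int = 0,
                                  meta: Optional[dict] = None) -> CocultureTrace:
    """A deliberately non-LV coculture generator.

    The partner's influence saturates with its own density — the interaction
    term uses ``S_j^2 / (saturation_od + S_j)`` instead of ``S_j`` — so the
    *effective* pairwise coefficient changes along the trajectory. Fitting a
    constant-coefficient LV model to such data yields coefficients that
    depend on the inoculum ratio, the hallmark of an inadequate LV
    description.
    """
    from scipy.integrate import solve_ivp

    if system.n != 2:
        raise ParameterError("requires a two-isolate system")
    initial = np.asarray(initial, dtype=float)
    t = _time_grid(sampling_interval, duration)
    r, K, lag = system.r, system.K, system.lag
    c = system.c.copy()
    np.fill_diagonal(c, 0.0)

    def rhs(tt, S):
        Sc = np.maximum(S, 0.0)
        sat = Sc**2 / (saturation_od + Sc)
        inter = c @ sat
        act = (tt >= lag).astype(float)
        return act * r * Sc * (1.0 - (Sc - inter) / K)

    sol = solve_ivp(rhs, (t[0], t[-1]), initial, t_eval=t, rtol=1e-8, atol=1e-10)
    if not sol.success:
        raise RuntimeError(f"saturating-coculture integration failed: {sol.message}")
    S = np.maximum(sol.y.T, 0.0)
    rng = np.random.default_rng(seed)
    total = noise.apply(rng, S.sum(axis=1))
    s1 = S[:, 0]
    if noise.multiplicative_sd > 0:
        s1 = s1 * np.exp(rng.normal(0.0, noise.multiplicative_sd, s1.shape))
    F = invert_gfp_calibration(np.maximum(s1, 0.0), calibration, extrapolate=True)
    if noise.additive_sd > 0:
        F = F + rng.normal(0.0, noise.additive_sd / calibration.linear_scale, F.shape)
    F = np.maximum(F, -calibration.linear_offset)
    m = {"pair": tuple(system.names), "initial": initial.tolist(), "replicate": 1,
         "generator": "saturating"}
    if meta:
        m.update(meta)
    return CocultureTrace(time=t, total_od=total, fluorescence=F, meta=m)


def table_pair_system(S0_1: float = 0.005, S0_2: float = 0.005) -> LVSystem:
    """The worked two-isolate reference system used throughout the docs and
    tests: a GFP-tagged pathobiont (r=1.85/h, K=0.61) against a slower
    commensal partner (r=1.56/h, K=0.35), mutually inhibitory
    (c12=-1.26, c21=-0.52), lags 2.35 h / 2.25 h."""
    iso1 = LogisticParams(r=1.85, K=0.61, S0=S0_1, lag=2.35, name="Sa")
    iso2 = LogisticParams(r=1.56, K=0.35, S0=S0_2, lag=2.25, name="Sna")
    c = np.array([[0.0, -1.26], [-0.52, 0.0]])
    return LVSystem(isolates=[iso1, iso2], c=c)


def demo_panel_isolates(n: int = 6, seed: int = 0
                        ) -> tuple[list[LogisticParams], np.ndarray]:
    """A plausible panel of isolates in a dilute complex medium: growth rates
    0.8-2.2/h, capacities 0.15-0.7 OD600, inocula 0.005, lags around 2 h;
    interactions mostly inhibitory (c in [-1.2, 0.3]), as observed for
    spent-medium assays in low-nutrient media."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 51966]))
    isolates = []
    for i in range(n):
        isolates.append(LogisticParams(
            r=float(rng.uniform(0.8, 2.2)),
            K=float(rng.uniform(0.15, 0.7)),
            S0=0.005, lag=float(rng.uniform(1.5, 2.5)),
            name=f"iso{i + 1}"))
    c = rng.uniform(-1.2, 0.3, size=(n, n))
    # keep conditioned capacities comfortably positive so every regression
    # has a full complement of contexts
    K = np.array([p.K for p in isolates])
    with np.errstate(divide="ignore"):
        cmin = -(K[:, None] - 0.02) / K[None, :]
    c = np.maximum(c, cmin * 0.9)
    return isolates, c
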