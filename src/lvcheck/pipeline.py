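"""End-to-end pipeline: plate CSV -> growth parameters -> consistency
verdicts -> coculture coefficient fits, with deterministic, hash-stamped
outputs."""

from __future__ import annotations

import hashlib
import json
import pathlib
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import yaml

from .coculture import (CocultureLV, CocultureTrace, GFPCalibration,
                        deconvolve_coculture)
from .consistency import RKConsistency
from .io import read_plate_csv
from .kinetics import (DETECTION_FLOOR, GrowthCurve, GrowthKinetics,
                       subtract_blank)
from .lv import interaction_coefficient
from .params import CFSMRecord, FitError, LogisticParams, ParameterError


@dataclass
class PipelineConfig:
    input_csv: str = ""
    output_dir: str = "lvcheck-out"
    upper_fraction: float = 0.3
    smooth_window: int = 5
    alpha: float = 0.05
    slope_tolerance: float = 0.25
    exp_window_hours: float = 4.5
    partner_floor: float = 0.005
    detection_floor: float = DETECTION_FLOOR
    blank: str = "auto"  # auto | wells | self | none
    curvature_correction: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("upper_fraction", "smooth_window", "alpha",
                     "slope_tolerance", "exp_window_hours", "partner_floor"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha1(payload).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


@dataclass
class PipelineResult:
    growth_params: pd.DataFrame
    context_means: pd.DataFrame
    verdicts: pd.DataFrame
    coculture_fits: pd.DataFrame
    report: dict


def _stamped_csv(df: pd.DataFrame, path: pathlib.Path, cfg_hash: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash: {cfg_hash}\n")
        df.to_csv(fh, index=False)


def fit_growth_table(curves: list[GrowthCurve], config: PipelineConfig,
                     blank=None) -> pd.DataFrame:
    """Per-well kinetics table for a list of monoculture curves."""
    rows = []
    for curve in curves:
        if blank is not None:
            curve = subtract_blank(curve, blank)
        elif config.blank == "self":
            curve = subtract_blank(curve)
        try:
            res = GrowthKinetics(
                curve, upper_fraction=config.upper_fraction,
                smooth_window=config.smooth_window,
                detection_floor=config.detection_floor,
                curvature_correction=config.curvature_correction).fit()
            rows.append({
                "isolate": curve.meta.get("isolate"),
                "context": curve.meta.get("context"),
                "replicate": curve.meta.get("replicate"),
                "r": res.r, "K": res.K, "S0": res.params.S0, "lag": res.lag,
                "r_squared": res.rate_diagnostics.r_squared,
                "no_growth": res.no_growth,
                "truncated_plateau": res.capacity_diagnostics.truncated_plateau,
                "widened": res.rate_diagnostics.widened,
                "error": "",
            })
        except FitError as exc:
            rows.append({
                "isolate": curve.meta.get("isolate"),
                "context": curve.meta.get("context"),
                "replicate": curve.meta.get("replicate"),
                "r": np.nan, "K": np.nan, "S0": np.nan, "lag": np.nan,
                "r_squared": np.nan, "no_growth": True,
                "truncated_plateau": False, "widened": False,
                "error": str(exc),
            })
    return pd.DataFrame(rows)


def consistency_from_table(growth: pd.DataFrame, config: PipelineConfig
                           ) -> tuple[pd.DataFrame, dict, dict]:
    """Aggregate a per-well kinetics table to per-(isolate, context) means,
    then run the r-K consistency test per isolate.

    Returns (verdict table, fresh-medium baselines by isolate, report dict).
    """
    ok = growth[~growth["no_growth"] & growth["error"].eq("")]
    means = (ok.groupby(["isolate", "context"], as_index=False)
             [["r", "K", "lag", "S0"]].mean())

    baselines: dict[str, LogisticParams] = {}
    for _, row in means[means["context"] == "fresh"].iterrows():
        baselines[row["isolate"]] = LogisticParams(
            r=max(row["r"], 0.0), K=row["K"],
            S0=min(max(row["S0"], 1e-6), row["K"]), lag=max(row["lag"], 0.0),
            name=row["isolate"])

    verdict_rows, reports = [], {}
    for isolate, base in sorted(baselines.items()):
        sub = means[(means["isolate"] == isolate)
                    & means["context"].str.startswith("cfsm:")]
        records = [CFSMRecord(focal=isolate, context=c[5:], r=max(r, 0.0), K=K)
                   for c, r, K in zip(sub["context"], sub["r"], sub["K"])]
        if len(records) < 3:
            continue
        try:
            res = RKConsistency(records, base, alpha=config.alpha,
                                slope_tolerance=config.slope_tolerance).fit()
        except ParameterError as exc:
            verdict_rows.append({"isolate": isolate, "lv_consistent": False,
                                 "error": str(exc)})
            continue
        verdict_rows.append({
            "isolate": isolate, "n_contexts": res.regression.n,
            "slope": res.regression.slope,
            "intercept": res.regression.intercept,
            "r_squared": res.regression.r_squared,
            "p_value": res.regression.p_value,
            "baseline_ratio": res.verdict.baseline_ratio,
            "lv_consistent": res.verdict.lv_consistent,
            "reasons": "; ".join(res.verdict.reasons), "error": "",
        })
        reports[isolate] = {
            "verdict": res.verdict.lv_consistent,
            "slope": res.regression.slope,
            "baseline_ratio": res.verdict.baseline_ratio,
            "habitat_quality": res.habitat_quality,
            "reasons": res.verdict.reasons,
        }
    return pd.DataFrame(verdict_rows), baselines, {"means": means,
                                                   "isolates": reports}


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full analysis on a long-format plate CSV.

    Stages: per-well growth fits -> per-(isolate, context) means -> per-isolate
    r-on-K regression and LV-consistency verdict -> (if coculture wells are
    present) deconvolution and joint LV coefficient fitting seeded from the
    spent-medium-derived coefficients. All tables are written under
    ``config.output_dir`` stamped with the config hash.
    """
    objects = read_plate_csv(config.input_csv)
    if not objects:
        raise ParameterError(f"no wells found in {config.input_csv}")
    curves = [o for o in objects if isinstance(o, GrowthCurve)]
    traces = [o for o in objects if isinstance(o, CocultureTrace)]
    blanks = [c for c in curves if c.meta.get("context") == "blank"]
    curves = [c for c in curves if c.meta.get("context") != "blank"]
    if not curves:
        raise ParameterError("no monoculture wells found (nothing to fit)")

    blank_vec = None
    if blanks and config.blank in ("auto", "wells"):
        blank_vec = np.median(np.vstack([b.od for b in blanks]), axis=0)

    growth = fit_growth_table(curves, config, blank=blank_vec)
    verdicts, baselines, cons_report = consistency_from_table(growth, config)
    means = cons_report["means"]
    reports = cons_report["isolates"]

    # spent-medium-derived interaction coefficients, used as coculture priors
    cfsm_c: dict[tuple[str, str], float] = {}
    for isolate, base in baselines.items():
        sub = means[(means["isolate"] == isolate)
                    & means["context"].str.startswith("cfsm:")]
        for c, K_ij in zip(sub["context"], sub["K"]):
            donor = c[5:]
            if donor in baselines and donor != isolate:
                cfsm_c[(isolate, donor)] = interaction_coefficient(
                    K_ij, base.K, baselines[donor].K)

    fit_rows = []
    by_pair: dict[tuple[str, str], list[CocultureTrace]] = {}
    for tr in traces:
        pair = tuple(tr.meta.get("pair", ("sp1", "sp2")))
        by_pair.setdefault(pair, []).append(tr)
    cal = GFPCalibration()
    for pair, pair_traces in sorted(by_pair.items()):
        a, b = pair
        if a not in baselines or b not in baselines:
            fit_rows.append({"pair": f"{a}|{b}",
                             "error": "missing monoculture baselines"})
            continue
        dec = [deconvolve_coculture(tr, cal) for tr in pair_traces]
        c0 = (cfsm_c.get((a, b), 0.0), cfsm_c.get((b, a), 0.0))
        try:
            res = CocultureLV(dec, (baselines[a], baselines[b]), c0=c0).fit()
        except FitError as exc:
            fit_rows.append({"pair": f"{a}|{b}", "error": str(exc)})
            continue
        rm = res.rmse()
        cmp = res.compare_cfsm(*c0)
        fit_rows.append({
            "pair": f"{a}|{b}", "n_traces": len(dec),
            "c12_fit": res.c12, "c21_fit": res.c21,
            "c12_cfsm": c0[0], "c21_cfsm": c0[1],
            "rmse_od1": rm["od1"], "rmse_od2": rm["od2"],
            "sign_agree_c12": bool(cmp["sign_agree_c12"]),
            "sign_agree_c21": bool(cmp["sign_agree_c21"]),
            "error": "",
        })
    coc = pd.DataFrame(fit_rows)

    outdir = pathlib.Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    h = config.config_hash()
    _stamped_csv(growth, outdir / "growth_params.csv", h)
    _stamped_csv(means, outdir / "context_means.csv", h)
    if len(verdicts):
        _stamped_csv(verdicts, outdir / "consistency_verdicts.csv", h)
    if len(coc):
        _stamped_csv(coc, outdir / "coculture_fits.csv", h)
    from .io import _to_builtin

    report = _to_builtin({"config_hash": h, "config": asdict(config),
                          "n_wells": len(curves), "n_cocultures": len(traces),
                          "isolates": reports})
    with open(outdir / "report.yaml", "w") as fh:
        yaml.safe_dump(report, fh, sort_keys=False)
    import lvcheck

    with open(outdir / "run.log", "w") as fh:
        fh.write(f"lvcheck {lvcheck.__version__}\nconfig_hash {h}\n")
        fh.write(yaml.safe_dump(asdict(config), sort_keys=False))
    return PipelineResult(growth, means, verdicts, coc, report)
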