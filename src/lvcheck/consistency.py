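"""The r-K linear-consistency criterion.

Under a Lotka-Volterra description, an isolate grown in the spent media of
its community partners keeps a constant ratio of growth rate to carrying
capacity: every conditioned pair ``(K_ij, r_ij)`` falls on a line through
the origin with slope ``r_i / K_i``, the isolate's fresh-medium ratio. The
criterion therefore regresses the measured growth rates on the measured
capacities across spent-medium contexts and asks whether the relationship is
(a) significantly positive and (b) has the baseline slope. A failed test
rules the LV description out; a passed test only fails to rule it out —
other generative models can produce the same line.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .params import CFSMRecord, LogisticParams, ParameterError


@dataclass
class RegressionResult:
    """Per-isolate OLS of r_ij on K_ij across spent-medium contexts."""

    slope: float
    intercept: float
    r_squared: float
    p_value: float  # slope significance (equivalently the model F-test)
    n: int
    focal: str
    slope_se: float = float("nan")
    slope_ci: tuple[float, float] = (float("nan"), float("nan"))


def fit_rk_regression(records: Sequence[CFSMRecord],
                      alpha: float = 0.05) -> RegressionResult:
    """OLS of growth rate (response) on carrying capacity (predictor),
    matching the orientation in which the LV derivation makes ``r_i / K_i``
    the slope. Requires >= 3 records with non-degenerate capacity spread."""
    records = [rec for rec in records if not rec.suppressed]
    if len(records) < 3:
        raise ParameterError(
            f"need >= 3 usable spent-medium records, got {len(records)}"
        )
    K = np.array([rec.K for rec in records])
    r = np.array([rec.r for rec in records])
    if np.ptp(K) <= 1e-12:
        raise ParameterError("carrying capacities are degenerate (zero variance)")
    X = sm.add_constant(K)
    fit = sm.OLS(r, X).fit()
    ci = fit.conf_int(alpha=alpha)
    return RegressionResult(
        slope=float(fit.params[1]), intercept=float(fit.params[0]),
        r_squared=float(fit.rsquared), p_value=float(fit.pvalues[1]),
        n=len(records), focal=records[0].focal,
        slope_se=float(fit.bse[1]),
        slope_ci=(float(ci[1, 0]), float(ci[1, 1])),
    )


@dataclass
class ConsistencyVerdict:
    """Outcome of the LV-consistency test for one isolate.

    ``lv_consistent`` is True only when the slope is significantly positive
    and matches the fresh-medium ratio ``r_i / K_i`` within the relative
    tolerance; ``reasons`` explains each failed clause."""

    lv_consistent: bool
    slope_matches_baseline: bool
    slope_ci: tuple[float, float]
    baseline_ratio: float
    slope: float
    p_value: float
    reasons: list[str] = field(default_factory=list)


def lv_consistency_test(result: RegressionResult, baseline: LogisticParams,
                        alpha: float = 0.05,
                        slope_tolerance: float = 0.25) -> ConsistencyVerdict:
    """Apply the criterion to a fitted r-on-K regression.

    ``slope_tolerance`` is the allowed relative deviation of the regression
    slope from the baseline ratio (the study never quantifies "matches";
    0.25 is this package's default and is exposed in every interface)."""
    ratio = baseline.r / baseline.K
    reasons = []
    if not (result.p_value < alpha):
        reasons.append(
            f"slope not significant (p={result.p_value:.3g} >= alpha={alpha})")
    if not (result.slope > 0):
        reasons.append(f"negative slope ({result.slope:.3g})")
    matches = abs(result.slope - ratio) <= slope_tolerance * ratio
    if not matches:
        reasons.append(
            f"slope {result.slope:.3g} deviates from baseline r/K={ratio:.3g} "
            f"by more than {slope_tolerance:.0%}")
    return ConsistencyVerdict(
        lv_consistent=not reasons, slope_matches_baseline=matches,
        slope_ci=result.slope_ci, baseline_ratio=ratio,
        slope=result.slope, p_value=result.p_value, reasons=reasons)


def habitat_quality(record: CFSMRecord, baseline: LogisticParams) -> float:
    """Position along the r-K line: ``q = K_ij / K_i``.

    1 means the spent medium supports fresh-medium-level growth, 0 means no
    growth; under an exact LV description this equals ``r_ij / r_i`` as well,
    so a single scalar summarizes the habitat."""
    if baseline.K <= 0:
        raise ParameterError("baseline carrying capacity must be > 0")
    return record.K / baseline.K


@dataclass
class AdditivityVerdict:
    additive: bool
    p_value: float
    mean_mixed: float
    mean_pairwise: float
    mean_difference: float
    relative_difference: float
    reasons: list[str] = field(default_factory=list)


def combined_cfsm_additivity(resp_j, resp_k, resp_mixed,
                             alpha: float = 0.05,
                             effect_band: float = 0.15) -> AdditivityVerdict:
    """Test whether the response to a 1:1 mix of two spent media equals the
    average of the responses to each medium alone.

    Welch's two-sample t-test compares the mixed-medium replicates against
    the per-replicate pairwise means of the single-medium responses; the
    verdict is *additive* when the test fails to reject at ``alpha`` AND the
    mean difference stays within ``effect_band`` of the pairwise-mean
    magnitude (a pure hypothesis test would declare any large-n dataset
    non-additive on trivial differences, and any tiny-n dataset additive)."""
    resp_j = np.asarray(resp_j, dtype=float)
    resp_k = np.asarray(resp_k, dtype=float)
    resp_mixed = np.asarray(resp_mixed, dtype=float)
    if min(len(resp_j), len(resp_k), len(resp_mixed)) < 3:
        raise ParameterError("need >= 3 replicates per group")
    if len(resp_j) != len(resp_k):
        raise ParameterError(
            "single-medium groups must have matching replicate counts to form "
            "per-replicate pairwise means")
    pairwise = (resp_j + resp_k) / 2.0
    tt = stats.ttest_ind(resp_mixed, pairwise, equal_var=False)
    mean_mixed = float(np.mean(resp_mixed))
    mean_pw = float(np.mean(pairwise))
    diff = mean_mixed - mean_pw
    rel = abs(diff) / abs(mean_pw) if mean_pw != 0 else float("inf")
    reasons = []
    if tt.pvalue < alpha:
        reasons.append(f"Welch test rejects equality (p={tt.pvalue:.3g})")
    if rel > effect_band:
        reasons.append(
            f"mean difference {diff:.3g} exceeds {effect_band:.0%} of the "
            f"pairwise mean {mean_pw:.3g}")
    return AdditivityVerdict(
        additive=not reasons, p_value=float(tt.pvalue),
        mean_mixed=mean_mixed, mean_pairwise=mean_pw,
        mean_difference=diff, relative_difference=rel, reasons=reasons)


class RKConsistency:
    """Model object: the r-K consistency criterion for one focal isolate.

    Parameters
    ----------
    records : sequence of CFSMRecord
        Conditioned growth parameters of the focal isolate across contexts
        (its own spent medium included, as in the assay design).
    baseline : LogisticParams
        Fresh-medium kinetics of the same isolate.
    """

    def __init__(self, records: Sequence[CFSMRecord], baseline: LogisticParams,
                 alpha: float = 0.05, slope_tolerance: float = 0.25):
        self.records = list(records)
        self.baseline = baseline
        self.alpha = alpha
        self.slope_tolerance = slope_tolerance

    def fit(self) -> "RKConsistencyResults":
        reg = fit_rk_regression(self.records, alpha=self.alpha)
        verdict = lv_consistency_test(reg, self.baseline, self.alpha,
                                      self.slope_tolerance)
        quality = {rec.context: habitat_quality(rec, self.baseline)
                   for rec in self.records if not rec.suppressed}
        return RKConsistencyResults(self, reg, verdict, quality)


@dataclass
class RKConsistencyResults:
    model: RKConsistency
    regression: RegressionResult
    verdict: ConsistencyVerdict
    habitat_quality: dict

    def summary(self) -> str:
        rg, vd = self.regression, self.verdict
        lines = [
            "r-K consistency test",
            "====================",
            f"focal isolate:     {rg.focal}",
            f"contexts (n):      {rg.n}",
            f"slope:             {rg.slope:.4f} 1/h per OD600  "
            f"(95% CI {rg.slope_ci[0]:.4f} .. {rg.slope_ci[1]:.4f})",
            f"intercept:         {rg.intercept:.4f} 1/h",
            f"R-squared:         {rg.r_squared:.4f}",
            f"slope p-value:     {rg.p_value:.3g}",
            f"baseline r/K:      {vd.baseline_ratio:.4f}",
            f"LV-consistent:     {vd.lv_consistent}",
        ]
        for reason in vd.reasons:
            lines.append(f"  - {reason}")
        return "\n".join(lines)

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        recs = [r for r in self.model.records if not r.suppressed]
        K = np.array([r.K for r in recs])
        r = np.array([r.r for r in recs])
        ax.plot(K, r, "o", label="spent-medium contexts")
        kk = np.linspace(0, max(K.max(), self.model.baseline.K) * 1.05, 50)
        ax.plot(kk, self.regression.intercept + self.regression.slope * kk,
                "-", label=f"fit (R2={self.regression.r_squared:.2f})")
        ax.plot(kk, self.verdict.baseline_ratio * kk, "--",
                label="baseline r/K line")
        ax.set_xlabel("carrying capacity K (OD600)")
        ax.set_ylabel("growth rate r (1/h)")
        ax.set_title(self.regression.focal)
        ax.legend()
        return ax
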