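# Methods

## Scientific setting

Pairwise microbial interactions are often summarized by generalized
Lotka–Volterra (LV) coefficients, but LV is an assumption, not a fact about
a community. `lvcheck` operationalizes a falsification test built entirely
from monoculture-style measurements: grow each isolate in the cell-free
spent medium (CFSM) of each partner, extract growth rate and carrying
capacity, and check the linear relationship an LV description forces
between them. The package covers the full chain — synthetic data generation,
growth-curve kinetics, the consistency criterion, coculture deconvolution
and coefficient inference — so the statistical behaviour of every stage is
measurable.

## Model and conventions

Community dynamics: `dS_i/dt = r_i S_i (1 − (S_i − Σ_{j≠i} c_ij S_j)/K_i)`.

* Sign convention: `c_ij < 0` is inhibition, `c_ij > 0` facilitation, and
  the conditioned capacity is `K_ij = K_i + c_ij K_j`, equivalently
  `c_ij = (K_ij − K_i)/K_j`. (The same model is sometimes written with the
  opposite sign on `c`; this package consistently uses the convention in
  which the measurable coefficient for an inhibitory pair is negative.)
* The diagonal `c_ii` is stored — an isolate's own spent medium is a real
  assay — but excluded from the dynamics: self-limitation already lives in
  `K_i`.
* Lags are hard delays: the whole growth term of isolate *i* is zero for
  `t < T_iL`. In cocultures with unequal lags this is well-defined because
  the delay gates the growth term, not the time axis.
* The classical rate coefficient is `a_ij = c_ij r_i/K_i` (1/h per OD600).

## Estimation rules

**Carrying capacity.** `K` = maximum of the median-then-mean smoothed OD
record (window 5 points; smoothing prevents a single read spike from
setting K). Flags: `no_growth` when the record never rises meaningfully
above its minimum; `truncated_plateau` when the final smoothed value is
within 5% of the maximum while the last-quarter slope still exceeds 2% of K
per hour (K is then a lower bound).

**Growth rate.** Ordinary least squares of `ln OD` on time over the
early-exponential window, defined robustly: locate the pre-growth plateau
via the smoothed minimum, summarize its level and scatter by median and
MAD, and keep points that clear both twice the plateau median and four
robust sigmas above it, up to 30% of K (widening once to 50%, then relaxing
the clearance to 1.2× for wells whose K sits close to the inoculum). The
reported rate divides the OLS slope by the first-order logistic correction
`1 − mean(OD_window)/K`; without it the slope is biased low by 7–10% for
typical inoculum-to-capacity ratios because `d ln S/dt = r (1 − S/K)`
inside the window, not `r`. The raw slope stays in the diagnostics and the
correction can be disabled. Readings at or below the detection floor
(0.001 OD default) never enter log fits.

**Lag time.** The time at which a line of slope `r` through the centroid of
the exponential window extrapolates back to `ln S0`, clipped at zero. On
noise-free synthetic curves this recovers the true lag within half a
sampling interval.

**Blank correction.** Dedicated blank wells (context `blank`) are
subtracted as a per-time median. Self-blanking by the curve's own pre-growth
minimum is available but off by default: the pre-growth reading is blank
*plus inoculum*, so self-blanking over-corrects by `S0` and distorts the
log-linear fit exactly where it is fitted.

**The r–K criterion.** Per focal isolate, OLS of `r_ij` (response) on
`K_ij` (predictor) across CFSM contexts, own spent medium included
(statsmodels OLS; slope t-test p-value). The verdict `lv_consistent`
requires (i) slope significantly positive at `alpha` (default 0.05), and
(ii) slope within `slope_tolerance` (default 0.25, deliberately exposed —
no principled value exists) of the fresh-medium ratio `r_i/K_i`. The test
is one-directional: failure rules LV out; success only fails to rule it
out, since other generative models can produce the same line.

**Habitat quality.** `q = K_ij/K_i`, the position along the r–K line
(equal to `r_ij/r_i` under exact LV); 1 = fresh-medium-equivalent, 0 = no
growth.

**Combined-CFSM additivity.** Welch's t-test of mixed-medium replicates
against per-replicate pairwise means of the single-medium responses, AND an
effect-size band (mean difference within 15% of the pairwise mean). The
band exists because "indistinguishable" by hypothesis test alone is not
falsifiable: large n rejects trivial differences, tiny n rejects nothing.
Monte-Carlo under the null (n = 6 per group) shows the verdict rejects at
the nominal 5%.

**GFP calibration.** Fluorescence converts to tagged-species OD piecewise:
linear `2.97e-5·(F + 200)` below 3000 units, `−a + sqrt(a² − b)` with
`a = 0.0283`, `b = 5.2e-6·(100 − F)` above. (The square-root reading of the
upper branch is the only one that is positive and continuous with the
linear branch; the literal polynomial reading is negative at the
threshold.) The two branches leave a gap in OD (~0.0950–0.0977) with no
preimage; inversion maps gap ODs to the threshold and can flag them. For
synthesizing fluorescence channels, the inverse may extrapolate the linear
branch down to OD 0 (`F = −200`), since real inocula are dimmer than the
calibration's zero-signal OD (0.00594).

**Coculture deconvolution.** `od1 = gfp_to_od(F)`; `od2 = max(0, total −
od1)`; points where od1 exceeds the total are clamped and the clamped
fraction reported.

**Empirical coefficient trace.** Inverting the focal species' growth
equation pointwise gives `ĉ_ij(t) = [S_i − K_i + K_i (d ln S_i/dt)/r_i]/S_j`
over the exponential window (lag to lag + 4.5 h). Numerical choices that
matter: the derivative is a centered difference of the *log* density
(truncation error smaller by ~`K_i/S_i` at low OD — critical because any
derivative error is amplified by `1/S_j` early in growth); the window
starts one full difference-plus-smoothing stencil after the lag (the lag
kink otherwise contaminates the stencil); points with partner density below
0.005 OD are invalid (division guard). Channel smoothing defaults to the
identity: pointwise estimates are exact on clean data and the window
*median* stays nearly unbiased under multiplicative noise, whereas
pre-smoothing biases it (a moving mean inflates a convex exponential).

**Coefficient fitting.** `scipy.optimize.least_squares` on the stacked
residuals of both deconvolved channels across all traces and inoculum
ratios jointly, baselines fixed at monoculture values, `(c12, c21)` free
(optionally the lags), box bounds ±5. Start from the CFSM-derived
coefficients when available — they are the natural prior. Initial densities
come from each trace's pre-lag deconvolved readings, absorbing inoculation
error.

## Numerical integration

`scipy.integrate.solve_ivp` (RK45, rtol 1e-8, atol 1e-10), with the time
axis split at lag breakpoints so the adaptive stepper never straddles the
growth-term discontinuity. Densities are clipped at zero on output (the
dynamics cannot cross zero analytically). With all `c_ij = 0` the simulator
matches the logistic closed form to better than 1e-6 relative on a
10-minute, 48-hour grid.

## Synthetic data: what it emulates and what it does not

The generators emulate dilute-complex-medium plate-reader assays: 10-minute
sampling; 48 h monocultures/CFSM panels and 24 h cocultures; 4 replicates
for panels and 6 for cocultures; lognormal multiplicative noise (sd 0.02)
plus additive read noise (sd 0.003 OD) plus an optional constant blank and
a 0.001 OD detection floor. The demo community used in the discrimination
studies draws r from U(0.8, 2.2)/h, K from U(0.15, 0.7) OD600, lags from
U(1.5, 2.5) h, inocula 0.005 OD, and interactions from U(−1.2, 0.3)
(mostly inhibitory, as observed for spent media in low-nutrient
conditions), clipped so conditioned capacities stay positive. The reference
pair used throughout docs and tests is a GFP-tagged fast grower
(r = 1.85/h, K = 0.61) against a slower partner (r = 1.56/h, K = 0.35) with
mutual inhibition c12 = −1.26, c21 = −0.52 and lags 2.35/2.25 h.

Violation regimes make the criterion's discrimination measurable:
`rate_yield_tradeoff` couples rate *against* capacity
(`r_ij = r_i (1 + s(1 − K_ij/K_i))`), `shuffled_K` permutes conditioned
capacities across contexts within each focal isolate. A separate
deliberately non-LV coculture generator saturates the partner's influence
(`S_j² /(h + S_j)` in place of `S_j`, h = 0.05 OD), reproducing the
qualitative signature of LV failure: constant-coefficient fits whose
coefficients depend on the inoculum ratio.

What green tests do **not** establish: the generators assume exactly
logistic baselines, hard lags, time-stationary interactions, and
well-mixed, geometry-free wells. Real data add pH drift, metabolic shifts
mid-growth (visible as slope changes no logistic fit captures), nonlinear
OD-to-cell-density mapping above ~0.5 OD, and contact- or induction-
dependent interactions invisible to spent-medium assays. Passing the
synthetic recovery studies therefore validates the *statistical machinery*,
not any claim about a particular real community.

## Degenerate inputs and tie-breaks

No-growth wells yield `r = 0` with a flag rather than an error; suppressed
spent-medium predictions (`K_ij ≤ 0`) yield flagged zero-capacity records;
coculture points where the converted tagged-species OD exceeds the total
are clamped with a reported fraction; regression requires ≥ 3 contexts with
non-degenerate capacities; the additivity test requires ≥ 3 replicates per
group and equal single-medium group sizes.

## Known limitations

* The logistic curvature correction assumes the within-window dynamics are
  logistic; strongly diauxic curves violate it (and everything else here).
* The r-on-K regression treats per-context means as homoscedastic;
  replicate-level weighting is not implemented.
* Coefficient fitting is a local search; with the recommended CFSM starting
  point it is reliable on LV-like data, but a global optimum is not
  guaranteed for strongly non-LV data.
* N > 2 communities are simulated but not experimentally validated by any
  stage of this pipeline; the criterion is inherently pairwise.
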