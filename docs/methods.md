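# Methods

## Problem and model

After an intravenous bolus of a filtration marker (iohexol, FITC-inulin),
glomerular filtration rate is estimated as plasma clearance

    PC = D / AUC                                    [mL/min]

where D is the injected dose (µg) and AUC the area under the plasma
concentration–time curve (µg·min/mL). The package implements four AUC
estimators for curves sampled on the 12-point schedule
0, 2, 5, 10, 20, 30, 60, 90, 120, 180, 240, 300 min:

1. **Trapezoidal (non-compartmental).** Sum of trapezoids across the
   post-dose sample points, plus a log-linear tail. The tail rate λ is the
   least-squares slope of ln C over the last k points above the threshold
   (default k = 3; the choice is ours, any 2–4 is defensible on 12-point
   curves) and the tail area is the analytic integral of the fitted
   exponential from the last observation down to the threshold
   concentration, `(C_last − c_thr)/λ`, clamped at zero. The default
   threshold is 0.5 µg/mL; integration stops there rather than at zero,
   with the threshold configurable (set 0 to integrate the fitted tail
   fully).
2. **Two-compartment.** C(t) = A·e^(−αt) + B·e^(−βt) with plateau 0,
   fitted by unweighted nonlinear least squares on raw concentrations
   (Levenberg–Marquardt on log-parameters, ftol 1e−10, ≤10⁴ evaluations),
   initialized by curve stripping: terminal log-linear fit for (B, β),
   log-linear fit of the positive early residuals for (A, α).
   AUC = A/α + B/β.
3. **One-compartment.** C(t) = B·e^(−βt) over samples from t_min = 30 min
   onward (the distribution phase is complete by then), estimated by
   ordinary least squares on ln C — exact on noiseless monoexponential
   data. AUC = B/β.
4. **Two-sample.** The one-compartment estimate from exactly two timed
   samples: β = ln(c₁/c₂)/(t₂−t₁), B = (c₁^t₂/c₂^t₁)^{1/(t₂−t₁)},
   PC = D·β/B. The implementation contract is algebraic identity with the
   two-point one-compartment fit, which pins down the intercept as a
   quotient of powers (the alternative product form is not consistent
   with the monoexponential derivation).

### Degenerate inputs and guards

* The t = 0 sample is the pre-dose draw: it defines the background
  concentration (unless one is given explicitly) and is removed before
  any fit. Background subtraction clamps at zero and flags clamped
  samples; a curve entirely at or below background raises.
* Samples flagged below the assay LLOQ (default 0.2 µg/mL) are excluded
  from all fits and AUC sums.
* Biexponential fits fall back to the one-compartment estimate, with a
  logged warning and a diagnostics tag, when (a) curve stripping finds no
  separable fast phase, (b) the optimizer fails, (c) the fitted rates are
  closer than α/β = 1.5 (non-identifiable), or (d) less than half of the
  fitted model's AUC lies inside the sampled time window. Guard (d)
  matters in practice: with multiplicative noise the optimizer
  occasionally converges to a spike exponential through the first sample
  (A huge, α fast) or a near-zero terminal rate, either of which puts
  nearly all the fitted area outside the data; such fits are
  extrapolation, not measurement.
* A non-declining (terminal) series raises rather than returning a
  negative rate.

## Agreement statistics

For paired series (reference, comparative) on the same subject-weeks:
bias_i = ref_i − comp_i (signed; the mean is the reported bias, its SD the
precision), %bias_i = 100·bias_i / mean(ref_i, comp_i), P10/P15 = percent
of pairs with |%bias| < 10 or 15, Bland–Altman limits bias ± 2·SD
(deliberately 2, not 1.96), and the R² of the linear regression of
comparative on reference weighted 1/y² (1/x² behind an option). Pairs with
zero mean are excluded with a warning.

Sensitivity to declining function is assessed two ways:

* **Percent-of-function normalization.** The reference measure
  (trapezoidal inulin clearance by default) is expressed as percent of its
  cohort week-0 mean; each other measure is mapped linearly so its week-0
  mean sits at 100% and its cohort-worst value at the floor of the
  reference percent series (data-derived, not hard-coded), with
  orientation flipped for markers that rise as function falls. On that
  common scale a straight line and a sixth-order polynomial are compared
  by the extra-sum-of-squares F-test, F = ((SS₁−SS₆)/5)/(SS₆/(n−7)):
  a clearance tracking the reference fits the line; an endogenous marker
  with a delayed rise fits the polynomial.
* **First significant week.** A repeated-measures one-way ANOVA across
  weeks gates paired t-tests of each week against week 0; p-values are
  Holm-adjusted (a studentized-range adjustment is available behind a
  flag — the common "Tukey-corrected paired t-tests" phrasing has no
  single standard definition, and Holm is the conservative default). The
  earliest week with adjusted p < 0.05 is reported.

## Synthetic cohorts

The generator emulates a longitudinal rat nephropathy study: 8 subjects,
6 weekly sessions, GFR declining along fixed per-week multipliers, two
exogenous markers per session on the 12-point schedule, and weekly
steady-state endogenous markers. Ground truth is known everywhere, so
every estimator can be scored against the generating clearance.

Exogenous marker curves come from the open two-compartment model: with
k10 = CL/V1, k12 = Q/V1, k21 = Q/V2, the hybrid rates α > β are the roots
of s² − (k10+k12+k21)s + k10·k21 and A, B follow in closed form;
D/(A/α + B/β) = CL exactly, by construction. (In the Q → 0 limit the
surviving elimination mode is the larger root α → k10; the β root tends
to zero with vanishing AUC share.)

Defaults, chosen once for a ~450 g rat and the study design above:

| parameter | default | rationale |
|---|---|---|
| baseline GFR | 2.5 mL/min | healthy adult-rat scale |
| trajectory | 1.0, 0.85, 0.62, 0.45, 0.33, 0.238 | detectable decline from week 1, floor 23.8% of baseline; the week-1 step (−15%) is set by a power analysis: clearance estimators (CV 5%, n = 8 paired) detect it with non-centrality ≈ 6 while buffered endogenous markers stay below detection |
| iohexol-like PK | V1 50, V2 40 mL, Q 8 mL/min | small molecule, fast equilibration; distribution phase ≈ 7% of AUC |
| inulin-like PK | V1 30, V2 60 mL, Q 1.5 mL/min | large polysaccharide, slow equilibration; distribution phase ≈ 50% of AUC |
| dose | 10 000 µg | peak concentrations ~200–330 µg/mL, inside a 1–400 µg/mL assay range |
| exogenous noise CV | 5% | typical LC-MS/MS / fluorometric intra-assay performance |
| LLOQ | 0.2 µg/mL | quantification limit; values below are flagged |
| endogenous markers | production/(GFR + CL_nonrenal), CV 0.25–0.30, CL_nonrenal 0.75–1.5 × baseline GFR | tubular secretion and chromogen background (creatinine), production variability and reabsorption (urea), assay/inflammation variability (cystatin C); these are what make endogenous markers lag true GFR loss in practice, beyond the hyperbolic dilution alone |

Noise is multiplicative lognormal with unit mean (assay error scales with
concentration); additive Gaussian is available behind a flag. Endogenous
markers are simulated at weekly steady state — no intra-week accumulation
dynamics — which is sufficient for the delayed-rise phenomenon. Each
(subject, week, marker) draws from its own seeded substream, so cohorts
are bit-reproducible and independent of generation order.

### What the generator does not emulate

Real assay error profiles (gross errors from hemolysis or handling,
CV inflation near the LLOQ), sample-timing jitter in awake animals,
between-subject PK heterogeneity, and adaptive physiology (e.g. rising
tubular secretion as CKD progresses) are all absent. Consequently,
passing tests show that the estimators and statistics are correct and
that the qualitative method-comparison structure (one-compartment bias
driven by distribution-phase share; endogenous markers lagging clearance)
emerges under clean conditions — they do not certify performance on real
plasma data.

One known consequence: among the two-sample schedule pairs, (30, 90) and
(60, 120) share the same 60-min spacing, and under constant-CV noise
their precision ranking follows the position of the terminal time
constant 1/β, which crosses 120 min once GFR has fallen by half. The
clean-noise simulation therefore ranks (30, 90) clearly above the
narrower pairs (that mechanism is structural and tested) but leaves
(30, 90) vs (60, 120) close to a tie across seeds, whereas studies on
real data report a clearer (30, 90) advantage, attributing the
degradation of late samples to measurement error at low concentrations —
an assay-error feature outside this generator.

## Problem sizes

Monte-Carlo checks use 500 replicate sessions per noise condition, 1000
replicates for F-test calibration and the two-sample identity, and 20
cohort seeds for the structural claims; these sizes give stable medians
and rates while keeping the full suite fast.

## Numerical choices

Log-linear fits use `numpy.polyfit` on ln C; the biexponential fit
optimizes log-parameters (positivity without constraints) with
LM; weighted regression goes through `statsmodels` WLS; the nested F-test
fits scaled-domain polynomials (`numpy.polynomial.Polynomial.fit`) for
degree-6 conditioning and guards SS₆ ≤ SS₁ against floating-point noise
on exact fits. Terminal-phase ties or small non-monotonicities are
tolerated by least squares everywhere except the two-sample input, whose
invariant c₁ > c₂ is hard. CSV round-trips write %.17g and read with
round-trip float parsing, so a written cohort reloads bit-identically.
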