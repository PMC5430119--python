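# plasmaclear

Plasma-clearance estimation of glomerular filtration rate (GFR) from
IV-bolus marker disappearance curves, with the method-agreement and
sampling-schedule analyses used to compare estimation strategies — plus a
synthetic rat-cohort simulator with known ground-truth GFR.

Endogenous markers of kidney function (creatinine, urea, cystatin C) are
insensitive to early GFR decline: a constantly produced marker cleared by
filtration sits at concentration P/(GFR + CL_nonrenal), a hyperbola that
barely moves until function has fallen substantially. Plasma clearance of
an injected exogenous marker (iohexol, FITC-inulin) measures GFR directly:

    PC = D / AUC

with dose D (µg) and AUC the area under the plasma concentration–time
curve. This package implements the four standard AUC routes —
trapezoidal with log-linear tail extrapolation, biexponential
(two-compartment) fit, terminal monoexponential (one-compartment) fit,
and the two-timed-samples simplification PC = D·β/B with
β = ln(c₁/c₂)/(t₂−t₁), B = (c₁^t₂/c₂^t₁)^{1/(t₂−t₁)} — and the statistics
to compare them: signed bias ± precision, %bias, P10/P15 accuracy,
1/C²-weighted regression R², Bland–Altman limits, line-vs-sixth-order
polynomial F-tests on a percent-of-function scale, and earliest-
significant-week detection (RM-ANOVA with Holm-adjusted paired t-tests).

See `docs/methods.md` for the models, defaults, and limitations.

## Worked example

```python
from plasmaclear import (
    SyntheticCohortConfig, simulate_cohort, subtract_background,
    clearance_trapezoidal, fit_one_compartment, two_sample_from_session,
)

cfg = SyntheticCohortConfig(seed=1)          # 8 rats x 6 weeks, 2 markers
sessions, endogenous, truth = simulate_cohort(cfg)

sess = subtract_background(sessions[0])      # R1, week 0, iohexol
print(sess.subject_id, sess.week, sess.marker)
trap = clearance_trapezoidal(sess)
one = fit_one_compartment(sess)
two = two_sample_from_session(sess, 30.0, 90.0)
print(f"trapezoidal  PC = {trap.clearance_ml_min:.3f} mL/min "
      f"(AUC {trap.auc_observed:.0f} observed + {trap.auc_extrapolated:.1f} tail)")
print(f"one-compartment PC = {one.clearance_ml_min:.3f} mL/min")
print(f"two-sample (30,90) PC = {two.clearance_ml_min:.3f} mL/min")
print(f"true clearance = {cfg.true_clearance(0):.3f} mL/min")
```

prints

```
R1 0 iohexol
trapezoidal  PC = 2.701 mL/min (AUC 3690 observed + 12.7 tail)
one-compartment PC = 2.679 mL/min
two-sample (30,90) PC = 2.715 mL/min
true clearance = 2.500 mL/min
```

For this fast-equilibrating (iohexol-like) marker all three estimates —
including the two-timed-samples simplification — agree with each other to
within ~1.5%; the common ~8% overshoot against the generating clearance
on this particular session reflects assay noise plus the structural AUC
truncation before the first 2-min sample. Run the same code with an
inulin-like marker (slow equilibration, large distribution-phase AUC
share) and the one-compartment estimate overshoots the trapezoidal one by
~30% — the structural reason a two-sample protocol works for iohexol but
not for inulin.

The same analyses run from the shell:

```
plasmaclear simulate --seed 1 --outdir cohort
plasmaclear fit cohort/sessions.csv --out estimates.csv
plasmaclear compare estimates.csv --out agreement.csv
plasmaclear schedules cohort/sessions.csv --pair 30 90 --pair 60 120
plasmaclear report --seed 1 --outdir report
```

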