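"""Method-agreement statistics for paired clearance (or biomarker) series.

Two estimates of the same quantity on the same subject-weeks are compared
with the conventions standard in GFR method-comparison work:

* bias_i = reference_i - comparative_i, summarized as mean (bias) and SD
  (precision);
* %bias_i = 100 · bias_i / mean(reference_i, comparative_i), summarized the
  same way;
* P10/P15 accuracy: the percentage of pairs with |%bias| below 10 or 15;
* a weighted (1/C²) linear-regression R²;
* Bland-Altman limits of agreement bias ± 2·SD.

The module also carries the sensitivity analyses used to compare markers
along a declining-function time course: normalization of each marker to a
percent-of-baseline-function scale, a straight-line vs sixth-order
polynomial F-test on that scale, and the earliest week at which a marker
departs significantly from baseline.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("plasmaclear")

DEFAULT_ALPHA = 0.05


@dataclass(frozen=True)
class PairedSeries:
    """Two aligned measurement series on the same (subject, week) keys."""

    reference: np.ndarray
    comparative: np.ndarray
    labels: tuple[str, str] = ("reference", "comparative")
    keys: tuple | None = None

    def __post_init__(self) -> None:
        ref = np.asarray(self.reference, dtype=float)
        comp = np.asarray(self.comparative, dtype=float)
        if ref.shape != comp.shape or ref.ndim != 1:
            raise ValueError("reference and comparative must be equal-length 1-D")
        if ref.size < 2:
            raise ValueError("need at least 2 pairs")
        object.__setattr__(self, "reference", ref)
        object.__setattr__(self, "comparative", comp)
        if self.keys is not None and len(self.keys) != ref.size:
            raise ValueError("keys must match the number of pairs")

    def __len__(self) -> int:
        return self.reference.size

    @classmethod
    def from_frame(
        cls, df: pd.DataFrame, ref_col: str, comp_col: str,
        key_cols: Sequence[str] = ("subject_id", "week"),
    ) -> "PairedSeries":
        sub = df.dropna(subset=[ref_col, comp_col])
        keys = tuple(map(tuple, sub[list(key_cols)].to_numpy())) if set(
            key_cols
        ) <= set(sub.columns) else None
        return cls(
            sub[ref_col].to_numpy(float), sub[comp_col].to_numpy(float),
            labels=(ref_col, comp_col), keys=keys,
        )


@dataclass(frozen=True)
class AgreementReport:
    """Paired-comparison statistics between two methods."""

    bias: float
    precision: float
    pct_bias: float
    pct_precision: float
    p10: float
    p15: float
    r2: float
    loa_low: float
    loa_high: float
    n: int
    n_excluded: int = 0
    labels: tuple[str, str] = ("reference", "comparative")


@dataclass(frozen=True)
class ModelSelectionResult:
    """Straight line vs sixth-order polynomial, by extra-sum-of-squares F."""

    f_statistic: float
    p_value: float
    chosen: str  # "line" | "polynomial6"
    fitted_coefficients: tuple[float, ...]
    ss_line: float = math.nan
    ss_poly: float = math.nan


def agreement_report(pairs: PairedSeries, weighting: str = "comparative") -> AgreementReport:
    """Bias, precision, %bias, P10/P15 accuracy, weighted R² and LoA.

    Pairs whose mean is zero have an undefined %bias and are excluded with
    a warning; the weighted R² is ``nan`` when the regression is not
    computable (fewer than 3 pairs or a degenerate axis).
    """
    ref, comp = pairs.reference, pairs.comparative
    mean = (ref + comp) / 2.0
    ok = mean != 0
    n_excluded = int((~ok).sum())
    if n_excluded:
        logger.warning("agreement_report: excluded %d pair(s) with zero mean", n_excluded)
    ref, comp, mean = ref[ok], comp[ok], mean[ok]
    if ref.size < 2:
        raise ValueError("fewer than 2 usable pairs")
    bias_i = ref - comp
    pct_i = 100.0 * bias_i / mean
    try:
        r2 = weighted_regression_r2(
            PairedSeries(ref, comp, labels=pairs.labels), weighting=weighting
        )
    except ValueError:
        r2 = math.nan
    bias = float(bias_i.mean())
    precision = float(bias_i.std(ddof=1))
    return AgreementReport(
        bias=bias,
        precision=precision,
        pct_bias=float(pct_i.mean()),
        pct_precision=float(pct_i.std(ddof=1)),
        p10=float(100.0 * (np.abs(pct_i) < 10).mean()),
        p15=float(100.0 * (np.abs(pct_i) < 15).mean()),
        r2=r2,
        loa_low=bias - 2.0 * precision,
        loa_high=bias + 2.0 * precision,
        n=int(ref.size),
        n_excluded=n_excluded,
        labels=pairs.labels,
    )


def weighted_regression_r2(pairs: PairedSeries, weighting: str = "comparative") -> float:
    """R² of the 1/C²-weighted linear regression of comparative on reference.

    Weights are 1/y² on the comparative measure by default (``weighting=
    "reference"`` switches to 1/x²); zero-valued weight sources are
    excluded with a warning.
    """
    import statsmodels.api as sm

    ref, comp = pairs.reference, pairs.comparative
    wsrc = comp if weighting == "comparative" else ref
    ok = wsrc != 0
    if (~ok).sum():
        logger.warning(
            "weighted_regression_r2: excluded %d pair(s) with zero %s value",
            int((~ok).sum()), weighting,
        )
    ref, comp, wsrc = ref[ok], comp[ok], wsrc[ok]
    if ref.size < 3:
        raise ValueError("weighted regression needs at least 3 pairs")
    if np.ptp(ref) == 0:
        raise ValueError("reference values are constant; R² undefined")
    model = sm.WLS(comp, sm.add_constant(ref), weights=1.0 / wsrc**2)
    return float(model.fit().rsquared)


def bland_altman_data(pairs: PairedSeries) -> pd.DataFrame:
    """Per-pair Bland-Altman coordinates: mean of the two methods vs bias."""
    return pd.DataFrame(
        {
            "mean": (pairs.reference + pairs.comparative) / 2.0,
            "bias": pairs.reference - pairs.comparative,
        }
    )


def select_line_vs_poly6(
    x: np.ndarray, y: np.ndarray, alpha: float = DEFAULT_ALPHA
) -> ModelSelectionResult:
    """Does a straight line or a sixth-order polynomial fit better?

    Nested-model extra-sum-of-squares test:
    F = ((SS1 - SS6)/5) / (SS6/(n - 7)), with the polynomial chosen iff
    p < alpha.  Returns the coefficients of the chosen model in ascending
    power order.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if y.size != n:
        raise ValueError("x and y must be the same length")
    if n <= 8:
        raise ValueError(f"need n > 8 observations for the nested F-test, got {n}")

    def _fit(deg: int) -> tuple[np.ndarray, float]:
        # Polynomial.fit maps x onto [-1, 1] for conditioning of the
        # sixth-order Vandermonde system.
        poly = np.polynomial.Polynomial.fit(x, y, deg)
        resid = y - poly(x)
        return poly.convert().coef, float(resid @ resid)

    coef1, ss1 = _fit(1)
    coef6, ss6 = _fit(6)
    ss6 = min(ss6, ss1)  # nested models: guard FP noise on exact fits
    df_num, df_den = 5, n - 7
    if ss6 == 0:
        f_stat = math.inf if ss1 > 0 else 0.0
        p = 0.0 if ss1 > 0 else 1.0
    else:
        f_stat = ((ss1 - ss6) / df_num) / (ss6 / df_den)
        p = float(stats.f.sf(f_stat, df_num, df_den))
    chosen = "polynomial6" if p < alpha else "line"
    return ModelSelectionResult(
        f_statistic=float(f_stat),
        p_value=p,
        chosen=chosen,
        fitted_coefficients=tuple(coef6 if chosen == "polynomial6" else coef1),
        ss_line=ss1,
        ss_poly=ss6,
    )


# ---------------------------------------------------------------------------
# Percent-of-function normalization
# ---------------------------------------------------------------------------

def reference_percent(clearance: pd.Series) -> pd.Series:
    """Express reference clearances as percent of the mean week-0 value.

    ``clearance`` is indexed by (subject_id, week); the week-0 cohort mean
    defines 100% kidney function.
    """
    try:
        week0 = clearance.xs(0, level="week")
    except KeyError:
        raise ValueError("no week-0 baseline values") from None
    if week0.empty:
        raise ValueError("no week-0 baseline values")
    return 100.0 * clearance / week0.mean()


def normalize_to_function_scale(
    marker_values: pd.Series,
    reference_pcts: pd.Series,
    direction: str = "decreases",
) -> pd.DataFrame:
    """Map a marker onto the percent-of-function scale of the reference.

    The marker's week-0 cohort mean maps to 100% and its cohort-worst value
    maps to the floor of the reference percent series (the lowest function
    observed), linearly in between.  ``direction`` states how the marker
    moves as function falls: ``"decreases"`` (a clearance) or
    ``"increases"`` (an accumulating endogenous marker, orientation
    flipped).  Returns aligned (reference_pct, marker_pct) pairs.
    """
    if direction not in {"decreases", "increases"}:
        raise ValueError(f"unknown direction {direction!r}")
    marker_values = marker_values.dropna()
    try:
        week0_mean = float(marker_values.xs(0, level="week").mean())
    except KeyError:
        raise ValueError("no week-0 baseline values for the marker") from None
    if math.isnan(week0_mean):
        raise ValueError("no week-0 baseline values for the marker")
    floor = float(reference_pcts.min())
    worst = float(
        marker_values.max() if direction == "increases" else marker_values.min()
    )
    if worst == week0_mean:
        raise ValueError("marker shows no range between baseline and worst value")
    marker_pct = floor + (marker_values - worst) * (100.0 - floor) / (week0_mean - worst)
    out = pd.concat(
        {"reference_pct": reference_pcts, "marker_pct": marker_pct},
        axis=1,
    ).dropna()
    return out


# ---------------------------------------------------------------------------
# Earliest detectable change from baseline
# ---------------------------------------------------------------------------

def first_significant_week(
    values: pd.DataFrame,
    alpha: float = DEFAULT_ALPHA,
    adjust: str = "holm",
) -> int | None:
    """Earliest week whose values differ significantly from week 0.

    ``values`` is long-form with columns ``subject_id``, ``week``,
    ``value`` on a complete subject × week grid.  A repeated-measures
    one-way ANOVA across weeks gates the per-week paired t-tests against
    week 0, whose p-values are multiplicity-adjusted (Holm by default,
    ``adjust="tukey"`` for a Tukey-HSD-style studentized-range
    adjustment).  Returns the earliest week with adjusted p < alpha, or
    None.
    """
    from statsmodels.stats.anova import AnovaRM
    from statsmodels.stats.multitest import multipletests

    required = {"subject_id", "week", "value"}
    if not required <= set(values.columns):
        raise ValueError(f"values needs columns {sorted(required)}")
    wide = values.pivot(index="subject_id", columns="week", values="value")
    if wide.isna().any().any():
        raise ValueError("incomplete subject × week grid")
    if wide.shape[0] < 3:
        raise ValueError("need at least 3 subjects")
    weeks = sorted(wide.columns)
    if 0 not in weeks:
        raise ValueError("week 0 baseline missing")
    if len(weeks) < 2:
        return None
    anova = AnovaRM(
        values, depvar="value", subject="subject_id", within=["week"]
    ).fit()
    p_anova = float(anova.anova_table["Pr > F"].iloc[0])
    if not p_anova < alpha:
        return None
    later = [w for w in weeks if w != 0]
    pvals = np.array(
        [stats.ttest_rel(wide[w], wide[0]).pvalue for w in later], dtype=float
    )
    pvals = np.nan_to_num(pvals, nan=1.0)  # zero-variance null weeks
    if adjust == "holm":
        reject, _, _, _ = multipletests(pvals, alpha=alpha, method="holm")
    elif adjust == "tukey":
        # Studentized-range adjustment over all pairwise week contrasts.
        k = len(weeks)
        df = wide.shape[0] - 1
        tstats = np.array(
            [abs(stats.ttest_rel(wide[w], wide[0]).statistic) for w in later]
        )
        reject = stats.studentized_range.sf(np.sqrt(2.0) * tstats, k, df) < alpha
    else:
        raise ValueError(f"unknown adjustment {adjust!r}")
    for w, rej in zip(later, reject):
        if rej:
            return int(w)
    return None
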