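"""Plasma clearance of an IV-bolus filtration marker, by four estimators.

After a single intravenous injection of an exogenous filtration marker
(iohexol, FITC-inulin), glomerular filtration rate is estimated as plasma
clearance PC = dose / AUC, where AUC is the area under the plasma
concentration-time curve extrapolated over the whole disappearance.  The
four estimators differ only in how they obtain the AUC:

``trapezoidal``
    Model-free: sum of trapezoids across the sampled time points plus a
    log-linear tail extrapolated down to a threshold concentration.
``two_compartment``
    Biexponential decay C(t) = A e^{-alpha t} + B e^{-beta t} (distribution
    plus elimination phase); AUC = A/alpha + B/beta.
``one_compartment``
    Monoexponential decay of the terminal (beta) phase only, fitted to
    samples taken after distribution is complete; AUC = B/beta.
``two_sample``
    The one-compartment estimate collapsed to exactly two timed samples —
    the minimal protocol usable in routine longitudinal animal studies.

All concentrations are µg/mL, times are minutes since injection, doses are
µg, clearances mL/min.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger("plasmaclear")

#: Concentration threshold (µg/mL) down to which the trapezoidal AUC is
#: extrapolated when the curve has not declined sufficiently.
DEFAULT_TAIL_THRESHOLD = 0.5
#: Number of terminal points used for the log-linear tail fit.
DEFAULT_TAIL_POINTS = 3
#: Samples earlier than this (minutes) are excluded from one-compartment
#: fits: the distribution (alpha) phase is complete by 30 min.
DEFAULT_T_MIN = 30.0
#: Assay lower limit of quantification, µg/mL.
DEFAULT_LLOQ = 0.2
#: Identifiability guard for the biexponential fit: if the fitted fast and
#: slow rates are closer than this ratio the model degenerates to one
#: exponential and the one-compartment estimate is used instead.
ALPHA_BETA_MIN_RATIO = 1.5
#: Second identifiability guard: at least this fraction of the fitted
#: model's AUC must fall inside the observed sampling window.  A fit whose
#: area lives mostly before the first sample (a spike exponential) or
#: after the last one (a near-zero terminal rate) is extrapolation, not
#: measurement.
MIN_OBSERVED_AUC_FRACTION = 0.5


class ClearanceError(Exception):
    """Base class for estimation failures on pathological curves."""


class NonInformativeCurveError(ClearanceError):
    """All post-dose concentrations at or below background."""


class NonDecliningCurveError(ClearanceError):
    """The (terminal) concentration series does not decline."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlasmaSample:
    """One timed plasma concentration measurement."""

    time_min: float
    concentration: float
    below_lloq: bool = False
    clamped: bool = False

    def __post_init__(self) -> None:
        if self.time_min < 0:
            raise ValueError(f"time_min must be >= 0, got {self.time_min}")
        if self.concentration < 0:
            raise ValueError(
                f"concentration must be >= 0, got {self.concentration}"
            )


@dataclass(frozen=True)
class SubjectSession:
    """One animal-week disappearance curve: dose, timed samples, background."""

    subject_id: str
    week: int
    marker: str
    dose_ug: float
    samples: tuple[PlasmaSample, ...]
    background_conc: float = 0.0

    def __post_init__(self) -> None:
        if self.dose_ug <= 0:
            raise ValueError(f"dose_ug must be > 0, got {self.dose_ug}")
        if self.background_conc < 0:
            raise ValueError("background_conc must be >= 0")
        object.__setattr__(self, "samples", tuple(self.samples))
        times = [s.time_min for s in self.samples]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("samples must be sorted strictly increasing in time")
        if sum(1 for t in times if t > 0) < 2:
            raise ValueError("session needs at least 2 post-dose samples")

    @property
    def post_dose(self) -> tuple[PlasmaSample, ...]:
        return tuple(s for s in self.samples if s.time_min > 0)


@dataclass(frozen=True)
class ExponentialTerm:
    """One decay component C0 e^{-rate t} of a compartmental model."""

    coefficient: float  # µg/mL
    rate: float  # 1/min

    def __post_init__(self) -> None:
        if self.coefficient <= 0:
            raise ValueError("coefficient must be > 0")
        if self.rate <= 0:
            raise ValueError("rate must be > 0")

    @property
    def auc(self) -> float:
        return self.coefficient / self.rate


@dataclass(frozen=True)
class ClearanceEstimate:
    """An AUC and the dose/AUC plasma clearance, tagged by method."""

    method: str
    auc: float  # µg·min/mL
    clearance_ml_min: float
    terms: tuple[ExponentialTerm, ...] = ()
    auc_observed: float | None = None
    auc_extrapolated: float | None = None
    diagnostics: dict = field(default_factory=dict)


@dataclass(frozen=True)
class TwoSampleInput:
    """Dose and two timed post-distribution concentrations."""

    dose_ug: float
    t1: float
    t2: float
    c1: float
    c2: float

    def __post_init__(self) -> None:
        if self.dose_ug <= 0:
            raise ValueError("dose_ug must be > 0")
        if not 0 < self.t1 < self.t2:
            raise ValueError(f"need 0 < t1 < t2, got t1={self.t1}, t2={self.t2}")
        if self.c2 <= 0:
            raise ValueError("concentrations must be > 0")
        if self.c1 <= self.c2:
            raise NonDecliningCurveError(
                f"need c1 > c2 for a declining curve, got {self.c1} <= {self.c2}"
            )


# ---------------------------------------------------------------------------
# Background handling
# ---------------------------------------------------------------------------

def subtract_background(session: SubjectSession) -> SubjectSession:
    """Subtract the pre-dose background from every sample.

    The t = 0 sample is the pre-dose draw (the curve cannot be sampled at
    the instant of injection): if present and no explicit background is
    set, its concentration becomes the background estimate, and it is
    removed from the working series either way.  Concentrations are clamped
    at zero and flagged when clamping occurred.

    Raises
    ------
    NonInformativeCurveError
        If every post-dose concentration is at or below background.
    """
    background = session.background_conc
    t0 = [s for s in session.samples if s.time_min == 0]
    if t0 and background == 0.0:
        background = t0[0].concentration
    post = session.post_dose
    if background == 0.0:
        return replace(session, samples=post, background_conc=0.0)
    if all(s.concentration <= background for s in post):
        raise NonInformativeCurveError(
            f"all post-dose samples of {session.subject_id} week {session.week} "
            f"({session.marker}) are <= background {background:g} µg/mL"
        )
    corrected = tuple(
        replace(
            s,
            concentration=max(s.concentration - background, 0.0),
            clamped=s.concentration < background,
        )
        for s in post
    )
    return replace(session, samples=corrected, background_conc=background)


# ---------------------------------------------------------------------------
# Trapezoidal (non-compartmental) AUC
# ---------------------------------------------------------------------------

def _as_arrays(samples: Iterable[PlasmaSample]) -> tuple[np.ndarray, np.ndarray]:
    t = np.array([s.time_min for s in samples], dtype=float)
    c = np.array([s.concentration for s in samples], dtype=float)
    return t, c


def trapezoid_auc(samples: Sequence[PlasmaSample]) -> float:
    """Sum of trapezoids across the sampled time points (µg·min/mL)."""
    if len(samples) < 2:
        raise ValueError("trapezoid_auc needs at least 2 samples")
    t, c = _as_arrays(samples)
    if np.any(np.diff(t) <= 0):
        raise ValueError("samples must have strictly increasing times")
    return float(np.trapezoid(c, t))


def log_linear_tail(
    samples: Sequence[PlasmaSample],
    threshold: float = DEFAULT_TAIL_THRESHOLD,
    k: int = DEFAULT_TAIL_POINTS,
) -> tuple[float, float]:
    """Log-linear extrapolation of the terminal phase down to ``threshold``.

    Fits ln C = ln C0 - lambda t by least squares over the last ``k``
    samples above the threshold and integrates the fitted exponential from
    the last observed point until the concentration reaches the threshold:
    tail = (C_last - threshold) / lambda, clamped at zero if the curve has
    already declined past the threshold.

    Returns ``(tail_auc, terminal_rate)``; the rate is ``nan`` when no
    extrapolation is needed or possible with fewer than two usable points.
    """
    usable = [s for s in samples if s.concentration > threshold and not s.below_lloq]
    if not usable or samples[-1].concentration <= threshold:
        return 0.0, math.nan
    tail = usable[-k:] if k > 0 else usable
    if len(tail) < 2:
        return 0.0, math.nan
    t, c = _as_arrays(tail)
    slope, _ = np.polyfit(t, np.log(c), 1)
    lam = -slope
    if lam <= 0:
        raise NonDecliningCurveError(
            f"terminal phase does not decline (fitted rate {lam:g}/min)"
        )
    c_last = samples[-1].concentration
    return max((c_last - threshold) / lam, 0.0), lam


def clearance_trapezoidal(
    session: SubjectSession,
    threshold: float = DEFAULT_TAIL_THRESHOLD,
    k_tail: int = DEFAULT_TAIL_POINTS,
) -> ClearanceEstimate:
    """Trapezoidal-AUC plasma clearance of a background-subtracted session."""
    samples = [s for s in session.samples if not s.below_lloq]
    if len(samples) < 2:
        raise ValueError("need at least 2 quantifiable samples")
    auc_obs = trapezoid_auc(samples)
    tail_auc, lam = log_linear_tail(samples, threshold=threshold, k=k_tail)
    auc = auc_obs + tail_auc
    if auc <= 0:
        raise NonInformativeCurveError("zero AUC")
    return ClearanceEstimate(
        method="trapezoidal",
        auc=auc,
        clearance_ml_min=session.dose_ug / auc,
        auc_observed=auc_obs,
        auc_extrapolated=tail_auc,
        diagnostics={"terminal_rate": lam, "n_samples": len(samples)},
    )


# ---------------------------------------------------------------------------
# One-compartment model
# ---------------------------------------------------------------------------

def _loglinear_fit(t: np.ndarray, c: np.ndarray) -> tuple[float, float, float]:
    """OLS of ln c on t; returns (coefficient, rate, residual SS on log scale)."""
    slope, intercept = np.polyfit(t, np.log(c), 1)
    resid = np.log(c) - (slope * t + intercept)
    return float(np.exp(intercept)), float(-slope), float(resid @ resid)


def fit_one_compartment(
    session: SubjectSession, t_min: float = DEFAULT_T_MIN
) -> ClearanceEstimate:
    """Monoexponential (terminal phase) clearance.

    Only samples from ``t_min`` onward enter the fit — the distribution
    phase is assumed complete by then.  B and beta come from ordinary least
    squares on ln C vs t, which is exact on noiseless monoexponential data;
    AUC = B/beta and PC = dose·beta/B.
    """
    usable = [
        s
        for s in session.post_dose
        if s.time_min >= t_min and s.concentration > 0 and not s.below_lloq
    ]
    if len(usable) < 2:
        raise ValueError(
            f"one-compartment fit needs >= 2 samples at t >= {t_min:g} min, "
            f"got {len(usable)}"
        )
    t, c = _as_arrays(usable)
    b, beta, rss = _loglinear_fit(t, c)
    if beta <= 0:
        raise NonDecliningCurveError(
            f"fitted terminal rate {beta:g}/min is not positive"
        )
    auc = b / beta
    return ClearanceEstimate(
        method="one_compartment",
        auc=auc,
        clearance_ml_min=session.dose_ug / auc,
        terms=(ExponentialTerm(b, beta),),
        diagnostics={"log_rss": rss, "n_samples": len(usable)},
    )


# ---------------------------------------------------------------------------
# Two-compartment model
# ---------------------------------------------------------------------------

def _strip_curve(
    t: np.ndarray, c: np.ndarray, t_boundary: float
) -> tuple[float, float, float, float] | None:
    """Curve-stripping starting values (A, alpha, B, beta) for the NLS fit.

    Terminal points (t >= boundary, or the last three) give (B, beta); the
    log-linear fit of the positive early residuals gives (A, alpha).
    Returns None when stripping degenerates (no distinct fast phase).
    """
    terminal = t >= t_boundary
    if terminal.sum() < 2:
        terminal = np.zeros_like(terminal)
        terminal[-3:] = True
    b, beta, _ = _loglinear_fit(t[terminal], c[terminal])
    if beta <= 0:
        return None
    resid = c - b * np.exp(-beta * t)
    early = (~terminal) & (resid > 0)
    if early.sum() < 2:
        return None
    a, alpha, _ = _loglinear_fit(t[early], resid[early])
    if alpha <= beta:
        return None
    return a, alpha, b, beta


def fit_two_compartment(
    session: SubjectSession, t_boundary: float = DEFAULT_T_MIN
) -> ClearanceEstimate:
    """Biexponential clearance C(t) = A e^{-alpha t} + B e^{-beta t}.

    Unweighted nonlinear least squares on the raw concentrations,
    initialized by curve stripping; terms are returned fast-then-slow and
    AUC = A/alpha + B/beta.  When the two rates are not separable
    (alpha/beta below the identifiability guard), when stripping finds no
    fast phase, or when the optimizer fails, the estimate falls back to the
    one-compartment fit with a logged warning.
    """
    from scipy.optimize import least_squares

    usable = [
        s
        for s in session.post_dose
        if s.concentration > 0 and not s.below_lloq
    ]
    if len(usable) < 5:
        raise ValueError(
            f"two-compartment fit needs >= 5 quantifiable samples, got {len(usable)}"
        )
    t, c = _as_arrays(usable)

    def fallback(reason: str) -> ClearanceEstimate:
        logger.warning(
            "two-compartment fit for %s week %s (%s): %s; "
            "falling back to one-compartment",
            session.subject_id, session.week, session.marker, reason,
        )
        one = fit_one_compartment(session, t_min=t_boundary)
        diag = dict(one.diagnostics, fallback=reason)
        return replace(one, method="two_compartment", diagnostics=diag)

    start = _strip_curve(t, c, t_boundary)
    if start is None:
        return fallback("curve stripping found no separable fast phase")
    theta0 = np.log(start)

    def residuals(theta: np.ndarray) -> np.ndarray:
        a, alpha, b, beta = np.exp(theta)
        return a * np.exp(-alpha * t) + b * np.exp(-beta * t) - c

    try:
        fit = least_squares(
            residuals, theta0, method="lm",
            ftol=1e-10, xtol=1e-12, gtol=1e-12, max_nfev=10_000,
        )
    except Exception as exc:  # pragma: no cover - optimizer pathologies
        return fallback(f"optimizer failed: {exc}")
    if not fit.success:
        return fallback(f"optimizer did not converge: {fit.message}")
    a, alpha, b, beta = np.exp(fit.x)
    if alpha < beta:
        a, alpha, b, beta = b, beta, a, alpha
    if alpha / beta < ALPHA_BETA_MIN_RATIO:
        return fallback(
            f"rates not separable (alpha/beta = {alpha / beta:.3g})"
        )
    terms = (ExponentialTerm(a, alpha), ExponentialTerm(b, beta))
    auc = sum(term.auc for term in terms)
    observed = sum(
        (term.coefficient / term.rate)
        * (math.exp(-term.rate * t[0]) - math.exp(-term.rate * t[-1]))
        for term in terms
    )
    if observed < MIN_OBSERVED_AUC_FRACTION * auc:
        return fallback(
            f"only {observed / auc:.1%} of the fitted AUC lies inside the "
            f"sampled window [{t[0]:g}, {t[-1]:g}] min"
        )
    return ClearanceEstimate(
        method="two_compartment",
        auc=auc,
        clearance_ml_min=session.dose_ug / auc,
        terms=terms,
        diagnostics={"rss": float(2 * fit.cost), "n_samples": len(usable)},
    )


# ---------------------------------------------------------------------------
# Two-sample one-compartment estimate
# ---------------------------------------------------------------------------

def clearance_two_sample(inp: TwoSampleInput) -> ClearanceEstimate:
    """Plasma clearance from exactly two timed post-distribution samples.

    The monoexponential through (t1, c1), (t2, c2) has rate
    beta = ln(c1/c2)/(t2 - t1) and back-extrapolated intercept
    B = (c1^{t2}/c2^{t1})^{1/(t2 - t1)}; PC = dose·beta/B.  This is
    algebraically the one-compartment fit restricted to the two points.
    """
    dt = inp.t2 - inp.t1
    beta = math.log(inp.c1 / inp.c2) / dt
    b = math.exp((inp.t2 * math.log(inp.c1) - inp.t1 * math.log(inp.c2)) / dt)
    auc = b / beta
    return ClearanceEstimate(
        method="two_sample",
        auc=auc,
        clearance_ml_min=inp.dose_ug / auc,
        terms=(ExponentialTerm(b, beta),),
        diagnostics={"t1": inp.t1, "t2": inp.t2},
    )


def two_sample_from_session(
    session: SubjectSession, t1: float, t2: float
) -> ClearanceEstimate:
    """Two-sample clearance using the session's samples at ``t1`` and ``t2``.

    Raises
    ------
    KeyError
        If either time point is missing from the session.
    ValueError
        If either sample is below the LLOQ.
    """
    by_time = {s.time_min: s for s in session.samples}
    try:
        s1, s2 = by_time[t1], by_time[t2]
    except KeyError as exc:
        raise KeyError(
            f"session {session.subject_id} week {session.week} has no sample "
            f"at t = {exc.args[0]} min"
        ) from None
    if s1.below_lloq or s2.below_lloq:
        raise ValueError("two-sample time point below the LLOQ")
    return clearance_two_sample(
        TwoSampleInput(session.dose_ug, t1, t2, s1.concentration, s2.concentration)
    )


#: Dispatch used by the pipeline and the schedule evaluator.
ESTIMATORS = {
    "trapezoidal": clearance_trapezoidal,
    "one_compartment": fit_one_compartment,
    "two_compartment": fit_two_compartment,
}
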