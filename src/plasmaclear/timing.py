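"""Which two sampling times give the best two-sample clearance?

Evaluates two-sample schedule permutations against full-curve reference
estimators across a cohort: for each (t1, t2) pair the two-sample
clearance is computed per session and compared with each reference method
(trapezoidal, one-compartment, two-compartment) via the standard agreement
statistics — weighted R², bias ± precision, and 10% accuracy.

Both times must lie at or after the post-distribution boundary (30 min):
an earlier first sample is contaminated by the distribution phase, and a
very late second sample sits near the LLOQ where measurement error is
amplified through the log-linear slope.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .agreement import PairedSeries, agreement_report
from .pk_models import (
    ClearanceError,
    ESTIMATORS,
    SubjectSession,
    subtract_background,
    two_sample_from_session,
)

logger = logging.getLogger("plasmaclear")

#: Distribution phase is complete by 30 min: earliest admissible sample time.
POST_DISTRIBUTION_MIN = 30.0

#: The five schedule permutations evaluated in the study design.
STANDARD_PAIRS = ((30.0, 60.0), (60.0, 90.0), (90.0, 120.0), (30.0, 90.0), (60.0, 120.0))


@dataclass(frozen=True)
class SchedulePair:
    """A candidate pair of sampling times for the two-sample estimate."""

    t1: float
    t2: float

    def __post_init__(self) -> None:
        if not self.t1 < self.t2:
            raise ValueError(f"need t1 < t2, got ({self.t1}, {self.t2})")

    def validate_boundary(self, boundary: float = POST_DISTRIBUTION_MIN) -> None:
        if self.t1 < boundary:
            raise ValueError(
                f"t1 = {self.t1:g} min precedes the post-distribution "
                f"boundary ({boundary:g} min)"
            )

    @property
    def label(self) -> str:
        return f"{self.t1:g}, {self.t2:g}"


def _coerce_pairs(pairs: Iterable) -> list[SchedulePair]:
    out = []
    for p in pairs:
        out.append(p if isinstance(p, SchedulePair) else SchedulePair(*p))
    return out


def evaluate_schedules(
    sessions: Sequence[SubjectSession],
    pairs: Iterable = STANDARD_PAIRS,
    references: Sequence[str] = ("one_compartment", "trapezoidal", "two_compartment"),
    allow_early: bool = False,
    weighting: str = "comparative",
) -> pd.DataFrame:
    """Agreement of each two-sample schedule pair with each reference method.

    Returns one row per (pair, reference) with columns ``pair``, ``t1``,
    ``t2``, ``reference``, ``n``, ``n_skipped``, ``r2``, ``bias``,
    ``precision``, ``pct_bias``, ``p10``.  Sessions missing a sample at a
    pair time, with a below-LLOQ value there, or with a non-declining pair
    are skipped from that pair's statistics and counted.
    """
    pair_objs = _coerce_pairs(pairs)
    if not allow_early:
        for p in pair_objs:
            p.validate_boundary()
    unknown = set(references) - set(ESTIMATORS)
    if unknown:
        raise ValueError(f"unknown reference method(s): {sorted(unknown)}")

    prepared = [subtract_background(s) for s in sessions]
    ref_values: dict[str, list[float | None]] = {m: [] for m in references}
    for sess in prepared:
        for method in references:
            try:
                ref_values[method].append(ESTIMATORS[method](sess).clearance_ml_min)
            except (ClearanceError, ValueError):
                ref_values[method].append(None)

    rows = []
    for pair in pair_objs:
        two_sample: list[float | None] = []
        n_skipped = 0
        for sess in prepared:
            try:
                est = two_sample_from_session(sess, pair.t1, pair.t2)
                two_sample.append(est.clearance_ml_min)
            except (KeyError, ValueError, ClearanceError):
                two_sample.append(None)
                n_skipped += 1
        if n_skipped:
            logger.info(
                "schedule pair (%s): skipped %d/%d session(s)",
                pair.label, n_skipped, len(prepared),
            )
        for method in references:
            kept = [
                (r, c)
                for r, c in zip(ref_values[method], two_sample)
                if r is not None and c is not None
            ]
            if len(kept) < 3:
                logger.warning(
                    "pair (%s) vs %s: only %d usable session(s); row skipped",
                    pair.label, method, len(kept),
                )
                continue
            ref_arr, comp_arr = zip(*kept)
            report = agreement_report(
                PairedSeries(ref_arr, comp_arr, labels=(method, "two_sample")),
                weighting=weighting,
            )
            rows.append(
                {
                    "pair": pair.label,
                    "t1": pair.t1,
                    "t2": pair.t2,
                    "reference": method,
                    "n": report.n,
                    "n_skipped": len(prepared) - report.n,
                    "r2": report.r2,
                    "bias": report.bias,
                    "precision": report.precision,
                    "pct_bias": report.pct_bias,
                    "p10": report.p10,
                }
            )
    return pd.DataFrame(rows)
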