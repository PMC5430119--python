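"""CSV formats, run configuration, and the end-to-end pipeline.

Session curves travel as long-form CSV with one row per timed sample and
the columns ``subject_id, week, marker, dose_ug, time_min,
concentration_ug_ml``; endogenous markers as ``subject_id, week, marker,
value``.  Units are part of the column names — nothing is inferred.

``run_pipeline`` ties the stages together: fit every clearance method on
every session, build the method-agreement table, the two-sample schedule
table, and the percent-of-function normalization / sensitivity outputs,
all deterministically under the configured seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import agreement as agr
from . import pk_models as pk
from . import timing as tim
from .simulate import SyntheticCohortConfig, simulate_cohort

logger = logging.getLogger("plasmaclear")

SESSION_COLUMNS = (
    "subject_id", "week", "marker", "dose_ug", "time_min", "concentration_ug_ml",
)
ENDOGENOUS_COLUMNS = ("subject_id", "week", "marker", "value")


# ---------------------------------------------------------------------------
# Session CSV round-trip
# ---------------------------------------------------------------------------

def read_sessions(path: str | Path) -> list[pk.SubjectSession]:
    """Read and validate a session CSV into SubjectSession objects.

    Row-level problems (negative values, duplicate time points,
    inconsistent dose within a session) are collected with their line
    numbers and raised together.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing = set(SESSION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    errors: list[str] = []
    df["_line"] = df.index + 2  # header is line 1
    for col in ("dose_ug", "time_min", "concentration_ug_ml"):
        for line, val in zip(df["_line"], df[col]):
            if pd.isna(val):
                errors.append(f"line {line}: missing {col}")
            elif val < 0 or (col == "dose_ug" and val == 0):
                errors.append(f"line {line}: invalid {col} = {val}")
    dup = df.duplicated(subset=["subject_id", "week", "marker", "time_min"], keep=False)
    for line in df.loc[dup & df.duplicated(
        subset=["subject_id", "week", "marker", "time_min"], keep="first"
    ), "_line"]:
        errors.append(f"line {line}: duplicate (subject, week, marker, time) sample")
    if errors:
        raise ValueError(f"{path}: {len(errors)} parse error(s):\n" + "\n".join(errors))

    sessions = []
    has_lloq = "below_lloq" in df.columns
    for (subj, week, marker), grp in df.groupby(
        ["subject_id", "week", "marker"], sort=True
    ):
        if grp["dose_ug"].nunique() > 1:
            raise ValueError(
                f"{path}: inconsistent dose_ug within session "
                f"({subj}, week {week}, {marker})"
            )
        grp = grp.sort_values("time_min")
        samples = tuple(
            pk.PlasmaSample(
                float(r.time_min),
                float(r.concentration_ug_ml),
                below_lloq=bool(r.below_lloq) if has_lloq else False,
            )
            for r in grp.itertuples()
        )
        sessions.append(
            pk.SubjectSession(
                subject_id=str(subj),
                week=int(week),
                marker=str(marker),
                dose_ug=float(grp["dose_ug"].iloc[0]),
                samples=samples,
            )
        )
    return sessions


def sessions_to_frame(sessions: list[pk.SubjectSession]) -> pd.DataFrame:
    rows = [
        {
            "subject_id": s.subject_id,
            "week": s.week,
            "marker": s.marker,
            "dose_ug": s.dose_ug,
            "time_min": smp.time_min,
            "concentration_ug_ml": smp.concentration,
            "below_lloq": smp.below_lloq,
        }
        for s in sessions
        for smp in s.samples
    ]
    return pd.DataFrame(rows, columns=[*SESSION_COLUMNS, "below_lloq"])


def write_sessions(sessions: list[pk.SubjectSession], path: str | Path) -> None:
    # %.17g keeps the write-read round trip bit-exact
    sessions_to_frame(sessions).to_csv(path, index=False, float_format="%.17g")


def read_endogenous(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(ENDOGENOUS_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    return df


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Everything a pipeline run depends on, serializable to YAML."""

    sessions_csv: str | None = None  # None -> simulate a cohort
    endogenous_csv: str | None = None
    outdir: str = "plasmaclear_out"
    seed: int = 0
    # model options
    t_min: float = pk.DEFAULT_T_MIN
    tail_threshold: float = pk.DEFAULT_TAIL_THRESHOLD
    k_tail: int = pk.DEFAULT_TAIL_POINTS
    weighting: str = "comparative"
    alpha: float = 0.05
    # comparison structure
    reference_marker: str = "inulin"
    reference_method: str = "trapezoidal"
    schedule_pairs: tuple = tim.STANDARD_PAIRS
    timing_marker: str = "iohexol"
    verbosity: str = "INFO"

    def __post_init__(self) -> None:
        if self.reference_method not in pk.ESTIMATORS:
            raise ValueError(f"unknown reference method {self.reference_method!r}")
        if self.weighting not in {"comparative", "reference"}:
            raise ValueError(f"unknown weighting {self.weighting!r}")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"{path}: unknown config key(s) {sorted(unknown)}")
        if "schedule_pairs" in raw:
            raw["schedule_pairs"] = tuple(tuple(p) for p in raw["schedule_pairs"])
        return cls(**raw)

    def digest(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Pipeline stages
# ---------------------------------------------------------------------------

def fit_all_methods(
    sessions: list[pk.SubjectSession], config: RunConfig | None = None
) -> pd.DataFrame:
    """Run every estimator on every session; one row per session × method."""
    cfg = config or RunConfig()
    rows = []
    for raw in sessions:
        try:
            sess = pk.subtract_background(raw)
        except pk.NonInformativeCurveError as exc:
            logger.warning("session excluded: %s", exc)
            continue
        fits = {
            "trapezoidal": lambda s: pk.clearance_trapezoidal(
                s, threshold=cfg.tail_threshold, k_tail=cfg.k_tail
            ),
            "one_compartment": lambda s: pk.fit_one_compartment(s, t_min=cfg.t_min),
            "two_compartment": lambda s: pk.fit_two_compartment(
                s, t_boundary=cfg.t_min
            ),
        }
        for method, fit in fits.items():
            try:
                est = fit(sess)
            except (pk.ClearanceError, ValueError) as exc:
                logger.warning(
                    "%s fit failed for %s week %s (%s): %s",
                    method, sess.subject_id, sess.week, sess.marker, exc,
                )
                continue
            rows.append(
                {
                    "subject_id": sess.subject_id,
                    "week": sess.week,
                    "marker": sess.marker,
                    "method": method,
                    "dose_ug": sess.dose_ug,
                    "auc": est.auc,
                    "auc_observed": est.auc_observed,
                    "auc_extrapolated": est.auc_extrapolated,
                    "clearance_ml_min": est.clearance_ml_min,
                    "fallback": est.diagnostics.get("fallback"),
                }
            )
    return pd.DataFrame(rows)


def clearance_pivot(estimates: pd.DataFrame) -> pd.DataFrame:
    """Wide table: one column per (marker, method) clearance, by subject-week."""
    wide = estimates.pivot_table(
        index=["subject_id", "week"],
        columns=["marker", "method"],
        values="clearance_ml_min",
    )
    wide.columns = [f"{m} {meth}" for m, meth in wide.columns]
    return wide


def agreement_table(
    estimates: pd.DataFrame,
    references: list[tuple[str, str]] | None = None,
    weighting: str = "comparative",
) -> pd.DataFrame:
    """Pairwise agreement of clearance measures, one row per comparison.

    ``references`` lists (marker, method) combinations to use as the
    reference measure; every other combination is compared against each.
    Defaults to the trapezoidal and two-compartment measures of each
    marker present.
    """
    wide = clearance_pivot(estimates)
    if references is None:
        references = [
            (m, meth)
            for m in sorted(estimates["marker"].unique())
            for meth in ("trapezoidal", "two_compartment")
            if f"{m} {meth}" in wide.columns
        ]
    rows = []
    for ref_marker, ref_method in references:
        ref_col = f"{ref_marker} {ref_method}"
        for comp_col in wide.columns:
            if comp_col == ref_col:
                continue
            pair = agr.PairedSeries.from_frame(
                wide.reset_index(), ref_col, comp_col
            )
            rep = agr.agreement_report(pair, weighting=weighting)
            rows.append(
                {
                    "reference": ref_col,
                    "comparative": comp_col,
                    "n": rep.n,
                    "r2": rep.r2,
                    "bias": rep.bias,
                    "precision": rep.precision,
                    "pct_bias": rep.pct_bias,
                    "pct_precision": rep.pct_precision,
                    "p10": rep.p10,
                    "p15": rep.p15,
                    "loa_low": rep.loa_low,
                    "loa_high": rep.loa_high,
                }
            )
    return pd.DataFrame(rows)


def sensitivity_table(
    estimates: pd.DataFrame,
    endogenous: pd.DataFrame | None,
    config: RunConfig,
) -> pd.DataFrame:
    """Percent-of-function normalization, model choice, and first flagged week.

    One row per marker: the reference clearance normalized against itself
    (unity), every other clearance measure, and each endogenous marker —
    with the line-vs-polynomial choice on the normalized scale and the
    earliest week significantly different from week 0.
    """
    wide = clearance_pivot(estimates)
    ref_col = f"{config.reference_marker} {config.reference_method}"
    if ref_col not in wide.columns:
        raise ValueError(f"reference measure {ref_col!r} absent from estimates")
    ref_pct = agr.reference_percent(wide[ref_col].dropna())

    series: list[tuple[str, pd.Series, str]] = [
        (col, wide[col].dropna(), "decreases") for col in wide.columns
    ]
    if endogenous is not None:
        for name, grp in endogenous.groupby("marker"):
            vals = grp.set_index(["subject_id", "week"])["value"]
            series.append((str(name), vals, "increases"))

    rows = []
    for name, vals, direction in series:
        try:
            norm = agr.normalize_to_function_scale(vals, ref_pct, direction=direction)
            sel = agr.select_line_vs_poly6(
                norm["reference_pct"].to_numpy(),
                norm["marker_pct"].to_numpy(),
                alpha=config.alpha,
            )
            chosen, f_stat, p_val = sel.chosen, sel.f_statistic, sel.p_value
        except ValueError as exc:
            logger.warning("normalization failed for %s: %s", name, exc)
            chosen, f_stat, p_val = None, float("nan"), float("nan")
        long = vals.reset_index()
        long.columns = ["subject_id", "week", "value"]
        try:
            week = agr.first_significant_week(long, alpha=config.alpha)
        except ValueError as exc:
            logger.warning("first_significant_week failed for %s: %s", name, exc)
            week = None
        rows.append(
            {
                "measure": name,
                "direction": direction,
                "chosen_model": chosen,
                "f_statistic": f_stat,
                "p_value": p_val,
                "first_significant_week": week,
            }
        )
    return pd.DataFrame(rows)


def run_pipeline(
    config: RunConfig, cohort: SyntheticCohortConfig | None = None
) -> dict[str, pd.DataFrame]:
    """Execute the full analysis and write the report bundle to ``outdir``.

    Stages: load (or simulate) the cohort, fit all clearance methods,
    build the agreement table, the two-sample schedule table, and the
    sensitivity table; write each as CSV plus a run manifest recording the
    config hash and seed.  Deterministic given config + seed.
    """
    logging.basicConfig(level=getattr(logging, config.verbosity, logging.INFO))
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    endogenous: pd.DataFrame | None = None
    if config.sessions_csv is not None:
        sessions = read_sessions(config.sessions_csv)
        if config.endogenous_csv is not None:
            endogenous = read_endogenous(config.endogenous_csv)
    else:
        cohort = cohort or SyntheticCohortConfig(seed=config.seed)
        sessions, endogenous, truth = simulate_cohort(cohort)
        write_sessions(sessions, outdir / "sessions.csv")
        endogenous.to_csv(outdir / "endogenous.csv", index=False)
        truth.to_csv(outdir / "truth.csv", index=False)

    estimates = fit_all_methods(sessions, config)
    if estimates.empty:
        raise RuntimeError("fit stage produced no estimates")
    agreement_df = agreement_table(estimates, weighting=config.weighting)
    timing_sessions = [s for s in sessions if s.marker == config.timing_marker]
    if timing_sessions:
        timing_df = tim.evaluate_schedules(
            timing_sessions, pairs=config.schedule_pairs, weighting=config.weighting
        )
    else:
        timing_df = pd.DataFrame()
    sensitivity_df = sensitivity_table(estimates, endogenous, config)

    outputs = {
        "estimates": estimates,
        "agreement": agreement_df,
        "schedules": timing_df,
        "sensitivity": sensitivity_df,
    }
    for name, df in outputs.items():
        df.to_csv(outdir / f"{name}.csv", index=False)
    manifest = {
        "config_digest": config.digest(),
        "seed": config.seed,
        "n_sessions": len(sessions),
        "outputs": sorted(outputs),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return outputs
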