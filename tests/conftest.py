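"""Shared fixtures: session builders and noise-free cohort configurations."""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pytest

from plasmaclear import (
    PlasmaSample,
    SubjectSession,
    SyntheticCohortConfig,
)

#: The 12-point sampling schedule used throughout (minutes).
SCHEDULE = (0.0, 2.0, 5.0, 10.0, 20.0, 30.0, 60.0, 90.0, 120.0, 180.0, 240.0, 300.0)


def make_session(
    times, concs, dose_ug=10_000.0, background=0.0, marker="iohexol",
    subject_id="S1", week=0,
) -> SubjectSession:
    samples = tuple(
        PlasmaSample(float(t), float(c)) for t, c in zip(times, concs)
    )
    return SubjectSession(
        subject_id=subject_id, week=week, marker=marker, dose_ug=dose_ug,
        samples=samples, background_conc=background,
    )


def monoexp_session(b, beta, times, dose_ug=10_000.0, **kw) -> SubjectSession:
    times = np.asarray(times, dtype=float)
    return make_session(times, b * np.exp(-beta * times), dose_ug=dose_ug, **kw)


def biexp_session(a, alpha, b, beta, times, dose_ug=10_000.0, **kw) -> SubjectSession:
    times = np.asarray(times, dtype=float)
    concs = a * np.exp(-alpha * times) + b * np.exp(-beta * times)
    return make_session(times, concs, dose_ug=dose_ug, **kw)


def noiseless_config(seed: int = 0, **kw) -> SyntheticCohortConfig:
    """Cohort config with all measurement noise switched off."""
    base = SyntheticCohortConfig(seed=seed, **kw)
    return replace(
        base,
        markers={k: replace(v, noise_cv=0.0) for k, v in base.markers.items()},
        endogenous={k: replace(v, noise_cv=0.0) for k, v in base.endogenous.items()},
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20170508)
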