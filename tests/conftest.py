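"""Shared fixtures: an engineered 31-patient cohort whose margin sweep
reproduces the published contingency counts at every margin."""

from __future__ import annotations

import numpy as np
import pytest

from icptrend import DailyAverages, PatientRecord


def _patient(pid: str, outcome: str) -> PatientRecord:
    return PatientRecord(
        patient_id=pid, age_months=4.0, sex="male",
        etiology="aqueductal_stenosis", opening_pressure=18.0,
        outcome_6mo=outcome,
    )


def _davs(pid: str, base: float, delta: float) -> DailyAverages:
    """Monotone trajectory when delta > 0, flat when delta = 0."""
    return DailyAverages(
        patient_id=pid,
        dav=(base, base + delta / 2, base + delta),
        n_readings=(24, 24, 24),
        complete=True,
    )


@pytest.fixture(scope="session")
def reference_cohort():
    """31 complete patients engineered so the progressive-increase counts at
    margins (1,2,3,4,5) are (9,4,3,2,1) and the trend-by-outcome cells match
    the published 2x2 tables at every margin.

    Net day-1->day-3 rises: 22 flat patients (11 failure / 11 success),
    five at +1.5 mmHg (4 failure / 1 success), and one each at +2.5, +3.5,
    +4.5 and +6 mmHg (all failures).
    """
    spec = (
        [(0.0, "failure")] * 11 + [(0.0, "success")] * 11
        + [(1.5, "failure")] * 4 + [(1.5, "success")]
        + [(2.5, "failure"), (3.5, "failure"), (4.5, "failure"), (6.0, "failure")]
    )
    patients, davs = [], []
    for i, (delta, outcome) in enumerate(spec):
        pid = f"R{i + 1:03d}"
        patients.append(_patient(pid, outcome))
        davs.append(_davs(pid, base=5.0, delta=delta))
    return patients, davs


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)
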