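"""Seedable synthetic post-ETV cohorts.

The generator emulates the monitoring protocol the analysis assumes: hourly
ICP readings for three postoperative days, averaged into DAVs downstream.
Each patient is drawn from one of two trajectory archetypes:

* *stable* — the per-day mean level stays at the day-1 level up to a small
  uniform jitter (kept below any classification margin);
* *progressive* — day means rise monotonically, the total day-1 to day-3
  increase equal to ``progressive_drift`` and split 50/50 between the two
  day-to-day steps.

Hourly readings are the day mean plus independent Gaussian noise of SD
``hourly_noise_sd``, floored at 0 mmHg.  Opening pressure is a truncated
normal clipped to the configured range.  The 6-month outcome is Bernoulli
conditional on archetype.  Monitoring dropout removes whole days (day 2
onward, or day 3 only, with equal probability), emulating accidental
catheter pull-out; dropped days simply have no rows in the series file.

All randomness flows from the mandatory ``seed``; identical configs produce
byte-identical output files.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .errors import ConfigurationError
from .ingest import (
    HOURS_PER_DAY,
    N_DAYS,
    PATIENTS_COLUMNS,
    SERIES_COLUMNS,
    ICPSeries,
    PatientRecord,
)

STABLE_ARCHETYPE = "stable"
PROGRESSIVE_ARCHETYPE = "progressive"

# Fraction of eventual 6-month failures already failed by 1 and by 3 months,
# chosen to reproduce the cohort-level success rates 62.5% / 40% / 35%.
_FAIL_BY_1MO = 0.375 / 0.65
_FAIL_BY_3MO = 0.60 / 0.65


@dataclass
class CohortConfig:
    """Generating distribution of a synthetic cohort.

    Defaults reproduce the source study's conditions: a 40-infant cohort,
    opening pressure ~ N(18.53, 6.61) truncated to [8, 44] mmHg, day-1 DAV
    ~ N(6.36, 2.46) mmHg, 4/31 progressive archetypes, failure probability
    15/27 under the stable archetype and 1 under the progressive one, and
    a 9/40 chance of losing days to catheter pull-out.
    """

    seed: int
    n_patients: int = 40
    opening_pressure_mean: float = 18.53
    opening_pressure_sd: float = 6.61
    opening_pressure_range: tuple = (8.0, 44.0)
    day1_dav_mean: float = 6.36
    day1_dav_sd: float = 2.46
    hourly_noise_sd: float = 1.0
    prop_progressive: float = 4 / 31
    progressive_drift: float = 3.0
    stable_jitter: float = 0.5
    p_failure_given_stable: float = 15 / 27
    p_failure_given_progressive: float = 1.0
    dropout_prob: float = 9 / 40
    age_months_weights: tuple = (0.425, 0.375, 0.20)  # strata (0-3], (3-6], (6-12]
    male_fraction: float = 0.85
    etiology_weights: tuple = (0.45, 0.275, 0.275)  # aqueductal, dandy_walker, other

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ConfigurationError(f"n_patients must be >= 1, got {self.n_patients}")
        for name in ("prop_progressive", "p_failure_given_stable",
                     "p_failure_given_progressive", "dropout_prob", "male_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        for name in ("opening_pressure_sd", "day1_dav_sd", "hourly_noise_sd",
                     "stable_jitter"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        lo, hi = self.opening_pressure_range
        if not lo < hi:
            raise ConfigurationError(
                f"opening_pressure_range min must be < max, got ({lo}, {hi})"
            )
        if self.progressive_drift <= 0:
            raise ConfigurationError("progressive_drift must be > 0")
        for name in ("age_months_weights", "etiology_weights"):
            w = getattr(self, name)
            if len(w) != 3 or any(x < 0 for x in w) or not math.isclose(sum(w), 1.0):
                raise ConfigurationError(f"{name} must be 3 non-negative weights summing to 1")
        if not isinstance(self.seed, int):
            raise ConfigurationError("seed is mandatory and must be an integer")


@dataclass(frozen=True)
class SyntheticCohort:
    patients: tuple  # of PatientRecord
    series: tuple  # of ICPSeries (dropout patients have < 72 readings)
    truth_labels: dict  # patient_id -> STABLE_ARCHETYPE | PROGRESSIVE_ARCHETYPE
    config: CohortConfig


_AGE_BOUNDS = ((0.5, 3.0), (3.0, 6.0), (6.0, 12.0))
_ETIOLOGIES = ("aqueductal_stenosis", "dandy_walker", "other")


def _draw_opening_pressure(cfg: CohortConfig, rng: np.random.Generator) -> float:
    a = (cfg.opening_pressure_range[0] - cfg.opening_pressure_mean) / cfg.opening_pressure_sd
    b = (cfg.opening_pressure_range[1] - cfg.opening_pressure_mean) / cfg.opening_pressure_sd
    return float(truncnorm.rvs(a, b, loc=cfg.opening_pressure_mean,
                               scale=cfg.opening_pressure_sd, random_state=rng))


def simulate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Draw a full cohort (clinical table + hourly series + ground truth)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    patients, series, truth = [], [], {}
    for i in range(config.n_patients):
        pid = f"P{i + 1:03d}"
        progressive = rng.random() < config.prop_progressive
        truth[pid] = PROGRESSIVE_ARCHETYPE if progressive else STABLE_ARCHETYPE

        # demographics
        stratum = rng.choice(3, p=config.age_months_weights)
        age = float(rng.uniform(*_AGE_BOUNDS[stratum]))
        sex = "male" if rng.random() < config.male_fraction else "female"
        etiology = _ETIOLOGIES[rng.choice(3, p=config.etiology_weights)]
        opening = _draw_opening_pressure(config, rng)

        # per-day mean levels
        level1 = float(rng.normal(config.day1_dav_mean, config.day1_dav_sd))
        level1 = max(level1, 0.0)
        if progressive:
            levels = (level1,
                      level1 + config.progressive_drift / 2.0,
                      level1 + config.progressive_drift)
        else:
            levels = (level1,
                      level1 + float(rng.uniform(-config.stable_jitter, config.stable_jitter)),
                      level1 + float(rng.uniform(-config.stable_jitter, config.stable_jitter)))

        # dropout: whole days lost from day 2 onward, or day 3 only
        n_days = N_DAYS
        if rng.random() < config.dropout_prob:
            n_days = 1 if rng.random() < 0.5 else 2

        readings = []
        for day in range(n_days):
            noise = rng.normal(0.0, config.hourly_noise_sd, HOURS_PER_DAY) \
                if config.hourly_noise_sd > 0 else np.zeros(HOURS_PER_DAY)
            for h in range(HOURS_PER_DAY):
                pressure = max(levels[day] + float(noise[h]), 0.0)
                readings.append((day * HOURS_PER_DAY + h, pressure))
        series.append(ICPSeries(patient_id=pid, readings=tuple(readings)))

        # outcome conditional on archetype; earlier-month outcomes nested
        p_fail = (config.p_failure_given_progressive if progressive
                  else config.p_failure_given_stable)
        failed_6mo = rng.random() < p_fail
        if failed_6mo:
            u = rng.random()
            failed_1mo = u < _FAIL_BY_1MO
            failed_3mo = u < _FAIL_BY_3MO
        else:
            failed_1mo = failed_3mo = False
        patients.append(PatientRecord(
            patient_id=pid,
            age_months=age,
            sex=sex,
            etiology=etiology,
            opening_pressure=opening,
            outcome_6mo="failure" if failed_6mo else "success",
            outcome_1mo="failure" if failed_1mo else "success",
            outcome_3mo="failure" if failed_3mo else "success",
            evans_ratio=float(np.clip(rng.normal(0.68, 0.11), 0.3, 1.0)),
        ))
    return SyntheticCohort(
        patients=tuple(patients), series=tuple(series), truth_labels=truth,
        config=config,
    )


def cohort_to_frames(cohort: SyntheticCohort) -> tuple:
    """(patients, series) DataFrames in the ingest CSV dialects."""
    pat = pd.DataFrame(
        {
            "patient_id": [p.patient_id for p in cohort.patients],
            "age_months": [p.age_months for p in cohort.patients],
            "sex": [p.sex for p in cohort.patients],
            "etiology": [p.etiology for p in cohort.patients],
            "opening_pressure_mmhg": [p.opening_pressure for p in cohort.patients],
            "outcome_1mo": [p.outcome_1mo for p in cohort.patients],
            "outcome_3mo": [p.outcome_3mo for p in cohort.patients],
            "outcome_6mo": [p.outcome_6mo for p in cohort.patients],
            "evans_ratio": [p.evans_ratio for p in cohort.patients],
        },
        columns=PATIENTS_COLUMNS,
    )
    rows = [
        (s.patient_id, h, p) for s in cohort.series for h, p in s.readings
    ]
    ser = pd.DataFrame(rows, columns=SERIES_COLUMNS)
    return pat, ser


def write_cohort(cohort: SyntheticCohort, out_dir) -> tuple:
    """Write ``patients.csv`` and ``icp_series.csv``; returns the two paths."""
    if not cohort.patients:
        raise ConfigurationError("empty cohort")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pat, ser = cohort_to_frames(cohort)
    patients_path = out_dir / "patients.csv"
    series_path = out_dir / "icp_series.csv"
    # 17 significant digits round-trip float64 losslessly and keep repeat
    # runs byte-identical
    pat.to_csv(patients_path, index=False, float_format="%.17g")
    ser.to_csv(series_path, index=False, float_format="%.17g")
    return patients_path, series_path
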