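"""Reading and validation of patient tables and hourly ICP series, and
computation of daily average values (DAV).

The monitoring clock starts at hour 0 (four hours after skin closure in the
original protocol; that offset is metadata and does not enter the indexing).
Hours 0-23 form postoperative day 1, 24-47 day 2, 48-71 day 3.  The analysis
horizon is fixed at three days; later readings are ignored with a warning.

A day's DAV is the arithmetic mean of its hourly pressures, computed only
when at least ``min_readings_per_day`` readings exist (default 24, i.e. a
day counts only when every hourly value was captured).  A patient is
*complete* when all three DAVs are present; only complete patients enter
trend classification downstream.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from .errors import ValidationError

logger = logging.getLogger("icptrend.ingest")

SEXES = frozenset({"male", "female"})
ETIOLOGIES = frozenset({"aqueductal_stenosis", "dandy_walker", "other"})
OUTCOMES = frozenset({"success", "failure"})

#: Plausibility window for any pressure value, in mmHg.  Values outside it
#: are treated as unit mistakes (e.g. cmH2O) and rejected, never clipped.
PRESSURE_SANITY_MMHG = (0.0, 100.0)

#: Hours per postoperative day and the fixed three-day analysis horizon.
HOURS_PER_DAY = 24
N_DAYS = 3

PATIENTS_COLUMNS = [
    "patient_id", "age_months", "sex", "etiology", "opening_pressure_mmhg",
    "outcome_1mo", "outcome_3mo", "outcome_6mo", "evans_ratio",
]
SERIES_COLUMNS = ["patient_id", "hour_index", "icp_mmhg"]


@dataclass(frozen=True)
class PatientRecord:
    """One patient's clinical row: demographics, opening pressure, outcomes."""

    patient_id: str
    age_months: float
    sex: str
    etiology: str
    opening_pressure: float
    outcome_6mo: str
    outcome_1mo: Optional[str] = None
    outcome_3mo: Optional[str] = None
    evans_ratio: Optional[float] = None

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ValidationError(f"patient {self.patient_id!r}: unknown sex {self.sex!r}")
        if self.etiology not in ETIOLOGIES:
            raise ValidationError(
                f"patient {self.patient_id!r}: unknown etiology {self.etiology!r}"
            )
        for name, val in (("outcome_6mo", self.outcome_6mo),
                          ("outcome_1mo", self.outcome_1mo),
                          ("outcome_3mo", self.outcome_3mo)):
            if val is not None and val not in OUTCOMES:
                raise ValidationError(
                    f"patient {self.patient_id!r}: {name}={val!r} "
                    f"(accepted codes: success|failure)"
                )
        if self.age_months < 0:
            raise ValidationError(f"patient {self.patient_id!r}: negative age")
        lo, hi = PRESSURE_SANITY_MMHG
        if not (lo <= self.opening_pressure <= hi):
            raise ValidationError(
                f"patient {self.patient_id!r}: opening pressure "
                f"{self.opening_pressure} mmHg outside sanity window [{lo}, {hi}]"
            )
        if self.evans_ratio is not None and not (0.0 < self.evans_ratio <= 1.0):
            raise ValidationError(
                f"patient {self.patient_id!r}: Evans ratio {self.evans_ratio} not in (0, 1]"
            )


@dataclass(frozen=True)
class ICPSeries:
    """One patient's hourly pressure recordings, indexed from monitoring start."""

    patient_id: str
    readings: tuple  # of (hour_index, pressure_mmHg)

    def __post_init__(self) -> None:
        prev = -1
        lo, hi = PRESSURE_SANITY_MMHG
        for hour, pressure in self.readings:
            if hour < 0:
                raise ValidationError(
                    f"patient {self.patient_id!r}: negative hour index {hour}"
                )
            if hour <= prev:
                raise ValidationError(
                    f"patient {self.patient_id!r}: hour indices not strictly "
                    f"increasing at hour {hour}"
                )
            if not math.isfinite(pressure) or not (lo <= pressure <= hi):
                raise ValidationError(
                    f"patient {self.patient_id!r}, hour {hour}: pressure "
                    f"{pressure} mmHg invalid or outside sanity window"
                )
            prev = hour


@dataclass(frozen=True)
class DailyAverages:
    """Per-patient DAVs for postoperative days 1-3 with per-day reading counts."""

    patient_id: str
    dav: tuple  # (day1, day2, day3), each float or None
    n_readings: tuple  # (int, int, int)
    complete: bool


def assign_day(hour_index: int) -> int:
    """Map an hour index (0-based from monitoring start) to a 1-based
    postoperative day: hours 0-23 -> day 1, 24-47 -> day 2, 48-71 -> day 3.
    Indices beyond hour 71 map past the analysis horizon (day 4+)."""
    if hour_index < 0:
        raise ValidationError(f"negative hour index {hour_index}")
    return hour_index // HOURS_PER_DAY + 1


def compute_dav(series: ICPSeries, min_readings_per_day: int = HOURS_PER_DAY) -> DailyAverages:
    """Average each day's pressures into a DAV; a day's DAV is missing when
    fewer than ``min_readings_per_day`` readings exist.  Readings past the
    three-day horizon are ignored."""
    if not 1 <= min_readings_per_day <= HOURS_PER_DAY:
        raise ValidationError(
            f"min_readings_per_day={min_readings_per_day} outside [1, {HOURS_PER_DAY}]"
        )
    sums = [0.0] * N_DAYS
    counts = [0] * N_DAYS
    n_beyond = 0
    for hour, pressure in series.readings:
        day = assign_day(hour)
        if day > N_DAYS:
            n_beyond += 1
            continue
        sums[day - 1] += pressure
        counts[day - 1] += 1
    if n_beyond:
        logger.warning(
            "patient %s: %d readings beyond hour %d ignored",
            series.patient_id, n_beyond, N_DAYS * HOURS_PER_DAY - 1,
        )
    dav = tuple(
        s / c if c >= min_readings_per_day else None for s, c in zip(sums, counts)
    )
    return DailyAverages(
        patient_id=series.patient_id,
        dav=dav,
        n_readings=tuple(counts),
        complete=all(v is not None for v in dav),
    )


# ---------------------------------------------------------------------------
# File dialects


def _opt_str(value) -> Optional[str]:
    if value is None or (isinstance(value, float) and math.isnan(value)) or value == "":
        return None
    return str(value)


def _opt_float(value) -> Optional[float]:
    if value is None or value == "":
        return None
    value = float(value)
    return None if math.isnan(value) else value


def read_patients(path) -> list[PatientRecord]:
    """Parse ``patients.csv`` (see module docstring for the dialect), validating
    categorical codes and id uniqueness.  Errors carry the offending row number."""
    df = pd.read_csv(path, dtype={"patient_id": str}, float_precision="round_trip")
    missing = [c for c in PATIENTS_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    records: list[PatientRecord] = []
    seen: set[str] = set()
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header = line 1
        try:
            rec = PatientRecord(
                patient_id=str(row.patient_id),
                age_months=float(row.age_months),
                sex=str(row.sex),
                etiology=str(row.etiology),
                opening_pressure=float(row.opening_pressure_mmhg),
                outcome_6mo=_opt_str(row.outcome_6mo) or "",
                outcome_1mo=_opt_str(row.outcome_1mo),
                outcome_3mo=_opt_str(row.outcome_3mo),
                evans_ratio=_opt_float(row.evans_ratio),
            )
        except (ValidationError, ValueError) as exc:
            raise ValidationError(f"{path}, row {i}: {exc}") from exc
        if rec.patient_id in seen:
            raise ValidationError(f"{path}, row {i}: duplicate patient_id {rec.patient_id!r}")
        seen.add(rec.patient_id)
        records.append(rec)
    return records


def read_series(path) -> list[ICPSeries]:
    """Parse ``icp_series.csv`` into one ICPSeries per patient, preserving
    file order of patients and sorting readings by hour."""
    df = pd.read_csv(path, dtype={"patient_id": str}, float_precision="round_trip")
    missing = [c for c in SERIES_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    out: list[ICPSeries] = []
    for pid in df["patient_id"].unique():
        sub = df[df["patient_id"] == pid].sort_values("hour_index")
        readings = tuple(
            (int(h), float(p)) for h, p in zip(sub["hour_index"], sub["icp_mmhg"])
        )
        try:
            out.append(ICPSeries(patient_id=str(pid), readings=readings))
        except ValidationError as exc:
            raise ValidationError(f"{path}: {exc}") from exc
    return out


def davs_to_frame(davs: Sequence[DailyAverages]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "patient_id": [d.patient_id for d in davs],
            "dav_day1": [d.dav[0] for d in davs],
            "dav_day2": [d.dav[1] for d in davs],
            "dav_day3": [d.dav[2] for d in davs],
            "n_day1": [d.n_readings[0] for d in davs],
            "n_day2": [d.n_readings[1] for d in davs],
            "n_day3": [d.n_readings[2] for d in davs],
            "complete": [d.complete for d in davs],
        }
    )


def frame_to_davs(df: pd.DataFrame) -> list[DailyAverages]:
    out = []
    for row in df.itertuples(index=False):
        dav = tuple(
            None if pd.isna(v) else float(v)
            for v in (row.dav_day1, row.dav_day2, row.dav_day3)
        )
        out.append(
            DailyAverages(
                patient_id=str(row.patient_id),
                dav=dav,
                n_readings=(int(row.n_day1), int(row.n_day2), int(row.n_day3)),
                complete=bool(row.complete),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Cohort summary


def _describe(values: Sequence[float]) -> dict:
    s = pd.Series(list(values), dtype=float)
    return {
        "n": int(s.count()),
        "mean": float(s.mean()),
        # SD reported as missing for n=1 (sample SD undefined)
        "sd": (float(s.std(ddof=1)) if s.count() > 1 else None),
        "median": float(s.median()),
        "min": float(s.min()),
        "max": float(s.max()),
    }


AGE_STRATA = (("0-3", 0.0, 3.0), (">3-6", 3.0, 6.0), (">6", 6.0, math.inf))


def cohort_summary(patients: Sequence[PatientRecord],
                   davs: Sequence[DailyAverages]) -> dict:
    """Descriptive summary of the cohort: counts and percentages by age
    stratum, sex and etiology (full-cohort denominator), and
    mean/SD/median/min/max of opening pressure and of DAV1-3 over complete
    patients."""
    if not patients:
        raise ValidationError("empty cohort")
    n = len(patients)
    by_age = {
        label: sum(1 for p in patients if lo < p.age_months <= hi or
                   (label == "0-3" and p.age_months == 0))
        for label, lo, hi in AGE_STRATA
    }
    by_sex = {s: sum(1 for p in patients if p.sex == s) for s in sorted(SEXES)}
    by_etiology = {
        e: sum(1 for p in patients if p.etiology == e) for e in sorted(ETIOLOGIES)
    }
    complete = [d for d in davs if d.complete]
    summary = {
        "n_patients": n,
        "n_complete": len(complete),
        "age_months": {k: {"count": v, "pct": 100.0 * v / n} for k, v in by_age.items()},
        "sex": {k: {"count": v, "pct": 100.0 * v / n} for k, v in by_sex.items()},
        "etiology": {k: {"count": v, "pct": 100.0 * v / n} for k, v in by_etiology.items()},
        "opening_pressure": _describe([p.opening_pressure for p in patients]),
    }
    for day in range(N_DAYS):
        key = f"dav_day{day + 1}"
        vals = [d.dav[day] for d in complete]
        summary[key] = _describe(vals) if vals else None
    return summary
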