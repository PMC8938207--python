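"""Three-day DAV trajectory classification.

A complete patient's trajectory is *progressive increase* at margin delta
when the DAVs rise strictly monotonically (DAV1 < DAV2 < DAV3) and the net
day-1 to day-3 rise exceeds delta (strict ">"); every other trajectory is
*stable*.  Ties therefore break toward stable, and a net rise of exactly
delta is stable.  Comparisons are exact on the computed DAVs; nothing is
rounded first.

The strict-monotonicity clause can be relaxed (``require_monotone=False``)
to label on the net rise alone, since published counts cannot distinguish
the two readings.

Because the progressive set can only shrink as delta grows, sweeping a grid
of margins produces nested calls; ``sweep_margins`` asserts this nesting on
every run.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .errors import ValidationError
from .ingest import DailyAverages

STABLE = "stable"
PROGRESSIVE = "progressive_increase"


@dataclass(frozen=True)
class TrendCall:
    patient_id: str
    margin_delta: float
    label: str  # STABLE | PROGRESSIVE
    dav_delta_13: float  # DAV3 - DAV1, mmHg
    monotone: bool  # DAV1 < DAV2 < DAV3 (strict)


@dataclass(frozen=True)
class MarginSweep:
    margins: tuple  # strictly increasing mmHg thresholds
    calls: Mapping[float, tuple]  # margin -> tuple of TrendCall


def classify_trend(davs: DailyAverages, margin_delta: float,
                   require_monotone: bool = True) -> TrendCall:
    """Label one complete patient's trajectory at a single margin."""
    if not davs.complete:
        raise ValidationError(
            f"patient {davs.patient_id!r}: incomplete daily averages; "
            f"exclude incomplete patients before classification"
        )
    if margin_delta <= 0:
        raise ValidationError(f"margin_delta must be > 0, got {margin_delta}")
    d1, d2, d3 = davs.dav
    monotone = d1 < d2 < d3
    delta13 = d3 - d1
    rising = (monotone if require_monotone else True) and delta13 > margin_delta
    return TrendCall(
        patient_id=davs.patient_id,
        margin_delta=margin_delta,
        label=PROGRESSIVE if rising else STABLE,
        dav_delta_13=delta13,
        monotone=monotone,
    )


def sweep_margins(davs_list: Sequence[DailyAverages], margins: Sequence[float],
                  require_monotone: bool = True) -> MarginSweep:
    """Classify every complete patient at every margin of a strictly
    increasing grid; incomplete patients are dropped (they carry no calls)."""
    if not margins:
        raise ValidationError("empty margin list")
    margins = tuple(float(m) for m in margins)
    if any(m <= 0 for m in margins):
        raise ValidationError("all margins must be > 0")
    if any(b <= a for a, b in zip(margins, margins[1:])):
        raise ValidationError("margins must be strictly increasing")
    complete = [d for d in davs_list if d.complete]
    calls = {
        m: tuple(classify_trend(d, m, require_monotone) for d in complete)
        for m in margins
    }
    # progressive sets must be nested downward as the margin grows
    prev: set | None = None
    for m in margins:
        current = {c.patient_id for c in calls[m] if c.label == PROGRESSIVE}
        assert prev is None or current <= prev, (
            f"nesting violated at margin {m}: {current - prev}"
        )
        prev = current
    return MarginSweep(margins=margins, calls=calls)


def calls_to_frame(sweep: MarginSweep) -> pd.DataFrame:
    rows = [
        (c.patient_id, m, c.label, c.dav_delta_13, c.monotone)
        for m in sweep.margins
        for c in sweep.calls[m]
    ]
    return pd.DataFrame(
        rows, columns=["patient_id", "margin_mmhg", "label", "dav_delta_13", "monotone"]
    )


def frame_to_sweep(df: pd.DataFrame) -> MarginSweep:
    margins = tuple(sorted(df["margin_mmhg"].unique()))
    calls = {}
    for m in margins:
        sub = df[df["margin_mmhg"] == m]
        calls[m] = tuple(
            TrendCall(
                patient_id=str(r.patient_id),
                margin_delta=float(m),
                label=str(r.label),
                dav_delta_13=float(r.dav_delta_13),
                monotone=bool(r.monotone),
            )
            for r in sub.itertuples(index=False)
        )
    return MarginSweep(margins=margins, calls=calls)


def label_counts(sweep: MarginSweep) -> pd.DataFrame:
    """Per-margin counts of stable vs progressive calls."""
    rows = []
    for m in sweep.margins:
        calls = sweep.calls[m]
        n_prog = sum(1 for c in calls if c.label == PROGRESSIVE)
        rows.append((m, len(calls) - n_prog, n_prog, len(calls)))
    return pd.DataFrame(rows, columns=["margin_mmhg", "n_stable", "n_progressive", "n_total"])
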