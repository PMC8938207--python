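"""Diagnostic-accuracy evaluation of the ICP trend against 6-month outcome.

The 2x2 table crosses trend (stable / progressive increase) with outcome
(success / failure).  Two prediction directions are reported:

* ``stable_predicts_success`` — condition positive is *success*, test
  positive is *stable*;
* ``progressive_predicts_failure`` — condition positive is *failure*, test
  positive is *progressive increase*.

The two directions are mirror images of each other: sensitivity in one is
specificity in the other, and PPV and NPV swap likewise.

Confidence intervals are exact Clopper-Pearson by default (Wilson score on
request).  Metrics with a zero denominator (e.g. NPV when no patient shows
a progressive trend) are reported as undefined, never as 0 or 1.  The
association test is the uncorrected Pearson chi-square on the 2x2 table;
Yates continuity correction is available by flag but off by default.

Multiple margins are evaluated without multiple-testing adjustment; reports
carry a note to that effect.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .errors import ValidationError
from .ingest import PatientRecord
from .trend import PROGRESSIVE, STABLE, MarginSweep, TrendCall

SUCCESS = "success"
FAILURE = "failure"

STABLE_PREDICTS_SUCCESS = "stable_predicts_success"
PROGRESSIVE_PREDICTS_FAILURE = "progressive_predicts_failure"
DIRECTIONS = (STABLE_PREDICTS_SUCCESS, PROGRESSIVE_PREDICTS_FAILURE)

CI_METHODS = {"clopper-pearson": "beta", "wilson": "wilson"}

MULTIPLICITY_NOTE = (
    "Metrics at multiple margins are reported without multiple-testing "
    "adjustment; interpret sweep-wide significance accordingly."
)


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 counts of trend x 6-month outcome at one margin."""

    stable_failure: int
    stable_success: int
    progressive_failure: int
    progressive_success: int
    margin_delta: Optional[float] = None

    def __post_init__(self) -> None:
        if min(self.stable_failure, self.stable_success,
               self.progressive_failure, self.progressive_success) < 0:
            raise ValidationError("contingency cells must be non-negative")

    @property
    def total(self) -> int:
        return (self.stable_failure + self.stable_success
                + self.progressive_failure + self.progressive_success)

    def as_array(self) -> np.ndarray:
        """Rows = (stable, progressive); columns = (failure, success)."""
        return np.array(
            [[self.stable_failure, self.stable_success],
             [self.progressive_failure, self.progressive_success]]
        )


@dataclass(frozen=True)
class ProportionCI:
    numerator: int
    denominator: int
    estimate: float
    ci_low: float
    ci_high: float
    confidence: float = 0.95

    def __post_init__(self) -> None:
        if not 0 <= self.numerator <= self.denominator:
            raise ValidationError(
                f"invalid proportion {self.numerator}/{self.denominator}"
            )
        assert self.ci_low <= self.estimate <= self.ci_high


@dataclass(frozen=True)
class DiagnosticReport:
    margin_delta: Optional[float]
    direction: str
    sensitivity: Optional[ProportionCI]
    specificity: Optional[ProportionCI]
    ppv: Optional[ProportionCI]
    npv: Optional[ProportionCI]
    success_rate_by_trend: dict  # trend -> ProportionCI | None
    chi_square: Optional[tuple]  # (statistic, df, p_value) or None when undefined
    note: str = MULTIPLICITY_NOTE


def proportion_ci(numerator: int, denominator: int, confidence: float = 0.95,
                  method: str = "clopper-pearson") -> ProportionCI:
    """Binomial proportion with a two-sided confidence interval."""
    if denominator <= 0 or not 0 <= numerator <= denominator:
        raise ValidationError(
            f"invalid counts: {numerator}/{denominator}"
        )
    if method not in CI_METHODS:
        raise ValidationError(
            f"unknown CI method {method!r}; choose from {sorted(CI_METHODS)}"
        )
    low, high = proportion_confint(
        numerator, denominator, alpha=1 - confidence, method=CI_METHODS[method]
    )
    return ProportionCI(
        numerator=numerator,
        denominator=denominator,
        estimate=numerator / denominator,
        ci_low=float(low),
        ci_high=float(high),
        confidence=confidence,
    )


def clopper_pearson(numerator: int, denominator: int,
                    confidence: float = 0.95) -> ProportionCI:
    """Exact (Clopper-Pearson) two-sided binomial interval.

    The bounds invert the binomial tail probabilities, equivalently Beta
    quantiles: lower = Beta(alpha/2; k, n-k+1), upper = Beta(1-alpha/2;
    k+1, n-k); the lower bound is exactly 0 for k = 0 and the upper exactly
    1 for k = n (for k = n the lower bound reduces to (alpha/2)^(1/n)).
    """
    return proportion_ci(numerator, denominator, confidence, method="clopper-pearson")


def build_contingency(calls: Sequence[TrendCall],
                      patients: Sequence[PatientRecord]) -> ContingencyTable:
    """Cross-tabulate one margin's trend calls against 6-month outcomes.

    Patients without a call (incomplete monitoring) are excluded; a call
    whose patient lacks a 6-month outcome is an error.
    """
    if not calls:
        raise ValidationError("no trend calls to tabulate")
    margins = {c.margin_delta for c in calls}
    if len(margins) != 1:
        raise ValidationError(f"calls span multiple margins: {sorted(margins)}")
    ids = [c.patient_id for c in calls]
    if len(ids) != len(set(ids)):
        raise ValidationError("multiple calls for the same patient at one margin")
    outcome_by_id = {p.patient_id: p.outcome_6mo for p in patients}
    missing = [pid for pid in ids if not outcome_by_id.get(pid)]
    if missing:
        raise ValidationError(f"patients with calls but no 6-month outcome: {missing}")
    cells = {(STABLE, FAILURE): 0, (STABLE, SUCCESS): 0,
             (PROGRESSIVE, FAILURE): 0, (PROGRESSIVE, SUCCESS): 0}
    for c in calls:
        cells[(c.label, outcome_by_id[c.patient_id])] += 1
    return ContingencyTable(
        stable_failure=cells[(STABLE, FAILURE)],
        stable_success=cells[(STABLE, SUCCESS)],
        progressive_failure=cells[(PROGRESSIVE, FAILURE)],
        progressive_success=cells[(PROGRESSIVE, SUCCESS)],
        margin_delta=next(iter(margins)),
    )


def _ci_or_none(num: int, den: int, confidence: float, method: str):
    return proportion_ci(num, den, confidence, method) if den > 0 else None


def diag_metrics(table: ContingencyTable, direction: str,
                 confidence: float = 0.95,
                 ci_method: str = "clopper-pearson") -> dict:
    """Sensitivity, specificity, PPV, NPV for one prediction direction.

    Returns a dict mapping metric name to ProportionCI, with None for any
    metric whose denominator is zero.
    """
    if table.total <= 0:
        raise ValidationError("empty contingency table")
    if direction not in DIRECTIONS:
        raise ValidationError(
            f"unknown direction {direction!r}; choose from {DIRECTIONS}"
        )
    sf, ss = table.stable_failure, table.stable_success
    pf, ps = table.progressive_failure, table.progressive_success
    if direction == STABLE_PREDICTS_SUCCESS:
        # condition positive = success; test positive = stable
        tp, fn = ss, ps
        tn, fp = pf, sf
    else:
        # condition positive = failure; test positive = progressive
        tp, fn = pf, sf
        tn, fp = ss, ps
    return {
        "sensitivity": _ci_or_none(tp, tp + fn, confidence, ci_method),
        "specificity": _ci_or_none(tn, tn + fp, confidence, ci_method),
        "ppv": _ci_or_none(tp, tp + fp, confidence, ci_method),
        "npv": _ci_or_none(tn, tn + fn, confidence, ci_method),
    }


def pearson_chi_square(table: ContingencyTable,
                       correction: bool = False) -> tuple:
    """Pearson chi-square on the 2x2 table, df = 1.

    Uncorrected by default (sum of (O-E)^2/E); pass ``correction=True`` for
    the Yates continuity correction.  Undefined when a row or column
    marginal is zero.
    """
    arr = table.as_array()
    if table.total <= 0:
        raise ValidationError("empty contingency table")
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise ValidationError("chi-square undefined: zero row or column marginal")
    statistic, p_value, dof, _ = stats.chi2_contingency(arr, correction=correction)
    return float(statistic), int(dof), float(p_value)


def success_rate_by_trend(table: ContingencyTable, confidence: float = 0.95,
                          ci_method: str = "clopper-pearson") -> dict:
    """Per-trend ETV success proportion with CI; None for an empty stratum."""
    if table.total <= 0:
        raise ValidationError("empty contingency table")
    return {
        STABLE: _ci_or_none(
            table.stable_success, table.stable_failure + table.stable_success,
            confidence, ci_method,
        ),
        PROGRESSIVE: _ci_or_none(
            table.progressive_success,
            table.progressive_failure + table.progressive_success,
            confidence, ci_method,
        ),
    }


def evaluate_table(table: ContingencyTable, direction: str,
                   confidence: float = 0.95,
                   ci_method: str = "clopper-pearson") -> DiagnosticReport:
    """Full diagnostic report for one table and direction."""
    metrics = diag_metrics(table, direction, confidence, ci_method)
    try:
        chi = pearson_chi_square(table)
    except ValidationError:
        chi = None
    return DiagnosticReport(
        margin_delta=table.margin_delta,
        direction=direction,
        success_rate_by_trend=success_rate_by_trend(table, confidence, ci_method),
        chi_square=chi,
        **metrics,
    )


def sweep_report(sweep: MarginSweep, patients: Sequence[PatientRecord],
                 directions: Sequence[str] = DIRECTIONS,
                 confidence: float = 0.95,
                 ci_method: str = "clopper-pearson") -> list[DiagnosticReport]:
    """One DiagnosticReport per (margin, direction) over a margin sweep."""
    if not sweep.margins:
        raise ValidationError("empty sweep")
    reports = []
    for m in sweep.margins:
        table = build_contingency(sweep.calls[m], patients)
        for direction in directions:
            reports.append(evaluate_table(table, direction, confidence, ci_method))
    return reports
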