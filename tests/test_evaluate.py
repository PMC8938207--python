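"""Diagnostic accuracy: exact binomial CIs, 2x2 metrics, duality, chi-square."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from icptrend import (
    PROGRESSIVE,
    PROGRESSIVE_PREDICTS_FAILURE,
    STABLE,
    STABLE_PREDICTS_SUCCESS,
    ContingencyTable,
    ValidationError,
    build_contingency,
    clopper_pearson,
    diag_metrics,
    evaluate_table,
    pearson_chi_square,
    proportion_ci,
    success_rate_by_trend,
    sweep_report,
)
from icptrend import DailyAverages, PatientRecord, TrendCall, sweep_margins

# Published 2x2 at margin >2 mmHg: rows (stable, progressive) x (failure, success)
TABLE_AT_2MM = ContingencyTable(15, 12, 4, 0, margin_delta=2.0)
# ... and at margin >1 mmHg
TABLE_AT_1MM = ContingencyTable(11, 11, 8, 1, margin_delta=1.0)


# ---------------------------------------------------------------------------
# Clopper-Pearson: independent oracle via bisection on exact binomial tails


def binom_tail_ge(k, n, p):
    """P(X >= k) for X ~ Binomial(n, p), by exact summation."""
    return sum(math.comb(n, i) * p**i * (1 - p) ** (n - i) for i in range(k, n + 1))


def binom_tail_le(k, n, p):
    return sum(math.comb(n, i) * p**i * (1 - p) ** (n - i) for i in range(0, k + 1))


def cp_oracle(k, n, conf=0.95):
    """Clopper-Pearson bounds by bisection on the binomial tail equalities."""
    alpha = 1 - conf

    def bisect(f, target):
        lo, hi = 0.0, 1.0
        for _ in range(200):
            mid = (lo + hi) / 2
            if f(mid) < target:
                lo = mid
            else:
                hi = mid
        return (lo + hi) / 2

    lower = 0.0 if k == 0 else bisect(lambda p: binom_tail_ge(k, n, p), alpha / 2)
    upper = 1.0 if k == n else bisect(lambda p: 1 - binom_tail_le(k, n, p), 1 - alpha / 2)
    return lower, upper


class TestClopperPearson:
    @pytest.mark.parametrize(
        "k,n,low,high",
        [
            (4, 4, 0.3976, 1.0),
            (4, 19, 0.0605, 0.4557),
            (12, 12, 0.7354, 1.0),
            (0, 10, 0.0, 0.3085),
        ],
    )
    def test_published_style_bounds(self, k, n, low, high):
        ci = clopper_pearson(k, n)
        assert ci.ci_low == pytest.approx(low, abs=5e-5)
        assert ci.ci_high == pytest.approx(high, abs=5e-5)

    def test_boundary_closed_forms(self):
        assert clopper_pearson(0, 7).ci_low == 0.0
        assert clopper_pearson(7, 7).ci_high == 1.0
        # k = n: lower bound reduces to (alpha/2)^(1/n)
        assert clopper_pearson(4, 4).ci_low == pytest.approx(0.025 ** 0.25, abs=1e-10)

    @settings(max_examples=60, derandomize=True)
    @given(n=st.integers(1, 40), k_frac=st.floats(0, 1))
    def test_matches_binomial_tail_bisection_oracle(self, n, k_frac):
        k = min(n, int(round(k_frac * n)))
        ci = clopper_pearson(k, n)
        lo, hi = cp_oracle(k, n)
        assert ci.ci_low == pytest.approx(lo, abs=1e-9)
        assert ci.ci_high == pytest.approx(hi, abs=1e-9)

    def test_invalid_counts_rejected(self):
        for k, n in [(-1, 5), (6, 5), (0, 0)]:
            with pytest.raises(ValidationError):
                clopper_pearson(k, n)

    def test_wilson_alternative_available(self):
        cp = clopper_pearson(4, 19)
        w = proportion_ci(4, 19, method="wilson")
        assert w.ci_low != cp.ci_low
        assert 0 < w.ci_low < w.estimate < w.ci_high < 1

    def test_coverage_is_conservative(self, rng):
        """Empirical coverage of the exact interval stays near/above nominal."""
        for n, p in [(10, 0.2), (31, 0.6), (20, 0.9)]:
            bounds = [clopper_pearson(k, n) for k in range(n + 1)]
            ks = rng.binomial(n, p, size=800)
            covered = sum(bounds[k].ci_low <= p <= bounds[k].ci_high for k in ks)
            assert covered / len(ks) >= 0.935


# ---------------------------------------------------------------------------
# 2x2 metrics


class TestDiagMetrics:
    def test_stable_predicts_success_at_2mm(self):
        m = diag_metrics(TABLE_AT_2MM, STABLE_PREDICTS_SUCCESS)
        assert m["sensitivity"].estimate == 1.0        # 12/12
        assert m["specificity"].estimate == pytest.approx(4 / 19)
        assert m["ppv"].estimate == pytest.approx(12 / 27)
        assert m["npv"].estimate == 1.0                # 4/4

    def test_progressive_direction_is_the_mirror(self):
        m = diag_metrics(TABLE_AT_2MM, PROGRESSIVE_PREDICTS_FAILURE)
        assert m["sensitivity"].estimate == pytest.approx(4 / 19)
        assert m["specificity"].estimate == 1.0
        assert m["ppv"].estimate == 1.0
        assert m["npv"].estimate == pytest.approx(12 / 27)

    @settings(max_examples=200, derandomize=True)
    @given(cells=st.tuples(*[st.integers(0, 30)] * 4))
    def test_duality_on_random_tables(self, cells):
        """Swapping direction swaps sensitivity<->specificity and PPV<->NPV."""
        table = ContingencyTable(*cells)
        if table.total == 0:
            return
        a = diag_metrics(table, STABLE_PREDICTS_SUCCESS)
        b = diag_metrics(table, PROGRESSIVE_PREDICTS_FAILURE)
        for x, y in [("sensitivity", "specificity"), ("ppv", "npv")]:
            for u, v in [(x, y), (y, x)]:
                if a[u] is None:
                    assert b[v] is None
                else:
                    assert a[u].estimate == b[v].estimate
                    assert a[u].ci_low == b[v].ci_low

    @settings(max_examples=100, derandomize=True)
    @given(cells=st.tuples(*[st.integers(0, 30)] * 4))
    def test_bayes_consistency(self, cells):
        """PPV from (sens, spec, prevalence) via Bayes equals the direct PPV."""
        table = ContingencyTable(*cells)
        m = diag_metrics(table, STABLE_PREDICTS_SUCCESS) if table.total else None
        if m is None or any(m[k] is None for k in ("sensitivity", "specificity", "ppv")):
            return
        prev = (table.stable_success + table.progressive_success) / table.total
        sens, spec = m["sensitivity"].estimate, m["specificity"].estimate
        denom = sens * prev + (1 - spec) * (1 - prev)
        if denom > 0:
            assert m["ppv"].estimate == pytest.approx(sens * prev / denom)

    def test_zero_denominator_reported_as_undefined(self):
        table = ContingencyTable(5, 7, 0, 0)  # nobody progressive
        m = diag_metrics(table, STABLE_PREDICTS_SUCCESS)
        assert m["npv"] is None
        assert m["sensitivity"] is not None


# ---------------------------------------------------------------------------
# Chi-square and success rates


class TestChiSquare:
    def test_published_association(self):
        stat, df, p = pearson_chi_square(TABLE_AT_1MM)
        assert df == 1
        assert round(p, 3) == 0.044

    def test_yates_correction_would_not_reproduce_it(self):
        _, _, p = pearson_chi_square(TABLE_AT_1MM, correction=True)
        assert round(p, 3) != 0.044

    def test_independent_table_gives_zero(self):
        stat, _, p = pearson_chi_square(ContingencyTable(5, 5, 5, 5))
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValidationError, match="marginal"):
            pearson_chi_square(ContingencyTable(5, 0, 3, 0))

    @settings(max_examples=100, derandomize=True)
    @given(cells=st.tuples(*[st.integers(0, 25)] * 4))
    def test_matches_oe_summation_oracle(self, cells):
        table = ContingencyTable(*cells)
        arr = table.as_array().astype(float)
        if (arr.sum(0) == 0).any() or (arr.sum(1) == 0).any():
            return
        expected = np.outer(arr.sum(1), arr.sum(0)) / arr.sum()
        oracle = ((arr - expected) ** 2 / expected).sum()
        stat, _, p = pearson_chi_square(table)
        assert stat == pytest.approx(oracle, rel=1e-12)
        assert 0.0 <= p <= 1.0


class TestSuccessRates:
    def test_published_rates_at_1mm(self):
        rates = success_rate_by_trend(TABLE_AT_1MM)
        assert rates[STABLE].estimate == pytest.approx(0.5)      # 11/22
        assert rates[PROGRESSIVE].estimate == pytest.approx(1 / 9)

    def test_zero_successes_in_progressive_stratum(self):
        rates = success_rate_by_trend(TABLE_AT_2MM)
        assert rates[PROGRESSIVE].estimate == 0.0  # 0/4
        assert rates[PROGRESSIVE].ci_low == 0.0

    def test_saturated_table(self):
        rates = success_rate_by_trend(ContingencyTable(0, 10, 0, 5))
        assert rates[STABLE].estimate == 1.0
        assert rates[PROGRESSIVE].estimate == 1.0


# ---------------------------------------------------------------------------
# Tabulation and the sweep report


def _patient(pid, outcome):
    return PatientRecord(pid, 4.0, "male", "other", 18.0, outcome)


class TestBuildContingency:
    def test_cells_match_call_outcome_pairs(self):
        calls = [
            TrendCall("a", 2.0, STABLE, 0.0, False),
            TrendCall("b", 2.0, STABLE, 0.5, True),
            TrendCall("c", 2.0, PROGRESSIVE, 3.0, True),
        ]
        patients = [_patient("a", "failure"), _patient("b", "success"),
                    _patient("c", "failure")]
        t = build_contingency(calls, patients)
        assert (t.stable_failure, t.stable_success,
                t.progressive_failure, t.progressive_success) == (1, 1, 1, 0)

    def test_empty_calls_rejected(self):
        with pytest.raises(ValidationError):
            build_contingency([], [])

    def test_call_without_outcome_lists_ids(self):
        calls = [TrendCall("a", 2.0, STABLE, 0.0, False)]
        with pytest.raises(ValidationError, match="a"):
            build_contingency(calls, [])


class TestSweepReport:
    def test_reference_cohort_reproduces_published_columns(self, reference_cohort):
        patients, davs = reference_cohort
        sweep = sweep_margins(davs, (1.0, 2.0, 3.0, 4.0, 5.0))
        reports = [r for r in sweep_report(sweep, patients)
                   if r.direction == STABLE_PREDICTS_SUCCESS]
        sens = [round(100 * r.sensitivity.estimate, 1) for r in reports]
        spec = [round(100 * r.specificity.estimate, 1) for r in reports]
        assert sens == [91.7, 100.0, 100.0, 100.0, 100.0]
        assert spec == [42.1, 21.1, 15.8, 10.5, 5.3]

    def test_sensitivity_monotone_under_nesting(self, reference_cohort):
        """With nested calls, stable-trend sensitivity can only rise and
        specificity only fall as the margin grows."""
        patients, davs = reference_cohort
        sweep = sweep_margins(davs, (1.0, 2.0, 3.0, 4.0, 5.0))
        reports = [r for r in sweep_report(sweep, patients)
                   if r.direction == STABLE_PREDICTS_SUCCESS]
        sens = [r.sensitivity.estimate for r in reports]
        spec = [r.specificity.estimate for r in reports]
        assert sens == sorted(sens)
        assert spec == sorted(spec, reverse=True)

    def test_single_margin_single_direction(self, reference_cohort):
        patients, davs = reference_cohort
        sweep = sweep_margins(davs, (2.0,))
        reports = sweep_report(sweep, patients, (STABLE_PREDICTS_SUCCESS,))
        assert len(reports) == 1
        assert reports[0].chi_square is not None

    def test_degenerate_stratum_skips_chi_square(self):
        davs = [DailyAverages(f"p{i}", (5.0, 5.0, 5.0), (24,) * 3, True)
                for i in range(4)]
        patients = [_patient(f"p{i}", "success") for i in range(4)]
        sweep = sweep_margins(davs, (2.0,))
        (report,) = sweep_report(sweep, patients, (STABLE_PREDICTS_SUCCESS,))
        assert report.chi_square is None
        assert report.npv is None
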