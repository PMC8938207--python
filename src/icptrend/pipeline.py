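"""End-to-end pipeline: ingest (or simulate) -> DAV -> classify -> evaluate.

A run is described by a :class:`RunConfig`, loadable from YAML/JSON.  Exactly
one input source is allowed: either paths to ``patients.csv`` and
``icp_series.csv``, or an inline ``simulate`` block (a CohortConfig) that
generates the cohort first.  All artifacts (DAV table, trend calls,
diagnostic reports, cohort summary, rendered tables) are written as plain
CSV/JSON/text under the output directory, each report embedding a hash of
the configuration for provenance.  Stage counts are logged to stderr with
machine-parsable ``[stage]`` markers.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from .errors import ConfigurationError, ValidationError
from . import ingest
from .trend import PROGRESSIVE, STABLE, calls_to_frame, label_counts, sweep_margins
from .evaluate import DIRECTIONS, DiagnosticReport, ProportionCI, sweep_report
from .simulate import CohortConfig, simulate_cohort, write_cohort

logger = logging.getLogger("icptrend.pipeline")

DEFAULT_MARGINS = (1.0, 2.0, 3.0, 4.0, 5.0)


@dataclass
class RunConfig:
    out_dir: str
    patients_path: Optional[str] = None
    series_path: Optional[str] = None
    simulate: Optional[CohortConfig] = None
    min_readings_per_day: int = 24
    margins: tuple = DEFAULT_MARGINS
    directions: tuple = DIRECTIONS
    ci_method: str = "clopper-pearson"
    require_monotone: bool = True
    confidence: float = 0.95
    log_level: str = "INFO"
    seed: Optional[int] = None

    def validate(self) -> None:
        have_files = self.patients_path is not None and self.series_path is not None
        if have_files == (self.simulate is not None):
            raise ConfigurationError(
                "exactly one of (patients_path + series_path) or a simulate "
                "block must be given"
            )
        if not self.margins:
            raise ConfigurationError("margins must be nonempty")
        m = tuple(float(x) for x in self.margins)
        if any(x <= 0 for x in m) or any(b <= a for a, b in zip(m, m[1:])):
            raise ConfigurationError("margins must be strictly increasing and > 0")
        if self.simulate is not None:
            self.simulate.validate()

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw)
        sim = raw.pop("simulate", None)
        if sim is not None:
            sim = CohortConfig(**sim)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config fields: {sorted(unknown)}")
        cfg = cls(simulate=sim, **raw)
        if "margins" in raw:
            cfg.margins = tuple(raw["margins"])
        return cfg

    def config_hash(self) -> str:
        """Provenance hash over the analytic configuration; output location
        and log verbosity do not alter the science and are excluded."""
        payload = _as_jsonable(self)
        payload.pop("out_dir", None)
        payload.pop("log_level", None)
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _as_jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _as_jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _as_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_as_jsonable(v) for v in obj]
    return obj


def _report_to_dict(r: DiagnosticReport) -> dict:
    def ci(p: Optional[ProportionCI]):
        if p is None:
            return None
        return {
            "numerator": p.numerator, "denominator": p.denominator,
            "estimate_pct": round(100 * p.estimate, 2),
            "ci_low_pct": round(100 * p.ci_low, 2),
            "ci_high_pct": round(100 * p.ci_high, 2),
            "confidence": p.confidence,
        }

    return {
        "margin_mmhg": r.margin_delta,
        "direction": r.direction,
        "sensitivity": ci(r.sensitivity),
        "specificity": ci(r.specificity),
        "ppv": ci(r.ppv),
        "npv": ci(r.npv),
        "success_rate_by_trend": {k: ci(v) for k, v in r.success_rate_by_trend.items()},
        "chi_square": (
            None if r.chi_square is None else
            {"statistic": round(r.chi_square[0], 4), "df": r.chi_square[1],
             "p_value": round(r.chi_square[2], 4)}
        ),
        "note": r.note,
    }


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; returns in-memory artifacts and writes files.

    Stages: (simulate) -> ingest -> DAV -> classify sweep -> diagnostic
    evaluation -> cohort summary -> rendered tables.
    """
    config.validate()
    logging.basicConfig(level=config.log_level)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    if config.simulate is not None:
        cohort = simulate_cohort(config.simulate)
        patients_path, series_path = write_cohort(cohort, out_dir)
        logger.info("[simulate] wrote %d patients to %s", len(cohort.patients), out_dir)
    else:
        patients_path, series_path = config.patients_path, config.series_path

    patients = ingest.read_patients(patients_path)
    series = ingest.read_series(series_path)
    logger.info("[ingest] patients read: %d; series read: %d", len(patients), len(series))

    davs = [ingest.compute_dav(s, config.min_readings_per_day) for s in series]
    n_complete = sum(d.complete for d in davs)
    logger.info("[dav] analyzable (all three days): %d; excluded: %d",
                n_complete, len(davs) - n_complete)
    davs_frame = ingest.davs_to_frame(davs)
    davs_frame.to_csv(out_dir / "davs.csv", index=False)

    sweep = sweep_margins(davs, config.margins, config.require_monotone)
    counts = label_counts(sweep)
    for row in counts.itertuples(index=False):
        logger.info("[classify] margin >%g mmHg: stable %d, progressive %d",
                    row.margin_mmhg, row.n_stable, row.n_progressive)
    calls_to_frame(sweep).to_csv(out_dir / "calls.csv", index=False)

    reports = sweep_report(sweep, patients, config.directions,
                           config.confidence, config.ci_method)
    summary = ingest.cohort_summary(patients, davs)
    logger.info("[evaluate] %d reports over %d margins", len(reports), len(sweep.margins))

    payload = {
        "config_hash": config.config_hash(),
        "n_patients": len(patients),
        "n_complete": n_complete,
        "reports": [_report_to_dict(r) for r in reports],
    }
    with open(out_dir / "report.json", "w") as fh:
        json.dump(payload, fh, indent=1)
    with open(out_dir / "summary.json", "w") as fh:
        json.dump({"config_hash": config.config_hash(), **_as_jsonable(summary)},
                  fh, indent=1)

    artifacts = {
        "patients": patients, "series": series, "davs": davs, "sweep": sweep,
        "reports": reports, "summary": summary, "label_counts": counts,
        "out_dir": out_dir,
    }
    tables = render_paper_tables(artifacts)
    (out_dir / "tables.txt").write_text(tables)
    artifacts["tables"] = tables
    return artifacts


# ---------------------------------------------------------------------------
# Human-readable tables in the journal style


def _fmt(x: Optional[float], nd=1) -> str:
    if x is None:
        return "-"
    return f"{x:.{nd}f}".rstrip("0").rstrip(".") if nd else f"{x:.0f}"


def _fmt_pct(p: Optional[ProportionCI]) -> str:
    if p is None:
        return "undefined*"
    return (f"{100 * p.estimate:.2f}% "
            f"({100 * p.ci_low:.2f}-{100 * p.ci_high:.2f})")


def render_paper_tables(artifacts: dict) -> str:
    """Render the DAV summary, per-direction metric tables, and the margin
    sweep as aligned text tables with journal-style rounding."""
    lines: list[str] = []
    summary = artifacts["summary"]

    lines.append("DAV summary (complete patients, mmHg)")
    lines.append(f"{'Measure':<18}{'Mean':>8}{'SD':>8}{'Median':>8}{'Min':>8}{'Max':>8}")
    rows = [("Opening pressure", summary["opening_pressure"])]
    rows += [(f"DAV at POD {d}", summary[f"dav_day{d}"]) for d in (1, 2, 3)]
    for name, st in rows:
        if st is None:
            continue
        sd = "-" if st["sd"] is None else f"{st['sd']:.2f}"
        lines.append(
            f"{name:<18}{st['mean']:>8.2f}{sd:>8}{st['median']:>8.2f}"
            f"{st['min']:>8.2f}{st['max']:>8.2f}"
        )
    lines.append("")

    undefined_seen = False
    for r in artifacts["reports"]:
        lines.append(
            f"Margin >{_fmt(r.margin_delta)} mmHg, direction: {r.direction}"
        )
        for metric in ("sensitivity", "specificity", "ppv", "npv"):
            val = getattr(r, metric)
            lines.append(f"  {metric:<12} {_fmt_pct(val)}")
            undefined_seen |= val is None
        lines.append("")

    lines.append("Margin sweep (stable-trend direction: sensitivity for success, "
                 "specificity against failure)")
    lines.append(f"{'Margin':<8}{'Trend':<12}{'Failure':>8}{'Success':>8}"
                 f"{'Total':>7}{'Sens%':>8}{'Spec%':>8}")
    sweep = artifacts["sweep"]
    by_margin = {r.margin_delta: r for r in artifacts["reports"]
                 if r.direction == "stable_predicts_success"}
    for m in sweep.margins:
        r = by_margin.get(m)
        if r is None:
            continue
        calls = sweep.calls[m]
        sens = "-" if r.sensitivity is None else f"{100 * r.sensitivity.estimate:.1f}"
        spec = "-" if r.specificity is None else f"{100 * r.specificity.estimate:.1f}"
        # counts straight from the contingency the report was built on
        tb = _table_from_calls(calls, artifacts["patients"])
        lines.append(f"{'>' + _fmt(m):<8}{'Stable':<12}{tb[0][0]:>8}{tb[0][1]:>8}"
                     f"{tb[0][0] + tb[0][1]:>7}{sens:>8}{spec:>8}")
        lines.append(f"{'':<8}{'Increasing':<12}{tb[1][0]:>8}{tb[1][1]:>8}"
                     f"{tb[1][0] + tb[1][1]:>7}{spec:>8}{sens:>8}")
    if undefined_seen:
        lines.append("")
        lines.append("* undefined: empty stratum (zero denominator); "
                     "reported as missing, never 0 or 1")
    return "\n".join(lines) + "\n"


def _table_from_calls(calls, patients):
    outcome = {p.patient_id: p.outcome_6mo for p in patients}
    cells = [[0, 0], [0, 0]]  # rows stable/progressive, cols failure/success
    for c in calls:
        i = 0 if c.label == STABLE else 1
        j = 0 if outcome[c.patient_id] == "failure" else 1
        cells[i][j] += 1
    return cells
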