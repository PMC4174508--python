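"""Reading raw-measurement tables (deposited-data workbook or CSV exports).

The raw-measurements workbook holds three kinds of sheets: per-figure data,
per-quadrant injury calls in the 16-segment model, and CNR/EER ROI
measurements.  This module reads them into typed rows and recomputes every
summary statistic that is derivable from them: cohort EER and CNR means,
per-quadrant diagnostic accuracy against 30-day LGE, kappa, and the percent
of quadrants with findings.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .agreement_stats import (cohens_kappa, confusion, diagnostic_summary,
                              t_test_two_sample)
from .segment_model import QUADRANTS, SEGMENT_KEYS, VEINS, InjuryCallSet
from .signal_metrics import CohortStats

KINDS = ("eer", "cnr", "thickness_mm", "call")

REQUIRED_COLUMNS = ("subject", "timepoint", "modality", "location", "kind",
                    "value")


@dataclass
class MeasurementRow:
    """One raw measurement: a ratio, CNR, thickness, or binary call."""

    subject: str
    timepoint: str
    modality: str
    location: str          # "VEIN/quadrant" for calls, ROI label otherwise
    kind: str
    value: float

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown measurement kind {self.kind!r}")
        if self.kind == "call" and self.value not in (0.0, 1.0):
            raise ValueError("calls must be 0 or 1")
        if self.kind == "thickness_mm" and self.value <= 0:
            raise ValueError("thickness must be positive")


def read_measurements(path, sheet=None, column_map: dict | None = None,
                      exclude_subjects=()) -> list[MeasurementRow]:
    """Read a measurements CSV/XLSX into typed rows.

    ``column_map`` maps the file's column names onto the canonical
    ``subject/timepoint/modality/location/kind/value``.  Unparseable cells
    are reported with their row and column, never silently dropped;
    ``exclude_subjects`` drops listed subjects (e.g. a subject imaged with a
    different contrast agent).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        df = pd.read_excel(path, sheet_name=sheet or 0)
    else:
        df = pd.read_csv(path, float_precision="round_trip")
    if column_map:
        df = df.rename(columns=column_map)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing required columns: {missing}")

    rows: list[MeasurementRow] = []
    errors: list[str] = []
    excluded = {str(s) for s in exclude_subjects}
    for i, rec in df.iterrows():
        subject = str(rec["subject"])
        if subject in excluded:
            continue
        try:
            value = float(rec["value"])
            if not np.isfinite(value):
                raise ValueError("non-finite")
        except (TypeError, ValueError):
            errors.append(f"row {i}, column 'value': "
                          f"unparseable cell {rec['value']!r}")
            continue
        try:
            rows.append(MeasurementRow(
                subject=subject, timepoint=str(rec["timepoint"]),
                modality=str(rec["modality"]), location=str(rec["location"]),
                kind=str(rec["kind"]), value=value))
        except ValueError as exc:
            errors.append(f"row {i}: {exc}")
    if errors:
        raise ValueError("unparseable measurement cells:\n  "
                         + "\n  ".join(errors))
    return rows


def write_measurements(rows: list[MeasurementRow], path) -> None:
    df = pd.DataFrame([{c: getattr(r, c) for c in REQUIRED_COLUMNS}
                       for r in rows])
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        df.to_excel(path, index=False)
    else:
        # %.17g keeps write->read an exact identity on doubles
        df.to_csv(path, index=False, float_format="%.17g")


def _calls_to_sets(rows: list[MeasurementRow], modality: str,
                   timepoint: str) -> list[InjuryCallSet]:
    by_subject: dict[str, dict] = {}
    for r in rows:
        if r.kind != "call" or r.modality != modality \
                or r.timepoint != timepoint:
            continue
        try:
            vein, quadrant = r.location.split("/")
        except ValueError:
            raise ValueError(f"call location {r.location!r} is not "
                             "'VEIN/quadrant'") from None
        if vein not in VEINS or quadrant not in QUADRANTS:
            raise ValueError(f"unknown segment {r.location!r}")
        by_subject.setdefault(r.subject, {})[(vein, quadrant)] = bool(r.value)
    sets = []
    for subject, calls in sorted(by_subject.items()):
        full = {key: calls.get(key) for key in SEGMENT_KEYS}
        sets.append(InjuryCallSet(subject_id=subject, modality=modality,
                                  timepoint=timepoint, calls=full))
    return sets


def _cohort(rows, kind, modality=None, timepoint=None):
    vals = [r.value for r in rows if r.kind == kind
            and (modality is None or r.modality == modality)
            and (timepoint is None or r.timepoint == timepoint)]
    if len(vals) < 2:
        return None
    return CohortStats.from_values(vals)


def _pct_positive(sets: list[InjuryCallSet]):
    vals = [v for s in sets for v in s.calls.values() if v is not None]
    if not vals:
        return None
    return 100.0 * sum(vals) / len(vals)


def table2_report(rows: list[MeasurementRow]) -> dict:
    """Recompute every summary statistic derivable from the raw rows.

    Statistics whose inputs are absent are reported as ``None``, never
    fabricated.  Keys mirror the summary table of the study this pipeline
    reproduces: cohort EER (pre / 24 h), ostial CNR (24 h / 30 d),
    diagnostic accuracy of each 24-hour modality against 30-day LGE, kappa
    between the two 24-hour readings, percent of quadrants with findings,
    and the wall-thickness comparison.
    """
    report: dict = {}

    for name, kind, mod, tp in (
            ("eer_pre", "eer", "t2w", "pre"),
            ("eer_24h", "eer", "t2w", "24h"),
            ("cnr_24h", "cnr", "lge", "24h"),
            ("cnr_30d", "cnr", "lge", "30d"),
            ("thickness_pre_mm", "thickness_mm", None, "pre"),
            ("thickness_24h_mm", "thickness_mm", None, "24h")):
        stats = _cohort(rows, kind, mod, tp)
        report[name] = (None if stats is None
                        else {"mean": stats.mean, "sd": stats.sd,
                              "n": stats.n})

    pre = [r.value for r in rows if r.kind == "thickness_mm"
           and r.timepoint == "pre"]
    post = [r.value for r in rows if r.kind == "thickness_mm"
            and r.timepoint == "24h"]
    if len(pre) >= 2 and len(post) >= 2:
        t, p = t_test_two_sample(post, pre)
        report["thickness_t_p"] = p
    else:
        report["thickness_t_p"] = None

    t2w24 = _calls_to_sets(rows, "t2w", "24h")
    lge24 = _calls_to_sets(rows, "lge", "24h")
    lge30 = _calls_to_sets(rows, "lge", "30d")
    t2wpre = _calls_to_sets(rows, "t2w", "pre")

    report["pct_quadrants_t2w_pre"] = _pct_positive(t2wpre)
    report["pct_quadrants_t2w_24h"] = _pct_positive(t2w24)
    report["pct_quadrants_lge_24h"] = _pct_positive(lge24)
    report["pct_quadrants_lge_30d"] = _pct_positive(lge30)

    for name, test in (("t2w_vs_30d", t2w24), ("lge24_vs_30d", lge24)):
        if test and lge30:
            c = confusion(test, lge30)
            s = diagnostic_summary(c)
            report[name] = {
                "sensitivity_pct": 100 * s.sensitivity,
                "specificity_pct": 100 * s.specificity,
                "accuracy_pct": 100 * s.accuracy,
                "sensitivity_ci_pct": [100 * v for v in s.ci["sensitivity"]],
                "specificity_ci_pct": [100 * v for v in s.ci["specificity"]],
                "n": c.n, "dropped": c.dropped}
        else:
            report[name] = None

    if t2w24 and lge24:
        report["kappa_t2w_vs_lge_24h"] = cohens_kappa(confusion(t2w24, lge24))
    else:
        report["kappa_t2w_vs_lge_24h"] = None
    return report
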