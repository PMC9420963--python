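"""Longitudinal MRD tracking of ctDNA quantification results.

Each patient accumulates an ordered series of timepoints, every one carrying
a droplet-quantification result.  Status calls describe the molecular
course: a detectable baseline, a molecular response (first undetectable
point after positivity), sustained negativity, a molecular recurrence
(detectable again after documented negativity), and rising/falling trends
across consecutive detectable points.

Detectability is delegated entirely to the droplet-quantification rule
(pooled positive-droplet counts); the tracker never re-thresholds
concentrations.  Borderline points (a single positive droplet) are treated
as inconclusive: they break both positivity and negativity runs and receive
no status of their own.
"""

from __future__ import annotations

import csv
import datetime as dt
import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .errors import ValidationError
from .quant import QuantResult

STATUS_VOCABULARY = (
    "baseline_positive",
    "molecular_response",
    "sustained_negativity",
    "molecular_recurrence",
    "rising",
    "falling",
    "invalid_qc",
)


@dataclass(frozen=True)
class TimePoint:
    """One plasma sample: collection date plus its quantification result."""

    patient_id: str
    date: dt.date
    result: QuantResult
    days_since_diagnosis: int | None = None
    note: str | None = None

    def __post_init__(self):
        if self.days_since_diagnosis is not None and self.days_since_diagnosis < 0:
            raise ValidationError("days_since_diagnosis must be >= 0")


@dataclass
class PatientSeries:
    """Date-ordered timepoints with per-timepoint status calls."""

    patient_id: str
    timepoints: list[TimePoint]
    statuses: list[list[str]] = field(default_factory=list)

    def __iter__(self):
        return iter(self.timepoints)

    def __len__(self):
        return len(self.timepoints)


def build_series(timepoints: Sequence[TimePoint]) -> PatientSeries:
    """Sort timepoints into a series; QC-invalid points are retained but
    marked ``invalid_qc`` and excluded from status logic."""
    if not timepoints:
        raise ValidationError("cannot build a series from zero timepoints")
    patients = {tp.patient_id for tp in timepoints}
    if len(patients) > 1:
        raise ValidationError(f"mixed patient ids in series: {sorted(patients)}")
    ordered = sorted(timepoints, key=lambda tp: (tp.date, tp.result.assay_id))
    seen = set()
    for tp in ordered:
        key = (tp.date, tp.result.assay_id)
        if key in seen:
            raise ValidationError(
                f"duplicate timepoint for assay {tp.result.assay_id} on {tp.date}"
            )
        seen.add(key)
    series = PatientSeries(patient_id=ordered[0].patient_id, timepoints=ordered)
    series.statuses = call_status(series)
    return series


def call_status(series: PatientSeries) -> list[list[str]]:
    """Per-timepoint MRD status calls.

    Rules (evaluated on QC-valid points only, in date order):

    - ``baseline_positive``: the first valid point is detectable.
    - ``molecular_response``: an undetectable point ending a positivity run.
    - ``sustained_negativity``: the 2nd and later consecutive undetectable
      point.
    - ``molecular_recurrence``: a detectable point after >= 1 consecutive
      undetectable point.
    - ``rising`` / ``falling``: the 3rd point of a strictly monotone run of
      copies/mL across consecutive detectable points.
    - borderline points (single positive droplet) reset all runs and carry
      no status.

    Calls only ever look backward, so appending a timepoint never changes
    earlier calls.
    """
    statuses: list[list[str]] = []
    det_run = 0  # consecutive detectable points ending at previous valid point
    undet_run = 0
    rise_len = 0
    fall_len = 0
    prev_valid_detectable_value: float | None = None
    any_valid = False

    for tp in series.timepoints:
        res = tp.result
        if not res.qc_valid:
            statuses.append(["invalid_qc"])
            continue
        calls: list[str] = []
        d = res.detectability
        first_valid = not any_valid
        any_valid = True
        if d == "detectable":
            if first_valid:
                calls.append("baseline_positive")
            elif undet_run >= 1:
                calls.append("molecular_recurrence")
            value = res.copies_per_mL_plasma
            if det_run >= 1 and prev_valid_detectable_value is not None:
                if value > prev_valid_detectable_value:
                    rise_len += 1
                    fall_len = 1
                elif value < prev_valid_detectable_value:
                    fall_len += 1
                    rise_len = 1
                else:
                    rise_len = fall_len = 1
            else:
                rise_len = fall_len = 1
            if rise_len >= 3:
                calls.append("rising")
            if fall_len >= 3:
                calls.append("falling")
            det_run += 1
            undet_run = 0
            prev_valid_detectable_value = value
        elif d == "undetectable":
            if det_run >= 1:
                calls.append("molecular_response")
            undet_run += 1
            if undet_run >= 2:
                calls.append("sustained_negativity")
            det_run = 0
            rise_len = fall_len = 0
            prev_valid_detectable_value = None
        else:  # borderline: inconclusive, breaks every run
            det_run = 0
            undet_run = 0
            rise_len = fall_len = 0
            prev_valid_detectable_value = None
        statuses.append(calls)

    if not any_valid:
        raise ValidationError("no evaluable series: all timepoints QC-invalid")
    return statuses


def transition_indices(series: PatientSeries) -> dict[str, int | None]:
    """First index (0-based) at which each transition status is called."""
    out: dict[str, int | None] = {
        "molecular_response": None,
        "molecular_recurrence": None,
        "rising": None,
    }
    for i, calls in enumerate(series.statuses):
        for name in out:
            if out[name] is None and name in calls:
                out[name] = i
    return out


def export_series(series: PatientSeries, path) -> None:
    """Write the series as CSV, one row per timepoint."""
    if not series.timepoints:
        raise ValidationError("cannot export an empty series")
    fields = [
        "patient",
        "date",
        "days_since_diagnosis",
        "assay",
        "n_total",
        "n_positive",
        "copies_per_ml",
        "allelic_fraction",
        "detectability",
        "qc_flags",
        "statuses",
    ]
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(fields)
        for tp, calls in zip(series.timepoints, series.statuses):
            r = tp.result
            writer.writerow(
                [
                    tp.patient_id,
                    tp.date.isoformat(),
                    "" if tp.days_since_diagnosis is None else tp.days_since_diagnosis,
                    r.assay_id,
                    r.n_total,
                    r.n_positive,
                    repr(r.copies_per_mL_plasma),
                    "" if r.allelic_fraction is None else repr(r.allelic_fraction),
                    r.detectability,
                    ";".join(r.qc_flags),
                    ";".join(calls),
                ]
            )


def export_status_json(series: PatientSeries, path=None) -> str:
    payload = json.dumps(
        {
            "patient": series.patient_id,
            "timepoints": [
                {
                    "date": tp.date.isoformat(),
                    "assay": tp.result.assay_id,
                    "copies_per_ml": tp.result.copies_per_mL_plasma,
                    "detectability": tp.result.detectability,
                    "statuses": calls,
                }
                for tp, calls in zip(series.timepoints, series.statuses)
            ],
            "transitions": transition_indices(series),
        },
        indent=2,
    )
    if path is not None:
        with open(path, "w") as fh:
            fh.write(payload + "\n")
    return payload


def plot_data(series: PatientSeries):
    """Timepoint-aligned arrays (dates, copies/mL, statuses) for plotting.

    Zeros are retained; whether to clip for a log axis is the renderer's
    concern.
    """
    if not series.timepoints:
        raise ValidationError("empty series")
    dates = [tp.date for tp in series.timepoints]
    copies = [tp.result.copies_per_mL_plasma for tp in series.timepoints]
    return dates, copies, list(series.statuses)
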