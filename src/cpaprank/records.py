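"""Data model and I/O for nightly CPAP telemetry logs.

A CPAP machine emits one row per patient-night: usage duration, mask air
leakage, apnea index (AI), apnea-hypopnea index (AHI) and, in auto-titration
mode, the nightly average mask pressure.  This module parses such logs from
delimited text, validates the physical invariants of the telemetry, applies
the short-night quality filter, and segments each patient's history into
consecutive 7-day windows anchored at the start of therapy.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "DailyRecord",
    "PatientLog",
    "WeekWindow",
    "LogValidationError",
    "DEFAULT_SCHEMA",
    "read_cpap_logs",
    "write_cpap_logs",
    "apply_short_night_filter",
    "segment_weeks",
]

MODES = ("auto", "fixed")
SEXES = ("male", "female")

#: canonical field -> default CSV column name
DEFAULT_SCHEMA: dict[str, str] = {
    "patient_id": "patient_id",
    "date": "date",
    "sex": "sex",
    "mode": "mode",
    "usage_min": "usage_min",
    "leak": "leak_lps",
    "ai": "ai",
    "ahi": "ahi",
    "mask_pressure": "mask_pressure_cmh2o",
    "cpap_start": "cpap_start",  # optional column
}


class LogValidationError(ValueError):
    """Raised when a CPAP log violates the data model's invariants."""


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise LogValidationError(msg)


@dataclass(frozen=True)
class DailyRecord:
    """One patient-night of CPAP telemetry.

    ``physio_valid`` marks whether the physiological fields (leak, AI, AHI,
    mask pressure) of this night may enter weekly aggregates; the short-night
    filter clears it for nights with too little usage, because event-per-hour
    indices are unreliable over short spans.
    """

    date: dt.date
    usage_min: float
    leak: float | None = None
    ai: float | None = None
    ahi: float | None = None
    mask_pressure: float | None = None
    mode: str = "auto"
    physio_valid: bool = True

    def __post_init__(self) -> None:
        _require(self.mode in MODES, f"unknown CPAP mode {self.mode!r}")
        _require(self.usage_min >= 0, f"negative usage_min on {self.date}")
        for name in ("leak", "ai", "ahi", "mask_pressure"):
            v = getattr(self, name)
            if v is not None:
                _require(v >= 0, f"negative {name} on {self.date}")
        if self.ai is not None and self.ahi is not None:
            _require(
                self.ahi >= self.ai,
                f"AHI < AI on {self.date} (hypopneas cannot be negative)",
            )
        if self.usage_min == 0:
            _require(
                all(
                    getattr(self, n) is None
                    for n in ("leak", "ai", "ahi", "mask_pressure")
                ),
                f"zero-usage night on {self.date} carries physiological values",
            )
        if self.mask_pressure is not None:
            _require(
                self.mode == "auto",
                f"mask pressure recorded in fixed mode on {self.date}",
            )


@dataclass(frozen=True)
class PatientLog:
    """All daily records of one patient plus static attributes."""

    patient_id: str
    sex: str
    cpap_start: dt.date
    records: tuple[DailyRecord, ...]

    def __post_init__(self) -> None:
        _require(self.sex in SEXES, f"unknown sex {self.sex!r}")
        dates = [r.date for r in self.records]
        _require(len(set(dates)) == len(dates), f"duplicate record dates for {self.patient_id}")
        _require(dates == sorted(dates), f"records of {self.patient_id} not sorted by date")
        _require(
            all(d >= self.cpap_start for d in dates),
            f"record before cpap_start for {self.patient_id}",
        )

    @property
    def modal_mode(self) -> str:
        """Most frequent titration mode across recorded nights (default auto)."""
        n_auto = sum(r.mode == "auto" for r in self.records)
        return "auto" if n_auto * 2 >= len(self.records) else "fixed"


@dataclass(frozen=True)
class WeekWindow:
    """The records falling in one 7-calendar-day block of therapy.

    Week ``k`` spans days ``[7*(k-1), 7*k)`` after ``cpap_start``.  Calendar
    days without a record are implicit zero-usage nights; only actually
    recorded nights are stored.
    """

    patient_id: str
    week_index: int
    start: dt.date
    records: tuple[DailyRecord, ...]

    N_DAYS = 7

    def __post_init__(self) -> None:
        _require(self.week_index >= 1, "week_index must be >= 1")
        for r in self.records:
            off = (r.date - self.start).days
            _require(0 <= off < self.N_DAYS, f"record {r.date} outside window {self.week_index}")

    @property
    def end(self) -> dt.date:
        """First day after the window."""
        return self.start + dt.timedelta(days=self.N_DAYS)

    def usage_by_day(self) -> list[float]:
        """Nightly usage minutes for all 7 days, zeros for unrecorded nights."""
        out = [0.0] * self.N_DAYS
        for r in self.records:
            out[(r.date - self.start).days] = float(r.usage_min)
        return out


def _cell(value) -> float | None:
    return None if pd.isna(value) else float(value)


def read_cpap_logs(
    path,
    schema: Mapping[str, str] | None = None,
) -> list[PatientLog]:
    """Read a delimited patient-night log file into :class:`PatientLog` objects.

    Parameters
    ----------
    path : path-like or file-like
        CSV with a header row; one row per patient-night.
    schema : mapping, optional
        Maps canonical field names (keys of :data:`DEFAULT_SCHEMA`) to the
        column names actually present in the file.  Vendors vary; the data
        model does not.  A ``cpap_start`` column is optional — when absent,
        each patient's earliest recorded night is taken as the therapy start.

    Returns
    -------
    list of PatientLog, sorted by patient id, records sorted by date.

    Raises
    ------
    LogValidationError
        On duplicate (patient, date) rows, negative telemetry, unknown
        mode/sex labels, or any per-record invariant violation.
    """
    cols = dict(DEFAULT_SCHEMA)
    if schema:
        cols.update(schema)
    df = pd.read_csv(path)
    for field in ("patient_id", "date", "sex", "mode", "usage_min"):
        _require(cols[field] in df.columns, f"missing required column {cols[field]!r}")

    dup = df.duplicated(subset=[cols["patient_id"], cols["date"]], keep=False)
    if dup.any():
        rows = [int(i) + 2 for i in df.index[dup]]  # +2: header + 1-based
        raise LogValidationError(f"duplicate (patient, date) rows at lines {rows}")

    logs: list[PatientLog] = []
    for pid, grp in df.groupby(cols["patient_id"], sort=True):
        sexes = set(grp[cols["sex"]].astype(str))
        _require(len(sexes) == 1, f"inconsistent sex for patient {pid}")
        sex = sexes.pop()
        grp = grp.sort_values(cols["date"])
        records = []
        for _, row in grp.iterrows():
            records.append(
                DailyRecord(
                    date=dt.date.fromisoformat(str(row[cols["date"]])),
                    usage_min=float(row[cols["usage_min"]]),
                    leak=_cell(row.get(cols["leak"])),
                    ai=_cell(row.get(cols["ai"])),
                    ahi=_cell(row.get(cols["ahi"])),
                    mask_pressure=_cell(row.get(cols["mask_pressure"])),
                    mode=str(row[cols["mode"]]),
                )
            )
        if cols["cpap_start"] in grp.columns and not grp[cols["cpap_start"]].isna().all():
            start = dt.date.fromisoformat(str(grp[cols["cpap_start"]].iloc[0]))
        else:
            start = records[0].date
        logs.append(PatientLog(str(pid), sex, start, tuple(records)))
    return logs


def write_cpap_logs(logs: Iterable[PatientLog], path) -> None:
    """Write patient logs to CSV in the canonical column layout.

    Inverse of :func:`read_cpap_logs` on valid, unfiltered logs.
    """
    rows = []
    for log in logs:
        for r in log.records:
            rows.append(
                {
                    "patient_id": log.patient_id,
                    "date": r.date.isoformat(),
                    "sex": log.sex,
                    "mode": r.mode,
                    "usage_min": r.usage_min,
                    "leak_lps": r.leak,
                    "ai": r.ai,
                    "ahi": r.ahi,
                    "mask_pressure_cmh2o": r.mask_pressure,
                    "cpap_start": log.cpap_start.isoformat(),
                }
            )
    pd.DataFrame(
        rows,
        columns=[
            "patient_id",
            "date",
            "sex",
            "mode",
            "usage_min",
            "leak_lps",
            "ai",
            "ahi",
            "mask_pressure_cmh2o",
            "cpap_start",
        ],
    ).to_csv(path, index=False)


def apply_short_night_filter(
    log: PatientLog,
    min_minutes: float = 30.0,
    scope: str = "physio",
) -> PatientLog:
    """Quality-filter nights whose usage did not exceed ``min_minutes``.

    Event-per-hour indices (AI, AHI) are unreliable for very short nights,
    so only nights used for *more than* ``min_minutes`` keep their
    physiological telemetry.  Idempotent.

    Parameters
    ----------
    scope : {"physio", "night"}
        ``"physio"`` (default) clears ``physio_valid`` but keeps the night's
        usage duration for the usage features.  ``"night"`` drops the record
        entirely, turning it into an implicit zero-usage night downstream.
    """
    if scope not in ("physio", "night"):
        raise ValueError(f"unknown filter scope {scope!r}")
    if scope == "night":
        kept = tuple(r for r in log.records if r.usage_min > min_minutes)
        return replace(log, records=kept)
    out = tuple(
        replace(r, physio_valid=False) if r.usage_min <= min_minutes else r
        for r in log.records
    )
    return replace(log, records=out)


def segment_weeks(log: PatientLog, max_weeks: int | None = None) -> list[WeekWindow]:
    """Split a patient log into consecutive complete 7-day windows.

    Windows are anchored at ``cpap_start`` (therapy weeks, not calendar
    weeks).  Only complete 7-day spans are emitted; a trailing partial week
    is dropped.  A log spanning fewer than 7 days yields an empty list.
    """
    if not log.records:
        return []
    span = (log.records[-1].date - log.cpap_start).days + 1
    n_weeks = span // WeekWindow.N_DAYS
    if max_weeks is not None:
        n_weeks = min(n_weeks, max_weeks)
    windows: list[WeekWindow] = []
    i = 0
    recs: Sequence[DailyRecord] = log.records
    for k in range(1, n_weeks + 1):
        start = log.cpap_start + dt.timedelta(days=WeekWindow.N_DAYS * (k - 1))
        end = start + dt.timedelta(days=WeekWindow.N_DAYS)
        in_window = []
        while i < len(recs) and recs[i].date < end:
            in_window.append(recs[i])
            i += 1
        windows.append(WeekWindow(log.patient_id, k, start, tuple(in_window)))
    return windows
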