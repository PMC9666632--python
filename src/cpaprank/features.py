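"""Weekly feature engineering for CPAP logs.

Eighteen features summarize one 7-day window: two static qualitative values
(sex, titration mode), fourteen weekly summaries of the nightly telemetry
(usage duration, leak, AI, AHI, auto-mode mask pressure — mean/SD and, for
usage, percentages and the weekly total), and two derived qualitative
values, the weekly OSAS severity class (from AHI) and the weekly OSAS
presence class (from AI), each obtained as the most frequent daily class in
the week.

Usage summaries run over all 7 calendar days with non-use nights as 0 min;
physiological summaries run over physio-valid nights only (see the
short-night filter); pressure summaries additionally require auto mode.

Categorical features are one-hot encoded by default and every encoded
column is z-scored against the training cohort, so that weight magnitudes
of qualitative and quantitative factors are comparable.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .records import WeekWindow

__all__ = [
    "SEVERITY_LEVELS",
    "PRESENCE_LEVELS",
    "WeeklyFeatures",
    "FeatureSchema",
    "Standardizer",
    "classify_severity",
    "classify_presence",
    "weekly_mode",
    "compute_weekly_features",
]

#: OSAS severity bands on AHI (events/h), least to most severe.
#: Boundaries are inclusive upward: AHI = 5 is Mild, 15 Moderate, 30 Severe.
SEVERITY_LEVELS = ("Normal", "Mild", "Moderate", "Severe")
_SEVERITY_CUTS = (5.0, 15.0, 30.0)

#: OSAS presence on AI: Normal (AI < 5) / OSAS (5 <= AI).
PRESENCE_LEVELS = ("Normal", "OSAS")


def classify_severity(ahi: float) -> str:
    """Classify one night's AHI into the standard severity bands."""
    if ahi < 0:
        raise ValueError("AHI must be non-negative")
    for cut, level in zip(_SEVERITY_CUTS, SEVERITY_LEVELS):
        if ahi < cut:
            return level
    return SEVERITY_LEVELS[-1]


def classify_presence(ai: float) -> str:
    """Classify one night's AI as Normal (AI < 5) or OSAS (5 <= AI)."""
    if ai < 0:
        raise ValueError("AI must be non-negative")
    return "Normal" if ai < 5.0 else "OSAS"


def weekly_mode(values: Sequence[str], ordering: Sequence[str]) -> str | None:
    """Most frequent daily class in a week; ties go to the more abnormal level.

    ``ordering`` lists the levels from least to most abnormal.  Returns
    ``None`` when there are no valid daily values.
    """
    vals = [v for v in values if v is not None]
    if not vals:
        return None
    counts = Counter(vals)
    best = max(counts.values())
    tied = [v for v, c in counts.items() if c == best]
    return max(tied, key=ordering.index)


@dataclass(frozen=True)
class WeeklyFeatures:
    """The 18 weekly features for one patient-week (physical units)."""

    sex: str
    cpap_mode: str
    pct_days_over_4h: float
    pct_days_used: float
    pct_days_unused: float
    mean_usage: float
    sd_usage: float
    total_usage: float
    mean_leak: float | None
    sd_leak: float | None
    mean_ai: float | None
    sd_ai: float | None
    mean_ahi: float | None
    sd_ahi: float | None
    mean_pressure: float | None
    sd_pressure: float | None
    weekly_severity: str | None
    weekly_presence: str | None


def _mean_sd(values: Sequence[float], ddof: int) -> tuple[float | None, float | None]:
    if not values:
        return None, None
    arr = np.asarray(values, dtype=float)
    if len(arr) <= ddof:
        return float(arr.mean()), None
    return float(arr.mean()), float(arr.std(ddof=ddof))


def compute_weekly_features(
    window: WeekWindow,
    sex: str,
    cpap_mode: str | None = None,
    ddof: int = 0,
) -> WeeklyFeatures:
    """Compute the 18 weekly features from one 7-day window.

    Parameters
    ----------
    window : WeekWindow
        A complete 7-day window, after the short-night filter.
    sex : str
        Patient sex ("male"/"female").
    cpap_mode : str, optional
        Patient-level titration mode; defaults to the modal mode of the
        window's recorded nights (auto when no night was recorded).
    ddof : int
        Delta degrees of freedom for the SD features; 0 (population
        convention) by default.
    """
    usage = np.asarray(window.usage_by_day(), dtype=float)
    n = float(WeekWindow.N_DAYS)
    used = usage > 0

    if cpap_mode is None:
        n_auto = sum(r.mode == "auto" for r in window.records)
        cpap_mode = "auto" if n_auto * 2 >= len(window.records) else "fixed"

    physio = [r for r in window.records if r.physio_valid]
    leaks = [r.leak for r in physio if r.leak is not None]
    ais = [r.ai for r in physio if r.ai is not None]
    ahis = [r.ahi for r in physio if r.ahi is not None]
    pressures = [
        r.mask_pressure
        for r in physio
        if r.mode == "auto" and r.mask_pressure is not None
    ]

    mean_leak, sd_leak = _mean_sd(leaks, ddof)
    mean_ai, sd_ai = _mean_sd(ais, ddof)
    mean_ahi, sd_ahi = _mean_sd(ahis, ddof)
    mean_pressure, sd_pressure = _mean_sd(pressures, ddof)

    severity = weekly_mode(
        [classify_severity(r.ahi) for r in physio if r.ahi is not None],
        SEVERITY_LEVELS,
    )
    presence = weekly_mode(
        [classify_presence(r.ai) for r in physio if r.ai is not None],
        PRESENCE_LEVELS,
    )

    return WeeklyFeatures(
        sex=sex,
        cpap_mode=cpap_mode,
        pct_days_over_4h=100.0 * float((usage > 240.0).sum()) / n,
        pct_days_used=100.0 * float(used.sum()) / n,
        pct_days_unused=100.0 * float((~used).sum()) / n,
        mean_usage=float(usage.mean()),
        sd_usage=float(usage.std(ddof=ddof)),
        total_usage=float(usage.sum()),
        mean_leak=mean_leak,
        sd_leak=sd_leak,
        mean_ai=mean_ai,
        sd_ai=sd_ai,
        mean_ahi=mean_ahi,
        sd_ahi=sd_ahi,
        mean_pressure=mean_pressure,
        sd_pressure=sd_pressure,
        weekly_severity=severity,
        weekly_presence=presence,
    )


_QUANT_COLUMNS = (
    "pct_days_over_4h",
    "pct_days_used",
    "pct_days_unused",
    "mean_usage",
    "sd_usage",
    "total_usage",
    "mean_leak",
    "sd_leak",
    "mean_ai",
    "sd_ai",
    "mean_ahi",
    "sd_ahi",
    "mean_pressure",
    "sd_pressure",
)


@dataclass(frozen=True)
class FeatureSchema:
    """Fixed column layout mapping :class:`WeeklyFeatures` to a numeric vector.

    Sex and mode become single indicators (female, auto); OSAS presence
    becomes the "Normal" indicator; severity becomes either four one-hot
    indicators (default) or a single ordinal column 0..3.  Missing values
    (e.g. pressure under fixed mode, or no physio-valid night) encode as NaN
    and are resolved by the standardizer.
    """

    severity_encoding: str = "onehot"  # "onehot" | "ordinal"

    def __post_init__(self) -> None:
        if self.severity_encoding not in ("onehot", "ordinal"):
            raise ValueError(f"unknown severity encoding {self.severity_encoding!r}")

    @property
    def columns(self) -> tuple[str, ...]:
        sev: tuple[str, ...]
        if self.severity_encoding == "onehot":
            sev = tuple(f"severity_{lev.lower()}" for lev in SEVERITY_LEVELS)
        else:
            sev = ("severity_ordinal",)
        return ("sex_female", "cpap_mode_auto") + _QUANT_COLUMNS + sev + ("presence_normal",)

    @property
    def dim(self) -> int:
        return len(self.columns)

    def encode(self, f: WeeklyFeatures) -> np.ndarray:
        """Encode weekly features as a float vector (NaN marks missing)."""
        if f.sex not in ("male", "female"):
            raise ValueError(f"unknown sex level {f.sex!r}")
        if f.cpap_mode not in ("auto", "fixed"):
            raise ValueError(f"unknown mode level {f.cpap_mode!r}")
        if f.weekly_severity is not None and f.weekly_severity not in SEVERITY_LEVELS:
            raise ValueError(f"unknown severity level {f.weekly_severity!r}")
        if f.weekly_presence is not None and f.weekly_presence not in PRESENCE_LEVELS:
            raise ValueError(f"unknown presence level {f.weekly_presence!r}")

        out = [1.0 if f.sex == "female" else 0.0, 1.0 if f.cpap_mode == "auto" else 0.0]
        for name in _QUANT_COLUMNS:
            v = getattr(f, name)
            out.append(np.nan if v is None else float(v))
        if self.severity_encoding == "onehot":
            if f.weekly_severity is None:
                out.extend([np.nan] * len(SEVERITY_LEVELS))
            else:
                out.extend(
                    1.0 if f.weekly_severity == lev else 0.0 for lev in SEVERITY_LEVELS
                )
        else:
            out.append(
                np.nan
                if f.weekly_severity is None
                else float(SEVERITY_LEVELS.index(f.weekly_severity))
            )
        if f.weekly_presence is None:
            out.append(np.nan)
        else:
            out.append(1.0 if f.weekly_presence == "Normal" else 0.0)
        return np.asarray(out, dtype=float)

    def decode_categoricals(self, vector: np.ndarray) -> dict[str, str | None]:
        """Recover the categorical labels from an (unstandardized) vector."""
        cols = self.columns
        v = dict(zip(cols, np.asarray(vector, dtype=float)))
        if self.severity_encoding == "onehot":
            hot = [lev for lev in SEVERITY_LEVELS if v[f"severity_{lev.lower()}"] == 1.0]
            severity = hot[0] if hot else None
        else:
            s = v["severity_ordinal"]
            severity = None if np.isnan(s) else SEVERITY_LEVELS[int(s)]
        p = v["presence_normal"]
        return {
            "sex": "female" if v["sex_female"] == 1.0 else "male",
            "cpap_mode": "auto" if v["cpap_mode_auto"] == 1.0 else "fixed",
            "weekly_severity": severity,
            "weekly_presence": None if np.isnan(p) else ("Normal" if p == 1.0 else "OSAS"),
        }


class Standardizer:
    """Per-column z-scoring, ``(a - mu) / sigma``, fitted on training data only.

    Columns with zero spread map to 0, and missing entries map to 0 — the
    standardized training mean — which is the weight-neutral default for a
    linear ranking score.
    """

    def __init__(self, ddof: int = 0, fitted_on: str | None = None):
        self.ddof = ddof
        self.fitted_on = fitted_on
        self.mu: np.ndarray | None = None
        self.sigma: np.ndarray | None = None

    def fit(self, X: np.ndarray) -> "Standardizer":
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] < 2:
            raise ValueError("need a 2-D array with at least 2 training rows")
        with np.errstate(invalid="ignore"):
            self.mu = np.nanmean(X, axis=0)
            self.sigma = np.nanstd(X, axis=0, ddof=self.ddof)
        # all-missing columns have undefined moments; treat as constant 0
        self.mu = np.nan_to_num(self.mu)
        self.sigma = np.nan_to_num(self.sigma)
        return self

    def _check(self) -> None:
        if self.mu is None:
            raise RuntimeError("Standardizer used before fit()")

    def transform(self, X: np.ndarray) -> np.ndarray:
        self._check()
        arr = np.asarray(X, dtype=float)
        one_d = arr.ndim == 1
        A = np.atleast_2d(arr)
        sigma = np.where(self.sigma > 0, self.sigma, 1.0)
        Z = (A - self.mu) / sigma
        Z[:, self.sigma == 0] = 0.0
        Z = np.nan_to_num(Z, nan=0.0)
        return Z[0] if one_d else Z

    def fit_transform(self, X: np.ndarray) -> np.ndarray:
        return self.fit(X).transform(X)

    def inverse_transform(self, Z: np.ndarray) -> np.ndarray:
        """Invert the affine map on sigma > 0 columns (constant columns map to mu)."""
        self._check()
        Z = np.asarray(Z, dtype=float)
        return Z * self.sigma + self.mu
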