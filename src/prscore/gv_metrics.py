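"""Routine glycemic-variability (GV) metrics from self-monitored blood glucose.

Clinicians summarize capillary blood-glucose (SMBG) series with four routine
parameters: mean glucose, standard deviation (SD), coefficient of variation
(CV = SD / mean) and the fraction of readings inside the normoglycemic window
70-180 mg/dL (time-in-range by count). These feed the GTAA1C remission score
in :mod:`prscore.remission_scores`.

Conventions
-----------
* The canonical glucose unit is mg/dL; mmol/L values are converted with the
  molar-mass factor 18.016 mg/dL per mmol/L.
* The normoglycemic interval is closed at both ends: 70 and 180 mg/dL count
  as in range.
* SD uses the population denominator ``n`` — these are descriptive summaries
  of the readings a patient brings to a consultation, not inferential
  estimates.
* A visit needs at least five readings before its summary is considered
  adequate for scoring (``GVSummary.sufficient``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from datetime import datetime
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "MMOL_TO_MGDL",
    "NORMO_LOW_MGDL",
    "NORMO_HIGH_MGDL",
    "MIN_READINGS",
    "GlucoseReading",
    "GVSummary",
    "convert_to_mgdl",
    "frac_in_range",
    "summarize_gv",
    "assign_to_visits",
]

#: mg/dL per mmol/L of glucose (molar mass 180.16 g/mol).
MMOL_TO_MGDL = 18.016

#: Normoglycemic window, mg/dL, both endpoints included.
NORMO_LOW_MGDL = 70.0
NORMO_HIGH_MGDL = 180.0

#: Minimum number of capillary readings for an adequate visit summary.
MIN_READINGS = 5

_UNIT_ALIASES = {
    "mg/dl": "mg/dL",
    "mgdl": "mg/dL",
    "mmol/l": "mmol/L",
    "mmoll": "mmol/L",
    "mm": "mmol/L",
}


@dataclass(frozen=True)
class GlucoseReading:
    """One timestamped capillary glucose value in mg/dL."""

    timestamp: datetime
    value: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.value) or self.value <= 0:
            raise ValueError(
                f"glucose value must be positive and finite, got {self.value!r}"
            )


@dataclass(frozen=True)
class GVSummary:
    """Per-visit GV summary: n, mean, SD, CV, fraction in range, adequacy flag."""

    n_readings: int
    mean_bg: float
    sd_bg: float
    cv: float
    frac_in_range: float
    sufficient: bool


def _normalize_unit(unit: str) -> str:
    key = unit.strip().lower()
    canonical = _UNIT_ALIASES.get(key, unit.strip())
    if canonical not in ("mg/dL", "mmol/L"):
        raise ValueError(
            f"unknown glucose unit {unit!r}: expected 'mg/dL' or 'mmol/L'"
        )
    return canonical


def convert_to_mgdl(value, unit: str):
    """Convert a glucose concentration to mg/dL.

    Parameters
    ----------
    value : float or array-like
        Glucose concentration(s), strictly positive.
    unit : str
        ``'mg/dL'`` (returned unchanged) or ``'mmol/L'`` (multiplied by
        18.016).
    """
    arr = np.asarray(value, dtype=float)
    if np.any(arr <= 0) or not np.all(np.isfinite(arr)):
        raise ValueError("glucose values must be positive and finite")
    canonical = _normalize_unit(unit)
    out = arr if canonical == "mg/dL" else arr * MMOL_TO_MGDL
    return float(out) if np.isscalar(value) or arr.ndim == 0 else out


def _values(readings: Iterable) -> np.ndarray:
    vals = np.asarray(
        [r.value if isinstance(r, GlucoseReading) else float(r) for r in readings],
        dtype=float,
    )
    if vals.size and (np.any(vals <= 0) or not np.all(np.isfinite(vals))):
        raise ValueError("glucose values must be positive and finite")
    return vals


def frac_in_range(
    readings: Iterable,
    low: float = NORMO_LOW_MGDL,
    high: float = NORMO_HIGH_MGDL,
) -> float:
    """Fraction of readings inside the closed interval [low, high] mg/dL.

    Accepts :class:`GlucoseReading` objects or bare mg/dL numbers. The
    interval is closed: readings equal to either endpoint count as in range.
    """
    vals = _values(readings)
    if vals.size == 0:
        raise ValueError("frac_in_range requires at least one reading")
    if low > high:
        raise ValueError(f"invalid range: low {low} > high {high}")
    return float(np.mean((vals >= low) & (vals <= high)))


def summarize_gv(readings: Iterable, min_readings: int = MIN_READINGS) -> GVSummary:
    """Summarize a list of readings into a :class:`GVSummary`.

    Mean, SD (population denominator ``n``), CV and fraction-in-range are
    computed on all supplied readings. ``sufficient`` is True when at least
    ``min_readings`` values are present; downstream GTAA1C scoring refuses
    insufficient summaries.
    """
    vals = _values(readings)
    n = int(vals.size)
    if n == 0:
        return GVSummary(0, float("nan"), float("nan"), float("nan"),
                         float("nan"), False)
    mean = float(np.mean(vals))
    sd = float(np.std(vals, ddof=0))
    cv = sd / mean if mean > 0 else float("nan")
    frac = float(np.mean((vals >= NORMO_LOW_MGDL) & (vals <= NORMO_HIGH_MGDL)))
    return GVSummary(n, mean, sd, cv, frac, n >= min_readings)


def assign_to_visits(
    reading_times: Sequence,
    visit_dates: Sequence,
) -> np.ndarray:
    """Attribute readings to visits by date window.

    A reading belongs to the visit whose window it falls in; the window for
    visit *i* runs from the previous visit date (exclusive) to visit *i*'s
    date (inclusive) — the readings a patient brings to a consultation are
    those logged since the last one. The first visit additionally collects
    anything on or before its date. Readings after the last visit get -1.

    Returns an integer array of visit indices aligned with
    ``reading_times``; ``visit_dates`` must be sorted ascending.
    """
    times = np.asarray(reading_times, dtype="datetime64[s]")
    dates = np.asarray(visit_dates, dtype="datetime64[s]")
    if dates.size == 0:
        raise ValueError("at least one visit date is required")
    if np.any(np.diff(dates) < np.timedelta64(0, "s")):
        raise ValueError("visit dates must be sorted ascending")
    idx = np.searchsorted(dates, times, side="left")
    idx[idx == dates.size] = -1
    return idx
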