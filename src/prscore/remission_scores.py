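"""Partial-remission (PR) scores for new-onset type 1 diabetes.

Three per-visit scores are implemented:

``IDAA1C``
    Insulin-dose-adjusted HbA1c, ``HbA1c(%) + 4 × DIR`` with DIR the daily
    insulin requirement in U/kg/day. PR is defined as IDAA1C ≤ 9.

``GTAA1C``
    Glycemic target-adjusted HbA1c, ``HbA1c(%) − 3 × f`` with ``f`` the
    FRACTION (0-1, not a 0-100 percentage) of capillary glucose readings in
    the 70-180 mg/dL normoglycemic window. PR is predicted when GTAA1C ≤ 4.5.
    Only the fractional reading is coherent with the threshold: with HbA1c
    near 7% and full time-in-range, 7.5 − 3×1.0 = 4.5.

``BETA-2``
    Composite index of residual β-cell function developed for islet-graft
    monitoring: ``√C-peptide[nmol/L] × (1 − DIR) / (glucose[mmol/L] ×
    HbA1c[%]) × 1000``. Reported as computed; DIR > 1 U/kg/day yields
    negative values, which are not clamped.

A PR *episode* over a visit series is the first maximal run of consecutive
visits satisfying the chosen criterion. Interrupted remissions are possible;
re-entry runs can be listed with :func:`pr_episodes` but only the first run
counts as "the" episode.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import date, datetime
from typing import Optional, Sequence

import numpy as np

from .gv_metrics import GVSummary

__all__ = [
    "IDAA1C_PR_THRESHOLD",
    "GTAA1C_PR_THRESHOLD",
    "DAYS_PER_MONTH",
    "VisitRecord",
    "RemissionScorecard",
    "PREpisode",
    "idaa1c",
    "gtaa1c",
    "beta2",
    "classify_pr",
    "score_visit",
    "pr_episode",
    "pr_episodes",
]

IDAA1C_PR_THRESHOLD = 9.0
GTAA1C_PR_THRESHOLD = 4.5

#: Mean Gregorian month length used to express episode durations in months.
DAYS_PER_MONTH = 30.44

_CRITERIA = {"idaa1c": IDAA1C_PR_THRESHOLD, "gtaa1c": GTAA1C_PR_THRESHOLD}


@dataclass
class VisitRecord:
    """One clinic visit: HbA1c, insulin dose, GV summary, C-peptide, SH flag.

    ``c_peptide`` is in pmol/mL (numerically equal to nmol/L);
    ``fasting_glucose`` in mmol/L. Either may be absent (None).
    """

    patient_id: str
    visit_date: date
    months_since_dx: float
    hba1c_pct: float
    dir: float
    gv: Optional[GVSummary] = None
    c_peptide: Optional[float] = None
    fasting_glucose: Optional[float] = None
    severe_hypo: bool = False

    def __post_init__(self) -> None:
        if not (3.0 < self.hba1c_pct < 20.0):
            raise ValueError(
                f"hba1c_pct {self.hba1c_pct} outside the plausible (3, 20)% range"
            )
        if self.dir < 0:
            raise ValueError(f"daily insulin requirement must be >= 0, got {self.dir}")
        if self.months_since_dx < 0:
            raise ValueError("months_since_dx must be >= 0")


@dataclass(frozen=True)
class RemissionScorecard:
    """The three scores and PR flags for one visit.

    ``gtaa1c``/``pr_gtaa1c`` are None when the visit's GV summary is absent
    or insufficient; ``beta2`` is None when C-peptide or fasting glucose is
    missing.
    """

    idaa1c: float
    gtaa1c: Optional[float]
    beta2: Optional[float]
    pr_idaa1c: bool
    pr_gtaa1c: Optional[bool]


@dataclass(frozen=True)
class PREpisode:
    """A contiguous run of visits in partial remission under one criterion."""

    onset_date: date
    end_date: date
    duration_months: float
    criterion: str
    n_visits: int = 1


def idaa1c(hba1c_pct, dir):
    """Insulin-dose-adjusted HbA1c: ``HbA1c(%) + 4 × DIR``."""
    h = np.asarray(hba1c_pct, dtype=float)
    d = np.asarray(dir, dtype=float)
    if np.any(d < 0):
        raise ValueError("daily insulin requirement must be >= 0")
    out = h + 4.0 * d
    return float(out) if out.ndim == 0 else out


def gtaa1c(hba1c_pct, frac_normo):
    """Glycemic target-adjusted HbA1c: ``HbA1c(%) − 3 × frac_normo``.

    ``frac_normo`` is the fraction (0-1) of readings in 70-180 mg/dL.
    """
    h = np.asarray(hba1c_pct, dtype=float)
    f = np.asarray(frac_normo, dtype=float)
    if np.any((f < 0) | (f > 1)):
        raise ValueError("frac_normo must be a fraction in [0, 1], not a percentage")
    out = h - 3.0 * f
    return float(out) if out.ndim == 0 else out


def beta2(
    fasting_cpeptide: float,
    fasting_glucose: float,
    hba1c_pct: float,
    dir: float,
    postprandial: bool = False,
) -> float:
    """BETA-2 score: ``√C-peptide × (1 − DIR) / (glucose × HbA1c) × 1000``.

    C-peptide in nmol/L (= pmol/mL), glucose in mmol/L, HbA1c in %, DIR in
    U/kg/day. ``postprandial`` records that the sample was not fasted (the
    score was designed for fasting samples); it does not change the
    arithmetic. Negative results (DIR > 1) are returned as computed.
    """
    if fasting_cpeptide < 0:
        raise ValueError("C-peptide must be >= 0")
    if fasting_glucose <= 0:
        raise ValueError("plasma glucose must be > 0 mmol/L")
    if hba1c_pct <= 0:
        raise ValueError("HbA1c must be > 0 %")
    return math.sqrt(fasting_cpeptide) * (1.0 - dir) / (fasting_glucose * hba1c_pct) * 1000.0


def classify_pr(score, criterion: str):
    """True when the score meets the criterion's PR threshold (inclusive).

    IDAA1C: PR iff score ≤ 9. GTAA1C: PR iff score ≤ 4.5.
    """
    key = criterion.strip().lower()
    if key not in _CRITERIA:
        raise ValueError(
            f"unknown PR criterion {criterion!r}: expected 'idaa1c' or 'gtaa1c'"
        )
    s = np.asarray(score, dtype=float)
    if np.any(~np.isfinite(s)):
        raise ValueError("score must be finite")
    out = s <= _CRITERIA[key]
    return bool(out) if out.ndim == 0 else out


def score_visit(visit: VisitRecord) -> RemissionScorecard:
    """Compute all available scores and PR flags for one visit.

    GTAA1C is refused (None) when the GV summary is absent or has fewer than
    the minimum number of readings; BETA-2 needs C-peptide and fasting
    glucose.
    """
    ida = idaa1c(visit.hba1c_pct, visit.dir)
    gta = pr_gta = None
    if visit.gv is not None and visit.gv.sufficient:
        gta = gtaa1c(visit.hba1c_pct, visit.gv.frac_in_range)
        pr_gta = classify_pr(gta, "gtaa1c")
    b2 = None
    if visit.c_peptide is not None and visit.fasting_glucose is not None:
        b2 = beta2(visit.c_peptide, visit.fasting_glucose, visit.hba1c_pct, visit.dir)
    return RemissionScorecard(ida, gta, b2, classify_pr(ida, "idaa1c"), pr_gta)


def _duration_months(onset, end) -> float:
    d0 = np.datetime64(onset, "D")
    d1 = np.datetime64(end, "D")
    return float((d1 - d0) / np.timedelta64(1, "D")) / DAYS_PER_MONTH


def pr_episodes(
    visit_dates: Sequence,
    in_pr: Sequence[bool],
    criterion: str = "idaa1c",
) -> list[PREpisode]:
    """All maximal contiguous runs of PR-qualifying visits, in date order.

    ``visit_dates`` must be sorted ascending; ``in_pr`` is the per-visit PR
    flag under ``criterion``. A run containing a single qualifying visit has
    duration 0 months.
    """
    dates = list(visit_dates)
    flags = [bool(f) for f in in_pr]
    if len(dates) != len(flags):
        raise ValueError("visit_dates and in_pr must be aligned")
    if len(dates) == 0:
        raise ValueError("at least one visit is required")
    as64 = np.asarray(dates, dtype="datetime64[s]")
    if np.any(np.diff(as64) < np.timedelta64(0, "s")):
        raise ValueError("visits must be sorted by date")
    episodes: list[PREpisode] = []
    i = 0
    n = len(flags)
    while i < n:
        if flags[i]:
            j = i
            while j + 1 < n and flags[j + 1]:
                j += 1
            episodes.append(
                PREpisode(
                    onset_date=dates[i],
                    end_date=dates[j],
                    duration_months=_duration_months(dates[i], dates[j]),
                    criterion=criterion.lower(),
                    n_visits=j - i + 1,
                )
            )
            i = j + 1
        else:
            i += 1
    return episodes


def pr_episode(
    visit_dates: Sequence,
    in_pr: Sequence[bool],
    criterion: str = "idaa1c",
) -> Optional[PREpisode]:
    """The first maximal PR run over a visit series, or None if no visit
    qualifies. See :func:`pr_episodes` for the run convention."""
    eps = pr_episodes(visit_dates, in_pr, criterion)
    return eps[0] if eps else None
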