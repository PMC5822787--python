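"""Reading, writing and validation of cohort tables, and the full pipeline.

The on-disk interchange format is plain delimited text: comma-separated,
UTF-8, one header row, ISO-8601 dates, ``.`` decimal separator and ``NA``
for missing values. Three tables make up a cohort:

``patients.csv``
    one row per patient: ``patient_id`` plus demographics and diagnosis
    features (``dx_date``, ``age_at_dx``, ``sex``, ``dka``/``ph``/
    ``bicarbonate``, ...).
``visits.csv``
    one row per consultation: ``patient_id, visit_date, months_since_dx,
    hba1c_pct, dir`` and optionally ``c_peptide`` (pmol/mL),
    ``fasting_glucose`` (mmol/L), ``severe_hypo``.
``readings.csv``
    one row per capillary glucose value: ``patient_id, timestamp, value,
    unit`` (mg/dL or mmol/L; converted to mg/dL on load).

:func:`run_pipeline` chains the library end to end: per-visit GV summaries
from the readings, the three remission scores, PR episodes, and the
cohort-level evaluation (diagnostic performance of one PR definition
against the other, contingency analyses, determinant regression, GV
variable selection, score-band vs duration analysis).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .gv_metrics import MMOL_TO_MGDL, NORMO_LOW_MGDL, NORMO_HIGH_MGDL, MIN_READINGS
from .remission_scores import (
    idaa1c, gtaa1c, beta2, classify_pr, pr_episodes, DAYS_PER_MONTH,
)
from . import cohort_stats as cs
from .synthetic_cohort import SimulatedCohort

__all__ = [
    "NA_TOKEN",
    "SchemaError",
    "CohortBundle",
    "PipelineReport",
    "load_cohort",
    "write_cohort",
    "bundle_from_cohort",
    "run_pipeline",
    "write_report",
]

NA_TOKEN = "NA"

_REQUIRED = {
    "patients": ["patient_id"],
    "visits": ["patient_id", "visit_date", "months_since_dx", "hba1c_pct", "dir"],
    "readings": ["patient_id", "timestamp", "value"],
}

_TRUE = {"true", "1", "yes"}
_FALSE = {"false", "0", "no"}


class SchemaError(ValueError):
    """A cohort table failed schema or referential-integrity validation."""


@dataclass
class CohortBundle:
    """Validated in-memory cohort: three aligned tables plus provenance."""

    patients: pd.DataFrame
    visits: pd.DataFrame
    readings: pd.DataFrame
    provenance: dict = field(default_factory=dict)


@dataclass
class PipelineReport:
    """Everything :func:`run_pipeline` computes, ready to serialize."""

    scorecards: pd.DataFrame
    episodes: pd.DataFrame
    performance: Optional[cs.DiagnosticPerformance]
    score_r2: Optional[float]
    score_r2_p: Optional[float]
    contingency: pd.DataFrame
    determinants: Optional[cs.DeterminantModel]
    gv_selection: Optional[pd.DataFrame]
    band_duration: Optional[pd.DataFrame]
    counts: dict
    log: dict


def _parse_bool(series: pd.Series, table: str, column: str) -> pd.Series:
    def one(v):
        if pd.isna(v):
            return False
        s = str(v).strip().lower()
        if s in _TRUE:
            return True
        if s in _FALSE:
            return False
        raise SchemaError(f"{table}.{column}: cannot parse boolean value {v!r}")
    return series.map(one)


def _read_table(path, name: str, parse_dates=()) -> pd.DataFrame:
    df = pd.read_csv(path, na_values=[NA_TOKEN])
    missing = [c for c in _REQUIRED[name] if c not in df.columns]
    if missing:
        raise SchemaError(f"{name} table {path}: missing required column(s) {missing}")
    for col in parse_dates:
        if col in df.columns:
            df[col] = pd.to_datetime(df[col])
    return df


def load_cohort(
    patients_path,
    visits_path,
    readings_path,
    glucose_unit: Optional[str] = None,
) -> CohortBundle:
    """Load and validate the three cohort tables.

    Glucose is converted to mg/dL using the per-row ``unit`` column, or the
    declared ``glucose_unit`` when the column is absent. Row-level failures
    (non-positive glucose, unknown units) are collected and reported with
    1-based data line numbers; referential-integrity violations (visits or
    readings whose ``patient_id`` is unknown, duplicate visit dates) are
    rejected naming the offender.
    """
    patients = _read_table(patients_path, "patients", parse_dates=("dx_date",))
    visits = _read_table(visits_path, "visits", parse_dates=("visit_date",))
    readings = _read_table(readings_path, "readings", parse_dates=("timestamp",))

    known = set(patients["patient_id"])
    orphans = sorted(set(visits["patient_id"]) - known)
    if orphans:
        raise SchemaError(f"visits reference unknown patient_id(s): {orphans[:5]}")
    orphans = sorted(set(readings["patient_id"]) - known)
    if orphans:
        raise SchemaError(f"readings reference unknown patient_id(s): {orphans[:5]}")
    dup = visits.duplicated(subset=["patient_id", "visit_date"])
    if dup.any():
        bad = visits.loc[dup, "patient_id"].unique()[:5]
        raise SchemaError(f"duplicate visit dates for patient_id(s): {list(bad)}")

    # unit conversion with row-level error collection (line 1 = header)
    if "unit" in readings.columns:
        units = readings["unit"].astype(str).str.strip().str.lower()
    elif glucose_unit is not None:
        units = pd.Series(glucose_unit.strip().lower(), index=readings.index)
    else:
        units = pd.Series("mg/dl", index=readings.index)
    problems = []
    factor = np.ones(len(readings))
    is_mmol = units.isin(["mmol/l", "mmoll", "mm"])
    is_mgdl = units.isin(["mg/dl", "mgdl"])
    for i in readings.index[~(is_mmol | is_mgdl)][:20]:
        problems.append(f"line {i + 2}: unknown glucose unit {readings['unit'][i]!r}")
    factor[is_mmol] = MMOL_TO_MGDL
    values = pd.to_numeric(readings["value"], errors="coerce") * factor
    bad = ~np.isfinite(values) | (values <= 0)
    for i in readings.index[bad][:20]:
        problems.append(f"line {i + 2}: non-positive or unparseable glucose value")
    if problems:
        raise SchemaError("readings table rejected:\n  " + "\n  ".join(problems))
    readings = readings.assign(value=values, unit="mg/dL")

    for col in ("severe_hypo",):
        if col in visits.columns:
            visits[col] = _parse_bool(visits[col], "visits", col)
    for col in ("dka",):
        if col in patients.columns:
            patients[col] = _parse_bool(patients[col], "patients", col)

    provenance = {
        "patients_path": str(patients_path),
        "visits_path": str(visits_path),
        "readings_path": str(readings_path),
        "glucose_unit_declared": glucose_unit,
        "schema_version": "1",
        "prscore_version": __version__,
    }
    return CohortBundle(patients, visits, readings, provenance)


def bundle_from_cohort(cohort: SimulatedCohort) -> CohortBundle:
    """Wrap a simulated cohort as a validated bundle (no disk round trip)."""
    return CohortBundle(
        patients=cohort.patients.copy(),
        visits=cohort.visits.copy(),
        readings=cohort.readings.copy(),
        provenance={"source": "synthetic", "seed": cohort.config.seed,
                    "schema_version": "1", "prscore_version": __version__},
    )


def write_cohort(cohort, outdir) -> dict:
    """Write a cohort's tables as CSV under ``outdir``; returns the paths."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    tables = {"patients": cohort.patients, "visits": cohort.visits,
              "readings": cohort.readings}
    if getattr(cohort, "truth", None) is not None:
        tables["truth"] = cohort.truth
    paths = {}
    for name, df in tables.items():
        p = out / f"{name}.csv"
        df.to_csv(p, index=False, na_rep=NA_TOKEN, date_format="%Y-%m-%dT%H:%M:%S")
        paths[name] = str(p)
    return paths


# --------------------------------------------------------------------------
# pipeline
# --------------------------------------------------------------------------

def _per_visit_gv(visits: pd.DataFrame, readings: pd.DataFrame,
                  min_readings: int) -> pd.DataFrame:
    """Attribute readings to visit windows and summarize GV per visit.

    Window for a visit runs from the previous visit (exclusive) to the visit
    date (inclusive); readings after a patient's last visit are dropped.
    """
    v = visits[["patient_id", "visit_date"]].sort_values("visit_date", kind="mergesort")
    r = readings.sort_values("timestamp", kind="mergesort")
    joined = pd.merge_asof(
        r, v, left_on="timestamp", right_on="visit_date",
        by="patient_id", direction="forward", allow_exact_matches=True,
    ).dropna(subset=["visit_date"])
    in_range = joined["value"].between(NORMO_LOW_MGDL, NORMO_HIGH_MGDL)
    g = joined.assign(in_range=in_range).groupby(
        ["patient_id", "visit_date"], sort=False)
    gv = pd.DataFrame(
        {
            "n_readings": g["value"].size(),
            "mean_bg": g["value"].mean(),
            "sd_bg": g["value"].std(ddof=0),
            "frac_normo": g["in_range"].mean(),
        }
    ).reset_index()
    gv["cv"] = gv["sd_bg"] / gv["mean_bg"]
    gv["sufficient"] = gv["n_readings"] >= min_readings
    return gv


def _score_table(visits: pd.DataFrame, gv: pd.DataFrame) -> pd.DataFrame:
    df = visits.merge(gv, on=["patient_id", "visit_date"], how="left")
    df["n_readings"] = df["n_readings"].fillna(0).astype(int)
    df["sufficient"] = df["sufficient"].notna() & df["sufficient"].eq(True)
    df["idaa1c"] = idaa1c(df["hba1c_pct"].to_numpy(), df["dir"].to_numpy())
    gta = np.full(len(df), np.nan)
    ok = df["sufficient"].to_numpy()
    gta[ok] = gtaa1c(df.loc[ok, "hba1c_pct"].to_numpy(),
                     df.loc[ok, "frac_normo"].to_numpy())
    df["gtaa1c"] = gta
    b2 = np.full(len(df), np.nan)
    if {"c_peptide", "fasting_glucose"} <= set(df.columns):
        has = df["c_peptide"].notna() & df["fasting_glucose"].notna()
        sub = df.loc[has]
        b2[has.to_numpy()] = (np.sqrt(sub["c_peptide"].to_numpy())
                              * (1.0 - sub["dir"].to_numpy())
                              / (sub["fasting_glucose"].to_numpy()
                                 * sub["hba1c_pct"].to_numpy()) * 1000.0)
    df["beta2"] = b2
    df["pr_idaa1c"] = classify_pr(df["idaa1c"].to_numpy(), "idaa1c")
    df["pr_gtaa1c"] = np.where(np.isfinite(gta),
                               gta <= 4.5, np.nan)  # NaN = not scorable
    return df.sort_values(["patient_id", "visit_date"],
                          kind="mergesort").reset_index(drop=True)


def _episode_table(scorecards: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for pid, sub in scorecards.groupby("patient_id", sort=True):
        sub = sub.sort_values("visit_date", kind="mergesort")
        for criterion, col in (("idaa1c", "pr_idaa1c"), ("gtaa1c", "pr_gtaa1c")):
            flagged = sub[sub[col].notna()]
            if flagged.empty:
                continue
            eps = pr_episodes(flagged["visit_date"].to_numpy(),
                              flagged[col].astype(bool).to_numpy(), criterion)
            for k, ep in enumerate(eps):
                rows.append(
                    {
                        "patient_id": pid,
                        "criterion": criterion,
                        "episode_index": k,
                        "onset_date": ep.onset_date,
                        "end_date": ep.end_date,
                        "duration_months": round(ep.duration_months, 3),
                        "n_visits": ep.n_visits,
                    }
                )
    cols = ["patient_id", "criterion", "episode_index", "onset_date",
            "end_date", "duration_months", "n_visits"]
    return pd.DataFrame(rows, columns=cols)


def _ever_pr(scorecards: pd.DataFrame, criterion: str) -> pd.Series:
    col = f"pr_{criterion}"
    sub = scorecards[scorecards[col].notna()]
    return sub.groupby("patient_id")[col].apply(lambda s: bool(s.astype(bool).any()))


def run_pipeline(
    bundle: CohortBundle,
    reference: str = "idaa1c",
    test: str = "gtaa1c",
    min_readings: int = MIN_READINGS,
    bands: Sequence[float] = (3.5, 4.0, 4.5, 5.0),
    horizon_days: float = 300.0,
) -> PipelineReport:
    """Run the full evaluation: GV → scores → episodes → cohort statistics.

    The evaluation unit for sensitivity/specificity is the patient-level
    "ever entered PR" label (per-visit scores are still available in
    ``scorecards``). Visits with fewer than ``min_readings`` glucose values
    are excluded from GTAA1C scoring and counted in the report.
    """
    if reference == test:
        raise ValueError("reference and test criteria must differ")
    gv = _per_visit_gv(bundle.visits, bundle.readings, min_readings)
    scorecards = _score_table(bundle.visits, gv)
    episodes = _episode_table(scorecards)

    counts = {
        "n_patients": int(bundle.patients["patient_id"].nunique()),
        "n_visits": int(len(scorecards)),
        "n_visits_insufficient_gv": int((~scorecards["sufficient"]).sum()),
        "n_readings": int(len(bundle.readings)),
    }

    ever_ref = _ever_pr(scorecards, reference)
    ever_test = _ever_pr(scorecards, test)
    both = ever_ref.index.intersection(ever_test.index)
    performance = score_r2 = score_r2_p = None
    paired = scorecards.dropna(subset=[reference, test])
    if len(paired) >= 3 and paired[reference].nunique() > 1 and paired[test].nunique() > 1:
        score_r2, score_r2_p = cs.correlate(paired[reference], paired[test])
    if len(both) and ever_ref.loc[both].any() and not ever_ref.loc[both].all():
        performance = cs.diagnostic_performance(
            ever_ref.loc[both].to_numpy(), ever_test.loc[both].to_numpy(),
            r_squared=score_r2,
        )

    # contingency analyses on patient-level ever-PR under the reference
    patients = bundle.patients.set_index("patient_id")
    pr_flag = ever_ref.reindex(patients.index).fillna(False).astype(bool)
    cont_rows = []

    def _add_contingency(name: str, exposure: pd.Series):
        sub = exposure.dropna()
        tab_pr = pr_flag.loc[sub.index]
        levels = sorted(sub.unique())
        if len(levels) != 2:
            return
        a = int(((sub == levels[0]) & tab_pr).sum())
        b = int(((sub == levels[0]) & ~tab_pr).sum())
        c = int(((sub == levels[1]) & tab_pr).sum())
        d = int(((sub == levels[1]) & ~tab_pr).sum())
        try:
            res = cs.contingency_test(cs.ContingencyTable2x2(a, b, c, d))
        except ValueError:
            return
        cont_rows.append({"analysis": name, "levels": f"{levels[0]} vs {levels[1]}",
                          "a": a, "b": b, "c": c, "d": d,
                          "test": res.test, "p_value": res.p_value})

    if "age_group" in patients.columns:
        ag = patients["age_group"]
        _add_contingency("pr_by_age_under5_vs_5to10",
                         ag[ag.isin(["under5", "five_to_ten"])])
    if "sex" in patients.columns:
        _add_contingency("pr_by_sex", patients["sex"])
    if "dka" in patients.columns:
        _add_contingency("pr_by_dka", patients["dka"].astype(bool))
    if "severe_hypo" in scorecards.columns:
        sh_ever = (scorecards.groupby("patient_id")["severe_hypo"].any()
                   .reindex(pr_flag.index).fillna(False).astype(bool))
        a = int((pr_flag & sh_ever).sum())
        b = int((pr_flag & ~sh_ever).sum())
        c = int((~pr_flag & sh_ever).sum())
        d = int((~pr_flag & ~sh_ever).sum())
        try:
            res = cs.contingency_test(cs.ContingencyTable2x2(a, b, c, d))
            cont_rows.append({"analysis": "severe_hypo_by_pr",
                              "levels": "PR vs noPR", "a": a, "b": b, "c": c,
                              "d": d, "test": res.test, "p_value": res.p_value})
        except ValueError:
            pass
    contingency = pd.DataFrame(
        cont_rows, columns=["analysis", "levels", "a", "b", "c", "d", "test", "p_value"])

    determinants = None
    covs = [c for c in ("dka", "sex", "age_group") if c in patients.columns]
    if covs and pr_flag.nunique() == 2:
        det_df = patients[covs].copy()
        det_df["pr"] = pr_flag.astype(int)
        try:
            determinants = cs.pr_determinant_model(det_df, covariates=covs)
        except ValueError:
            determinants = None

    gv_selection = None
    scored = scorecards.dropna(subset=["gtaa1c"])
    try:
        gv_selection = cs.gv_predictor_selection(
            scored.rename(columns={"frac_normo": "frac_normo"}))
    except (ValueError, KeyError):
        gv_selection = None

    band_duration = None
    three_mo = scorecards[np.isclose(scorecards["months_since_dx"], 3.0, atol=0.75)]
    three_mo = three_mo.dropna(subset=["gtaa1c"]).groupby("patient_id")["gtaa1c"].first()
    if len(three_mo):
        ref_eps = episodes[(episodes["criterion"] == reference)
                           & (episodes["episode_index"] == 0)]
        dur = ref_eps.set_index("patient_id")["duration_months"]
        dur = dur.reindex(three_mo.index).fillna(0.0)  # no episode = zero duration
        band_duration = cs.band_duration_analysis(
            three_mo.to_numpy(), dur.to_numpy(), bands=bands,
            horizon_days=horizon_days)

    log = {
        "prscore_version": __version__,
        "reference": reference,
        "test": test,
        "min_readings": min_readings,
        "bands": list(bands),
        "horizon_days": horizon_days,
        "provenance": bundle.provenance,
    }
    return PipelineReport(
        scorecards=scorecards, episodes=episodes, performance=performance,
        score_r2=score_r2, score_r2_p=score_r2_p, contingency=contingency,
        determinants=determinants, gv_selection=gv_selection,
        band_duration=band_duration, counts=counts, log=log,
    )


def write_report(report: PipelineReport, outdir) -> dict:
    """Serialize a pipeline report: CSV tables plus a JSON run log."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name in ("scorecards", "episodes", "contingency", "band_duration"):
        df = getattr(report, name)
        if df is None:
            continue
        p = out / f"{name}.csv"
        df.to_csv(p, index=False, na_rep=NA_TOKEN, date_format="%Y-%m-%dT%H:%M:%S")
        paths[name] = str(p)
    if report.gv_selection is not None:
        p = out / "gv_selection.csv"
        report.gv_selection.to_csv(p, na_rep=NA_TOKEN)
        paths["gv_selection"] = str(p)
    if report.determinants is not None and len(report.determinants.table):
        p = out / "determinants.csv"
        report.determinants.table.to_csv(p, na_rep=NA_TOKEN)
        paths["determinants"] = str(p)
    summary = {
        "counts": report.counts,
        "log": report.log,
        "score_r2": report.score_r2,
        "score_r2_p": report.score_r2_p,
    }
    if report.performance is not None:
        summary["diagnostic_performance"] = asdict(report.performance)
    p = out / "report.json"
    p.write_text(json.dumps(summary, indent=2, default=str))
    paths["report"] = str(p)
    return paths
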