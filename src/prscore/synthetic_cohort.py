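"""Seeded generative model of a pediatric new-onset type 1 diabetes cohort.

The generator produces the three tables the scoring pipeline consumes
(patients, visits, glucose readings) plus a latent truth table, with the
statistical structure the analysis assumes:

* an age-stratified cohort (~16/37/47% in the <5, 5-10 and ≥10-year groups)
  with ~70% of patients entering partial remission (PR);
* remitters follow declining HbA1c (toward ≈6.9% during remission) and
  declining insulin-dose trajectories so that IDAA1C dips to ≤9 during the
  latent episode, while non-remitters plateau near 7.8% HbA1c with full
  substitution doses and keep IDAA1C > 9;
* per-visit capillary glucose readings are drawn so the window mean tracks
  HbA1c through the ADAG linear relation mean(mg/dL) = 28.7 × HbA1c − 46.7,
  with a within-window coefficient of variation that is lower during
  remission (residual β-cell function damps glycemic variability);
* PR duration is gamma-distributed with mean 8.9 and SD 8.6 months,
  truncated to 1.8-44.3 months, and — through ``duration_coupling`` —
  longer episodes come with tighter control, so the 3-month GTAA1C is
  inversely related to eventual duration;
* C-peptide is simulated at the patient-year level only (yearly assays),
  declining over two years with remitters above non-remitters.

Everything is driven by one ``numpy`` Generator seeded from the config, so
identical configs give byte-identical tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort_stats import age_group

__all__ = [
    "SimulationConfig",
    "SimulatedCohort",
    "simulate_cohort",
    "simulate_visit_readings",
    "DEFAULT_VISIT_SCHEDULE",
]

#: Clinic schedule in months since diagnosis: 15 days, 1 month, then q3mo.
DEFAULT_VISIT_SCHEDULE = (0.0, 0.5, 1.0, 3.0, 6.0, 9.0, 12.0, 15.0, 18.0,
                          21.0, 24.0, 27.0, 30.0, 33.0, 36.0)

_DAYS_PER_MONTH = 30.44


@dataclass
class SimulationConfig:
    """Parameters of the cohort generator.

    Defaults emulate a 239-patient tertiary-center series: age-group weights
    39/88/112, ~70% remitters, baseline HbA1c 10.8 ± 2.7%, visits at 15
    days, 1 month and then every 3 months up to 3 years, and at least five
    capillary readings per visit window.
    """

    n_patients: int = 239
    seed: int = 0
    remitter_fraction: float = 0.70
    age_group_weights: tuple = (39 / 239, 88 / 239, 112 / 239)
    male_fraction: float = 127 / 239
    dka_prob: float = 0.30
    #: Odds ratios tilting remission probability; the intercept is
    #: recalibrated so the marginal remitter fraction stays as configured.
    dka_remission_or: float = 0.5
    mid_age_remission_or: float = 2.0
    visit_schedule_months: tuple = DEFAULT_VISIT_SCHEDULE
    baseline_hba1c_mean_sd: tuple = (10.8, 2.7)
    #: HbA1c plateau during remission / outside remission (% , patient-level SD).
    pr_hba1c_target_mean_sd: tuple = (6.9, 0.30)
    nonpr_hba1c_target_mean_sd: tuple = (7.8, 0.4)
    hba1c_decay_months: float = 1.5
    #: Faster approach to the remission plateau once the episode starts —
    #: the honeymoon is defined by rapidly restored control.
    pr_hba1c_decay_months: float = 0.4
    hba1c_visit_noise_sd: float = 0.2
    #: Daily insulin requirement U/kg/day (mean, patient-level SD).
    pr_dir_mean_sd: tuple = (0.28, 0.06)
    nonpr_dir_mean_sd: tuple = (0.85, 0.12)
    dir_visit_noise_sd: float = 0.05
    #: Within-window SMBG coefficient of variation by remission state
    #: (literature-informed; the source series reports none).
    within_day_cv_pr: float = 0.25
    within_day_cv_nonpr: float = 0.33
    #: ADAG linear map from HbA1c (%) to mean glucose (mg/dL).
    adag_slope: float = 28.7
    adag_intercept: float = -46.7
    #: PR episode timing: onset snapped to an early visit, duration gamma
    #: with the stated mean/SD, truncated to the stated range (months).
    pr_onset_choices_months: tuple = (0.5, 1.0, 3.0)
    pr_onset_probs: tuple = (0.2, 0.5, 0.3)
    pr_duration_mean_sd: tuple = (8.9, 8.6)
    pr_duration_range: tuple = (1.8, 44.3)
    #: Strength of the inverse link between episode duration and the
    #: remission-phase HbA1c plateau / glycemic variability (0 = none).
    duration_coupling: float = 1.0
    readings_per_day: int = 5
    days_sampled_per_visit: int = 14
    glucose_dist: str = "lognormal"  # or "truncnorm"
    #: Cumulative 3-year severe-hypoglycemia risk by remission state.
    sh_risk_pr: float = 0.235
    sh_risk_nonpr: float = 0.348
    #: Yearly C-peptide medians (pmol/mL) at years 0/1/2 by remission state.
    cpeptide_medians_pr: tuple = (0.21, 0.22, 0.11)
    cpeptide_medians_nonpr: tuple = (0.15, 0.05, 0.02)
    cpeptide_log_sigma: float = 0.5

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        w = np.asarray(self.age_group_weights, dtype=float)
        if w.size != 3 or abs(w.sum() - 1.0) > 1e-9 or np.any(w < 0):
            raise ValueError("age_group_weights must be 3 non-negative weights summing to 1")
        for name in ("remitter_fraction", "male_fraction", "dka_prob",
                     "sh_risk_pr", "sh_risk_nonpr"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a fraction in [0, 1], got {v}")
        if self.readings_per_day < 1 or self.days_sampled_per_visit < 1:
            raise ValueError("readings_per_day and days_sampled_per_visit must be >= 1")
        if self.glucose_dist not in ("lognormal", "truncnorm"):
            raise ValueError("glucose_dist must be 'lognormal' or 'truncnorm'")
        p = np.asarray(self.pr_onset_probs, dtype=float)
        if abs(p.sum() - 1.0) > 1e-9 or np.any(p < 0):
            raise ValueError("pr_onset_probs must sum to 1")
        lo, hi = self.pr_duration_range
        if not 0 < lo < hi:
            raise ValueError("pr_duration_range must be 0 < lo < hi")

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        """Build a config from a flat mapping (e.g. a parsed YAML file)."""
        kwargs = {}
        for key, value in d.items():
            if key not in cls.__dataclass_fields__:
                raise ValueError(f"unknown simulation parameter {key!r}")
            kwargs[key] = tuple(value) if isinstance(value, list) else value
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SimulatedCohort:
    """Generated tables plus the latent per-patient truth."""

    patients: pd.DataFrame
    visits: pd.DataFrame
    readings: pd.DataFrame
    truth: pd.DataFrame
    config: SimulationConfig


def _lognormal_params(mean: np.ndarray, sd: np.ndarray):
    cv2 = (sd / mean) ** 2
    sigma2 = np.log1p(cv2)
    mu = np.log(mean) - sigma2 / 2.0
    return mu, np.sqrt(sigma2)


def simulate_visit_readings(
    target_mean: float,
    sd: float,
    n: int,
    rng: np.random.Generator,
    dist: str = "lognormal",
) -> np.ndarray:
    """Draw ``n`` positive glucose values with the given mean and SD (mg/dL).

    ``dist='lognormal'`` (default) matches the right skew of SMBG data;
    ``'truncnorm'`` truncates a normal at 10 mg/dL (renormalized by
    resampling, so the realized moments drift slightly upward at extreme
    CVs). ``sd=0`` returns a constant series.
    """
    if target_mean <= 0:
        raise ValueError("target_mean must be > 0")
    if n < 1:
        raise ValueError("n must be >= 1")
    if sd < 0:
        raise ValueError("sd must be >= 0")
    if sd == 0:
        return np.full(n, float(target_mean))
    if dist == "lognormal":
        mu, sigma = _lognormal_params(np.asarray(target_mean, float),
                                      np.asarray(sd, float))
        return rng.lognormal(mean=float(mu), sigma=float(sigma), size=n)
    if dist == "truncnorm":
        out = rng.normal(target_mean, sd, size=n)
        bad = out < 10.0
        while bad.any():
            out[bad] = rng.normal(target_mean, sd, size=int(bad.sum()))
            bad = out < 10.0
        return out
    raise ValueError("dist must be 'lognormal' or 'truncnorm'")


def _truncated_gamma(rng, mean, sd, lo, hi, size):
    """Gamma(mean, sd) samples restricted to [lo, hi] by rejection."""
    shape = (mean / sd) ** 2
    scale = sd ** 2 / mean
    out = np.empty(size)
    need = np.ones(size, dtype=bool)
    while need.any():
        draw = rng.gamma(shape, scale, size=int(need.sum()))
        ok = (draw >= lo) & (draw <= hi)
        idx = np.flatnonzero(need)[ok]
        out[idx] = draw[ok]
        need[idx] = False
    return out


def _calibrate_intercept(eta: np.ndarray, target: float) -> float:
    """Intercept b0 such that mean(expit(b0 + eta)) == target (bisection)."""
    lo, hi = -20.0, 20.0
    for _ in range(80):
        mid = (lo + hi) / 2.0
        if np.mean(1.0 / (1.0 + np.exp(-(mid + eta)))) < target:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


def simulate_cohort(config: SimulationConfig | None = None) -> SimulatedCohort:
    """Generate a full synthetic cohort. Deterministic given the config seed."""
    cfg = config or SimulationConfig()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_patients
    t = np.asarray(cfg.visit_schedule_months, dtype=float)
    m = t.size

    # ---- patients -------------------------------------------------------
    ids = np.array([f"P{i + 1:05d}" for i in range(n)])
    grp_idx = rng.choice(3, size=n, p=np.asarray(cfg.age_group_weights, float))
    age_lo = np.array([1.0, 5.0, 10.0])[grp_idx]
    age_hi = np.array([5.0, 10.0, 16.5])[grp_idx]
    age = rng.uniform(age_lo, age_hi)
    sex = np.where(rng.random(n) < cfg.male_fraction, "M", "F")
    dka = rng.random(n) < cfg.dka_prob
    # acid-base values consistent with the DKA flag (pH<7.3 and/or HCO3<16)
    ph = np.where(dka,
                  np.clip(7.29 - np.abs(rng.normal(0.0, 0.12, n)), 6.85, 7.29),
                  rng.uniform(7.31, 7.44, n))
    bicarb = np.where(dka, rng.uniform(4.0, 15.9, n), rng.uniform(16.5, 28.0, n))

    # latent remitter status: logistic in DKA and mid-age, intercept
    # recalibrated so the marginal fraction matches the config
    eta = (math.log(cfg.dka_remission_or) * dka.astype(float)
           + math.log(cfg.mid_age_remission_or) * (grp_idx == 1).astype(float))
    b0 = _calibrate_intercept(eta, cfg.remitter_fraction)
    p_remit = 1.0 / (1.0 + np.exp(-(b0 + eta)))
    remitter = rng.random(n) < p_remit

    h_mean, h_sd = cfg.baseline_hba1c_mean_sd
    group_offset = np.array([-1.1, -0.4, 0.6])[grp_idx]  # HbA1c rises with age at onset
    baseline_h = np.clip(rng.normal(h_mean + group_offset, h_sd * 0.96), 6.0, 19.5)

    dx_date = (np.datetime64("2005-01-01")
               + rng.integers(0, 8 * 365, size=n).astype("timedelta64[D]"))

    # ---- latent PR episode ---------------------------------------------
    onset = rng.choice(np.asarray(cfg.pr_onset_choices_months, float), size=n,
                       p=np.asarray(cfg.pr_onset_probs, float))
    dur_mean, dur_sd = cfg.pr_duration_mean_sd
    duration = _truncated_gamma(rng, dur_mean, dur_sd, *cfg.pr_duration_range, size=n)
    onset = np.where(remitter, onset, np.nan)
    duration = np.where(remitter, duration, np.nan)
    # coupling: longer episodes come with tighter control during remission
    z_dur = np.clip((np.nan_to_num(duration, nan=dur_mean) - dur_mean) / dur_sd,
                    -1.5, 2.5)
    c = cfg.duration_coupling
    pr_mu, pr_sig = cfg.pr_hba1c_target_mean_sd
    pr_target = np.clip(rng.normal(pr_mu - 0.35 * c * z_dur, pr_sig), 5.2, 8.3)
    np_mu, np_sig = cfg.nonpr_hba1c_target_mean_sd
    nonpr_target = np.clip(rng.normal(np_mu, np_sig, n), 6.5, 11.0)
    d_mu, d_sig = cfg.pr_dir_mean_sd
    pr_dir = np.clip(rng.normal(d_mu - 0.03 * c * z_dur, d_sig), 0.05, 0.6)
    nd_mu, nd_sig = cfg.nonpr_dir_mean_sd
    nonpr_dir = np.clip(rng.normal(nd_mu, nd_sig, n), 0.3, 1.6)
    cv_pr = np.clip(cfg.within_day_cv_pr - 0.04 * c * z_dur, 0.10, 0.45)

    # ---- per-visit states (n, m) ---------------------------------------
    T = np.broadcast_to(t, (n, m))
    in_pr = (remitter[:, None]
             & (T >= onset[:, None])
             & (T < (onset + duration)[:, None]))
    plateau = np.where(in_pr, pr_target[:, None], nonpr_target[:, None])
    tau = np.where(in_pr, cfg.pr_hba1c_decay_months, cfg.hba1c_decay_months)
    decay = np.exp(-T / tau)
    hba1c = (plateau + (baseline_h[:, None] - plateau) * decay
             + rng.normal(0.0, cfg.hba1c_visit_noise_sd, (n, m)))
    hba1c = np.clip(hba1c, 4.2, 19.5)
    dir_base = np.where(in_pr, pr_dir[:, None],
                        nonpr_dir[:, None] + 0.10 * T / 36.0)
    dir_ukg = np.clip(dir_base + rng.normal(0.0, cfg.dir_visit_noise_sd, (n, m)),
                      0.02, 2.5)
    mean_bg = np.clip(cfg.adag_slope * hba1c + cfg.adag_intercept, 50.0, None)
    win_cv = np.where(in_pr, cv_pr[:, None], cfg.within_day_cv_nonpr)

    visit_offset_days = np.round(t * _DAYS_PER_MONTH).astype("timedelta64[D]")
    visit_date = dx_date[:, None] + visit_offset_days[None, :]

    # severe hypoglycemia: per-visit hazard from the 3-year cumulative risk
    risk = np.where(remitter, cfg.sh_risk_pr, cfg.sh_risk_nonpr)
    p_visit = 1.0 - (1.0 - risk) ** (1.0 / max(m - 1, 1))
    severe_hypo = rng.random((n, m)) < p_visit[:, None]
    severe_hypo[:, 0] = False

    # yearly C-peptide and fasting glucose at months 0 / 12 / 24
    cpep = np.full((n, m), np.nan)
    fast_gluc = np.full((n, m), np.nan)
    for year, month in enumerate((0.0, 12.0, 24.0)):
        j = int(np.argmin(np.abs(t - month)))
        med = np.where(remitter,
                       cfg.cpeptide_medians_pr[year],
                       cfg.cpeptide_medians_nonpr[year])
        # residual beta-cell function tracks the remission state: remitters
        # still in episode at the assay, and those with longer episodes,
        # secrete more
        mult = np.ones(n)
        if month > 0:
            mult = np.where(remitter & in_pr[:, j], 1.25,
                            np.where(remitter, 0.75, 1.0))
        mult = np.where(remitter, mult * np.exp(0.3 * z_dur), mult)
        cpep[:, j] = np.maximum(
            rng.lognormal(np.log(np.maximum(med * mult, 1e-3)),
                          cfg.cpeptide_log_sigma, n), 0.001)
        fast_gluc[:, j] = np.clip(
            mean_bg[:, j] / 18.016 * rng.lognormal(0.0, 0.12, n), 3.0, 30.0)

    visits = pd.DataFrame(
        {
            "patient_id": np.repeat(ids, m),
            "visit_date": visit_date.reshape(-1).astype("datetime64[s]"),
            "months_since_dx": np.tile(t, n),
            "hba1c_pct": np.round(hba1c.reshape(-1), 2),
            "dir": np.round(dir_ukg.reshape(-1), 3),
            "c_peptide": np.round(cpep.reshape(-1), 3),
            "fasting_glucose": np.round(fast_gluc.reshape(-1), 2),
            "severe_hypo": severe_hypo.reshape(-1),
        }
    )

    # ---- glucose readings ----------------------------------------------
    n_per_visit = cfg.readings_per_day * cfg.days_sampled_per_visit
    flat_mean = mean_bg.reshape(-1)
    flat_sd = (win_cv * mean_bg).reshape(-1)
    reps = np.full(flat_mean.size, n_per_visit)
    means_r = np.repeat(flat_mean, reps)
    sds_r = np.repeat(flat_sd, reps)
    if cfg.glucose_dist == "lognormal":
        mu, sigma = _lognormal_params(means_r, sds_r)
        values = rng.lognormal(mu, sigma)
    else:
        values = rng.normal(means_r, sds_r)
        bad = values < 10.0
        while bad.any():
            values[bad] = rng.normal(means_r[bad], sds_r[bad])
            bad = values < 10.0
    values = np.clip(values, 20.0, 900.0)

    gap_days = np.diff(visit_date.astype("datetime64[D]").astype(int),
                       axis=1, prepend=visit_date[:, :1].astype("datetime64[D]").astype(int) - 1)
    gaps_r = np.maximum(np.repeat(gap_days.reshape(-1), reps), 1)
    day_off = rng.integers(0, gaps_r)  # [0, gap-1]
    sec_off = rng.integers(0, 86400, size=values.size)
    stamps = (np.repeat(visit_date.reshape(-1).astype("datetime64[s]"), reps)
              - day_off.astype("timedelta64[D]").astype("timedelta64[s]")
              - sec_off.astype("timedelta64[s]"))

    readings = pd.DataFrame(
        {
            "patient_id": np.repeat(ids, m * n_per_visit),
            "timestamp": stamps,
            "value": np.round(values, 1),
            "unit": "mg/dL",
        }
    ).sort_values(["patient_id", "timestamp"], kind="mergesort").reset_index(drop=True)

    patients = pd.DataFrame(
        {
            "patient_id": ids,
            "dx_date": dx_date.astype("datetime64[s]"),
            "age_at_dx": np.round(age, 2),
            "age_group": [age_group(a) for a in age],
            "sex": sex,
            "dka": dka,
            "ph": np.round(ph, 2),
            "bicarbonate": np.round(bicarb, 1),
            "baseline_hba1c": np.round(baseline_h, 2),
        }
    )

    truth = pd.DataFrame(
        {
            "patient_id": ids,
            "remitter": remitter,
            "pr_onset_months": np.round(onset, 2),
            "pr_duration_months": np.round(duration, 2),
        }
    )

    return SimulatedCohort(patients=patients, visits=visits,
                           readings=readings, truth=truth, config=cfg)
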