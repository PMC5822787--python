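"""Cohort-level statistics: diagnostics, contingency, regression, bands."""

import math

import numpy as np
import pandas as pd
import pytest

from prscore.cohort_stats import (
    ContingencyTable2x2,
    age_group,
    band_duration_analysis,
    classify_dka,
    compare_groups,
    contingency_test,
    correlate,
    diagnostic_performance,
    gv_predictor_selection,
    pr_determinant_model,
)


# ---------------------------------------------------------------- diagnostics

def test_diagnostic_performance_perfect_agreement():
    ref = [True, True, False, False]
    perf = diagnostic_performance(ref, ref)
    assert perf.sensitivity == 1.0 and perf.specificity == 1.0


def test_diagnostic_performance_all_negative_test():
    perf = diagnostic_performance([True, True, False], [False, False, False])
    assert perf.sensitivity == 0.0 and perf.specificity == 1.0


def test_diagnostic_performance_counts():
    perf = diagnostic_performance([1, 1, 1, 0, 0], [1, 1, 0, 0, 1])
    assert perf.sensitivity == pytest.approx(2 / 3)
    assert perf.specificity == pytest.approx(0.5)
    assert (perf.n_true_pos, perf.n_false_neg, perf.n_true_neg,
            perf.n_false_pos) == (2, 1, 1, 1)


def test_diagnostic_performance_rejects_degenerate_reference():
    with pytest.raises(ValueError, match="no negative"):
        diagnostic_performance([True, True], [True, False])
    with pytest.raises(ValueError, match="no positive"):
        diagnostic_performance([False, False], [True, False])


# ---------------------------------------------------------------- contingency

def test_contingency_chi_square_without_continuity_correction():
    """The published age-group PR table requires the correction-free
    chi-square to reproduce its p-value (with Yates' correction p ~ 0.06)."""
    res = contingency_test(ContingencyTable2x2(23, 16, 68, 20))
    assert res.test == "chi-square"
    assert res.p_value == pytest.approx(0.035, abs=5e-4)


def test_contingency_homogeneous_table():
    res = contingency_test(ContingencyTable2x2(10, 10, 10, 10))
    assert res.p_value == pytest.approx(1.0)


def test_contingency_small_counts_route_to_fisher():
    res = contingency_test(ContingencyTable2x2(2, 8, 7, 3))
    assert res.test == "fisher-exact"
    # oracle: exhaustive hypergeometric enumeration (two-sided, by point
    # probability ordering)
    assert res.p_value == pytest.approx(_fisher_enumeration(2, 8, 7, 3), abs=1e-12)


def _fisher_enumeration(a, b, c, d):
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def pmf(x):
        return (math.comb(r1, x) * math.comb(r2, c1 - x)) / math.comb(n, c1)

    p_obs = pmf(a)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    return sum(pmf(x) for x in range(lo, hi + 1) if pmf(x) <= p_obs * (1 + 1e-9))


def test_contingency_rejects_invalid_tables():
    with pytest.raises(ValueError, match="margin"):
        contingency_test(ContingencyTable2x2(0, 0, 5, 5))
    with pytest.raises(ValueError):
        ContingencyTable2x2(-1, 2, 3, 4)
    with pytest.raises(ValueError):
        ContingencyTable2x2(0, 0, 0, 0)


# ---------------------------------------------------------------- correlation

def test_correlate_exact_linearity_and_symmetry(rng):
    x = rng.normal(size=30)
    r2, p = correlate(x, 2 * x + 1)
    assert r2 == pytest.approx(1.0)
    r2a, _ = correlate(x, -0.5 * x + 3)
    assert r2a == pytest.approx(1.0)
    y = rng.normal(size=30)
    assert correlate(x, y)[0] == pytest.approx(correlate(y, x)[0])


def test_correlate_orthogonal_residuals(rng):
    x = rng.normal(size=50)
    y = rng.normal(size=50)
    resid = y - np.polyval(np.polyfit(x, y, 1), x)  # orthogonal to x
    r2, p = correlate(x, resid)
    assert r2 == pytest.approx(0.0, abs=1e-12)


def test_correlate_hand_computed():
    r2, _ = correlate([1, 2, 3, 4], [1, 3, 2, 4])  # Pearson r = 0.8
    assert r2 == pytest.approx(0.64)


def test_correlate_rejects_constant_vector():
    with pytest.raises(ValueError, match="constant"):
        correlate([1, 1, 1, 1], [1, 2, 3, 4])


# ------------------------------------------------------------- group compare

def test_compare_groups_identical_groups_t_route(rng):
    g = rng.normal(10, 2, size=40)
    vals = np.concatenate([g, g])
    labels = ["a"] * 40 + ["b"] * 40
    res = compare_groups(vals, labels)
    assert res.test == "t-test"
    assert res.p_value == pytest.approx(1.0)


def test_compare_groups_detects_large_shift(rng):
    vals = np.concatenate([rng.normal(0, 1, 50), rng.normal(3, 1, 50)])
    labels = ["a"] * 50 + ["b"] * 50
    res = compare_groups(vals, labels)
    assert res.p_value < 1e-3


def test_compare_groups_heavy_tails_route_to_mann_whitney(rng):
    vals = np.concatenate([rng.lognormal(0, 1.5, 60), rng.lognormal(0.2, 1.5, 60)])
    labels = ["a"] * 60 + ["b"] * 60
    res = compare_groups(vals, labels)
    assert res.test == "mann-whitney"


def test_compare_groups_rejects_bad_grouping():
    with pytest.raises(ValueError):
        compare_groups([1, 2, 3], ["a", "a", "a"])
    with pytest.raises(ValueError):
        compare_groups([1, 2, 3, 4], ["a", "a", "a", "b"])


# --------------------------------------------------------------- determinants

def _logistic_patients(rng, n, or_true, p_exposure=0.5, base_logit=0.0):
    x = rng.random(n) < p_exposure
    logit = base_logit + math.log(or_true) * x
    y = rng.random(n) < 1 / (1 + np.exp(-logit))
    return pd.DataFrame({"exposure": x.astype(int), "pr": y.astype(int)})


def test_determinant_model_null_covariate_ci_covers_one(rng):
    df = _logistic_patients(rng, 500, or_true=1.0, base_logit=0.8)
    model = pr_determinant_model(df, covariates=["exposure"])
    assert model.converged
    row = model.table.loc["exposure"]
    assert row["ci_low"] <= 1.0 <= row["ci_high"]


def test_determinant_model_recovers_planted_odds_ratio(rng):
    df = _logistic_patients(rng, 2000, or_true=3.0)
    model = pr_determinant_model(df, covariates=["exposure"])
    est = model.table.loc["exposure", "odds_ratio"]
    assert 3.0 * 0.7 <= est <= 3.0 * 1.3


def test_determinant_model_univariate_screen_selects_signal(rng):
    n = 1500
    signal = rng.random(n) < 0.5
    noise = rng.random(n) < 0.5
    logit = math.log(3.0) * signal
    y = rng.random(n) < 1 / (1 + np.exp(-logit))
    df = pd.DataFrame({"signal": signal.astype(int), "noise": noise.astype(int),
                       "pr": y.astype(int)})
    model = pr_determinant_model(df, covariates=["signal", "noise"])
    assert "signal" in model.selected
    assert model.univariate.loc["signal", "p_value"] < 0.05


def test_determinant_model_rejects_constant_covariate():
    df = pd.DataFrame({"flat": [0, 0, 0, 0], "pr": [0, 1, 0, 1]})
    with pytest.raises(ValueError, match="variation"):
        pr_determinant_model(df, covariates=["flat"])


def test_determinant_model_reports_separation_instead_of_raising():
    # outcome fully determined by the covariate: complete separation
    df = pd.DataFrame({"x": [0] * 20 + [1] * 20, "pr": [0] * 20 + [1] * 20})
    model = pr_determinant_model(df, covariates=["x"])
    assert (not model.converged) or model.table.loc["x", "ci_high"] > 1e4


# ------------------------------------------------------------- GV regression

def _gv_frame(rng, n=400):
    h = rng.normal(8, 1.5, n)
    frac = np.clip(rng.normal(0.6, 0.15, n), 0, 1)
    mean_bg = 28.7 * h - 46.7 + rng.normal(0, 15, n)
    sd_bg = np.abs(rng.normal(55, 12, n))
    return pd.DataFrame({"hba1c_pct": h, "frac_normo": frac, "mean_bg": mean_bg,
                         "sd_bg": sd_bg, "cv": sd_bg / mean_bg})


def test_gv_selection_recovers_pure_hba1c_dependence(rng):
    df = _gv_frame(rng)
    df["idaa1c"] = df["hba1c_pct"] + rng.normal(0, 0.05, len(df))
    out = gv_predictor_selection(df)
    assert out.loc["hba1c_pct", "coef"] == pytest.approx(1.0, abs=0.05)
    assert out.loc["hba1c_pct", "p_value"] < 1e-10
    for other in ("frac_normo", "sd_bg", "cv"):
        assert abs(out.loc[other, "coef_std"]) < 0.05


def test_gv_selection_flags_rank_deficiency(rng):
    df = _gv_frame(rng)
    df["mean_bg"] = 2.0 * df["hba1c_pct"]  # exact collinearity
    df["idaa1c"] = df["hba1c_pct"]
    out = gv_predictor_selection(df)
    assert out.attrs["rank_deficient"]


def test_gv_selection_rejects_underdetermined_fit(rng):
    df = _gv_frame(rng, n=5)
    df["idaa1c"] = df["hba1c_pct"]
    with pytest.raises(ValueError, match="underdetermined"):
        gv_predictor_selection(df.head(4))


# ------------------------------------------------------------------ banding

def test_band_duration_all_exceed_horizon():
    out = band_duration_analysis([3.0, 3.8, 4.2, 4.8, 6.0],
                                 [20, 20, 20, 20, 20])
    assert np.allclose(out["proportion"], 1.0)


def test_band_duration_direct_assignment():
    # durations in days: 400, 400, 100, 100 -> expressed in months
    months = np.array([400, 400, 100, 100]) / 30.44
    out = band_duration_analysis([3.0, 3.7, 4.2, 4.8], months)
    assert out["proportion"].tolist()[:4] == [1.0, 1.0, 0.0, 0.0]
    assert math.isnan(out["proportion"].iloc[4])  # empty (5, inf] band
    assert out["n"].iloc[4] == 0


def test_band_duration_rejects_unordered_bands():
    with pytest.raises(ValueError):
        band_duration_analysis([3.0], [10.0], bands=(4.0, 3.5))


# ------------------------------------------------------------------- clinical

@pytest.mark.parametrize(
    "ph,bicarb,expected",
    [
        (7.25, 20.0, True),   # acidemia arm
        (7.35, 15.0, True),   # bicarbonate arm
        (7.30, 16.0, False),  # both boundaries strict
        (7.40, 24.0, False),
    ],
)
def test_classify_dka(ph, bicarb, expected):
    assert classify_dka(ph, bicarb) is expected


def test_classify_dka_rejects_implausible_physiology():
    with pytest.raises(ValueError):
        classify_dka(6.2, 20.0)
    with pytest.raises(ValueError):
        classify_dka(7.4, -1.0)


@pytest.mark.parametrize(
    "age,expected",
    [(4.9, "under5"), (5.0, "five_to_ten"), (9.99, "five_to_ten"),
     (10.0, "ten_plus"), (16.0, "ten_plus")],
)
def test_age_group_boundaries(age, expected):
    assert age_group(age) == expected


def test_age_group_rejects_out_of_range():
    with pytest.raises(ValueError):
        age_group(25.0)
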