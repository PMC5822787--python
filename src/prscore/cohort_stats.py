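"""Cohort-level evaluation of partial-remission definitions.

Diagnostic performance of one PR definition against a reference, 2×2
contingency testing (Pearson chi-square or Fisher's exact), score
correlation, two-group comparison with normality-based routing,
logistic-regression determinant modelling, the GV-parameter linear
regression behind the GTAA1C variable selection, and the 3-month-score-band
vs PR-duration analysis.

Test routing follows common clinical-statistics practice: chi-square is used
WITHOUT Yates continuity correction when all expected cell counts are at
least 5 (the correction-free variant is validated against a published 2×2
in the test suite), otherwise two-sided Fisher's exact; continuous two-group
comparisons use Student's t when Shapiro-Wilk accepts normality in both
groups at α = 0.05, otherwise Mann-Whitney.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

__all__ = [
    "ContingencyTable2x2",
    "DiagnosticPerformance",
    "StatTestResult",
    "DeterminantModel",
    "diagnostic_performance",
    "contingency_test",
    "correlate",
    "compare_groups",
    "pr_determinant_model",
    "gv_predictor_selection",
    "band_duration_analysis",
    "classify_dka",
    "age_group",
    "AGE_GROUP_LABELS",
]

AGE_GROUP_LABELS = ("under5", "five_to_ten", "ten_plus")

#: Expected-count rule of thumb below which Fisher's exact test is used.
_EXPECTED_MIN = 5.0


@dataclass(frozen=True)
class ContingencyTable2x2:
    """2×2 cell counts; rows are exposure/group, columns outcome."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        cells = (self.a, self.b, self.c, self.d)
        if any(x < 0 for x in cells):
            raise ValueError("contingency cells must be non-negative")
        if sum(cells) == 0:
            raise ValueError("contingency table must have a positive total")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)


@dataclass(frozen=True)
class DiagnosticPerformance:
    """Sensitivity/specificity of a test definition against a reference."""

    sensitivity: float
    specificity: float
    n_true_pos: int
    n_false_pos: int
    n_true_neg: int
    n_false_neg: int
    r_squared: Optional[float] = None


@dataclass(frozen=True)
class StatTestResult:
    """A p-value together with which test produced it."""

    p_value: float
    test: str
    statistic: Optional[float] = None


@dataclass
class DeterminantModel:
    """Univariate-screen-then-multivariate logistic regression summary.

    ``table`` has one row per covariate in the multivariate model with
    columns coef, odds_ratio, ci_low, ci_high, p_value (Wald 95% CI);
    ``univariate`` holds the per-covariate screening p-values.
    """

    table: pd.DataFrame
    univariate: pd.DataFrame
    converged: bool = True
    message: str = ""
    n: int = 0
    selected: list = field(default_factory=list)


def diagnostic_performance(
    reference_labels: Sequence[bool],
    test_labels: Sequence[bool],
    r_squared: Optional[float] = None,
) -> DiagnosticPerformance:
    """Confusion-matrix sensitivity and specificity of test vs reference.

    Both label vectors must be aligned and the reference must contain at
    least one positive and one negative, otherwise sensitivity or
    specificity would be undefined.
    """
    ref = np.asarray(reference_labels, dtype=bool)
    tst = np.asarray(test_labels, dtype=bool)
    if ref.shape != tst.shape or ref.ndim != 1:
        raise ValueError("reference and test labels must be aligned 1-d vectors")
    if not ref.any():
        raise ValueError("degenerate reference: no positive cases")
    if ref.all():
        raise ValueError("degenerate reference: no negative cases")
    tp = int(np.sum(ref & tst))
    fn = int(np.sum(ref & ~tst))
    tn = int(np.sum(~ref & ~tst))
    fp = int(np.sum(~ref & tst))
    return DiagnosticPerformance(
        sensitivity=tp / (tp + fn),
        specificity=tn / (tn + fp),
        n_true_pos=tp,
        n_false_pos=fp,
        n_true_neg=tn,
        n_false_neg=fn,
        r_squared=r_squared,
    )


def contingency_test(table: ContingencyTable2x2) -> StatTestResult:
    """Pearson chi-square (no continuity correction) or Fisher's exact.

    Chi-square is used when every expected cell count is at least 5;
    otherwise the two-sided Fisher's exact test. Tables with a zero row or
    column margin are rejected (no association is estimable).
    """
    arr = table.as_array()
    if np.any(arr.sum(axis=0) == 0) or np.any(arr.sum(axis=1) == 0):
        raise ValueError("contingency table has a zero margin")
    expected = stats.contingency.expected_freq(arr)
    if np.all(expected >= _EXPECTED_MIN):
        chi2, p, _, _ = stats.chi2_contingency(arr, correction=False)
        return StatTestResult(p_value=float(p), test="chi-square", statistic=float(chi2))
    odds, p = stats.fisher_exact(arr, alternative="two-sided")
    return StatTestResult(p_value=float(p), test="fisher-exact", statistic=float(odds))


def correlate(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Squared Pearson correlation r² and its two-sided p-value."""
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape or xa.ndim != 1 or xa.size < 3:
        raise ValueError("correlate needs two aligned vectors of length >= 3")
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        raise ValueError("correlation is undefined for a constant vector")
    r, p = stats.pearsonr(xa, ya)
    return float(r) ** 2, float(p)


def compare_groups(
    values: Sequence[float],
    groups: Sequence,
    alpha: float = 0.05,
) -> StatTestResult:
    """Two-group comparison routed by Shapiro-Wilk normality screening.

    Both groups normal at ``alpha`` → unpaired two-sided t-test; otherwise
    Mann-Whitney rank-sum. Each group needs at least 3 values (the Shapiro
    minimum).
    """
    vals = np.asarray(values, dtype=float)
    grp = np.asarray(groups)
    if vals.shape != grp.shape:
        raise ValueError("values and groups must be aligned")
    levels = pd.unique(grp)
    if len(levels) != 2:
        raise ValueError(f"exactly two group levels required, got {len(levels)}")
    g1 = vals[grp == levels[0]]
    g2 = vals[grp == levels[1]]
    if min(g1.size, g2.size) < 3:
        raise ValueError("each group needs at least 3 values")

    def _normal(g: np.ndarray) -> bool:
        if np.ptp(g) == 0:  # Shapiro is undefined on constant data
            return True
        return stats.shapiro(g).pvalue >= alpha

    if _normal(g1) and _normal(g2):
        res = stats.ttest_ind(g1, g2)
        return StatTestResult(float(res.pvalue), "t-test", float(res.statistic))
    res = stats.mannwhitneyu(g1, g2, alternative="two-sided")
    return StatTestResult(float(res.pvalue), "mann-whitney", float(res.statistic))


def _logit_fit(y: np.ndarray, X: pd.DataFrame):
    model = sm.Logit(y, sm.add_constant(X, has_constant="add"))
    return model.fit(disp=0, maxiter=200)


def pr_determinant_model(
    patients: pd.DataFrame,
    covariates: Sequence[str],
    outcome: str = "pr",
    alpha_enter: float = 0.05,
) -> DeterminantModel:
    """Determinants of PR: univariate screen, then multivariate logistic fit.

    Each covariate is screened in a univariate logistic regression
    (likelihood-ratio p-value; a categorical covariate is screened as its
    whole indicator block, with the first level in sorted order as the
    reference). Covariates with univariate p < ``alpha_enter`` enter the
    multivariate model together; if none pass, all are entered so that a
    model is always reported. Effects are odds ratios with Wald 95% CIs.

    Complete separation or non-convergence is reported via
    ``converged=False`` rather than raised.
    """
    y = patients[outcome].astype(float).to_numpy()
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    if y.min() == y.max():
        raise ValueError("outcome has no variation")

    blocks: dict[str, pd.DataFrame] = {}
    for cov in covariates:
        col = patients[cov]
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            dummies = pd.get_dummies(col, prefix=cov, drop_first=True).astype(float)
            block = dummies
        else:
            block = col.astype(float).to_frame(cov)
        if any(block[c].nunique() < 2 for c in block.columns):
            raise ValueError(f"covariate {cov!r} has no variation")
        blocks[cov] = block

    uni_rows = []
    for cov, block in blocks.items():
        try:
            fit = _logit_fit(y, block)
            p = float(fit.llr_pvalue)
            ok = bool(fit.mle_retvals.get("converged", True))
        except Exception as exc:  # separation / singular fit
            p, ok = np.nan, False
        uni_rows.append({"covariate": cov, "p_value": p, "converged": ok})
    univariate = pd.DataFrame(uni_rows).set_index("covariate")

    selected = [
        cov for cov in covariates
        if np.isfinite(univariate.loc[cov, "p_value"])
        and univariate.loc[cov, "p_value"] < alpha_enter
    ]
    entered = selected if selected else list(covariates)
    X = pd.concat([blocks[cov] for cov in entered], axis=1)

    try:
        fit = _logit_fit(y, X)
        converged = bool(fit.mle_retvals.get("converged", True))
        message = "" if converged else "maximum-likelihood fit did not converge"
    except Exception as exc:
        return DeterminantModel(
            table=pd.DataFrame(), univariate=univariate, converged=False,
            message=f"logistic fit failed: {exc}", n=len(y), selected=selected,
        )

    params = fit.params.drop("const")
    conf = fit.conf_int().drop(index="const")
    table = pd.DataFrame(
        {
            "coef": params,
            "odds_ratio": np.exp(params),
            "ci_low": np.exp(conf[0]),
            "ci_high": np.exp(conf[1]),
            "p_value": fit.pvalues.drop("const"),
        }
    )
    return DeterminantModel(
        table=table, univariate=univariate, converged=converged,
        message=message, n=len(y), selected=selected,
    )


def gv_predictor_selection(
    visits: pd.DataFrame,
    response: str = "idaa1c",
    predictors: Sequence[str] = ("hba1c_pct", "frac_normo", "mean_bg", "sd_bg", "cv"),
) -> pd.DataFrame:
    """Multiple linear regression of a PR score on routine GV parameters.

    The predictors are regressed on the response by OLS; the returned frame
    has one row per predictor with the natural-scale coefficient, the
    standardized (per-SD) coefficient and the p-value, mirroring the
    variable-selection step that reduced the GV panel to HbA1c and
    %-normoglycemia. Rank deficiency (CV = SD/mean can induce exact
    collinearity) is flagged in a ``rank_deficient`` attribute rather than
    silently dropping a column.
    """
    cols = [response, *predictors]
    df = visits[cols].dropna()
    n, p = len(df), len(predictors)
    if n <= p + 1:
        raise ValueError(f"underdetermined fit: n={n} rows for p={p} predictors")
    X = df[list(predictors)].astype(float)
    sd = X.std(ddof=0)
    if (sd == 0).any():
        raise ValueError(f"constant predictor(s): {list(sd.index[sd == 0])}")
    fit = sm.OLS(df[response].astype(float), sm.add_constant(X)).fit()
    params = fit.params.drop("const")
    out = pd.DataFrame(
        {
            "coef": params,
            "coef_std": params * sd,
            "p_value": fit.pvalues.drop("const"),
        }
    )
    rank = np.linalg.matrix_rank(((X - X.mean()) / sd).to_numpy())
    out.attrs["rank_deficient"] = bool(rank < p)
    out.attrs["rank"] = int(rank)
    out.attrs["r_squared"] = float(fit.rsquared)
    return out


def band_duration_analysis(
    three_month_scores: Sequence[float],
    durations_months: Sequence[float],
    bands: Sequence[float] = (3.5, 4.0, 4.5, 5.0),
    horizon_days: float = 300.0,
    days_per_month: float = 30.44,
) -> pd.DataFrame:
    """Fraction of patients with PR duration beyond a horizon, per score band.

    Patients are binned by their 3-month GTAA1C into bands delimited by the
    given strictly increasing thresholds: (−∞, b₀], (b₀, b₁], …, (b_last, ∞).
    For each band the fraction with PR duration exceeding ``horizon_days``
    is reported; an empty band yields NaN (undefined), not 0.
    """
    s = np.asarray(three_month_scores, dtype=float)
    d = np.asarray(durations_months, dtype=float)
    if s.shape != d.shape or s.ndim != 1:
        raise ValueError("scores and durations must be aligned 1-d vectors")
    b = np.asarray(bands, dtype=float)
    if b.size == 0 or np.any(np.diff(b) <= 0):
        raise ValueError("bands must be strictly increasing thresholds")
    exceeds = d * days_per_month > horizon_days
    edges = np.concatenate([[-np.inf], b, [np.inf]])
    rows = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        mask = (s > lo) & (s <= hi)
        n_band = int(mask.sum())
        rows.append(
            {
                "band": f"({lo:g}, {hi:g}]",
                "lo": lo,
                "hi": hi,
                "n": n_band,
                "n_exceeding": int(exceeds[mask].sum()),
                "proportion": float(exceeds[mask].mean()) if n_band else float("nan"),
            }
        )
    return pd.DataFrame(rows)


def classify_dka(ph: float, bicarbonate: float) -> bool:
    """Diabetic ketoacidosis at diagnosis: pH < 7.3 and/or bicarbonate < 16 mM.

    Both comparisons are strict; pH must be physiologically plausible
    (6.5-8) and bicarbonate non-negative.
    """
    if not (6.5 < ph < 8.0):
        raise ValueError(f"pH {ph} outside the physiological range (6.5, 8)")
    if bicarbonate < 0:
        raise ValueError("bicarbonate must be >= 0 mM")
    return ph < 7.3 or bicarbonate < 16.0


def age_group(age_at_dx: float) -> str:
    """Age-at-diagnosis group: [0,5) → under5, [5,10) → five_to_ten, ≥10 → ten_plus."""
    if not (0 < age_at_dx < 20):
        raise ValueError(f"pediatric age at diagnosis expected in (0, 20), got {age_at_dx}")
    if age_at_dx < 5:
        return "under5"
    if age_at_dx < 10:
        return "five_to_ten"
    return "ten_plus"
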