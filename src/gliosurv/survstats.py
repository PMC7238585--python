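"""Sex-stratified survival statistics.

The analysis battery applied separately to male and female cohorts:

* Welch two-sample t-tests comparing the eight quantitative pre-treatment
  variables between survival groups (extreme survivors vs the rest,
  extreme vs short-term, short-term vs the rest);
* univariate Cox proportional-hazards fits per covariate, with promotion
  of every covariate reaching p < 0.10 into a joint multivariate fit;
* Kaplan-Meier curves with two-sided log-rank tests;
* the Cochran-Armitage trend test for ordered categories (extent of
  resection);
* per-category survival reports (pairwise log-rank, categorical Cox with
  and without age adjustment).

Cox models use the Efron approximation for tied event times.  All tests
are two-sided and p-values are reported raw (an optional
Benjamini-Hochberg column is available as an extension, clearly marked).
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError as _LLConvergenceError
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats

from .geometry import (
    KINETIC_VARIABLES,
    QUANTITATIVE_VARIABLES,
)

logger = logging.getLogger("gliosurv")

#: the three survival-group contrasts of the analysis
CONTRASTS = ("EXS_vs_NonEXS", "EXS_vs_STS", "STS_vs_NonSTS")

PROMOTION_P = 0.10


class CoxConvergenceError(RuntimeError):
    """Cox partial-likelihood maximization failed (separation or otherwise)."""


# ---------------------------------------------------------------------------
# Welch t-tests


@dataclass
class TTestResult:
    mean_a: float
    mean_b: float
    t_statistic: float
    welch_df: float
    p_two_sided: float
    n_a: int = 0
    n_b: int = 0
    flag: str = ""


def welch_t_test(sample_a, sample_b) -> TTestResult:
    """Two-sided Welch t-test (unequal variances, Satterthwaite df).

    Degenerate zero-variance inputs are resolved by convention: equal
    means give p = 1, unequal means the p -> 0 limit with a flag.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) < 2 or len(b) < 2 or not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("both samples need >= 2 finite values")
    mean_a, mean_b = float(a.mean()), float(b.mean())
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        if math.isclose(mean_a, mean_b):
            return TTestResult(mean_a, mean_b, 0.0, float(len(a) + len(b) - 2), 1.0,
                               len(a), len(b), "zero-variance")
        return TTestResult(mean_a, mean_b, math.inf if mean_a > mean_b else -math.inf,
                           float(len(a) + len(b) - 2), 0.0, len(a), len(b),
                           "zero-variance-unequal-means")
    res = stats.ttest_ind(a, b, equal_var=False)
    return TTestResult(
        mean_a=mean_a, mean_b=mean_b,
        t_statistic=float(res.statistic),
        welch_df=float(res.df),
        p_two_sided=float(res.pvalue),
        n_a=len(a), n_b=len(b),
    )


def _contrast_masks(group: pd.Series, contrast: str) -> tuple[pd.Series, pd.Series]:
    if contrast == "EXS_vs_NonEXS":
        return group == "EXS", group != "EXS"
    if contrast == "EXS_vs_STS":
        return group == "EXS", group == "STS"
    if contrast == "STS_vs_NonSTS":
        return group == "STS", group != "STS"
    raise ValueError(f"unknown contrast {contrast!r}")


def group_comparisons(
    cohort: pd.DataFrame,
    variables=QUANTITATIVE_VARIABLES,
    contrasts=CONTRASTS,
) -> pd.DataFrame:
    """The full t-test matrix: sex x contrast x quantitative variable.

    Kinetic variables are implicitly restricted to the imaging sub-cohort
    because subjects without T2/FLAIR carry NaN there and are dropped
    per-variable.  Contrasts with fewer than two subjects on either side
    are skipped with a logged notice.
    """
    rows = []
    for sex in ("male", "female"):
        sub = cohort[cohort["sex"] == sex]
        for contrast in contrasts:
            mask_a, mask_b = _contrast_masks(sub["survival_group"], contrast)
            for var in variables:
                va = sub.loc[mask_a, var].dropna()
                vb = sub.loc[mask_b, var].dropna()
                if len(va) < 2 or len(vb) < 2:
                    logger.warning(
                        "skipping %s / %s / %s: group too small (%d vs %d)",
                        sex, contrast, var, len(va), len(vb),
                    )
                    continue
                r = welch_t_test(va, vb)
                rows.append(
                    {
                        "sex": sex, "contrast": contrast, "variable": var,
                        "mean_a": r.mean_a, "mean_b": r.mean_b,
                        "t": r.t_statistic, "df": r.welch_df,
                        "p": r.p_two_sided, "n_a": r.n_a, "n_b": r.n_b,
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Cox proportional hazards


@dataclass
class CoxFit:
    """A fitted proportional-hazards model.

    ``table`` has one row per covariate with columns coef, hr, hr_lo,
    hr_hi (Wald 95% CI, symmetric on the log scale), se, p (two-sided
    Wald).
    """

    table: pd.DataFrame
    log_likelihood: float
    n: int
    events: int

    def hr(self, covariate: str) -> float:
        return float(self.table.loc[covariate, "hr"])

    def p(self, covariate: str) -> float:
        return float(self.table.loc[covariate, "p"])

    def ci(self, covariate: str) -> tuple[float, float]:
        row = self.table.loc[covariate]
        return float(row["hr_lo"]), float(row["hr_hi"])


def fit_cox(
    cohort: pd.DataFrame,
    covariates,
    duration_col: str = "os_days",
    event_col: str = "event",
) -> CoxFit:
    """Cox proportional hazards via partial likelihood with Efron ties.

    Rows with missing covariate values are dropped (complete-case).
    Raises :class:`CoxConvergenceError` on separation / non-convergence
    rather than returning a silently unstable fit.
    """
    covariates = list(covariates)
    df = cohort[[duration_col, event_col, *covariates]].dropna()
    if df[event_col].sum() < 1:
        raise ValueError("need at least one observed event")
    for c in covariates:
        if df[c].nunique() <= 1:
            raise ValueError(f"covariate {c!r} is constant")
    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col=duration_col, event_col=event_col)
    except (_LLConvergenceError, Warning) as exc:
        raise CoxConvergenceError(str(exc)) from exc
    summ = cph.summary
    table = pd.DataFrame(
        {
            "coef": summ["coef"],
            "hr": summ["exp(coef)"],
            "hr_lo": summ["exp(coef) lower 95%"],
            "hr_hi": summ["exp(coef) upper 95%"],
            "se": summ["se(coef)"],
            "p": summ["p"],
        }
    )
    table.index.name = "covariate"
    return CoxFit(
        table=table,
        log_likelihood=float(cph.log_likelihood_),
        n=int(len(df)),
        events=int(df[event_col].sum()),
    )


def promote_to_multivariate(univariate: dict[str, CoxFit], threshold: float = PROMOTION_P) -> list[str]:
    """Covariates significant or almost significant in univariate analysis.

    Strict inequality p < threshold (default 0.10); input order preserved.
    An empty selection is returned with a logged notice.
    """
    selected = [
        name for name, fit in univariate.items() if fit.p(name) < threshold
    ]
    if not selected:
        logger.info("no covariate reached p < %.2f; multivariate step skipped", threshold)
    return selected


def univariate_then_multivariate(
    cohort: pd.DataFrame, covariates, threshold: float = PROMOTION_P
) -> tuple[dict[str, CoxFit], CoxFit | None, list[str]]:
    """The univariate -> multivariate promotion pipeline for one sex."""
    uni: dict[str, CoxFit] = {}
    for c in covariates:
        try:
            uni[c] = fit_cox(cohort, [c])
        except (ValueError, CoxConvergenceError) as exc:
            logger.warning("univariate Cox for %s failed: %s", c, exc)
    promoted = promote_to_multivariate(uni, threshold)
    multi = fit_cox(cohort, promoted) if promoted else None
    return uni, multi, promoted


# ---------------------------------------------------------------------------
# Kaplan-Meier and log-rank


@dataclass
class KMCurve:
    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    censor_times: np.ndarray = field(default_factory=lambda: np.array([]))


def km_curve(durations, events=None) -> KMCurve:
    """Product-limit survival estimate."""
    durations = np.asarray(durations, dtype=float)
    if events is None:
        events = np.ones_like(durations)
    events = np.asarray(events)
    if len(durations) == 0:
        raise ValueError("need at least one subject")
    kmf = KaplanMeierFitter()
    kmf.fit(durations, events)
    times = kmf.survival_function_.index.to_numpy(dtype=float)
    surv = kmf.survival_function_.iloc[:, 0].to_numpy(dtype=float)
    at_risk = kmf.event_table["at_risk"].reindex(times).to_numpy(dtype=float)
    return KMCurve(
        times=times, survival=surv, at_risk=at_risk,
        censor_times=np.sort(durations[events == 0]),
    )


def log_rank(
    durations_a, durations_b, events_a=None, events_b=None
) -> tuple[float, float]:
    """Two-sided log-rank test; returns (chi-square with 1 df, p)."""
    durations_a = np.asarray(durations_a, dtype=float)
    durations_b = np.asarray(durations_b, dtype=float)
    events_a = np.ones_like(durations_a) if events_a is None else np.asarray(events_a)
    events_b = np.ones_like(durations_b) if events_b is None else np.asarray(events_b)
    if len(durations_a) == 0 or len(durations_b) == 0:
        raise ValueError("both groups need at least one subject")
    res = _ll_logrank(durations_a, durations_b, event_observed_A=events_a,
                      event_observed_B=events_b)
    return float(res.test_statistic), float(res.p_value)


# ---------------------------------------------------------------------------
# Cochran-Armitage trend test


@dataclass
class TrendResult:
    z_statistic: float
    p_two_sided: float
    scores: np.ndarray


def cochran_armitage(counts, scores=None) -> TrendResult:
    """Cochran-Armitage test for trend in a 2 x k table of ordered categories.

    ``counts`` is a 2 x k array: row 0 = successes, row 1 = failures per
    ordered category (e.g. biopsy < subtotal < gross-total resection).
    Equally spaced integer scores by default.  Categories with zero column
    total are dropped with a warning.  The statistic is the usual
    score-based z with variance conditional on the margins; two-sided
    normal p-value.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.shape[0] != 2 or counts.shape[1] < 3:
        raise ValueError("counts must be a 2 x k table with k >= 3")
    if (counts < 0).any() or not np.allclose(counts, np.round(counts)):
        raise ValueError("counts must be non-negative integers")
    scores = np.arange(counts.shape[1], dtype=float) if scores is None else np.asarray(scores, dtype=float)
    if len(scores) != counts.shape[1]:
        raise ValueError("one score per category required")
    col_tot = counts.sum(axis=0)
    keep = col_tot > 0
    if not keep.all():
        logger.warning("dropping %d empty categories from trend test", int((~keep).sum()))
        counts, scores, col_tot = counts[:, keep], scores[keep], col_tot[keep]
        if counts.shape[1] < 2:
            raise ValueError("fewer than two non-empty categories")
    n = counts.sum()
    r1 = counts[0].sum()  # successes overall
    p1 = r1 / n
    t_obs = float(np.dot(counts[0], scores))
    e_t = r1 * np.dot(col_tot, scores) / n
    s2 = np.dot(col_tot, scores**2) - (np.dot(col_tot, scores) ** 2) / n
    var_t = p1 * (1 - p1) * s2 * n / (n - 1)
    if var_t <= 0:
        return TrendResult(0.0, 1.0, scores)
    z = (t_obs - e_t) / math.sqrt(var_t)
    p = 2.0 * stats.norm.sf(abs(z))
    return TrendResult(float(z), float(min(p, 1.0)), scores)


# ---------------------------------------------------------------------------
# categorical survival report

REFERENCE_LEVELS = {
    "laterality": "right",
    "eor": "biopsy",
    "idh1": "wt",
    "mgmt": "unmethylated",
}


def categorical_survival_report(
    cohort: pd.DataFrame,
    variable: str,
    reference: str | None = None,
    adjust_for_age: bool = True,
) -> dict:
    """Per-sex survival impact of one categorical covariate.

    For each sex: pairwise log-rank tests between levels, a Cox model with
    the categorical covariate dummy-coded against a reference level, and
    an age-adjusted Cox variant.  Levels coded ``"unknown"`` are excluded;
    levels with zero events are flagged.
    """
    if variable not in REFERENCE_LEVELS:
        raise ValueError(f"unsupported categorical variable {variable!r}")
    reference = reference or REFERENCE_LEVELS[variable]
    out: dict = {"variable": variable, "reference": reference, "by_sex": {}}
    for sex in ("male", "female"):
        sub = cohort[(cohort["sex"] == sex) & (cohort[variable] != "unknown")]
        levels = sorted(sub[variable].unique())
        entry: dict = {"levels": levels, "n": int(len(sub))}
        if len(levels) < 2:
            entry["notice"] = "fewer than two non-empty levels; report empty"
            out["by_sex"][sex] = entry
            continue
        zero_event = [
            lv for lv in levels if sub.loc[sub[variable] == lv, "event"].sum() == 0
        ]
        if zero_event:
            entry["zero_event_levels"] = zero_event
        pairwise = {}
        for la, lb in itertools.combinations(levels, 2):
            a = sub[sub[variable] == la]
            b = sub[sub[variable] == lb]
            chi2, p = log_rank(a["os_days"], b["os_days"], a["event"], b["event"])
            pairwise[f"{la}_vs_{lb}"] = {"chi2": chi2, "p": p}
        entry["pairwise_logrank"] = pairwise
        dummies = pd.get_dummies(sub[variable], prefix=variable, dtype=float)
        ref_col = f"{variable}_{reference}"
        design = pd.concat(
            [sub[["os_days", "event", "age_years"]], dummies.drop(columns=[ref_col], errors="ignore")],
            axis=1,
        )
        dummy_cols = [c for c in design.columns if c.startswith(f"{variable}_")]
        try:
            entry["cox"] = fit_cox(design, dummy_cols)
            if adjust_for_age:
                entry["cox_age_adjusted"] = fit_cox(design, dummy_cols + ["age_years"])
        except (ValueError, CoxConvergenceError) as exc:
            entry["cox_error"] = str(exc)
        out["by_sex"][sex] = entry
    return out


def benjamini_hochberg(p_values) -> np.ndarray:
    """BH-adjusted q-values (optional extension column, not used for the
    primary reporting, which mirrors raw p-values)."""
    p = np.asarray(p_values, dtype=float)
    order = np.argsort(p)
    ranked = p[order] * len(p) / (np.arange(len(p)) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty_like(ranked)
    out[order] = np.minimum(ranked, 1.0)
    return out
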