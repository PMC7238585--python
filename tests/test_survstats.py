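import itertools
import math

import numpy as np
import pandas as pd
import pytest

from gliosurv.cohort import GeneratorConfig, generate_cohort
from gliosurv.survstats import (
    cochran_armitage,
    categorical_survival_report,
    fit_cox,
    group_comparisons,
    km_curve,
    log_rank,
    promote_to_multivariate,
    univariate_then_multivariate,
    welch_t_test,
)
from .conftest import null_generator_config


# ---------------------------------------------------------------------------
# Welch t-tests


def test_welch_identical_samples():
    r = welch_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert r.t_statistic == pytest.approx(0.0)
    assert r.p_two_sided == pytest.approx(1.0)


def test_welch_hand_example():
    """a = [1,2,3], b = [2,3,4]: equal variances 1, so t = -sqrt(3/2),
    Satterthwaite df = 4; p frozen from the t(4) tail."""
    r = welch_t_test([1, 2, 3], [2, 3, 4])
    assert r.t_statistic == pytest.approx(-1.224744871, rel=1e-6)
    assert r.welch_df == pytest.approx(4.0, rel=1e-9)
    assert r.p_two_sided == pytest.approx(0.2878641, rel=1e-4)


def test_welch_scale_invariance():
    a, b = [1.2, 3.4, 2.2, 5.0], [2.0, 4.4, 6.1]
    r1 = welch_t_test(a, b)
    r2 = welch_t_test([10 * x for x in a], [10 * x for x in b])
    assert r1.t_statistic == pytest.approx(r2.t_statistic)
    assert r1.welch_df == pytest.approx(r2.welch_df)
    assert r1.p_two_sided == pytest.approx(r2.p_two_sided)


def test_welch_zero_variance_conventions():
    same = welch_t_test([2.0, 2.0], [2.0, 2.0, 2.0])
    assert same.p_two_sided == 1.0
    diff = welch_t_test([2.0, 2.0], [3.0, 3.0])
    assert diff.p_two_sided == 0.0 and diff.flag


def test_group_comparisons_shape(synthetic_cohort_494):
    table = group_comparisons(synthetic_cohort_494)
    # 2 sexes x 3 contrasts x 8 variables
    assert len(table) == 48
    assert set(table["sex"]) == {"male", "female"}
    assert table.groupby(["sex", "contrast"]).size().eq(8).all()


def test_planted_age_shift_is_detected():
    """A one-SD age shift planted on extreme survivors is flagged by the
    EXS-vs-rest age comparison in at least 90% of seeded replicates."""
    hits = 0
    n_rep = 60
    for seed in range(n_rep):
        cfg = GeneratorConfig(
            n=400, seed=1000 + seed,
            planted_effects={"age_years": {"EXS": -13.8}},
        )
        table = group_comparisons(generate_cohort(cfg), variables=("age_years",))
        rows = table[(table["contrast"] == "EXS_vs_NonEXS")]
        if len(rows) and (rows["p"] < 0.05).any():
            hits += 1
    assert hits / n_rep >= 0.90


def test_type_one_error_calibrated():
    """On null cohorts (survival independent of all covariates) the t-test
    battery rejects at close to the nominal 5% rate."""
    p_values = []
    for seed in range(500):
        frame = generate_cohort(null_generator_config(150, 20_000 + seed))
        table = group_comparisons(
            frame, variables=("age_years", "t1gd_radius_mm"),
            contrasts=("STS_vs_NonSTS",),
        )
        p_values.extend(table["p"].tolist())
    p = np.asarray(p_values)
    rate = float((p < 0.05).mean())
    # binomial 3-sigma band around 0.05 at this many tests
    se = math.sqrt(0.05 * 0.95 / len(p))
    assert abs(rate - 0.05) < 3 * se + 0.005


# ---------------------------------------------------------------------------
# Cox proportional hazards


def _efron_log_partial_likelihood(beta, durations, events, x):
    """Independent brute-force Efron partial likelihood for one covariate."""
    order = np.argsort(durations)
    durations, events, x = durations[order], events[order], x[order]
    ll = 0.0
    for t in np.unique(durations[events == 1]):
        tied = (durations == t) & (events == 1)
        at_risk = durations >= t
        xs = x[tied]
        m = tied.sum()
        ll += beta * xs.sum()
        risk = np.exp(beta * x[at_risk]).sum()
        tied_risk = np.exp(beta * xs).sum()
        for ell in range(m):
            ll -= math.log(risk - ell / m * tied_risk)
    return ll


def test_cox_log_likelihood_matches_brute_force():
    durations = np.array([5.0, 8.0, 12.0, 20.0, 25.0, 30.0])
    events = np.array([1, 1, 0, 1, 1, 1])
    x = np.array([0.5, -1.0, 0.2, 1.5, -0.3, 0.8])
    df = pd.DataFrame({"os_days": durations, "event": events, "x": x})
    fit = fit_cox(df, ["x"])
    beta_hat = float(fit.table.loc["x", "coef"])
    ll_oracle = _efron_log_partial_likelihood(beta_hat, durations, events, x)
    assert fit.log_likelihood == pytest.approx(ll_oracle, abs=1e-6)
    # and the fitted beta maximizes the brute-force likelihood on a grid
    grid = np.linspace(beta_hat - 1.0, beta_hat + 1.0, 201)
    lls = [_efron_log_partial_likelihood(b, durations, events, x) for b in grid]
    assert abs(grid[int(np.argmax(lls))] - beta_hat) <= 0.011


def test_cox_null_covariate():
    """A covariate shuffled independently of survival has HR ~ 1."""
    rng = np.random.default_rng(3)
    hits = 0
    for _ in range(40):
        n = 150
        df = pd.DataFrame({
            "os_days": rng.exponential(400.0, n),
            "event": np.ones(n, dtype=int),
            "x": rng.normal(size=n),
        })
        fit = fit_cox(df, ["x"])
        coef = float(fit.table.loc["x", "coef"])
        se = float(fit.table.loc["x", "se"])
        hits += abs(coef) < 3 * se
    assert hits / 40 >= 0.95


def test_cox_recovers_true_hazard_ratio():
    """Two-group exponential survival with true HR 2: the estimate lands
    in [1.7, 2.35] in at least 90% of replicates at n = 500."""
    rng = np.random.default_rng(7)
    ok = 0
    n_rep = 60
    for _ in range(n_rep):
        n = 500
        g = rng.integers(0, 2, n)
        t = rng.exponential(1.0, n) / np.where(g == 1, 2.0, 1.0)
        df = pd.DataFrame({"os_days": t, "event": np.ones(n, dtype=int), "g": g})
        hr = fit_cox(df, ["g"]).hr("g")
        ok += 1.7 <= hr <= 2.35
    assert ok / n_rep >= 0.90


def test_cox_invariances():
    """Shifting a covariate leaves the coefficient unchanged; scaling by
    kappa scales the coefficient by 1/kappa."""
    rng = np.random.default_rng(11)
    n = 200
    x = rng.normal(size=n)
    t = rng.exponential(1.0, n) * np.exp(-0.5 * x)
    df = pd.DataFrame({"os_days": t, "event": np.ones(n, dtype=int), "x": x})
    base = float(fit_cox(df, ["x"]).table.loc["x", "coef"])
    shifted = df.assign(x=df["x"] + 100.0)
    scaled = df.assign(x=df["x"] * 4.0)
    assert float(fit_cox(shifted, ["x"]).table.loc["x", "coef"]) == pytest.approx(base, rel=1e-5)
    assert float(fit_cox(scaled, ["x"]).table.loc["x", "coef"]) == pytest.approx(base / 4.0, rel=1e-5)


def test_cox_rejects_constant_covariate():
    df = pd.DataFrame({"os_days": [1.0, 2.0, 3.0], "event": [1, 1, 1], "x": [1.0, 1.0, 1.0]})
    with pytest.raises(ValueError):
        fit_cox(df, ["x"])


def test_promotion_rule():
    class FakeFit:
        def __init__(self, p):
            self._p = p

        def p(self, _):
            return self._p

    uni = {"a": FakeFit(0.02), "b": FakeFit(0.09), "c": FakeFit(0.11)}
    assert promote_to_multivariate(uni) == ["a", "b"]
    # p = 0.10 exactly is excluded: the rule is strict
    assert promote_to_multivariate({"x": FakeFit(0.10)}) == []
    assert promote_to_multivariate({"x": FakeFit(0.2), "y": FakeFit(0.5)}) == []


def test_univariate_then_multivariate_pipeline(synthetic_cohort_494):
    males = synthetic_cohort_494[synthetic_cohort_494["sex"] == "male"]
    uni, multi, promoted = univariate_then_multivariate(
        males, ("age_years", "t1gd_radius_mm", "pihna_D")
    )
    assert set(uni) == {"age_years", "t1gd_radius_mm", "pihna_D"}
    if promoted:
        assert multi is not None and list(multi.table.index) == promoted
    else:
        assert multi is None


# ---------------------------------------------------------------------------
# Kaplan-Meier and log-rank


def test_km_hand_example():
    """Times {1, 2+, 3} with events at 1 and 3: S = 2/3 after t=1 and 0
    after t=3 (hand product-limit computation)."""
    curve = km_curve([1.0, 2.0, 3.0], [1, 0, 1])
    s_at = dict(zip(curve.times, curve.survival))
    assert s_at[0.0] == pytest.approx(1.0)
    assert s_at[1.0] == pytest.approx(2.0 / 3.0)
    assert s_at[3.0] == pytest.approx(0.0)


def test_km_without_censoring_is_empirical_survival():
    rng = np.random.default_rng(5)
    t = rng.exponential(10.0, 40)
    curve = km_curve(t)
    emp = np.array([(t > u).mean() for u in curve.times])
    assert np.allclose(curve.survival, emp, atol=1e-12)


def test_log_rank_self_comparison():
    t = [3.0, 5.0, 9.0, 12.0]
    chi2, p = log_rank(t, t)
    assert chi2 == pytest.approx(0.0, abs=1e-12)
    assert p == pytest.approx(1.0)


def test_log_rank_equals_cox_score_test():
    """With a single binary covariate and no ties, the log-rank chi-square
    equals the Cox score test computed by hand."""
    rng = np.random.default_rng(9)
    n = 60
    g = np.repeat([0, 1], n // 2)
    t = rng.exponential(1.0, n) / np.where(g == 1, 1.8, 1.0)
    assert len(np.unique(t)) == n  # no ties
    chi2, _ = log_rank(t[g == 0], t[g == 1])

    # hand score test: U(0)^2 / I(0)
    order = np.argsort(t)
    ts, gs = t[order], g[order]
    U = 0.0
    I = 0.0
    for i in range(n):
        at_risk = ts >= ts[i]
        p1 = gs[at_risk].mean()
        U += gs[i] - p1
        I += p1 * (1 - p1)
    assert chi2 == pytest.approx(U**2 / I, rel=1e-6)


def test_log_rank_power_with_planted_hazard():
    rng = np.random.default_rng(13)
    hits = 0
    n_rep = 50
    for _ in range(n_rep):
        n = 200
        g = np.repeat([0, 1], n // 2)
        t = rng.exponential(1.0, n) / np.where(g == 1, 2.0, 1.0)
        _, p = log_rank(t[g == 0], t[g == 1])
        hits += p < 0.05
    assert hits / n_rep >= 0.80


def test_log_rank_zero_event_group_defined():
    chi2, p = log_rank([5.0, 6.0], [1.0, 2.0], events_a=[0, 0], events_b=[1, 1])
    assert np.isfinite(chi2) and 0 <= p <= 1


# ---------------------------------------------------------------------------
# Cochran-Armitage trend


def test_trend_equal_proportions():
    res = cochran_armitage([[10, 10, 10], [10, 10, 10]])
    assert res.z_statistic == pytest.approx(0.0, abs=1e-12)
    assert res.p_two_sided == pytest.approx(1.0)


def test_trend_matches_permutation_oracle():
    counts = np.array([[10, 20, 30], [30, 20, 10]])
    res = cochran_armitage(counts)
    # permutation null of the score statistic T = sum(scores * successes)
    rng = np.random.default_rng(17)
    scores = np.repeat([0.0, 1.0, 2.0], counts.sum(axis=0))
    labels = np.repeat([1, 0], counts.sum(axis=1))
    t_obs = float(np.dot([0.0, 1.0, 2.0], counts[0]))
    sims = np.empty(10_000)
    for k in range(len(sims)):
        perm = rng.permutation(labels)
        sims[k] = scores[perm == 1].sum()
    z_perm = (t_obs - sims.mean()) / sims.std(ddof=1)
    assert res.z_statistic == pytest.approx(z_perm, rel=0.05)


def test_trend_reversal_flips_sign():
    counts = [[5, 10, 25], [20, 10, 5]]
    fwd = cochran_armitage(counts)
    rev = cochran_armitage([row[::-1] for row in counts])
    assert rev.z_statistic == pytest.approx(-fwd.z_statistic, rel=1e-9)
    assert rev.p_two_sided == pytest.approx(fwd.p_two_sided, rel=1e-9)


def test_trend_drops_empty_category():
    res = cochran_armitage([[5, 0, 10, 20], [15, 0, 10, 5]])
    assert np.isfinite(res.z_statistic)


def test_trend_input_validation():
    with pytest.raises(ValueError):
        cochran_armitage([[1, 2], [3, 4]])  # k < 3


# ---------------------------------------------------------------------------
# categorical survival report


def test_planted_mgmt_benefit_detected():
    """A planted methylation survival benefit shows up in the
    age-adjusted categorical Cox fit for both sexes."""
    cfg = GeneratorConfig(
        n=1200, seed=29,
        categorical_log_hazards={("mgmt", "methylated"): math.log(0.45)},
    )
    cfg.distributions.category_prevalences["mgmt"] = {
        "methylated": 0.3, "unmethylated": 0.5, "unknown": 0.2,
    }
    frame = generate_cohort(cfg)
    report = categorical_survival_report(frame, "mgmt")
    for sex in ("male", "female"):
        fit = report["by_sex"][sex]["cox_age_adjusted"]
        assert fit.hr("mgmt_methylated") < 1.0
        assert fit.p("mgmt_methylated") < 0.05


def test_all_unknown_variable_reports_empty(synthetic_cohort_494):
    frame = synthetic_cohort_494.copy()
    frame["idh1"] = "unknown"
    report = categorical_survival_report(frame, "idh1")
    for sex in ("male", "female"):
        assert "notice" in report["by_sex"][sex]


def test_three_laterality_levels_give_three_pairwise_tests(synthetic_cohort_494):
    report = categorical_survival_report(synthetic_cohort_494, "laterality")
    for sex in ("male", "female"):
        pairs = report["by_sex"][sex]["pairwise_logrank"]
        assert len(pairs) == len(list(itertools.combinations(
            report["by_sex"][sex]["levels"], 2
        )))
        assert len(report["by_sex"][sex]["levels"]) == 3
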