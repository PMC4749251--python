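import numpy as np
import pandas as pd
import pytest

from octmac.cohort import CohortModel, generate_cohort
from octmac.stats import CollinearityError, age_group_summary, compare_groups, \
    correlation_screen, icc_two_operator, stepwise_ols, univariate_screen


# -- ICC --------------------------------------------------------------------


def test_icc_identical_columns_is_one():
    x = np.column_stack([np.arange(10.0), np.arange(10.0)])
    r = icc_two_operator(x)
    assert r.icc2 == 1.0 and r.icc3 == 1.0


def test_icc_pure_rater_offset_hand_oracle():
    """{A: 1..6, B: A+10}: consistency is perfect, agreement is penalized.

    Hand mean squares: MSR = 2*var(rowmeans)* ... computed directly below and
    compared at 1e-10."""
    a = np.arange(1.0, 7.0)
    x = np.column_stack([a, a + 10])
    r = icc_two_operator(x)
    assert r.icc3 == pytest.approx(1.0, abs=1e-12)
    assert r.icc2 < r.icc3
    # direct mean-squares arithmetic (independent of the implementation)
    n, k = x.shape
    grand = x.mean()
    msr = k * ((x.mean(1) - grand) ** 2).sum() / (n - 1)
    msc = n * ((x.mean(0) - grand) ** 2).sum() / (k - 1)
    mse = ((x - x.mean(1)[:, None] - x.mean(0)[None, :] + grand) ** 2).sum() / ((n - 1) * (k - 1))
    icc2_hand = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
    assert r.icc2 == pytest.approx(icc2_hand, abs=1e-10)


def test_icc_agrees_with_pingouin():
    pg = pytest.importorskip("pingouin")
    rng = np.random.default_rng(0)
    x = rng.normal(0, 1, (12, 2)) + rng.normal(0, 2, (12, 1))
    mine = icc_two_operator(x)
    df = pd.DataFrame({"s": np.repeat(np.arange(12), 2),
                       "r": np.tile([0, 1], 12), "y": x.ravel()})
    ref = pg.intraclass_corr(df, targets="s", raters="r", ratings="y")
    assert mine.icc2 == pytest.approx(
        float(ref[ref.Type == "ICC(A,1)"].ICC.iloc[0]), abs=1e-10)
    assert mine.icc3 == pytest.approx(
        float(ref[ref.Type == "ICC(C,1)"].ICC.iloc[0]), abs=1e-10)


def test_icc_degenerate_zero_between_subject_variance():
    x = np.ones((8, 2))
    r = icc_two_operator(x)
    assert r.degenerate and np.isnan(r.icc2)


# -- correlations -----------------------------------------------------------


def test_pearson_exact_linear():
    df = pd.DataFrame({"x": np.arange(20.0), "RNFL": 2 * np.arange(20.0) + 1})
    scr = correlation_screen(df, covariates=["x"], layers=["RNFL"])
    assert scr.r.iloc[0] == pytest.approx(1.0)


def test_spearman_rank_invariance():
    x = np.linspace(0.1, 3, 30)
    df = pd.DataFrame({"x": x, "RNFL": np.exp(x)})
    sp = correlation_screen(df, "spearman", covariates=["x"], layers=["RNFL"])
    pe = correlation_screen(df, "pearson", covariates=["x"], layers=["RNFL"])
    assert sp.r.iloc[0] == pytest.approx(1.0)
    assert pe.r.iloc[0] < 1.0


def test_zero_variance_column_flagged():
    df = pd.DataFrame({"x": np.ones(20), "RNFL": np.arange(20.0)})
    scr = correlation_screen(df, covariates=["x"], layers=["RNFL"])
    assert not scr.defined.iloc[0] and np.isnan(scr.r.iloc[0])


def test_cohort_sign_pattern_reproduced():
    """Age negative for RNFL..PR, positive RPE; imageQ positive everywhere;
    reproduced in >= 95/100 simulated cohorts at the study size."""
    model = CohortModel()
    ok = 0
    for s in range(100):
        coh = generate_cohort(model, 231, seed=s)
        scr = correlation_screen(coh, covariates=["age", "image_q"])
        piv = scr.pivot(index="covariate", columns="layer", values="r")
        good = all(piv.loc["age", l] < 0 for l in
                   ["RNFL", "GCL", "IPL", "INL", "OPL", "ONL", "PR"])
        good &= piv.loc["age", "RPE"] > 0
        good &= (piv.loc["image_q"] > 0).all()
        ok += good
    assert ok >= 95


def test_all_p_values_in_unit_interval():
    coh = generate_cohort(CohortModel(), 60, seed=2)
    scr = correlation_screen(coh)
    assert scr.p.dropna().between(0, 1).all()


# -- t-tests ----------------------------------------------------------------


def test_identical_groups_t_zero_p_one():
    a = np.arange(10.0)
    r = compare_groups(a, a.copy(), mode="paired")
    assert r.t == 0.0 and r.p == 1.0


def test_constant_paired_difference_degenerate():
    a = np.arange(10.0)
    r = compare_groups(a + 5, a, mode="paired")
    assert r.degenerate and np.isinf(r.t)


def test_shifted_normals_detected():
    hits = 0
    for s in range(100):
        rng = np.random.default_rng(s)
        a = rng.normal(0, 1, 30)
        b = rng.normal(1, 1, 30)
        hits += compare_groups(a, b).p < 0.05
    assert hits >= 95


def test_too_small_groups_rejected():
    with pytest.raises(ValueError):
        compare_groups(np.array([1.0]), np.arange(5.0))


# -- stepwise ---------------------------------------------------------------


def test_perfect_predictor_selected_with_unit_beta():
    rng = np.random.default_rng(0)
    x = rng.normal(0, 1, 40)
    df = pd.DataFrame({"x": x, "y": x.copy()})
    res = stepwise_ols(df, "y", ["x"])
    assert res.selected == ["x"]
    assert res.beta_std["x"] == pytest.approx(1.0)
    assert res.r_squared == pytest.approx(1.0)


def test_stepwise_reduces_to_full_ols_with_unit_alphas():
    rng = np.random.default_rng(1)
    df = pd.DataFrame(rng.normal(0, 1, (60, 4)), columns=list("abcy"))
    res = stepwise_ols(df, "y", ["a", "b", "c"], alpha_in=1.0, alpha_out=1.0)
    assert set(res.selected) == {"a", "b", "c"}


def test_standardized_beta_invariant_to_affine_rescaling():
    rng = np.random.default_rng(2)
    x = rng.normal(0, 1, 80)
    y = 2 * x + rng.normal(0, 0.5, 80)
    r1 = stepwise_ols(pd.DataFrame({"x": x, "y": y}), "y", ["x"])
    r2 = stepwise_ols(pd.DataFrame({"x": 1000 * x + 7, "y": y}), "y", ["x"])
    assert r1.beta_std["x"] == pytest.approx(r2.beta_std["x"], abs=1e-9)


def test_negating_predictor_negates_beta_preserves_p():
    rng = np.random.default_rng(3)
    x = rng.normal(0, 1, 80)
    y = x + rng.normal(0, 1, 80)
    r1 = stepwise_ols(pd.DataFrame({"x": x, "y": y}), "y", ["x"])
    r2 = stepwise_ols(pd.DataFrame({"x": -x, "y": y}), "y", ["x"])
    assert r1.beta_std["x"] == pytest.approx(-r2.beta_std["x"], abs=1e-12)
    assert r1.p_values["x"] == pytest.approx(r2.p_values["x"], abs=1e-12)


def test_collinear_candidates_named():
    rng = np.random.default_rng(4)
    x = rng.normal(0, 1, 60)
    df = pd.DataFrame({"x1": x, "x2": 2 * x, "y": rng.normal(0, 1, 60)})
    with pytest.raises(CollinearityError, match="x1"):
        stepwise_ols(df, "y", ["x1", "x2"])


def test_univariate_screen_keeps_true_predictors():
    coh = generate_cohort(CohortModel(), 231, seed=5)
    kept = univariate_screen(coh, "RNFL", ["age", "image_q", "height"])
    assert "age" in kept and "image_q" in kept


# -- age groups -------------------------------------------------------------


def test_single_age_cohort_fills_one_bin():
    coh = generate_cohort(CohortModel(), 20, seed=6)
    coh["age"] = 25.0
    table, _ = age_group_summary(coh)
    assert table.n.tolist()[0] == 20 and table.n.tolist()[1:] == [0] * 5


def test_deterministic_decline_gives_perfect_trend():
    coh = generate_cohort(CohortModel(), 40, seed=7)
    coh["RNFL"] = 50000.0 - coh["age"]
    _, trends = age_group_summary(coh)
    assert trends["RNFL"][0] == pytest.approx(-1.0)


def test_generated_cohort_age_trends_signed():
    """RNFL declines after 50, RPE rises across bins, in >= 95/100 seeds."""
    ok = 0
    for s in range(100):
        coh = generate_cohort(CohortModel(), 231, seed=1000 + s)
        _, trends = age_group_summary(coh)
        ok += (trends["RNFL"][0] < 0) and (trends["RPE"][0] > 0)
    assert ok >= 95


def test_under_18_rejected():
    coh = generate_cohort(CohortModel(), 20, seed=8)
    coh.loc[0, "age"] = 16.0
    with pytest.raises(ValueError):
        age_group_summary(coh)
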