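"""The statistical battery over a cohort table.

Covers the analyses a normative optical-intensity study runs: two-operator
reproducibility (intraclass correlation from the two-way ANOVA mean squares),
a univariate correlation screen of covariates against per-layer intensities,
independent and paired t-tests, forward-stepwise multiple regression with
standardized coefficients, and age-decade summaries with Spearman trends.

No multiple-testing correction is applied in the primary outputs (matching
the analysis this package reproduces); a Holm-corrected view of the screen is
available as a clearly separate column.
"""

from __future__ import annotations

import dataclasses
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .cohort import COVARIATES
from .layers import LAYER_NAMES


# -- reproducibility --------------------------------------------------------


@dataclasses.dataclass
class ICCResult:
    icc2: float          # two-way random, absolute agreement, single measures
    icc3: float          # two-way mixed, consistency, single measures
    f_value: float
    p_value: float
    ms_rows: float
    ms_cols: float
    ms_err: float
    degenerate: bool = False


def icc_two_operator(pairs: np.ndarray) -> ICCResult:
    """Intraclass correlation for per-subject two-operator measurement pairs.

    Computed directly from the two-way ANOVA decomposition: with n subjects
    and k = 2 raters,

        ICC(2,1) = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)
        ICC(3,1) = (MSR - MSE) / (MSR + (k-1) MSE)

    and the significance test is F = MSR / MSE on (n-1, (n-1)(k-1)) df.
    Zero between-subject variance makes the coefficient undefined; the result
    is flagged degenerate with NaN estimates rather than a silent value.
    """
    x = np.asarray(pairs, dtype=np.float64)
    if x.ndim != 2 or x.shape[1] != 2:
        raise ValueError("expected an (n_subjects, 2) array of measurement pairs")
    n, k = x.shape
    if n < 5:
        raise ValueError("need at least 5 subjects")
    if not np.isfinite(x).all():
        raise ValueError("missing cells are not supported")
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    msr = k * np.sum((row_means - grand) ** 2) / (n - 1)
    msc = n * np.sum((col_means - grand) ** 2) / (k - 1)
    sse = np.sum((x - row_means[:, None] - col_means[None, :] + grand) ** 2)
    mse = sse / ((n - 1) * (k - 1))

    if msr <= 0 or (msr == 0 and mse == 0):
        return ICCResult(np.nan, np.nan, np.nan, np.nan, msr, msc, mse, degenerate=True)
    if mse == 0 and msc == msr:
        # all columns identical to the rows: perfect agreement
        return ICCResult(1.0, 1.0, np.inf, 0.0, msr, msc, mse)
    icc2 = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
    icc3 = (msr - mse) / (msr + (k - 1) * mse)
    if mse == 0:
        f, p = np.inf, 0.0
    else:
        f = msr / mse
        p = float(sps.f.sf(f, n - 1, (n - 1) * (k - 1)))
    return ICCResult(float(icc2), float(icc3), float(f), p, msr, msc, mse)


# -- correlation screen -----------------------------------------------------


def correlation_screen(cohort: pd.DataFrame, method: str = "pearson",
                       covariates: Optional[Sequence[str]] = None,
                       layers: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """Correlation (r, two-sided p) of every covariate with every layer.

    Complete cases per pair; zero-variance columns yield NaN r flagged in the
    ``defined`` column. A Holm-adjusted p across the whole screen is appended
    as ``p_holm`` (an optional stricter view; the primary columns are
    uncorrected).
    """
    if method not in ("pearson", "spearman"):
        raise ValueError("method must be 'pearson' or 'spearman'")
    covariates = list(covariates) if covariates is not None else list(COVARIATES)
    layers = list(layers) if layers is not None else list(LAYER_NAMES)
    fn = sps.pearsonr if method == "pearson" else sps.spearmanr
    rows = []
    for cov in covariates:
        for layer in layers:
            sub = cohort[[cov, layer]].dropna()
            x, y = sub[cov].to_numpy(float), sub[layer].to_numpy(float)
            if len(sub) < 3 or np.std(x) == 0 or np.std(y) == 0:
                rows.append((cov, layer, np.nan, np.nan, False, len(sub)))
                continue
            r, p = fn(x, y)
            rows.append((cov, layer, float(r), float(p), True, len(sub)))
    df = pd.DataFrame(rows, columns=["covariate", "layer", "r", "p", "defined", "n"])
    ok = df["p"].notna()
    holm = np.full(len(df), np.nan)
    if ok.any():
        p = df.loc[ok, "p"].to_numpy()
        order = np.argsort(p)
        m = len(p)
        adj = np.minimum.accumulate(np.minimum((m - np.arange(m)) * p[order], 1.0)[::-1])[::-1]
        out = np.empty(m)
        out[order] = np.maximum.accumulate((m - np.arange(m)) * p[order])
        holm[np.flatnonzero(ok)] = np.minimum(out, 1.0)
    df["p_holm"] = holm
    return df


# -- group comparisons ------------------------------------------------------


@dataclasses.dataclass
class TTestResult:
    t: float
    p: float
    n1: int
    n2: int
    degenerate: bool = False


def compare_groups(a: np.ndarray, b: np.ndarray, mode: str = "independent") -> TTestResult:
    """Two-sided t-test: independent groups or paired vectors.

    Paired data with a constant nonzero difference (zero difference variance)
    is flagged degenerate (infinite t) rather than erroring.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if mode == "independent":
        if len(a) < 2 or len(b) < 2:
            raise ValueError("need at least 2 observations per group")
        if np.std(a) == 0 and np.std(b) == 0:
            if a.mean() == b.mean():
                return TTestResult(0.0, 1.0, len(a), len(b))
            return TTestResult(np.inf, 0.0, len(a), len(b), degenerate=True)
        t, p = sps.ttest_ind(a, b)
        return TTestResult(float(t), float(p), len(a), len(b))
    if mode == "paired":
        if len(a) != len(b) or len(a) < 2:
            raise ValueError("paired mode needs matched vectors of length >= 2")
        d = a - b
        if np.std(d) == 0:
            if d.mean() == 0:
                return TTestResult(0.0, 1.0, len(a), len(b))
            return TTestResult(np.inf if d.mean() > 0 else -np.inf, 0.0,
                               len(a), len(b), degenerate=True)
        t, p = sps.ttest_rel(a, b)
        return TTestResult(float(t), float(p), len(a), len(b))
    raise ValueError("mode must be 'independent' or 'paired'")


# -- stepwise regression ----------------------------------------------------


@dataclasses.dataclass
class RegressionResult:
    response: str
    selected: List[str]
    beta_std: Dict[str, float]       # standardized coefficients
    p_values: Dict[str, float]
    r_squared: float
    trace: List[Tuple[str, str, float]]   # (action, predictor, p at decision)


class CollinearityError(ValueError):
    pass


def univariate_screen(cohort: pd.DataFrame, response: str,
                      candidates: Sequence[str], alpha: float = 0.05,
                      method: str = "pearson") -> List[str]:
    """Candidates whose univariate correlation with the response has p < alpha."""
    keep = []
    scr = correlation_screen(cohort, method=method, covariates=list(candidates),
                             layers=[response])
    for _, row in scr.iterrows():
        if row["defined"] and row["p"] < alpha:
            keep.append(row["covariate"])
    return keep


def _ols_p_values(z: pd.DataFrame, response: str, terms: List[str]):
    import statsmodels.api as sm

    xmat = sm.add_constant(z[terms], has_constant="add")
    fit = sm.OLS(z[response], xmat).fit()
    return fit


def stepwise_ols(cohort: pd.DataFrame, response: str, candidates: Sequence[str],
                 alpha_in: float = 0.05, alpha_out: float = 0.10) -> RegressionResult:
    """Classic forward-stepwise OLS with removal, on standardized variables.

    At each step the candidate with the smallest partial-F p enters if below
    ``alpha_in``; any included predictor whose p rises above ``alpha_out`` is
    then removed; iterate to a fixed point. Coefficients are reported on
    z-scored response and predictors (standardized betas). With
    alpha_in = alpha_out = 1 this reduces to full OLS on all candidates.
    """
    candidates = list(candidates)
    if len(cohort) <= len(candidates) + 10:
        raise ValueError("need n > number of candidates + 10")
    data = cohort[[response] + candidates].dropna()
    z = (data - data.mean()) / data.std(ddof=1)

    if len(candidates) > 1:
        xs = z[candidates].to_numpy()
        cond = np.linalg.cond(xs)
        if cond > 1e8:
            raise CollinearityError(
                f"candidate design matrix is ill-conditioned (cond={cond:.2e}): "
                + ", ".join(candidates))

    selected: List[str] = []
    trace: List[Tuple[str, str, float]] = []
    while True:
        changed = False
        remaining = [c for c in candidates if c not in selected]
        if remaining:
            best, best_p = None, None
            for cand in remaining:
                fit = _ols_p_values(z, response, selected + [cand])
                p = float(fit.pvalues[cand])
                if best_p is None or p < best_p:
                    best, best_p = cand, p
            if best is not None and best_p < alpha_in:
                selected.append(best)
                trace.append(("add", best, best_p))
                changed = True
        if selected:
            fit = _ols_p_values(z, response, selected)
            worst = max(selected, key=lambda c: float(fit.pvalues[c]))
            worst_p = float(fit.pvalues[worst])
            if worst_p > alpha_out:
                selected.remove(worst)
                trace.append(("remove", worst, worst_p))
                changed = True
        if not changed:
            break

    if selected:
        fit = _ols_p_values(z, response, selected)
        beta = {c: float(fit.params[c]) for c in selected}
        pvals = {c: float(fit.pvalues[c]) for c in selected}
        r2 = float(fit.rsquared)
    else:
        beta, pvals, r2 = {}, {}, 0.0
    return RegressionResult(response, selected, beta, pvals, r2, trace)


# -- age groups -------------------------------------------------------------

AGE_BIN_EDGES = [20, 30, 40, 50, 60, 70]
AGE_BIN_LABELS = ["20-29", "30-39", "40-49", "50-59", "60-69", "70+"]

#: layers whose intensity declines with age (Spearman trend on age >= 50);
#: RPE rises across the whole age range instead
DECLINING_LAYERS = ["RNFL", "GCL", "IPL", "INL", "OPL", "ONL", "PR"]


def age_group_summary(cohort: pd.DataFrame,
                      layers: Optional[Sequence[str]] = None,
                      trend_min_age: float = 50.0):
    """Per-decade mean +/- SD per layer, plus Spearman age trends.

    Subjects younger than 20 are pooled into the first decade (flagged in the
    returned table). The trend statistic mirrors the two reported tests: for
    declining layers, Spearman r of intensity vs age among subjects aged >=
    ``trend_min_age``; for RPE, across all ages.
    """
    layers = list(layers) if layers is not None else list(LAYER_NAMES)
    if (cohort["age"] < 18).any():
        raise ValueError("cohort contains subjects younger than 18")
    bins = AGE_BIN_EDGES + [np.inf]
    which = np.digitize(cohort["age"], bins) - 1  # <20 -> -1
    pooled_under = int((which < 0).sum())
    which = np.clip(which, 0, len(AGE_BIN_LABELS) - 1)

    rows = []
    for gi, label in enumerate(AGE_BIN_LABELS):
        sub = cohort[which == gi]
        row = {"age_group": label, "n": len(sub),
               "pooled_under_20": pooled_under if gi == 0 else 0}
        for layer in layers:
            row[f"{layer}_mean"] = sub[layer].mean() if len(sub) else np.nan
            row[f"{layer}_sd"] = sub[layer].std(ddof=1) if len(sub) > 1 else np.nan
        rows.append(row)
    table = pd.DataFrame(rows)

    trends = {}
    older = cohort[cohort["age"] >= trend_min_age]
    for layer in layers:
        sub = older if layer in DECLINING_LAYERS else cohort
        if len(sub) >= 3 and sub[layer].std() > 0 and sub["age"].std() > 0:
            r, p = sps.spearmanr(sub["age"], sub[layer])
            trends[layer] = (float(r), float(p))
        else:
            trends[layer] = (np.nan, np.nan)
    return table, trends
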