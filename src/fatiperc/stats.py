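"""Resampling and regression inference for the cohort analyses.

Permutation tests are the workhorse: distribution-free two-sample (or
paired sign-flip) tests with exhaustive enumeration whenever the arrangement
space is small enough, otherwise seeded Monte-Carlo with the add-one
estimator p = (1 + #{|T*| >= |T|}) / (n_perm + 1). Bootstrap resampling
compares regression slopes across conditions; ordinary least squares (via
statsmodels) handles the partial, multivariable and sensory-distortion
regressions.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sct

from .models import aic as model_aic
from .models import bic as model_bic

__all__ = [
    "StatResult",
    "permutation_test",
    "paired_pre_post_test",
    "partial_regression_residuals",
    "fit_regression",
    "compare_nested_regressions",
    "bootstrap_slope_comparison",
    "distortion_regression",
]

EXHAUSTIVE_LIMIT = 20_000


@dataclass(frozen=True)
class StatResult:
    """Outcome of one resampling or paired test."""

    statistic: float
    p_value: float
    effect_size: float
    ci: tuple[float, float]
    n_resamples: int
    seed: int | None = None
    method: str = ""


def _cohens_d_independent(x: np.ndarray, y: np.ndarray) -> float:
    nx, ny = x.size, y.size
    sp2 = ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx + ny - 2)
    if sp2 <= 0:
        return 0.0
    return float((x.mean() - y.mean()) / math.sqrt(sp2))


def _mean_diff_ci(x: np.ndarray, y: np.ndarray, alpha: float = 0.05) -> tuple[float, float]:
    nx, ny = x.size, y.size
    sp2 = ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx + ny - 2)
    se = math.sqrt(sp2 * (1 / nx + 1 / ny))
    d = x.mean() - y.mean()
    tcrit = sct.t.ppf(1 - alpha / 2, nx + ny - 2)
    return (float(d - tcrit * se), float(d + tcrit * se))


def _statistic(x: np.ndarray, y: np.ndarray, kind: str) -> float:
    if kind == "mean_difference":
        return float(x.mean() - y.mean())
    if kind == "t":
        return float(sct.ttest_ind(x, y, equal_var=True).statistic)
    raise ValueError(f"unknown statistic {kind!r}")


def permutation_test(
    x,
    y,
    statistic: str = "mean_difference",
    n_perm: int = 10_000,
    paired: bool = False,
    seed: int | None = None,
) -> StatResult:
    """Two-sided permutation test of a two-sample (or paired) difference.

    Independent samples: group labels are permuted (exhaustively when the
    number of distinct reassignments is at most 20,000). Paired: signs of
    the within-pair differences are flipped (exhaustive up to 2^n <= 20,000).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("need at least 2 observations per sample")
    if paired and x.size != y.size:
        raise ValueError("paired test requires equal lengths")

    if np.all(x == x.flat[0]) and np.all(y == x.flat[0]):
        warnings.warn("all values identical in both samples; p = 1", stacklevel=2)
        return StatResult(0.0, 1.0, 0.0, (0.0, 0.0), 0, seed, "degenerate")

    rng = np.random.default_rng(seed)
    if paired:
        diff = x - y
        obs = float(diff.mean())
        n = diff.size
        if 2**n <= EXHAUSTIVE_LIMIT:
            signs = np.array(list(itertools.product([-1.0, 1.0], repeat=n)))
            stats = np.abs(signs @ diff) / n
            p = float(np.mean(stats >= abs(obs) - 1e-12))
            n_res = signs.shape[0]
            method = "paired-exhaustive"
        else:
            signs = rng.choice([-1.0, 1.0], size=(n_perm, n))
            stats = np.abs(signs @ diff) / n
            p = float((1 + np.sum(stats >= abs(obs) - 1e-12)) / (n_perm + 1))
            n_res = n_perm
            method = "paired-montecarlo"
        sd = diff.std(ddof=1)
        d = float(obs / sd) if sd > 0 else 0.0
        se = sd / math.sqrt(n) if sd > 0 else 0.0
        tcrit = sct.t.ppf(0.975, n - 1)
        return StatResult(obs, p, d, (obs - tcrit * se, obs + tcrit * se), n_res, seed, method)

    obs = _statistic(x, y, statistic)
    pooled = np.concatenate([x, y])
    nx, n = x.size, x.size + y.size
    n_arrangements = math.comb(n, nx)
    if n_arrangements <= EXHAUSTIVE_LIMIT:
        count = 0
        idx_all = np.arange(n)
        for combo in itertools.combinations(range(n), nx):
            sel = np.zeros(n, dtype=bool)
            sel[list(combo)] = True
            t = _statistic(pooled[sel], pooled[~sel], statistic)
            if abs(t) >= abs(obs) - 1e-12:
                count += 1
        p = count / n_arrangements
        n_res = n_arrangements
        method = "exhaustive"
    else:
        if statistic == "mean_difference":
            # vectorized label permutation
            perms = np.argsort(rng.random((n_perm, n)), axis=1)
            permuted = pooled[perms]
            gx = permuted[:, :nx].mean(axis=1)
            gy = permuted[:, nx:].mean(axis=1)
            stats = np.abs(gx - gy)
        else:
            stats = np.empty(n_perm)
            for i in range(n_perm):
                perm = rng.permutation(pooled)
                stats[i] = abs(_statistic(perm[:nx], perm[nx:], statistic))
        p = float((1 + np.sum(stats >= abs(obs) - 1e-12)) / (n_perm + 1))
        n_res = n_perm
        method = "montecarlo"
    return StatResult(
        obs, p, _cohens_d_independent(x, y), _mean_diff_ci(x, y), n_res, seed, method
    )


def paired_pre_post_test(pre, post, method: str = "t") -> StatResult:
    """Paired pre/post comparison (paired t or Wilcoxon signed-rank).

    Effect size is Cohen's d for paired designs (mean difference over the SD
    of the differences); the CI is the 95% t-interval of the mean difference.
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.size != post.size or pre.size < 3:
        raise ValueError("need equal lengths >= 3")
    diff = post - pre
    sd = diff.std(ddof=1)
    if sd <= 0:
        if np.allclose(diff, 0):  # no change at all: trivially null
            return StatResult(0.0, 1.0, 0.0, (0.0, 0.0), 0, None, method)
        raise ValueError("zero-variance differences: paired test undefined")
    n = diff.size
    if method == "t":
        res = sct.ttest_rel(post, pre)
        stat, p = float(res.statistic), float(res.pvalue)
    elif method == "wilcoxon":
        res = sct.wilcoxon(post, pre)
        stat, p = float(res.statistic), float(res.pvalue)
    else:
        raise ValueError(f"unknown method {method!r}")
    d = float(diff.mean() / sd)
    se = sd / math.sqrt(n)
    tcrit = sct.t.ppf(0.975, n - 1)
    m = diff.mean()
    return StatResult(stat, p, d, (float(m - tcrit * se), float(m + tcrit * se)), 0, None, method)


def _ols(y: np.ndarray, X: pd.DataFrame):
    Xc = sm.add_constant(X, has_constant="add")
    arr = np.asarray(Xc, dtype=float)
    rank = np.linalg.matrix_rank(arr)
    if rank < arr.shape[1]:
        raise ValueError(f"rank-deficient design ({rank} < {arr.shape[1]}); columns {list(Xc.columns)}")
    return sm.OLS(y, Xc).fit()


def partial_regression_residuals(
    table: pd.DataFrame,
    covariates: list[str],
    response: str,
    by_group: str = "group",
    fit: str = "pooled",
) -> dict:
    """OLS of the response on the covariates; residuals split by condition.

    Regressing out heart-rate, muscle-fatigue and pleasure changes leaves
    residual variation attributable to the manipulated prediction error,
    which is then compared across conditions by permutation.

    ``fit="pooled"`` (default) fits one covariate model over all rows so a
    condition-specific shift survives into the residuals; ``fit="per_group"``
    fits separately per condition — note that the per-condition intercept
    then absorbs any mean shift, leaving only shape/variance differences.
    """
    out = {}
    if fit == "pooled":
        model = _ols(np.asarray(table[response], dtype=float), table[covariates])
        resid = np.asarray(model.resid)
        for g, idx in table.groupby(by_group, sort=True).indices.items():
            out[g] = resid[idx]
    elif fit == "per_group":
        for g, sub in table.groupby(by_group, sort=True):
            m = _ols(np.asarray(sub[response], dtype=float), sub[covariates])
            out[g] = np.asarray(m.resid)
    else:
        raise ValueError(f"unknown fit mode {fit!r}")
    return out


def _build_design(table: pd.DataFrame, terms: list[str]) -> pd.DataFrame:
    cols = {}
    for term in terms:
        if ":" in term:
            parts = term.split(":")
            col = np.ones(len(table))
            for p in parts:
                col = col * np.asarray(table[p], dtype=float)
            cols[term] = col
        else:
            cols[term] = np.asarray(table[term], dtype=float)
    return pd.DataFrame(cols, index=table.index)


def fit_regression(table: pd.DataFrame, response: str, terms: list[str]) -> pd.DataFrame:
    """OLS with main effects and ':'-separated interaction products.

    Returns one row per term (plus the intercept) with estimate, standard
    error, two-sided p-value and 95% CI.
    """
    X = _build_design(table, terms)
    if len(table) <= X.shape[1]:
        raise ValueError("not enough rows for the number of terms")
    fit = _ols(np.asarray(table[response], dtype=float), X)
    ci = fit.conf_int()
    return pd.DataFrame(
        {
            "term": fit.params.index,
            "estimate": fit.params.values,
            "se": fit.bse.values,
            "p": fit.pvalues.values,
            "ci_lo": np.asarray(ci)[:, 0],
            "ci_hi": np.asarray(ci)[:, 1],
        }
    )


def compare_nested_regressions(
    table: pd.DataFrame,
    response: str,
    full_terms: list[str],
    drop_sets: dict[str, list[str]],
    unit_col: str = "subject",
    n_perm: int = 5000,
    seed: int | None = 0,
) -> dict:
    """Compare a full regression against variants with terms deleted.

    Each variant is fitted on the pooled rows; per-unit residual sums of
    squares yield per-unit AIC/BIC (same parameterization as the model
    selection), and variants are compared pairwise by paired sign-flip
    permutation on those distributions.
    """
    variants = {"full": full_terms}
    for name, dropped in drop_sets.items():
        kept = [t for t in full_terms if t not in dropped]
        if not kept:
            raise ValueError(f"variant {name!r} drops every term")
        variants[name] = kept
    units = table[unit_col].to_numpy()
    unit_ids = np.unique(units)
    per_unit: dict[str, dict[str, np.ndarray]] = {}
    coef_tables = {}
    for name, terms in variants.items():
        X = _build_design(table, terms)
        fit = _ols(np.asarray(table[response], dtype=float), X)
        coef_tables[name] = fit.params
        resid = np.asarray(fit.resid)
        k = X.shape[1] + 1  # + intercept
        aics, bics = [], []
        for u in unit_ids:
            r = resid[units == u]
            err = float(np.sum(r**2))
            aics.append(model_aic(k, r.size, max(err, 1e-12)))
            bics.append(model_bic(k, r.size, max(err, 1e-12)))
        per_unit[name] = {"aic": np.asarray(aics), "bic": np.asarray(bics)}
    rng = np.random.default_rng(seed)
    pairwise = {}
    names = list(variants)
    for a, b in itertools.combinations(names, 2):
        pairwise[(a, b)] = {
            "delta_aic_mean": float(np.mean(per_unit[a]["aic"] - per_unit[b]["aic"])),
            "delta_bic_mean": float(np.mean(per_unit[a]["bic"] - per_unit[b]["bic"])),
            "p_aic": unpaired_perm_p(per_unit[a]["aic"], per_unit[b]["aic"], n_perm, rng),
            "p_bic": unpaired_perm_p(per_unit[a]["bic"], per_unit[b]["bic"], n_perm, rng),
        }
    return {"per_unit": per_unit, "pairwise": pairwise, "coefficients": coef_tables}


def unpaired_perm_p(a: np.ndarray, b: np.ndarray, n_perm: int, rng: np.random.Generator) -> float:
    """Two-sided unpaired permutation p for a mean difference (vectorized)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    obs = abs(a.mean() - b.mean())
    pooled = np.concatenate([a, b])
    if np.allclose(pooled, pooled[0]):
        return 1.0
    n, na = pooled.size, a.size
    perms = np.argsort(rng.random((n_perm, n)), axis=1)
    permuted = pooled[perms]
    stats = np.abs(permuted[:, :na].mean(axis=1) - permuted[:, na:].mean(axis=1))
    return float((1 + np.sum(stats >= obs - 1e-12)) / (n_perm + 1))


def _boot_slopes(x: np.ndarray, y: np.ndarray, n_boot: int, rng) -> tuple[float, np.ndarray]:
    n = x.size
    vx = x.var()
    if vx <= 0:
        raise ValueError("zero-variance regressor")
    slope = float(np.cov(x, y, bias=True)[0, 1] / vx)
    idx = rng.integers(0, n, size=(n_boot, n))
    xs, ys = x[idx], y[idx]
    mx = xs.mean(axis=1)
    my = ys.mean(axis=1)
    cov = (xs * ys).mean(axis=1) - mx * my
    var = (xs**2).mean(axis=1) - mx**2
    var = np.where(var <= 0, np.nan, var)
    return slope, cov / var


def bootstrap_slope_comparison(
    table: pd.DataFrame,
    x: str,
    y: str,
    group_col: str = "group",
    n_boot: int = 5000,
    seed: int | None = 0,
) -> dict:
    """Compare the slope of y on x across conditions by bootstrap.

    Rows are resampled with replacement within each condition; pairwise
    slope differences get percentile 95% CIs and a two-sided bootstrap p
    (twice the smaller tail probability of the difference distribution
    crossing zero).
    """
    rng = np.random.default_rng(seed)
    slopes, dists = {}, {}
    for g, sub in table.groupby(group_col, sort=True):
        if len(sub) < 10:
            raise ValueError(f"condition {g!r} has fewer than 10 rows")
        xv = np.asarray(sub[x], dtype=float)
        yv = np.asarray(sub[y], dtype=float)
        slopes[g], dists[g] = _boot_slopes(xv, yv, n_boot, rng)
    pairwise = {}
    for a, b in itertools.combinations(sorted(slopes), 2):
        d = dists[a] - dists[b]
        d = d[np.isfinite(d)]
        lo, hi = np.percentile(d, [2.5, 97.5])
        p = 2 * min(float(np.mean(d <= 0)), float(np.mean(d >= 0)))
        pairwise[(a, b)] = {
            "slope_diff": slopes[a] - slopes[b],
            "ci": (float(lo), float(hi)),
            "p": min(max(p, 1.0 / n_boot), 1.0),
        }
    return {"slopes": slopes, "pairwise": pairwise, "n_boot": n_boot, "seed": seed}


def distortion_regression(
    perceived, actual, fi, group_codes
) -> pd.DataFrame:
    """Sensory-distortion regression: |perceived − actual| on FI + condition.

    One row per subject×condition session; the Fatigue Index coefficient
    quantifies how much worse fatigued participants judge total exercise
    duration/distance, controlling for the condition code
    (standard=1, advanced=2, delayed=3).
    """
    perceived = np.asarray(perceived, dtype=float)
    actual = np.asarray(actual, dtype=float)
    distortion = np.abs(perceived - actual)
    tab = pd.DataFrame(
        {
            "distortion": distortion,
            "fi": np.asarray(fi, dtype=float),
            "condition": np.asarray(group_codes, dtype=float),
        }
    )
    return fit_regression(tab, "distortion", ["fi", "condition"])
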