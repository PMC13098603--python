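"""Resampling inference: permutation, paired tests, regressions, bootstrap."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from fatiperc import stats


# ----------------------------------------------------------- permutation


def test_permutation_identical_samples_p_one():
    res = stats.permutation_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert res.p_value == pytest.approx(1.0)
    assert res.method == "exhaustive"


def test_permutation_small_sample_exact_p():
    res = stats.permutation_test([1.0, 2.0], [10.0, 11.0])
    assert res.p_value == pytest.approx(2.0 / 6.0)


def test_permutation_matches_bruteforce_enumeration_oracle():
    """Independent oracle: enumerate every label assignment directly."""
    rng = np.random.default_rng(5)
    for nx, ny in [(3, 3), (4, 4), (3, 5)]:
        x = rng.normal(size=nx)
        y = rng.normal(1.0, 1.0, size=ny)
        res = stats.permutation_test(x, y)
        pooled = np.concatenate([x, y])
        obs = abs(x.mean() - y.mean())
        count, total = 0, 0
        for combo in itertools.combinations(range(nx + ny), nx):
            sel = np.zeros(nx + ny, dtype=bool)
            sel[list(combo)] = True
            t = abs(pooled[sel].mean() - pooled[~sel].mean())
            count += t >= obs - 1e-12
            total += 1
        assert res.p_value == pytest.approx(count / total)
        assert total == math.comb(nx + ny, nx)


def test_permutation_montecarlo_seed_deterministic():
    rng = np.random.default_rng(0)
    x = rng.normal(size=40)
    y = rng.normal(0.3, 1.0, size=40)
    a = stats.permutation_test(x, y, n_perm=500, seed=9)
    b = stats.permutation_test(x, y, n_perm=500, seed=9)
    assert a.p_value == b.p_value
    assert a.method == "montecarlo"
    assert a.p_value >= 1.0 / 501.0


def test_permutation_paired_signflip():
    pre = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
    post = pre + np.array([0.1, -0.1, 0.05, 0.0, -0.05])
    res = stats.permutation_test(post, pre, paired=True)
    assert res.method == "paired-exhaustive"
    assert res.p_value > 0.5  # no systematic shift


# ------------------------------------------------------------ paired test


def test_paired_pre_post_no_change():
    pre = np.array([3.0, 4.0, 5.0, 4.0])
    res = stats.paired_pre_post_test(pre, pre)
    assert res.p_value == pytest.approx(1.0)
    assert res.effect_size == 0.0


def test_paired_pre_post_constant_shift_degenerate():
    pre = np.array([3.0, 4.0, 5.0])
    with pytest.raises(ValueError):
        stats.paired_pre_post_test(pre, pre + 1.0)


def test_paired_effect_size_recovery():
    rng = np.random.default_rng(2)
    ds = []
    for _ in range(300):
        pre = rng.normal(size=30)
        post = pre + rng.normal(1.0, 1.0, size=30)
        ds.append(stats.paired_pre_post_test(pre, post).effect_size)
    assert np.mean(ds) == pytest.approx(1.0, abs=0.1)


def test_paired_wilcoxon_available():
    rng = np.random.default_rng(3)
    pre = rng.normal(size=20)
    res = stats.paired_pre_post_test(pre, pre + rng.normal(1.0, 0.5, size=20), method="wilcoxon")
    assert res.p_value < 0.01


# ------------------------------------------------------- partial regression


def test_partial_regression_exact_linear_response_zero_residuals():
    rng = np.random.default_rng(4)
    n = 60
    tab = pd.DataFrame(
        {
            "hr": rng.normal(size=n),
            "mf": rng.normal(size=n),
            "pleasure": rng.normal(size=n),
            "group": np.repeat(["a", "b", "c"], n // 3),
        }
    )
    tab["dsf"] = 2.0 * tab["hr"] - 1.0 * tab["mf"] + 0.5 * tab["pleasure"] + 3.0
    res = stats.partial_regression_residuals(tab, ["hr", "mf", "pleasure"], "dsf")
    for resid in res.values():
        assert np.max(np.abs(resid)) < 1e-10


def test_partial_regression_independent_covariates_keep_variance():
    rng = np.random.default_rng(5)
    n = 3000
    tab = pd.DataFrame(
        {
            "hr": rng.normal(size=n),
            "mf": rng.normal(size=n),
            "pleasure": rng.normal(size=n),
            "dsf": rng.normal(size=n),
            "group": "all",
        }
    )
    resid = stats.partial_regression_residuals(tab, ["hr", "mf", "pleasure"], "dsf")["all"]
    assert resid.var() == pytest.approx(tab["dsf"].var(), rel=0.05)


def test_partial_regression_detects_group_shift():
    rng = np.random.default_rng(6)
    frames = []
    for g, shift in [("a", 0.0), ("b", 0.0), ("c", 1.0)]:
        n = 30
        f = pd.DataFrame({"hr": rng.normal(size=n), "mf": rng.normal(size=n), "group": g})
        f["dsf"] = 0.5 * f["hr"] + shift + 0.5 * rng.normal(size=n)
        frames.append(f)
    tab = pd.concat(frames, ignore_index=True)
    res = stats.partial_regression_residuals(tab, ["hr", "mf"], "dsf")
    cmp = stats.permutation_test(res["a"], res["c"], n_perm=2000, seed=0)
    assert cmp.p_value < 0.05


def test_partial_regression_collinear_covariates_rejected():
    tab = pd.DataFrame({"x1": [1.0, 2.0, 3.0, 4.0], "x2": [2.0, 4.0, 6.0, 8.0], "y": [1.0, 2.0, 3.0, 4.0], "group": "g"})
    with pytest.raises(ValueError, match="rank"):
        stats.partial_regression_residuals(tab, ["x1", "x2"], "y")


# ---------------------------------------------------------- fit_regression


def test_regression_noiseless_interaction_recovery():
    rng = np.random.default_rng(7)
    n = 50
    tab = pd.DataFrame({"x1": rng.normal(size=n), "x2": rng.normal(size=n)})
    tab["y"] = 2.0 * tab["x1"] - 3.0 * tab["x1"] * tab["x2"]
    out = stats.fit_regression(tab, "y", ["x1", "x2", "x1:x2"]).set_index("term")
    assert out.loc["x1", "estimate"] == pytest.approx(2.0, abs=1e-10)
    assert out.loc["x1:x2", "estimate"] == pytest.approx(-3.0, abs=1e-10)
    assert out.loc["x2", "estimate"] == pytest.approx(0.0, abs=1e-10)


def test_regression_null_calibration():
    rng = np.random.default_rng(8)
    rejections = 0
    reps = 400
    for _ in range(reps):
        tab = pd.DataFrame({"x1": rng.normal(size=25), "y": rng.normal(size=25)})
        out = stats.fit_regression(tab, "y", ["x1"]).set_index("term")
        rejections += out.loc["x1", "p"] < 0.05
    assert rejections / reps == pytest.approx(0.05, abs=0.03)


def test_regression_interaction_recovery_with_noise():
    rng = np.random.default_rng(9)
    n = 360
    tab = pd.DataFrame({"cond": rng.integers(1, 4, size=n).astype(float), "mf": rng.normal(size=n)})
    tab["y"] = 0.5 * tab["cond"] + 1.0 * tab["mf"] - 0.4 * tab["cond"] * tab["mf"] + 0.3 * rng.normal(size=n)
    out = stats.fit_regression(tab, "y", ["cond", "mf", "cond:mf"]).set_index("term")
    row = out.loc["cond:mf"]
    assert row["ci_lo"] <= -0.4 <= row["ci_hi"]
    assert row["p"] < 0.001


# ------------------------------------------------------- nested regressions


def _nested_cohort(seed=0, cond_effect=0.6, hr_effect=0.0, n_sub=12, reps=4):
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_sub):
        for cond in (1.0, 2.0, 3.0):
            for _ in range(reps):
                hr = rng.normal()
                mf = rng.normal()
                pl = rng.normal()
                y = cond_effect * cond + hr_effect * hr + 1.0 * mf + 0.4 * rng.normal()
                rows.append(
                    {"subject": s, "condition": cond, "hr": hr, "mf": mf, "pleasure": pl, "dsf": y}
                )
    return pd.DataFrame(rows)


def test_dropping_true_condition_effect_worsens_aic():
    tab = _nested_cohort(seed=1, cond_effect=0.8)
    out = stats.compare_nested_regressions(
        tab,
        "dsf",
        ["condition", "hr", "mf", "pleasure"],
        {"no_condition": ["condition"], "no_hr": ["hr"]},
        n_perm=500,
        seed=0,
    )
    pair = out["pairwise"][("full", "no_condition")]
    assert pair["delta_aic_mean"] < 0  # full fits better
    assert pair["p_aic"] < 0.05


def test_dropping_absent_hr_effect_changes_little():
    tab = _nested_cohort(seed=2, cond_effect=0.8, hr_effect=0.0)
    out = stats.compare_nested_regressions(
        tab,
        "dsf",
        ["condition", "hr", "mf", "pleasure"],
        {"no_hr": ["hr"]},
        n_perm=500,
        seed=0,
    )
    assert out["pairwise"][("full", "no_hr")]["p_aic"] > 0.05


def test_identical_variants_delta_zero():
    tab = _nested_cohort(seed=3)
    out = stats.compare_nested_regressions(
        tab, "dsf", ["condition", "hr"], {"same": []}, n_perm=100, seed=0
    )
    assert out["pairwise"][("full", "same")]["delta_aic_mean"] == pytest.approx(0.0)
    assert out["pairwise"][("full", "same")]["p_aic"] == 1.0


# ---------------------------------------------------------------- bootstrap


def _slope_table(slopes, n=120, noise=0.5, seed=0):
    rng = np.random.default_rng(seed)
    frames = []
    for g, b in slopes.items():
        x = rng.normal(size=n)
        frames.append(pd.DataFrame({"x": x, "y": b * x + noise * rng.normal(size=n), "group": g}))
    return pd.concat(frames, ignore_index=True)


def test_bootstrap_detects_different_slopes():
    tab = _slope_table({"a": 1.0, "b": 3.0})
    out = stats.bootstrap_slope_comparison(tab, "x", "y", n_boot=2000, seed=1)
    lo, hi = out["pairwise"][("a", "b")]["ci"]
    assert hi < 0  # slope(a) - slope(b) clearly negative
    assert out["pairwise"][("a", "b")]["p"] < 0.05


def test_bootstrap_seed_deterministic():
    tab = _slope_table({"a": 1.0, "b": 1.0}, seed=2)
    r1 = stats.bootstrap_slope_comparison(tab, "x", "y", n_boot=500, seed=3)
    r2 = stats.bootstrap_slope_comparison(tab, "x", "y", n_boot=500, seed=3)
    assert r1["pairwise"][("a", "b")]["ci"] == r2["pairwise"][("a", "b")]["ci"]


def test_bootstrap_requires_enough_rows():
    tab = _slope_table({"a": 1.0, "b": 1.0}, n=5)
    with pytest.raises(ValueError):
        stats.bootstrap_slope_comparison(tab, "x", "y")


# --------------------------------------------------------------- distortion


def test_distortion_zero_when_perception_perfect():
    n = 30
    rng = np.random.default_rng(10)
    actual = rng.uniform(900, 1500, size=n)
    fi = rng.uniform(1.0, 1.5, size=n)
    codes = rng.integers(1, 4, size=n)
    out = stats.distortion_regression(actual, actual, fi, codes).set_index("term")
    assert out.loc["fi", "estimate"] == pytest.approx(0.0, abs=1e-10)


def test_distortion_shuffled_fi_rarely_significant():
    rng = np.random.default_rng(11)
    hits = 0
    reps = 200
    for _ in range(reps):
        n = 90
        fi = rng.uniform(1.0, 1.5, size=n)
        codes = np.tile([1.0, 2.0, 3.0], n // 3)
        actual = np.full(n, 1200.0)
        perceived = actual + 100.0 * codes + 5.0 * rng.normal(size=n)
        out = stats.distortion_regression(
            perceived, actual, rng.permutation(fi), codes
        ).set_index("term")
        hits += out.loc["fi", "p"] < 0.05
    assert hits / reps <= 0.10
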