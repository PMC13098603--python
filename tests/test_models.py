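"""Model library, constrained fitting, information criteria, selection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import fatiperc as fp
from fatiperc import models
from fatiperc.models import (
    ModelSpec,
    aic,
    apply_form,
    bic,
    candidate_forms,
    compare_model_groups,
    evaluate_model,
    fit_model,
    model_library,
    select_best_form,
)
from fatiperc.simulate import CANONICAL_WINNERS


# ------------------------------------------------------------------ forms


@pytest.mark.parametrize(
    "form, x, expected",
    [("lin", 3.0, 3.0), ("par", 3.0, 9.0), ("hyp", 2.0, 0.5), ("exp", 0.0, 1.0)],
)
def test_elementary_forms(form, x, expected):
    assert apply_form(form, np.array([x]))[0] == pytest.approx(expected)


def test_candidate_forms_lists_all_four():
    assert set(candidate_forms("TE")) == {"lin", "par", "hyp", "exp"}


def test_hyperbola_with_coefficients():
    # a/x + b with a=2, b=1 at x=2 -> 2
    spec = ModelSpec(1, "temporal", ((("error", "hyp"),), ()))
    assert evaluate_model(spec, (2.0, 1.0), {"error": np.array([2.0])})[0] == pytest.approx(2.0)


# ---------------------------------------------------------------- library


def test_temporal_library_contains_canonical_group1_winner():
    lib = model_library("temporal", groups=(1,))
    assert CANONICAL_WINNERS[(1, "temporal")] in lib


def test_spatial_library_excludes_hyperbolic_error():
    lib = model_library("spatial")
    for spec in lib:
        for term in spec.terms:
            assert ("error", "hyp") not in term


def test_every_canonical_winner_is_in_its_library():
    for (group, modality), spec in CANONICAL_WINNERS.items():
        lib = model_library(modality, groups=(group,))
        assert spec in lib


def test_library_parameter_counts():
    for spec in model_library("temporal"):
        assert spec.k == (3 if spec.group == 5 else 2)


# --------------------------------------------------------------- evaluate


def test_evaluate_group4_temporal_example():
    spec = CANONICAL_WINNERS[(4, "temporal")]
    rows = {"error": np.array([1.0]), "mf": np.array([2.0])}
    assert evaluate_model(spec, (1.0, 1.0), rows)[0] == pytest.approx(5.0)


def test_evaluate_group4_spatial_example():
    spec = CANONICAL_WINNERS[(4, "spatial")]
    rows = {"error": np.array([0.0]), "mf": np.array([1.0])}
    assert evaluate_model(spec, (2.0, 3.0), rows)[0] == pytest.approx(2.0)


def test_evaluate_group5_zeroed_terms():
    spec = CANONICAL_WINNERS[(5, "temporal")]
    rows = {"error": np.array([1.0]), "mf": np.array([0.0]), "hr": np.array([0.7])}
    assert evaluate_model(spec, (0.0, 0.0, 1.0), rows)[0] == pytest.approx(0.7)


def test_hyperbolic_division_by_zero_names_row():
    spec = CANONICAL_WINNERS[(4, "temporal")]
    rows = {"error": np.array([1.0, 0.0]), "mf": np.array([1.0, 1.0])}
    with pytest.raises(ZeroDivisionError, match="rows \\[1\\]"):
        evaluate_model(spec, (1.0, 1.0), rows)


# --------------------------------------------------------------- criteria


def test_aic_bic_closed_forms():
    assert aic(2, 12, 1.0) == pytest.approx(4.0)
    assert bic(2, 12, 1.0) == pytest.approx(2.0 * np.log(12.0))
    assert aic(1, 10, np.e) == pytest.approx(12.0)


@settings(max_examples=40, deadline=None)
@given(
    k=st.integers(1, 5),
    n=st.integers(2, 500),
    err=st.floats(1e-6, 1e6),
    factor=st.floats(1.01, 100.0),
)
def test_aic_bic_strictly_increasing_in_err_and_k(k, n, err, factor):
    assert aic(k, n, err * factor) > aic(k, n, err)
    assert bic(k, n, err * factor) > bic(k, n, err)
    assert aic(k + 1, n, err) > aic(k, n, err)
    assert bic(k + 1, n, err) > bic(k, n, err)


def test_perfect_fit_error_floor_warns():
    with pytest.warns(RuntimeWarning):
        assert aic(2, 10, 0.0) == pytest.approx(4.0 + 10 * np.log(1e-12))


# ---------------------------------------------------------------- fitting


def _mg1_table(a=0.8, b=0.5, n=24, noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    te = rng.uniform(-2.0, 2.0, size=n)
    y = a * te**2 + b + noise * rng.normal(size=n)
    return pd.DataFrame({"error": te, "sf_norm": y, "subject": np.repeat(np.arange(n // 4), 4), "block": np.tile(np.arange(1, 5), n // 4), "group": "standard"})


def test_fit_model_noiseless_recovery():
    spec = CANONICAL_WINNERS[(1, "temporal")]
    fit = fit_model(spec, _mg1_table())
    assert fit.params == pytest.approx((0.8, 0.5), rel=1e-6)


def test_fit_model_multistart_matches_exact_and_beats_every_start():
    spec = CANONICAL_WINNERS[(1, "temporal")]
    tab = _mg1_table(noise=0.3, seed=2)
    exact = fit_model(spec, tab)
    multi = fit_model(spec, tab, method="multistart", n_restarts=10, seed=7)
    assert multi.err_sf == pytest.approx(exact.err_sf, rel=1e-6)
    A = models.design_matrix(spec, tab)
    y = tab["sf_norm"].to_numpy()
    rng = np.random.default_rng(7)
    for _ in range(10):
        x0 = rng.uniform(0, 1, size=spec.k)
        assert multi.err_sf <= np.sum((A @ x0 - y) ** 2) + 1e-9


def test_fit_model_same_seed_identical():
    spec = CANONICAL_WINNERS[(1, "temporal")]
    tab = _mg1_table(noise=0.3, seed=3)
    a = fit_model(spec, tab, method="multistart", n_restarts=5, seed=11)
    b = fit_model(spec, tab, method="multistart", n_restarts=5, seed=11)
    assert a.params == b.params and a.err_sf == b.err_sf


def test_fit_model_positivity_bound_active_when_truth_negative():
    rng = np.random.default_rng(5)
    te = rng.uniform(0.5, 2.0, size=40)
    y = -1.0 * te + 0.2  # negative slope truth, constraint must bind
    tab = pd.DataFrame({"error": te, "sf_norm": y})
    spec = ModelSpec(1, "temporal", ((("error", "lin"),), ()))
    fit = fit_model(spec, tab)
    assert fit.params[0] >= models.PARAM_LOWER_BOUND * 0.999
    assert fit.params[0] < 1e-6


def test_fit_model_underdetermined_rejected():
    spec = CANONICAL_WINNERS[(1, "temporal")]
    with pytest.raises(ValueError):
        fit_model(spec, _mg1_table().head(2))


def test_fit_profiling_oracle_on_fixed_intercept_grid():
    """Independent check: profile the slope in closed form over a b-grid."""
    spec = CANONICAL_WINNERS[(1, "temporal")]
    tab = _mg1_table(noise=0.25, seed=9)
    fit = fit_model(spec, tab)
    phi = tab["error"].to_numpy() ** 2
    y = tab["sf_norm"].to_numpy()
    lb = models.PARAM_LOWER_BOUND
    best = np.inf
    for b in np.linspace(lb, 2.0, 4001):
        a = max((phi * (y - b)).sum() / (phi * phi).sum(), lb)
        best = min(best, np.sum((a * phi + b - y) ** 2))
    assert fit.err_sf == pytest.approx(best, abs=1e-6)


def test_nested_spec_never_fits_worse():
    tab = _mg1_table(noise=0.4, seed=4)
    tab["mf"] = np.random.default_rng(0).normal(size=len(tab))
    small = ModelSpec(3, "temporal", ((("mf", "par"),), (("error", "par"),)))
    # group-5-style superset of the same terms plus an extra regressor
    big = ModelSpec(5, "temporal", ((("mf", "par"),), (("error", "par"),), (("mf", "lin"),)))
    tab["hr"] = 0.0
    f_small = fit_model(small, tab, sf_col="sf_norm")
    f_big = fit_model(big, tab, sf_col="sf_norm")
    # the extra coefficient can sit no lower than the positivity bound 1e-8,
    # so the nested optimum may be exceeded by an O(bound) sliver
    assert f_big.err_sf <= f_small.err_sf + 1e-6


# -------------------------------------------------------------- selection


def test_select_best_form_recovers_parabola():
    rng = np.random.default_rng(6)
    n_sub = 12
    te = rng.uniform(-2, 2, size=n_sub * 4)
    y = 0.9 * te**2 + 0.4 + 0.1 * rng.normal(size=te.size)
    tab = pd.DataFrame(
        {
            "error": te,
            "sf_norm": y,
            "subject": np.repeat(np.arange(n_sub), 4),
            "block": np.tile(np.arange(1, 5), n_sub),
            "group": "standard",
        }
    )
    specs = model_library("temporal", groups=(1,))
    best = select_best_form(specs, tab, fit_unit="pooled")
    assert best.spec == CANONICAL_WINNERS[(1, "temporal")]


def test_select_best_form_single_spec_passthrough(temporal_cohort):
    spec = CANONICAL_WINNERS[(4, "temporal")]
    best = select_best_form([spec], temporal_cohort.features, sf_col="sf_model")
    assert best.spec == spec


def test_select_best_form_duplicate_specs_deterministic(temporal_cohort):
    spec = CANONICAL_WINNERS[(4, "temporal")]
    best = select_best_form([spec, spec], temporal_cohort.features, sf_col="sf_model")
    assert best.spec == spec


def test_compare_model_groups_recovers_generating_group(temporal_cohort):
    cmp = compare_model_groups(
        temporal_cohort.features, "temporal", sf_col="sf_model", seed=0, n_perm=200
    )
    assert cmp.winner_group == 4
    assert cmp.best[4].spec == CANONICAL_WINNERS[(4, "temporal")]


def test_compare_model_groups_mg1_truth_does_not_make_mg1_worst():
    truth = fp.simulate.GroundTruth(
        model_form=CANONICAL_WINNERS[(1, "temporal")], params=(0.8, 0.5), noise_sd=0.2
    )
    c = fp.simulate_feature_cohort(15, "temporal", truth, seed=21)
    cmp = compare_model_groups(c.features, "temporal", sf_col="sf_model", seed=0, n_perm=200)
    ranks = sorted(cmp.best, key=lambda g: cmp.best[g].mean_aic)
    assert ranks[-1] != 1  # error-only family is not the worst under its own truth


def test_identical_criterion_vectors_give_p_one():
    rng = np.random.default_rng(0)
    v = np.full(20, 3.3)
    assert models._unpaired_perm_p(v, v, 500, rng) == 1.0
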