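"""Candidate model library and constrained least-squares model selection.

Five nested model groups relate the per-block normalized subjective-fatigue
rating SF to the standardized sensory prediction error E (temporal TE or
spatial SE), the standardized muscle-fatigue score MF, and the standardized
heart-rate change HR:

* group 1 — prediction error only:        SF = a·g(E) + b
* group 2 — muscle fatigue only:          SF = a·g(MF) + b
* group 3 — additive error + fatigue:     SF = a·gM(MF) + b·gE(E)
* group 4 — error×fatigue interaction:    SF = a·gE1(E)·gM(MF) + b·gE2(E)
* group 5 — group-4 skeleton + heart rate: SF = a·gE1(E)·gM(MF) + b·gE2(E) + c·gH(HR)

where every g is one of four elementary forms — linear x, parabola x²,
hyperbola 1/x, exponential e^x — and a, b, c are constrained to be positive.
Hyperbolic forms of a variable are excluded whenever that variable contains
exact zeros (in particular the spatial error, which is identically zero in
the standard condition).

Goodness of fit is the residual sum of squares ERR_SF, and model comparison
uses the information criteria in the exact parameterization used throughout:

    AIC = 2k + n·ln(ERR_SF)        BIC = k·ln(n) + n·ln(ERR_SF)

(These differ from the textbook n·ln(ERR/n) forms by an n-dependent constant
that cancels whenever models are compared at equal n.)

Every candidate form is linear in its coefficients, so the positivity-
constrained least-squares problem is convex with a unique optimum; the
default fitting path computes it exactly by enumerating active sets of the
bound constraints, vectorized across fit units. A multi-start bounded
trust-region-reflective path (the field's standard realization of bounded
Levenberg-Marquardt fitting) is available as ``method="multistart"`` and
agrees with the exact path to solver tolerance.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "FORM_NAMES",
    "ModelSpec",
    "ModelFit",
    "GroupSelection",
    "ComparisonResult",
    "candidate_forms",
    "apply_form",
    "model_library",
    "design_matrix",
    "evaluate_model",
    "aic",
    "bic",
    "fit_model",
    "select_best_form",
    "compare_model_groups",
]

FORM_NAMES = ("lin", "par", "hyp", "exp")

PARAM_LOWER_BOUND = 1e-8
ERR_FLOOR = 1e-12


def apply_form(form: str, x: np.ndarray) -> np.ndarray:
    """Apply one elementary form to a value or array."""
    x = np.asarray(x, dtype=float)
    if form == "lin":
        return x
    if form == "par":
        return x**2
    if form == "hyp":
        if np.any(x == 0):
            raise ZeroDivisionError("hyperbolic form evaluated at zero")
        return 1.0 / x
    if form == "exp":
        return np.exp(x)
    raise ValueError(f"unknown form {form!r}")


# A term is a product of (variable, form) factors; the empty term is the
# intercept (a column of ones).
Term = tuple[tuple[str, str], ...]


def _term_id(term: Term) -> str:
    if not term:
        return "1"
    return "*".join(f"{form}({var})" for var, form in term)


@dataclass(frozen=True)
class ModelSpec:
    """One candidate functional form for SF."""

    group: int
    modality: str
    terms: tuple[Term, ...]

    @property
    def k(self) -> int:
        return len(self.terms)

    @property
    def form_id(self) -> str:
        coeffs = "abc"
        parts = [f"{coeffs[i]}·{_term_id(t)}" for i, t in enumerate(self.terms)]
        return f"mg{self.group}:" + "+".join(parts)

    @property
    def variables(self) -> set[str]:
        return {var for term in self.terms for var, _ in term}


@dataclass(frozen=True)
class ModelFit:
    """Result of fitting one ModelSpec on one fit unit."""

    spec: ModelSpec
    params: tuple[float, ...]
    err_sf: float
    n: int
    k: int
    aic: float
    bic: float
    n_restarts: int
    converged: bool
    seed: int | None = None


def candidate_forms(variable: str = "x") -> dict[str, str]:
    """The four elementary single-variable forms a·g(x)+b, keyed by name."""
    return {
        "lin": f"a·{variable} + b",
        "par": f"a·{variable}² + b",
        "hyp": f"a/{variable} + b",
        "exp": f"a·e^{variable} + b",
    }


def _error_forms(exclude_hyperbolic_error: bool) -> tuple[str, ...]:
    return tuple(f for f in FORM_NAMES if not (exclude_hyperbolic_error and f == "hyp"))


def model_library(
    modality: str,
    groups: tuple[int, ...] = (1, 2, 3, 4, 5),
    exclude_hyperbolic_error: bool | None = None,
) -> list[ModelSpec]:
    """Every candidate spec for the requested model groups.

    ``exclude_hyperbolic_error`` defaults to True in the spatial modality,
    where the standard condition's error is exactly zero and 1/SE is
    undefined.
    """
    if modality not in ("temporal", "spatial"):
        raise ValueError(f"unknown modality {modality!r}")
    if exclude_hyperbolic_error is None:
        exclude_hyperbolic_error = modality == "spatial"
    e_forms = _error_forms(exclude_hyperbolic_error)
    specs: list[ModelSpec] = []
    for g in groups:
        if g == 1:
            for fe in e_forms:
                specs.append(ModelSpec(1, modality, ((("error", fe),), ())))
        elif g == 2:
            for fm in FORM_NAMES:
                specs.append(ModelSpec(2, modality, ((("mf", fm),), ())))
        elif g == 3:
            for fm, fe in itertools.product(FORM_NAMES, e_forms):
                specs.append(ModelSpec(3, modality, ((("mf", fm),), (("error", fe),))))
        elif g == 4:
            for fe1, fm, fe2 in itertools.product(e_forms, FORM_NAMES, e_forms):
                specs.append(
                    ModelSpec(4, modality, ((("error", fe1), ("mf", fm)), (("error", fe2),)))
                )
        elif g == 5:
            for fe1, fm, fe2, fh in itertools.product(e_forms, FORM_NAMES, e_forms, FORM_NAMES):
                specs.append(
                    ModelSpec(
                        5,
                        modality,
                        ((("error", fe1), ("mf", fm)), (("error", fe2),), (("hr", fh),)),
                    )
                )
        else:
            raise ValueError(f"unknown model group {g}")
    return specs


def design_matrix(spec: ModelSpec, rows: pd.DataFrame | dict) -> np.ndarray:
    """Regressor matrix Φ (n × k): model value is Φ @ (a, b, c…)."""
    cols = []
    for term in spec.terms:
        if not term:
            n = len(rows["error"]) if not isinstance(rows, pd.DataFrame) else len(rows)
            cols.append(np.ones(n))
            continue
        col = None
        for var, form in term:
            x = np.asarray(rows[var], dtype=float)
            try:
                fx = apply_form(form, x)
            except ZeroDivisionError as exc:
                bad = np.flatnonzero(x == 0)
                raise ZeroDivisionError(
                    f"{spec.form_id}: hyperbolic term 1/{var} undefined at rows {bad.tolist()}"
                ) from exc
            col = fx if col is None else col * fx
        cols.append(col)
    return np.column_stack(cols)


def evaluate_model(spec: ModelSpec, params, rows: pd.DataFrame | dict) -> np.ndarray:
    """Predicted SF for each row under the given parameters."""
    params = np.asarray(params, dtype=float)
    if params.size != spec.k:
        raise ValueError(f"{spec.form_id} expects {spec.k} parameters, got {params.size}")
    return design_matrix(spec, rows) @ params


def _floor_err(err: float) -> float:
    if err <= ERR_FLOOR:
        warnings.warn(
            f"ERR_SF={err:.3g} at or below floor {ERR_FLOOR}; clamping before log",
            RuntimeWarning,
            stacklevel=3,
        )
        return ERR_FLOOR
    return err


def aic(k: int, n: int, err: float) -> float:
    """AIC = 2k + n·ln(ERR_SF)."""
    if k < 1 or n < 1:
        raise ValueError("need k >= 1 and n >= 1")
    return 2.0 * k + n * float(np.log(_floor_err(err)))


def bic(k: int, n: int, err: float) -> float:
    """BIC = k·ln(n) + n·ln(ERR_SF)."""
    if k < 1 or n < 1:
        raise ValueError("need k >= 1 and n >= 1")
    return k * float(np.log(n)) + n * float(np.log(_floor_err(err)))


# ---------------------------------------------------------------------------
# bounded least squares
# ---------------------------------------------------------------------------


def _bounded_lstsq_batch(A: np.ndarray, y: np.ndarray, lb: float) -> tuple[np.ndarray, np.ndarray]:
    """Exact solution of min ||A p − y||² s.t. p >= lb, batched over units.

    A has shape (U, n, k), y has shape (U, n). The objective is convex, so
    the optimum is found by enumerating the 2^k possible active sets of the
    lower bounds, solving the free coordinates by (pseudo-inverse) least
    squares with the active ones clamped at lb, and keeping the best
    feasible candidate per unit.
    """
    U, n, k = A.shape
    best_p = np.full((U, k), lb)
    resid0 = y - A @ np.full(k, lb)
    best_sse = np.einsum("un,un->u", resid0, resid0)
    for mask in itertools.product([False, True], repeat=k):
        free = np.array(mask)
        if not free.any():
            continue  # all-clamped candidate already evaluated
        fixed = ~free
        Af = A[:, :, free]
        resid_target = y - A[:, :, fixed] @ np.full(int(fixed.sum()), lb)
        pf = np.einsum("ukn,un->uk", np.linalg.pinv(Af), resid_target)
        feasible = np.all(pf >= lb - 1e-12, axis=1)
        if not feasible.any():
            continue
        p_full = np.full((U, k), lb)
        p_full[:, free] = np.clip(pf, lb, None)
        resid = y - np.einsum("unk,uk->un", A, p_full)
        sse = np.einsum("un,un->u", resid, resid)
        better = feasible & (sse < best_sse)
        best_p[better] = p_full[better]
        best_sse[better] = sse[better]
    return best_p, best_sse


def _fit_multistart(
    A: np.ndarray, y: np.ndarray, n_restarts: int, seed: int | None, lb: float
) -> tuple[np.ndarray, float, bool]:
    """Multi-start bounded nonlinear least squares (trust-region reflective).

    Initial draws are uniform in the open interval (0, 1), one fit per
    restart; the best restart is returned.
    """
    rng = np.random.default_rng(seed)
    k = A.shape[1]
    best_p, best_sse, ok = None, np.inf, False
    for _ in range(max(n_restarts, 1)):
        x0 = rng.uniform(0.0, 1.0, size=k)
        try:
            res = least_squares(
                lambda p: A @ p - y,
                x0,
                jac=lambda p: A,
                bounds=(lb, np.inf),
                method="trf",
            )
        except Exception:
            continue
        sse = 2.0 * res.cost
        if sse < best_sse:
            best_p, best_sse, ok = res.x, sse, bool(res.success)
    if best_p is None:
        raise RuntimeError("all restarts failed to converge")
    return best_p, float(best_sse), ok


def fit_model(
    spec: ModelSpec,
    table: pd.DataFrame,
    n_restarts: int = 50,
    seed: int | None = None,
    method: str = "exact",
    sf_col: str = "sf_norm",
    lb: float = PARAM_LOWER_BOUND,
) -> ModelFit:
    """Fit one spec on one table by positivity-constrained least squares.

    ``method="exact"`` (default) solves the convex problem directly;
    ``method="multistart"`` runs ``n_restarts`` seeded bounded
    trust-region-reflective fits from random draws in (0, 1) and keeps the
    best, mirroring classic multi-start practice for non-convex fits.
    """
    n = len(table)
    if n < spec.k + 1:
        raise ValueError(f"{spec.form_id}: {n} rows cannot identify {spec.k} parameters")
    A = design_matrix(spec, table)
    y = np.asarray(table[sf_col], dtype=float)
    if method == "exact":
        p, sse = _bounded_lstsq_batch(A[None], y[None], lb)
        params, err, converged = p[0], float(sse[0]), True
    elif method == "multistart":
        params, err, converged = _fit_multistart(A, y, n_restarts, seed, lb)
    else:
        raise ValueError(f"unknown method {method!r}")
    return ModelFit(
        spec=spec,
        params=tuple(float(v) for v in params),
        err_sf=err,
        n=n,
        k=spec.k,
        aic=aic(spec.k, n, err),
        bic=bic(spec.k, n, err),
        n_restarts=n_restarts if method == "multistart" else 1,
        converged=converged,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# selection across fit units
# ---------------------------------------------------------------------------


def _unit_frames(table: pd.DataFrame, fit_unit: str) -> list[pd.DataFrame]:
    if fit_unit == "pooled":
        return [table]
    if fit_unit == "subject":
        keys = ["subject"]
    elif fit_unit == "session":
        keys = ["subject", "group"]
    else:
        raise ValueError(f"unknown fit_unit {fit_unit!r}; use subject, session or pooled")
    return [g.sort_values("block", kind="stable") for _, g in table.groupby(keys, sort=True)]


def _batch_design(spec: ModelSpec, units: list[pd.DataFrame]) -> np.ndarray:
    return np.stack([design_matrix(spec, u) for u in units])


@dataclass
class GroupSelection:
    """Best form of one model group with its per-unit criteria."""

    spec: ModelSpec
    unit_aic: np.ndarray
    unit_bic: np.ndarray
    unit_err: np.ndarray
    unit_params: np.ndarray
    mean_aic: float = field(init=False)
    mean_bic: float = field(init=False)

    def __post_init__(self) -> None:
        self.mean_aic = float(np.mean(self.unit_aic))
        self.mean_bic = float(np.mean(self.unit_bic))


def _fit_spec_over_units(
    spec: ModelSpec, units: list[pd.DataFrame], sf_col: str, lb: float
) -> GroupSelection:
    A = _batch_design(spec, units)
    y = np.stack([np.asarray(u[sf_col], dtype=float) for u in units])
    params, sse = _bounded_lstsq_batch(A, y, lb)
    n = y.shape[1]
    err = np.maximum(sse, ERR_FLOOR)
    unit_aic = 2.0 * spec.k + n * np.log(err)
    unit_bic = spec.k * np.log(n) + n * np.log(err)
    return GroupSelection(spec, unit_aic, unit_bic, err, params)


def select_best_form(
    group_specs: list[ModelSpec],
    table: pd.DataFrame,
    fit_unit: str = "subject",
    sf_col: str = "sf_norm",
    lb: float = PARAM_LOWER_BOUND,
) -> GroupSelection:
    """Fit every spec on every unit; rank by mean AIC, ties by mean BIC, k.

    Specs whose design matrix cannot be built (hyperbolic term at zero) are
    skipped — the same rule that excludes 1/SE in the spatial modality.
    """
    if not group_specs:
        raise ValueError("need at least one spec")
    units = _unit_frames(table, fit_unit)
    results: list[GroupSelection] = []
    for spec in group_specs:
        try:
            results.append(_fit_spec_over_units(spec, units, sf_col, lb))
        except ZeroDivisionError:
            continue
    if not results:
        raise ValueError("no spec in the group is evaluable on this table")
    results.sort(key=lambda r: (r.mean_aic, r.mean_bic, r.spec.k, r.spec.form_id))
    return results[0]


@dataclass
class ComparisonResult:
    """Cross-group comparison of each group's best form."""

    modality: str
    fit_unit: str
    best: dict[int, GroupSelection]
    winner_group: int
    pairwise_aic_p: dict[tuple[int, int], float]
    pairwise_bic_p: dict[tuple[int, int], float]
    seed: int | None = None

    def summary(self) -> pd.DataFrame:
        rows = [
            {
                "group": g,
                "form_id": sel.spec.form_id,
                "k": sel.spec.k,
                "mean_aic": sel.mean_aic,
                "mean_bic": sel.mean_bic,
            }
            for g, sel in sorted(self.best.items())
        ]
        return pd.DataFrame(rows)


def _unpaired_perm_p(a: np.ndarray, b: np.ndarray, n_perm: int, rng: np.random.Generator) -> float:
    """Two-sided unpaired permutation test on two per-unit criterion samples."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    obs = abs(a.mean() - b.mean())
    pooled = np.concatenate([a, b])
    n, na = pooled.size, a.size
    perms = np.argsort(rng.random((n_perm, n)), axis=1)
    permuted = pooled[perms]
    stats = np.abs(permuted[:, :na].mean(axis=1) - permuted[:, na:].mean(axis=1))
    return float((1 + np.sum(stats >= obs - 1e-12)) / (n_perm + 1))


def compare_model_groups(
    table: pd.DataFrame,
    modality: str,
    fit_unit: str = "subject",
    seed: int | None = 0,
    sf_col: str = "sf_norm",
    groups: tuple[int, ...] = (1, 2, 3, 4, 5),
    n_perm: int = 2000,
    exclude_hyperbolic_error: bool | None = None,
) -> ComparisonResult:
    """Select each group's best form and compare groups on per-unit AIC/BIC.

    The winner minimizes the mean per-unit AIC among the group bests; the
    unpaired permutation tests report, for every pair of groups, whether
    their per-unit criterion distributions differ.
    """
    library = model_library(modality, groups, exclude_hyperbolic_error)
    best: dict[int, GroupSelection] = {}
    for g in groups:
        specs = [s for s in library if s.group == g]
        best[g] = select_best_form(specs, table, fit_unit=fit_unit, sf_col=sf_col)
    winner = min(best, key=lambda g: (best[g].mean_aic, best[g].mean_bic, best[g].spec.k))
    rng = np.random.default_rng(seed)
    p_aic: dict[tuple[int, int], float] = {}
    p_bic: dict[tuple[int, int], float] = {}
    for g1, g2 in itertools.combinations(sorted(best), 2):
        p_aic[(g1, g2)] = _unpaired_perm_p(best[g1].unit_aic, best[g2].unit_aic, n_perm, rng)
        p_bic[(g1, g2)] = _unpaired_perm_p(best[g1].unit_bic, best[g2].unit_bic, n_perm, rng)
    return ComparisonResult(
        modality=modality,
        fit_unit=fit_unit,
        best=best,
        winner_group=winner,
        pairwise_aic_p=p_aic,
        pairwise_bic_p=p_bic,
        seed=seed,
    )
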