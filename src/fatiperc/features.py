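"""Construction of the modelling table from per-block session aggregates.

One row per (subject, condition, block) with standardized columns:

* ``error`` — signed sensory prediction error (temporal TE in seconds or
  spatial SE in meters), standardized scale-only by default (divided by the
  pooled SD, no centering) so that a condition whose raw error is a nonzero
  constant keeps a nonzero constant value and a condition whose raw error is
  exactly zero stays exactly zero;
* ``mf`` — muscle-fatigue score: the first principal component of the two
  muscles' median-frequency changes from baseline (default), or the z-scored
  composite Fatigue Index for the robustness re-run;
* ``hr`` — z-scored block-mean heart-rate change from baseline;
* ``sf_norm`` — the subjective fatigue rating standardized within subject,
  SF̃ = (SF − avg(SF)) / std(SF), absorbing between-subject scale usage.

Baseline is the first block of each session — the only within-session
reference available in every condition.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

__all__ = [
    "zscore",
    "normalize_sf",
    "iqr_filter",
    "pc1_muscle_fatigue",
    "block_aggregate",
    "baseline_delta",
    "build_feature_table",
    "CONDITION_CODES_MAIN",
    "CONDITION_CODES_DISTORTION",
]

#: Numeric condition coding for the main regressions.
CONDITION_CODES_MAIN = {"advanced": 1, "standard": 2, "delayed": 3}
#: Coding used by the sensory-distortion regression.
CONDITION_CODES_DISTORTION = {"standard": 1, "advanced": 2, "delayed": 3}


def zscore(series, ddof: int = 1) -> np.ndarray:
    """Standardize to mean 0, sd 1 (sample sd by default)."""
    x = np.asarray(series, dtype=float)
    sd = x.std(ddof=ddof)
    if sd <= 0 or not np.isfinite(sd):
        raise ValueError("cannot z-score a constant series")
    return (x - x.mean()) / sd


def _scale_only(series, ddof: int = 1) -> np.ndarray:
    x = np.asarray(series, dtype=float)
    sd = x.std(ddof=ddof)
    if sd <= 0 or not np.isfinite(sd):
        raise ValueError("cannot scale a constant series")
    return x / sd


def normalize_sf(sf_per_subject, subject: str | int | None = None) -> np.ndarray:
    """Within-subject standardization of fatigue ratings.

    SF̃(i) = (SF(i) − avg(SF)) / std(SF) computed over one subject's ratings,
    making scale usage comparable across subjects. Affine-invariant: two
    subjects using different portions of the 1-7 scale but with proportional
    ratings get identical SF̃ series.
    """
    try:
        return zscore(sf_per_subject)
    except ValueError as exc:
        who = f" for subject {subject!r}" if subject is not None else ""
        raise ValueError(f"constant ratings{who}: cannot normalize") from exc


def iqr_filter(values, k: float = 1.5) -> np.ndarray:
    """Boolean keep-mask under Tukey fences [Q1 − k·IQR, Q3 + k·IQR].

    Quartiles use linear interpolation (type-7). Fewer than 4 values passes
    everything through with a warning.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 4:
        warnings.warn("fewer than 4 values: IQR filter passes all through", stacklevel=2)
        return np.ones(x.size, dtype=bool)
    q1, q3 = np.percentile(x, [25, 75])
    iqr = q3 - q1
    atol = 1e-9 * max(abs(q1), abs(q3), 1.0)  # keep exact ties when IQR = 0
    return (x >= q1 - k * iqr - atol) & (x <= q3 + k * iqr + atol)


def pc1_muscle_fatigue(mdf_a, mdf_b) -> tuple[np.ndarray, float]:
    """PC1 scores of two muscles' fatigue series and its variance share.

    Both columns are standardized before the PCA, and the sign of the
    component is fixed so that the scores correlate non-negatively with the
    mean of the two columns — a common decline in both muscles therefore
    always maps to the same direction of the score.
    """
    a = np.asarray(mdf_a, dtype=float)
    b = np.asarray(mdf_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 3:
        raise ValueError("need >= 3 paired observations")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("non-finite inputs")
    X = np.column_stack([zscore(a), zscore(b)])
    pca = PCA(n_components=1)
    scores = pca.fit_transform(X)[:, 0]
    colmean = X.mean(axis=1)
    if np.dot(scores, colmean) < 0:
        scores = -scores
    return scores, float(pca.explained_variance_ratio_[0])


def block_aggregate(
    table: pd.DataFrame, value_cols: list[str], by: list[str] | None = None
) -> pd.DataFrame:
    """Mean of each feature per block (and any extra grouping keys)."""
    by = by or ["block"]
    if table.empty:
        raise ValueError("empty feature table")
    grouped = table.groupby(by, sort=True)[value_cols].agg(["mean", "count"])
    for col in value_cols:
        empty = grouped[(col, "count")] == 0
        if empty.any():
            raise ValueError(f"no data for {col} in blocks {list(grouped.index[empty])}")
    out = grouped.xs("mean", axis=1, level=1).reset_index()
    return out


def baseline_delta(block_means, baseline: float) -> np.ndarray:
    """Per-block change from the baseline value."""
    if baseline is None or not np.isfinite(baseline):
        raise ValueError("missing or non-finite baseline")
    return np.asarray(block_means, dtype=float) - float(baseline)


def _session_deltas(df: pd.DataFrame, cols: list[str]) -> pd.DataFrame:
    """Baseline (block-1) deltas of ``cols`` within each subject×group."""
    out = df.copy()
    for col in cols:
        base = df[df["block"] == 1].set_index(["subject", "group"])[col]
        idx = pd.MultiIndex.from_frame(df[["subject", "group"]])
        base_vals = base.reindex(idx).to_numpy()
        if np.isnan(base_vals).any():
            missing = sorted(set(map(tuple, df.loc[np.isnan(base_vals), ["subject", "group"]].values)))
            raise ValueError(f"missing block-1 baseline for {col} in sessions {missing[:5]}")
        out["d_" + col] = df[col].to_numpy() - base_vals
    return out


def build_feature_table(
    block_table: pd.DataFrame,
    mf_metric: str = "pc1",
    standardize_errors: str = "scale",
    hr_mode: str = "delta",
    allow_missing_ratings: bool = False,
) -> pd.DataFrame:
    """Build the standardized modelling table from per-block aggregates.

    ``block_table`` needs one row per subject×group×block with columns
    ``subject, modality, group, block, error_raw, mdf_rectus, mdf_tibialis,
    hr_mean, fi, rating`` (plus optional ``pleasure`` and ``sf_model``).

    ``mf_metric`` selects the muscle-fatigue column: ``pc1`` (principal
    component of the two muscles' median-frequency deltas) or ``fi``
    (z-scored composite Fatigue Index). Switching the metric changes only
    the ``mf`` column.

    ``standardize_errors``: ``scale`` (pooled SD only; default), ``pooled``
    (full z-score) or ``none``.
    """
    if mf_metric not in ("pc1", "fi"):
        raise ValueError(f"unknown mf_metric {mf_metric!r}")
    if standardize_errors not in ("scale", "pooled", "none"):
        raise ValueError(f"unknown standardize_errors {standardize_errors!r}")
    modalities = block_table["modality"].unique()
    if len(modalities) != 1:
        raise ValueError("feature table is built per modality; got " + str(modalities))
    df = block_table.sort_values(["subject", "group", "block"], kind="stable").reset_index(drop=True)
    required = {"subject", "group", "block", "error_raw", "mdf_rectus", "mdf_tibialis", "hr_mean"}
    if not allow_missing_ratings:
        required = required | {"rating"}
    missing_cols = required - set(df.columns)
    if missing_cols:
        raise ValueError(f"block table missing columns {sorted(missing_cols)}")
    have_ratings = "rating" in df.columns and not df["rating"].isna().all()
    if not allow_missing_ratings and df["rating"].isna().any():
        bad = df.loc[df["rating"].isna(), ["subject", "group", "block"]].values.tolist()
        raise ValueError(f"missing block ratings: {bad[:5]}")

    df = _session_deltas(df, ["mdf_rectus", "mdf_tibialis", "hr_mean"])

    out = df[["subject", "modality", "group", "block"]].copy()
    out["condition"] = df["group"].map(CONDITION_CODES_MAIN)
    out["cond_distortion"] = df["group"].map(CONDITION_CODES_DISTORTION)
    out["error_raw"] = df["error_raw"].to_numpy()
    if standardize_errors == "scale":
        out["error"] = _scale_only(df["error_raw"])
    elif standardize_errors == "pooled":
        out["error"] = zscore(df["error_raw"])
    else:
        out["error"] = df["error_raw"].to_numpy()

    scores, evr = pc1_muscle_fatigue(df["d_mdf_rectus"], df["d_mdf_tibialis"])
    out["mf_pc1"] = zscore(scores)
    if "fi" in df.columns:
        out["mf_fi"] = zscore(df["fi"])
    out["mf"] = out["mf_pc1"] if mf_metric == "pc1" else out["mf_fi"]
    out.attrs["pc1_explained"] = evr

    hr_series = df["d_hr_mean"] if hr_mode == "delta" else df["hr_mean"]
    out["hr"] = zscore(hr_series)

    if have_ratings:
        out["rating"] = df["rating"].to_numpy()
        out["sf_norm"] = (
            df.groupby("subject")["rating"]
            .transform(lambda s: normalize_sf(s, subject=s.name))
            .to_numpy()
        )
    for passthrough in ("pleasure", "sf_model", "fi"):
        if passthrough in df.columns:
            out[passthrough] = df[passthrough].to_numpy()
    return out
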