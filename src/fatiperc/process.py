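"""Signal-level processing of a session into per-block aggregates.

Runs the full preprocessing chain on one session's traces — 50 Hz notch,
20-500 Hz fourth-order Butterworth band-pass, heel-strike segmentation from
the foot-pressure channels, per-step median/mean frequency and RMS, 10-part
block partitioning, heart-rate artifact removal and smoothing — and reduces
everything to the per-block rows that feed the feature table, in the same
schema the feature-level generator emits.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import sigproc
from .protocol import prediction_error

__all__ = ["process_session", "steps_table", "block_signal_summary"]

MUSCLES = ("rectus", "tibialis")


def _filtered(trace: sigproc.SampledTrace) -> sigproc.SampledTrace:
    return sigproc.bandpass_filter(sigproc.notch_filter(trace))


def steps_table(session, muscle: str, events: np.ndarray) -> pd.DataFrame:
    """Per-step spectral features of one muscle as a tidy table."""
    emg = session.emg[muscle]
    feats = sigproc.step_features(_filtered(emg), events)
    return pd.DataFrame(
        {
            "step": [f.step_index for f in feats],
            "t_start": [f.t_start for f in feats],
            "t_end": [f.t_end for f in feats],
            "mdf": [f.median_frequency_hz for f in feats],
            "mnf": [f.mean_frequency_hz for f in feats],
            "rms": [f.amplitude_rms for f in feats],
        }
    )


def _assign_block(times: np.ndarray, bounds: np.ndarray) -> np.ndarray:
    return np.searchsorted(bounds, times, side="right") + 1


def block_signal_summary(values: np.ndarray, n_parts: int = 10) -> tuple[np.ndarray, float]:
    """10-part partition means and their overall mean for one block."""
    parts = sigproc.split_block_into_parts(values, n_parts=n_parts)
    return parts, float(parts.mean())


def process_session(session, n_parts: int = 10) -> tuple[pd.DataFrame, dict[str, pd.DataFrame]]:
    """Reduce one session (in-memory or read from disk) to block rows.

    Accepts a :class:`~fatiperc.simulate.SyntheticSession` or a
    :class:`~fatiperc.session_io.SessionData`. Returns ``(block_rows,
    steps_by_muscle)`` where ``block_rows`` matches the feature-level block
    table schema (mdf/mnf/amp per muscle, hr mean, FI, error, ratings).
    """
    if hasattr(session, "manifest"):  # SessionData from disk
        manifest = session.manifest
        subject = manifest["subject"]
        modality = manifest["modality"]
        group = manifest["group"]
        told = float(manifest["told_per_block"])
        bounds = np.asarray(manifest["block_bounds_s"], dtype=float)
        actual = np.asarray(manifest["actual_per_block"], dtype=float)
        speed = manifest["speed_fraction"] * manifest["mrv"]
    else:  # SyntheticSession
        subject = session.subject
        modality = session.modality
        group = session.group
        told = float(session.protocol.told_per_block)
        bounds = np.asarray(session.block_bounds_s, dtype=float)
        actual = np.asarray(session.protocol.actual_per_block, dtype=float)
        speed = session.protocol.speed_fraction * session.protocol.mrv
    n_blocks = bounds.size
    durations = np.diff(np.concatenate([[0.0], bounds]))

    events = sigproc.segment_steps(list(session.pressure.values()))
    steps = {m: steps_table(session, m, events) for m in MUSCLES}

    hr = sigproc.clean_heart_rate(session.heart_rate)
    # cleaned samples keep their original pacing well enough for block means
    hr_block = _assign_block(np.linspace(0, bounds[-1], hr.values.size, endpoint=False), bounds)

    ratings = session.ratings.set_index("block")
    rows = []
    base: dict[str, float] = {}
    for b in range(1, n_blocks + 1):
        if modality == "temporal":
            measured = durations[b - 1]
            err = prediction_error(measured, told)
        else:
            measured = actual[b - 1]
            err = prediction_error(measured, told) if measured != told else 0.0
        row = {
            "subject": subject,
            "modality": modality,
            "group": group,
            "block": b,
            "actual_nominal": float(actual[b - 1]),
            "actual_measured": float(measured),
            "told": told,
            "duration_min": float(durations[b - 1] / 60.0),
            "error_raw": float(err),
        }
        for m in MUSCLES:
            sb = steps[m][_assign_block(steps[m]["t_start"].to_numpy(), bounds) == b]
            if sb.empty:
                raise ValueError(f"block {b} has no valid steps for muscle {m}")
            for feat in ("mdf", "mnf", "rms"):
                _, mean = block_signal_summary(sb[feat].to_numpy(), n_parts=min(n_parts, len(sb)))
                key = {"mdf": f"mdf_{m}", "mnf": f"mnf_{m}", "rms": f"amp_{m}"}[feat]
                row[key] = mean
        hb = hr.values[hr_block == b]
        if hb.size == 0:
            raise ValueError(f"block {b} has no heart-rate samples after cleaning")
        _, row["hr_mean"] = block_signal_summary(hb, n_parts=min(n_parts, hb.size))
        if b == 1:
            base = {k: row[k] for k in row if str(k).startswith(("amp_", "mnf_"))}
        row["fi"] = float(
            np.mean(
                [
                    sigproc.fatigue_index(
                        row[f"amp_{m}"], base[f"amp_{m}"], row[f"mnf_{m}"], base[f"mnf_{m}"]
                    )
                    for m in MUSCLES
                ]
            )
        )
        if b in ratings.index:
            row["rating"] = float(ratings.loc[b, "rating"])
            row["pleasure"] = float(ratings.loc[b, "pleasure"])
        rows.append(row)
    return pd.DataFrame(rows), steps
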