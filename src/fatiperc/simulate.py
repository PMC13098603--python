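"""Synthetic cohort generator with known ground truth.

Emulates the running-task protocol end to end: seeded block schedules,
surface-EMG traces whose spectral median declines with accumulating fatigue,
foot-pressure pulses at each heel strike, a drifting heart-rate trace with
bracelet artifacts, per-block fatigue/pleasure ratings generated from a
chosen candidate model form plus noise, and a perceived-total report whose
error grows with the composite Fatigue Index. Every downstream estimator can
therefore be checked against the quantities that generated the data.

Two levels of fidelity:

* :func:`simulate_feature_cohort` — per-block aggregate features only
  (median/mean frequency and RMS per muscle, heart-rate block means,
  ratings, perceived totals). Fast; used for model-recovery studies.
* :func:`simulate_session_signals` / :func:`simulate_cohort` with
  ``with_signals=True`` — full sampled traces (EMG 1111 Hz, pressure 100 Hz,
  heart rate 10 Hz) consistent with the same block-level truth, for testing
  the signal-processing chain.

Study conditions baked into the defaults: four blocks told as 5 min / 750 m;
advanced/delayed schedules drawn without replacement from the fixed sets;
prompts in the temporal modality carry a constant +2 s latency (so the
standard condition's temporal error is a small nonzero constant, while the
spatial standard error is exactly zero — distance prompts trigger exactly);
treadmill speed 70 % of each subject's maximum running velocity; ratings on
a 7-point scale; pleasure flat (no true pre/post change).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .features import build_feature_table, CONDITION_CODES_DISTORTION
from .models import ModelSpec, evaluate_model
from .protocol import GROUPS, MODALITIES, ProtocolDesign, build_protocol, prediction_error
from .sigproc import SampledTrace

__all__ = [
    "CANONICAL_WINNERS",
    "GroundTruth",
    "Cohort",
    "SyntheticSession",
    "default_truth",
    "simulate_emg",
    "simulate_pressure",
    "simulate_heart_rate",
    "simulate_ratings",
    "simulate_feature_cohort",
    "simulate_cohort",
    "simulate_session_signals",
]

#: Prompt latency added to every temporal block's measured duration (s).
TEMPORAL_PROMPT_LATENCY_S = 2.0

EMG_FS = 1111.0
PRESSURE_FS = 100.0
HR_FS = 10.0
STEP_RATE_HZ = 2.8  # merged heel strikes of both feet while running

# Canonical best-fitting form of each model group, per modality; these are
# the library members the generator uses as ground-truth defaults.
CANONICAL_WINNERS: dict[tuple[int, str], ModelSpec] = {
    (1, "temporal"): ModelSpec(1, "temporal", ((("error", "par"),), ())),
    (1, "spatial"): ModelSpec(1, "spatial", ((("error", "par"),), ())),
    (2, "temporal"): ModelSpec(2, "temporal", ((("mf", "hyp"),), ())),
    (2, "spatial"): ModelSpec(2, "spatial", ((("mf", "par"),), ())),
    (3, "temporal"): ModelSpec(3, "temporal", ((("mf", "par"),), (("error", "lin"),))),
    (3, "spatial"): ModelSpec(3, "spatial", ((("mf", "par"),), (("error", "par"),))),
    (4, "temporal"): ModelSpec(
        4, "temporal", ((("error", "lin"), ("mf", "par")), (("error", "hyp"),))
    ),
    (4, "spatial"): ModelSpec(
        4, "spatial", ((("error", "exp"), ("mf", "par")), (("error", "par"),))
    ),
    (5, "temporal"): ModelSpec(
        5, "temporal", ((("error", "par"), ("mf", "exp")), (("error", "lin"),), (("hr", "lin"),))
    ),
    (5, "spatial"): ModelSpec(
        5, "spatial", ((("error", "exp"), ("mf", "lin")), (("error", "lin"),), (("hr", "hyp"),))
    ),
}


@dataclass(frozen=True)
class GroundTruth:
    """Which generating model, with which parameters, drives the ratings."""

    model_form: ModelSpec
    params: tuple[float, ...]
    noise_sd: float = 0.2
    distortion_slope: float = 0.2
    hr_artifact_rate: float = 0.02
    discretize_ratings: bool = False

    def __post_init__(self) -> None:
        if len(self.params) != self.model_form.k:
            raise ValueError("params length must match the model form's k")
        if any(p <= 0 for p in self.params):
            raise ValueError("ground-truth params must be strictly positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @property
    def model_group(self) -> int:
        return self.model_form.group


def default_truth(modality: str, **overrides) -> GroundTruth:
    """Group-4 canonical winner with a=0.8, b=0.5 — the default study truth."""
    spec = CANONICAL_WINNERS[(4, modality)]
    kw = dict(model_form=spec, params=(0.8, 0.5))
    kw.update(overrides)
    return GroundTruth(**kw)


# ---------------------------------------------------------------------------
# raw-signal generators
# ---------------------------------------------------------------------------


def simulate_emg(
    duration_s: float,
    fs: float = EMG_FS,
    mdf_start_hz: float = 100.0,
    mdf_end_hz: float = 85.0,
    step_rate_hz: float = STEP_RATE_HZ,
    seed: int | None = 0,
    bandwidth_hz: float = 40.0,
    rms_start: float = 1.0,
    rms_end: float | None = None,
) -> tuple[SampledTrace, np.ndarray, np.ndarray]:
    """Band-limited stochastic EMG whose median frequency declines linearly.

    Each inter-step segment is synthesized in the frequency domain as
    complex Gaussian noise confined to a flat band of width ``bandwidth_hz``
    centred on that step's target median frequency, so the spectral median
    of the segment equals the target up to estimation error.

    Returns ``(trace, step_times, true_mdf_per_step)``.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    nyq = fs / 2
    if not (0 < mdf_end_hz <= mdf_start_hz < nyq):
        raise ValueError("need 0 < mdf_end_hz <= mdf_start_hz < fs/2")
    if mdf_start_hz + bandwidth_hz / 2 >= nyq:
        raise ValueError("band upper edge exceeds Nyquist")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fs))
    step_times = np.arange(0.0, duration_s, 1.0 / step_rate_hz)
    bounds = np.round(np.append(step_times, duration_s) * fs).astype(int)
    bounds = np.unique(np.clip(bounds, 0, n))
    if bounds[0] != 0:
        bounds = np.insert(bounds, 0, 0)
    if bounds[-1] != n:
        bounds = np.append(bounds, n)
    rms_end = rms_start if rms_end is None else rms_end
    out = np.empty(n)
    mdf_true = []
    n_seg = len(bounds) - 1
    for i in range(n_seg):
        i0, i1 = bounds[i], bounds[i + 1]
        length = i1 - i0
        frac = (0.5 * (i0 + i1) / n) if n else 0.0
        target = mdf_start_hz + (mdf_end_hz - mdf_start_hz) * frac
        rms = rms_start + (rms_end - rms_start) * frac
        mdf_true.append(target)
        freqs = np.fft.rfftfreq(length, d=1.0 / fs)
        lo = max(target - bandwidth_hz / 2, 1.0)
        hi = min(target + bandwidth_hz / 2, 0.98 * nyq)
        band = (freqs >= lo) & (freqs <= hi)
        spec = np.zeros(freqs.size, dtype=complex)
        m = int(band.sum())
        spec[band] = rng.normal(size=m) + 1j * rng.normal(size=m)
        seg = np.fft.irfft(spec, n=length)
        seg_rms = np.sqrt(np.mean(seg**2))
        if seg_rms > 0:
            seg *= rms / seg_rms
        out[i0:i1] = seg
    # true MDF for actual steps only (segment i spans step i to i+1)
    mdf_per_step = np.asarray(mdf_true[: max(len(step_times) - 1, 0)])
    return SampledTrace(out, fs=fs), step_times, mdf_per_step


def simulate_pressure(
    step_times,
    fs: float = PRESSURE_FS,
    seed: int | None = 0,
    duration_s: float | None = None,
    pulse_width_s: float = 0.12,
    amplitude: float = 1.0,
    noise_sd: float = 0.02,
) -> SampledTrace:
    """Foot-pressure trace: one supra-threshold pulse per step time.

    Sub-threshold Gaussian noise elsewhere; an empty step list yields a flat
    noise trace (zero events downstream).
    """
    step_times = np.asarray(step_times, dtype=float)
    if step_times.size > 1 and np.any(np.diff(step_times) <= 0):
        raise ValueError("step_times must be strictly increasing")
    if duration_s is None:
        duration_s = float(step_times[-1] + 1.0) if step_times.size else 1.0
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fs))
    v = rng.normal(0.0, noise_sd, size=n)
    w = max(int(round(pulse_width_s * fs)), 2)
    pulse = amplitude * np.sin(np.linspace(0, np.pi, w))
    for t in step_times:
        i0 = int(round(t * fs))
        i1 = min(i0 + w, n)
        if i0 < n:
            v[i0:i1] += pulse[: i1 - i0]
    return SampledTrace(v, fs=fs)


def simulate_heart_rate(
    baseline_bpm: float,
    drift_bpm: float,
    artifact_rate: float,
    duration_s: float,
    seed: int | None = 0,
    fs: float = HR_FS,
    noise_sd: float = 1.5,
) -> tuple[SampledTrace, np.ndarray]:
    """Slowly drifting heart-rate series with out-of-range artifact samples.

    Clean samples stay inside (40, 200) bpm; each sample independently
    becomes an artifact (placed outside [40, 200]) with probability
    ``artifact_rate``. Returns ``(trace, artifact_indices)`` so removal can
    be audited downstream.
    """
    if not (40 < baseline_bpm < 200):
        raise ValueError("baseline_bpm outside the physiologic range (40, 200)")
    if not (0 <= artifact_rate < 1):
        raise ValueError("artifact_rate must be in [0, 1)")
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    v = (
        baseline_bpm
        + drift_bpm * t / duration_s
        + 1.2 * np.sin(2 * np.pi * t / 47.0)
        + rng.normal(0.0, noise_sd, size=n)
    )
    v = np.clip(v, 41.0, 199.0)
    artifact = rng.random(n) < artifact_rate
    idx = np.flatnonzero(artifact)
    if idx.size:
        low = rng.uniform(5.0, 35.0, size=idx.size)
        high = rng.uniform(205.0, 240.0, size=idx.size)
        v[idx] = np.where(rng.random(idx.size) < 0.5, low, high)
    return SampledTrace(v, fs=fs), idx


# ---------------------------------------------------------------------------
# ratings
# ---------------------------------------------------------------------------


def simulate_ratings(
    protocol: ProtocolDesign,
    features_truth: pd.DataFrame | dict,
    truth: GroundTruth,
    seed: int | None = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Raw model-scale fatigue values and pleasure ratings for one session.

    ``features_truth`` supplies the standardized per-block ``error``, ``mf``
    and (for heart-rate forms) ``hr``. The fatigue values are the model form
    evaluated at the true features plus Normal(0, noise_sd) noise — on the
    model's own scale, before any mapping onto the 1-7 rating scale (the
    cohort generator applies a recorded per-subject affine map afterwards).
    Pleasure is flat: baseline plus noise, with no true change.
    """
    needed = truth.model_form.variables
    for var in needed:
        if var not in features_truth:
            raise ValueError(f"model form requires {var!r} but it is absent from features_truth")
    rng = np.random.default_rng(seed)
    m = evaluate_model(truth.model_form, truth.params, features_truth)
    sf_raw = m + rng.normal(0.0, truth.noise_sd, size=m.shape) if truth.noise_sd > 0 else m
    pleasure = np.clip(4.5 + rng.normal(0.0, 0.3, size=m.shape), 1.0, 7.0)
    return sf_raw, pleasure


def _rating_map(y: np.ndarray, lo: float = 1.0, hi: float = 7.0) -> tuple[float, float]:
    """Affine map sending a subject's value range onto the rating scale."""
    ymin, ymax = float(np.min(y)), float(np.max(y))
    if ymax - ymin <= 1e-12:
        return 1.0, (lo + hi) / 2 - ymin
    slope = (hi - lo) / (ymax - ymin)
    return slope, lo - slope * ymin


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

# Perceived-total offsets (s or m) per condition, linear in the distortion
# condition code so the distortion regression has known truth; sign of the
# misperception: early prompts make subjects over-estimate, late prompts
# under-estimate.
_DISTORTION_BASE = {"temporal": 30.0, "spatial": 75.0}
_DISTORTION_STEP = {"temporal": 150.0, "spatial": 375.0}
_DISTORTION_NOISE_SD = {"temporal": 5.0, "spatial": 12.0}
_DISTORTION_SIGN = {"standard": 1.0, "advanced": 1.0, "delayed": -1.0}


@dataclass
class Cohort:
    """A simulated cohort: per-block table, modelling table, session table."""

    modality: str
    truth: GroundTruth
    seed: int
    blocks: pd.DataFrame
    features: pd.DataFrame
    sessions: pd.DataFrame
    subject_scale_maps: pd.DataFrame

    @property
    def n_subjects(self) -> int:
        return self.blocks["subject"].nunique()


def _subject_physiology(rng: np.random.Generator) -> dict:
    """Stable per-subject latent parameters."""
    return {
        "mrv": float(np.clip(rng.normal(3.2, 0.25), 2.4, 4.2)),
        "mdf_base_rectus": float(rng.normal(85.0, 6.0)),
        "mdf_base_tibialis": float(rng.normal(110.0, 8.0)),
        "mdf_rate": float(np.clip(rng.normal(0.45, 0.08), 0.15, 0.9)),  # Hz per min
        "mnf_rel_rate": float(np.clip(rng.normal(0.005, 0.001), 0.002, 0.009)),  # /min
        "amp_base": float(rng.normal(50.0, 8.0)),
        "amp_rel_rate": float(np.clip(rng.normal(0.006, 0.0015), 0.002, 0.011)),  # /min
        "hr_base": float(rng.normal(118.0, 7.0)),
        "hr_gain": float(np.clip(rng.normal(28.0, 5.0), 12.0, 45.0)),
        "hr_tau_min": 6.0,
    }


def _session_blocks(
    subject: int,
    modality: str,
    group: str,
    phys: dict,
    proto: ProtocolDesign,
    rng: np.random.Generator,
) -> list[dict]:
    """Per-block physiological aggregates for one session."""
    rows = []
    speed = proto.speed_fraction * phys["mrv"]  # m/s
    cum_min = 0.0
    base = {}
    for b, actual in enumerate(proto.actual_per_block, start=1):
        if modality == "temporal":
            measured = actual + TEMPORAL_PROMPT_LATENCY_S
            dur_min = measured / 60.0
        else:
            measured = actual  # meters; distance counter is exact
            dur_min = actual / speed / 60.0
        cum_min += dur_min
        L = cum_min
        row = {
            "subject": subject,
            "modality": modality,
            "group": group,
            "block": b,
            "actual_nominal": float(actual),
            "actual_measured": float(measured),
            "told": proto.told_per_block,
            "duration_min": dur_min,
            "error_raw": prediction_error(measured, proto.told_per_block),
            "hr_mean": phys["hr_base"]
            + phys["hr_gain"] * (1 - np.exp(-L / phys["hr_tau_min"]))
            + rng.normal(0, 1.5),
        }
        for muscle in ("rectus", "tibialis"):
            mdf0 = phys[f"mdf_base_{muscle}"]
            row[f"mdf_{muscle}"] = mdf0 - phys["mdf_rate"] * L + rng.normal(0, 1.0)
            row[f"mnf_{muscle}"] = 1.18 * mdf0 * (1 - phys["mnf_rel_rate"] * L) + rng.normal(0, 1.0)
            row[f"amp_{muscle}"] = phys["amp_base"] * (1 + phys["amp_rel_rate"] * L) + rng.normal(
                0, 0.8
            )
        if b == 1:
            base = {k: row[k] for k in row if k.startswith(("amp_", "mnf_"))}
        fi_per_muscle = [
            (row[f"amp_{m}"] / base[f"amp_{m}"]) / (row[f"mnf_{m}"] / base[f"mnf_{m}"])
            for m in ("rectus", "tibialis")
        ]
        row["fi"] = float(np.mean(fi_per_muscle))
        rows.append(row)
    return rows


def simulate_feature_cohort(
    n_subjects: int,
    modality: str,
    truth: GroundTruth | None = None,
    seed: int = 0,
) -> Cohort:
    """Simulate a cohort at the per-block feature level (no raw traces).

    Every subject completes all three feedback conditions in a random order;
    ratings are generated from ``truth``'s model form evaluated at the true
    standardized features, then mapped onto the 1-7 scale with a recorded
    per-subject affine map; perceived totals encode the Fatigue-Index →
    sensory-distortion link with slope ``truth.distortion_slope``.
    """
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    if modality not in MODALITIES:
        raise ValueError(f"unknown modality {modality!r}")
    truth = truth or default_truth(modality)
    if truth.model_form.modality != modality:
        raise ValueError("truth.model_form modality does not match the cohort modality")
    ss = np.random.SeedSequence(seed)
    master = np.random.default_rng(ss)
    rows: list[dict] = []
    order_records = []
    for subject in range(1, n_subjects + 1):
        sub_rng = np.random.default_rng(ss.spawn(1)[0])
        phys = _subject_physiology(sub_rng)
        group_order = list(master.permutation(GROUPS))
        order_records.append({"subject": subject, "order": ",".join(group_order), **phys})
        for group in group_order:
            proto = build_protocol(
                modality, group, int(sub_rng.integers(0, 2**31 - 1)), mrv=phys["mrv"]
            )
            rows.extend(_session_blocks(subject, modality, group, phys, proto, sub_rng))
    blocks = pd.DataFrame(rows)

    # standardized true features (ratings not yet generated)
    feats = build_feature_table(blocks.assign(rating=np.nan), allow_missing_ratings=True)

    # ratings from the generating model form at the true features
    sf_raw = np.empty(len(feats))
    pleasure = np.empty(len(feats))
    feats = feats.sort_values(["subject", "group", "block"], kind="stable").reset_index(drop=True)
    blocks = blocks.sort_values(["subject", "group", "block"], kind="stable").reset_index(drop=True)
    for (subject, group), idx in feats.groupby(["subject", "group"], sort=True).groups.items():
        idx = np.asarray(idx)
        session_feats = feats.loc[idx]
        rng = np.random.default_rng(ss.spawn(1)[0])
        m = evaluate_model(truth.model_form, truth.params, session_feats)
        noise = rng.normal(0.0, truth.noise_sd, size=m.shape) if truth.noise_sd > 0 else 0.0
        sf_raw[idx] = m + noise
        pleasure[idx] = np.clip(4.5 + rng.normal(0.0, 0.3, size=m.shape), 1.0, 7.0)

    # per-subject affine map onto the 1-7 scale, recorded for inversion
    blocks["sf_model"] = sf_raw
    blocks["pleasure"] = pleasure
    maps = []
    ratings = np.empty(len(blocks))
    for subject, idx in blocks.groupby("subject", sort=True).groups.items():
        idx = np.asarray(idx)
        slope, intercept = _rating_map(sf_raw[idx])
        r = slope * sf_raw[idx] + intercept
        if truth.discretize_ratings:
            r = np.round(r)
        ratings[idx] = np.clip(r, 1.0, 7.0)
        maps.append({"subject": subject, "slope": slope, "intercept": intercept})
    blocks["rating"] = ratings
    subject_maps = pd.DataFrame(maps)

    features = build_feature_table(blocks)

    # session-level table: perceived totals and session-mean Fatigue Index
    sess = (
        blocks.groupby(["subject", "group"], sort=True)
        .agg(
            actual_total=("actual_measured", "sum"),
            fi_mean=("fi", "mean"),
        )
        .reset_index()
    )
    sess["cond_distortion"] = sess["group"].map(CONDITION_CODES_DISTORTION)
    rng = np.random.default_rng(ss.spawn(1)[0])
    base = _DISTORTION_BASE[modality]
    step = _DISTORTION_STEP[modality]
    noise_sd = _DISTORTION_NOISE_SD[modality]
    offset = base + step * (sess["cond_distortion"].to_numpy() - 1)
    interior = (
        truth.distortion_slope * sess["fi_mean"].to_numpy()
        + offset
        + rng.normal(0.0, noise_sd, size=len(sess))
    )
    sign = sess["group"].map(_DISTORTION_SIGN).to_numpy()
    sess["perceived_total"] = sess["actual_total"].to_numpy() + sign * interior
    sess["distortion"] = np.abs(sess["perceived_total"] - sess["actual_total"])
    sess["modality"] = modality

    return Cohort(
        modality=modality,
        truth=truth,
        seed=seed,
        blocks=blocks,
        features=features,
        sessions=sess,
        subject_scale_maps=subject_maps,
    )


# ---------------------------------------------------------------------------
# full-signal sessions
# ---------------------------------------------------------------------------


@dataclass
class SyntheticSession:
    """Full sampled traces for one subject × condition session."""

    subject: int
    modality: str
    group: str
    protocol: ProtocolDesign
    emg: dict[str, SampledTrace]
    pressure: dict[str, SampledTrace]
    heart_rate: SampledTrace
    hr_artifact_idx: np.ndarray
    block_bounds_s: np.ndarray  # cumulative block end times (s)
    ratings: pd.DataFrame  # block, rating, pleasure
    perceived_total: float
    block_truth: pd.DataFrame


def simulate_session_signals(cohort: Cohort, subject: int, group: str, seed: int = 0) -> SyntheticSession:
    """Render one cohort session as full sampled traces.

    EMG per muscle is synthesized block by block at the session's true block
    median frequencies and RMS amplitudes; pressure pulses follow the step
    schedule (split into left/right heel sensors); the heart-rate trace
    tracks the true block means with bracelet artifacts injected at the
    truth's artifact rate.
    """
    rows = cohort.blocks[
        (cohort.blocks["subject"] == subject) & (cohort.blocks["group"] == group)
    ].sort_values("block")
    if rows.empty:
        raise ValueError(f"no session for subject {subject}, group {group}")
    modality = cohort.modality
    durations_s = rows["duration_min"].to_numpy() * 60.0
    bounds = np.cumsum(durations_s)
    total_s = float(bounds[-1])
    ss = np.random.SeedSequence(seed)
    rngs = iter(ss.spawn(8))

    emg = {}
    for muscle in ("rectus", "tibialis"):
        mdfs = rows[f"mdf_{muscle}"].to_numpy()
        amps = rows[f"amp_{muscle}"].to_numpy()
        segs = []
        child = np.random.default_rng(next(rngs))
        for i, dur in enumerate(durations_s):
            tr, _, _ = simulate_emg(
                dur,
                fs=EMG_FS,
                mdf_start_hz=float(mdfs[i]),
                mdf_end_hz=float(mdfs[i]),
                seed=int(child.integers(0, 2**31 - 1)),
                rms_start=float(amps[i]),
            )
            segs.append(tr.values)
        emg[muscle] = SampledTrace(np.concatenate(segs), fs=EMG_FS)

    step_times = np.arange(0.0, total_s - 1.0 / STEP_RATE_HZ, 1.0 / STEP_RATE_HZ)
    child = np.random.default_rng(next(rngs))
    pressure = {
        "heel_left": simulate_pressure(
            step_times[0::2], fs=PRESSURE_FS, seed=int(child.integers(0, 2**31 - 1)), duration_s=total_s
        ),
        "heel_right": simulate_pressure(
            step_times[1::2], fs=PRESSURE_FS, seed=int(child.integers(0, 2**31 - 1)), duration_s=total_s
        ),
    }

    # heart rate: linear interpolation through block-mean truth + noise + artifacts
    n_hr = int(round(total_s * HR_FS))
    t = np.arange(n_hr) / HR_FS
    mids = bounds - np.asarray(durations_s) / 2
    hr_truth = np.interp(t, mids, rows["hr_mean"].to_numpy())
    child = np.random.default_rng(next(rngs))
    v = np.clip(hr_truth + child.normal(0, 1.5, size=n_hr), 41.0, 199.0)
    artifact = child.random(n_hr) < cohort.truth.hr_artifact_rate
    idx = np.flatnonzero(artifact)
    if idx.size:
        low = child.uniform(5.0, 35.0, size=idx.size)
        high = child.uniform(205.0, 240.0, size=idx.size)
        v[idx] = np.where(child.random(idx.size) < 0.5, low, high)
    hr_trace = SampledTrace(v, fs=HR_FS)

    proto = ProtocolDesign(
        modality=modality,
        group=group,
        told_per_block=float(rows["told"].iloc[0]),
        actual_per_block=tuple(rows["actual_nominal"].to_numpy()),
    )
    sess_row = cohort.sessions[
        (cohort.sessions["subject"] == subject) & (cohort.sessions["group"] == group)
    ]
    return SyntheticSession(
        subject=subject,
        modality=modality,
        group=group,
        protocol=proto,
        emg=emg,
        pressure=pressure,
        heart_rate=hr_trace,
        hr_artifact_idx=idx,
        block_bounds_s=bounds,
        ratings=rows[["block", "rating", "pleasure"]].reset_index(drop=True),
        perceived_total=float(sess_row["perceived_total"].iloc[0]),
        block_truth=rows.reset_index(drop=True),
    )


def simulate_cohort(
    n_subjects: int,
    modality: str,
    truth: GroundTruth | None = None,
    seed: int = 0,
    out_dir=None,
    with_signals: bool = False,
) -> Cohort:
    """Simulate a full cohort; optionally render and write session traces.

    Without ``with_signals`` this is :func:`simulate_feature_cohort`. With it
    (or with ``out_dir`` set) each subject×condition session is rendered as
    full traces; ``out_dir`` writes one session directory per session in the
    delimited-text session format.
    """
    cohort = simulate_feature_cohort(n_subjects, modality, truth, seed)
    if not (with_signals or out_dir):
        return cohort
    from . import session_io

    ss = np.random.SeedSequence(seed + 1_000_003)
    for (subject, group), _ in cohort.blocks.groupby(["subject", "group"], sort=True):
        sess = simulate_session_signals(
            cohort, subject, group, seed=int(np.random.default_rng(ss.spawn(1)[0]).integers(0, 2**31 - 1))
        )
        if out_dir is not None:
            session_io.write_session(out_dir, sess)
    return cohort
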