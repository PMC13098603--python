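"""EMG / heart-rate preprocessing and per-step spectral features.

The preprocessing chain mirrors standard surface-EMG practice for running:
a 50 Hz notch to remove mains interference, a fourth-order Butterworth
band-pass (20-500 Hz), gait-based segmentation of the EMG into steps using
foot-pressure heel strikes, and per-step spectral descriptors (median
frequency, mean frequency, RMS amplitude). Muscle fatigue manifests as a
decline of the median frequency and a rise of amplitude over the session;
the composite Fatigue Index combines both relative to a baseline.

All filters are applied zero-phase (forward-backward) so step boundaries are
not shifted by group delay.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

__all__ = [
    "SampledTrace",
    "StepFeature",
    "notch_filter",
    "bandpass_filter",
    "segment_steps",
    "median_frequency",
    "mean_frequency",
    "step_features",
    "fatigue_index",
    "clean_heart_rate",
    "split_block_into_parts",
]

logger = logging.getLogger(__name__)

MIN_SEGMENT_SAMPLES = 64


@dataclass(frozen=True)
class SampledTrace:
    """A uniformly sampled physical signal (µV, bpm, a.u.)."""

    values: np.ndarray
    fs: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if v.ndim != 1 or v.size < 1:
            raise ValueError("trace must be a non-empty 1-D array")
        if not np.all(np.isfinite(v)):
            raise ValueError("trace contains non-finite values")

    @property
    def duration(self) -> float:
        return self.values.size / self.fs

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.values.size) / self.fs

    def replace_values(self, values: np.ndarray) -> "SampledTrace":
        return SampledTrace(values=np.asarray(values, dtype=float), fs=self.fs, t0=self.t0)


@dataclass(frozen=True)
class StepFeature:
    """Spectral descriptors of one gait cycle of one muscle."""

    step_index: int
    t_start: float
    t_end: float
    median_frequency_hz: float
    mean_frequency_hz: float
    amplitude_rms: float


def notch_filter(trace: SampledTrace, f0: float = 50.0, q: float = 20.0) -> SampledTrace:
    """Zero-phase IIR notch removing mains interference at ``f0``."""
    if f0 >= trace.fs / 2:
        raise ValueError(f"notch frequency {f0} Hz is at or above Nyquist ({trace.fs / 2} Hz)")
    b, a = sps.iirnotch(f0, q, fs=trace.fs)
    return trace.replace_values(sps.filtfilt(b, a, trace.values))


def bandpass_filter(
    trace: SampledTrace, lo: float = 20.0, hi: float = 500.0, order: int = 4
) -> SampledTrace:
    """Zero-phase Butterworth band-pass of the stated order."""
    nyq = trace.fs / 2
    if not (0 < lo < hi):
        raise ValueError("need 0 < lo < hi")
    if hi >= nyq:
        raise ValueError(f"upper edge {hi} Hz is at or above Nyquist ({nyq} Hz)")
    sos = sps.butter(order, [lo, hi], btype="bandpass", fs=trace.fs, output="sos")
    return trace.replace_values(sps.sosfiltfilt(sos, trace.values))


def segment_steps(
    pressure_traces: list[SampledTrace] | SampledTrace,
    refractory_s: float = 0.25,
    percentiles: tuple[float, float] = (5.0, 95.0),
) -> np.ndarray:
    """Detect heel-strike times from foot-pressure traces.

    Each upward crossing of an adaptive threshold (midpoint of the robust
    low/high percentiles of the trace) counts as one event; crossings within
    ``refractory_s`` of the previous event are suppressed. Events from
    multiple sensors are merged and the merged train is de-bounced again.
    Returns strictly increasing event times in seconds.
    """
    if isinstance(pressure_traces, SampledTrace):
        pressure_traces = [pressure_traces]
    if not pressure_traces:
        raise ValueError("need at least one pressure trace")
    all_events: list[float] = []
    for tr in pressure_traces:
        v = tr.values
        lo, hi = np.percentile(v, percentiles)
        # require real pulses: the robust range must clear the noise floor
        sigma = 1.4826 * np.median(np.abs(v - np.median(v)))
        if hi - lo <= max(6.0 * sigma, 1e-12):  # flat or noise-only: no steps
            continue
        thr = 0.5 * (lo + hi)
        above = v > thr
        crossings = np.flatnonzero(~above[:-1] & above[1:]) + 1
        last = -np.inf
        for idx in crossings:
            t = tr.t0 + idx / tr.fs
            if t - last >= refractory_s:
                all_events.append(t)
                last = t
    if not all_events:
        return np.empty(0)
    merged = np.sort(np.asarray(all_events))
    keep = [merged[0]]
    for t in merged[1:]:
        if t - keep[-1] >= refractory_s:
            keep.append(t)
    return np.asarray(keep)


def _periodogram(segment: np.ndarray, fs: float, window: str = "hann"):
    return sps.periodogram(sps.detrend(segment), fs=fs, window=window)


def median_frequency(segment: np.ndarray, fs: float) -> float:
    """Median frequency of a segment's power spectrum.

    The frequency m at which the cumulative periodogram reaches half the
    total power, with linear interpolation between frequency bins.
    """
    segment = np.asarray(segment, dtype=float)
    if segment.size < MIN_SEGMENT_SAMPLES:
        raise ValueError(f"segment too short ({segment.size} < {MIN_SEGMENT_SAMPLES} samples)")
    f, pxx = _periodogram(segment, fs)
    cum = np.cumsum(pxx)
    total = cum[-1]
    if total <= 0:
        raise ValueError("segment has no power")
    half = 0.5 * total
    i = int(np.searchsorted(cum, half))
    if i == 0:
        return float(f[0])
    # linear interpolation inside bin i
    frac = (half - cum[i - 1]) / (cum[i] - cum[i - 1])
    return float(f[i - 1] + frac * (f[i] - f[i - 1]))


def mean_frequency(segment: np.ndarray, fs: float) -> float:
    """PSD-weighted spectral centroid of a segment."""
    segment = np.asarray(segment, dtype=float)
    if segment.size < MIN_SEGMENT_SAMPLES:
        raise ValueError(f"segment too short ({segment.size} < {MIN_SEGMENT_SAMPLES} samples)")
    f, pxx = _periodogram(segment, fs)
    total = pxx.sum()
    if total <= 0:
        raise ValueError("segment has no power")
    return float((f * pxx).sum() / total)


def step_features(
    emg_trace: SampledTrace,
    events: np.ndarray,
    min_samples: int = MIN_SEGMENT_SAMPLES,
    iqr_k: float = 1.5,
) -> list[StepFeature]:
    """Per-step spectral features of a filtered EMG trace.

    Steps span consecutive heel strikes. Steps shorter than ``min_samples``
    are dropped, and steps whose duration or RMS falls outside the session's
    IQR fences (factor ``iqr_k``) are discarded as irregular movements.
    """
    events = np.asarray(events, dtype=float)
    if events.size < 2:
        raise ValueError("need at least two gait events to form a step")
    raw: list[StepFeature] = []
    for i in range(events.size - 1):
        t0, t1 = events[i], events[i + 1]
        i0 = int(round((t0 - emg_trace.t0) * emg_trace.fs))
        i1 = int(round((t1 - emg_trace.t0) * emg_trace.fs))
        i0 = max(i0, 0)
        i1 = min(i1, emg_trace.values.size)
        seg = emg_trace.values[i0:i1]
        if seg.size < min_samples:
            logger.debug("dropping step %d: %d samples < %d", i, seg.size, min_samples)
            continue
        raw.append(
            StepFeature(
                step_index=i,
                t_start=float(t0),
                t_end=float(t1),
                median_frequency_hz=median_frequency(seg, emg_trace.fs),
                mean_frequency_hz=mean_frequency(seg, emg_trace.fs),
                amplitude_rms=float(np.sqrt(np.mean(seg**2))),
            )
        )
    if not raw:
        raise ValueError("no valid steps after segmentation")
    # Irregular-movement rejection: IQR fences on step duration and RMS.
    if len(raw) >= 4:
        durs = np.array([s.t_end - s.t_start for s in raw])
        rmss = np.array([s.amplitude_rms for s in raw])
        keep = _iqr_mask(durs, iqr_k) & _iqr_mask(rmss, iqr_k)
        kept = [s for s, k in zip(raw, keep) if k]
        if kept:
            if len(kept) < len(raw):
                logger.debug("dropped %d irregular steps", len(raw) - len(kept))
            raw = kept
    return raw


def _iqr_mask(values: np.ndarray, k: float) -> np.ndarray:
    q1, q3 = np.percentile(values, [25, 75])
    iqr = q3 - q1
    atol = 1e-9 * max(abs(q1), abs(q3), 1.0)  # guard against ulp jitter when IQR = 0
    return (values >= q1 - k * iqr - atol) & (values <= q3 + k * iqr + atol)


def fatigue_index(
    amplitude: float,
    amplitude_baseline: float,
    mean_freq: float,
    mean_freq_baseline: float,
) -> float:
    """Composite Fatigue Index: (A/A0) / (MNF/MNF0).

    Rises when amplitude grows or mean frequency falls relative to baseline;
    equals 1 when the block matches its baseline.
    """
    vals = (amplitude, amplitude_baseline, mean_freq, mean_freq_baseline)
    if any(v <= 0 for v in vals):
        raise ValueError("all fatigue-index inputs must be positive")
    return (amplitude / amplitude_baseline) / (mean_freq / mean_freq_baseline)


def clean_heart_rate(
    trace: SampledTrace,
    lo: float = 40.0,
    hi: float = 200.0,
    cutoff_hz: float = 10.0,
) -> SampledTrace:
    """Remove physiologically impossible heart-rate samples, then smooth.

    Samples outside [lo, hi] bpm (bounds inclusive — the bounds describe the
    normal range) are treated as bracelet artifacts and dropped; the kept
    series is then low-pass filtered. A requested cutoff at or above the
    realizable limit for the sampling rate is clamped to 0.45*fs and logged.
    """
    v = trace.values
    keep = (v >= lo) & (v <= hi)
    if not np.any(keep):
        raise ValueError("all heart-rate samples removed as artifacts")
    kept = v[keep]
    eff_cutoff = min(cutoff_hz, 0.45 * trace.fs)
    if eff_cutoff < cutoff_hz:
        logger.info(
            "heart-rate low-pass cutoff clamped from %g Hz to %g Hz (fs=%g Hz)",
            cutoff_hz,
            eff_cutoff,
            trace.fs,
        )
    if kept.size > 12:  # enough samples for a stable zero-phase 2nd-order pass
        sos = sps.butter(2, eff_cutoff, btype="lowpass", fs=trace.fs, output="sos")
        kept = sps.sosfiltfilt(sos, kept)
    return SampledTrace(values=kept, fs=trace.fs, t0=trace.t0)


def split_block_into_parts(series: np.ndarray, n_parts: int = 10) -> np.ndarray:
    """Mean of each of ``n_parts`` contiguous, near-equal partitions.

    When the length is not divisible the remainder is spread over the
    leading parts (numpy.array_split convention).
    """
    series = np.asarray(series, dtype=float)
    if series.ndim != 1:
        raise ValueError("series must be 1-D")
    if series.size < n_parts:
        raise ValueError(f"series length {series.size} < n_parts {n_parts}")
    return np.array([chunk.mean() for chunk in np.array_split(series, n_parts)])
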