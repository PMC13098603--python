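"""Delimited-text session directories.

One directory per subject × condition session::

    sub03_advanced/
      manifest.yaml          # subject, modality, group, schedule, block bounds
      emg_rectus.csv         # t_s, uV
      emg_tibialis.csv
      pressure_heel_left.csv # t_s, value
      pressure_heel_right.csv
      hr.csv                 # t_s, bpm
      ratings.csv            # block, rating, pleasure
      perceived.csv          # perceived_total, units
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .sigproc import SampledTrace

__all__ = ["write_session", "read_session", "SessionData", "session_dir_name"]


def session_dir_name(subject: int, group: str) -> str:
    return f"sub{subject:02d}_{group}"


def _write_trace(path: Path, trace: SampledTrace, value_name: str) -> None:
    df = pd.DataFrame({"t_s": trace.times, value_name: trace.values})
    df.to_csv(path, index=False, float_format="%.6g")


def _read_trace(path: Path, value_name: str, fs: float) -> SampledTrace:
    df = pd.read_csv(path)
    t0 = float(df["t_s"].iloc[0]) if len(df) else 0.0
    return SampledTrace(df[value_name].to_numpy(dtype=float), fs=fs, t0=t0)


@dataclass
class SessionData:
    """A session read back from disk."""

    manifest: dict
    emg: dict[str, SampledTrace]
    pressure: dict[str, SampledTrace]
    heart_rate: SampledTrace
    ratings: pd.DataFrame
    perceived_total: float
    units: str

    @property
    def block_bounds_s(self) -> np.ndarray:
        return np.asarray(self.manifest["block_bounds_s"], dtype=float)


def write_session(root, sess) -> Path:
    """Write one synthetic session to its directory; returns the path."""
    root = Path(root)
    d = root / session_dir_name(sess.subject, sess.group)
    d.mkdir(parents=True, exist_ok=True)
    units = "s" if sess.modality == "temporal" else "m"
    manifest = {
        "subject": int(sess.subject),
        "modality": sess.modality,
        "group": sess.group,
        "told_per_block": float(sess.protocol.told_per_block),
        "actual_per_block": [float(x) for x in sess.protocol.actual_per_block],
        "mrv": float(sess.protocol.mrv),
        "speed_fraction": float(sess.protocol.speed_fraction),
        "block_bounds_s": [float(x) for x in sess.block_bounds_s],
        "fs": {"emg": sess.emg["rectus"].fs, "pressure": 100.0, "hr": sess.heart_rate.fs},
        "units": units,
    }
    (d / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=False))
    for muscle, tr in sess.emg.items():
        _write_trace(d / f"emg_{muscle}.csv", tr, "uV")
    for site, tr in sess.pressure.items():
        _write_trace(d / f"pressure_{site}.csv", tr, "value")
    _write_trace(d / "hr.csv", sess.heart_rate, "bpm")
    sess.ratings.to_csv(d / "ratings.csv", index=False)
    pd.DataFrame({"perceived_total": [sess.perceived_total], "units": [units]}).to_csv(
        d / "perceived.csv", index=False
    )
    return d


def read_session(path) -> SessionData:
    """Read a session directory back into memory."""
    d = Path(path)
    manifest = yaml.safe_load((d / "manifest.yaml").read_text())
    fs = manifest["fs"]
    emg = {
        p.stem.removeprefix("emg_"): _read_trace(p, "uV", float(fs["emg"]))
        for p in sorted(d.glob("emg_*.csv"))
    }
    pressure = {
        p.stem.removeprefix("pressure_"): _read_trace(p, "value", float(fs["pressure"]))
        for p in sorted(d.glob("pressure_*.csv"))
    }
    hr = _read_trace(d / "hr.csv", "bpm", float(fs["hr"]))
    ratings = pd.read_csv(d / "ratings.csv")
    perceived = pd.read_csv(d / "perceived.csv")
    return SessionData(
        manifest=manifest,
        emg=emg,
        pressure=pressure,
        heart_rate=hr,
        ratings=ratings,
        perceived_total=float(perceived["perceived_total"].iloc[0]),
        units=str(perceived["units"].iloc[0]),
    )
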