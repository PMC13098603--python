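"""Experimental protocol designs for the running task.

A session consists of four running blocks. Before each block the participant
is told they will run 5 min (temporal modality) or 750 m (spatial modality);
the actual amount run per block depends on the feedback condition:

* ``standard`` — actual equals told in every block,
* ``advanced`` — the progress prompt arrives early (actual < told),
* ``delayed`` — the prompt arrives late (actual > told).

The advanced/delayed block amounts are drawn without replacement from fixed
published sets, so every session in a condition has the same total exposure:
15/20/25 min in the temporal modality, 2.25/3/3.75 km in the spatial one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "MODALITIES",
    "GROUPS",
    "ProtocolDesign",
    "build_protocol",
    "prediction_error",
    "block_schedule_set",
    "told_per_block",
]

MODALITIES = ("temporal", "spatial")
GROUPS = ("standard", "advanced", "delayed")

# Told amount per block: 300 s or 750 m.
_TOLD = {"temporal": 300.0, "spatial": 750.0}

# Actual per-block sets for the manipulated conditions (seconds / meters).
_SETS = {
    ("temporal", "advanced"): (270.0, 240.0, 210.0, 180.0),  # 4.5..3.0 min
    ("temporal", "delayed"): (330.0, 360.0, 390.0, 420.0),  # 5.5..7.0 min
    ("spatial", "advanced"): (675.0, 600.0, 525.0, 450.0),
    ("spatial", "delayed"): (825.0, 900.0, 975.0, 1050.0),
}

N_BLOCKS = 4

#: Main-task treadmill speed as a fraction of the maximum running velocity.
SPEED_FRACTION = 0.70


def _check_modality_group(modality: str, group: str) -> None:
    if modality not in MODALITIES:
        raise ValueError(f"unknown modality {modality!r}; expected one of {MODALITIES}")
    if group not in GROUPS:
        raise ValueError(f"unknown group {group!r}; expected one of {GROUPS}")


def told_per_block(modality: str) -> float:
    """Amount (s or m) the participant is told each block lasts."""
    if modality not in MODALITIES:
        raise ValueError(f"unknown modality {modality!r}")
    return _TOLD[modality]


def block_schedule_set(modality: str, group: str) -> tuple[float, ...]:
    """The unordered set of actual per-block amounts for a condition."""
    _check_modality_group(modality, group)
    if group == "standard":
        return (_TOLD[modality],) * N_BLOCKS
    return _SETS[(modality, group)]


@dataclass(frozen=True)
class ProtocolDesign:
    """One session's design: condition, told and actual block schedule."""

    modality: str
    group: str
    told_per_block: float
    actual_per_block: tuple[float, ...]
    n_blocks: int = N_BLOCKS
    speed_fraction: float = SPEED_FRACTION
    mrv: float = 3.2  # m/s; maximum running velocity from calibration

    def __post_init__(self) -> None:
        _check_modality_group(self.modality, self.group)
        if len(self.actual_per_block) != self.n_blocks:
            raise ValueError("actual_per_block must have one entry per block")
        if sorted(self.actual_per_block) != sorted(block_schedule_set(self.modality, self.group)):
            raise ValueError(
                "actual_per_block is not a permutation of the fixed "
                f"{self.modality}/{self.group} schedule set"
            )

    @property
    def actual_total(self) -> float:
        return float(sum(self.actual_per_block))

    @property
    def told_total(self) -> float:
        return self.told_per_block * self.n_blocks


def build_protocol(
    modality: str,
    group: str,
    seed: int,
    *,
    mrv: float = 3.2,
) -> ProtocolDesign:
    """Draw a session design with a seed-determined block order.

    For advanced/delayed conditions the per-block actual amounts are a random
    permutation (sampling without replacement) of the condition's fixed set;
    the standard condition repeats the told amount.
    """
    _check_modality_group(modality, group)
    rng = np.random.default_rng(seed)
    schedule = np.asarray(block_schedule_set(modality, group), dtype=float)
    if group != "standard":
        schedule = rng.permutation(schedule)
    return ProtocolDesign(
        modality=modality,
        group=group,
        told_per_block=_TOLD[modality],
        actual_per_block=tuple(float(x) for x in schedule),
        mrv=mrv,
    )


def prediction_error(actual: float, told: float) -> float:
    """Signed sensory prediction error: actual minus told (s or m).

    Negative in the advanced condition (prompt before the target is reached),
    positive in the delayed condition, zero when feedback is accurate. The
    opposite sign convention (told − actual) also appears in the source
    literature; callers wanting it can negate the result.
    """
    if actual <= 0 or told <= 0:
        raise ValueError("actual and told must be positive and in the same units")
    return float(actual) - float(told)
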