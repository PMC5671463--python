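"""Core domain types shared across the pipeline.

Streams are plain pandas DataFrames with a ``time_s`` column (seconds on a
common session clock starting at 0) plus one or more value columns; this keeps
them trivially serializable as delimited text and easy to inspect.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "Condition",
    "Protocol",
    "SessionData",
    "SprintSegment",
    "SEA_LEVEL",
    "MODERATE_ALTITUDE",
    "HIGH_ALTITUDE",
    "DEFAULT_CONDITIONS",
]


@dataclass(frozen=True)
class Condition:
    """A normobaric-hypoxia exposure level.

    Parameters
    ----------
    label : str
        Altitude tag, conventionally ``"400m"``, ``"2000m"`` or ``"3800m"``.
    fio2 : float
        Inspired oxygen fraction (unitless). Sea level is 0.209; values above
        that are physically possible (hyperoxia) but outside the intended
        range and trigger a warning.
    """

    label: str
    fio2: float

    def __post_init__(self) -> None:
        if not 0.0 < self.fio2 <= 1.0:
            raise ValueError(f"fio2 must be in (0, 1], got {self.fio2}")
        if self.fio2 > 0.209:
            warnings.warn(
                f"fio2={self.fio2} exceeds the normoxic reference of 0.209",
                stacklevel=2,
            )


SEA_LEVEL = Condition("400m", 0.209)
MODERATE_ALTITUDE = Condition("2000m", 0.165)
HIGH_ALTITUDE = Condition("3800m", 0.133)
DEFAULT_CONDITIONS = (SEA_LEVEL, MODERATE_ALTITUDE, HIGH_ALTITUDE)


@dataclass(frozen=True)
class Protocol:
    """Repeated-sprint test protocol: all-out sprints with active recovery
    repeated until task failure (cadence below ``cadence_fail_rpm``).

    Defaults encode the 10-s sprint / 20-s recovery (1:2 work-to-rest)
    format with a 1-min lead-in at 20 W and a fixed torque factor of
    0.8 Nm per kg body mass.
    """

    lead_in_s: float = 60.0
    sprint_s: float = 10.0
    recovery_s: float = 20.0
    cadence_fail_rpm: float = 70.0
    torque_factor: float = 0.8

    def __post_init__(self) -> None:
        if self.sprint_s <= 0 or self.recovery_s <= 0 or self.lead_in_s < 0:
            raise ValueError("protocol durations must be positive")

    @property
    def cycle_s(self) -> float:
        """Duration of one sprint + recovery cycle (s)."""
        return self.sprint_s + self.recovery_s


@dataclass(frozen=True)
class SprintSegment:
    """A detected sprint phase: 1-based index and [t_start, t_end] in
    session-clock seconds."""

    index: int
    t_start: float
    t_end: float

    def __post_init__(self) -> None:
        if self.t_end <= self.t_start:
            raise ValueError("segment must have t_end > t_start")

    @property
    def duration_s(self) -> float:
        return self.t_end - self.t_start


@dataclass
class SessionData:
    """One subject x condition recording.

    All streams share a session clock starting at 0 s. NIRS frames carry
    columns ``time_s, o2hb_uM, hhb_uM, tsi_pct``; crank frames carry
    ``power_w`` / ``cadence_rpm``; ``spo2`` is the 5 Hz pulse-oximetry
    stream; ``vo2`` is the breath-by-breath (irregular) oxygen-uptake
    series; ``hr`` is the 5 Hz heart-rate stream.

    ``extras`` holds scalar side measurements (warm-up best sprint power,
    pre/post femoral blood flow) and ``truth`` optionally holds generator
    ground truth for recovery tests.
    """

    subject_id: str
    condition: Condition
    protocol: Protocol
    nirs_muscle: pd.DataFrame
    nirs_cerebral: Optional[pd.DataFrame]
    power: pd.DataFrame
    cadence: pd.DataFrame
    spo2: pd.DataFrame
    vo2: pd.DataFrame
    hr: Optional[pd.DataFrame] = None
    extras: dict = field(default_factory=dict)
    truth: Optional[dict] = None

    def streams(self) -> dict:
        """Mapping of stream name -> DataFrame for the streams present."""
        out = {
            "nirs_muscle": self.nirs_muscle,
            "power": self.power,
            "cadence": self.cadence,
            "spo2": self.spo2,
            "vo2": self.vo2,
        }
        if self.nirs_cerebral is not None:
            out["nirs_cerebral"] = self.nirs_cerebral
        if self.hr is not None:
            out["hr"] = self.hr
        return out

    def validate(self) -> None:
        """Check the shared-clock invariants (t >= 0, strictly increasing)."""
        for name, df in self.streams().items():
            t = np.asarray(df["time_s"], dtype=float)
            if t.size == 0:
                raise ValueError(f"stream {name} is empty")
            if t[0] < 0:
                raise ValueError(f"stream {name} starts before the session clock")
            if np.any(np.diff(t) <= 0):
                raise ValueError(f"stream {name} has non-increasing timestamps")
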