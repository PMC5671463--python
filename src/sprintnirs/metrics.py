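"""Per-session performance, saturation, and metabolic summary metrics.

Covers the scalar outcomes of a repeated-sprint-to-exhaustion session:
per-sprint mean power, the percent-decrement fatigue index

    S_dec(%) = [1 - (S_1 + ... + S_n) / (S_best * n)] * 100,

total work, task-failure detection from cadence, the highest 30-s rolling
average of oxygen uptake, the SpO2 minimum, and pre/post percent changes.
"""
from __future__ import annotations

from dataclasses import asdict, dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .types import SessionData, SprintSegment

__all__ = [
    "per_sprint_power",
    "fatigue_index",
    "total_work",
    "detect_exhaustion",
    "rolling_peak",
    "stream_min",
    "percent_change",
    "PerformanceSummary",
    "summarize_performance",
]


def _window_mask(t: np.ndarray, seg: SprintSegment) -> np.ndarray:
    return (t >= seg.t_start - 1e-9) & (t <= seg.t_end + 1e-9)


def per_sprint_power(
    power: pd.DataFrame, segments: Sequence[SprintSegment]
) -> list[float]:
    """Arithmetic mean of the power samples inside each sprint window (W),
    in segment order."""
    t = np.asarray(power["time_s"], dtype=float)
    p = np.asarray(power["power_w"], dtype=float)
    means = []
    for seg in segments:
        mask = _window_mask(t, seg)
        if not np.any(mask):
            raise ValueError(f"sprint {seg.index} contains no power samples")
        means.append(float(np.mean(p[mask])))
    return means


def fatigue_index(sprint_powers: Sequence[float]) -> float:
    """Percent decrement score across the scored sprints.

    ``S_dec = [1 - sum(S_i) / (S_best * n)] * 100`` with
    ``S_best = max(S_i)``. Zero when all sprints equal the best; invariant
    to rescaling all powers by a common positive factor.
    """
    powers = np.asarray(sprint_powers, dtype=float)
    if powers.size == 0:
        raise ValueError("need at least one sprint power")
    if np.any(powers <= 0):
        raise ValueError("sprint powers must be positive")
    s_best = float(np.max(powers))
    return float((1.0 - powers.sum() / (s_best * powers.size)) * 100.0)


def total_work(
    power: pd.DataFrame, segments: Sequence[SprintSegment]
) -> float:
    """Trapezoidal integral of power over all sprint windows, in kJ."""
    t = np.asarray(power["time_s"], dtype=float)
    p = np.asarray(power["power_w"], dtype=float)
    joules = 0.0
    for seg in segments:
        mask = _window_mask(t, seg)
        if np.count_nonzero(mask) < 2:
            raise ValueError(f"sprint {seg.index} has too few power samples")
        joules += float(np.trapezoid(p[mask], t[mask]))
    return joules / 1000.0


def detect_exhaustion(
    cadence: pd.DataFrame,
    segments: Sequence[SprintSegment],
    threshold_rpm: float = 70.0,
) -> Optional[int]:
    """1-based index of the first sprint whose cadence falls below the
    task-failure threshold, or None if cadence never drops."""
    t = np.asarray(cadence["time_s"], dtype=float)
    c = np.asarray(cadence["cadence_rpm"], dtype=float)
    for seg in segments:
        mask = _window_mask(t, seg)
        if np.any(mask) and np.min(c[mask]) < threshold_rpm:
            return seg.index
    return None


def rolling_peak(
    time_s: np.ndarray, values: np.ndarray, window_s: float = 30.0
) -> float:
    """Maximum time-weighted mean over all ``window_s`` windows anchored at
    each sample (used for the highest 30-s VO2 average).

    Works on irregular series: the window mean is the trapezoidal integral
    of the linear interpolant over [t, t + window_s], divided by window_s.
    """
    t = np.asarray(time_s, dtype=float)
    y = np.asarray(values, dtype=float)
    if t.size < 2:
        raise ValueError("need at least 2 samples")
    if t[-1] - t[0] < window_s:
        raise ValueError(
            f"series span {t[-1] - t[0]:.1f} s shorter than window {window_s} s"
        )
    # cumulative trapezoidal integral, linearly interpolable at window edges
    cum = np.concatenate([[0.0], np.cumsum(np.diff(t) * (y[:-1] + y[1:]) / 2.0)])

    def integral_at(x: np.ndarray) -> np.ndarray:
        idx = np.searchsorted(t, x, side="right") - 1
        idx = np.clip(idx, 0, t.size - 2)
        frac = x - t[idx]
        y_at = y[idx] + (y[idx + 1] - y[idx]) * frac / (t[idx + 1] - t[idx])
        return cum[idx] + frac * (y[idx] + y_at) / 2.0

    starts = t[t <= t[-1] - window_s + 1e-9]
    if starts.size == 0:
        starts = t[:1]
    means = (integral_at(starts + window_s) - integral_at(starts)) / window_s
    return float(np.max(means))


def stream_min(spo2: pd.DataFrame | np.ndarray) -> float:
    """Global minimum of the raw stream (the session SpO2 statistic)."""
    if isinstance(spo2, pd.DataFrame):
        values = np.asarray(spo2["spo2_pct"], dtype=float)
    else:
        values = np.asarray(spo2, dtype=float)
    if values.size == 0:
        raise ValueError("empty stream")
    return float(np.min(values))


def percent_change(pre: float, post: float) -> float:
    """(post - pre) / pre * 100."""
    if pre == 0:
        raise ValueError("pre value must be nonzero")
    return (post - pre) / pre * 100.0


@dataclass
class PerformanceSummary:
    """One row of the per-session performance table."""

    subject_id: str
    condition: str
    n_sprints: int
    mean_power_w: float
    total_work_kj: float
    s_dec_pct: float
    spo2_min_pct: float
    vo2_peak30_mlkgmin: float
    hr_max_bpm: float
    exhaustion_sprint: Optional[int]
    pacing_ok: bool

    def as_dict(self) -> dict:
        return asdict(self)


def summarize_performance(
    session: SessionData,
    segments: Sequence[SprintSegment],
    pacing_threshold: float = 0.95,
) -> PerformanceSummary:
    """Assemble the Table-1-style summary for one session.

    ``mean_power_w`` is the mean of the per-sprint mean powers. The pacing
    flag checks that sprints 1-2 reached at least ``pacing_threshold`` of
    the warm-up best sprint (carried in ``session.extras``); it is True
    when no warm-up reference is available.
    """
    powers = per_sprint_power(session.power, segments)
    warmup_best = session.extras.get("warmup_best_w")
    if warmup_best:
        first_two = powers[: min(2, len(powers))]
        pacing_ok = all(p >= pacing_threshold * warmup_best for p in first_two)
    else:
        pacing_ok = True
    hr_max = (
        float(np.max(session.hr["hr_bpm"])) if session.hr is not None else float("nan")
    )
    return PerformanceSummary(
        subject_id=session.subject_id,
        condition=session.condition.label,
        n_sprints=len(segments),
        mean_power_w=float(np.mean(powers)),
        total_work_kj=total_work(session.power, segments),
        s_dec_pct=fatigue_index(powers),
        spo2_min_pct=stream_min(session.spo2),
        vo2_peak30_mlkgmin=rolling_peak(
            np.asarray(session.vo2["time_s"]), np.asarray(session.vo2["vo2_mlkgmin"])
        ),
        hr_max_bpm=hr_max,
        exhaustion_sprint=detect_exhaustion(
            session.cadence, segments, session.protocol.cadence_fail_rpm
        ),
        pacing_ok=pacing_ok,
    )
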