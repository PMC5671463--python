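"""Sprint-phase detection from filtered muscle HHb and per-sprint
max/min/delta extraction for all channels.

Deoxyhemoglobin is the reference signal for sprint onsets: each sprint
produces a steep HHb rise, so candidate onsets are upward threshold
crossings of the HHb first derivative (threshold = k * MAD of the
derivative, a robust scale that is insensitive to slow drift). Because the
zero-phase low-pass filter spreads the rise symmetrically around the true
onset, the crossing time alone is biased early by a fraction of a second;
each candidate is therefore refined by maximizing the correlation between
the local derivative and the derivative of a canonical sprint/recovery
cycle passed through the same filter (a matched filter built from the
protocol timing alone).

Cerebral channels reuse the muscle-derived segments: all streams share one
session clock and one event set.
"""
from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .preprocess import (
    ChannelSet,
    DEFAULT_CUTOFF_HZ,
    DEFAULT_ORDER,
    lowpass_zero_phase,
)
from .types import Protocol, SprintSegment

__all__ = ["detect_sprints", "extract_deltas"]

#: nominal deoxygenation / reoxygenation time constants (s) of the matched
#: template; only the template shape depends on these, not the data model
TEMPLATE_TAU_DEOXY_S = 2.5
TEMPLATE_TAU_REOXY_S = 8.0


def _cycle_template_derivative(
    fs: float,
    protocol: Protocol,
    cutoff_hz: float,
    order: int,
) -> tuple[np.ndarray, int]:
    """Derivative of one canonical sprint/recovery cycle after the standard
    zero-phase filter. Returns (derivative, index of the onset sample)."""
    pre = protocol.recovery_s
    total = pre + protocol.cycle_s + protocol.recovery_s
    t = np.arange(int(total * fs) + 1) / fs
    x = np.zeros_like(t)
    rise = (t >= pre) & (t < pre + protocol.sprint_s)
    x[rise] = 1.0 - np.exp(-(t[rise] - pre) / TEMPLATE_TAU_DEOXY_S)
    level = 1.0 - np.exp(-protocol.sprint_s / TEMPLATE_TAU_DEOXY_S)
    fall = t >= pre + protocol.sprint_s
    x[fall] = level * np.exp(
        -(t[fall] - pre - protocol.sprint_s) / TEMPLATE_TAU_REOXY_S
    )
    xf = lowpass_zero_phase(x, fs, order=order, cutoff_hz=cutoff_hz)
    d = np.gradient(xf, 1.0 / fs)
    return d, int(round(pre * fs))


def _refine_onset(
    deriv: np.ndarray,
    i0: int,
    template: np.ndarray,
    template_onset: int,
    fs: float,
    search_s: float,
) -> int:
    """Shift a coarse onset within +-search_s to maximize correlation with
    the template derivative."""
    w = int(round(search_s * fs))
    best_i, best_score = i0, -np.inf
    for shift in range(-w, w + 1):
        start = i0 + shift - template_onset
        if start < 0 or start + template.size > deriv.size:
            continue
        score = float(np.dot(deriv[start : start + template.size], template))
        if score > best_score:
            best_score, best_i = score, i0 + shift
    return best_i, best_score


def _grid_onsets_by_xcorr(
    hhb: np.ndarray,
    t: np.ndarray,
    fs: float,
    protocol: Protocol,
    cutoff_hz: float,
    order: int,
) -> np.ndarray:
    """Fallback: align a protocol-periodic template with the signal by
    cross-correlation over one cycle of phase offsets."""
    template, t_onset = _cycle_template_derivative(fs, protocol, cutoff_hz, order)
    core = template[t_onset : t_onset + int(protocol.cycle_s * fs)]
    deriv = np.gradient(hhb, 1.0 / fs)
    cycle_n = int(round(protocol.cycle_s * fs))
    n_cycles = max((deriv.size - core.size) // cycle_n, 1)
    best_phase, best_score = 0, -np.inf
    for phase in range(cycle_n):
        score = 0.0
        for k in range(n_cycles):
            start = phase + k * cycle_n
            if start + core.size > deriv.size:
                break
            score += float(np.dot(deriv[start : start + core.size], core))
        if score > best_score:
            best_score, best_phase = score, phase
    onsets = []
    start = best_phase
    while start + int(protocol.sprint_s * fs) < deriv.size:
        onsets.append(t[start])
        start += cycle_n
    return np.asarray(onsets)


def detect_sprints(
    hhb_ref: np.ndarray | ChannelSet,
    protocol: Protocol,
    sample_rate_hz: float | None = None,
    time_s: np.ndarray | None = None,
    k_mad: float = 3.0,
    min_gap_s: float = 25.0,
    grid_fallback: bool = False,
    refine: bool = True,
    fill_gaps: bool = True,
    refine_search_s: float = 3.0,
    cutoff_hz: float = DEFAULT_CUTOFF_HZ,
    order: int = DEFAULT_ORDER,
) -> list[SprintSegment]:
    """Detect sprint phases from the filtered muscle HHb series.

    Parameters
    ----------
    hhb_ref
        Filtered muscle HHb series (or a ChannelSet, whose ``hhb_uM`` and
        grid are used).
    protocol
        Sprint/recovery timing; each detected segment spans
        ``[onset, onset + protocol.sprint_s]``.
    k_mad
        Derivative threshold in multiples of the MAD of the derivative.
    min_gap_s
        Refractory gap between onsets; the default (25 s) sits just below
        one 30-s work:rest cycle.
    grid_fallback
        If fewer than 3 crossings are found, fall back to protocol-grid
        onsets aligned by cross-correlation instead of raising.

    Returns
    -------
    list of SprintSegment in increasing time order; its length defines the
    session's sprint count for all downstream stages.
    """
    if isinstance(hhb_ref, ChannelSet):
        time_s = hhb_ref.time_s
        sample_rate_hz = hhb_ref.sample_rate_hz
        hhb = np.asarray(hhb_ref.hhb_uM, dtype=float)
    else:
        hhb = np.asarray(hhb_ref, dtype=float)
        if sample_rate_hz is None:
            raise ValueError("sample_rate_hz required when passing a bare array")
        if time_s is None:
            time_s = np.arange(hhb.size) / sample_rate_hz
    if hhb.size == 0:
        raise ValueError("empty HHb series")
    fs = float(sample_rate_hz)
    dt = 1.0 / fs

    deriv = np.gradient(hhb, dt)
    med = np.median(deriv)
    mad = np.median(np.abs(deriv - med))
    threshold = k_mad * mad

    if mad > 0:
        above = deriv >= threshold
        crossings = np.flatnonzero(~above[:-1] & above[1:]) + 1
    else:
        crossings = np.array([], dtype=int)

    kept: list[int] = []
    last_t = -np.inf
    for i in crossings:
        if time_s[i] - last_t >= min_gap_s:
            kept.append(int(i))
            last_t = time_s[i]

    if len(kept) < 3 and grid_fallback:
        onsets = _grid_onsets_by_xcorr(hhb, time_s, fs, protocol, cutoff_hz, order)
        return [
            SprintSegment(index=k + 1, t_start=float(t0), t_end=float(t0 + protocol.sprint_s))
            for k, t0 in enumerate(onsets)
        ]
    if not kept:
        raise ValueError(
            "no sprint onsets detected; pass grid_fallback=True to fall back "
            "to protocol-grid alignment"
        )

    if fill_gaps and len(kept) >= 2:
        # the ergometer enforces a strict work:rest period, so an
        # inter-onset gap of ~2+ cycles means a missed (low-amplitude)
        # sprint; insert candidates on the cycle grid and let the matched
        # filter lock them onto the actual rise
        cycle_n = protocol.cycle_s * fs
        filled: list[int] = []
        for a, b in zip(kept[:-1], kept[1:]):
            filled.append(a)
            m = int(round((b - a) / cycle_n))
            if m >= 2 and (b - a) > 1.6 * cycle_n:
                step = (b - a) / m
                filled.extend(int(round(a + j * step)) for j in range(1, m))
        filled.append(kept[-1])
        kept = filled

    if refine:
        template, t_onset = _cycle_template_derivative(fs, protocol, cutoff_hz, order)
        refined = [
            _refine_onset(deriv, i, template, t_onset, fs, refine_search_s)
            for i in kept
        ]
        # matched-filter score validation: a spurious crossing (e.g. in the
        # lead-in) scores far below the session's typical sprint, and a
        # missed final sprint shows up as a scoring candidate one cycle on
        med_score = float(np.median([s for _, s in refined]))
        floor = 0.25 * med_score
        # probing beyond the detected range demands stronger evidence than
        # keeping an onset the crossing detector already proposed
        probe_floor = 0.5 * med_score
        refined = [(i, s) for i, s in refined if s >= floor]
        cycle_n = int(round(protocol.cycle_s * fs))
        sprint_n = int(round(protocol.sprint_s * fs))
        while refined:
            cand = refined[-1][0] + cycle_n
            if cand + sprint_n >= deriv.size:
                break
            i, s = _refine_onset(
                deriv, cand, template, t_onset, fs, refine_search_s
            )
            if s < probe_floor or time_s[i] - time_s[refined[-1][0]] < min_gap_s:
                break
            refined.append((i, s))
        while refined:
            cand = refined[0][0] - cycle_n
            if cand - int(round(refine_search_s * fs)) < 0:
                break
            i, s = _refine_onset(
                deriv, cand, template, t_onset, fs, refine_search_s
            )
            if s < probe_floor or time_s[refined[0][0]] - time_s[i] < min_gap_s:
                break
            refined.insert(0, (i, s))
        kept = sorted({i for i, _ in refined})

    segments = []
    for k, i in enumerate(kept):
        t0 = float(time_s[i])
        segments.append(
            SprintSegment(index=k + 1, t_start=t0, t_end=t0 + protocol.sprint_s)
        )
    return segments


def extract_deltas(
    channel_sets: Iterable[ChannelSet] | ChannelSet,
    segments: Sequence[SprintSegment],
    lag_s: float = 0.0,
    channels: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-sprint max/min/delta for every channel of every site.

    For each segment the extremes are searched over
    ``[t_start, t_end + lag_s]`` (inclusive). Ties go to the earliest
    sample. ``channels`` optionally restricts extraction to a subset of
    channel names. Returns a long-format frame with columns
    ``sprint_index, site, channel, t_start_s, max, min, delta``.
    """
    if isinstance(channel_sets, ChannelSet):
        channel_sets = [channel_sets]
    rows = []
    for cs in channel_sets:
        t = np.asarray(cs.time_s, dtype=float)
        use = cs.channel_names if channels is None else tuple(channels)
        series = {ch: cs.channel(ch) for ch in use}
        for seg in segments:
            lo, hi = seg.t_start - 1e-9, seg.t_end + lag_s + 1e-9
            if lo < t[0] - 1e-9 or hi > t[-1] + 1e-9:
                raise ValueError(
                    f"segment {seg.index} [{seg.t_start}, {seg.t_end + lag_s}] "
                    f"outside recorded range [{t[0]}, {t[-1]}] for site {cs.site}"
                )
            i0 = int(np.searchsorted(t, lo, side="left"))
            i1 = int(np.searchsorted(t, hi, side="right"))
            if i1 <= i0:
                raise ValueError(f"segment {seg.index} contains no samples")
            for ch in use:
                y = series[ch][i0:i1]
                vmax = float(np.max(y))
                vmin = float(np.min(y))
                rows.append(
                    {
                        "sprint_index": seg.index,
                        "site": cs.site,
                        "channel": ch,
                        "t_start_s": seg.t_start,
                        "max": vmax,
                        "min": vmin,
                        "delta": vmax - vmin,
                    }
                )
    return pd.DataFrame(rows)
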