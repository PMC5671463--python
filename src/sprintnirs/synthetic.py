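"""Synthetic repeated-sprint session generator.

Emulates the signal structure the analysis pipeline assumes: muscle and
cerebral hemoglobin concentrations that deoxygenate mono-exponentially during
each 10-s sprint and reoxygenate during each 20-s recovery, a decrementing
crank-power profile ending in task failure (cadence < 70 rpm), pedal-stroke
sinusoidal artifacts, slow instrument drift, white measurement noise,
per-subject random amplitude intercepts shared across conditions, and a
logistic SpO2 decline whose floor depends on the hypoxia level.

Every generated session carries a ``truth`` block (sprint onsets, per-sprint
asymptotic and realized deltas per channel, sprint count) so that detection
and extraction can be scored against known ground truth.

Within-sprint kinetics are mono-exponential toward (current level + delta):
with sprint duration T and deoxygenation time constant tau, the realized
max - min of the noiseless HHb trace on a sprint window is exactly
``delta * (1 - exp(-T / tau))``, which serves as a closed-form oracle.
"""
from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence, Union

import numpy as np
import pandas as pd

from .types import (
    Condition,
    DEFAULT_CONDITIONS,
    Protocol,
    SessionData,
)

__all__ = ["SynthParams", "generate_session", "generate_cohort"]

PerCondition = Union[float, Mapping[str, float]]

#: channels synthesized per NIRS site; o2hb/tsi are mirrored off the HHb
#: excursion so that the closed-form delta oracle holds for every channel
CHANNELS = ("hhb", "o2hb", "tsi")


def _default_amp() -> dict:
    # sprint-phase asymptotic delta amplitudes at the sea-level reference;
    # uM for Hb channels, percentage points for TSI
    return {
        "muscle_hhb": 10.0,
        "muscle_o2hb": 9.0,
        "muscle_tsi": 12.0,
        "cerebral_hhb": 4.0,
        "cerebral_o2hb": 5.0,
        "cerebral_tsi": 4.0,
    }


def _default_amp_scale() -> dict:
    # per-condition multiplier on the per-channel amplitudes: muscle deltas
    # shrink at severe hypoxia while cerebral deltas grow
    return {"400m": 1.0, "2000m": 1.0, "3800m": 0.8}


def _default_n_sprints_mean() -> dict:
    return {"400m": 30.0, "2000m": 20.0, "3800m": 15.0}


def _default_spo2_end() -> dict:
    return {"400m": 94.0, "2000m": 87.0, "3800m": 77.0}


def _default_vo2_peak() -> dict:
    return {"400m": 40.0, "2000m": 36.5, "3800m": 32.0}


def _default_hr_max() -> dict:
    return {"400m": 185.0, "2000m": 183.0, "3800m": 178.0}


def _default_blood_flow() -> dict:
    # femoral-artery blood flow (ml/min) pre and 1-min post test
    return {
        "400m": (405.0, 694.0),
        "2000m": (633.0, 847.0),
        "3800m": (782.0 / 1.24, 782.0),
    }


@dataclass(frozen=True)
class SynthParams:
    """Parameters of the synthetic cohort.

    Per-condition fields accept either a scalar (applied to every condition)
    or a mapping from condition label to value. Hb amplitudes are in uM, TSI
    amplitudes in percentage points, time constants in seconds.
    """

    n_subjects: int = 11
    n_sprints_mean: PerCondition = field(default_factory=_default_n_sprints_mean)
    n_sprints_sd: float = 8.0
    n_sprints_min: int = 5
    amp: Mapping[str, float] = field(default_factory=_default_amp)
    amp_scale: PerCondition = field(default_factory=_default_amp_scale)
    amp_trend: PerCondition = -0.2
    tau_deoxy_s: float = 2.5
    tau_reoxy_s: float = 8.0
    noise_sd: float = 1.0
    pedal_amp: float = 2.0
    pedal_hz: float = 85.0 / 60.0
    drift_per_min: float = 0.2
    subject_sd: float = 1.5
    power_best_w: float = 750.0
    power_decrement_frac: float = 0.03
    power_noise_w: float = 10.0
    spo2_start: PerCondition = 98.0
    spo2_end: PerCondition = field(default_factory=_default_spo2_end)
    vo2_peak: PerCondition = field(default_factory=_default_vo2_peak)
    hr_max: PerCondition = field(default_factory=_default_hr_max)
    muscle_rate_hz: float = 10.0
    cerebral_rate_hz: float = 50.0
    include_cerebral: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        for name in ("n_sprints_sd", "noise_sd", "subject_sd", "power_noise_w"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.power_decrement_frac < 1.0:
            raise ValueError("power_decrement_frac must be in [0, 1)")
        if self.tau_deoxy_s <= 0 or self.tau_reoxy_s <= 0:
            raise ValueError("time constants must be positive")
        for ch, a in self.amp.items():
            if a <= 0:
                raise ValueError(f"amp[{ch}] must be > 0")

    def per_condition(self, name: str, condition: Condition) -> float:
        """Resolve a scalar-or-mapping field for one condition."""
        value = getattr(self, name)
        if isinstance(value, Mapping):
            try:
                return float(value[condition.label])
            except KeyError:
                raise KeyError(
                    f"{name} has no entry for condition {condition.label!r}"
                ) from None
        return float(value)


def _condition_key(condition: Condition) -> int:
    # stable across processes (unlike hash()), independent of condition order
    return zlib.crc32(condition.label.encode()) & 0x7FFFFFFF


def _subject_rng(seed: int, subject_index: int) -> np.random.Generator:
    return np.random.default_rng([seed, 0x5EED, subject_index])


def _session_rng(seed: int, subject_index: int, condition: Condition) -> np.random.Generator:
    return np.random.default_rng([seed, subject_index, _condition_key(condition)])


def _draw_n_sprints(
    rng: np.random.Generator, mean: float, sd: float, floor: int
) -> int:
    """Rounded-normal sprint count, re-drawn below ``floor``.

    The floor defaults to 5 so every session supports the 5-point
    set-duration grid (observed real-world sessions span roughly 7-47
    sprints); draws below 3 additionally warn, draws below 1 are treated
    as re-draws of an ill-posed configuration and error out if persistent.
    """
    if mean < 1:
        raise ValueError("n_sprints mean below 1 cannot define a session")
    floor = max(floor, 1)
    warned = False
    for _ in range(100):
        n = int(round(rng.normal(mean, sd)))
        if n >= floor:
            return n
        if n < 3 and not warned:
            warnings.warn(f"n_sprints draw {n} < 3; re-drawing", stacklevel=3)
            warned = True
    raise ValueError(
        f"could not draw n_sprints >= {floor} from N({mean}, {sd}^2) in 100 attempts"
    )


def _excursion(
    t: np.ndarray,
    onsets: np.ndarray,
    deltas: np.ndarray,
    sprint_s: float,
    tau_deoxy_s: float,
    tau_reoxy_s: float,
) -> np.ndarray:
    """Piecewise mono-exponential deoxygenation excursion (baseline 0).

    During sprint k the level rises toward (level at onset + deltas[k]) with
    time constant ``tau_deoxy_s``; during recovery it decays back toward 0
    with ``tau_reoxy_s``. Residual deoxygenation carries over between
    sprints, so the session baseline creeps upward, but the within-window
    max - min stays exactly deltas[k] * (1 - exp(-sprint_s / tau_deoxy_s)).
    """
    x = np.zeros_like(t)
    level = 0.0
    n = len(onsets)
    t_stop = t[-1] + 1.0
    for k in range(n):
        t_on = onsets[k]
        t_off = t_on + sprint_s
        t_next = onsets[k + 1] if k + 1 < n else t_stop
        i_on = np.searchsorted(t, t_on, side="left")
        i_off = np.searchsorted(t, t_off, side="left")
        i_next = np.searchsorted(t, t_next, side="left")
        target = level + deltas[k]
        x[i_on:i_off] = target - deltas[k] * np.exp(
            -(t[i_on:i_off] - t_on) / tau_deoxy_s
        )
        level_off = target - deltas[k] * np.exp(-sprint_s / tau_deoxy_s)
        x[i_off:i_next] = level_off * np.exp(
            -(t[i_off:i_next] - t_off) / tau_reoxy_s
        )
        level = level_off * np.exp(-(t_next - t_off) / tau_reoxy_s)
    return x


def _sprint_mask(
    t: np.ndarray, onsets: np.ndarray, sprint_s: float, closed: bool = False
) -> np.ndarray:
    """Sprint-phase sample mask; ``closed`` includes the sample at exactly
    onset + sprint_s (the ergometer holds the sprint load through the final
    sample, whereas the NIRS excursion is continuous there)."""
    mask = np.zeros(t.shape, dtype=bool)
    side = "right" if closed else "left"
    for t_on in onsets:
        i0 = np.searchsorted(t, t_on, side="left")
        i1 = np.searchsorted(t, t_on + sprint_s, side=side)
        mask[i0:i1] = True
    return mask


def generate_session(
    params: SynthParams,
    subject_index: int,
    condition: Condition,
    protocol: Protocol | None = None,
) -> SessionData:
    """Generate one subject x condition session with ground truth.

    The per-subject amplitude intercept is drawn from a subject-keyed random
    stream, so the same subject_index yields the same intercept in every
    condition (the random-effect structure the mixed model assumes).
    """
    protocol = protocol or Protocol()
    rng = _session_rng(params.seed, subject_index, condition)
    subj_rng = _subject_rng(params.seed, subject_index)
    b_subject = subj_rng.normal(0.0, params.subject_sd) if params.subject_sd > 0 else 0.0

    mean_n = params.per_condition("n_sprints_mean", condition)
    n_sprints = _draw_n_sprints(
        rng, mean_n, params.n_sprints_sd, params.n_sprints_min
    )

    onsets = protocol.lead_in_s + protocol.cycle_s * np.arange(n_sprints)
    session_end = onsets[-1] + protocol.cycle_s + protocol.recovery_s
    amp_scale = params.per_condition("amp_scale", condition)
    trend = params.per_condition("amp_trend", condition)
    frac = np.arange(1, n_sprints + 1) / n_sprints

    ref_amp = params.amp["muscle_hhb"]
    truth_deltas: dict[str, np.ndarray] = {}
    site_excursion_amps: dict[str, np.ndarray] = {}
    for site in ("muscle", "cerebral"):
        base = params.amp[f"{site}_hhb"] * amp_scale + b_subject * (
            params.amp[f"{site}_hhb"] / ref_amp
        )
        base = max(base, 0.1 * params.amp[f"{site}_hhb"])
        d_hhb = base * (1.0 + trend * frac)
        d_hhb = np.maximum(d_hhb, 0.05 * params.amp[f"{site}_hhb"])
        site_excursion_amps[site] = d_hhb
        for ch in CHANNELS:
            ratio = params.amp[f"{site}_{ch}"] / params.amp[f"{site}_hhb"]
            truth_deltas[f"{site}_{ch}"] = d_hhb * ratio

    gain = 1.0 - np.exp(-protocol.sprint_s / params.tau_deoxy_s)

    def nirs_frame(site: str, rate_hz: float) -> pd.DataFrame:
        n = int(np.floor(session_end * rate_hz)) + 1
        t = np.arange(n) / rate_hz
        exc = _excursion(
            t,
            onsets,
            site_excursion_amps[site],
            protocol.sprint_s,
            params.tau_deoxy_s,
            params.tau_reoxy_s,
        )
        in_sprint = _sprint_mask(t, onsets, protocol.sprint_s)
        pedal = np.where(
            in_sprint,
            params.pedal_amp * np.sin(2.0 * np.pi * params.pedal_hz * t),
            0.0,
        )
        drift = params.drift_per_min / 60.0 * t
        r_o2hb = params.amp[f"{site}_o2hb"] / params.amp[f"{site}_hhb"]
        r_tsi = params.amp[f"{site}_tsi"] / params.amp[f"{site}_hhb"]
        tsi_base = 70.0 if site == "muscle" else 68.0
        noise = lambda scale: (  # noqa: E731
            rng.normal(0.0, scale, n) if scale > 0 else 0.0
        )
        hhb = exc + pedal + drift + noise(params.noise_sd)
        o2hb = -r_o2hb * exc + r_o2hb * pedal + drift + noise(params.noise_sd)
        tsi = tsi_base - r_tsi * exc + r_tsi * pedal + noise(
            params.noise_sd if params.noise_sd > 0 else 0.0
        )
        return pd.DataFrame(
            {"time_s": t, "o2hb_uM": o2hb, "hhb_uM": hhb, "tsi_pct": tsi}
        )

    nirs_muscle = nirs_frame("muscle", params.muscle_rate_hz)
    nirs_cerebral = (
        nirs_frame("cerebral", params.cerebral_rate_hz)
        if params.include_cerebral
        else None
    )

    # crank streams at the muscle-NIRS rate
    rate = params.muscle_rate_hz
    n = int(np.floor(session_end * rate)) + 1
    t = np.arange(n) / rate
    in_sprint = _sprint_mask(t, onsets, protocol.sprint_s, closed=True)
    sprint_idx = np.clip(
        np.searchsorted(onsets, t, side="right") - 1, 0, n_sprints - 1
    )
    decay = (1.0 - params.power_decrement_frac) ** sprint_idx
    sprint_power = params.power_best_w * decay
    power = np.where(in_sprint, sprint_power, 20.0)
    if params.power_noise_w > 0:
        power = power + np.where(
            in_sprint, rng.normal(0.0, params.power_noise_w, n), 0.0
        )

    cadence = np.full(n, 85.0)
    sprint_cadence = np.maximum(110.0 * decay, 78.0)
    cadence = np.where(in_sprint, sprint_cadence, cadence)
    # final sprint: cadence collapses through the task-failure threshold
    last = (t >= onsets[-1]) & (t < onsets[-1] + protocol.sprint_s)
    ramp = (t[last] - onsets[-1]) / protocol.sprint_s
    cadence[last] = 90.0 - ramp * (90.0 - (protocol.cadence_fail_rpm - 5.0))
    if params.noise_sd > 0:
        cad_noise = rng.normal(0.0, 1.0, n)
        cadence = cadence + cad_noise
        # keep the failure criterion attributable to the final sprint only
        not_last_sprint = in_sprint & ~last
        cadence[not_last_sprint] = np.maximum(
            cadence[not_last_sprint], protocol.cadence_fail_rpm + 2.0
        )

    power_df = pd.DataFrame({"time_s": t, "power_w": power})
    cadence_df = pd.DataFrame({"time_s": t, "cadence_rpm": cadence})

    # SpO2 at 5 Hz: logistic decline from spo2_start to spo2_end
    t5 = np.arange(int(np.floor(session_end * 5.0)) + 1) / 5.0
    s0 = params.per_condition("spo2_start", condition)
    s1 = params.per_condition("spo2_end", condition)
    set_dur = session_end - protocol.lead_in_s
    t_mid = protocol.lead_in_s + 0.4 * set_dur
    width = max(set_dur / 8.0, 1.0)
    spo2 = s1 + (s0 - s1) / (1.0 + np.exp((t5 - t_mid) / width))
    if params.noise_sd > 0:
        spo2 = spo2 + rng.normal(0.0, 0.3, t5.size)
    spo2_df = pd.DataFrame({"time_s": t5, "spo2_pct": spo2})

    # heart rate at 5 Hz: saturating rise to the condition's maximum
    hr_max = params.per_condition("hr_max", condition)
    hr = 90.0 + (hr_max - 90.0) * (1.0 - np.exp(-np.maximum(t5 - 30.0, 0.0) / 60.0))
    if params.noise_sd > 0:
        hr = hr + rng.normal(0.0, 1.0, t5.size)
    hr_df = pd.DataFrame({"time_s": t5, "hr_bpm": hr})

    # breath-by-breath VO2 on an irregular clock (~1 Hz with jitter)
    breath_t = []
    tb = 0.0
    while tb < session_end:
        breath_t.append(tb)
        interval = 1.8 if tb < protocol.lead_in_s else 1.0
        if params.noise_sd > 0:
            interval *= 1.0 + 0.15 * rng.uniform(-1.0, 1.0)
        tb += max(interval, 0.3)
    breath_t = np.asarray(breath_t)
    vo2_peak = params.per_condition("vo2_peak", condition)
    vo2 = 8.0 + (vo2_peak - 8.0) * (
        1.0 - np.exp(-np.maximum(breath_t - protocol.lead_in_s, 0.0) / 45.0)
    )
    if params.noise_sd > 0:
        vo2 = vo2 + rng.normal(0.0, 1.0, breath_t.size)
    vo2_df = pd.DataFrame({"time_s": breath_t, "vo2_mlkgmin": vo2})

    bf_pre, bf_post = _default_blood_flow().get(
        condition.label, (500.0, 750.0)
    )
    extras = {
        "warmup_best_w": params.power_best_w,
        "blood_flow_pre_mlmin": bf_pre,
        "blood_flow_post_mlmin": bf_post,
    }

    truth = {
        "n_sprints": n_sprints,
        "sprint_onsets_s": onsets.copy(),
        "delta_asym": truth_deltas,
        "delta_realized": {ch: d * gain for ch, d in truth_deltas.items()},
        "sprint_power_w": params.power_best_w
        * (1.0 - params.power_decrement_frac) ** np.arange(n_sprints),
        "subject_intercept": b_subject,
    }

    return SessionData(
        subject_id=f"S{subject_index + 1:02d}",
        condition=condition,
        protocol=protocol,
        nirs_muscle=nirs_muscle,
        nirs_cerebral=nirs_cerebral,
        power=power_df,
        cadence=cadence_df,
        spo2=spo2_df,
        vo2=vo2_df,
        hr=hr_df,
        extras=extras,
        truth=truth,
    )


def generate_cohort(
    params: SynthParams,
    conditions: Sequence[Condition] = DEFAULT_CONDITIONS,
    protocol: Protocol | None = None,
) -> list[SessionData]:
    """Generate every subject under every condition (a full crossover cohort).

    Per-subject random intercepts are shared across that subject's sessions.
    """
    if len(conditions) < 1:
        raise ValueError("at least one condition is required")
    sessions = []
    for i in range(params.n_subjects):
        for cond in conditions:
            sessions.append(generate_session(params, i, cond, protocol))
    return sessions


def null_params(base: SynthParams | None = None, **overrides) -> SynthParams:
    """Params with identical amplitudes across conditions (a true null for
    the condition effect); other structure is left at the study defaults."""
    base = base or SynthParams()
    return replace(base, amp_scale=1.0, **overrides)
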