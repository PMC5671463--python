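"""NIRS preprocessing: resampling to a common grid, zero-phase low-pass
filtering, and derivation of the Hbdiff / tHb channels.

Processing order is fixed: resample -> filter -> derive. All concentration
channels and TSI are treated identically. Native rates differ by site
(10 Hz muscle, 50 Hz cerebral), so both are first brought onto a uniform
10 Hz analysis grid by linear interpolation.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, filtfilt

from .types import SessionData

__all__ = [
    "ChannelSet",
    "resample_to_grid",
    "lowpass_zero_phase",
    "derive_channels",
    "preprocess_session",
    "DEFAULT_RATE_HZ",
    "DEFAULT_CUTOFF_HZ",
    "DEFAULT_ORDER",
]

DEFAULT_RATE_HZ = 10.0
DEFAULT_CUTOFF_HZ = 0.2
DEFAULT_ORDER = 4

#: differential pathlength factors used at acquisition (metadata only;
#: concentrations arrive already converted)
DPF = {"muscle": 4.0, "cerebral": 6.0}


@dataclass
class ChannelSet:
    """Uniformly sampled, filtered NIRS channels for one site.

    Invariants: ``thb = o2hb + hhb`` and ``hbdiff = o2hb - hhb`` hold
    sample-wise by construction.
    """

    site: str
    time_s: np.ndarray
    o2hb_uM: np.ndarray
    hhb_uM: np.ndarray
    hbdiff_uM: np.ndarray
    thb_uM: np.ndarray
    tsi_pct: np.ndarray
    sample_rate_hz: float
    dpf: float = float("nan")

    def channel(self, name: str) -> np.ndarray:
        return getattr(self, f"{name}_uM" if name != "tsi" else "tsi_pct")

    @property
    def channel_names(self) -> tuple:
        return ("o2hb", "hhb", "hbdiff", "thb", "tsi")


def resample_to_grid(
    time_s: np.ndarray, values: np.ndarray, target_rate_hz: float
) -> tuple[np.ndarray, np.ndarray]:
    """Linearly interpolate an (irregular) series onto a uniform grid.

    The grid starts at the first input timestamp and never extends beyond
    the last one (no extrapolation).
    """
    t = np.asarray(time_s, dtype=float)
    y = np.asarray(values, dtype=float)
    if t.size < 2:
        raise ValueError("need at least 2 samples to resample")
    dt = np.diff(t)
    if np.any(dt < 0):
        raise ValueError("timestamps must be strictly increasing")
    if np.any(dt == 0):
        raise ValueError("duplicate timestamps")
    if target_rate_hz <= 0:
        raise ValueError("target_rate_hz must be positive")
    span = t[-1] - t[0]
    n = int(np.floor(span * target_rate_hz + 1e-9)) + 1
    grid = t[0] + np.arange(n) / target_rate_hz
    return grid, np.interp(grid, t, y)


def lowpass_zero_phase(
    x: np.ndarray,
    sample_rate_hz: float,
    order: int = DEFAULT_ORDER,
    cutoff_hz: float = DEFAULT_CUTOFF_HZ,
) -> np.ndarray:
    """Zero-phase low-pass Butterworth filter (forward-backward).

    The filter is applied forward then backward, giving the squared
    magnitude response and zero net phase. Edges are reflect-padded with
    3 * (order + 1) samples, removed after filtering, so a constant input
    passes through bit-exactly up to floating-point error.
    """
    x = np.asarray(x, dtype=float)
    nyquist = sample_rate_hz / 2.0
    if cutoff_hz >= nyquist:
        raise ValueError(
            f"cutoff {cutoff_hz} Hz must be below the Nyquist rate {nyquist} Hz"
        )
    padlen = 3 * (order + 1)
    if x.size <= padlen:
        raise ValueError(
            f"series of length {x.size} too short for reflect padding "
            f"({padlen} samples)"
        )
    b, a = butter(order, cutoff_hz / nyquist, btype="low")
    return filtfilt(b, a, x, padtype="even", padlen=padlen)


def derive_channels(
    o2hb: np.ndarray, hhb: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Hbdiff = O2Hb - HHb (oxygenation balance) and tHb = O2Hb + HHb
    (regional blood volume), elementwise."""
    o2hb = np.asarray(o2hb, dtype=float)
    hhb = np.asarray(hhb, dtype=float)
    if o2hb.shape != hhb.shape:
        raise ValueError("o2hb and hhb must have the same shape")
    return o2hb - hhb, o2hb + hhb


def raw_channelset(session: SessionData, site: str = "muscle") -> ChannelSet:
    """ChannelSet on the native grid with no filtering.

    Useful for diagnostics and oracle checks where the filter's passband
    attenuation of fast within-sprint kinetics would otherwise enter the
    comparison; production analyses use :func:`preprocess_session`.
    """
    df = session.nirs_muscle if site == "muscle" else session.nirs_cerebral
    if df is None:
        raise ValueError(f"session has no {site} NIRS stream")
    t = np.asarray(df["time_s"], dtype=float)
    rate = 1.0 / float(np.median(np.diff(t)))
    o2hb = np.asarray(df["o2hb_uM"], dtype=float)
    hhb = np.asarray(df["hhb_uM"], dtype=float)
    hbdiff, thb = derive_channels(o2hb, hhb)
    return ChannelSet(
        site=site,
        time_s=t,
        o2hb_uM=o2hb,
        hhb_uM=hhb,
        hbdiff_uM=hbdiff,
        thb_uM=thb,
        tsi_pct=np.asarray(df["tsi_pct"], dtype=float),
        sample_rate_hz=rate,
        dpf=DPF.get(site, float("nan")),
    )


def preprocess_session(
    session: SessionData,
    target_rate_hz: float = DEFAULT_RATE_HZ,
    cutoff_hz: float = DEFAULT_CUTOFF_HZ,
    order: int = DEFAULT_ORDER,
) -> dict[str, ChannelSet]:
    """Run the full chain (resample -> filter -> derive) for every NIRS site
    present in the session. Returns a mapping site -> ChannelSet."""
    out: dict[str, ChannelSet] = {}
    frames = {"muscle": session.nirs_muscle}
    if session.nirs_cerebral is not None:
        frames["cerebral"] = session.nirs_cerebral
    for site, df in frames.items():
        t = np.asarray(df["time_s"], dtype=float)
        grid = None
        filtered = {}
        for col in ("o2hb_uM", "hhb_uM", "tsi_pct"):
            grid, y = resample_to_grid(t, np.asarray(df[col], dtype=float), target_rate_hz)
            filtered[col] = lowpass_zero_phase(
                y, target_rate_hz, order=order, cutoff_hz=cutoff_hz
            )
        hbdiff, thb = derive_channels(filtered["o2hb_uM"], filtered["hhb_uM"])
        out[site] = ChannelSet(
            site=site,
            time_s=grid,
            o2hb_uM=filtered["o2hb_uM"],
            hhb_uM=filtered["hhb_uM"],
            hbdiff_uM=hbdiff,
            thb_uM=thb,
            tsi_pct=filtered["tsi_pct"],
            sample_rate_hz=target_rate_hz,
            dpf=DPF.get(site, float("nan")),
        )
    return out
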