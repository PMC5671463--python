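"""Delimited-text persistence for sessions and results.

One TSV per stream (``<subject>_<condition>_<stream>.tsv``, UTF-8, LF line
endings, ``.`` decimal separator, columns ``time_s`` + value columns) plus a
JSON sidecar (``<subject>_<condition>_meta.json``) carrying the protocol,
condition, extras, and optional ground truth.
"""
from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .types import Condition, Protocol, SessionData

__all__ = ["write_session", "read_session", "list_sessions", "write_table", "read_table"]

_FLOAT_FMT = "%.10g"


def _session_stem(session: SessionData) -> str:
    return f"{session.subject_id}_{session.condition.label}"


def write_table(df: pd.DataFrame, path: Path | str) -> None:
    """Write a DataFrame as TSV (UTF-8, LF, '.' decimals)."""
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT, lineterminator="\n")


def read_table(path: Path | str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, np.ndarray):
        return [float(v) for v in obj.ravel()]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_session(session: SessionData, out_dir: Path | str) -> list[Path]:
    """Write every stream of a session plus the JSON sidecar; returns the
    paths written."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stem = _session_stem(session)
    paths = []
    for name, df in session.streams().items():
        p = out_dir / f"{stem}_{name}.tsv"
        write_table(df, p)
        paths.append(p)
    meta = {
        "subject_id": session.subject_id,
        "condition": dataclasses.asdict(session.condition),
        "protocol": dataclasses.asdict(session.protocol),
        "extras": _jsonable(session.extras),
        "truth": _jsonable(session.truth) if session.truth is not None else None,
        "streams": sorted(session.streams().keys()),
    }
    p = out_dir / f"{stem}_meta.json"
    with open(p, "w", encoding="utf-8", newline="\n") as fh:
        json.dump(meta, fh, indent=1, sort_keys=True)
        fh.write("\n")
    paths.append(p)
    return paths


def read_session(out_dir: Path | str, subject_id: str, condition_label: str) -> SessionData:
    """Reconstruct a SessionData from the writer's files."""
    out_dir = Path(out_dir)
    stem = f"{subject_id}_{condition_label}"
    meta_path = out_dir / f"{stem}_meta.json"
    if not meta_path.exists():
        raise FileNotFoundError(f"no session {stem} in {out_dir}")
    meta = json.loads(meta_path.read_text(encoding="utf-8"))

    def stream(name: str) -> pd.DataFrame | None:
        p = out_dir / f"{stem}_{name}.tsv"
        return read_table(p) if p.exists() else None

    truth = meta.get("truth")
    if truth is not None:
        for key in ("sprint_onsets_s", "sprint_power_w"):
            if key in truth:
                truth[key] = np.asarray(truth[key], dtype=float)
        for block in ("delta_asym", "delta_realized"):
            if block in truth:
                truth[block] = {
                    ch: np.asarray(v, dtype=float) for ch, v in truth[block].items()
                }
    return SessionData(
        subject_id=meta["subject_id"],
        condition=Condition(**meta["condition"]),
        protocol=Protocol(**meta["protocol"]),
        nirs_muscle=stream("nirs_muscle"),
        nirs_cerebral=stream("nirs_cerebral"),
        power=stream("power"),
        cadence=stream("cadence"),
        spo2=stream("spo2"),
        vo2=stream("vo2"),
        hr=stream("hr"),
        extras=meta.get("extras", {}),
        truth=truth,
    )


def list_sessions(out_dir: Path | str) -> list[tuple[str, str]]:
    """(subject_id, condition_label) pairs present in a session directory."""
    out_dir = Path(out_dir)
    pairs = []
    for p in sorted(out_dir.glob("*_meta.json")):
        meta = json.loads(p.read_text(encoding="utf-8"))
        pairs.append((meta["subject_id"], meta["condition"]["label"]))
    return pairs
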