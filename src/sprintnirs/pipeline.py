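"""End-to-end orchestration: sessions -> preprocessing -> segmentation ->
deltas -> performance table -> normalized long table -> mixed models.
"""
from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import pandas as pd

from .io import write_table
from .metrics import summarize_performance
from .preprocess import (
    DEFAULT_CUTOFF_HZ,
    DEFAULT_ORDER,
    DEFAULT_RATE_HZ,
    preprocess_session,
)
from .segmentation import detect_sprints, extract_deltas
from .stats import LmmResult, build_long_table, fit_mixed_model
from .types import SessionData

__all__ = ["analyze_session", "analyze_cohort", "run_pipeline"]


def analyze_session(
    session: SessionData,
    target_rate_hz: float = DEFAULT_RATE_HZ,
    cutoff_hz: float = DEFAULT_CUTOFF_HZ,
    order: int = DEFAULT_ORDER,
    lag_s: float = 0.0,
    min_gap_s: float = 25.0,
) -> tuple[pd.DataFrame, dict]:
    """Preprocess, segment and extract one session.

    Returns the per-sprint delta table (with subject/condition columns
    attached) and the performance summary as a dict.
    """
    channel_sets = preprocess_session(
        session, target_rate_hz=target_rate_hz, cutoff_hz=cutoff_hz, order=order
    )
    segments = detect_sprints(
        channel_sets["muscle"],
        session.protocol,
        min_gap_s=min_gap_s,
        grid_fallback=True,
        cutoff_hz=cutoff_hz,
        order=order,
    )
    deltas = extract_deltas(list(channel_sets.values()), segments, lag_s=lag_s)
    deltas.insert(0, "subject", session.subject_id)
    deltas.insert(1, "condition", session.condition.label)
    perf = summarize_performance(session, segments).as_dict()
    return deltas, perf


def analyze_cohort(
    sessions: Sequence[SessionData],
    responses: Sequence[tuple[str, str]] = (("muscle", "hhb"),),
    interaction: bool = False,
    **session_kwargs,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, dict[str, LmmResult]]:
    """Run the full pipeline over a cohort.

    Returns (performance table, per-sprint delta table, normalized long
    table, mixed-model results keyed "site_channel").
    """
    all_deltas, perf_rows = [], []
    for session in sessions:
        deltas, perf = analyze_session(session, **session_kwargs)
        all_deltas.append(deltas)
        perf_rows.append(perf)
    delta_table = pd.concat(all_deltas, ignore_index=True)
    performance = pd.DataFrame(perf_rows)

    subjects = sorted({s.subject_id for s in sessions})
    conditions = list(dict.fromkeys(s.condition.label for s in sessions))
    long_table = build_long_table(
        delta_table, expected_subjects=subjects, expected_conditions=conditions
    )

    results: dict[str, LmmResult] = {}
    for site, channel in responses:
        results[f"{site}_{channel}"] = fit_mixed_model(
            long_table, site=site, channel=channel, interaction=interaction
        )
    return performance, delta_table, long_table, results


def run_pipeline(
    sessions: Sequence[SessionData],
    out_dir: Path | str,
    responses: Sequence[tuple[str, str]] = (("muscle", "hhb"),),
    interaction: bool = False,
    **session_kwargs,
) -> dict:
    """Analyze a cohort and write ``performance.tsv``, ``deltas.tsv``,
    ``profiles.tsv`` and ``lmm_results.json`` under ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    performance, delta_table, long_table, results = analyze_cohort(
        sessions, responses=responses, interaction=interaction, **session_kwargs
    )
    write_table(performance, out_dir / "performance.tsv")
    write_table(delta_table, out_dir / "deltas.tsv")
    write_table(long_table, out_dir / "profiles.tsv")
    payload = {key: res.to_dict() for key, res in results.items()}
    with open(out_dir / "lmm_results.json", "w", encoding="utf-8", newline="\n") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return {
        "performance": performance,
        "deltas": delta_table,
        "profiles": long_table,
        "lmm": results,
    }
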