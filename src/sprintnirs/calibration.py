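"""Monte-Carlo calibration of the mixed-model inference.

Repeatedly simulates full cohorts (generation -> preprocessing ->
segmentation -> delta extraction -> normalization -> mixed-model fit) and
records the condition-effect likelihood-ratio p-value, to estimate the
test's type-I error rate under a true null (equal amplitudes across
conditions) and its power under a stated amplitude reduction at the most
hypoxic condition.

Cohorts here synthesize only the muscle site and extract only the HHb
channel: the condition-effect test consumes a single response, and the
remaining channels are deterministic transforms of the same excursion
process, so they add compute without adding information.
"""
from __future__ import annotations

from dataclasses import replace
from typing import Sequence

import numpy as np
import pandas as pd

from .preprocess import preprocess_session
from .segmentation import detect_sprints, extract_deltas
from .stats import build_long_table, fit_mixed_model
from .synthetic import SynthParams, generate_cohort
from .types import Condition, DEFAULT_CONDITIONS

__all__ = [
    "cohort_condition_pvalue",
    "lrt_rejection_rate",
    "null_amp_scale",
    "reduced_amp_scale",
]


def null_amp_scale() -> dict:
    """Equal amplitudes in every condition: a true null for the condition
    effect."""
    return {c.label: 1.0 for c in DEFAULT_CONDITIONS}


def reduced_amp_scale(ratio: float = 0.6) -> dict:
    """Amplitude ratio ``ratio`` at the most hypoxic condition versus the
    others (the power-analysis alternative)."""
    scale = {c.label: 1.0 for c in DEFAULT_CONDITIONS}
    scale["3800m"] = ratio
    return scale


def _fast_params(params: SynthParams, seed: int) -> SynthParams:
    return replace(params, seed=seed, include_cerebral=False)


def cohort_condition_pvalue(
    params: SynthParams,
    conditions: Sequence[Condition] = DEFAULT_CONDITIONS,
) -> float:
    """Simulate one cohort, run the pipeline, and return the
    condition-effect LRT p-value for muscle HHb."""
    sessions = generate_cohort(params, conditions)
    frames = []
    for session in sessions:
        cs = preprocess_session(session)["muscle"]
        segments = detect_sprints(cs, session.protocol, grid_fallback=True)
        deltas = extract_deltas(cs, segments, channels=("hhb",))
        deltas.insert(0, "subject", session.subject_id)
        deltas.insert(1, "condition", session.condition.label)
        frames.append(deltas)
    table = build_long_table(pd.concat(frames, ignore_index=True))
    result = fit_mixed_model(
        table,
        site="muscle",
        channel="hhb",
        lrt_effects=("condition",),
        compute_contrasts=False,
    )
    return result.lrt["condition"][2]


def lrt_rejection_rate(
    n_cohorts: int,
    seed: int,
    amp_scale: dict | float = 1.0,
    alpha: float = 0.05,
    base_params: SynthParams | None = None,
    conditions: Sequence[Condition] = DEFAULT_CONDITIONS,
) -> tuple[float, np.ndarray]:
    """Fraction of simulated cohorts whose condition-effect LRT rejects at
    ``alpha``. Returns (rate, array of p-values).

    Each cohort uses an independent sub-seed derived from ``seed``, so the
    whole study is reproducible from one integer.
    """
    base = base_params or SynthParams()
    base = replace(base, amp_scale=amp_scale)
    root = np.random.SeedSequence(seed)
    sub_seeds = root.generate_state(n_cohorts) % (2**31 - 1)
    pvals = np.empty(n_cohorts)
    for i in range(n_cohorts):
        params = _fast_params(base, int(sub_seeds[i]))
        pvals[i] = cohort_condition_pvalue(params, conditions)
    return float(np.mean(pvals < alpha)), pvals
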