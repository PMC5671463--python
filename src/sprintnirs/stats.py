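"""Set-duration normalization and linear mixed-model inference.

Because each participant completes a different number of sprints in each
condition, per-sprint deltas are first mapped onto a common set-duration
axis (20, 40, 60, 80, 100% of sprints performed) by linear interpolation on
the 1-based sprint index: the target position for grid point k of 5 is
``x = k * N / 5``, so the 100% point is always exactly the final sprint.

Inference follows the repeated-measures design: a linear mixed model with
categorical fixed effects (condition, set duration, optionally their
interaction) and a per-subject random intercept. Effect p-values come from
likelihood-ratio tests of maximum-likelihood fits with and without the
effect; pairwise least-squares-mean contrasts carry Tukey
(multivariate-t max-|T|) adjusted p-values.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.regression.mixed_linear_model import MixedLM

__all__ = [
    "NormalizedProfile",
    "normalize_profile",
    "build_long_table",
    "LmmResult",
    "fit_mixed_model",
    "pairwise_contrasts",
]

SET_PCT_GRID = (20, 40, 60, 80, 100)

#: draws for the Monte-Carlo evaluation of the max-|T| (Tukey) family
#: distribution; fixed internal seed keeps adjusted p-values reproducible
_TUKEY_MC_DRAWS = 40_000
_TUKEY_MC_SEED = 20_170_846


@dataclass(frozen=True)
class NormalizedProfile:
    """Channel deltas at 20/40/60/80/100% of the set duration."""

    grid: tuple = SET_PCT_GRID
    values: np.ndarray = field(default_factory=lambda: np.empty(0))
    n_sprints_source: int = 0


def normalize_profile(
    deltas: Sequence[float], n_points: int = 5
) -> NormalizedProfile:
    """Interpolate per-sprint deltas onto the set-duration grid.

    For grid point k (k = 1..n_points) the target position on the 1-based
    sprint index is ``x = k * N / n_points``; integer positions take the
    sprint's delta directly, fractional positions interpolate linearly
    between the flanking sprints. Sessions with fewer sprints than grid
    points are rejected (the grid would extrapolate).
    """
    d = np.asarray(deltas, dtype=float)
    n = d.size
    if n == 0:
        raise ValueError("empty delta sequence")
    if n < n_points:
        raise ValueError(
            f"need at least {n_points} sprints to normalize, got {n}"
        )
    k = np.arange(1, n_points + 1)
    x = k * n / n_points
    values = np.interp(x, np.arange(1, n + 1), d)
    grid = tuple(int(round(100 * kk / n_points)) for kk in k)
    return NormalizedProfile(grid=grid, values=values, n_sprints_source=n)


def build_long_table(
    deltas: pd.DataFrame,
    expected_subjects: Optional[Sequence[str]] = None,
    expected_conditions: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Normalize per-sprint deltas into the tidy modeling table.

    Parameters
    ----------
    deltas
        Long frame with columns ``subject, condition, sprint_index, site,
        channel, delta`` (one row per sprint x channel), e.g. the
        segmentation output augmented with session identifiers.
    expected_subjects, expected_conditions
        If given, every subject x condition pair must be present; a missing
        session raises an error naming it.

    Returns
    -------
    DataFrame with columns ``subject, condition, set_pct, site, channel,
    delta`` — one row per subject x condition x grid point x channel.
    """
    required = {"subject", "condition", "sprint_index", "site", "channel", "delta"}
    missing = required - set(deltas.columns)
    if missing:
        raise ValueError(f"deltas table missing columns: {sorted(missing)}")

    if expected_subjects is not None and expected_conditions is not None:
        have = set(zip(deltas["subject"], deltas["condition"]))
        for s in expected_subjects:
            for c in expected_conditions:
                if (s, c) not in have:
                    raise ValueError(f"missing session: subject {s} condition {c}")

    key_cols = ["subject", "condition", "site", "channel"]
    dup = deltas.duplicated(subset=key_cols + ["sprint_index"])
    if dup.any():
        raise ValueError("duplicate (session, sprint, channel) rows in deltas table")

    rows = []
    for (subj, cond, site, ch), grp in deltas.groupby(key_cols, sort=True):
        grp = grp.sort_values("sprint_index")
        prof = normalize_profile(grp["delta"].to_numpy())
        for pct, val in zip(prof.grid, prof.values):
            rows.append(
                {
                    "subject": subj,
                    "condition": cond,
                    "set_pct": pct,
                    "site": site,
                    "channel": ch,
                    "delta": float(val),
                }
            )
    out = pd.DataFrame(rows)
    return out.sort_values(
        ["site", "channel", "subject", "condition", "set_pct"]
    ).reset_index(drop=True)


# ---------------------------------------------------------------------------
# mixed model


def _design(
    df: pd.DataFrame,
    cond_levels: list,
    pct_levels: list,
    include_condition: bool,
    include_set: bool,
    include_interaction: bool,
) -> tuple[np.ndarray, list[str]]:
    """Treatment-coded fixed-effects design matrix and column names."""
    n = len(df)
    cols = [np.ones(n)]
    names = ["Intercept"]
    cond_dummies = {
        lv: (df["condition"] == lv).to_numpy(float) for lv in cond_levels[1:]
    }
    pct_dummies = {
        lv: (df["set_pct"] == lv).to_numpy(float) for lv in pct_levels[1:]
    }
    if include_condition:
        for lv, v in cond_dummies.items():
            cols.append(v)
            names.append(f"condition[{lv}]")
    if include_set:
        for lv, v in pct_dummies.items():
            cols.append(v)
            names.append(f"set_pct[{lv}]")
    if include_interaction:
        for lc, vc in cond_dummies.items():
            for lp, vp in pct_dummies.items():
                cols.append(vc * vp)
                names.append(f"condition[{lc}]:set_pct[{lp}]")
    return np.column_stack(cols), names


def _fit_ml(endog, exog, groups):
    """ML fit of a random-intercept model, with convergence bookkeeping."""
    model = MixedLM(endog, exog, groups=groups)
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        fit = model.fit(reml=False)
    converged = bool(getattr(fit, "converged", True))
    singular = any("singular" in str(w.message).lower() for w in caught)
    boundary = any("boundary" in str(w.message).lower() for w in caught)
    return fit, converged, singular or boundary


@dataclass
class LmmResult:
    """Fitted mixed model for one response channel.

    ``lrt`` maps effect name -> (statistic, df, p); ``contrasts`` holds the
    Tukey-adjusted pairwise least-squares-mean comparisons for each fixed
    factor; variance components are the subject-intercept and residual
    variances from the display (full additive or interaction) model.
    """

    site: str
    channel: str
    fe_params: dict
    llf: dict
    lrt: dict
    group_var: float
    resid_var: float
    contrasts: pd.DataFrame
    converged: bool
    singular: bool
    n_obs: int
    n_subjects: int

    def to_dict(self) -> dict:
        return {
            "site": self.site,
            "channel": self.channel,
            "fe_params": {k: float(v) for k, v in self.fe_params.items()},
            "llf": {k: float(v) for k, v in self.llf.items()},
            "lrt": {
                k: {"stat": float(v[0]), "df": int(v[1]), "p": float(v[2])}
                for k, v in self.lrt.items()
            },
            "group_var": float(self.group_var),
            "resid_var": float(self.resid_var),
            "contrasts": self.contrasts.to_dict(orient="records"),
            "converged": self.converged,
            "singular": self.singular,
            "n_obs": self.n_obs,
            "n_subjects": self.n_subjects,
        }


def fit_mixed_model(
    table: pd.DataFrame,
    site: str = "muscle",
    channel: str = "hhb",
    interaction: bool = False,
    lrt_effects: Sequence[str] = ("condition", "set_pct"),
    compute_contrasts: bool = True,
) -> LmmResult:
    """Fit the repeated-measures mixed model for one response channel.

    Model: delta ~ condition + set_pct (+ condition:set_pct) with a
    per-subject random intercept. All fits use maximum likelihood so the
    likelihood-ratio tests are valid; each effect's p-value compares the
    model containing the effect against the model omitting it.
    """
    df = table[(table["site"] == site) & (table["channel"] == channel)]
    if df.empty:
        raise ValueError(f"no rows for site={site!r} channel={channel!r}")
    df = df.reset_index(drop=True)
    cond_levels = list(pd.unique(df["condition"]))
    pct_levels = list(pd.unique(df["set_pct"]))
    if len(cond_levels) < 2 or len(pct_levels) < 2:
        raise ValueError("need at least 2 levels per fixed factor")
    if df["subject"].nunique() < 2:
        raise ValueError("need at least 2 subjects")

    endog = df["delta"].to_numpy(float)
    groups = df["subject"].to_numpy()

    def fit_with(cond: bool, setp: bool, inter: bool):
        X, names = _design(df, cond_levels, pct_levels, cond, setp, inter)
        fit, conv, sing = _fit_ml(endog, X, groups)
        return fit, names, conv, sing

    fit_add, names_add, conv_add, sing_add = fit_with(True, True, False)

    def lrt(full, reduced) -> tuple[float, int, float]:
        stat = max(2.0 * (full.llf - reduced.llf), 0.0)
        dof = int(full.k_fe - reduced.k_fe)
        return stat, dof, float(sps.chi2.sf(stat, dof))

    lrt_table = {}
    llf = {"additive": float(fit_add.llf)}
    if "condition" in lrt_effects:
        fit_nocond, _, _, _ = fit_with(False, True, False)
        lrt_table["condition"] = lrt(fit_add, fit_nocond)
        llf["no_condition"] = float(fit_nocond.llf)
    if "set_pct" in lrt_effects:
        fit_noset, _, _, _ = fit_with(True, False, False)
        lrt_table["set_pct"] = lrt(fit_add, fit_noset)
        llf["no_set_pct"] = float(fit_noset.llf)

    display_fit, display_names = fit_add, names_add
    converged, singular = conv_add, sing_add
    if interaction:
        fit_int, names_int, conv_int, sing_int = fit_with(True, True, True)
        lrt_table["interaction"] = lrt(fit_int, fit_add)
        llf["interaction"] = float(fit_int.llf)
        display_fit, display_names = fit_int, names_int
        converged = converged and conv_int
        singular = singular or sing_int

    if not converged:
        warnings.warn(
            f"mixed model for {site}/{channel} did not fully converge; "
            "estimates may be unreliable",
            stacklevel=2,
        )

    if compute_contrasts:
        contrasts = pd.concat(
            [
                _factor_contrasts(
                    display_fit, display_names, df, cond_levels, pct_levels,
                    factor="condition",
                ),
                _factor_contrasts(
                    display_fit, display_names, df, cond_levels, pct_levels,
                    factor="set_pct",
                ),
            ],
            ignore_index=True,
        )
    else:
        contrasts = pd.DataFrame(
            columns=[
                "factor", "level_a", "level_b", "estimate", "se", "t",
                "df", "p_unadj", "p_tukey",
            ]
        )

    fe = dict(zip(display_names, np.asarray(display_fit.fe_params, dtype=float)))
    return LmmResult(
        site=site,
        channel=channel,
        fe_params=fe,
        llf=llf,
        lrt=lrt_table,
        group_var=float(np.asarray(display_fit.cov_re).ravel()[0]),
        resid_var=float(display_fit.scale),
        contrasts=contrasts,
        converged=converged,
        singular=singular,
        n_obs=len(df),
        n_subjects=int(df["subject"].nunique()),
    )


def _lsmean_rows(
    names: list[str], cond_levels: list, pct_levels: list, factor: str
) -> tuple[list, np.ndarray]:
    """Design rows whose product with the fixed effects gives the
    least-squares mean of each level of ``factor`` (averaging uniformly
    over the levels of the other factor)."""
    levels = cond_levels if factor == "condition" else pct_levels
    other = pct_levels if factor == "condition" else cond_levels
    rows = np.zeros((len(levels), len(names)))
    for i, lv in enumerate(levels):
        for ov in other:
            cond_lv, pct_lv = (lv, ov) if factor == "condition" else (ov, lv)
            cell = np.zeros(len(names))
            for j, nm in enumerate(names):
                if nm == "Intercept":
                    cell[j] = 1.0
                elif nm == f"condition[{cond_lv}]":
                    cell[j] = 1.0
                elif nm == f"set_pct[{pct_lv}]":
                    cell[j] = 1.0
                elif nm == f"condition[{cond_lv}]:set_pct[{pct_lv}]":
                    cell[j] = 1.0
            rows[i] += cell / len(other)
    return levels, rows


def _containment_df(fit) -> float:
    """Containment denominator degrees of freedom: observations minus fixed
    effects minus the (n_subjects - 1) subject-intercept dimensions."""
    n_obs = fit.model.exog.shape[0]
    n_groups = fit.model.n_groups
    return float(max(n_obs - fit.k_fe - (n_groups - 1), 1))


def _factor_contrasts(
    fit,
    names: list[str],
    df: pd.DataFrame,
    cond_levels: list,
    pct_levels: list,
    factor: str,
) -> pd.DataFrame:
    levels, rows = _lsmean_rows(names, cond_levels, pct_levels, factor)
    beta = np.asarray(fit.fe_params, dtype=float)
    cov = np.asarray(fit.cov_params())[: len(beta), : len(beta)]
    dof = _containment_df(fit)

    pairs = [(i, j) for i in range(len(levels)) for j in range(i + 1, len(levels))]
    L = np.array([rows[i] - rows[j] for i, j in pairs])
    est = L @ beta
    cov_c = L @ cov @ L.T
    se = np.sqrt(np.diag(cov_c))
    tval = est / se
    p_unadj = 2.0 * sps.t.sf(np.abs(tval), dof)

    if len(pairs) == 1:
        p_adj = p_unadj.copy()
    else:
        p_adj = _tukey_maxt(tval, cov_c, dof)
        p_adj = np.maximum(p_adj, p_unadj)  # family p can never beat marginal p

    return pd.DataFrame(
        {
            "factor": factor,
            "level_a": [str(levels[i]) for i, _ in pairs],
            "level_b": [str(levels[j]) for _, j in pairs],
            "estimate": est,
            "se": se,
            "t": tval,
            "df": dof,
            "p_unadj": p_unadj,
            "p_tukey": np.minimum(p_adj, 1.0),
        }
    )


def _tukey_maxt(tval: np.ndarray, cov_c: np.ndarray, dof: float) -> np.ndarray:
    """Single-step max-|T| (Tukey) adjustment by Monte Carlo.

    Draws from the multivariate t distribution of the contrast statistics
    (which is rank-deficient for a full pairwise set, so sampling is done
    through the underlying normal) and returns, for each observed |t|, the
    probability that the family maximum exceeds it under the null.
    """
    scale = np.sqrt(np.diag(cov_c))
    R = cov_c / np.outer(scale, scale)
    rng = np.random.default_rng(_TUKEY_MC_SEED)
    # eigendecomposition handles the singular correlation matrix
    w, V = np.linalg.eigh(R)
    w = np.clip(w, 0.0, None)
    A = V * np.sqrt(w)
    Z = rng.standard_normal((_TUKEY_MC_DRAWS, R.shape[0])) @ A.T
    chi = rng.chisquare(dof, _TUKEY_MC_DRAWS)
    T = Z / np.sqrt(chi / dof)[:, None]
    max_abs = np.max(np.abs(T), axis=1)
    return np.array([np.mean(max_abs >= abs(t)) for t in tval])


def pairwise_contrasts(result: LmmResult, factor: Optional[str] = None) -> pd.DataFrame:
    """Tukey-adjusted pairwise least-squares-mean contrasts from a fitted
    model, optionally restricted to one fixed factor."""
    table = result.contrasts
    if factor is not None:
        table = table[table["factor"] == factor].reset_index(drop=True)
        if table.empty:
            raise ValueError(f"no contrasts for factor {factor!r}")
    return table
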