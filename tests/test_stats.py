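"""Set-duration normalization and the mixed-model inference layer."""
import json

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from sprintnirs import (
    build_long_table,
    fit_mixed_model,
    normalize_profile,
    pairwise_contrasts,
)

delta_vectors = st.lists(
    st.floats(-50.0, 50.0, allow_nan=False), min_size=5, max_size=40
)


def synth_table(
    n_subjects=8,
    conditions=("400m", "2000m", "3800m"),
    cond_effects=(0.0, 0.0, 0.0),
    subject_sd=1.0,
    resid_sd=0.5,
    seed=0,
):
    """Delta-level table drawn straight from the random-intercept model the
    fitter assumes (independent oracle for estimation behavior)."""
    rng = np.random.default_rng(seed)
    rows = []
    pct_effect = {20: 0.0, 40: -0.3, 60: -0.6, 80: -0.9, 100: -1.2}
    for i in range(n_subjects):
        b = rng.normal(0.0, subject_sd)
        for cond, eff in zip(conditions, cond_effects):
            for pct, peff in pct_effect.items():
                rows.append(
                    {
                        "subject": f"S{i:02d}",
                        "condition": cond,
                        "set_pct": pct,
                        "site": "muscle",
                        "channel": "hhb",
                        "delta": 10.0 + eff + peff + b + rng.normal(0, resid_sd),
                    }
                )
    return pd.DataFrame(rows)


class TestNormalizeProfile:
    def test_five_sprints_identity(self):
        prof = normalize_profile([1.0, 2.0, 3.0, 4.0, 5.0])
        np.testing.assert_allclose(prof.values, [1, 2, 3, 4, 5])
        assert prof.grid == (20, 40, 60, 80, 100)

    def test_ten_sprints_even_positions(self):
        prof = normalize_profile(np.arange(1.0, 11.0))
        np.testing.assert_allclose(prof.values, [2, 4, 6, 8, 10])

    def test_seven_sprint_fractional_interpolation(self):
        """N=7: the 20% point sits at index 1.4, hence
        10 + 0.4 * (8 - 10) = 9.2."""
        prof = normalize_profile([10.0, 8.0, 6.0, 5.0, 4.0, 3.0, 2.0])
        assert prof.values[0] == pytest.approx(9.2)
        assert prof.values[-1] == 2.0  # 100% point is the final sprint

    @pytest.mark.parametrize("n", [5, 10, 15, 40])
    def test_multiples_of_five_reproduce_raw_deltas(self, n, rng):
        d = rng.normal(size=n)
        prof = normalize_profile(d)
        step = n // 5
        np.testing.assert_allclose(prof.values, d[step - 1 :: step], atol=1e-12)

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(delta_vectors, delta_vectors, st.floats(-5, 5), st.floats(-5, 5))
    def test_linearity(self, d, e, a, b):
        n = min(len(d), len(e))
        d, e = np.asarray(d[:n]), np.asarray(e[:n])
        combo = normalize_profile(a * d + b * e).values
        parts = a * normalize_profile(d).values + b * normalize_profile(e).values
        np.testing.assert_allclose(combo, parts, atol=1e-7)

    def test_too_few_sprints_rejected(self):
        with pytest.raises(ValueError, match="at least 5"):
            normalize_profile([1.0, 2.0, 3.0, 4.0])
        with pytest.raises(ValueError, match="empty"):
            normalize_profile([])


class TestLongTable:
    def _deltas(self, subjects, conditions, n_sprints=8):
        rows = []
        for s in subjects:
            for c in conditions:
                for k in range(1, n_sprints + 1):
                    rows.append(
                        {
                            "subject": s,
                            "condition": c,
                            "sprint_index": k,
                            "site": "muscle",
                            "channel": "hhb",
                            "delta": 10.0 - 0.2 * k,
                        }
                    )
        return pd.DataFrame(rows)

    def test_cardinality(self):
        subjects = [f"S{i:02d}" for i in range(11)]
        conditions = ["400m", "2000m", "3800m"]
        table = build_long_table(self._deltas(subjects, conditions))
        assert len(table) == 11 * 3 * 5

    def test_tsv_round_trip(self, tmp_path):
        from sprintnirs.io import read_table, write_table

        table = build_long_table(self._deltas(["S01", "S02"], ["400m"]))
        path = tmp_path / "profiles.tsv"
        write_table(table, path)
        back = read_table(path)
        pd.testing.assert_frame_equal(back, table, check_exact=False, rtol=1e-9)

    def test_missing_session_named(self):
        deltas = self._deltas(["S01", "S02"], ["400m", "2000m"])
        deltas = deltas[~((deltas.subject == "S02") & (deltas.condition == "2000m"))]
        with pytest.raises(ValueError, match="S02 condition 2000m"):
            build_long_table(
                deltas,
                expected_subjects=["S01", "S02"],
                expected_conditions=["400m", "2000m"],
            )

    def test_duplicate_rows_rejected(self):
        deltas = self._deltas(["S01"], ["400m"])
        dup = pd.concat([deltas, deltas.iloc[[0]]], ignore_index=True)
        with pytest.raises(ValueError, match="duplicate"):
            build_long_table(dup)


class TestMixedModel:
    def test_lrt_invariants_and_set_effect_detected(self):
        table = synth_table(seed=3)
        res = fit_mixed_model(table)
        for stat, dof, p in res.lrt.values():
            assert stat >= 0.0
            assert dof >= 1
            assert 0.0 <= p <= 1.0
        # the built-in set-duration trend is strong relative to noise
        assert res.lrt["set_pct"][2] < 1e-4

    def test_condition_effect_recovered(self):
        table = synth_table(cond_effects=(0.0, 0.0, -4.0), seed=4)
        res = fit_mixed_model(table)
        assert res.lrt["condition"][2] < 1e-6
        est = res.fe_params.get("condition[3800m]")
        assert est == pytest.approx(-4.0, abs=0.5)

    def test_zero_subject_sd_degenerate_variance(self):
        table = synth_table(subject_sd=0.0, resid_sd=1.0, seed=5)
        res = fit_mixed_model(table)
        assert res.group_var < 0.05 * res.resid_var

    def test_interaction_lrt_reported(self):
        table = synth_table(seed=6)
        res = fit_mixed_model(table, interaction=True)
        assert "interaction" in res.lrt
        assert res.lrt["interaction"][1] == 8  # (3-1) * (5-1) parameters

    def test_missing_levels_rejected(self):
        table = synth_table(conditions=("400m",), cond_effects=(0.0,))
        with pytest.raises(ValueError, match="2 levels"):
            fit_mixed_model(table)

    def test_result_json_serializable(self):
        res = fit_mixed_model(synth_table(seed=7))
        payload = json.dumps(res.to_dict())
        assert "lrt" in json.loads(payload)


class TestContrasts:
    def test_three_conditions_three_contrasts(self):
        res = fit_mixed_model(synth_table(seed=8))
        table = pairwise_contrasts(res, factor="condition")
        assert len(table) == 3
        table_pct = pairwise_contrasts(res, factor="set_pct")
        assert len(table_pct) == 10  # C(5, 2)

    def test_adjusted_p_never_below_unadjusted(self):
        for seed in range(6):
            res = fit_mixed_model(synth_table(seed=100 + seed))
            table = res.contrasts
            assert (table["p_tukey"] >= table["p_unadj"] - 1e-12).all()
            assert table["p_tukey"].between(0, 1).all()

    def test_two_level_factor_adjustment_is_identity(self):
        table = synth_table(conditions=("400m", "3800m"), cond_effects=(0.0, -2.0))
        res = fit_mixed_model(table)
        cond = pairwise_contrasts(res, factor="condition")
        assert len(cond) == 1
        assert cond["p_tukey"].iloc[0] == pytest.approx(cond["p_unadj"].iloc[0])

    def test_unknown_factor_rejected(self):
        res = fit_mixed_model(synth_table(seed=9))
        with pytest.raises(ValueError, match="no contrasts"):
            pairwise_contrasts(res, factor="altitude")
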