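"""Filtering, condition medians, and the latency-normalized effect statistic."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cfsbias.design import DesignSpec
from cfsbias.preprocess import (EmptyCellError, condition_medians,
                                filter_trials, latency_normalized_difference,
                                normality_check)
from cfsbias.simulate import EffectProfile, simulate_experiment


def make_trials(rts_by_cell, participant=0, arm="suppression"):
    """Minimal trial table from {(repetition, congruence): [rt, ...]}."""
    rows = []
    for (rep, cong), rts in rts_by_cell.items():
        for rt in rts:
            rows.append({
                "participant_id": participant, "arm": arm, "sequence_index": 0,
                "repetition": rep, "congruence": cong, "cued_category": "red",
                "discarded_category": "blue", "retro_cue": 1, "hemifield": "left",
                "rt_ms": rt, "localization_correct": True,
                "recognition_correct": True, "timed_out": False,
            })
    return pd.DataFrame(rows)


def summary_row(match, mismatch):
    return pd.DataFrame([{
        "participant_id": 0, "arm": "suppression", "repetition": "all",
        "median_match": match, "median_mismatch": mismatch,
        "n_trials_match": 10, "n_trials_mismatch": 10,
    }])


class TestFilter:
    def test_counts_excluded_trials(self):
        t = make_trials({(r, c): [1000.0] * 16 for r in range(1, 7)
                         for c in ("match", "mismatch")})
        assert len(t) == 192
        t.loc[0, "timed_out"] = True
        t.loc[1, "timed_out"] = True
        t.loc[16, "localization_correct"] = False
        kept, report = filter_trials(t)
        assert len(kept) == 189
        assert report.loc[0, "timeout"] == 2
        assert report.loc[0, "localization_error"] == 1
        assert report.loc[0, "excluded"] == 3

    def test_clean_input_is_identity(self):
        t = make_trials({(r, c): [1000.0, 1100.0] for r in range(1, 7)
                         for c in ("match", "mismatch")})
        kept, report = filter_trials(t)
        assert len(kept) == len(t)
        assert report["excluded"].sum() == 0

    def test_emptied_cell_raises_with_cell_name(self):
        t = make_trials({(r, c): [1000.0] for r in range(1, 7)
                         for c in ("match", "mismatch")})
        t.loc[(t.repetition == 3) & (t.congruence == "match"), "timed_out"] = True
        with pytest.raises(EmptyCellError, match=r"repetition 3 / match"):
            filter_trials(t)


class TestConditionMedians:
    def test_median_conventions(self):
        t = make_trials({(1, "match"): [900.0, 1000.0, 1100.0],
                         (1, "mismatch"): [900.0, 1100.0]})
        s = condition_medians(t, by_repetition=True)
        assert s.loc[0, "median_match"] == 1000.0     # odd count
        assert s.loc[0, "median_mismatch"] == 1000.0  # even count: midpoint
        assert s.loc[0, "n_trials_match"] == 3

    def test_order_invariance(self, exp1_trials):
        kept, _ = filter_trials(exp1_trials)
        shuffled = kept.sample(frac=1.0, random_state=1)
        a = condition_medians(kept).sort_values(["participant_id", "repetition"])
        b = condition_medians(shuffled).sort_values(["participant_id", "repetition"])
        np.testing.assert_allclose(a["median_match"].to_numpy(),
                                   b["median_match"].to_numpy())

    def test_pooled_medians_use_all_trials(self):
        t = make_trials({(r, "match"): [800.0 + r] for r in range(1, 7)})
        t2 = make_trials({(r, "mismatch"): [900.0 + r] for r in range(1, 7)})
        s = condition_medians(pd.concat([t, t2]), by_repetition=False)
        assert (s["repetition"] == "all").all()
        assert s.loc[0, "n_trials_match"] == 6


class TestNormalizedDifference:
    def test_hand_arithmetic(self):
        d = latency_normalized_difference(summary_row(900.0, 1100.0))
        assert d.loc[0, "d"] == pytest.approx(0.20)

    def test_equal_medians_give_zero(self):
        assert latency_normalized_difference(summary_row(1000.0, 1000.0)).loc[0, "d"] == 0.0

    def test_headline_effect_pair(self):
        # medians solved from the reported 4.2% / 61 ms pairing
        out = latency_normalized_difference(summary_row(1421.9, 1482.9))
        assert out.loc[0, "d"] == pytest.approx(0.042, abs=5e-4)
        assert 1482.9 - 1421.9 == pytest.approx(61.0)

    def test_nonpositive_median_raises(self):
        with pytest.raises(ValueError):
            latency_normalized_difference(summary_row(0.0, 1100.0))

    @given(m=st.floats(100.0, 4000.0), mm=st.floats(100.0, 4000.0),
           scale=st.floats(0.1, 10.0))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_antisymmetry_and_scale_invariance(self, m, mm, scale):
        d = latency_normalized_difference(summary_row(m, mm)).loc[0, "d"]
        d_swapped = latency_normalized_difference(summary_row(mm, m)).loc[0, "d"]
        d_scaled = latency_normalized_difference(
            summary_row(m * scale, mm * scale)).loc[0, "d"]
        assert d == pytest.approx(-d_swapped, abs=1e-12)
        assert d == pytest.approx(d_scaled, rel=1e-9, abs=1e-12)
        assert -2.0 < d < 2.0


def effects_frame(x, repetition=1):
    return pd.DataFrame({"participant_id": np.arange(len(x)),
                         "arm": "suppression", "repetition": repetition, "d": x})


class TestNormalityCheck:
    def test_size_calibration_under_normality(self):
        """The Shapiro-Wilk check should flag ~5% of truly normal samples."""
        rng = np.random.default_rng(3)
        flags = [normality_check(effects_frame(rng.normal(size=36)))["violated"][0]
                 for _ in range(300)]
        assert 0.02 <= np.mean(flags) <= 0.09

    def test_power_against_heavy_skew(self):
        rng = np.random.default_rng(4)
        flags = [normality_check(effects_frame(rng.exponential(size=36)))["violated"][0]
                 for _ in range(100)]
        assert np.mean(flags) > 0.9

    def test_constant_sample_flagged_degenerate(self):
        out = normality_check(effects_frame(np.ones(10)))
        assert out.loc[0, "degenerate"] and not out.loc[0, "violated"]

    def test_too_few_participants_raise(self):
        with pytest.raises(ValueError):
            normality_check(effects_frame(np.array([0.1, 0.2])))


def test_group_mean_d_converges_to_delta(large_exp1_trials, exp1_preset):
    """Parameter recovery: the per-repetition group mean of d estimates the
    generator's delta profile."""
    from cfsbias.preprocess import normalized_effects

    _, profile = exp1_preset
    prof = (normalized_effects(large_exp1_trials)
            .groupby("repetition")["d"].mean().sort_index().to_numpy())
    np.testing.assert_allclose(prof, profile.delta, atol=0.033)
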