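"""JZS Bayes factors: frozen oracle values, symmetry identities, monotonicity."""

import numpy as np
import pytest

from cfsbias.bayes import (bf_from_effects, classify_evidence,
                           jzs_bf_one_sample, jzs_bf_two_sample, one_sample_t,
                           t_from_summary, t_from_two_summaries)

# Frozen values from the brute-force fixed-grid trapezoid oracle
# (1e6 nodes over delta in [-50r, 50r]); see conftest.brute_force_jzs_bf.
FROZEN = [
    # (t, n_or_(n1,n2), direction, expected_bf)
    (1.0, 36, "two_sided", 0.2842360657),
    (3.2727, 36, "positive", 29.0347225029),
    (2.0, (20, 30), "positive", 2.7392732390),
    (2.0, (20, 30), "two_sided", 1.4239610612),
]


class TestAgainstFrozenOracle:
    @pytest.mark.parametrize("t,n,direction,expected", FROZEN)
    def test_matches_brute_force_values(self, t, n, direction, expected):
        if isinstance(n, tuple):
            res = jzs_bf_two_sample(t, *n, direction=direction)
        else:
            res = jzs_bf_one_sample(t, n, direction=direction)
        assert res.bf == pytest.approx(expected, rel=1e-6)


class TestPriorSymmetryIdentity:
    @pytest.mark.parametrize("t", [-3.0, -0.7, 0.0, 0.5, 1.3, 2.8])
    @pytest.mark.parametrize("n", [5, 24, 80])
    def test_directional_average_equals_two_sided(self, t, n):
        """(BF_+0 + BF_-0)/2 = BF_10: the half-Cauchy halves tile the prior."""
        pos = jzs_bf_one_sample(t, n, direction="positive").bf
        neg = jzs_bf_one_sample(t, n, direction="negative").bf
        two = jzs_bf_one_sample(t, n, direction="two_sided").bf
        assert (pos + neg) / 2 == pytest.approx(two, rel=1e-7)

    @pytest.mark.parametrize("t,n", [(1.7, 12), (-2.4, 40)])
    def test_sign_flip_swaps_directional_variants(self, t, n):
        assert jzs_bf_one_sample(t, n, direction="positive").bf == pytest.approx(
            jzs_bf_one_sample(-t, n, direction="negative").bf, rel=1e-9)

    def test_reciprocal_consistency(self):
        res = jzs_bf_one_sample(2.0, 30, direction="positive")
        assert res.bf * res.bf_null == pytest.approx(1.0, rel=1e-12)


class TestMonotonicity:
    def test_two_sided_increases_in_abs_t(self):
        ts = np.linspace(0.0, 5.0, 21)
        bfs = [jzs_bf_one_sample(t, 36).bf for t in ts]
        assert np.all(np.diff(bfs) > 0)

    def test_directional_increases_in_t(self):
        ts = np.linspace(-3.0, 3.0, 13)
        bfs = [jzs_bf_one_sample(t, 36, direction="positive").bf for t in ts]
        assert np.all(np.diff(bfs) > 0)

    @pytest.mark.parametrize("n", [2, 5, 36, 200])
    def test_null_favored_at_zero_t(self, n):
        assert jzs_bf_one_sample(0.0, n).bf < 1.0


class TestTwoSample:
    def test_equal_groups_reduce_to_one_sample_form(self):
        """n1 = n2 = n equals the one-sample kernel at n_eff = n/2, df = 2n-2."""
        from cfsbias.bayes import _jzs_bf

        res = jzs_bf_two_sample(1.8, 24, 24, direction="positive")
        ref = _jzs_bf(1.8, df=46, n_eff=12.0, r=0.707, direction="positive")
        assert res.bf == pytest.approx(ref.bf, rel=1e-12)
        assert res.df == 46 and res.n_eff == 12.0

    def test_pooled_t_from_summaries(self):
        t = t_from_two_summaries(7.1, 15.0, 36, 0.3, 7.0, 36)
        assert t == pytest.approx(2.4648, abs=1e-3)


class TestExtremeT:
    def test_log_space_survives_astronomical_evidence(self):
        """t ~ 39 at n = 36 (the recognition-vs-chance regime) must yield a
        finite log-BF on the order of 10^27."""
        t = t_from_summary(85.8 - 50.0, 5.5, 36)
        res = jzs_bf_one_sample(t, 36, direction="positive")
        assert np.isfinite(res.log_bf)
        assert 26.0 < res.log_bf / np.log(10) < 29.0

    def test_very_negative_t_is_conclusive_for_null(self):
        """Strong evidence against a positive effect: BF_+0 well below 1/6
        (it decays slowly in t because the half-Cauchy keeps mass near 0;
        frozen value from the brute-force oracle)."""
        res = jzs_bf_one_sample(-8.0, 36, direction="positive")
        assert res.bf < 1 / 6
        assert res.bf == pytest.approx(0.0303398067, rel=1e-6)


class TestEvidenceLabels:
    @pytest.mark.parametrize("bf,label", [
        (10.8, "substantial_alternative"),
        (3.0, "substantial_alternative"),   # boundary to the substantial side
        (1.0, "inconclusive"),
        (1 / 3, "substantial_null"),
        (0.25, "substantial_null"),         # i.e. BF_0+ = 4
    ])
    def test_threshold_convention(self, bf, label):
        assert classify_evidence(bf) == label

    def test_nonpositive_bf_rejected(self):
        with pytest.raises(ValueError):
            classify_evidence(0.0)


class TestInputValidation:
    def test_bad_inputs_raise(self):
        with pytest.raises(ValueError):
            jzs_bf_one_sample(np.nan, 36)
        with pytest.raises(ValueError):
            jzs_bf_one_sample(1.0, 1)
        with pytest.raises(ValueError):
            jzs_bf_one_sample(1.0, 36, r=-0.5)
        with pytest.raises(ValueError):
            jzs_bf_two_sample(1.0, 1, 30)
        with pytest.raises(ValueError):
            jzs_bf_one_sample(1.0, 36, direction="sideways")


class TestDataWrapper:
    def test_paired_route_matches_t_summary(self):
        rng = np.random.default_rng(8)
        d = rng.normal(0.05, 0.1, size=30)
        t, n = one_sample_t(d)
        assert t == pytest.approx(d.mean() / (d.std(ddof=1) / np.sqrt(30)))
        res = bf_from_effects(d)
        assert res.bf == pytest.approx(jzs_bf_one_sample(t, n, direction="positive").bf)


def test_cross_check_against_independent_library():
    """Two-sided values agree with pingouin's closed-form JZS implementation."""
    pg = pytest.importorskip("pingouin")
    for t, n in [(0.5, 10), (1.0, 36), (2.5, 20), (3.2727, 36), (-1.5, 50)]:
        mine = jzs_bf_one_sample(t, n).bf
        ref = float(pg.bayesfactor_ttest(t, n, r=0.707))
        assert mine == pytest.approx(ref, rel=1e-8)
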