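"""Meta-analysis: effect sizes, pooling, heterogeneity, bias and
influence diagnostics."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from mirkey.meta import (StudyEffect, compute_smd, egger_test, heterogeneity,
                         influence_loo, log2_transform, pool_auto, pool_fixed,
                         pool_random, select_model, sensitivity_switch,
                         subgroup_pool)

effects_lists = st.lists(
    st.tuples(
        st.floats(-3, 3, allow_nan=False),
        st.floats(0.05, 2.0, allow_nan=False),
    ),
    min_size=2,
    max_size=8,
).map(
    lambda rows: [
        StudyEffect(f"s{i}", g, v, 10, 10, "A") for i, (g, v) in enumerate(rows)
    ]
)


class TestLog2Transform:
    @pytest.mark.parametrize("x,expected", [(0, 0), (3, 2), (1023, 10)])
    def test_offset_one_values(self, x, expected):
        assert log2_transform(np.array([x]))[0] == pytest.approx(expected)

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            log2_transform(np.array([-1.0]))


class TestComputeSMD:
    def test_hand_worked_example(self):
        e = compute_smd([3, 4, 5], [1, 2, 3])
        assert e.g == pytest.approx(1.6)
        assert e.var_g == pytest.approx(0.88, abs=1e-4)

    def test_identical_groups_zero(self):
        e = compute_smd([1, 2, 3, 4], [4, 3, 2, 1])
        assert e.g == pytest.approx(0.0)

    def test_antisymmetry(self):
        a, b = [3.1, 4.0, 5.2], [1.0, 2.3, 3.0]
        assert compute_smd(a, b).g == pytest.approx(-compute_smd(b, a).g)

    def test_constant_groups_rejected(self):
        with pytest.raises(ValueError):
            compute_smd([2, 2, 2], [2, 2, 2])

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            compute_smd([1], [2, 3])


class TestPooling:
    def test_fixed_hand_example(self):
        eff = [StudyEffect(f"s{i}", g, v) for i, (g, v) in
               enumerate([(1, 1.0), (2, 0.5), (3, 0.25)])]
        assert pool_fixed(eff).pooled == pytest.approx(17 / 7)

    def test_single_study_passthrough(self):
        e = StudyEffect("s", 1.3, 0.4)
        r = pool_fixed([e])
        assert r.pooled == pytest.approx(1.3)
        assert r.ci_high - r.ci_low == pytest.approx(2 * 1.959964 * np.sqrt(0.4), rel=1e-6)

    def test_equal_variance_symmetry(self):
        eff = [StudyEffect("a", 1, 0.3), StudyEffect("b", 3, 0.3)]
        assert pool_fixed(eff).pooled == pytest.approx(2.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            pool_fixed([])

    def test_random_homogeneous_equals_fixed(self):
        eff = [StudyEffect(f"s{i}", 1.2, 0.5) for i in range(4)]
        rn, fx = pool_random(eff), pool_fixed(eff)
        assert rn.tau2 == 0.0
        assert rn.pooled == pytest.approx(fx.pooled)

    def test_tau2_truncated_at_zero(self):
        eff = [StudyEffect("a", 1.0, 1.0), StudyEffect("b", 1.1, 1.0)]
        assert pool_random(eff).tau2 == 0.0

    def test_random_hand_example(self):
        # g={0,4}, var={1,1}: Q=8, df=1, C = 2 - 2/2 = 1 -> tau2 = 7
        eff = [StudyEffect("a", 0.0, 1.0), StudyEffect("b", 4.0, 1.0)]
        r = pool_random(eff)
        assert r.pooled == pytest.approx(2.0)
        assert r.tau2 == pytest.approx(7.0)

    @given(effects_lists)
    def test_fixed_equals_weighted_mean_oracle(self, eff):
        w = [1.0 / e.var_g for e in eff]
        expected = sum(wi * e.g for wi, e in zip(w, eff)) / sum(w)
        assert pool_fixed(eff).pooled == pytest.approx(expected, rel=1e-12)

    @given(effects_lists)
    def test_meta_result_invariants(self, eff):
        for r in (pool_fixed(eff), pool_random(eff)):
            assert r.ci_low <= r.pooled <= r.ci_high
            assert r.tau2 >= 0
            assert 0 <= r.I2 <= 100

    def test_cross_check_against_statsmodels(self):
        from statsmodels.stats.meta_analysis import combine_effects

        rng = np.random.default_rng(3)
        g = rng.normal(1.0, 1.0, 6)
        v = rng.uniform(0.1, 0.6, 6)
        eff = [StudyEffect(f"s{i}", gi, vi) for i, (gi, vi) in enumerate(zip(g, v))]
        ref = combine_effects(g, v, method_re="dl")
        df = ref.summary_frame()
        assert pool_fixed(eff).pooled == pytest.approx(
            df.loc["fixed effect", "eff"], rel=1e-8)
        rn = pool_random(eff)
        assert rn.pooled == pytest.approx(df.loc["random effect", "eff"], rel=1e-8)
        assert rn.tau2 == pytest.approx(ref.tau2, rel=1e-8)


class TestHeterogeneity:
    def test_identical_effects_i2_zero(self):
        eff = [StudyEffect(f"s{i}", 0.7, 0.2) for i in range(3)]
        Q, df, p, I2 = heterogeneity(eff)
        assert Q == pytest.approx(0.0)
        assert I2 == 0.0

    def test_percent_scale(self):
        eff = [StudyEffect("a", 0.0, 0.01), StudyEffect("b", 4.0, 0.01)]
        _, _, _, I2 = heterogeneity(eff)
        assert 50 < I2 <= 100  # percent, not proportion

    def test_variance_doubling_halves_q(self):
        eff = [StudyEffect("a", 0.0, 0.5), StudyEffect("b", 2.0, 1.0)]
        eff2 = [StudyEffect("a", 0.0, 1.0), StudyEffect("b", 2.0, 2.0)]
        assert heterogeneity(eff)[0] == pytest.approx(2 * heterogeneity(eff2)[0])


class TestModelSelection:
    @pytest.mark.parametrize(
        "p_Q,I2,expected",
        [
            (0.001, 88.0, "random"),
            (0.2, 30.0, "fixed"),
            (0.2, 50.0, "fixed"),  # boundary: strict inequality
            (0.049, 10.0, "random"),
            (0.05, 10.0, "fixed"),
        ],
    )
    def test_rule(self, p_Q, I2, expected):
        assert select_model(p_Q, I2) == expected


class TestEgger:
    def test_symmetric_effects_not_significant(self):
        eff = [
            StudyEffect("a", 1.0, 0.04), StudyEffect("b", 3.0, 0.04),
            StudyEffect("c", 1.5, 0.09), StudyEffect("d", 2.5, 0.09),
        ]
        r = egger_test(eff)
        assert abs(r.intercept) < 1e-8
        assert not r.significant

    def test_minimal_three_studies_finite(self):
        eff = [StudyEffect("a", 0.5, 0.1), StudyEffect("b", 1.0, 0.3),
               StudyEffect("c", 2.0, 0.6)]
        r = egger_test(eff)
        assert np.isfinite(r.intercept) and 0 <= r.p <= 1

    def test_too_few_studies(self):
        with pytest.raises(ValueError):
            egger_test([StudyEffect("a", 1, 1), StudyEffect("b", 1, 1)])


class TestInfluence:
    def test_identical_studies_unflagged(self):
        eff = [StudyEffect(f"s{i}", 1.0, 0.05) for i in range(4)]
        res = influence_loo(eff)
        assert len(res) == 4
        assert not any(r.flagged for r in res)

    def test_outlier_omission_flagged(self):
        eff = [StudyEffect(f"s{i}", 0.0, 0.02) for i in range(3)]
        eff.append(StudyEffect("outlier", 5.0, 0.02))
        res = influence_loo(eff)
        flagged = {r.omitted_study for r in res if r.flagged}
        assert "outlier" in flagged

    @given(effects_lists.filter(lambda e: len(e) >= 3))
    def test_omitting_one_duplicate_recovers_original(self, eff):
        dup = eff + [eff[0]]
        res = influence_loo(dup, model="fixed")
        omitted_first = [r for r in res if r.omitted_study == eff[0].study_id][0]
        original = pool_fixed(eff)
        assert omitted_first.result.pooled == pytest.approx(original.pooled)
        assert np.sign(omitted_first.result.pooled) == np.sign(original.pooled)


class TestSensitivityAndSubgroups:
    def test_homogeneous_models_agree(self):
        eff = [StudyEffect(f"s{i}", 2.0, 0.3) for i in range(4)]
        fx, rn, consistent = sensitivity_switch(eff)
        assert fx.pooled == pytest.approx(rn.pooled)
        assert consistent

    def test_random_ci_at_least_as_wide(self):
        eff = [StudyEffect("a", 0.0, 0.05), StudyEffect("b", 3.0, 0.05),
               StudyEffect("c", 1.0, 0.05)]
        fx, rn, _ = sensitivity_switch(eff)
        assert rn.tau2 > 0
        assert (rn.ci_high - rn.ci_low) >= (fx.ci_high - fx.ci_low)

    def test_single_subgroup_equals_overall(self):
        eff = [StudyEffect(f"s{i}", 1.0 + 0.1 * i, 0.2, subgroup="SCC")
               for i in range(4)]
        res = subgroup_pool(eff)
        assert set(res) == {"SCC"}
        assert res["SCC"].pooled == pytest.approx(pool_auto(eff).pooled)

    def test_internally_homogeneous_subgroups(self):
        eff = [StudyEffect(f"a{i}", 1.0, 0.2, subgroup="SCC") for i in range(3)]
        eff += [StudyEffect(f"b{i}", 3.0, 0.2, subgroup="ADC") for i in range(3)]
        res = subgroup_pool(eff)
        assert res["SCC"].I2 == 0.0 and res["ADC"].I2 == 0.0
        assert res["SCC"].pooled == pytest.approx(1.0)
        assert res["ADC"].pooled == pytest.approx(3.0)

    def test_single_study_subgroup_warns(self):
        eff = [StudyEffect("a", 1.0, 0.2, subgroup="SCC"),
               StudyEffect("b", 2.0, 0.2, subgroup="ADC"),
               StudyEffect("c", 2.5, 0.2, subgroup="ADC")]
        with pytest.warns(UserWarning):
            res = subgroup_pool(eff)
        assert res["SCC"].pooled == pytest.approx(1.0)
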