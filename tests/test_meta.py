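import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from mycometa.meta import (
    Grouping,
    HeterogeneityResult,
    Model,
    estimate_tau2_values,
    heterogeneity_values,
    pool,
    pool_values,
    select_model,
    subgroup_pool,
    tau2_dl,
    tau2_reml,
)
from mycometa.records import CompoundClass, InoculumMode, Organ

from conftest import make_effect


# --- independent brute-force oracles (pure python loops) ------------------

def brute_weighted_mean(y, v, tau2=0.0):
    w = [1.0 / (vi + tau2) for vi in v]
    return sum(wi * yi for wi, yi in zip(w, y)) / sum(w), 1.0 / math.sqrt(sum(w))


def brute_q(y, v):
    w = [1.0 / vi for vi in v]
    mu = sum(wi * yi for wi, yi in zip(w, y)) / sum(w)
    return sum(wi * (yi - mu) ** 2 for wi, yi in zip(w, y))


def brute_dl(y, v):
    w = [1.0 / vi for vi in v]
    q = brute_q(y, v)
    c = sum(w) - sum(wi * wi for wi in w) / sum(w)
    return max(0.0, (q - (len(y) - 1)) / c)


class TestTau2:
    def test_dl_on_three_effect_instance(self):
        y, v = [0.1, 0.5, 0.9], [0.04, 0.04, 0.04]
        assert tau2_dl(y, v) == pytest.approx(brute_dl(y, v), rel=1e-12)
        assert tau2_dl(y, v) == pytest.approx(0.12, rel=1e-12)

    def test_homogeneous_effects_give_zero_both_methods(self):
        y, v = [0.3] * 5, [0.02] * 5
        assert tau2_dl(y, v) == 0.0
        assert tau2_reml(y, v) == 0.0

    def test_reml_recovers_true_tau2_on_average(self):
        # 500 simulated meta-analyses, k=200, true tau=0.3, v ~ 0.01
        rng = np.random.default_rng(42)
        tau2_true = 0.09
        estimates = []
        for _ in range(500):
            v = np.full(200, 0.01)
            y = rng.normal(0.2, np.sqrt(v + tau2_true))
            estimates.append(tau2_reml(y, v))
        assert np.mean(estimates) == pytest.approx(tau2_true, rel=0.10)

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError):
            estimate_tau2_values([0.1, 0.2], [0.01, 0.01], method="SJ")

    def test_requires_two_effects(self):
        with pytest.raises(ValueError):
            tau2_dl([0.1], [0.01])


class TestHeterogeneity:
    def test_identical_effects_give_zero_q_and_i2(self):
        het = heterogeneity_values([0.4, 0.4], [0.02, 0.05])
        assert het.Q == pytest.approx(0.0, abs=1e-12)
        assert het.I2 == 0.0

    def test_q_matches_brute_force_and_i2_formula(self):
        y = [0.1, 0.5, -0.2, 0.8, 0.3]
        v = [0.02, 0.01, 0.05, 0.03, 0.02]
        het = heterogeneity_values(y, v)
        assert het.Q == pytest.approx(brute_q(y, v), rel=1e-12)
        assert het.df == 4
        expected_i2 = max(0.0, (het.Q - het.df) / het.Q * 100.0)
        assert het.I2 == pytest.approx(expected_i2, rel=1e-12)

    def test_q_near_df_under_homogeneity(self):
        # chi-square expectation: Q/df ~ 1 and I2 near zero on average
        rng = np.random.default_rng(3)
        ratios, i2s = [], []
        for _ in range(200):
            v = rng.uniform(0.005, 0.02, size=100)
            y = rng.normal(0.25, np.sqrt(v))
            het = heterogeneity_values(y, v)
            ratios.append(het.Q / het.df)
            i2s.append(het.I2)
        assert np.mean(ratios) == pytest.approx(1.0, abs=0.05)
        assert np.median(i2s) < 5.0

    def test_single_effect_raises(self):
        with pytest.raises(ValueError):
            heterogeneity_values([0.1], [0.01])


class TestModelSelection:
    @pytest.mark.parametrize("i2,expected", [(0.0, Model.FIXED), (75.0, Model.RANDOM), (50.0, Model.FIXED)])
    def test_i2_threshold_rule(self, i2, expected):
        het = HeterogeneityResult(Q=10, df=4, p_value=0.05, I2=i2, tau2=0.1)
        assert select_model(het) is expected


class TestPooling:
    def test_single_effect_passthrough(self):
        p = pool_values([0.4], [0.01], label="solo")
        assert p.unpooled and p.k == 1
        assert p.estimate_lnrr == 0.4
        assert p.ci_low == pytest.approx(0.4 - 1.959963984540054 * 0.1)

    def test_zero_tau2_random_equals_fixed(self):
        y, v = [0.3, 0.3, 0.3], [0.01, 0.02, 0.03]
        pr = pool_values(y, v, model="RANDOM", tau2_method="DL")
        pf = pool_values(y, v, model="FIXED")
        assert pr.estimate_lnrr == pytest.approx(pf.estimate_lnrr, rel=1e-12)
        assert pr.se == pytest.approx(pf.se, rel=1e-12)

    def test_three_effect_instance_matches_brute_force(self):
        y, v = [0.1, 0.5, 0.9], [0.04, 0.04, 0.04]
        tau2 = brute_dl(y, v)
        est, se = brute_weighted_mean(y, v, tau2)
        p = pool_values(y, v, model="RANDOM", tau2_method="DL")
        assert p.estimate_lnrr == pytest.approx(est, rel=1e-12)
        assert p.se == pytest.approx(se, rel=1e-12)

    def test_estimate_bounded_by_inputs(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            y = rng.normal(0, 1, size=6)
            v = rng.uniform(0.005, 0.05, size=6)
            p = pool_values(y, v, model="RANDOM", tau2_method="REML")
            assert y.min() - 1e-12 <= p.estimate_lnrr <= y.max() + 1e-12

    def test_adding_effect_at_pooled_mean_leaves_estimate(self):
        y, v = [0.1, 0.5, 0.9], [0.04, 0.02, 0.05]
        p = pool_values(y, v, model="FIXED")
        p2 = pool_values(y + [p.estimate_lnrr], v + [0.03], model="FIXED")
        assert p2.estimate_lnrr == pytest.approx(p.estimate_lnrr, rel=1e-12)

    @given(
        data=st.lists(
            st.tuples(st.floats(-2, 2), st.floats(0.001, 0.5)), min_size=2, max_size=10
        ),
        seed=st.integers(0, 1000),
    )
    def test_permutation_invariance(self, data, seed):
        y = [d[0] for d in data]
        v = [d[1] for d in data]
        rng = np.random.default_rng(seed)
        perm = rng.permutation(len(y))
        p1 = pool_values(y, v, model="RANDOM", tau2_method="DL")
        p2 = pool_values(
            [y[i] for i in perm], [v[i] for i in perm], model="RANDOM", tau2_method="DL"
        )
        assert p2.estimate_lnrr == pytest.approx(p1.estimate_lnrr, abs=1e-12, rel=1e-10)
        assert p2.se == pytest.approx(p1.se, abs=1e-12, rel=1e-10)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            pool_values([], [])

    def test_auto_mode_applies_selection_rule(self):
        y_hom = [0.30, 0.31, 0.29, 0.30]
        v = [0.02] * 4
        assert pool_values(y_hom, v, model="auto").model is Model.FIXED
        y_het = [-1.0, 1.2, -0.8, 1.5]
        assert pool_values(y_het, v, model="auto").model is Model.RANDOM


class TestSubgroups:
    def test_single_group_equals_overall_pool(self):
        effects = [
            make_effect(0.2, 0.01, obs_id="a", organ=Organ.ABOVEGROUND),
            make_effect(0.5, 0.02, obs_id="b", organ=Organ.ABOVEGROUND),
            make_effect(0.1, 0.03, obs_id="c", organ=Organ.ABOVEGROUND),
        ]
        table = subgroup_pool(effects, Grouping.ORGAN, model="RANDOM", tau2_method="DL")
        assert len(table.groups) == 1
        overall = pool(effects, model="RANDOM", tau2_method="DL")
        assert table.groups[0].estimate_lnrr == pytest.approx(overall.estimate_lnrr)
        assert table.groups[0].label == "ABOVEGROUND"

    def test_multi_inoculum_excluded_from_genus_grouping(self):
        effects = [
            make_effect(0.2, 0.01, obs_id="a", mode=InoculumMode.SINGLE),
            make_effect(0.3, 0.01, obs_id="b", mode=InoculumMode.SINGLE),
            make_effect(0.4, 0.01, obs_id="c", mode=InoculumMode.MULTI),
            make_effect(0.5, 0.01, obs_id="d", mode=InoculumMode.MULTI),
        ]
        table = subgroup_pool(effects, Grouping.AMF_GENUS)
        assert table.n_excluded == 2
        assert sum(g.k for g in table.groups) == 2

    def test_low_k_groups_reported_and_flagged(self):
        effects = [
            make_effect(0.2, 0.01, obs_id="a", compound=CompoundClass.PHENOLS),
            make_effect(0.3, 0.01, obs_id="b", compound=CompoundClass.FLAVONOIDS),
            make_effect(0.4, 0.01, obs_id="c", compound=CompoundClass.FLAVONOIDS),
        ]
        table = subgroup_pool(effects, Grouping.COMPOUND_CLASS, min_k=2)
        by_label = {g.label: g for g in table.groups}
        assert by_label["PHENOLS"].low_k and by_label["PHENOLS"].unpooled
        assert not by_label["FLAVONOIDS"].low_k

    def test_crossed_grouping_labels(self):
        effects = [
            make_effect(0.2, 0.01, obs_id="a", compound=CompoundClass.PHENOLS,
                        organ=Organ.ABOVEGROUND),
            make_effect(0.3, 0.01, obs_id="b", compound=CompoundClass.PHENOLS,
                        organ=Organ.BELOWGROUND),
        ]
        table = subgroup_pool(effects, Grouping.COMPOUND_CLASS_BY_ORGAN)
        assert [g.label for g in table.groups] == [
            "PHENOLS|ABOVEGROUND",
            "PHENOLS|BELOWGROUND",
        ]
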