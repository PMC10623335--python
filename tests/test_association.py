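import numpy as np
import pytest

from mycometa.association import (
    DegenerateFitError,
    PairedEffect,
    linear_fit,
    pair_effects,
    regression_table,
)
from mycometa.records import VariableKind

from conftest import make_effect


def _pairs(x, y, factor=VariableKind.GS):
    return [
        PairedEffect(study_id=f"s{i}", factor=factor, x=float(xi), y=float(yi))
        for i, (xi, yi) in enumerate(zip(x, y))
    ]


class TestPairing:
    def test_one_to_one_pairing(self):
        ing = [
            make_effect(0.2, 0.01, obs_id="a", study_id="s1"),
            make_effect(0.4, 0.01, obs_id="b", study_id="s2"),
        ]
        phys = [
            make_effect(0.1, 0.01, obs_id="p1", study_id="s1",
                        variable_kind=VariableKind.GS),
            make_effect(0.3, 0.01, obs_id="p2", study_id="s2",
                        variable_kind=VariableKind.GS),
        ]
        pairs, dropped = pair_effects(ing, phys, VariableKind.GS)
        assert len(pairs) == 2 and dropped == 0

    def test_multiple_ingredients_each_paired(self):
        ing = [
            make_effect(0.2, 0.01, obs_id=f"a{i}", study_id="s1") for i in range(3)
        ]
        phys = [
            make_effect(0.1, 0.01, obs_id="p1", study_id="s1",
                        variable_kind=VariableKind.PN)
        ]
        pairs, dropped = pair_effects(ing, phys, VariableKind.PN)
        assert len(pairs) == 3 and dropped == 0
        assert {p.x for p in pairs} == {0.1}

    def test_disjoint_studies_give_no_pairs(self):
        ing = [make_effect(0.2, 0.01, obs_id="a", study_id="s1")]
        phys = [
            make_effect(0.1, 0.01, obs_id="p", study_id="s9",
                        variable_kind=VariableKind.GS)
        ]
        pairs, dropped = pair_effects(ing, phys, VariableKind.GS)
        assert pairs == [] and dropped == 1

    def test_study_mean_rule_collapses_to_one_pair_per_study(self):
        ing = [
            make_effect(0.2, 0.01, obs_id="a1", study_id="s1"),
            make_effect(0.6, 0.01, obs_id="a2", study_id="s1"),
        ]
        phys = [
            make_effect(0.1, 0.01, obs_id="p", study_id="s1",
                        variable_kind=VariableKind.GS)
        ]
        pairs, _ = pair_effects(ing, phys, VariableKind.GS, rule="study_mean")
        assert len(pairs) == 1
        assert pairs[0].y == pytest.approx(0.4)


class TestLinearFit:
    def test_exact_collinearity(self):
        x = [0.0, 0.5, 1.0, 1.5]
        fit = linear_fit(_pairs(x, [2 * xi + 1 for xi in x]))
        assert fit.slope == pytest.approx(2.0)
        assert fit.intercept == pytest.approx(1.0)
        assert fit.r2 == pytest.approx(1.0)

    def test_r2_equals_squared_pearson(self):
        rng = np.random.default_rng(5)
        x = rng.normal(0, 1, 40)
        y = 0.5 * x + rng.normal(0, 0.5, 40)
        fit = linear_fit(_pairs(x, y))
        assert fit.r2 == pytest.approx(np.corrcoef(x, y)[0, 1] ** 2, rel=1e-10)

    def test_order_invariance_and_x_scaling(self):
        rng = np.random.default_rng(6)
        x = rng.normal(0, 1, 30)
        y = 0.8 * x + rng.normal(0, 0.2, 30)
        fit = linear_fit(_pairs(x, y))
        perm = rng.permutation(30)
        fit_perm = linear_fit(_pairs(x[perm], y[perm]))
        assert fit_perm.slope == pytest.approx(fit.slope, rel=1e-12)
        fit_scaled = linear_fit(_pairs(3.0 * x, y))
        assert fit_scaled.slope == pytest.approx(fit.slope / 3.0, rel=1e-12)

    def test_null_relationship_has_small_r2_and_uniform_p(self):
        rng = np.random.default_rng(7)
        fit = linear_fit(_pairs(rng.normal(0, 1, 1000), rng.normal(0, 1, 1000)))
        assert fit.r2 < 0.02
        pvals = []
        for _ in range(200):
            f = linear_fit(_pairs(rng.normal(0, 1, 50), rng.normal(0, 1, 50)))
            pvals.append(f.p_value)
        assert np.mean(pvals) == pytest.approx(0.5, abs=0.1)

    def test_degenerate_x_raises(self):
        with pytest.raises(DegenerateFitError):
            linear_fit(_pairs([1.0, 1.0, 1.0], [0.1, 0.2, 0.3]))

    def test_too_few_pairs_raises(self):
        with pytest.raises(ValueError):
            linear_fit(_pairs([1.0, 2.0], [0.1, 0.2]))


def test_regression_table_fits_each_reported_factor():
    rng = np.random.default_rng(9)
    ing, phys = [], []
    for i in range(10):
        sid = f"s{i}"
        x = float(rng.normal(0.3, 0.4))
        ing.append(make_effect(0.8 * x + float(rng.normal(0, 0.1)), 0.01,
                               obs_id=f"a{i}", study_id=sid))
        phys.append(make_effect(x, 0.01, obs_id=f"p{i}", study_id=sid,
                                variable_kind=VariableKind.CHL_A))
    phys.append(make_effect(0.2, 0.01, obs_id="lone", study_id="s0",
                            variable_kind=VariableKind.WUE))
    results, dropped = regression_table(ing, phys)
    factors = {r.factor for r in results}
    assert VariableKind.CHL_A in factors
    assert VariableKind.WUE not in factors  # only 1 pair, below minimum
    assert dropped[VariableKind.WUE.value] == 9
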