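"""Two-machine and 2^k-machine counterfactual risk estimation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import riskmachines as rm

probs = st.floats(0.01, 0.99)


class TestEffectFunctions:
    def _pair(self, p0, p1):
        n = len(p0)
        return rm.CounterfactualPair(
            p0=np.asarray(p0, dtype=float),
            p1=np.asarray(p1, dtype=float),
            observed_arm=np.zeros(n, dtype=int),
            target="X1",
            n0=n // 2 + 1,
            n1=n - n // 2 - 1,
        )

    def test_identity_case(self):
        est = rm.effect_functions(self._pair([0.4], [0.4]), eps=1e-6)
        assert est.rd[0] == 0 and est.rr[0] == 1 and est.or_[0] == 1

    def test_hand_computed_cases(self):
        est = rm.effect_functions(self._pair([0.3, 0.5], [6 / 13, 0.8]), eps=1e-6)
        assert est.or_[0] == pytest.approx(2.0)
        assert est.rd[1] == pytest.approx(0.3)
        assert est.rr[1] == pytest.approx(1.6)
        assert est.or_[1] == pytest.approx(4.0)

    @settings(max_examples=200, deadline=None)
    @given(probs, probs)
    def test_algebraic_identities_hold_pointwise(self, p0, p1):
        """or = rr(1-p0)/(1-p1) and rd = p0(rr-1) for any probability pair."""
        est = rm.effect_functions(self._pair([p0], [p1]), eps=1e-9)
        assert est.or_[0] == pytest.approx(est.rr[0] * (1 - p0) / (1 - p1), rel=1e-9)
        assert est.rd[0] == pytest.approx(p0 * (est.rr[0] - 1), abs=1e-12)

    @settings(max_examples=100, deadline=None)
    @given(probs, probs)
    def test_relabeling_antisymmetry_of_the_functions(self, p0, p1):
        fwd = rm.effect_functions(self._pair([p0], [p1]), eps=1e-9)
        rev = rm.effect_functions(self._pair([p1], [p0]), eps=1e-9)
        assert rev.rd[0] == pytest.approx(-fwd.rd[0], abs=1e-12)
        assert rev.or_[0] == pytest.approx(1 / fwd.or_[0], rel=1e-9)
        assert rev.rr[0] == pytest.approx(p0 / p1, rel=1e-9)

    def test_default_eps_scales_with_subgroup_resolution(self):
        assert rm.default_eps(100) == pytest.approx(1 / 200)
        assert rm.default_eps(10**9) == 1e-6


class TestAggregate:
    def _est(self, or_vals):
        n = len(or_vals)
        return rm.EffectEstimates(
            rd=np.zeros(n), rr=np.asarray(or_vals, float), or_=np.asarray(or_vals, float), eps=1e-6
        )

    def test_constant_effects_aggregate_to_the_constant(self):
        for stat in ("median", "mean"):
            agg = rm.aggregate(self._est([2.0, 2.0, 2.0]), stat=stat)
            assert agg.aggregate_or == 2.0

    def test_median_of_small_set(self):
        assert rm.aggregate(self._est([1.0, 2.0, 4.0]), stat="median").aggregate_or == 2.0

    def test_subgroup_mask_restricts_the_summary(self):
        est = self._est([1.0, 2.0, 3.0, 10.0])
        mask = np.array([True, True, True, False])
        assert rm.aggregate(est, subgroup=mask).aggregate_or == 2.0
        with pytest.raises(ValueError, match="no subjects"):
            rm.aggregate(est, subgroup=np.zeros(4, bool))

    def test_unknown_statistic_rejected(self):
        with pytest.raises(ValueError):
            rm.aggregate(self._est([1.0]), stat="mode")


class TestTwoMachine:
    def test_null_data_gives_null_odds_ratio(self):
        spec = rm.LogisticModelSpec(n_features=5, baseline_prob=0.4)
        data = rm.simulate(spec, 4000, seed=41)
        pair = rm.two_machine(data, "X1", seed=42)
        agg = rm.aggregate(rm.effect_functions(pair))
        assert 0.8 < agg.aggregate_or < 1.25

    def test_probabilities_and_bookkeeping(self, model1_data):
        pair = rm.two_machine(model1_data, "X3", seed=43)
        assert pair.n0 + pair.n1 == model1_data.n
        assert np.all((pair.p0 >= 0) & (pair.p0 <= 1))
        assert np.all((pair.p1 >= 0) & (pair.p1 <= 1))
        # observed/counterfactual split is keyed by the subject's arm
        x3 = model1_data.column("X3")
        assert np.array_equal(pair.observed_prob[x3 == 1], pair.p1[x3 == 1])
        assert np.array_equal(pair.counterfactual_prob[x3 == 1], pair.p0[x3 == 1])

    def test_constant_target_rejected(self):
        data = rm.BinaryDataset(
            y=np.array([0, 1] * 30),
            X=np.column_stack([np.zeros(60, int), np.tile([0, 1], 30)]),
            feature_names=("X1", "X2"),
        )
        with pytest.raises(ValueError, match="no counterfactual contrast"):
            rm.two_machine(data, "X1")

    def test_undersized_subgroup_names_the_cell(self, model1_data):
        with pytest.raises(ValueError, match="minimum subgroup size 600"):
            rm.two_machine(model1_data, "X3", min_subgroup=600)

    def test_relabeling_the_target_inverts_every_effect(self, model1_data):
        """Flipping the target's 0/1 coding (and the machine seeds with it)
        swaps p0 and p1 exactly, so rd -> -rd and or -> 1/or per subject."""
        s0, s1 = 71, 72
        fwd = rm.two_machine(model1_data, "X3", seeds=(s0, s1))
        j = model1_data.feature_names.index("X3")
        Xf = model1_data.X.copy()
        Xf[:, j] = 1 - Xf[:, j]
        flipped = rm.BinaryDataset(
            y=model1_data.y, X=Xf, feature_names=model1_data.feature_names
        )
        rev = rm.two_machine(flipped, "X3", seeds=(s1, s0))
        assert np.array_equal(rev.p0, fwd.p1) and np.array_equal(rev.p1, fwd.p0)
        ef, er = rm.effect_functions(fwd, eps=1e-6), rm.effect_functions(rev, eps=1e-6)
        assert np.allclose(er.rd, -ef.rd)
        assert np.allclose(er.or_, 1 / ef.or_)


class TestMultiMachine:
    def test_k1_reduces_exactly_to_two_machine(self, model1_data):
        table = rm.multi_machine(model1_data, ["X3"], seed=51)
        pair = rm.two_machine(model1_data, "X3", seed=51)
        assert np.array_equal(table.column((0,)), pair.p0)
        assert np.array_equal(table.column((1,)), pair.p1)

    def test_k3_cell_means_track_the_saturated_table(self):
        spec = rm.builtin_model("model3")
        data = rm.simulate(spec, 20_000, seed=52)
        table = rm.multi_machine(data, ["X1", "X2", "X3"], seed=53)
        for combo in table.combos:
            assert table.column(combo).mean() == pytest.approx(
                spec.stratum_table[combo], abs=0.05
            )
        assert sum(table.cell_sizes.values()) == data.n

    def test_subgroup_aggregates_recover_stratum_specific_odds_ratios(self):
        """Saturated-model subgroup effects: OR for X1 within (X2, X3) strata
        matches the ratio implied by the stratum probabilities."""
        spec = rm.builtin_model("model3")
        data = rm.simulate(spec, 20_000, seed=54)
        pair = rm.two_machine(data, "X1", seed=55)
        est = rm.effect_functions(pair)
        t = spec.stratum_table

        def true_or(x2, x3):
            p0, p1 = t[(0, x2, x3)], t[(1, x2, x3)]
            return (p1 / (1 - p1)) / (p0 / (1 - p0))

        for x2, x3 in [(0, 0), (1, 1)]:
            mask = (data.column("X2") == x2) & (data.column("X3") == x3)
            agg = rm.aggregate(est, subgroup=mask)
            assert agg.aggregate_or == pytest.approx(true_or(x2, x3), rel=0.25)

    def test_undersized_cells_are_listed(self, model1_data):
        with pytest.raises(ValueError, match="X2.*X3|cell"):
            rm.multi_machine(model1_data, ["X2", "X3"], min_subgroup=500)

    def test_k_cap_and_duplicates_rejected(self, model1_data):
        with pytest.raises(ValueError, match="between 1 and 3"):
            rm.multi_machine(model1_data, ["X1", "X2", "X3", "X4"])
        with pytest.raises(ValueError, match="distinct"):
            rm.multi_machine(model1_data, ["X1", "X1"])
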