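"""Scaling, lag products, curve estimators and per-lag tests."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from axiscorr.correlation import (
    DegenerateFragmentError,
    EmptyLagError,
    LagProducts,
    ScaledFragment,
    compare_conditions,
    correlation_curve,
    lag_products,
    lag_ttest,
    scale_fragment,
    scale_series,
)
from axiscorr.profiles import AxisProfile
from axiscorr.simulate import SyntheticParams

from conftest import make_scaled, random_scaled_fragments, scaled_cohort
from oracles import brute_force_curve, t_pvalue_by_integration


class TestScaling:
    def test_hand_computed_example(self):
        np.testing.assert_allclose(scale_series([1.0, 2.0, 3.0]), [-1.0, 0.0, 1.0])

    def test_constant_series_is_degenerate(self):
        with pytest.raises(DegenerateFragmentError):
            scale_series([4.0, 4.0, 4.0])

    @settings(max_examples=50, derandomize=True)
    @given(
        st.lists(
            st.floats(min_value=-1e6, max_value=1e6, allow_nan=False),
            min_size=3,
            max_size=40,
        )
    )
    def test_scaled_output_is_centered_unit_sd(self, values):
        v = np.asarray(values)
        try:
            out = scale_series(v)
        except DegenerateFragmentError:
            # legitimate only for (numerically) constant input
            assert v.std(ddof=1) <= 1e-9 * (1.0 + np.abs(v).max())
            return
        assert abs(out.mean()) < 1e-9
        assert abs(out.std(ddof=1) - 1.0) < 1e-9

    def test_scale_fragment_from_profile(self):
        profile = AxisProfile(
            intensities={"platform": np.array([1.0, 2.0, 3.0]),
                         "focus": np.array([3.0, 2.0, 1.0])},
            fragment_id="f0",
        )
        frag = scale_fragment(profile, "platform", "focus")
        np.testing.assert_allclose(frag.s, [-1.0, 0.0, 1.0])
        np.testing.assert_allclose(frag.r, [1.0, 0.0, -1.0])

    def test_unscaled_input_rejected_by_type(self):
        with pytest.raises(ValueError):
            ScaledFragment(s=np.array([1.0, 2.0, 3.0]), r=np.array([-1.0, 0.0, 1.0]))


class TestLagProducts:
    def test_auto_enumeration(self):
        frag = make_scaled([1.0, 2.0, 3.0])  # s = [-1, 0, 1]
        prods = lag_products(frag, "auto", 2)
        np.testing.assert_allclose(prods.pooled(1), [0.0, 0.0])
        np.testing.assert_allclose(prods.pooled(2), [-1.0])

    def test_cross_lag0_equals_auto_lag0_when_r_is_s(self):
        frag = make_scaled([3.0, 1.0, 4.0, 1.0, 5.0])
        auto = lag_products(frag, "auto", 0).pooled(0)
        cross = lag_products(frag, "cross", 0).pooled(0)
        np.testing.assert_allclose(np.sort(cross), np.sort(auto))

    def test_cross_lag0_enumeration(self):
        frag = make_scaled([1.0, 2.0, 3.0], [3.0, 2.0, 1.0])
        np.testing.assert_allclose(lag_products(frag, "cross", 0).pooled(0), [-1.0, 0.0, -1.0])

    def test_cross_positive_lag_has_both_orientations(self):
        frag = make_scaled([1.0, 2.0, 3.0], [3.0, 2.0, 1.0])
        # s=[-1,0,1], r=[1,0,-1]; lag 1: s0*r1, s1*r2, s1*r0, s2*r1 = 0,0,0,0
        assert lag_products(frag, "cross", 1).pooled(1).size == 4

    def test_short_fragment_contributes_nothing_beyond_its_length(self):
        frag = make_scaled([1.0, 2.0, 3.0])
        prods = lag_products(frag, "auto", 10)
        assert prods.n_products(5) == 0


class TestCorrelationCurve:
    def test_single_fragment_hand_computation(self):
        curve = correlation_curve([make_scaled([1.0, 2.0, 3.0])], "auto", 2)
        np.testing.assert_allclose(curve.values, [2.0 / 3.0, 0.0, -1.0], atol=1e-15)

    def test_averaging_identical_fragments_is_idempotent(self):
        one = correlation_curve([make_scaled([1.0, 5.0, 2.0, 4.0])], "auto", 3)
        two = correlation_curve([make_scaled([1.0, 5.0, 2.0, 4.0])] * 2, "auto", 3)
        np.testing.assert_allclose(one.values, two.values)

    def test_sign_flip_of_partner_negates_cross_curve(self, rng):
        frags = random_scaled_fragments(rng, 4, min_len=8, max_len=12)
        flipped = [ScaledFragment(s=f.s, r=-f.r) for f in frags]
        g = correlation_curve(frags, "cross", 5)
        g_neg = correlation_curve(flipped, "cross", 5)
        np.testing.assert_allclose(g_neg.values, -g.values, atol=1e-12)

    def test_unsigned_lag_symmetry_swapping_series(self, rng):
        frags = random_scaled_fragments(rng, 5, min_len=6, max_len=12)
        swapped = [ScaledFragment(s=f.r, r=f.s) for f in frags]
        g_sr = correlation_curve(frags, "cross", 5)
        g_rs = correlation_curve(swapped, "cross", 5)
        np.testing.assert_allclose(g_sr.values, g_rs.values, atol=1e-12)

    def test_auto_lag0_equals_fragment_length_invariant(self, rng):
        frags = random_scaled_fragments(rng, 20, min_len=3, max_len=40)
        curve = correlation_curve(frags, "auto", 0)
        expected = np.mean([(f.length - 1) / f.length for f in frags])
        assert abs(curve.value_at(0) - expected) < 1e-12

    @pytest.mark.parametrize("mode", ["auto", "cross"])
    @pytest.mark.parametrize("estimator", ["fragment_mean", "pooled"])
    def test_matches_brute_force_all_pairs_oracle(self, rng, mode, estimator):
        frags = random_scaled_fragments(rng, 5, min_len=4, max_len=12)
        x_max = 3  # all fragments are at least 4 long
        curve = correlation_curve(frags, mode, x_max, estimator=estimator)
        expected = brute_force_curve(frags, mode, x_max, estimator)
        np.testing.assert_allclose(curve.values, expected, atol=1e-12)

    def test_empty_lag_raises_with_lag_listed(self):
        with pytest.raises(EmptyLagError, match="10"):
            correlation_curve([make_scaled([1.0, 2.0, 3.0])], "auto", 10)


class TestLagTTest:
    @staticmethod
    def _products(samples):
        prods = LagProducts(mode="cross", x_max=0)
        prods.products[0] = [np.asarray(samples, dtype=float)]
        prods.fragment_ids[0] = ["f0"]
        return prods

    def test_zero_mean_sample_gives_p_one(self):
        assert lag_ttest(self._products([1.0, -1.0, 1.0, -1.0]))[0] == 1.0

    def test_zero_variance_nonzero_mean_is_degenerate_p_zero(self):
        assert lag_ttest(self._products([1.0, 1.0, 1.0, 1.0]))[0] == 0.0

    def test_matches_independent_t_density_integration(self):
        samples = [0.5, 0.1, 0.3, 0.7, 0.4]
        p = lag_ttest(self._products(samples))[0]
        assert abs(p - t_pvalue_by_integration(samples)) < 1e-10

    def test_fewer_than_two_samples_is_undefined(self):
        with pytest.raises(EmptyLagError):
            lag_ttest(self._products([0.5]))

    def test_fragment_mean_unit_uses_one_sample_per_fragment(self, rng):
        frags = random_scaled_fragments(rng, 6, min_len=8, max_len=12)
        prods = LagProducts(mode="cross", x_max=0)
        for f in frags:
            prods.extend(lag_products(f, "cross", 0))
        means = prods.fragment_means(0)
        assert means.size == 6
        p = lag_ttest(prods, sample_unit="fragment_mean")[0]
        assert abs(p - t_pvalue_by_integration(means)) < 1e-10


class TestCompareConditions:
    def test_cohort_against_itself_is_all_zero(self, rng):
        frags = random_scaled_fragments(rng, 6, min_len=8, max_len=12)
        table = compare_conditions(frags, frags, x_max=5)
        np.testing.assert_allclose(table["difference"], 0.0)
        assert (table["p_bh"] > 0.05).all()

    def test_comparison_restricted_to_shared_lags(self, rng):
        short = random_scaled_fragments(rng, 5, min_len=6, max_len=6)
        long = random_scaled_fragments(rng, 5, min_len=25, max_len=30)
        table = compare_conditions(short, long, x_max=20)
        assert table["lag_px"].max() == 5  # length-6 fragments reach lag 5 only

    def test_depleted_vs_undepleted_negative_significant_at_lag0(self):
        depleted = scaled_cohort(SyntheticParams(depletion_depth=0.8), seed=11, n=300)
        flat = scaled_cohort(SyntheticParams(depletion_depth=0.0), seed=12, n=300)
        table = compare_conditions(depleted, flat, x_max=5)
        row0 = table.loc[table["lag_px"] == 0].iloc[0]
        assert row0["difference"] < 0
        assert row0["p_bh"] < 0.05
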