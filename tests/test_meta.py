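import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from strokemeta import (
    cochran_q,
    dl_tau2,
    egger_test,
    fixed_effect_pool,
    pool_mean_difference,
    random_effects_pool,
)

from ._oracles import dl_tau2 as oracle_tau2
from ._oracles import egger as oracle_egger
from ._oracles import fe_pool, q_stat, re_pool

pairs = st.lists(
    st.tuples(
        st.floats(-1.5, 1.5, allow_nan=False),
        st.floats(0.02, 1.0, allow_nan=False),
    ),
    min_size=2,
    max_size=12,
)


class TestFixedEffect:
    def test_single_study_identity(self):
        r = fixed_effect_pool([(0.3, 0.1)])
        assert (r.pooled, r.se_pooled) == (0.3, 0.1)
        assert r.tau2 == 0.0 and r.k == 1

    def test_equal_weights_give_mean(self):
        r = fixed_effect_pool([(0.2, 0.1), (0.4, 0.1)])
        assert r.pooled == pytest.approx(0.3, abs=1e-12)

    def test_matches_hand_weighted_mean(self):
        fx = [(0.1, 0.08), (0.5, 0.2), (0.3, 0.1)]
        mu, se = fe_pool(*zip(*fx))
        r = fixed_effect_pool(fx)
        assert r.pooled == pytest.approx(mu, abs=1e-12)
        assert r.se_pooled == pytest.approx(se, abs=1e-12)

    def test_empty_list_errors(self):
        with pytest.raises(ValueError):
            fixed_effect_pool([])

    def test_duplicating_studies_keeps_value_halves_variance(self):
        fx = [(0.1, 0.08), (0.5, 0.2), (0.3, 0.1)]
        r1 = fixed_effect_pool(fx)
        r2 = fixed_effect_pool(fx + fx)
        assert r2.pooled == pytest.approx(r1.pooled, abs=1e-12)
        assert r2.se_pooled == pytest.approx(r1.se_pooled / math.sqrt(2), abs=1e-12)


class TestHeterogeneity:
    def test_identical_studies_no_dispersion(self):
        q, df, p = cochran_q([(0.3, 0.1)] * 4)
        assert q == pytest.approx(0.0, abs=1e-12)
        assert df == 3 and p == pytest.approx(1.0)

    def test_two_study_hand_value(self):
        q, df, _ = cochran_q([(0.2, 0.1), (0.4, 0.1)])
        assert q == pytest.approx(2.0, abs=1e-12)
        assert df == 1

    def test_needs_two_studies(self):
        with pytest.raises(ValueError):
            cochran_q([(0.3, 0.1)])
        with pytest.raises(ValueError):
            dl_tau2([(0.3, 0.1)])

    def test_homogeneous_tau2_truncates_to_zero(self):
        assert dl_tau2([(0.3, 0.1), (0.31, 0.1), (0.29, 0.1)]) == 0.0

    def test_tau2_matches_closed_form(self):
        fx = [(0.0, 0.1), (1.0, 0.1)]
        assert dl_tau2(fx) == pytest.approx(oracle_tau2(*zip(*fx)), abs=1e-14)

    @given(pairs)
    @settings(max_examples=40, deadline=None)
    def test_tau2_order_invariant(self, fx):
        assert dl_tau2(fx) == pytest.approx(dl_tau2(fx[::-1]), abs=1e-12)


class TestRandomEffects:
    def test_homogeneous_equals_fixed(self):
        fx = [(0.3, 0.1), (0.3, 0.2), (0.3, 0.15)]
        fe, re = fixed_effect_pool(fx), random_effects_pool(fx)
        assert re.tau2 == 0.0
        assert re.pooled == pytest.approx(fe.pooled, abs=1e-12)
        assert re.se_pooled == pytest.approx(fe.se_pooled, abs=1e-12)

    def test_heterogeneous_ci_at_least_as_wide(self):
        fx = [(0.0, 0.1), (0.8, 0.12), (0.4, 0.09), (1.2, 0.2)]
        fe, re = fixed_effect_pool(fx), random_effects_pool(fx)
        assert re.se_pooled >= fe.se_pooled
        assert (re.ci_high - re.ci_low) >= (fe.ci_high - fe.ci_low)

    def test_matches_bruteforce_oracle(self, rng):
        for _ in range(5):
            k = int(rng.integers(3, 9))
            ys = rng.normal(0.2, 0.5, k).tolist()
            ses = rng.uniform(0.05, 0.5, k).tolist()
            mu, se = re_pool(ys, ses)
            r = random_effects_pool(list(zip(ys, ses)))
            assert r.pooled == pytest.approx(mu, abs=1e-10)
            assert r.se_pooled == pytest.approx(se, abs=1e-10)

    def test_matches_statsmodels_dl(self):
        # independent route: statsmodels' DerSimonian-Laird pooling
        from statsmodels.stats.meta_analysis import combine_effects

        ys = [0.12, 0.45, 0.30, -0.05, 0.6]
        ses = [0.1, 0.2, 0.15, 0.3, 0.25]
        ours = random_effects_pool(list(zip(ys, ses)))
        theirs = combine_effects(np.array(ys), np.array(ses) ** 2, method_re="dl")
        assert ours.tau2 == pytest.approx(theirs.tau2, rel=1e-10)
        assert ours.pooled == pytest.approx(theirs.mean_effect_re, rel=1e-10)

    @given(pairs)
    @settings(max_examples=40, deadline=None)
    def test_order_invariance(self, fx):
        r1, r2 = random_effects_pool(fx), random_effects_pool(fx[::-1])
        assert r1.pooled == pytest.approx(r2.pooled, abs=1e-12)
        assert r1.se_pooled == pytest.approx(r2.se_pooled, abs=1e-12)


class TestEgger:
    def test_symmetric_funnel_near_zero_intercept(self):
        # effects mirrored around the mean with matched precisions
        ses = [0.1, 0.2, 0.3, 0.1, 0.2, 0.3]
        ys = [0.3 + d * s for d, s in zip([1, 1, 1, -1, -1, -1], ses)]
        res = egger_test(list(zip(ys, ses)))
        assert abs(res.intercept) < 1e-10

    def test_matches_closed_form_ols(self, rng):
        ys = rng.normal(0.2, 0.3, 8).tolist()
        ses = rng.uniform(0.05, 0.5, 8).tolist()
        i0, se0, p0 = oracle_egger(ys, ses)
        res = egger_test(list(zip(ys, ses)))
        assert res.intercept == pytest.approx(i0, abs=1e-10)
        assert res.se_intercept == pytest.approx(se0, abs=1e-10)
        assert res.p == pytest.approx(p0, abs=1e-10)

    def test_needs_three_studies(self):
        with pytest.raises(ValueError):
            egger_test([(0.1, 0.1), (0.2, 0.2)])

    def test_equal_precisions_singular(self):
        with pytest.raises(ValueError, match="singular"):
            egger_test([(0.1, 0.2), (0.3, 0.2), (0.2, 0.2)])


class TestMeanDifference:
    def test_identical_studies_pool_to_common_difference(self):
        g = (100, 2.26, 0.4, 200, 3.0, 0.4)
        r = pool_mean_difference([g, g])
        assert r.pooled == pytest.approx(-0.74, abs=1e-12)
        assert r.scale == "mean_difference"

    def test_single_pair_identity(self):
        r = pool_mean_difference([(50, 1.0, 0.2, 60, 1.5, 0.3)])
        assert r.pooled == pytest.approx(-0.5, abs=1e-12)
        assert r.se_pooled == pytest.approx(math.sqrt(0.04 / 50 + 0.09 / 60), abs=1e-12)

    def test_matches_bruteforce_weighted_mean(self):
        groups = [
            (40, 5.0, 1.0, 50, 5.5, 1.2),
            (80, 4.8, 0.9, 90, 5.6, 1.1),
            (30, 5.2, 1.3, 35, 5.4, 1.0),
            (120, 4.9, 1.1, 110, 5.8, 1.2),
        ]
        ys = [m1 - m2 for _, m1, _, _, m2, _ in groups]
        ses = [
            math.sqrt(s1**2 / n1 + s2**2 / n2)
            for n1, _, s1, n2, _, s2 in groups
        ]
        mu, se = re_pool(ys, ses)
        r = pool_mean_difference(groups)
        assert r.pooled == pytest.approx(mu, abs=1e-10)
        assert r.se_pooled == pytest.approx(se, abs=1e-10)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            pool_mean_difference([(1, 5.0, 1.0, 50, 5.5, 1.2)])
        with pytest.raises(ValueError):
            pool_mean_difference([(50, 5.0, 0.0, 50, 5.5, 1.2)])


def test_i2_derived_from_q():
    fx = [(0.0, 0.1), (0.8, 0.1)]
    r = random_effects_pool(fx)
    assert r.i2 == pytest.approx(max(0.0, 100 * (r.q - 1) / r.q))
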