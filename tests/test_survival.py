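import numpy as np
import pytest
from scipy import stats as sps

from sighub.errors import DegenerateInputError, ParameterError
from sighub.survival import (cox_score_test, cox_univariate, km_estimate,
                             logrank_test, median_split)


def simulate_ph(rng, n, beta=0.0, censor_scale=None, binary=False):
    x = (rng.random(n) < 0.5).astype(float) if binary else rng.normal(size=n)
    t = rng.exponential(np.exp(-beta * x))
    if censor_scale is None:
        return t, np.ones(n, dtype=int), x
    c = rng.exponential(censor_scale, n)
    return np.minimum(t, c), (t <= c).astype(int), x


class TestKaplanMeier:
    def test_all_censored_is_flat_one(self):
        km = km_estimate([3.0, 5.0, 7.0], [0, 0, 0])
        assert km.times.size == 0
        assert km.survival_at(100.0) == 1.0

    def test_hand_product_limit_no_censoring(self):
        km = km_estimate([1, 2, 3], [1, 1, 1])
        assert km.survival == pytest.approx([2 / 3, 1 / 3, 0.0])

    def test_hand_product_limit_with_censoring(self):
        # middle subject censored at 2: S(1)=2/3, S(3)=(2/3)*(1-1/1)=0
        km = km_estimate([1, 2, 3], [1, 0, 1])
        assert km.times == pytest.approx([1.0, 3.0])
        assert km.survival == pytest.approx([2 / 3, 0.0])

    def test_order_invariance(self, rng):
        t = rng.exponential(1, 40)
        e = (rng.random(40) < 0.7).astype(int)
        perm = rng.permutation(40)
        km1, km2 = km_estimate(t, e), km_estimate(t[perm], e[perm])
        assert km1.times == pytest.approx(km2.times)
        assert km1.survival == pytest.approx(km2.survival)

    def test_monotone_non_increasing(self, rng):
        t = np.round(rng.exponential(1, 60), 1)
        e = (rng.random(60) < 0.6).astype(int)
        km = km_estimate(t, e)
        assert np.all(np.diff(km.survival) <= 1e-15)

    def test_empty_input_rejected(self):
        with pytest.raises(ParameterError):
            km_estimate([], [])


class TestLogrank:
    def test_identical_groups_statistic_zero(self):
        g = ([1.0, 2.0, 3.0], [1, 0, 1])
        r = logrank_test(g, g)
        assert r.statistic == pytest.approx(0.0, abs=1e-12)
        assert r.p_value == pytest.approx(1.0)

    def test_label_symmetry(self, rng):
        ga = (rng.exponential(1, 30), (rng.random(30) < 0.7).astype(int))
        gb = (rng.exponential(2, 25), (rng.random(25) < 0.7).astype(int))
        r1, r2 = logrank_test(ga, gb), logrank_test(gb, ga)
        assert r1.statistic == pytest.approx(r2.statistic, rel=1e-12)

    def test_six_subject_hand_table(self):
        # group A: 1, 3+, 5; group B: 2, 4, 5 (all events except 3+)
        ga = (np.array([1.0, 3.0, 5.0]), np.array([1, 0, 1]))
        gb = (np.array([2.0, 4.0, 5.0]), np.array([1, 1, 1]))
        # hand 2x2 hypergeometric sums over event times 1,2,4,5
        o = e = v = 0.0
        for t, (n1, n2, d1, d) in {
            1.0: (3, 3, 1, 1),
            2.0: (2, 3, 0, 1),
            4.0: (1, 2, 0, 1),
            5.0: (1, 1, 1, 2),
        }.items():
            n = n1 + n2
            o += d1
            e += d * n1 / n
            v += d * (n1 / n) * (n2 / n) * (n - d) / (n - 1) if n > 1 else 0.0
        r = logrank_test(ga, gb)
        assert r.extra["observed_a"] == pytest.approx(o)
        assert r.extra["expected_a"] == pytest.approx(e)
        assert r.extra["variance"] == pytest.approx(v)
        assert r.statistic == pytest.approx((o - e) ** 2 / v)

    def test_matches_lifelines(self, rng):
        from lifelines.statistics import logrank_test as ll
        ta = np.round(rng.exponential(1, 40), 1)
        tb = np.round(rng.exponential(1.5, 35), 1)
        ea = (rng.random(40) < 0.7).astype(int)
        eb = (rng.random(35) < 0.7).astype(int)
        r = logrank_test((ta, ea), (tb, eb))
        o = ll(ta, tb, ea, eb)
        assert r.statistic == pytest.approx(o.test_statistic, rel=1e-10)

    def test_no_events_rejected(self):
        with pytest.raises(DegenerateInputError):
            logrank_test(([1.0, 2.0], [0, 0]), ([3.0], [0]))

    def test_type_i_error_near_nominal(self, rng):
        hits = 0
        n_sim = 500
        for _ in range(n_sim):
            t, e, x = simulate_ph(rng, 120, beta=0.0, censor_scale=2.3,
                                  binary=True)
            g = x == 1
            hits += logrank_test((t[g], e[g]), (t[~g], e[~g])).p_value < 0.05
        assert 0.025 <= hits / n_sim <= 0.08


class TestMedianSplit:
    @pytest.mark.parametrize("values,low,high", [
        ([1, 2, 3, 4], [0, 1], [2, 3]),
        ([1, 2, 3], [0, 1], [2]),
        ([1, 1, 2, 2], [0, 1], [2, 3]),
    ])
    def test_split_examples(self, values, low, high):
        labels = median_split(values)
        assert list(np.flatnonzero(labels == "low")) == low
        assert list(np.flatnonzero(labels == "high")) == high

    def test_tie_at_median_fills_low_first_deterministically(self):
        labels = median_split([2.0, 2.0, 2.0, 1.0, 3.0])
        assert list(labels) == ["low", "low", "high", "low", "high"]

    def test_all_identical_rejected(self):
        with pytest.raises(DegenerateInputError):
            median_split([5.0, 5.0, 5.0])


class TestCox:
    def test_matches_lifelines_with_ties(self, rng):
        import pandas as pd
        from lifelines import CoxPHFitter
        t, e, x = simulate_ph(rng, 250, beta=0.6, censor_scale=2.0)
        t = np.round(t, 1) + 0.01          # force ties
        fit = cox_univariate(t, e, x)
        cph = CoxPHFitter().fit(
            pd.DataFrame({"t": t, "e": e, "x": x}), "t", "e")
        assert fit.beta == pytest.approx(float(cph.params_.iloc[0]), abs=1e-6)
        assert fit.se == pytest.approx(
            float(cph.standard_errors_.iloc[0]), abs=1e-6)
        assert fit.converged

    def test_score_test_equals_logrank_binary_no_ties(self, rng):
        t, e, x = simulate_ph(rng, 150, beta=0.4, binary=True)
        r = cox_score_test(t, e, x)
        g = x == 1
        lr = logrank_test((t[g], e[g]), (t[~g], e[~g]))
        assert r.statistic == pytest.approx(lr.statistic, abs=1e-8)

    def test_parameter_recovery(self, rng):
        betas = [cox_univariate(*simulate_ph(rng, 500, beta=0.5,
                                             censor_scale=2.0)).beta
                 for _ in range(20)]
        assert np.mean(betas) == pytest.approx(0.5, abs=0.08)

    def test_null_wald_p_uniform(self, rng):
        ps = [cox_univariate(*simulate_ph(rng, 150, beta=0.0,
                                          censor_scale=2.0)).p_value
              for _ in range(300)]
        assert sps.kstest(ps, "uniform").pvalue > 0.01

    def test_sign_agrees_with_lower_km_curve(self, rng):
        t, e, x = simulate_ph(rng, 400, beta=1.0, binary=True)
        fit = cox_univariate(t, e, x)
        km1 = km_estimate(t[x == 1], e[x == 1])
        km0 = km_estimate(t[x == 0], e[x == 0])
        t_star = min(t[x == 1].max(), t[x == 0].max())
        assert fit.beta > 0
        assert km1.survival_at(t_star) < km0.survival_at(t_star)

    def test_hr_and_ci_consistency(self, rng):
        fit = cox_univariate(*simulate_ph(rng, 200, beta=0.5,
                                          censor_scale=2.0))
        assert fit.ci95[0] < fit.hr < fit.ci95[1]
        assert fit.hr == pytest.approx(np.exp(fit.beta))

    def test_constant_covariate_rejected(self, rng):
        t, e, _ = simulate_ph(rng, 50)
        with pytest.raises(DegenerateInputError):
            cox_univariate(t, e, np.ones(50))

    def test_too_few_events_rejected(self, rng):
        t = rng.exponential(1, 30)
        e = np.zeros(30, dtype=int)
        e[:3] = 1
        with pytest.raises(DegenerateInputError):
            cox_univariate(t, e, rng.normal(size=30))
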