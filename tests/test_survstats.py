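import numpy as np
import pandas as pd
import pytest

from actbenefit import (chisq_independence, cox_fit, interaction_pvalue,
                        km_estimate, logrank_test)
from ._oracles import logrank_permutation_p


class TestKaplanMeier:
    def test_hand_product_limit(self):
        # events at 12 and 24 among four patients -> S(36) = 3/4 * 2/3 = 1/2
        km = km_estimate([12, 24, 40, 50], [True, True, False, False])
        assert km.at(36.0) == pytest.approx(0.5)
        assert km.at(0.0) == 1.0

    def test_no_events_survival_stays_one(self):
        km = km_estimate([10, 20, 30], [False] * 3)
        for t in (5, 25, 35):
            assert km.at(t) == 1.0

    def test_all_events_before_t_gives_zero(self):
        km = km_estimate([1, 2, 3], [True] * 3)
        assert km.at(10.0) == 0.0

    def test_no_censoring_equals_empirical_survival(self):
        rng = np.random.default_rng(0)
        times = rng.exponential(30, 50)
        km = km_estimate(times, np.ones(50, bool))
        for t in (5.0, 20.0, 50.0):
            assert km.at(t) == pytest.approx((times > t).mean(), abs=1e-12)

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            km_estimate([], [])


class TestLogrank:
    def test_identical_groups(self):
        t = [5.0, 10.0, 15.0]
        e = [True, True, False]
        stat, p = logrank_test(t, e, t, e)
        assert stat == pytest.approx(0.0, abs=1e-9)
        assert p == pytest.approx(1.0)

    def test_no_events_flagged_p_one(self):
        stat, p = logrank_test([10, 20], [False, False], [15], [False])
        assert (stat, p) == (0.0, 1.0)

    def test_power_under_hazard_ratio_three(self):
        hits = 0
        for seed in range(60):
            rng = np.random.default_rng(seed)
            a = rng.exponential(30, 100)
            b = rng.exponential(10, 100)
            _, p = logrank_test(a, np.ones(100, bool), b, np.ones(100, bool))
            hits += p < 0.01
        assert hits >= 57  # >= 95% power

    def test_time_unit_invariance(self):
        rng = np.random.default_rng(1)
        a, b = rng.exponential(20, 30), rng.exponential(35, 25)
        ea, eb = np.ones(30, bool), np.ones(25, bool)
        s1, p1 = logrank_test(a, ea, b, eb)
        s2, p2 = logrank_test(a * 12, ea, b * 12, eb)
        assert s1 == pytest.approx(s2) and p1 == pytest.approx(p2)

    @pytest.mark.parametrize("seed", range(4))
    def test_small_n_close_to_permutation_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = 8
        times = rng.exponential(20, n)
        events = rng.random(n) < 0.8
        group = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        _, p_chi2 = logrank_test(times[group == 0], events[group == 0],
                                 times[group == 1], events[group == 1])
        p_perm = logrank_permutation_p(times, events, group)
        assert abs(p_chi2 - p_perm) < 0.15


class TestCox:
    def test_recovers_known_hazard_ratio(self):
        # two-group exponential data, true HR 2, n = 500, all events:
        # the partial-likelihood estimate is unbiased with log-HR sampling
        # sd ~0.105, so ~87% of draws land in [1.7, 2.35]
        hits = 0
        logs = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            x = np.repeat([0.0, 1.0], 250)
            t = rng.exponential(1.0 / np.exp(np.log(2.0) * x))
            summ = cox_fit(pd.DataFrame({"x": x}), t, np.ones(500, bool))["x"]
            hits += 1.7 <= summ.hr <= 2.35
            logs.append(summ.coef)
            assert summ.ci95[0] <= summ.hr <= summ.ci95[1]
        assert hits >= 80
        assert np.mean(logs) == pytest.approx(np.log(2.0), abs=0.03)
        assert np.std(logs) < 0.13

    def test_constant_covariate_errors(self):
        with pytest.raises(ValueError, match="constant"):
            cox_fit(pd.DataFrame({"x": [1.0] * 10}),
                    np.arange(1, 11), np.ones(10, bool))

    def test_too_few_events_errors(self):
        df = pd.DataFrame({"a": np.arange(6.0), "b": np.arange(6.0)[::-1]})
        with pytest.raises(ValueError, match="events"):
            cox_fit(df, np.arange(1, 7), [True] + [False] * 5)

    def test_null_covariate_type1_calibrated(self):
        hits = 0
        n_sims = 150
        for seed in range(n_sims):
            rng = np.random.default_rng(seed)
            x = rng.normal(size=400)
            t = rng.exponential(1.0, 400)
            summ = cox_fit(pd.DataFrame({"x": x}), t, np.ones(400, bool))["x"]
            hits += summ.p < 0.05
        assert abs(hits / n_sims - 0.05) < 0.035


class TestInteraction:
    @staticmethod
    def _simulate(seed, effect):
        rng = np.random.default_rng(seed)
        n = 600
        treat = rng.random(n) < 0.5
        group = rng.random(n) < 0.5
        loghr = effect * (treat & group)
        t = rng.exponential(1.0 / (0.03 * np.exp(loghr)))
        c = rng.uniform(20, 80, n)
        times, events = np.minimum(t, c), t <= c
        return treat.astype(float), group.astype(float), times, events

    def test_power_for_planted_interaction(self):
        hits = 0
        for seed in range(40):
            treat, group, times, events = self._simulate(seed, np.log(0.5))
            p = interaction_pvalue(treat, group, None, times, events)
            hits += p < 0.05
        assert hits >= 36

    def test_constant_group_errors(self):
        treat, group, times, events = self._simulate(0, 0.0)
        with pytest.raises(ValueError, match="constant"):
            interaction_pvalue(treat, np.ones_like(group), None, times, events)

    def test_adjusters_are_included(self):
        treat, group, times, events = self._simulate(1, 0.0)
        adj = pd.DataFrame({"z": np.random.default_rng(1).normal(size=len(treat))})
        p = interaction_pvalue(treat, group, adj, times, events)
        assert 0.0 <= p <= 1.0


class TestChiSquare:
    def test_balanced_table_is_null(self):
        stat, df, p = chisq_independence([[10, 10], [10, 10]])
        assert stat == 0.0 and df == 1 and p == 1.0

    def test_hand_computed_example(self):
        stat, df, p = chisq_independence([[20, 10], [10, 20]])
        assert stat == pytest.approx(6.667, abs=5e-4)
        assert p == pytest.approx(0.0098, abs=5e-5)

    def test_sex_by_treatment_contingency(self):
        # 386 male / 320 female split across treatment arms
        _, _, p = chisq_independence([[162, 224], [147, 173]])
        assert round(p, 3) == 0.290

    def test_zero_marginal_errors(self):
        with pytest.raises(ValueError, match="marginal"):
            chisq_independence([[0, 0], [5, 10]])

    def test_one_dimensional_rejected(self):
        with pytest.raises(ValueError, match="2x2"):
            chisq_independence([[1, 2]])
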