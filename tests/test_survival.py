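"""Survival primitives: KM, log-rank, Harrell's C, Cox, C-difference."""

import math

import numpy as np
import pytest
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as ll_logrank
from lifelines.utils import concordance_index

from cardioreclass.survival import (
    cindex_difference,
    fit_cox,
    harrell_c,
    km_at,
    km_estimate,
    likelihood_ratio_test,
    logrank_test,
)


class TestKaplanMeier:
    def test_no_events_survival_one(self):
        curve = km_estimate([5, 8, 12], [0, 0, 0])
        assert km_at(curve, 100) == 1.0

    def test_hand_product(self):
        # S(1) = 2/3; at t=3 the last at-risk subject dies -> S(3) = 0
        curve = km_estimate([1, 2, 3], [1, 0, 1])
        assert km_at(curve, 1) == pytest.approx(2 / 3)
        assert km_at(curve, 2.5) == pytest.approx(2 / 3)
        assert km_at(curve, 3) == 0.0

    def test_uncensored_equals_empirical_survival(self, rng):
        t = rng.exponential(10, 200).round(2) + 0.01
        curve = km_estimate(t, np.ones_like(t))
        for q in (1.0, 5.0, 12.0):
            assert km_at(curve, q) == pytest.approx(np.mean(t > q))

    def test_matches_lifelines_under_censoring(self, rng):
        t = rng.exponential(10, 300) + 0.01
        e = rng.random(300) < 0.6
        kmf = KaplanMeierFitter().fit(t, e)
        curve = km_estimate(t, e)
        for q in (2.0, 8.0, 20.0):
            assert km_at(curve, q) == pytest.approx(
                float(kmf.predict(q)), abs=1e-10)

    def test_empty_and_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            km_estimate([], [])
        with pytest.raises(ValueError):
            km_estimate([0.0, 1.0], [1, 1])


class TestLogRank:
    def test_identical_groups_null(self):
        g = ([1, 2, 3, 4, 5], [1, 0, 1, 0, 1])
        res = logrank_test([g, g])
        assert res["chi2"] == pytest.approx(0.0, abs=1e-12)
        assert res["p"] == pytest.approx(1.0)

    def test_three_groups_df(self, rng):
        groups = [(rng.exponential(10, 30) + 0.1, rng.integers(0, 2, 30)) for _ in range(3)]
        assert logrank_test(groups)["df"] == 2

    def test_matches_lifelines_two_groups(self, rng):
        t1, t2 = rng.exponential(8, 80) + 0.1, rng.exponential(12, 70) + 0.1
        e1, e2 = rng.random(80) < 0.7, rng.random(70) < 0.7
        mine = logrank_test([(t1, e1), (t2, e2)])
        ref = ll_logrank(t1, t2, e1, e2)
        assert mine["chi2"] == pytest.approx(ref.test_statistic, rel=1e-6)
        assert mine["p"] == pytest.approx(ref.p_value, rel=1e-6)

    def test_permutation_null_distribution(self, rng):
        """The chi-square reference matches the label-permutation null."""
        t = rng.exponential(10, 60) + 0.1
        e = rng.random(60) < 0.7
        labels = np.arange(60) < 30
        obs = logrank_test([(t[labels], e[labels]), (t[~labels], e[~labels])])["chi2"]
        perm_stats = []
        for _ in range(500):
            lab = rng.permutation(labels)
            perm_stats.append(
                logrank_test([(t[lab], e[lab]), (t[~lab], e[~lab])])["chi2"])
        p_perm = np.mean(np.asarray(perm_stats) >= obs)
        from scipy import stats

        p_chi2 = stats.chi2.sf(obs, 1)
        assert abs(p_perm - p_chi2) < 0.08

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            logrank_test([([1, 2], [1, 1]), ([], [])])


class TestHarrellC:
    def test_constant_risk_is_half(self):
        assert harrell_c([1, 1, 1, 1], [1, 2, 3, 4], [1, 1, 1, 1]) == 0.5

    def test_perfect_ranking(self, rng):
        t = rng.exponential(5, 50) + 0.1
        assert harrell_c(-t, t, np.ones(50)) == 1.0

    def test_random_scores_near_half(self, rng):
        t = rng.exponential(5, 2000) + 0.1
        e = rng.random(2000) < 0.5
        c = harrell_c(rng.normal(size=2000), t, e)
        assert abs(c - 0.5) < 0.02

    def test_hand_enumerated_with_censoring(self):
        # pairs comparable under censoring, counted by hand:
        # times (2,4,6), events (1,1,0), risks (3,2,1):
        # (1,2): t1<t2, r1>r2 concordant; (1,3): t1<t3c, r1>r3 concordant;
        # (2,3): t2<t3c, r2>r3 concordant -> C = 3/3
        assert harrell_c([3, 2, 1], [2, 4, 6], [1, 1, 0]) == 1.0
        # flip one risk pair -> one discordant of three
        assert harrell_c([2, 3, 1], [2, 4, 6], [1, 1, 0]) == pytest.approx(2 / 3)

    def test_monotone_transform_invariance(self, rng):
        t = rng.exponential(5, 300) + 0.1
        e = rng.random(300) < 0.6
        r = rng.normal(size=300)
        assert harrell_c(r, t, e) == pytest.approx(harrell_c(np.exp(r), t, e))

    def test_no_comparable_pairs_missing(self):
        assert harrell_c([1, 2], [5, 6], [0, 0]) is None


class TestCindexDifference:
    def test_model_vs_itself(self, rng):
        t = rng.exponential(5, 200) + 0.1
        e = rng.random(200) < 0.6
        r = rng.normal(size=200)
        res = cindex_difference(r, r, t, e, n_boot=100, seed=1)
        assert res["delta"] == 0.0
        assert res["p"] == 1.0

    def test_null_added_covariate(self, rng):
        n = 1500
        x = rng.normal(size=n)
        t = rng.exponential(1.0 / np.exp(0.8 * x)) + 0.01
        e = np.ones(n, dtype=int)
        noise = rng.normal(size=n)
        res = cindex_difference(x, x + 0.01 * noise, t, e, n_boot=150, seed=2)
        assert abs(res["delta"]) < 0.01
        assert res["ci"][0] <= 0.0 <= res["ci"][1]

    def test_seeded_reproducibility(self, rng):
        t = rng.exponential(5, 150) + 0.1
        e = rng.random(150) < 0.6
        a, b = rng.normal(size=150), rng.normal(size=150)
        r1 = cindex_difference(a, b, t, e, n_boot=120, seed=9)
        r2 = cindex_difference(a, b, t, e, n_boot=120, seed=9)
        assert r1 == r2

    def test_low_n_boot_warns(self, rng):
        t = rng.exponential(5, 50) + 0.1
        with pytest.warns(UserWarning):
            cindex_difference(np.arange(50), np.arange(50), t, np.ones(50),
                              n_boot=50, seed=0)


class TestCox:
    def test_null_covariate(self, rng):
        import pandas as pd

        n = 800
        df = pd.DataFrame({"x": rng.normal(size=n)})
        t = rng.exponential(10, n) + 0.01
        fit = fit_cox(df, t, np.ones(n))
        assert abs(fit["log_hr"]["x"]) < 3 * fit["se"]["x"]

    def test_exponential_rate_ratio_oracle(self, rng):
        """Two-group exponential data: Cox log-HR approximates the closed
        form log((d1/T1)/(d0/T0)) of the exponential rate-ratio MLE."""
        import pandas as pd

        n = 4000
        x = (rng.random(n) < 0.5).astype(int)
        rate = 0.05 * np.exp(0.6 * x)
        t = rng.exponential(1 / rate)
        cens = np.full(n, 30.0)
        obs = np.minimum(t, cens)
        e = (t <= cens).astype(int)
        closed = math.log((e[x == 1].sum() / obs[x == 1].sum())
                          / (e[x == 0].sum() / obs[x == 0].sum()))
        fit = fit_cox(pd.DataFrame({"x": x}), obs, e)
        assert fit["log_hr"]["x"] == pytest.approx(closed, abs=0.05)

    def test_lrt_nested_fit(self, rng):
        import pandas as pd

        n = 2000
        x = rng.normal(size=n)
        z = rng.normal(size=n)
        t = rng.exponential(1 / (0.05 * np.exp(0.5 * x))) + 0.001
        e = np.ones(n, dtype=int)
        full = fit_cox(pd.DataFrame({"x": x, "z": z}), t, e)
        null = fit_cox(pd.DataFrame({"z": z}), t, e)
        res = likelihood_ratio_test(null, full, df=1)
        assert res["chi2"] > 0
        assert res["p"] < 1e-6
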