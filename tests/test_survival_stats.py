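"""Kaplan-Meier, logrank, IPCW-RMSE, c-index and bootstrap behaviour."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from aftsurv.survival_stats import (
    bootstrap_ci,
    harrell_c,
    ipcw_rmse,
    km_estimate,
    km_masses,
    km_survival_at,
    logrank_test,
)


class TestKaplanMeier:
    @pytest.mark.parametrize(
        "times, events, exp_times, exp_surv",
        [
            # hand product-limit: at t=2 risk set {2,2,4}, one death
            ([1, 2, 2, 4], [1, 0, 1, 1], [1, 2, 4], [3 / 4, 1 / 2, 0.0]),
            ([1, 2, 3], [1, 1, 1], [1, 2, 3], [2 / 3, 1 / 3, 0.0]),
        ],
    )
    def test_hand_examples(self, times, events, exp_times, exp_surv):
        km = km_estimate(times, events)
        np.testing.assert_allclose(km.times, exp_times)
        np.testing.assert_allclose(km.survival, exp_surv)

    def test_all_censored_is_flat_one(self):
        km = km_estimate([1.0, 2.0, 3.0], [0, 0, 0])
        assert km.times.size == 0
        assert km.survival_at(10.0) == 1.0

    def test_no_censoring_equals_empirical_survival(self, rng):
        t = rng.exponential(2.0, 200)
        km = km_estimate(t, np.ones_like(t, dtype=int))
        for q in (0.5, 1.0, 3.0):
            assert km.survival_at(q) == pytest.approx(np.mean(t > q))

    def test_survival_is_nonincreasing_and_starts_at_one(self, rng):
        t = rng.exponential(1.0, 100)
        d = (rng.random(100) < 0.7).astype(int)
        km = km_estimate(t, d)
        assert np.all(np.diff(km.survival) <= 1e-12)
        assert km.survival_before(km.times[0]) == 1.0

    def test_step_evaluation(self):
        km = km_estimate([1, 2, 2, 4], [1, 0, 1, 1])
        assert km_survival_at(km, 0.5) == (1.0, 0.0)
        assert km_survival_at(km, 2.0)[0] == pytest.approx(0.5)
        assert km_survival_at(km, 100.0)[0] == 0.0

    def test_greenwood_matches_lifelines(self, rng):
        lifelines = pytest.importorskip("lifelines")
        t = rng.exponential(2.0, 150)
        d = (rng.random(150) < 0.6).astype(int)
        km = km_estimate(t, d)
        kmf = lifelines.KaplanMeierFitter().fit(t, d)
        for q in (0.5, 1.5, 3.0):
            assert km.survival_at(q) == pytest.approx(
                float(kmf.predict(q)), abs=1e-10
            )
        # Greenwood SE against lifelines' variance estimate at event times
        ci = kmf.confidence_interval_survival_function_
        sf = kmf.survival_function_["KM_estimate"]
        # spot-check: lifelines' default CI uses the exp(-exp) transform, so
        # compare the variance via its internal Greenwood table instead
        var = (kmf._cumulative_sq_ * sf**2).dropna()
        for ti, sei in zip(km.times, km.greenwood_se):
            if ti in var.index and sf[ti] > 0:
                assert sei == pytest.approx(np.sqrt(var[ti]), rel=1e-6)

    def test_masses_sum_to_one_with_tail(self, rng):
        t = rng.exponential(1.0, 60)
        d = (rng.random(60) < 0.5).astype(int)
        _, masses, tail = km_masses(km_estimate(t, d))
        assert masses.sum() + tail == pytest.approx(1.0)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            km_estimate([], [])


def _brute_logrank(times, events, group):
    """Direct evaluation of the observed-minus-expected sums over all
    observed event times, with the hypergeometric variance."""
    times, events, group = map(np.asarray, (times, events, group))
    oe, var = 0.0, 0.0
    for f in np.unique(times[events == 1]):
        at_risk = times >= f
        n_f = at_risk.sum()
        n1 = (at_risk & (group == 1)).sum()
        d_f = ((times == f) & (events == 1)).sum()
        d1 = ((times == f) & (events == 1) & (group == 1)).sum()
        oe += d1 - d_f * n1 / n_f
        if n_f > 1:
            var += d_f * (n1 / n_f) * (1 - n1 / n_f) * (n_f - d_f) / (n_f - 1)
    return 0.0 if var == 0 else oe**2 / var


class TestLogrank:
    def test_identical_groups_give_zero(self):
        t = [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]
        d = [1, 1, 0, 1, 1, 0]
        g = [0, 0, 0, 1, 1, 1]
        res = logrank_test(t, d, g)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.pvalue == pytest.approx(1.0)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(20):
            n = 30
            t = rng.exponential(2.0, n)
            d = (rng.random(n) < 0.7).astype(int)
            g = (rng.random(n) < 0.5).astype(int)
            if g.min() == g.max() or d.sum() == 0:
                continue
            res = logrank_test(t, d, g)
            assert res.statistic == pytest.approx(_brute_logrank(t, d, g), rel=1e-10)

    def test_matches_lifelines(self, rng):
        lifelines = pytest.importorskip("lifelines")
        n = 80
        t = rng.exponential(2.0, n)
        t[:40] *= 1.8
        d = (rng.random(n) < 0.7).astype(int)
        g = np.r_[np.ones(40, int), np.zeros(40, int)]
        res = logrank_test(t, d, g)
        ll = lifelines.statistics.logrank_test(t[g == 1], t[g == 0],
                                               d[g == 1], d[g == 0])
        assert res.statistic == pytest.approx(ll.test_statistic, rel=1e-9)
        assert res.pvalue == pytest.approx(ll.p_value, rel=1e-9)

    def test_label_swap_invariance(self, rng):
        t = rng.exponential(2.0, 50)
        d = (rng.random(50) < 0.8).astype(int)
        g = (rng.random(50) < 0.4).astype(int)
        a = logrank_test(t, d, g)
        b = logrank_test(t, d, 1 - g)
        assert a.statistic == pytest.approx(b.statistic, rel=1e-12)
        # O1 - E1 = -(O2 - E2)
        np.testing.assert_allclose(
            a.observed - a.expected, -(a.observed - a.expected)[::-1], atol=1e-10
        )

    def test_no_events_gives_null_result(self):
        res = logrank_test([1, 2, 3, 4], [0, 0, 0, 0], [0, 0, 1, 1])
        assert (res.statistic, res.pvalue) == (0.0, 1.0)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            logrank_test([1, 2], [1, 1], [1, 1])


class TestIPCWRMSE:
    def test_no_censoring_equals_plain_rmse(self, rng):
        y = rng.exponential(3.0, 50)
        yhat = y * np.exp(rng.normal(0, 0.2, 50))
        d = np.ones(50, dtype=int)
        assert ipcw_rmse(y, d, yhat) == pytest.approx(
            np.sqrt(np.mean((y - yhat) ** 2)), rel=1e-12
        )

    def test_perfect_prediction_is_zero(self):
        y = np.array([1.0, 2.0, 3.0])
        assert ipcw_rmse(y, [1, 1, 1], y) == 0.0

    def test_hand_evaluated_mixed_censoring(self):
        # censoring KM: "events" at t=2 (risk 4) and t=4 (risk 2)
        # S^C = 3/4 on [2,4), 3/8 on [4,inf); left limits at y=1,3,5 are
        # 1, 3/4, 3/8
        y = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        d = np.array([1, 0, 1, 0, 1])
        yhat = np.full(5, 2.0)
        expected = np.sqrt((1 / 5) * (1 / 1 + 1 / (3 / 4) + 9 / (3 / 8)))
        assert ipcw_rmse(y, d, yhat) == pytest.approx(expected, rel=1e-12)

    def test_monotone_in_single_error(self, rng):
        y = rng.exponential(3.0, 30) + 0.1
        d = (rng.random(30) < 0.7).astype(int)
        d[0] = 1
        yhat = y.copy()
        vals = []
        for bump in (0.0, 0.5, 1.5):
            z = yhat.copy()
            z[0] = y[0] + bump
            vals.append(ipcw_rmse(y, d, z))
        assert vals[0] <= vals[1] <= vals[2]

    def test_all_censored_rejected(self):
        with pytest.raises(ValueError):
            ipcw_rmse([1, 2], [0, 0], [1, 1])


def _brute_c(times, events, preds):
    num = den = 0
    n = len(times)
    for i in range(n):
        for j in range(n):
            if i != j and events[i] == 1 and times[i] < times[j]:
                den += 1
                if preds[i] < preds[j]:
                    num += 1
    return num / den


class TestHarrellC:
    def test_perfect_and_reversed_order(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        d = np.ones(4, dtype=int)
        assert harrell_c(y, d, y) == 1.0
        assert harrell_c(y, d, -y) == 0.0

    def test_matches_pair_enumeration_oracle(self, rng):
        for _ in range(20):
            n = int(rng.integers(6, 11))
            y = rng.exponential(2.0, n)
            d = (rng.random(n) < 0.7).astype(int)
            d[0] = 1
            yhat = rng.exponential(2.0, n)
            assert harrell_c(y, d, yhat) == pytest.approx(_brute_c(y, d, yhat))

    def test_matches_lifelines_when_tie_free(self, rng):
        lifelines = pytest.importorskip("lifelines")
        n = 60
        y = rng.exponential(2.0, n)
        d = (rng.random(n) < 0.7).astype(int)
        d[:2] = 1
        yhat = rng.exponential(2.0, n)
        assert harrell_c(y, d, yhat) == pytest.approx(
            lifelines.utils.concordance_index(y, yhat, d)
        )

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(st.floats(min_value=0.1, max_value=5.0), st.floats(min_value=-3, max_value=3))
    def test_invariant_under_increasing_transform(self, scale, shift):
        rng = np.random.default_rng(4)
        y = rng.exponential(2.0, 25)
        d = (rng.random(25) < 0.8).astype(int)
        d[0] = 1
        yhat = rng.exponential(2.0, 25)
        base = harrell_c(y, d, yhat)
        assert harrell_c(y, d, scale * yhat + shift + np.exp(yhat) * 0) == base
        assert harrell_c(y, d, np.log(yhat) * scale + shift) == base

    def test_no_comparable_pairs_rejected(self):
        with pytest.raises(ValueError):
            harrell_c([2.0, 1.0], [1, 0], [1.0, 2.0])


class TestBootstrapCI:
    def test_constant_measure_zero_width(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        lo, hi = bootstrap_ci(lambda *a: 7.5, (y,), n_boot=50, seed=0)
        assert lo == hi == 7.5

    def test_seed_reproducibility_and_order(self, rng):
        y = rng.exponential(3.0, 40)
        d = np.ones(40, dtype=int)
        yhat = y * np.exp(rng.normal(0, 0.3, 40))
        a = bootstrap_ci(ipcw_rmse, (y, d, yhat), n_boot=200, seed=5)
        b = bootstrap_ci(ipcw_rmse, (y, d, yhat), n_boot=200, seed=5)
        assert a == b
        assert a[0] <= a[1]

    def test_coverage_for_known_truth(self):
        """Nested Monte-Carlo: percentile interval for the IPCW-RMSE covers
        the true RMSE ~95% of the time (bounded symmetric errors, ~25%
        censoring)."""
        truth = np.sqrt(4.0 / 3.0)  # sqrt E[U^2], U ~ Unif(-2, 2)
        R, B, n = 200, 200, 200
        cover = 0
        for r in range(R):
            rg = np.random.default_rng(3000 + r)
            y_true = 5.0 + rg.uniform(-2, 2, n)
            cens = rg.exponential(15.0, n)
            y = np.minimum(y_true, cens)
            d = (y_true <= cens).astype(int)
            lo, hi = bootstrap_ci(ipcw_rmse, (y, d, np.full(n, 5.0)), B, seed=rg)
            cover += lo <= truth <= hi
        assert 0.90 <= cover / R <= 1.0

    def test_mostly_undefined_measure_errors(self):
        def bad(*a):
            return np.nan

        with pytest.raises(RuntimeError):
            bootstrap_ci(bad, (np.arange(5.0),), n_boot=50, seed=0)
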