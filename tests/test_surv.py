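"""C-index, Kaplan–Meier, log-rank, time-dependent ROC, calibration, Cox."""

import numpy as np
import pandas as pd
import pytest

from pathomics import surv


def random_survival(rng, n, risk=None):
    risk = np.zeros(n) if risk is None else risk
    t_event = rng.exponential(1.0 / (0.02 * np.exp(risk)))
    t_cens = rng.exponential(60, n)
    return np.minimum(t_event, t_cens), t_event <= t_cens


def harrell_oracle(scores, times, events):
    num = den = 0.0
    n = len(scores)
    for i in range(n):
        for j in range(n):
            if times[i] < times[j] and events[i]:
                den += 1
                if scores[i] > scores[j]:
                    num += 1
                elif scores[i] == scores[j]:
                    num += 0.5
    return num / den


class TestCIndex:
    def test_full_concordance_and_discordance(self):
        c, _ = surv.c_index([3, 2, 1], [1, 2, 3], [1, 1, 1], n_bootstrap=0)
        assert c == 1.0
        c, _ = surv.c_index([1, 2, 3], [1, 2, 3], [1, 1, 1], n_bootstrap=0)
        assert c == 0.0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_pairwise_oracle_and_sksurv(self, seed):
        from sksurv.metrics import concordance_index_censored

        rng = np.random.default_rng(seed)
        times, events = random_survival(rng, 50)
        scores = rng.normal(size=50)
        c, _ = surv.c_index(scores, times, events, n_bootstrap=0)
        assert c == pytest.approx(harrell_oracle(scores, times, events), abs=1e-12)
        ref = concordance_index_censored(events, times, scores)[0]
        assert c == pytest.approx(ref, abs=1e-12)

    def test_score_negation_flips_c_index(self):
        rng = np.random.default_rng(1)
        times, events = random_survival(rng, 40)
        scores = rng.normal(size=40)  # continuous → no ties
        a, _ = surv.c_index(scores, times, events, n_bootstrap=0)
        b, _ = surv.c_index(-scores, times, events, n_bootstrap=0)
        assert a == pytest.approx(1.0 - b, abs=1e-12)

    def test_bootstrap_ci_brackets_estimate(self):
        rng = np.random.default_rng(2)
        times, events = random_survival(rng, 60, risk=rng.normal(size=60))
        scores = rng.normal(size=60)
        c, ci = surv.c_index(scores, times, events, n_bootstrap=200, seed=0)
        assert ci[0] <= c <= ci[1]

    def test_no_events_rejected(self):
        with pytest.raises(ValueError):
            surv.c_index([1, 2], [1, 2], [0, 0], n_bootstrap=0)


class TestKaplanMeier:
    def test_single_event_product_limit(self):
        km = surv.km_estimate([5, 8, 9, 10], [1, 0, 0, 0])
        assert km.survival_at(5) == pytest.approx(0.75)
        assert km.survival_at(4.9) == 1.0

    def test_no_censoring_equals_empirical_survival(self):
        rng = np.random.default_rng(3)
        times = rng.exponential(10, 25)
        km = surv.km_estimate(times, np.ones(25, bool))
        for t in np.quantile(times, [0.2, 0.5, 0.8]):
            assert km.survival_at(t) == pytest.approx((times > t).mean(), abs=1e-12)

    def test_survival_starts_at_one_and_never_increases(self):
        rng = np.random.default_rng(4)
        times, events = random_survival(rng, 30)
        km = surv.km_estimate(times, events)
        assert km.survival[0] <= 1.0 + 1e-12
        assert (np.diff(km.survival) <= 1e-12).all()


def logrank_oracle(ta, ea, tb, eb):
    """Hand-summed observed/expected computation."""
    t_all = np.concatenate([ta, tb])
    e_all = np.concatenate([ea, eb]).astype(bool)
    in_a = np.concatenate([np.ones(len(ta)), np.zeros(len(tb))]).astype(bool)
    O = E = V = 0.0
    for t in sorted(set(t_all[e_all])):
        n = (t_all >= t).sum()
        n1 = ((t_all >= t) & in_a).sum()
        d = ((t_all == t) & e_all).sum()
        d1 = ((t_all == t) & e_all & in_a).sum()
        O += d1
        E += d * n1 / n
        if n > 1:
            V += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return (O - E) ** 2 / V


class TestLogrank:
    def test_identical_groups_give_zero_statistic(self):
        t = np.array([2.0, 4.0, 6.0, 8.0])
        e = np.array([1, 1, 0, 1])
        chi2, p = surv.logrank(t, e, t, e)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_hand_summed_oracle_and_lifelines(self, seed):
        from lifelines.statistics import logrank_test

        rng = np.random.default_rng(seed)
        ta, ea = random_survival(rng, 10)
        tb, eb = random_survival(rng, 10, risk=np.ones(10))
        chi2, _ = surv.logrank(ta, ea, tb, eb)
        assert chi2 == pytest.approx(logrank_oracle(ta, ea, tb, eb), abs=1e-9)
        ref = logrank_test(ta, tb, ea, eb).test_statistic
        assert chi2 == pytest.approx(ref, abs=1e-9)

    def test_no_events_rejected(self):
        with pytest.raises(ValueError, match="events"):
            surv.logrank([1, 2], [0, 0], [3, 4], [0, 0])


class TestTdROC:
    def test_perfect_separation_gives_unit_auc(self):
        times = np.array([1, 2, 3, 10, 20, 30], float)
        events = np.array([1, 1, 1, 0, 0, 0], bool)
        scores = np.array([9, 8, 7, 1, 2, 3], float)
        out = surv.td_roc(scores, times, events, horizons=(5.0,))
        assert out[5.0] == 1.0

    def test_uninformative_scores_hover_near_half(self):
        rng = np.random.default_rng(5)
        times, events = random_survival(rng, 500)
        scores = rng.normal(size=500)
        out = surv.td_roc(scores, times, events, horizons=(24.0,))
        assert out[24.0] == pytest.approx(0.5, abs=0.06)

    def test_small_fixture_matches_exhaustive_pair_count(self):
        times = np.array([3, 10, 40, 50, 8, 60], float)
        events = np.array([1, 1, 0, 0, 0, 1], bool)
        scores = np.array([0.9, 0.3, 0.5, 0.2, 0.6, 0.1], float)
        t = 12.0
        cases = (times <= t) & events
        controls = times > t
        wins = 0.0
        total = 0
        for sc in scores[cases]:
            for sk in scores[controls]:
                total += 1
                wins += 1.0 if sc > sk else (0.5 if sc == sk else 0.0)
        out = surv.td_roc(scores, times, events, horizons=(t,))
        assert out[t] == pytest.approx(wins / total, abs=1e-12)

    def test_undefined_horizon_reported_absent(self):
        out = surv.td_roc([1, 2], [5, 6], [0, 0], horizons=(10.0,))
        assert out[10.0] is None


class TestCalibration:
    def test_self_consistent_risks_are_calibrated(self):
        rng = np.random.default_rng(6)
        horizon = 24.0
        p = rng.uniform(0.05, 0.95, 1000)
        hazard = -np.log(1 - p) / horizon
        times = rng.exponential(1.0 / hazard)
        events = np.ones(1000, bool)
        out = surv.calibration(p, times, events, horizon, n_bins=5)
        assert (out["predicted"] - out["observed"]).abs().max() < 0.1

    def test_constant_predictions_collapse_to_event_rate(self):
        rng = np.random.default_rng(7)
        times, events = random_survival(rng, 200)
        horizon = np.median(times)
        out = surv.calibration(np.full(200, 0.4), times, events, horizon, n_bins=4)
        assert len(out) == 1
        km = surv.km_estimate(times, events)
        assert out["observed"].iloc[0] == pytest.approx(1 - km.survival_at(horizon))


class TestCoxFit:
    def test_recovers_binary_covariate_effect(self):
        rng = np.random.default_rng(8)
        x = rng.integers(0, 2, 400).astype(float)
        times, events = random_survival(rng, 400, risk=1.0 * x)
        df = pd.DataFrame({"time": times, "event": events.astype(int), "x": x})
        fit = surv.cox_fit(df, "time", "event", ["x"])
        assert fit.summary.loc["x", "beta"] == pytest.approx(1.0, abs=0.25)
        assert fit.summary.loc["x", "ci_low"] <= fit.hr("x") <= fit.summary.loc["x", "ci_high"]

    def test_duplicated_covariate_rejected(self):
        rng = np.random.default_rng(9)
        times, events = random_survival(rng, 50)
        df = pd.DataFrame({"time": times, "event": events.astype(int),
                           "a": rng.normal(size=50)})
        df["b"] = df["a"]
        with pytest.raises(ValueError, match="collinear"):
            surv.cox_fit(df, "time", "event", ["a", "b"])

    def test_score_test_identity_with_logrank(self):
        # On tie-free data the Cox score test at β=0 for a binary covariate
        # equals the log-rank chi-square.
        rng = np.random.default_rng(10)
        x = rng.integers(0, 2, 30).astype(float)
        times = rng.exponential(20, 30) + rng.random(30) * 1e-6  # no ties
        events = rng.random(30) < 0.7
        if not events.any():
            events[0] = True
        exp0 = np.ones(30)
        U = I = 0.0
        for t in times[events]:
            at_risk = times >= t
            xbar = x[at_risk].mean()
            U += (x[times == t] - xbar).sum()
            p1 = x[at_risk].mean()
            I += p1 * (1 - p1)
        score_chi2 = U**2 / I
        chi2, _ = surv.logrank(times[x == 1], events[x == 1],
                               times[x == 0], events[x == 0])
        assert chi2 == pytest.approx(score_chi2, abs=1e-6)

    def test_univariate_screen_feeds_multivariate(self):
        rng = np.random.default_rng(11)
        n = 300
        good = rng.normal(size=n)
        junk = rng.normal(size=n)
        times, events = random_survival(rng, n, risk=0.8 * good)
        df = pd.DataFrame({"time": times, "event": events.astype(int),
                           "good": good, "junk": junk})
        table, multi = surv.uni_multi_cox(df, "time", "event", ["good", "junk"])
        assert table.loc["good", "p"] < 0.05
        assert multi is not None and "good" in multi.summary.index
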