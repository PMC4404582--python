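"""Survival statistics against hand-computed and brute-force oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from lifelines.statistics import logrank_test as lifelines_logrank

from sigscreen import (
    concordance_index,
    cox_multivariate,
    cox_univariate,
    km_curve,
    logrank_two_groups,
)


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------

def logrank_oracle(times, events, group1_mask):
    """Naive observed-vs-expected log-rank table, one event time at a time."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    g1 = np.asarray(group1_mask, bool)
    O_minus_E, V = 0.0, 0.0
    for t in sorted(set(times[events == 1])):
        at_risk = times >= t
        n, n1 = at_risk.sum(), (at_risk & g1).sum()
        d = ((times == t) & (events == 1)).sum()
        d1 = ((times == t) & (events == 1) & g1).sum()
        O_minus_E += d1 - d * n1 / n
        if n > 1:
            V += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    chi2 = O_minus_E**2 / V
    from scipy.stats import chi2 as chi2_dist

    return chi2, chi2_dist.sf(chi2, 1)


def cox_partial_loglik(beta, times, events, x):
    """Breslow partial log-likelihood for a single covariate (no tied events)."""
    ll = 0.0
    for i in np.where(np.asarray(events) == 1)[0]:
        risk = np.asarray(times) >= times[i]
        ll += beta * x[i] - np.log(np.sum(np.exp(beta * np.asarray(x)[risk])))
    return ll


def concordance_oracle(risk, times, events):
    """Exhaustive comparable-pair enumeration for Harrell's c."""
    num = den = 0.0
    n = len(times)
    for i, j in itertools.combinations(range(n), 2):
        lo, hi = (i, j) if times[i] < times[j] else (j, i)
        if times[i] == times[j]:
            if events[i] == events[j] == 1:
                num += 0.5 if risk[i] != risk[j] else 0.5
                den += 1
            continue
        if events[lo] != 1:
            continue  # earlier time censored: not comparable
        den += 1
        if risk[lo] > risk[hi]:
            num += 1
        elif risk[lo] == risk[hi]:
            num += 0.5
    return num / den


# ---------------------------------------------------------------------------
# Log-rank
# ---------------------------------------------------------------------------

class TestLogrank:
    def test_identical_groups_give_null_result(self):
        times = [1, 2, 3, 4, 1, 2, 3, 4]
        events = [1, 1, 0, 1, 1, 1, 0, 1]
        groups = [0, 0, 0, 0, 1, 1, 1, 1]
        chi2, p = logrank_two_groups(times, events, groups)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_matches_hand_table_and_lifelines_on_six_subjects(self):
        times = np.array([1.0, 2.0, 3.0, 10.0, 11.0, 12.0])
        events = np.ones(6, dtype=int)
        g1 = np.array([True, True, True, False, False, False])
        chi2, p = logrank_two_groups(times, events, g1)
        chi2_o, p_o = logrank_oracle(times, events, g1)
        assert chi2 == pytest.approx(chi2_o, abs=1e-10)
        assert p == pytest.approx(p_o, abs=1e-10)
        lr = lifelines_logrank(times[g1], times[~g1], events[g1], events[~g1])
        assert chi2 == pytest.approx(lr.test_statistic, abs=1e-8)
        assert p == pytest.approx(lr.p_value, abs=1e-8)

    def test_agrees_with_lifelines_on_random_data(self):
        rng = np.random.default_rng(42)
        for _ in range(10):
            n = 60
            times = rng.exponential(5, n).round(1) + 0.1  # ties included
            events = (rng.random(n) < 0.7).astype(int)
            g1 = rng.random(n) < 0.5
            if events[g1].sum() == 0 or events[~g1].sum() == 0:
                continue
            chi2, p = logrank_two_groups(times, events, g1)
            lr = lifelines_logrank(times[g1], times[~g1], events[g1], events[~g1])
            assert chi2 == pytest.approx(lr.test_statistic, rel=1e-9)
            assert p == pytest.approx(lr.p_value, rel=1e-9)

    def test_invariances(self):
        rng = np.random.default_rng(1)
        times = rng.exponential(5, 40)
        events = (rng.random(40) < 0.8).astype(int)
        g = rng.random(40) < 0.4
        chi2, p = logrank_two_groups(times, events, g)
        chi2_s, p_s = logrank_two_groups(times, events, ~g)
        assert (chi2, p) == (pytest.approx(chi2_s), pytest.approx(p_s))
        perm = rng.permutation(40)
        chi2_p, p_p = logrank_two_groups(times[perm], events[perm], g[perm])
        assert p == pytest.approx(p_p, abs=1e-12)

    def test_errors(self):
        with pytest.raises(ValueError, match="2 group"):
            logrank_two_groups([1, 2], [1, 1], [0, 0])
        with pytest.raises(ValueError, match="zero events"):
            logrank_two_groups([1, 2], [0, 0], [0, 1])


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------

class TestKM:
    def survival_at(self, curve, t):
        return float(curve[curve["time"] <= t]["survival"].iloc[-1])

    def test_all_censored_stays_at_one(self):
        curve = km_curve([1, 2, 3], [0, 0, 0])
        assert (curve["survival"] == 1.0).all()

    def test_two_events_no_censoring(self):
        curve = km_curve([1, 2], [1, 1])
        assert self.survival_at(curve, 1) == pytest.approx(0.5)
        assert self.survival_at(curve, 2) == pytest.approx(0.0)

    def test_censoring_product_limit(self):
        # subjects: censored at 1, events at 2 and 3
        # S(2) = 1 * (1 - 1/2) = 0.5 ; S(3) = 0.5 * (1 - 1/1) = 0
        curve = km_curve([1, 2, 3], [0, 1, 1])
        assert self.survival_at(curve, 2) == pytest.approx(0.5)
        assert self.survival_at(curve, 3) == pytest.approx(0.0)

    def test_starts_at_one(self):
        curve = km_curve([5.0], [1])
        assert curve.iloc[0]["time"] == 0.0
        assert curve.iloc[0]["survival"] == 1.0


# ---------------------------------------------------------------------------
# Cox models
# ---------------------------------------------------------------------------

class TestCox:
    def test_null_case_hr_near_one(self):
        rng = np.random.default_rng(3)
        times = np.tile(rng.exponential(5, 50), 2)
        events = np.tile((rng.random(50) < 0.8).astype(int), 2)
        groups = np.repeat([0, 1], 50)
        fit = cox_univariate(groups, times, events)
        assert fit.converged
        assert abs(fit.coef) < 0.05

    def test_six_subject_grid_search_oracle(self):
        times = np.array([1.0, 3.0, 5.0, 2.0, 4.0, 6.0])
        events = np.array([1, 1, 0, 1, 1, 1])
        x = np.array([1, 1, 1, 0, 0, 0], dtype=float)
        fit = cox_univariate(x, times, events)
        grid = np.arange(-3, 3, 1e-3)
        ll = [cox_partial_loglik(b, times, events, x) for b in grid]
        beta_star = grid[int(np.argmax(ll))]
        # no tied event times, so Efron == Breslow == the oracle likelihood
        assert fit.coef == pytest.approx(beta_star, abs=2e-3)

    def test_parameter_recovery_binary_exposure(self):
        hits = 0
        for s in range(20):
            rng = np.random.default_rng(100 + s)
            x = (rng.random(500) < 0.5).astype(float)
            t = rng.exponential(1.0 / (0.1 * np.exp(1.0 * x)))
            c = rng.uniform(0, 20, 500)
            times, events = np.minimum(t, c), (t <= c).astype(int)
            fit = cox_univariate(x, times, events)
            hits += abs(fit.coef - 1.0) <= 0.2
        assert hits >= 16  # 80% of replicates

    def test_multivariate_empty_covariates_equals_univariate(self):
        rng = np.random.default_rng(5)
        x = (rng.random(80) < 0.5).astype(float)
        times = rng.exponential(5, 80)
        events = (rng.random(80) < 0.8).astype(int)
        uni = cox_univariate(x, times, events)
        multi = cox_multivariate(x, pd.DataFrame(index=range(80)), times, events)
        assert multi.coef == pytest.approx(uni.coef, abs=1e-8)

    def test_multivariate_irrelevant_covariate_barely_moves_hr(self):
        devs = []
        for s in range(10):
            rng = np.random.default_rng(200 + s)
            x = (rng.random(500) < 0.5).astype(float)
            z = rng.normal(size=500)  # independent of x and outcome
            t = rng.exponential(1.0 / (0.1 * np.exp(0.8 * x)))
            c = rng.uniform(0, 20, 500)
            times, events = np.minimum(t, c), (t <= c).astype(int)
            uni = cox_univariate(x, times, events)
            multi = cox_multivariate(x, pd.DataFrame({"z": z}), times, events)
            devs.append(abs(multi.hr / uni.hr - 1))
        assert np.median(devs) < 0.10

    def test_adjusting_for_true_driver_attenuates_group_hr(self, signal_dataset):
        ds, truth = signal_dataset
        score = truth.program_score
        groups = (score > np.median(score)).astype(float)
        times = ds.clinical["time"].to_numpy()
        events = ds.clinical["event"].to_numpy()
        uni = cox_univariate(groups, times, events)
        adj = cox_multivariate(groups, pd.DataFrame({"score": score}), times, events)
        assert abs(adj.coef) < abs(uni.coef)

    def test_rank_deficiency_names_columns(self):
        rng = np.random.default_rng(9)
        x = (rng.random(40) < 0.5).astype(float)
        z = rng.normal(size=40)
        cov = pd.DataFrame({"z1": z, "z2": 2 * z})
        with pytest.raises(ValueError, match="collinear"):
            cox_multivariate(x, cov, rng.exponential(5, 40), np.ones(40, int))

    def test_separation_flagged_not_raised(self):
        # group 1 all fails before any group 0 subject: monotone likelihood
        times = np.array([1.0, 2.0, 3.0, 10.0, 11.0, 12.0])
        events = np.ones(6, int)
        x = np.array([1, 1, 1, 0, 0, 0], dtype=float)
        fit = cox_univariate(x, times, events)
        assert not fit.converged


# ---------------------------------------------------------------------------
# Concordance
# ---------------------------------------------------------------------------

class TestConcordance:
    def test_perfect_concordance(self):
        times = [1, 2, 3, 10, 11, 12]
        events = [1, 1, 1, 1, 1, 1]
        # distinct risk scores in the true failure order: every comparable
        # pair is concordant
        risk = [5, 4, 3, 2, 1, 0]
        assert concordance_index(risk, times, events) == pytest.approx(1.0)
        # a binary predictor cannot reach 1 under the Harrell tie rule:
        # within-group pairs count half, so the same data give (9 + 6/2)/15
        assert concordance_index([1, 1, 1, 0, 0, 0], times, events) == pytest.approx(0.8)

    def test_five_subject_brute_force(self):
        times = np.array([2.0, 5.0, 3.0, 8.0, 1.0])
        events = np.array([1, 0, 1, 1, 1])
        risk = np.array([0.9, 0.1, 0.5, 0.5, 0.7])
        c = concordance_index(risk, times, events)
        assert c == pytest.approx(concordance_oracle(risk, times, events), abs=1e-10)

    def test_random_risk_near_half(self):
        rng = np.random.default_rng(11)
        times = rng.exponential(5, 100)
        events = (rng.random(100) < 0.8).astype(int)
        cs = []
        for _ in range(100):
            cs.append(concordance_index(rng.random(100) < 0.5, times, events))
        assert np.mean(cs) == pytest.approx(0.5, abs=0.05)

    def test_complement_property_without_ties(self):
        rng = np.random.default_rng(12)
        times = rng.exponential(5, 50)
        events = (rng.random(50) < 0.8).astype(int)
        risk = rng.normal(size=50)
        c = concordance_index(risk, times, events)
        assert concordance_index(-risk, times, events) == pytest.approx(1 - c, abs=1e-10)
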