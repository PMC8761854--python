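"""AUC, random-forest outcome model, adjusted OR and relapse survival."""

import numpy as np
import pandas as pd
import pytest

from guildomics.prognosis import (
    auc,
    combined_marker_model,
    logistic_adjusted_or,
    relapse_survival,
    rf_outcome_model,
)
from guildomics.simulate import simulate_relapse_times


class TestAuc:
    def test_perfect_separation(self):
        assert auc([3, 4, 5], [0, 1, 2]) == 1.0

    def test_pairwise_enumeration_value(self):
        assert auc([0.9, 0.4], [0.5, 0.1]) == pytest.approx(0.75)

    def test_identical_multisets_half(self):
        assert auc([1, 2, 3], [1, 2, 3]) == pytest.approx(0.5)

    def test_empty_class_errors(self):
        with pytest.raises(ValueError):
            auc([], [1, 2])

    def test_matches_trapezoidal_roc_integral(self, rng):
        from sklearn.metrics import roc_auc_score

        for _ in range(100):
            n1, n0 = rng.integers(3, 20, size=2)
            pos = np.round(rng.normal(0.5, 1.0, n1), 1)  # induce ties
            neg = np.round(rng.normal(0.0, 1.0, n0), 1)
            y = np.r_[np.ones(n1), np.zeros(n0)]
            s = np.r_[pos, neg]
            assert auc(pos, neg) == pytest.approx(roc_auc_score(y, s), abs=1e-12)


def _features(rng, n=60, p=30, signal=0.0):
    x = pd.DataFrame(rng.normal(size=(n, p)),
                     index=[f"s{i}" for i in range(n)],
                     columns=[f"f{j}" for j in range(p)])
    logit = signal * x["f0"]
    y = pd.Series((rng.random(n) < 1 / (1 + np.exp(-logit))).astype(int),
                  index=x.index)
    if y.nunique() < 2:
        y.iloc[0] = 1 - y.iloc[0]
    return x, y


class TestRfModel:
    def test_pure_noise_auc_near_half(self, rng):
        aucs = []
        for seed in range(10):
            x, y = _features(rng, n=40, p=15)
            rep = rf_outcome_model(x, y, n_trees=100, n_repeats=2, n_boot=50,
                                   seed=seed, compute_importance=False)
            aucs.append(rep.auc)
        assert 0.35 <= np.mean(aucs) <= 0.65

    def test_signal_feature_found(self, rng):
        x, y = _features(rng, n=80, p=20, signal=3.0)
        rep = rf_outcome_model(x, y, n_trees=300, n_repeats=2, n_boot=100, seed=0)
        assert rep.auc > 0.7
        assert rep.importances.index[0] == "f0"
        assert rep.auc_ci[0] <= rep.auc <= rep.auc_ci[1]

    def test_determinism_under_fixed_seed(self, rng):
        x, y = _features(rng, n=40, p=10, signal=2.0)
        a = rf_outcome_model(x, y, n_trees=100, n_repeats=2, n_boot=50, seed=3)
        b = rf_outcome_model(x, y, n_trees=100, n_repeats=2, n_boot=50, seed=3)
        assert np.array_equal(a.scores, b.scores)
        assert a.auc == b.auc
        pd.testing.assert_series_equal(a.importances, b.importances)

    def test_single_class_errors(self, rng):
        x, _ = _features(rng, n=20, p=5)
        with pytest.raises(ValueError):
            rf_outcome_model(x, pd.Series(1, index=x.index), n_trees=50)

    def test_noise_importance_centered_at_zero(self, rng):
        vals = []
        for seed in range(5):
            x, y = _features(rng, n=40, p=10)
            rep = rf_outcome_model(x, y, n_trees=100, n_repeats=2, n_boot=20,
                                   seed=seed, top_k=None)
            vals.append(rep.importances.mean())
        assert abs(np.mean(vals)) < 0.02

    def test_default_cohort_recovery(self, default_cohort):
        """Planted prognostic marker ranks in the top 3 importances with
        held-out AUC >= 0.8 on the default synthetic cohort."""
        from guildomics.guilds import filter_otus

        c = default_cohort
        filt = filter_otus(c.counts)
        pats = c.clinical.patients().index
        rel = filt.relative_abundance().loc[pats]
        outcome = c.clinical.data.loc[pats, "outcome6m_poor"].astype(int)
        rep = rf_outcome_model(rel, outcome, n_trees=500, n_boot=200, seed=0)
        assert rep.auc >= 0.8
        top3 = list(rep.importances.index[:3])
        assert c.truth.prognostic_otus[0] in top3


class TestCombinedModel:
    def test_combined_panel_dominates_singletons(self, rng):
        n = 80
        idx = [f"s{i}" for i in range(n)]
        latent = rng.normal(size=n)
        y = pd.Series((rng.random(n) < 1 / (1 + np.exp(-2.5 * latent))).astype(int),
                      index=idx)
        def noisy():
            return pd.Series(latent + rng.normal(0, 1.0, n), index=idx)
        neos, otu = noisy(), noisy()
        serum = pd.concat([noisy(), noisy()], axis=1, keys=["k", "ch"])
        fecal = pd.concat([noisy(), noisy()], axis=1, keys=["lp", "lc"])
        rep = combined_marker_model(neos, otu, serum, fecal, y,
                                    n_trees=200, n_repeats=2, n_boot=50, seed=0)
        singles = []
        for s in (neos, otu):
            singles.append(auc(s[y == 1], s[y == 0]))
        assert rep.auc >= max(singles) - 0.02

    def test_constant_panel_errors(self):
        idx = [f"s{i}" for i in range(20)]
        const = pd.Series(1.0, index=idx)
        two = pd.concat([const, const], axis=1, keys=["a", "b"])
        y = pd.Series([0, 1] * 10, index=idx)
        with pytest.raises(ValueError):
            combined_marker_model(const, const, two, two, y, n_trees=10)

    def test_permuted_outcome_auc_half(self, rng):
        """Shuffling the outcome destroys the panel's discrimination; the
        held-out AUC averages to ~0.5 over repeated draws (a single n=60
        draw with strongly correlated panel features is noisy)."""
        aucs = []
        for seed in range(6):
            n = 60
            idx = [f"s{i}" for i in range(n)]
            latent = rng.normal(size=n)
            y = pd.Series(rng.permutation((latent > 0).astype(int)), index=idx)
            f = pd.Series(latent, index=idx)
            two = pd.concat([f + rng.normal(size=n), f + rng.normal(size=n)],
                            axis=1, keys=["a", "b"])
            rep = combined_marker_model(f, f, two, two, y, n_trees=100,
                                        n_repeats=2, n_boot=20, seed=seed)
            aucs.append(rep.auc)
        assert 0.35 <= np.mean(aucs) <= 0.65


class TestLogisticOr:
    def test_two_by_two_cross_product(self):
        # a=10 (marker1,poor), b=5 (marker1,good), c=2, d=8 -> OR = 8.0
        marker = pd.Series([1.0] * 15 + [0.0] * 10)
        y = pd.Series([1] * 10 + [0] * 5 + [1] * 2 + [0] * 8)
        or_, ci, p = logistic_adjusted_or(marker, y, dichotomize=False)
        assert or_ == pytest.approx(8.0, rel=1e-4)

    def test_random_tables_match_cross_product(self, rng):
        for _ in range(50):
            a, b, c, d = rng.integers(3, 20, size=4)
            marker = pd.Series([1.0] * (a + b) + [0.0] * (c + d))
            y = pd.Series([1] * a + [0] * b + [1] * c + [0] * d)
            or_, _, _ = logistic_adjusted_or(marker, y, dichotomize=False)
            assert or_ == pytest.approx(a * d / (b * c), rel=1e-3)

    def test_null_ci_coverage(self, rng):
        covered = 0
        n_rep = 200
        for _ in range(n_rep):
            marker = pd.Series(rng.normal(size=80))
            y = pd.Series(rng.integers(0, 2, size=80))
            if y.nunique() < 2:
                continue
            try:
                _, (lo, hi), _ = logistic_adjusted_or(marker, y)
            except ValueError:
                continue
            covered += lo <= 1.0 <= hi
        assert covered / n_rep >= 0.90

    def test_marker_recoding_inverts_or(self, rng):
        marker = pd.Series(rng.normal(size=60))
        y = pd.Series((marker + rng.normal(0, 1, 60) > 0).astype(int))
        bin_marker = (marker > marker.median()).astype(float)
        or1, _, _ = logistic_adjusted_or(bin_marker, y, dichotomize=False)
        or2, _, _ = logistic_adjusted_or(1 - bin_marker, y, dichotomize=False)
        assert or1 == pytest.approx(1 / or2, rel=1e-6)

    def test_separation_detected(self):
        marker = pd.Series([0.0] * 10 + [1.0] * 10)
        y = pd.Series([0] * 10 + [1] * 10)
        with pytest.raises(ValueError):
            logistic_adjusted_or(marker, y, dichotomize=False)


def _km_oracle(times, events):
    """Hand product-limit estimator."""
    order = np.argsort(times)
    t_sorted, e_sorted = np.asarray(times)[order], np.asarray(events)[order]
    surv = 1.0
    steps = {}
    at_risk = len(t_sorted)
    for t, e in zip(t_sorted, e_sorted):
        if e:
            surv *= (1 - 1 / at_risk)
            steps[t] = surv
        at_risk -= 1
    return steps


class TestSurvival:
    def test_identical_strata_null(self, rng):
        time = pd.Series(rng.exponential(10, size=40).clip(max=6.0))
        event = pd.Series((time < 6.0).astype(int))
        strata = pd.Series([0] * 20 + [1] * 20)
        rep = relapse_survival(time, event, strata)
        assert rep.hr_ci[0] <= 1.0 <= rep.hr_ci[1]
        assert rep.logrank_p > 0.01

    def test_large_sample_hr_recovery(self):
        """Cox log-HR within 10% of log 2.7 at n=2000 per group."""
        rng = np.random.default_rng(11)
        low = np.r_[np.ones(2000), np.zeros(2000)].astype(bool)
        time, event = simulate_relapse_times(low, hr=2.7, base_rate=0.05,
                                             followup=6.0, rng=rng)
        rep = relapse_survival(pd.Series(time), pd.Series(event),
                               pd.Series(low.astype(int)))
        assert rep.log_hr == pytest.approx(np.log(2.7), rel=0.10)
        assert rep.hr_ci[0] <= 2.7 <= rep.hr_ci[1]

    def test_small_worked_example_km_and_logrank(self):
        """KM steps match hand product-limit arithmetic on <= 8 subjects and
        the log-rank agrees with an observed-minus-expected oracle."""
        times = [1.0, 2.0, 3.0, 4.0, 2.5, 5.0, 6.0, 6.0]
        events = [1, 1, 0, 1, 1, 1, 0, 0]
        strata = [0, 0, 0, 0, 1, 1, 1, 1]
        rep = relapse_survival(pd.Series(times), pd.Series(events),
                               pd.Series(strata))
        for lev in (0, 1):
            idx = [i for i, s in enumerate(strata) if s == lev]
            oracle = _km_oracle([times[i] for i in idx], [events[i] for i in idx])
            curve = rep.km_curves[lev].set_index("time")["survival"]
            for t, s in oracle.items():
                assert curve.loc[t] == pytest.approx(s, abs=1e-9)
        # independent log-rank oracle via lifelines' chi2 on the same data is
        # the implementation itself; instead verify O-E arithmetic by hand
        from guildomics.prognosis import relapse_survival as _  # noqa: F401
        import itertools
        # observed events per group
        obs1 = sum(e for e, s in zip(events, strata) if s == 1)
        # expected events in group 1 summed over event times
        expected1 = 0.0
        var = 0.0
        for t in sorted({t for t, e in zip(times, events) if e}):
            d = sum(1 for tt, e in zip(times, events) if e and tt == t)
            n_at = sum(1 for tt in times if tt >= t)
            n1_at = sum(1 for tt, s in zip(times, strata) if tt >= t and s == 1)
            expected1 += d * n1_at / n_at
            if n_at > 1:
                var += d * (n1_at / n_at) * (1 - n1_at / n_at) * (n_at - d) / (n_at - 1)
        chi2 = (obs1 - expected1) ** 2 / var
        assert rep.logrank_stat == pytest.approx(chi2, abs=1e-6)

    def test_zero_events_flagged(self):
        time = pd.Series([6.0] * 10)
        event = pd.Series([0] * 10)
        strata = pd.Series([0] * 5 + [1] * 5)
        rep = relapse_survival(time, event, strata)
        assert np.isnan(rep.logrank_p) and np.isnan(rep.hr)
        assert rep.n_events == 0

    def test_at_risk_counts(self):
        time = pd.Series([1.5, 3.5, 6.0, 6.0])
        event = pd.Series([1, 1, 0, 0])
        strata = pd.Series([0, 0, 1, 1])
        rep = relapse_survival(time, event, strata)
        assert rep.at_risk.loc[0, 0] == 2
        assert rep.at_risk.loc[0, 2] == 1
        assert rep.at_risk.loc[1, 6] == 2

    def test_cox_single_covariate_matches_rate_ratio(self, rng):
        """With exponential hazards and no censoring the Cox log-HR
        approximates the log event-rate ratio."""
        n = 1500
        low = np.r_[np.ones(n), np.zeros(n)].astype(bool)
        time, event = simulate_relapse_times(low, hr=2.0, base_rate=0.4,
                                             followup=100.0, rng=rng)
        rep = relapse_survival(pd.Series(time), pd.Series(event),
                               pd.Series(low.astype(int)), followup_months=100)
        rate_ratio = (event[low].sum() / time[low].sum()) / (
            event[~low].sum() / time[~low].sum())
        assert rep.log_hr == pytest.approx(np.log(rate_ratio), abs=0.1)
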