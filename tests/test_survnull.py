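import numpy as np
import pandas as pd
import pytest

from _oracles import brute_force_null_values, brute_force_p, null_atoms, tv_distance
from hotspotsurv.survnull import (
    SurvivalSample,
    asymptotic_p,
    cox_fit,
    empirical_p,
    exact_null,
    km_estimate,
    logrank_scores,
    logrank_statistic,
    logrank_test,
)
from hotspotsurv.synthetic_data import simulate_survival_sample


def sample_of(times, events, minority_idx):
    times = np.asarray(times, float)
    g = np.zeros(len(times), bool)
    g[list(minority_idx)] = True
    return SurvivalSample(times, np.asarray(events, bool), g)


class TestLogRankStatistic:
    def test_two_patient_hand_value(self):
        # single informative event time: L = 1 - 1/2
        L, V = logrank_statistic(sample_of([1, 2], [True, True], [0]))
        assert L == pytest.approx(0.5)
        assert V == pytest.approx(0.25)

    def test_all_censored_is_zero(self):
        L, V = logrank_statistic(sample_of([1, 2, 3], [False] * 3, [0]))
        assert (L, V) == (0.0, 0.0)

    def test_label_swap_negates_L(self, rng):
        s = simulate_survival_sample(rng, 40, 10, censoring_fraction=0.3)
        L, V = logrank_statistic(s)
        L2, V2 = logrank_statistic(s.swapped())
        assert L2 == pytest.approx(-L)
        assert V2 == pytest.approx(V)

    def test_matches_lifelines(self, rng):
        from lifelines.statistics import logrank_test as ll_logrank

        s = simulate_survival_sample(rng, 120, 40, censoring_fraction=0.25, hazard_ratio=1.8)
        L, V = logrank_statistic(s)
        res = ll_logrank(
            s.times[s.group], s.times[~s.group],
            event_observed_A=s.events[s.group], event_observed_B=s.events[~s.group],
        )
        assert L * L / V == pytest.approx(res.test_statistic, rel=1e-9)
        assert asymptotic_p(L, V) == pytest.approx(res.p_value, rel=1e-9)

    @pytest.mark.parametrize("seed", range(4))
    def test_score_linearization_identity(self, seed):
        # the minority-group score sum must equal L for any assignment,
        # and the scores sum to zero over the cohort
        rng = np.random.default_rng(seed)
        s = simulate_survival_sample(rng, 25, 7, censoring_fraction=0.4)
        w = logrank_scores(s.times, s.events)
        L, _ = logrank_statistic(s)
        assert w.sum() == pytest.approx(0.0, abs=1e-10)
        assert w[s.group].sum() == pytest.approx(L, abs=1e-10)


class TestAsymptoticP:
    def test_zero_statistic(self):
        assert asymptotic_p(0.0, 3.0) == 1.0

    def test_chi2_quantile(self):
        assert asymptotic_p(np.sqrt(3.841), 1.0) == pytest.approx(0.05, abs=1e-3)

    def test_zero_variance(self):
        assert asymptotic_p(1.0, 0.0) == 1.0


class TestExactNullEnumeration:
    def test_singleton_minority_support(self, rng):
        # n=5, all events at distinct times, n1=1: exactly 5 equiprobable points
        s = sample_of([1, 2, 3, 4, 5], [True] * 5, [0])
        null = exact_null(s, seed=0)
        assert null.mode == "exact-enumeration"
        assert len(null.support) == 5
        assert np.allclose(null.weights, 0.2)
        assert np.allclose(brute_force_null_values(s), np.sort(null_atoms(null)[0]))

    def test_matches_bruteforce_small_instances(self):
        rng = np.random.default_rng(99)
        for _ in range(5):
            n = int(rng.integers(5, 13))
            n1 = int(rng.integers(1, min(4, n - 1) + 1))
            s = simulate_survival_sample(rng, n, n1, censoring_fraction=0.3)
            null = exact_null(s, seed=1)
            vals, wts = null_atoms(null)
            oracle = brute_force_null_values(s)
            assert tv_distance(vals, wts, oracle, np.full(len(oracle), 1 / len(oracle))) < 1e-12

    def test_complement_group_negates_distribution(self, rng):
        s = simulate_survival_sample(rng, 9, 1, censoring_fraction=0.2)
        flipped = SurvivalSample(s.times, s.events, ~s.group)
        a = exact_null(s, seed=0)
        b = exact_null(flipped, seed=0)
        assert np.allclose(np.sort(null_atoms(a)[0]), -np.sort(null_atoms(b)[0])[::-1], atol=1e-10)

    def test_invalid_group_sizes_raise(self):
        s = sample_of([1, 2, 3], [True] * 3, [])
        with pytest.raises(ValueError):
            exact_null(s, seed=0)

    def test_weights_sum_to_one(self, rng):
        s = simulate_survival_sample(rng, 10, 3, censoring_fraction=0.3)
        null = exact_null(s, seed=0)
        assert null.weights.sum() == pytest.approx(1.0, abs=1e-9)
        assert sum(st.weight for st in null.strata) == pytest.approx(1.0, abs=1e-9)


class TestStratifiedSampling:
    def test_hybrid_matches_enumeration_closely(self, rng):
        s = simulate_survival_sample(rng, 12, 3, censoring_fraction=0.3)
        exact = exact_null(s, seed=0)
        hybrid = exact_null(s, seed=3, enum_limit=1, n_perm_per_stratum=10_000)
        assert hybrid.mode == "stratified-sampling"
        assert tv_distance(*null_atoms(hybrid), *null_atoms(exact)) < 0.02

    def test_pure_sampling_tv_decreases(self, rng):
        s = simulate_survival_sample(rng, 12, 3, censoring_fraction=0.3)
        exact = exact_null(s, seed=0)
        tvs = []
        for m in (100, 1000, 10000):
            samp = exact_null(s, seed=11, enum_limit=1, n_perm_per_stratum=m,
                              stratum_enum_limit=0)
            tvs.append(tv_distance(*null_atoms(samp), *null_atoms(exact)))
        assert tvs[0] > tvs[1] > tvs[2]

    def test_stratum_weights_are_hypergeometric(self, rng):
        from scipy import stats

        s = simulate_survival_sample(rng, 40, 5, censoring_fraction=0.3)
        null = exact_null(s, seed=2, enum_limit=10, n_perm_per_stratum=200)
        for stratum in null.strata:
            expected = stats.hypergeom.pmf(stratum.k, s.n, s.d, s.n1)
            assert stratum.weight == pytest.approx(expected, rel=1e-9)

    def test_reproducible_given_seed(self, rng):
        s = simulate_survival_sample(rng, 50, 4, censoring_fraction=0.3)
        a = exact_null(s, seed=7, enum_limit=10, n_perm_per_stratum=300)
        b = exact_null(s, seed=7, enum_limit=10, n_perm_per_stratum=300)
        for sa, sb in zip(a.strata, b.strata):
            assert np.array_equal(sa.values, sb.values)


class TestEmpiricalP:
    def test_extreme_of_five_is_point_four(self):
        # the most extreme of 5 equiprobable values: p = 2 * (1/5)
        s = sample_of([1, 2, 3, 4, 5], [True] * 5, [0])
        null = exact_null(s, seed=0)
        assert empirical_p(null, null.support[0]) == pytest.approx(0.4)
        assert empirical_p(null, null.support[-1]) == pytest.approx(0.4)

    def test_median_value_capped_at_one(self):
        s = sample_of([1, 2, 3, 4, 5], [True] * 5, [0])
        null = exact_null(s, seed=0)
        assert empirical_p(null, float(np.median(null.support))) == 1.0

    def test_beyond_all_support(self):
        s = sample_of([1, 2, 3, 4, 5], [True] * 5, [0])
        null = exact_null(s, seed=0)
        assert empirical_p(null, null.support[-1] + 10.0) == pytest.approx(0.0, abs=1e-12)

    def test_matches_bruteforce_oracle(self, rng):
        for _ in range(5):
            s = simulate_survival_sample(rng, 10, 2, censoring_fraction=0.3)
            null = exact_null(s, seed=0)
            L, _ = logrank_statistic(s)
            assert empirical_p(null, L) == pytest.approx(
                brute_force_p(brute_force_null_values(s), L), abs=1e-12
            )

    def test_invariant_under_label_swap(self, rng):
        for _ in range(3):
            s = simulate_survival_sample(rng, 11, 3, censoring_fraction=0.2)
            L, _ = logrank_statistic(s)
            Ls, _ = logrank_statistic(s.swapped())
            p1 = empirical_p(exact_null(s, seed=0), L)
            p2 = empirical_p(exact_null(s.swapped(), seed=0), Ls)
            assert p1 == pytest.approx(p2, abs=1e-12)


class TestLogRankTestWrapper:
    def test_bundles_both_pvalues(self, rng):
        s = simulate_survival_sample(rng, 30, 5, censoring_fraction=0.3)
        null = exact_null(s, seed=0)
        res = logrank_test(s, null)
        assert res.p_asymptotic == asymptotic_p(res.L, res.V)
        assert res.p_empirical == empirical_p(null, res.L)


class TestCoxFit:
    def test_matches_lifelines_breslow(self, rng):
        from lifelines import CoxPHFitter

        s = simulate_survival_sample(rng, 250, 70, censoring_fraction=0.3, hazard_ratio=2.0)
        ours = cox_fit(s)
        df = pd.DataFrame({"t": s.times, "e": s.events.astype(int), "x": s.group.astype(int)})
        ref = CoxPHFitter().fit(df, "t", "e")
        assert ours.log_hr == pytest.approx(float(ref.params_["x"]), abs=1e-3)
        assert ours.se == pytest.approx(float(ref.standard_errors_["x"]), abs=1e-3)
        assert ours.p_cox == pytest.approx(float(ref.summary.loc["x", "p"]), rel=1e-2)

    def test_null_data_recovers_unit_hazard(self):
        rng = np.random.default_rng(5)
        s = simulate_survival_sample(rng, 1000, 500, censoring_fraction=0.2, hazard_ratio=1.0)
        res = cox_fit(s)
        assert res.degenerate == "none"
        assert abs(res.log_hr) < 0.2

    def test_minority_without_events_flags_low_risk(self):
        s = sample_of([5, 6, 1, 2, 3], [False, False, True, True, True], [0, 1])
        res = cox_fit(s)
        assert res.degenerate == "no_events_in_group"
        assert res.hr_label == "<1"
        assert res.hr is None

    def test_majority_without_events_flags_high_risk(self):
        s = sample_of([1, 2, 5, 6, 7], [True, True, False, False, False], [0, 1])
        res = cox_fit(s)
        assert res.degenerate == "no_events_in_group"
        assert res.hr_label == ">1"

    def test_no_events_at_all(self):
        s = sample_of([1, 2, 3], [False] * 3, [0])
        assert cox_fit(s).degenerate == "no_events"

    def test_temporal_separation_reports_direction_only(self):
        # every minority event precedes every comparison event: monotone
        # partial likelihood, hazard ratio diverges, only the sign is real
        times = [1, 2, 3, 10, 11, 12, 13]
        events = [True] * 7
        s = sample_of(times, events, [0, 1, 2])
        res = cox_fit(s)
        assert res.degenerate == "nonconvergence"
        assert res.hr_label == ">1"
        assert res.hr is None


class TestKaplanMeier:
    def test_two_event_hand_curve(self):
        km = km_estimate([1, 2], [True, True])
        # S: 1 -> 0.5 after t=1 -> 0 after t=2; median is the first t with S <= 0.5
        lookup = dict(zip(km.times, km.survival))
        assert lookup[1.0] == pytest.approx(0.5)
        assert lookup[2.0] == pytest.approx(0.0)
        assert km.median_survival == 1.0

    def test_all_censored_flat_curve(self):
        km = km_estimate([3, 4, 5], [False] * 3)
        assert np.all(km.survival == 1.0)
        assert km.median_survival is None

    def test_single_event(self):
        km = km_estimate([5], [True])
        assert km.median_survival == 5.0
        assert km.survival[-1] == pytest.approx(0.0)

    def test_survival_is_monotone_from_one(self, rng):
        s = simulate_survival_sample(rng, 60, 10, censoring_fraction=0.4)
        km = km_estimate(s.times, s.events)
        assert km.survival[0] == 1.0
        assert np.all(np.diff(km.survival) <= 1e-12)
        assert np.all((km.survival >= 0) & (km.survival <= 1))
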