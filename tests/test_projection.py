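"""Leslie assembly, growth rate, R0/GenT, stage collapse, Monte Carlo."""

import numpy as np
import pytest

from bearvitals import datasets
from bearvitals.bootstrap import BootstrapDistribution
from bearvitals.projection import (N_AGE_CLASSES, SurvivorshipSchedule,
                                   VitalRateSet, build_leslie,
                                   euler_lotka_rate, extract_vital_rates,
                                   generation_time, growth_rate,
                                   monte_carlo_projection,
                                   net_reproductive_rate,
                                   stable_age_distribution,
                                   stable_stage_distribution,
                                   stage_transition_rate, survivorship)


def _random_rates(rng):
    return VitalRateSet(*rng.uniform(0.3, 1.0, 4), rng.uniform(0.05, 0.5))


class TestAssembly:
    def test_structure(self):
        v = datasets.vital_rates("MM")
        L = build_leslie(v)
        assert L.shape == (25, 25)
        sub = L[np.arange(1, 25), np.arange(24)]
        assert set(np.round(sub, 2)) == {0.85, 1.0}
        assert np.count_nonzero(L[0]) == 19
        assert np.allclose(L[0, 6:25], 0.23)

    def test_round_trip(self):
        v = datasets.vital_rates("NSN")
        assert extract_vital_rates(build_leslie(v)) == v

    def test_prebreeding_discounts_fecundity(self):
        v = datasets.vital_rates("NSN")
        L = build_leslie(v, convention="prebreeding")
        assert np.allclose(L[0, 6:25], 0.33 * 0.19)


class TestGrowthRate:
    @pytest.mark.parametrize("pop,expected", [("MM", 1.09), ("NSN", 0.84)])
    def test_published_lambda(self, pop, expected):
        lam = growth_rate(build_leslie(datasets.vital_rates(pop)))
        assert lam == pytest.approx(expected, abs=0.02)

    def test_eigenvalue_equals_euler_lotka_root(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            L = build_leslie(_random_rates(rng))
            assert growth_rate(L) == pytest.approx(euler_lotka_rate(L),
                                                   abs=1e-6)

    def test_lambda_monotone_in_vital_rates(self):
        base = dict(s_cub=0.7, s_yearling=0.8, s_subadult=0.85, s_adult=0.9,
                    m_adult=0.2)
        lam0 = growth_rate(build_leslie(VitalRateSet(**base)))
        for key in base:
            bumped = dict(base)
            bumped[key] = min(1.0, base[key] + 0.05) if key != "m_adult" \
                else base[key] + 0.05
            assert growth_rate(build_leslie(VitalRateSet(**bumped))) > lam0


class TestR0AndGenerationTime:
    def test_zero_fecundity_zero_r0(self):
        v = VitalRateSet(0.8, 0.8, 0.8, 0.8, 0.0)
        assert net_reproductive_rate(build_leslie(v)) == 0.0

    def test_hand_computed_r0(self):
        # survivorship (1, .5, .25, 0, ...) with unit fecundity at ages 1-2
        L = np.zeros((25, 25))
        L[1, 0] = 0.5
        L[2, 1] = 0.5
        L[0, 1] = L[0, 2] = 1.0
        assert net_reproductive_rate(L) == pytest.approx(0.75)

    def test_lambda_one_iff_r0_one(self):
        # all survival 1: R0 = 19 m, so m = 1/19 pins lambda at 1
        v = VitalRateSet(1.0, 1.0, 1.0, 1.0, 1 / 19)
        L = build_leslie(v)
        assert net_reproductive_rate(L) == pytest.approx(1.0)
        assert growth_rate(L) == pytest.approx(1.0, abs=1e-9)
        # the limit branch returns the mean age of offspring production
        t = generation_time(L)
        assert 7 < t < 26 and np.isfinite(t)

    def test_sign_consistency(self):
        rng = np.random.default_rng(1)
        for _ in range(25):
            L = build_leslie(_random_rates(rng))
            assert np.sign(growth_rate(L) - 1) == \
                np.sign(net_reproductive_rate(L) - 1)


class TestStageCollapse:
    def test_single_age_stage_rate_is_one(self):
        sched = SurvivorshipSchedule(survivorship(
            build_leslie(datasets.vital_rates("MM"))), 1.09)
        assert stage_transition_rate(3, 4, sched) == pytest.approx(1.0)

    def test_uniform_case(self):
        # lambda = 1 and constant survivorship across a width-w stage -> 1/w
        l = np.ones(N_AGE_CLASSES)
        sched = SurvivorshipSchedule(l, 1.0)
        assert stage_transition_rate(2, 6, sched) == pytest.approx(0.25)

    def test_stage_model_matches_aggregated_eigenvector(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            v = _random_rates(rng)
            stage, agg = stable_stage_distribution(v)
            assert np.max(np.abs(stage - agg)) < 1e-6

    def test_growing_population_is_younger(self):
        w_mm = stable_age_distribution(build_leslie(datasets.vital_rates("MM")))
        w_nsn = stable_age_distribution(build_leslie(datasets.vital_rates("NSN")))
        assert w_mm[1:6].sum() > w_nsn[1:6].sum()

    def test_zero_survivorship_stage_rejected(self):
        l = np.zeros(N_AGE_CLASSES)
        l[0] = 1.0
        with pytest.raises(ValueError, match="survivorship"):
            stage_transition_rate(2, 6, SurvivorshipSchedule(l, 1.0))


class TestMonteCarlo:
    def _degenerate(self, pop):
        v = datasets.vital_rates(pop)
        return {k: getattr(v, k) for k in
                ("s_cub", "s_yearling", "s_subadult", "s_adult", "m_adult")}

    def test_degenerate_distributions_recover_point_lambda(self):
        dists = self._degenerate("MM")
        summary = monte_carlo_projection(dists, n_iter=50, seed=0)
        point = growth_rate(build_leslie(datasets.vital_rates("MM")))
        assert summary.lam == pytest.approx(point)
        assert summary.lam_ci[0] == pytest.approx(summary.lam_ci[1])

    def test_jensen_direction_with_skewed_cub_survival(self):
        # a left-skewed cub-survival distribution pulls mean lambda below
        # the lambda of the mean rates (concavity of lambda in S_cub here)
        rng = np.random.default_rng(9)
        reps = np.clip(rng.beta(1.2, 2.4, size=2000), 0, 1)  # mean ~0.33
        dists = self._degenerate("NSN")
        dists["s_cub"] = BootstrapDistribution.from_replicates(
            "s_cub", float(reps.mean()), reps)
        summary = monte_carlo_projection(dists, n_iter=800, seed=2)
        v = datasets.vital_rates("NSN")
        lam_at_mean = growth_rate(build_leslie(VitalRateSet(
            float(reps.mean()), v.s_yearling, v.s_subadult, v.s_adult,
            v.m_adult)))
        assert summary.lam < lam_at_mean

    def test_missing_rate_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            monte_carlo_projection({"s_cub": 0.8}, n_iter=5, seed=0)
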