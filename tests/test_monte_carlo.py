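"""Sampling primitives and the Monte Carlo dose simulation."""

import itertools

import numpy as np
import pytest

from mesodose.add_models import add_method1, add_method2, add_method3
from mesodose.domain_types import (
    BodyWeightTable,
    ConfigurationError,
    MesoActivity,
    Season,
    WeightedBodyWeight,
)
from mesodose.monte_carlo import (
    SimulationConfig,
    pools_from_cohort,
    run_simulation,
    sample_body_weight,
    sample_exposure_factor,
    sample_task_rate,
)

A = MesoActivity


def weighted(*pairs):
    return BodyWeightTable(
        mode="weighted_sample",
        samples=tuple(WeightedBodyWeight(w, p) for w, p in pairs),
    )


class TestSampleBodyWeight:
    def test_single_entry_is_deterministic(self):
        rng = np.random.default_rng(0)
        draws = sample_body_weight(weighted((70.0, 1.0)), rng, size=1000)
        assert np.all(draws == 70.0)

    def test_frequencies_follow_population_weights(self):
        rng = np.random.default_rng(1)
        draws = sample_body_weight(weighted((60.0, 1.0), (90.0, 3.0)), rng, size=100_000)
        assert np.mean(draws == 90.0) == pytest.approx(0.75, abs=0.01)

    def test_sample_mean_matches_weighted_mean(self):
        table = weighted((55.0, 2.0), (72.0, 5.0), (99.0, 1.0), (120.0, 0.5))
        values = np.array([s.weight_kg for s in table.samples])
        w = np.array([s.population_weight for s in table.samples])
        expected = np.average(values, weights=w)
        rng = np.random.default_rng(2)
        draws = sample_body_weight(table, rng, size=100_000)
        se = draws.std() / np.sqrt(draws.size)
        assert abs(draws.mean() - expected) < 3 * se

    def test_empty_table_is_a_configuration_error(self):
        with pytest.raises(ConfigurationError):
            sample_body_weight(weighted(), np.random.default_rng(0))


class TestSampleExposureFactor:
    def test_singleton_pool(self):
        rng = np.random.default_rng(0)
        assert np.all(sample_exposure_factor([7.5], rng, size=100) == 7.5)

    def test_two_value_pool_mean(self):
        rng = np.random.default_rng(3)
        draws = sample_exposure_factor([0.0, 10.0], rng, size=100_000)
        se = 5.0 / np.sqrt(draws.size)  # sd of {0,10} uniform = 5
        assert abs(draws.mean() - 5.0) < 3 * se

    def test_distinct_values_are_equally_likely(self):
        pool = [1.0, 2.0, 3.0, 4.0, 5.0]
        rng = np.random.default_rng(4)
        draws = sample_exposure_factor(pool, rng, size=100_000)
        p = 1 / len(pool)
        se = np.sqrt(p * (1 - p) / draws.size)
        for v in pool:
            assert abs(np.mean(draws == v) - p) < 3 * se

    def test_empty_pool_errors(self):
        with pytest.raises(ConfigurationError):
            sample_exposure_factor([], np.random.default_rng(0))


class TestSampleTaskRate:
    def test_doubled_task_draws_stay_in_published_band(self):
        rng = np.random.default_rng(5)
        draws = sample_task_rate(45.25, 2.0, 0.2, rng, size=100_000)
        assert draws.min() >= 45.25 * 1.8
        assert draws.max() <= 45.25 * 2.2

    def test_zero_halfwidth_is_deterministic(self):
        rng = np.random.default_rng(6)
        draws = sample_task_rate(45.25, 0.5, 0.0, rng, size=100)
        assert np.all(draws == 22.625)

    def test_mean_converges_to_midpoint(self):
        rng = np.random.default_rng(7)
        draws = sample_task_rate(45.25, 0.5, 0.2, rng, size=100_000)
        # sd of U(0.3, 0.7) x 45.25 = 45.25 x 0.4/sqrt(12)
        se = 45.25 * 0.4 / np.sqrt(12) / np.sqrt(draws.size)
        assert abs(draws.mean() - 22.625) < 3 * se

    def test_halfwidth_reaching_zero_multiplier_errors(self):
        with pytest.raises(ConfigurationError):
            sample_task_rate(45.25, 0.5, 0.5, np.random.default_rng(0))


def degenerate_config(method, pools, n=200, seed=9, **kw):
    return SimulationConfig(
        method=method, season=Season.SPRING, bodyweight_table=weighted((80.0, 1.0)),
        factor_pools=pools, n_growers=n, seed=seed,
        rate_perturbation_halfwidth=0.0, **kw,
    )


class TestRunSimulation:
    def test_degenerate_collapse_method1(self, rate_set):
        res = run_simulation(degenerate_config(1, [21.75]), rate_set)
        expected = add_method1(400, 378, 21.75, 80).add_total
        assert np.all(res.add_total == expected)

    def test_method1_zero_pool_gives_zero_doses(self, rate_set):
        res = run_simulation(degenerate_config(1, [0.0]), rate_set)
        assert np.all(res.add_total == 0.0)

    def test_degenerate_collapse_method2_is_bit_exact(self, rate_set):
        res = run_simulation(degenerate_config(2, [174.0]), rate_set)
        expected = add_method2(400, 45.25, 1.375, 174.0, 80).add_total
        assert np.all(res.add_total == expected)

    def test_degenerate_collapse_method3_is_bit_exact(self, rate_set):
        pools = {a: [10.0] for a in A}
        res = run_simulation(degenerate_config(3, pools), rate_set)
        expected = add_method3(400, rate_set, {a: 10.0 for a in A}, 80).add_total
        assert np.all(res.add_total == expected)

    def test_same_seed_reproduces_draws_bitwise(self, rate_set, weighted_table):
        config = SimulationConfig(
            method=3, season=Season.SUMMER, bodyweight_table=weighted_table,
            factor_pools={a: [0.0, 10.0, 40.0] for a in A}, n_growers=2000, seed=42,
        )
        first = run_simulation(config, rate_set)
        second = run_simulation(config, rate_set)
        assert first.draws.equals(second.draws)
        assert first.summary == second.summary

    def test_percentile_sanity_and_nonnegativity(self, rate_set, weighted_table):
        config = SimulationConfig(
            method=2, season=Season.FALL, bodyweight_table=weighted_table,
            factor_pools=[0.0, 50.0, 174.0, 300.0], n_growers=5000, seed=8,
        )
        res = run_simulation(config, rate_set)
        s = res.summary["add_total"]
        assert s["p5"] <= s["median"] <= s["p95"]
        assert np.all(res.add_total >= 0)

    def test_summary_is_stable_in_n(self, rate_set, weighted_table):
        """Growing the population only moves summaries by Monte Carlo error."""
        def summary_at(n, seed):
            config = SimulationConfig(
                method=2, season=Season.FALL, bodyweight_table=weighted_table,
                factor_pools=[0.0, 50.0, 174.0, 300.0], n_growers=n, seed=seed,
            )
            res = run_simulation(config, rate_set)
            return res.summary["add_total"]["mean"], res.add_total.std()

        m_small, sd = summary_at(1000, 13)
        m_large, _ = summary_at(10_000, 14)
        se = sd * np.sqrt(1 / 1000 + 1 / 10_000)
        assert abs(m_small - m_large) < 4 * se

    def test_simulated_mean_matches_enumeration_oracle(self, rate_set):
        """Brute-force enumeration of pool x table combinations (midpoint rates)."""
        table = weighted((60.0, 1.0), (90.0, 3.0), (75.0, 2.0))
        pools = {a: [0.0, 5.0, 20.0] for a in A}
        config = SimulationConfig(
            method=3, season=Season.SPRING, bodyweight_table=table,
            factor_pools=pools, n_growers=100_000, seed=21,
        )
        res = run_simulation(config, rate_set)

        bw_values = [s.weight_kg for s in table.samples]
        bw_weights = np.array([s.population_weight for s in table.samples])
        bw_probs = bw_weights / bw_weights.sum()
        total, mass = 0.0, 0.0
        for combo in itertools.product(*(pools[a] for a in A)):
            task_hours = dict(zip(A, combo))
            for bw, p in zip(bw_values, bw_probs):
                weight = p * (1 / 3) ** len(A)
                dose = add_method3(400, rate_set, task_hours, bw).add_total
                total += weight * dose
                mass += weight
        expected = total / mass
        se = res.add_total.std() / np.sqrt(res.add_total.size)
        assert abs(res.add_total.mean() - expected) < 3 * se

    def test_method2_pool_beyond_averaging_time_errors(self, rate_set):
        with pytest.raises(ConfigurationError):
            run_simulation(degenerate_config(2, [800.0]), rate_set)

    def test_missing_task_pool_names_activity(self, rate_set):
        pools = {a: [1.0] for a in A if a is not A.WEEDING}
        with pytest.raises(ConfigurationError, match="weeding"):
            run_simulation(degenerate_config(3, pools), rate_set)

    def test_row_bootstrap_preserves_within_row_structure(self, rate_set):
        # two rows: all-or-nothing task hours; independent sampling would mix them
        pools = {a: [0.0, 12.0] for a in A}
        config = degenerate_config(3, pools, n=500, row_bootstrap=True)
        res = run_simulation(config, rate_set)
        task_cols = [f"add_{a.value}" for a in A]
        per_draw = res.draws[task_cols].to_numpy()
        # every draw reproduces exactly one of the two rows
        assert np.all((per_draw.sum(axis=1) == 0) | np.all(per_draw > 0, axis=1))


def test_pools_from_cohort_shapes(small_cohort):
    days = pools_from_cohort(small_cohort, 1, Season.SPRING)
    hours = pools_from_cohort(small_cohort, 2, Season.SPRING)
    tasks = pools_from_cohort(small_cohort, 3, Season.SPRING)
    n = sum(1 for r in small_cohort if Season.SPRING in r.seasons)
    assert len(days) == len(hours) == n
    assert set(tasks) == set(A)
    assert all(len(v) == n for v in tasks.values())
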