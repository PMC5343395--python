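"""Life-cycle step and full runs: oracle equivalence, invariants, controls."""

import numpy as np
import pytest

from cellmem import (
    EnvironmentParams,
    SimulationParams,
    make_fixture,
    run_simulation,
    step,
)
from cellmem.errors import ExtinctionError, ParameterError
from cellmem.population import TRAIT_NAMES
from cellmem.streams import RandomStream, RecordedStream

from conftest import make_env_set, tiny_population
from oracle import Draws, OCell, oracle_step

F, W, S = 0, 1, 2


def _as_ocells(pop):
    return [
        OCell(*pop.traits[i].tolist(), float(pop.protection[i]),
              int(pop.env_index[i]))
        for i in range(len(pop))
    ]


import math

_ORACLE_SURVIVAL = {
    "identity": lambda p: p,
    "quadratic": lambda p: p * p,
    "power15": lambda p: p * math.sqrt(p),
}


def _assert_matches_oracle(pop, env_set, params, values, n_envs=1):
    """Run step() and the scalar oracle on the same recorded stream and
    require bit-exact agreement on every cell."""
    expected = oracle_step(
        _as_ocells(pop),
        env_set.state_matrix[:, 0].tolist(),
        capacity=params.capacity,
        kill_rate=params.random_kill_rate,
        mutation_rate=params.mutation_rate,
        draws=Draws(list(values)),
        split_mode=params.split_mode,
        migration_mode=params.resolved_migration_mode,
        n_envs=n_envs,
        survival=_ORACLE_SURVIVAL[params.survival_form],
        mutation_kernel=params.mutation_kernel,
    )
    new_pop, rec = step(pop, env_set, 0, params, RecordedStream(values))
    if expected.extinct:
        assert len(new_pop) == 0 and rec.extinct
        return expected
    assert len(new_pop) == len(expected.cells)
    for i, c in enumerate(expected.cells):
        assert new_pop.traits[i].tolist() == [c.basal, c.increase, c.decrease,
                                              c.memdist]
        assert float(new_pop.protection[i]) == c.protection
        assert int(new_pop.env_index[i]) == c.env
    assert rec.random_deaths == expected.random_deaths
    assert rec.stress_deaths == expected.stress_deaths
    assert rec.births == expected.births
    return expected


class TestStepOracleEquivalence:
    def test_registered_stress_fixture(self):
        fx = make_fixture("one-step-stress")
        values = fx.stream._values.tolist()
        _assert_matches_oracle(fx.population, fx.env_set, fx.params, values)

    def test_registered_fixture_expected_protections(self):
        fx = make_fixture("one-step-stress")
        new_pop, rec = step(fx.population, fx.env_set, 0, fx.params, fx.stream)
        assert new_pop.protection.tolist() == fx.extra["expected_protections"]
        assert rec.random_deaths == fx.extra["expected_random_deaths"]
        assert rec.stress_deaths == fx.extra["expected_stress_deaths"]
        assert fx.stream.remaining == 0  # stream sized exactly

    def test_favorable_fixture_protection_update_only(self):
        fx = make_fixture("one-step-favorable")
        new_pop, rec = step(fx.population, fx.env_set, 0, fx.params, fx.stream)
        assert new_pop.protection.tolist() == pytest.approx(
            fx.extra["expected_protections"]
        )
        assert rec.births == 0 and rec.random_deaths == 0

    def test_division_split_fixture_mother_keeps_memory(self):
        fx = make_fixture("division-split")
        new_pop, _ = step(fx.population, fx.env_set, 0, fx.params, fx.stream)
        assert new_pop.protection.tolist() == [
            fx.extra["expected_mother"], fx.extra["expected_daughter"],
        ]

    def test_mutation_branch(self):
        pop = tiny_population(
            [(0.2, 0.3, 0.1, 0.5, 0.8, 0), (0.1, 0.2, 0.4, 0.6, 0.5, 0)]
        )
        params = SimulationParams(
            capacity=2, n_steps=1, random_kill_rate=0.0, mutation_rate=0.5,
            env_params=EnvironmentParams(n_steps=1),
        )
        env_set = make_env_set([[F]])
        # kills (2), mutation decisions (2: first mutates), trait (memdist),
        # value: step kernel moves memdist by 0.2*(2*0.33-1) = -0.068
        values = [0.5, 0.5, 0.1, 0.9, 0.99, 0.33]
        expected = _assert_matches_oracle(pop, env_set, params, values)
        assert expected.cells[0].memdist == pytest.approx(0.432)

    def test_repeat_sampled_parent_divides_sequentially(self):
        pop = tiny_population([(0.0, 0.0, 0.0, 0.5, 0.8, 0)], capacity=4)
        params = SimulationParams(
            capacity=4, n_steps=1, random_kill_rate=0.0, mutation_rate=0.0,
            env_params=EnvironmentParams(n_steps=1),
        )
        env_set = make_env_set([[F]])
        # kill (1), parents (3 draws, sole parent), mutation decisions (4)
        values = [0.9, 0.1, 0.5, 0.9, 0.9, 0.9, 0.9, 0.9]
        _assert_matches_oracle(pop, env_set, params, values)
        new_pop, _ = step(pop, env_set, 0, params, RecordedStream(values))
        # sequential halving: daughters 0.4, 0.2, 0.1; mother left with 0.1
        assert sorted(new_pop.protection.tolist()) == pytest.approx(
            [0.1, 0.1, 0.2, 0.4]
        )

    def test_evolvable_split_and_random_migration(self):
        pop = tiny_population(
            [(0.3, 0.2, 0.1, 0.25, 0.9, 0), (0.1, 0.6, 0.3, 0.8, 0.4, 1)]
        )
        params = SimulationParams(
            capacity=4, n_steps=1, random_kill_rate=0.1, mutation_rate=0.2,
            split_mode="evolvable", migration_mode="random",
            survival_form="identity",
            env_params=EnvironmentParams(
                regime="informative", n_steps=1, n_envs=2
            ),
        )
        env_set = make_env_set([[W], [S]], n_envs=2)
        # kills(2), stress for cell1 (survives: 0.2 < 0.4), parents(2),
        # daughter envs(2), mutation decisions(4: third mutates),
        # trait(1 -> increase), value
        values = [0.5, 0.5, 0.2, 0.1, 0.8, 0.9, 0.4, 0.9, 0.9, 0.05, 0.9,
                  0.3, 0.77]
        _assert_matches_oracle(pop, env_set, params, values, n_envs=2)

    def test_always_leave_two_envs(self):
        pop = tiny_population(
            [(0.2, 0.1, 0.0, 0.5, 0.7, 0), (0.3, 0.2, 0.1, 0.5, 0.6, 1)]
        )
        params = SimulationParams(
            capacity=3, n_steps=1, random_kill_rate=0.0, mutation_rate=0.0,
            migration_mode="always_leave",
            env_params=EnvironmentParams(n_steps=1, n_envs=2),
        )
        env_set = make_env_set([[F], [F]], n_envs=2)
        # kills(2), parent(1), mutation decisions(3); no env draws (n_envs=2)
        values = [0.9, 0.9, 0.2, 0.9, 0.9, 0.9]
        expected = _assert_matches_oracle(pop, env_set, params, values, n_envs=2)
        daughter = expected.cells[-1]
        assert daughter.env == 1  # left the birth environment

    def test_quadratic_survival_stress_branch(self):
        pop = tiny_population(
            [(0.0, 0.0, 0.0, 0.5, 0.8, 0), (0.0, 0.0, 0.0, 0.5, 0.9, 0)]
        )
        params = SimulationParams(
            capacity=2, n_steps=1, random_kill_rate=0.0, mutation_rate=0.0,
            survival_form="quadratic",
            env_params=EnvironmentParams(n_steps=1),
        )
        env_set = make_env_set([[S]])
        # survival probabilities are squared: 0.64 and 0.81, so u=0.7 kills
        # the first cell but not the second
        # kills(2), stress(2), parent(1), mutation decisions(2)
        values = [0.9, 0.9, 0.7, 0.7, 0.3, 0.9, 0.9]
        expected = _assert_matches_oracle(pop, env_set, params, values)
        assert expected.stress_deaths == 1
        assert expected.cells[0].protection == 0.45  # surviving mother split

    def test_stress_extinction(self):
        pop = tiny_population(
            [(0.0, 0.0, 0.0, 0.5, 0.0, 0), (0.0, 0.0, 0.0, 0.5, 0.0, 0)]
        )
        params = SimulationParams(
            capacity=2, n_steps=1, random_kill_rate=0.0, mutation_rate=0.0,
            env_params=EnvironmentParams(n_steps=1),
        )
        env_set = make_env_set([[S]])
        # kills(2), stress draws(2): survival prob 0 -> all die
        values = [0.9, 0.9, 0.5, 0.5]
        expected = _assert_matches_oracle(pop, env_set, params, values)
        assert expected.extinct

    def test_zero_weight_fallback_uniform(self):
        # produced == 1 for both cells -> all weights zero -> uniform sampling
        pop = tiny_population(
            [(0.0, 1.0, 0.0, 0.5, 0.0, 0), (0.0, 1.0, 0.0, 0.5, 0.0, 0)]
        )
        params = SimulationParams(
            capacity=3, n_steps=1, random_kill_rate=0.0, mutation_rate=0.0,
            env_params=EnvironmentParams(n_steps=1),
        )
        env_set = make_env_set([[W]])
        values = [0.9, 0.9, 0.6, 0.9, 0.9, 0.9]
        expected = _assert_matches_oracle(pop, env_set, params, values)
        # u=0.6 over uniform weights -> second cell is the parent
        assert expected.cells[-1].protection == 0.5


class TestStepContracts:
    def test_no_deaths_at_capacity_only_updates_protection(self):
        pop = tiny_population(
            [(0.1, 0.2, 0.05, 0.5, 0.5, 0),
             (0.0, 0.0, 0.3, 0.5, 0.2, 0),
             (0.6, 0.1, 0.0, 0.5, 0.6, 0)]
        )
        params = SimulationParams(
            capacity=3, n_steps=1, random_kill_rate=0.0, mutation_rate=0.0,
            env_params=EnvironmentParams(n_steps=1),
        )
        env_set = make_env_set([[F]])
        new_pop, rec = step(pop, env_set, 0, params,
                            RecordedStream([0.9, 0.9, 0.9, 0.9, 0.9, 0.9]))
        assert rec.births == 0
        assert np.array_equal(new_pop.traits, pop.traits)
        assert new_pop.protection.tolist() == pytest.approx([0.45, 0.0, 0.6])

    def test_empty_population_rejected(self):
        pop = tiny_population([(0.1, 0.1, 0.1, 0.5, 0.5, 0)], capacity=5)
        params = SimulationParams(
            capacity=5, n_steps=1, env_params=EnvironmentParams(n_steps=1),
        )
        env_set = make_env_set([[F]])
        from cellmem.population import Population

        empty = Population(np.empty((0, 4)), np.empty(0),
                           np.empty(0, dtype=np.int64), 5)
        with pytest.raises(ExtinctionError):
            step(empty, env_set, 0, params, RandomStream(0))

    def test_refill_to_capacity_and_turnover_scaling(self):
        results = {}
        for kill in (0.02, 0.2):
            params = SimulationParams(
                capacity=400, n_steps=60, random_kill_rate=kill, seed=21,
                env_params=EnvironmentParams(n_steps=60), record_every=1,
            )
            res = run_simulation(params)
            assert (res.trajectory["size"] == 400).all()
            results[kill] = res.trajectory["births"].mean()
            # births replace deaths each step
            deaths = (res.trajectory["random_deaths"]
                      + res.trajectory["stress_deaths"])
            assert (res.trajectory["births"] == deaths).all()
        assert results[0.2] > results[0.02]


class TestRunSimulation:
    def test_minimal_run_has_record_and_snapshot(self):
        params = SimulationParams(
            capacity=20, n_steps=1, env_params=EnvironmentParams(n_steps=1),
            record_every=1, seed=3,
        )
        res = run_simulation(params)
        assert len(res.trajectory) == 1
        assert len(res.final_population) == 20
        assert not res.extinct

    def test_determinism_bit_identical(self):
        params = SimulationParams(
            capacity=150, n_steps=300, seed=42, record_every=25,
            env_params=EnvironmentParams(regime="informative", n_steps=300,
                                         p_warning=0.02),
        )
        a = run_simulation(params)
        b = run_simulation(params)
        assert a.trajectory.equals(b.trajectory)
        assert np.array_equal(a.final_population.traits,
                              b.final_population.traits)
        assert np.array_equal(a.final_population.protection,
                              b.final_population.protection)

    def test_different_seeds_differ(self):
        base = dict(capacity=100, n_steps=100,
                    env_params=EnvironmentParams(n_steps=100))
        a = run_simulation(SimulationParams(seed=1, **base))
        b = run_simulation(SimulationParams(seed=2, **base))
        assert not np.array_equal(a.final_population.protection,
                                  b.final_population.protection)

    def test_extinction_halts_gracefully(self):
        # certain stress death: all-stress environment, zero protection forced
        # by survival form that is 0 below 2 -> use kill rate 1 instead
        params = SimulationParams(
            capacity=30, n_steps=10, random_kill_rate=1.0, seed=5,
            env_params=EnvironmentParams(n_steps=10), record_every=1,
        )
        res = run_simulation(params)
        assert res.extinct
        assert res.steps_completed == 1
        assert len(res.final_population) == 0
        assert bool(res.trajectory["extinct"].iloc[-1])

    def test_invalid_params_rejected_before_running(self):
        with pytest.raises(ParameterError):
            SimulationParams(n_steps=0)
        with pytest.raises(ParameterError):
            SimulationParams(random_kill_rate=1.5)
        with pytest.raises(ParameterError):
            SimulationParams(migration_mode="always_leave",
                             env_params=EnvironmentParams(n_envs=1))


class TestNeutralityControls:
    def test_neutral_drift_keeps_trait_means_near_half(self):
        """With no stress and no reproduction cost, no trait is under
        selection: replicate-averaged final means stay near 0.5."""
        finals = []
        for seed in range(10):
            params = SimulationParams(
                capacity=300, n_steps=1_500, cost_form="constant", seed=100 + seed,
                env_params=EnvironmentParams(p_warning=0.0, p_stress=0.0,
                                             n_steps=1_500),
                record_every=1_500,
            )
            res = run_simulation(params)
            finals.append([res.final_trait_means()[t] for t in TRAIT_NAMES])
        finals = np.asarray(finals)
        grand = finals.mean(axis=0)
        se = finals.std(axis=0, ddof=1) / np.sqrt(finals.shape[0])
        for j, trait in enumerate(TRAIT_NAMES):
            assert abs(grand[j] - 0.5) < max(4 * se[j], 0.1), trait

    def test_memdist_drifts_uniform_under_fixed_half(self):
        """With the split fixed at one half the memory distribution factor is
        a neutral marker: single populations drift, but across replicates its
        pooled distribution stays broad and centered like its uniform
        starting law, even when other traits are under selection."""
        pooled = []
        means = []
        for seed in range(6):
            params = SimulationParams(
                capacity=1_000, n_steps=1_000, split_mode="fixed_half",
                seed=880 + seed, record_every=1_000,
                env_params=EnvironmentParams(regime="informative",
                                             n_steps=1_000),
            )
            md = run_simulation(params).final_population.traits[:, 3]
            pooled.append(md)
            means.append(md.mean())
        pooled = np.concatenate(pooled)
        assert abs(np.mean(means) - 0.5) < 0.1
        assert 0.04 < pooled.var() < 0.15
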