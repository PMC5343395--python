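"""Deterministic hand-traceable fixtures.

Each fixture bundles a tiny population, simulation parameters, an environment
and a :class:`~cellmem.streams.RecordedStream` sized for exactly one step, so
a test (or a curious reader) can trace every uniform draw by hand against the
stream discipline documented in :mod:`cellmem.evolution`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .environment import (
    EnvironmentParams,
    EnvironmentSequence,
    EnvironmentSet,
    EnvState,
)
from .errors import FixtureError
from .evolution import SimulationParams
from .population import Cell, Genotype, Population
from .streams import RecordedStream

__all__ = ["Fixture", "make_fixture", "FIXTURE_NAMES"]


@dataclass
class Fixture:
    name: str
    description: str
    population: Population
    params: SimulationParams
    env_set: EnvironmentSet
    stream: RecordedStream
    extra: dict = field(default_factory=dict)


def _env_set(states, n_envs: int = 1) -> EnvironmentSet:
    states = np.asarray(states, dtype=np.int8).reshape(n_envs, -1)
    params = EnvironmentParams(n_steps=states.shape[1], n_envs=n_envs)
    seqs = [
        EnvironmentSequence(states=row, params=params, seed=None) for row in states
    ]
    return EnvironmentSet(sequences=seqs, seeds=[])


def _one_step_stress() -> Fixture:
    """Three cells under STRESS: one random kill, one stress kill, the sole
    survivor updates protection, divides twice and no mutation fires.

    Identity survival keeps the trace readable (survive iff u < protection).
    Hand trace (kill rate 0.2, identity survival, production cost, fixed
    half split, capacity 3):

    * kills: A u=0.9 lives, B u=0.05 dies, C u=0.5 lives;
    * stress: A u=0.7 < p=0.8 survives, C u=0.95 >= p=0.9 dies;
    * update A: 0.8 + 0.3 - 0.1 = 1.0, produced 0.2, weight 0.8;
    * two offspring, both from A (u=0.3, 0.6): first daughter 0.5, A -> 0.5;
      second daughter 0.25, A -> 0.25;
    * mutation decisions 0.5, 0.5, 0.5 with rate 0: nothing mutates.

    Final population: A at protection 0.25, daughters at 0.5 and 0.25.
    """
    cells = [
        Cell(Genotype(0.2, 0.3, 0.1, 0.5), protection=0.8, env_index=0),
        Cell(Genotype(0.0, 0.5, 0.2, 0.5), protection=0.4, env_index=0),
        Cell(Genotype(0.5, 0.0, 0.0, 0.5), protection=0.9, env_index=0),
    ]
    pop = Population.from_cells(cells, capacity=3)
    params = SimulationParams(
        capacity=3,
        n_steps=1,
        random_kill_rate=0.2,
        mutation_rate=0.0,
        split_mode="fixed_half",
        survival_form="identity",
        env_params=EnvironmentParams(n_steps=1),
        record_every=1,
    )
    env_set = _env_set([[int(EnvState.STRESS)]])
    stream = RecordedStream(
        [0.9, 0.05, 0.5, 0.7, 0.95, 0.3, 0.6, 0.5, 0.5, 0.5]
    )
    return Fixture(
        name="one-step-stress",
        description=_one_step_stress.__doc__,
        population=pop,
        params=params,
        env_set=env_set,
        stream=stream,
        extra={
            "expected_protections": [0.25, 0.5, 0.25],
            "expected_random_deaths": 1,
            "expected_stress_deaths": 1,
        },
    )


def _one_step_favorable() -> Fixture:
    """Three cells at capacity under FAVORABLE with zero kill rate: nothing
    dies, nothing is born; only the protection update (and three unused
    mutation decisions) happen.
    """
    cells = [
        Cell(Genotype(0.1, 0.2, 0.05, 0.5), protection=0.5, env_index=0),
        Cell(Genotype(0.0, 0.0, 0.3, 0.5), protection=0.2, env_index=0),
        Cell(Genotype(0.6, 0.1, 0.0, 0.5), protection=0.6, env_index=0),
    ]
    pop = Population.from_cells(cells, capacity=3)
    params = SimulationParams(
        capacity=3,
        n_steps=1,
        random_kill_rate=0.0,
        mutation_rate=0.0,
        env_params=EnvironmentParams(n_steps=1),
        record_every=1,
    )
    env_set = _env_set([[int(EnvState.FAVORABLE)]])
    stream = RecordedStream([0.1, 0.2, 0.3, 0.5, 0.5, 0.5])
    return Fixture(
        name="one-step-favorable",
        description=_one_step_favorable.__doc__,
        population=pop,
        params=params,
        env_set=env_set,
        stream=stream,
        extra={"expected_protections": [0.45, 0.0, 0.6]},
    )


def _division_split() -> Fixture:
    """A single cell with protection 0.6 and memory distribution factor 0:
    under the evolvable split the mother keeps the entire memory."""
    cell = Cell(Genotype(0.0, 0.0, 0.0, 0.0), protection=0.6, env_index=0)
    pop = Population.from_cells([cell], capacity=2)
    params = SimulationParams(
        capacity=2,
        n_steps=1,
        random_kill_rate=0.0,
        mutation_rate=0.0,
        split_mode="evolvable",
        env_params=EnvironmentParams(n_steps=1),
        record_every=1,
    )
    env_set = _env_set([[int(EnvState.FAVORABLE)]])
    # one kill draw, one parent draw, two mutation decisions
    stream = RecordedStream([0.9, 0.3, 0.5, 0.5])
    return Fixture(
        name="division-split",
        description=_division_split.__doc__,
        population=pop,
        params=params,
        env_set=env_set,
        stream=stream,
        extra={"expected_mother": 0.6, "expected_daughter": 0.0},
    )


_REGISTRY = {
    "one-step-stress": _one_step_stress,
    "one-step-favorable": _one_step_favorable,
    "division-split": _division_split,
}

FIXTURE_NAMES = tuple(sorted(_REGISTRY))


def make_fixture(name: str) -> Fixture:
    """Build a registered fixture by name."""
    try:
        builder = _REGISTRY[name]
    except KeyError:
        raise FixtureError(
            f"unknown fixture {name!r}; known: {list(FIXTURE_NAMES)}"
        ) from None
    return builder()
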