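import numpy as np
import pytest

from cellmem import EnvironmentParams, Population, SimulationParams
from cellmem.environment import EnvironmentSequence, EnvironmentSet
from cellmem.population import Cell, Genotype


def make_env_set(states, n_envs=1):
    """EnvironmentSet from an explicit (n_envs, n_steps) state array."""
    states = np.asarray(states, dtype=np.int8).reshape(n_envs, -1)
    params = EnvironmentParams(n_steps=states.shape[1], n_envs=n_envs)
    seqs = [EnvironmentSequence(states=row, params=params) for row in states]
    return EnvironmentSet(sequences=seqs, seeds=[])


def tiny_population(specs, capacity=None):
    """Population from (basal, increase, decrease, memdist, protection, env)
    tuples."""
    cells = [
        Cell(Genotype(b, i, d, m), protection=p, env_index=e)
        for b, i, d, m, p, e in specs
    ]
    return Population.from_cells(cells, capacity or len(cells))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def small_params(**kw):
    defaults = dict(
        capacity=50,
        n_steps=10,
        env_params=EnvironmentParams(n_steps=10),
        record_every=1,
        seed=7,
    )
    defaults.update(kw)
    return SimulationParams(**defaults)
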