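"""Cells, genotypes and protection dynamics.

A cell carries four genetically encoded traits, each a dimensionless value in
[0, 1]:

``basal``      the minimal protection level maintained at all times (a floor);
``increase``   the amount of protection added when a warning or stress is sensed;
``decrease``   the amount subtracted from the protection level every step;
``memdist``    the memory distribution factor: the share of the protection
               level handed to the daughter at division (0 = the mother keeps
               everything, 1 = the daughter receives everything; forced to 0.5
               when the split mode is ``fixed_half``).

The phenotype is a single protection level in [0, 1] — the cell's memory
state — which determines stress survival.  Producing protection is costly:
the reproduction weight of a cell decreases with the amount of protection it
produced in the current step (default form ``1 - produced``), so constitutive
or induced protection trades off against fecundity.

Populations are stored as structure-of-arrays (a trait matrix plus protection
and environment-index vectors) so that a whole simulation step is a handful of
vectorized operations; scalar :class:`Genotype` / :class:`Cell` views exist
for hand-written fixtures and single-cell reasoning.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import MonotonicityError, ParameterError
from .streams import UniformStream

__all__ = [
    "TRAIT_NAMES",
    "BASAL",
    "INCREASE",
    "DECREASE",
    "MEMDIST",
    "Genotype",
    "Cell",
    "Population",
    "init_population",
    "update_protection",
    "update_protection_arrays",
    "stress_survival_probability",
    "reproduction_weight",
    "resolve_survival_form",
    "resolve_cost_form",
    "divide",
    "mutate_population",
    "SURVIVAL_FORMS",
    "COST_FORMS",
]

TRAIT_NAMES = ("basal", "increase", "decrease", "memdist")
BASAL, INCREASE, DECREASE, MEMDIST = range(4)
N_TRAITS = 4

SPLIT_MODES = ("fixed_half", "evolvable")


def _check_unit(name: str, value: float) -> float:
    value = float(value)
    if not (0.0 <= value <= 1.0):
        raise ParameterError(f"{name}={value} must lie in [0, 1]")
    return value


@dataclass
class Genotype:
    """The four evolvable traits of one cell."""

    basal: float
    increase: float
    decrease: float
    memdist: float = 0.5

    def __post_init__(self) -> None:
        for name in TRAIT_NAMES:
            setattr(self, name, _check_unit(name, getattr(self, name)))

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.basal, self.increase, self.decrease, self.memdist], dtype=float
        )

    @classmethod
    def from_array(cls, a) -> "Genotype":
        return cls(*(float(x) for x in a))


@dataclass
class Cell:
    """One cell: genotype, current protection level, environment index."""

    genotype: Genotype
    protection: float
    env_index: int = 0

    def __post_init__(self) -> None:
        self.protection = _check_unit("protection", self.protection)
        self.env_index = int(self.env_index)


class Population:
    """Structure-of-arrays container for up to ``capacity`` cells."""

    def __init__(
        self,
        traits: np.ndarray,
        protection: np.ndarray,
        env_index: np.ndarray,
        capacity: int,
    ) -> None:
        self.traits = np.asarray(traits, dtype=float).reshape(-1, N_TRAITS)
        self.protection = np.asarray(protection, dtype=float).ravel()
        self.env_index = np.asarray(env_index, dtype=np.int64).ravel()
        self.capacity = int(capacity)
        n = self.traits.shape[0]
        if self.protection.size != n or self.env_index.size != n:
            raise ParameterError("traits, protection and env_index lengths differ")
        if self.capacity < 1:
            raise ParameterError(f"capacity={capacity} must be >= 1")
        if n > self.capacity:
            raise ParameterError(f"{n} cells exceed capacity {self.capacity}")

    def __len__(self) -> int:
        return self.traits.shape[0]

    def cell(self, i: int) -> Cell:
        """Scalar view of cell ``i``."""
        return Cell(
            genotype=Genotype.from_array(self.traits[i]),
            protection=float(self.protection[i]),
            env_index=int(self.env_index[i]),
        )

    @classmethod
    def from_cells(cls, cells, capacity: int | None = None) -> "Population":
        cells = list(cells)
        traits = np.array([c.genotype.as_array() for c in cells], dtype=float)
        prot = np.array([c.protection for c in cells], dtype=float)
        env = np.array([c.env_index for c in cells], dtype=np.int64)
        return cls(traits, prot, env, capacity or len(cells))

    def copy(self) -> "Population":
        return Population(
            self.traits.copy(), self.protection.copy(), self.env_index.copy(),
            self.capacity,
        )

    # -- delimited-text snapshots ---------------------------------------
    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.traits, columns=list(TRAIT_NAMES))
        df["protection"] = self.protection
        df["env_index"] = self.env_index
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame, capacity: int | None = None) -> "Population":
        traits = df[list(TRAIT_NAMES)].to_numpy(dtype=float)
        return cls(
            traits,
            df["protection"].to_numpy(dtype=float),
            df["env_index"].to_numpy(dtype=np.int64),
            capacity or len(df),
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(Path(path), index=False)

    @classmethod
    def from_csv(cls, path, capacity: int | None = None) -> "Population":
        return cls.from_frame(pd.read_csv(Path(path)), capacity)


def init_population(
    capacity: int, n_envs: int, rand_stream: UniformStream
) -> Population:
    """Initialize ``capacity`` cells with all traits and protection ~ U(0, 1).

    Stream discipline: ``capacity`` uniforms for each trait in the order
    basal, increase, decrease, memdist, then ``capacity`` for protection, then
    ``capacity`` mapped to environment indices (drawn even when ``n_envs`` is
    1, to keep the consumption count independent of ``n_envs``).
    """
    capacity = int(capacity)
    if capacity < 1:
        raise ParameterError(f"capacity={capacity} must be >= 1")
    if int(n_envs) < 1:
        raise ParameterError(f"n_envs={n_envs} must be >= 1")
    traits = np.empty((capacity, N_TRAITS), dtype=float)
    for j in range(N_TRAITS):
        traits[:, j] = rand_stream.uniform(capacity)
    protection = rand_stream.uniform(capacity)
    u_env = rand_stream.uniform(capacity)
    env_index = np.minimum((u_env * n_envs).astype(np.int64), n_envs - 1)
    return Population(traits, protection, env_index, capacity)


# ---------------------------------------------------------------------------
# protection dynamics
# ---------------------------------------------------------------------------

def update_protection_arrays(
    protection: np.ndarray,
    basal: np.ndarray,
    increase: np.ndarray,
    decrease: np.ndarray,
    alert,
) -> np.ndarray:
    """Vectorized one-step protection update.

    ``p' = clamp_[0,1](p + increase * alert - decrease)`` followed by the
    basal floor ``p' = max(p', basal)``.  ``alert`` is truthy on WARNING and
    STRESS steps.  Increase and decrease apply within the same step (the
    decay also runs during warning/stress periods).
    """
    if np.ndim(alert) == 0 and not alert:
        # adding an exact zero is a no-op, so the increase term can be
        # skipped entirely on favorable steps
        p = protection - decrease
    else:
        p = protection + increase * alert - decrease
    p = np.clip(p, 0.0, 1.0)
    return np.maximum(p, basal)


def update_protection(protection: float, genotype: Genotype, env_state) -> float:
    """Scalar protection update for one cell (see the array version)."""
    from .environment import EnvState

    alert = env_state in (EnvState.WARNING, EnvState.STRESS)
    out = update_protection_arrays(
        np.asarray(float(protection)),
        np.asarray(genotype.basal),
        np.asarray(genotype.increase),
        np.asarray(genotype.decrease),
        alert,
    )
    return float(out)


# ---------------------------------------------------------------------------
# survival and reproduction forms
# ---------------------------------------------------------------------------

def _power15(p):
    a = np.asarray(p, dtype=float)
    return a * np.sqrt(a)


#: monotone non-decreasing maps protection -> survival probability.  The
#: default is the 3/2 power, which balances two constraints: survival must
#: accelerate with protection (be convex) for asymmetric segregation of
#: memory to be adaptive at all — with a linear curve the expected number of
#: offspring surviving a stress is invariant to how protection is split at
#: division, so the memory distribution factor would be quasi-neutral — but
#: survival near full protection must not saturate selection so strongly
#: that a constitutively protected population becomes an inescapable local
#: optimum in environments where inducible protection is the better
#: strategy.  The quadratic (stronger curvature) and identity (no curvature)
#: bracket the default.
SURVIVAL_FORMS = {
    "power15": _power15,
    "quadratic": lambda p: np.square(np.asarray(p, dtype=float)),
    "identity": lambda p: np.asarray(p, dtype=float),
    "sqrt": lambda p: np.sqrt(np.asarray(p, dtype=float)),
}

#: monotone non-increasing maps (protection, produced) -> reproduction weight
COST_FORMS = {
    # cost on the amount of protection produced this step (default): cells pay
    # for synthesizing protection, not for carrying it
    "production": lambda p, produced: 1.0 - np.asarray(produced, dtype=float),
    # cost on the maintained level
    "level": lambda p, produced: 1.0 - np.asarray(p, dtype=float),
    # both multiplicatively
    "level_production": lambda p, produced: (1.0 - np.asarray(p, dtype=float))
    * (1.0 - np.asarray(produced, dtype=float)),
    # no cost at all (neutral-drift controls)
    "constant": lambda p, produced: np.ones_like(np.asarray(p, dtype=float)),
}

_GRID = np.linspace(0.0, 1.0, 101)


def resolve_survival_form(form):
    """Return a validated survival map ``[0,1] -> [0,1]``.

    ``form`` is a registry name or a callable; callables are checked on a
    101-point grid for range and (non-strict) monotone increase at load time.
    """
    fn = SURVIVAL_FORMS[form] if isinstance(form, str) else form
    vals = np.asarray(fn(_GRID), dtype=float)
    if vals.shape != _GRID.shape:
        raise MonotonicityError("survival form must map arrays elementwise")
    if np.any(vals < -1e-12) or np.any(vals > 1.0 + 1e-12):
        raise MonotonicityError("survival form must map [0,1] into [0,1]")
    if np.any(np.diff(vals) < -1e-12):
        raise MonotonicityError("survival form must be non-decreasing in protection")
    return fn


def resolve_cost_form(form):
    """Return a validated reproduction-weight map, non-increasing in both
    the protection level and the produced amount, with non-negative values."""
    fn = COST_FORMS[form] if isinstance(form, str) else form
    for produced in (0.0, 0.5):
        vals = np.asarray(fn(_GRID, np.full_like(_GRID, produced)), dtype=float)
        if np.any(vals < -1e-12):
            raise MonotonicityError("cost form must be non-negative")
        if np.any(np.diff(vals) > 1e-12):
            raise MonotonicityError("cost form must be non-increasing in protection")
    for level in (0.0, 0.5):
        vals = np.asarray(fn(np.full_like(_GRID, level), _GRID), dtype=float)
        if np.any(np.diff(vals) > 1e-12):
            raise MonotonicityError("cost form must be non-increasing in production")
    return fn


def get_survival_form(form):
    """Fetch a survival form without re-running grid validation.

    Registry names are trusted; callables are assumed to have been validated
    once (e.g. by ``SimulationParams``) via :func:`resolve_survival_form`.
    """
    return SURVIVAL_FORMS[form] if isinstance(form, str) else form


def get_cost_form(form):
    """Fetch a cost form without re-running grid validation."""
    return COST_FORMS[form] if isinstance(form, str) else form


def stress_survival_probability(protection, form="power15"):
    """Probability of surviving one stress period at a given protection."""
    fn = resolve_survival_form(form)
    out = fn(np.asarray(protection, dtype=float))
    return float(out) if np.isscalar(protection) else out


def reproduction_weight(protection, protection_produced=0.0, form="production"):
    """Relative weight with which a cell is sampled for reproduction.

    The default charges only the protection *produced* in the current step
    (``w = 1 - produced``); carrying a high level is free, synthesizing it is
    not.  ``level`` and ``level_production`` forms charge the maintained
    level instead/in addition.
    """
    fn = resolve_cost_form(form)
    out = fn(
        np.asarray(protection, dtype=float),
        np.asarray(protection_produced, dtype=float),
    )
    if np.isscalar(protection) and np.isscalar(protection_produced):
        return float(out)
    return out


# ---------------------------------------------------------------------------
# division and mutation
# ---------------------------------------------------------------------------

def split_daughter_share(p, m):
    """Daughter's protection share at division, elementwise.

    Returns ``m * p`` rounded once; for ``m <= 0.5`` it is computed as the
    exact remainder ``p - (1 - m) * p`` so that ``(p - share) + share == p``
    exactly in IEEE arithmetic (the mother's share ``p - share`` is then also
    exact).  Works on scalars and arrays alike.
    """
    p = np.asarray(p, dtype=float)
    m = np.asarray(m, dtype=float)
    out = np.where(m > 0.5, m * p, p - (1.0 - m) * p)
    return float(out) if out.ndim == 0 else out


def divide(cell: Cell, split_mode: str = "fixed_half") -> tuple[Cell, Cell]:
    """Split one cell into (mother, daughter).

    The daughter receives ``m * p`` of the parent's protection and the mother
    keeps the rest, where ``m`` is 0.5 under ``fixed_half`` and the genotype's
    memory distribution factor under ``evolvable``.  The larger share is
    computed by multiplication and the smaller as the remainder, so (by the
    Sterbenz lemma, the subtrahend being within a factor two of the parent)
    conservation ``mother + daughter == parent`` holds to the last bit for
    every ``m``.  Both cells inherit an identical copy of the genotype; both
    start in the parent's environment (migration of the daughter is the
    simulation loop's job).
    """
    if split_mode not in SPLIT_MODES:
        raise ParameterError(f"unknown split_mode {split_mode!r}")
    m = 0.5 if split_mode == "fixed_half" else cell.genotype.memdist
    d = split_daughter_share(cell.protection, m)
    g = cell.genotype
    mother = Cell(
        genotype=Genotype(g.basal, g.increase, g.decrease, g.memdist),
        protection=cell.protection - d,
        env_index=cell.env_index,
    )
    daughter = Cell(
        genotype=Genotype(g.basal, g.increase, g.decrease, g.memdist),
        protection=d,
        env_index=cell.env_index,
    )
    return mother, daughter


MUTATION_KERNELS = ("step", "resample")

#: half-width of the uniform step kernel; mean absolute step 0.1
STEP_WIDTH = 0.2


def reflect_unit(x):
    """Fold values into [0, 1] by reflection at the boundaries."""
    x = np.abs(np.asarray(x, dtype=float))
    x = np.where(x > 1.0, 2.0 - x, x)
    return x


def mutate_population(
    pop: Population,
    mutation_rate: float,
    rand_stream: UniformStream,
    kernel: str = "step",
) -> Population:
    """Mutate each cell independently with probability ``mutation_rate``.

    A mutating cell has exactly one of its four traits chosen uniformly and
    perturbed; all other traits (and the protection level) stay untouched.
    The memory distribution factor is mutable regardless of the split mode,
    so under ``fixed_half`` it stays a neutrally drifting marker.

    Two kernels:

    ``step`` (default)
        the trait moves by a uniform step in ``[-0.2, 0.2]``, reflected at
        the boundaries — mutations of small effect, under which adaptation
        proceeds as a hill-climbing walk.  The reflected random walk has the
        uniform distribution as its stationary law, so unselected traits
        still drift toward Uniform(0, 1).
    ``resample``
        the trait is redrawn from Uniform(0, 1) — mutations of unbounded
        effect (maximal exploration, but a heavy mutation load near boundary
        optima).

    Stream discipline: ``len(pop)`` decision uniforms in cell order, then one
    trait-choice uniform per mutant (in cell order), then one value uniform
    per mutant.  Mutation happens in place; the population is also returned.
    """
    if not (0.0 <= mutation_rate <= 1.0):
        raise ParameterError(f"mutation_rate={mutation_rate} must lie in [0, 1]")
    if kernel not in MUTATION_KERNELS:
        raise ParameterError(f"unknown mutation kernel {kernel!r}")
    n = len(pop)
    u = rand_stream.uniform(n)
    mutants = np.flatnonzero(u < mutation_rate)
    k = mutants.size
    if k:
        u_trait = rand_stream.uniform(k)
        u_value = rand_stream.uniform(k)
        trait_idx = np.minimum((u_trait * N_TRAITS).astype(np.int64), N_TRAITS - 1)
        if kernel == "resample":
            pop.traits[mutants, trait_idx] = u_value
        else:
            old = pop.traits[mutants, trait_idx]
            step = STEP_WIDTH * (2.0 * u_value - 1.0)
            pop.traits[mutants, trait_idx] = reflect_unit(old + step)
    return pop
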