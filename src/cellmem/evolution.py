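"""The per-time-step life cycle and full simulation runs.

Each time step executes, in this order:

1. **Random death** — every cell dies with probability ``random_kill_rate``
   (default 5%), independent of the environment; this is what frees room for
   reproduction.
2. **Stress death** — every surviving cell whose environment is in the STRESS
   state dies with probability ``1 - survival(protection)`` (default survival
   form: identity, i.e. survive with probability equal to the protection
   level).
3. **Protection update** — survivors update their protection level from their
   genotype and their environment's current state (see
   :func:`cellmem.population.update_protection_arrays`).
4. **Reproduction to capacity** — parents are sampled with replacement with
   probability proportional to their reproduction weight (default
   ``1 - produced``) until the population is back at capacity.  Each sampled
   parent divides: the mother keeps ``(1 - m)`` of the protection and stays in
   its environment; the daughter receives ``m`` and is placed according to the
   migration mode.  A parent sampled several times divides sequentially from
   its already-reduced level.  If every weight is zero, parents are sampled
   uniformly.
5. **Mutation** — each cell mutates with probability ``mutation_rate``
   (default 0.1%): one uniformly chosen trait is resampled from U(0, 1).

If steps 1–2 kill every cell the population is extinct; the step reports it
and :func:`run_simulation` halts gracefully.

Migration modes for the daughter: ``stay`` / ``always_stay`` keep her in the
birth environment; ``random`` places her uniformly among all ``n_envs``
environments (so with two environments she leaves with probability 50%);
``always_leave`` places her uniformly among the other environments.

Uniform-stream discipline (exact draw order within one step, needed to replay
a step from a recorded stream):

a. one uniform per cell, in population order (random kill; dead if u < rate);
b. one uniform per *surviving* cell in a STRESS environment, in population
   order (dies if u >= survival(p));
c. one uniform per offspring for parent selection: parent = first survivor i
   with cumsum(w)[i] > u * sum(w);
d. one uniform per offspring for the daughter's environment when the
   migration mode is ``random`` (index = floor(u * n_envs)) or
   ``always_leave`` with more than two environments (index skips the birth
   environment); no draws otherwise;
e. the mutation draws of :func:`cellmem.population.mutate_population` on the
   refilled population (survivors in their original order, then daughters in
   draw order).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from numba import njit

from .environment import (
    EnvState,
    EnvironmentParams,
    EnvironmentSet,
    make_environment_set,
    with_n_steps,
)
from .errors import ExtinctionError, ParameterError
from .population import (
    MEMDIST,
    TRAIT_NAMES,
    Population,
    get_cost_form,
    get_survival_form,
    init_population,
    mutate_population,
    resolve_cost_form,
    resolve_survival_form,
    split_daughter_share,
    update_protection_arrays,
)
from .streams import RandomStream, UniformStream, derive_seeds

__all__ = [
    "SimulationParams",
    "StepRecord",
    "SimulationResult",
    "step",
    "run_simulation",
    "MIGRATION_MODES",
]

MIGRATION_MODES = ("stay", "random", "always_leave", "always_stay")

_MODE_CODES = {"stay": 0, "always_stay": 0, "random": 1, "always_leave": 2}


@njit(cache=True)
def _compact_update_weights(traits, prot, env, alive, alert_env, any_alert,
                            capacity):
    """Fused survivor compaction, protection update and reproduction-weight
    accumulation for the default production-cost form.

    Fills the first ``n_surv`` rows of capacity-sized output arrays and
    returns the sequential cumulative weight vector.  Arithmetic is
    statement-for-statement the scalar equivalent of the generic numpy path,
    so results are bit-identical.
    """
    n = traits.shape[0]
    out_traits = np.empty((capacity, 4))
    out_prot = np.empty(capacity)
    out_env = np.empty(capacity, np.int64)
    n_surv = 0
    for i in range(n):
        if alive[i]:
            n_surv += 1
    cum = np.empty(n_surv)
    acc = 0.0
    j = 0
    for i in range(n):
        if not alive[i]:
            continue
        b = traits[i, 0]
        inc = traits[i, 1]
        dec = traits[i, 2]
        p_old = prot[i]
        e = env[i]
        if any_alert and alert_env[e]:
            p = (p_old + inc) - dec
        else:
            p = p_old - dec
        if p < 0.0:
            p = 0.0
        elif p > 1.0:
            p = 1.0
        if p < b:
            p = b
        produced = p - p_old
        if produced < 0.0:
            produced = 0.0
        acc += 1.0 - produced
        cum[j] = acc
        out_traits[j, 0] = b
        out_traits[j, 1] = inc
        out_traits[j, 2] = dec
        out_traits[j, 3] = traits[i, 3]
        out_prot[j] = p
        out_env[j] = e
        j += 1
    return out_traits, out_prot, out_env, cum, n_surv


@njit(cache=True)
def _reproduce_fill(out_traits, out_prot, out_env, cum, n_surv, u_parent,
                    u_env, mode_code, n_envs, evolvable, uniform_fallback):
    """Sequential weighted reproduction into the tail of the output arrays.

    Parent lookup replicates ``np.searchsorted(cum, u*cum[-1], 'right')``;
    repeat-sampled parents divide sequentially from their reduced level, in
    draw order, with the Sterbenz-exact share split.
    """
    n_off = u_parent.size
    total = cum[n_surv - 1]
    for j in range(n_off):
        if uniform_fallback:
            x = u_parent[j] * n_surv
            pi = int(x)
        else:
            x = u_parent[j] * total
            lo = 0
            hi = n_surv
            while lo < hi:
                mid = (lo + hi) >> 1
                if cum[mid] <= x:
                    lo = mid + 1
                else:
                    hi = mid
            pi = lo
        if pi > n_surv - 1:
            pi = n_surv - 1
        m = out_traits[pi, 3] if evolvable else 0.5
        pp = out_prot[pi]
        d = m * pp if m > 0.5 else pp - (1.0 - m) * pp
        out_prot[pi] = pp - d
        k = n_surv + j
        out_traits[k, 0] = out_traits[pi, 0]
        out_traits[k, 1] = out_traits[pi, 1]
        out_traits[k, 2] = out_traits[pi, 2]
        out_traits[k, 3] = out_traits[pi, 3]
        out_prot[k] = d
        if mode_code == 0:
            e = out_env[pi]
        elif mode_code == 1:
            e = int(u_env[j] * n_envs)
            if e > n_envs - 1:
                e = n_envs - 1
        else:
            if n_envs == 2:
                e = 1 - out_env[pi]
            else:
                kk = int(u_env[j] * (n_envs - 1))
                if kk > n_envs - 2:
                    kk = n_envs - 2
                e = kk + (1 if kk >= out_env[pi] else 0)
        out_env[k] = e


@dataclass
class SimulationParams:
    """Everything needed to reproduce one simulation run.

    Defaults follow the reference experiment: 10'000 cells evolved for
    100'000 steps, 5% random kill, 0.1% mutation, protection split in half at
    division, convex (3/2-power) survival and production-cost reproduction
    weight.
    """

    capacity: int = 10_000
    n_steps: int = 100_000
    random_kill_rate: float = 0.05
    mutation_rate: float = 0.001
    mutation_kernel: str = "step"
    split_mode: str = "fixed_half"
    migration_mode: str | None = None  # None -> stay for 1 env, random otherwise
    env_params: EnvironmentParams = field(default_factory=EnvironmentParams)
    survival_form: str | object = "power15"
    cost_form: str | object = "production"
    seed: int = 0
    record_every: int = 100

    def __post_init__(self) -> None:
        if int(self.capacity) < 1:
            raise ParameterError(f"capacity={self.capacity} must be >= 1")
        if int(self.n_steps) < 1:
            raise ParameterError(f"n_steps={self.n_steps} must be >= 1")
        if int(self.record_every) < 1:
            raise ParameterError(f"record_every={self.record_every} must be >= 1")
        for name in ("random_kill_rate", "mutation_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ParameterError(f"{name}={v} must be a probability in [0, 1]")
        if self.split_mode not in ("fixed_half", "evolvable"):
            raise ParameterError(f"unknown split_mode {self.split_mode!r}")
        if self.mutation_kernel not in ("step", "resample"):
            raise ParameterError(
                f"unknown mutation_kernel {self.mutation_kernel!r}"
            )
        if self.migration_mode is not None and self.migration_mode not in MIGRATION_MODES:
            raise ParameterError(f"unknown migration_mode {self.migration_mode!r}")
        if (
            self.migration_mode == "always_leave"
            and self.env_params.n_envs < 2
        ):
            raise ParameterError("always_leave requires at least two environments")
        self.capacity = int(self.capacity)
        self.n_steps = int(self.n_steps)
        self.record_every = int(self.record_every)
        # fail fast on malformed functional forms
        resolve_survival_form(self.survival_form)
        resolve_cost_form(self.cost_form)

    @property
    def resolved_migration_mode(self) -> str:
        if self.migration_mode is not None:
            return self.migration_mode
        return "stay" if self.env_params.n_envs == 1 else "random"


@dataclass
class StepRecord:
    """Per-step summary written into the trajectory."""

    step: int
    size: int
    mean_basal: float
    mean_increase: float
    mean_decrease: float
    mean_memdist: float
    mean_protection: float
    env_states: tuple
    random_deaths: int
    stress_deaths: int
    births: int
    extinct: bool = False


@dataclass
class SimulationResult:
    """Trajectory, final snapshot and provenance of one run."""

    trajectory: pd.DataFrame
    final_population: Population
    params: SimulationParams
    extinct: bool
    steps_completed: int

    def final_trait_means(self) -> dict[str, float]:
        """Population-mean traits (and protection) of the final snapshot."""
        pop = self.final_population
        out = {
            name: float(pop.traits[:, j].mean())
            for j, name in enumerate(TRAIT_NAMES)
        }
        out["protection"] = float(pop.protection.mean())
        return out


def _make_record(
    t: int,
    pop: Population,
    states_t: np.ndarray,
    random_deaths: int,
    stress_deaths: int,
    births: int,
    extinct: bool = False,
) -> StepRecord:
    n = len(pop)
    if n:
        means = pop.traits.mean(axis=0)
        mp = float(pop.protection.mean())
    else:
        means = np.full(4, np.nan)
        mp = float("nan")
    return StepRecord(
        step=t,
        size=n,
        mean_basal=float(means[0]),
        mean_increase=float(means[1]),
        mean_decrease=float(means[2]),
        mean_memdist=float(means[3]),
        mean_protection=mp,
        env_states=tuple(int(s) for s in states_t),
        random_deaths=int(random_deaths),
        stress_deaths=int(stress_deaths),
        births=int(births),
        extinct=extinct,
    )


def step(
    pop: Population,
    env_set: EnvironmentSet,
    t: int,
    params: SimulationParams,
    rand_stream: UniformStream,
    record: bool = True,
) -> tuple[Population, StepRecord | None]:
    """Execute one life-cycle step; returns the new population and a record.

    The population object is not modified; a new one is returned.  On
    extinction the returned population is empty and the record is flagged.
    """
    n = len(pop)
    if n == 0:
        raise ExtinctionError("step() requires a non-empty population")
    if t >= env_set.n_steps:
        raise ParameterError(f"t={t} beyond environment length {env_set.n_steps}")
    # forms were grid-validated when params were built; just fetch them here
    survival = get_survival_form(params.survival_form)
    cost = get_cost_form(params.cost_form)
    states_t = env_set.state_matrix[:, t]

    # most steps are globally favorable; checking the n_envs-sized state
    # vector lets those steps skip the per-cell state gathers entirely
    any_stress = bool(np.any(states_t == int(EnvState.STRESS)))
    alert_env = (states_t == int(EnvState.WARNING)) | (
        states_t == int(EnvState.STRESS)
    )
    any_alert = bool(alert_env.any())

    # (a) random kill
    u_kill = rand_stream.uniform(n)
    alive = u_kill >= params.random_kill_rate
    random_deaths = int(n - alive.sum())

    # (b) protection-dependent stress kill
    stress_deaths = 0
    if any_stress:
        cell_state = states_t[pop.env_index]
        stressed = np.flatnonzero(alive & (cell_state == int(EnvState.STRESS)))
        if stressed.size:
            u_stress = rand_stream.uniform(stressed.size)
            dies = u_stress >= survival(pop.protection[stressed])
            alive[stressed[dies]] = False
            stress_deaths = int(dies.sum())

    if not alive.any():
        empty = Population(
            np.empty((0, 4)), np.empty(0), np.empty(0, dtype=np.int64),
            params.capacity,
        )
        rec = _make_record(t, empty, states_t, random_deaths, stress_deaths, 0, True)
        return empty, rec

    # fused fast path for the default production-cost form; bit-identical to
    # the generic path below (the oracle-equivalence tests pin this down)
    if params.cost_form == "production":
        out_traits, out_prot, out_env, cum, n_surv = _compact_update_weights(
            pop.traits, pop.protection, pop.env_index, alive,
            alert_env, any_alert, params.capacity,
        )
        n_off = params.capacity - n_surv
        births = n_off
        if n_off > 0:
            mode = params.resolved_migration_mode
            n_envs = env_set.n_envs
            u_parent = np.atleast_1d(rand_stream.uniform(n_off))
            if mode == "random" or (mode == "always_leave" and n_envs > 2):
                u_env = np.atleast_1d(rand_stream.uniform(n_off))
            else:
                u_env = np.empty(0)
            _reproduce_fill(
                out_traits, out_prot, out_env, cum, n_surv, u_parent, u_env,
                _MODE_CODES[mode], n_envs,
                params.split_mode == "evolvable",
                bool(cum[n_surv - 1] <= 0.0),
            )
        new_pop = Population(out_traits, out_prot, out_env, params.capacity)
        mutate_population(
            new_pop, params.mutation_rate, rand_stream,
            kernel=params.mutation_kernel,
        )
        rec = None
        if record:
            rec = _make_record(
                t, new_pop, states_t, random_deaths, stress_deaths, births
            )
        return new_pop, rec

    # compact to survivors, preserving order (boolean indexing copies)
    traits = pop.traits[alive]
    prot_old = pop.protection[alive]
    env = pop.env_index[alive]
    n_surv = traits.shape[0]

    # (c) protection update (alert=False adds an exact 0, so skipping the
    # increase term on globally favorable steps is bit-identical)
    alert = alert_env[env] if any_alert else False
    prot = update_protection_arrays(
        prot_old, traits[:, 0], traits[:, 1], traits[:, 2], alert
    )
    produced = np.maximum(prot - prot_old, 0.0)

    # (d) reproduction back to capacity
    n_off = params.capacity - n_surv
    births = n_off
    if n_off > 0:
        w = np.asarray(cost(prot, produced), dtype=float)
        total = w.sum()
        if total <= 0.0:
            w = np.ones(n_surv)
            total = float(n_surv)
        cum = np.cumsum(w)
        u_parent = rand_stream.uniform(n_off)
        parent = np.searchsorted(cum, u_parent * cum[-1], side="right")
        parent = np.minimum(parent, n_surv - 1)

        mode = params.resolved_migration_mode
        n_envs = env_set.n_envs
        if mode == "random":
            u_env = rand_stream.uniform(n_off)
            d_env = np.minimum((u_env * n_envs).astype(np.int64), n_envs - 1)
        elif mode == "always_leave":
            if n_envs == 2:
                d_env = 1 - env[parent]
            else:
                u_env = rand_stream.uniform(n_off)
                k = np.minimum(
                    (u_env * (n_envs - 1)).astype(np.int64), n_envs - 2
                )
                d_env = k + (k >= env[parent])
        else:  # stay / always_stay
            d_env = env[parent].copy()

        if params.split_mode == "fixed_half":
            m = np.full(n_off, 0.5)
        else:
            m = traits[parent, MEMDIST]

        # sequential division: a parent sampled repeatedly divides from its
        # already-reduced protection.  Parents sampled once take the
        # vectorized path; repeat-sampled parents loop over their draws in
        # order — identical arithmetic either way (see split_daughter_share).
        d_prot = np.empty(n_off)
        counts = np.bincount(parent, minlength=n_surv)
        once = counts[parent] == 1
        idx_once = parent[once]
        d = split_daughter_share(prot[idx_once], m[once])
        d_prot[once] = d
        prot[idx_once] = prot[idx_once] - d
        for j in np.flatnonzero(~once):
            # scalar float arithmetic, identical to split_daughter_share
            pi = parent[j]
            mj = float(m[j])
            pp = float(prot[pi])
            dj = mj * pp if mj > 0.5 else pp - (1.0 - mj) * pp
            d_prot[j] = dj
            prot[pi] = pp - dj

        new_traits = np.concatenate([traits, traits[parent]], axis=0)
        new_prot = np.concatenate([prot, d_prot])
        new_env = np.concatenate([env, d_env])
    else:
        new_traits, new_prot, new_env = traits, prot, env

    new_pop = Population(new_traits, new_prot, new_env, params.capacity)

    # (e) mutation
    mutate_population(
        new_pop, params.mutation_rate, rand_stream,
        kernel=params.mutation_kernel,
    )

    rec = None
    if record:
        rec = _make_record(
            t, new_pop, states_t, random_deaths, stress_deaths, births
        )
    return new_pop, rec


def run_simulation(params: SimulationParams) -> SimulationResult:
    """Generate environments, initialize a population and iterate ``step``.

    Deterministic given ``params.seed``: three independent streams are derived
    from it for the environment set, the initialization and the per-step loop,
    so the environment realization does not depend on population-level
    branching.  The trajectory records every ``record_every``-th step plus the
    final one; the final population snapshot is kept at full resolution.
    """
    env_seed, init_seed, loop_seed = derive_seeds(params.seed, 3)
    env_params = with_n_steps(params.env_params, params.n_steps)
    env_set = make_environment_set(env_params, env_seed)
    pop = init_population(params.capacity, env_params.n_envs, RandomStream(init_seed))
    stream = RandomStream(loop_seed)

    records: list[StepRecord] = []
    extinct = False
    steps_completed = 0
    for t in range(params.n_steps):
        want = (t % params.record_every == 0) or (t == params.n_steps - 1)
        pop, rec = step(pop, env_set, t, params, stream, record=want)
        steps_completed = t + 1
        if len(pop) == 0:
            extinct = True
            if rec is not None:
                records.append(rec)
            break
        if rec is not None:
            records.append(rec)

    trajectory = pd.DataFrame([r.__dict__ for r in records])
    return SimulationResult(
        trajectory=trajectory,
        final_population=pop,
        params=params,
        extinct=extinct,
        steps_completed=steps_completed,
    )


def params_with(params: SimulationParams, **updates) -> SimulationParams:
    """Copy of ``params`` with updates; env_* keys go to the nested
    EnvironmentParams."""
    env_keys = {
        k: v
        for k, v in updates.items()
        if k in ("regime", "p_warning", "p_stress", "p_follow", "switch_rate", "n_envs")
    }
    sim_keys = {k: v for k, v in updates.items() if k not in env_keys}
    env_params = (
        replace(params.env_params, **env_keys) if env_keys else params.env_params
    )
    return replace(params, env_params=env_params, **sim_keys)
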