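"""Independent scalar reference implementation of one life-cycle step.

This is a deliberately plain, loop-based re-implementation of the per-step
rules (random kill, protection-dependent stress kill, protection update,
weighted reproduction with sequential division, mutation), consuming uniform
variates from a recorded list in the documented order.  It shares no code
with the vectorized implementation; tests assert bit-exact agreement on tiny
populations.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass
class OCell:
    basal: float
    increase: float
    decrease: float
    memdist: float
    protection: float
    env: int


@dataclass
class Draws:
    values: list
    cursor: int = 0

    def take(self) -> float:
        v = self.values[self.cursor]
        self.cursor += 1
        return v


@dataclass
class OStepOutcome:
    cells: list = field(default_factory=list)
    random_deaths: int = 0
    stress_deaths: int = 0
    births: int = 0
    extinct: bool = False


FAVORABLE, WARNING, STRESS = 0, 1, 2


def daughter_share(p: float, m: float) -> float:
    # larger share by multiplication, smaller as exact remainder
    if m > 0.5:
        return m * p
    return p - (1.0 - m) * p


def mutate_value(old: float, u: float, kernel: str) -> float:
    if kernel == "resample":
        return u
    x = abs(old + 0.2 * (2.0 * u - 1.0))
    return 2.0 - x if x > 1.0 else x


def oracle_step(
    cells: list[OCell],
    states_t: list[int],
    capacity: int,
    kill_rate: float,
    mutation_rate: float,
    draws: Draws,
    split_mode: str = "fixed_half",
    migration_mode: str = "stay",
    n_envs: int = 1,
    survival=lambda p: p,
    cost=lambda p, produced: 1.0 - produced,
    mutation_kernel: str = "step",
) -> OStepOutcome:
    out = OStepOutcome()

    # (a) random kill, one uniform per cell in order
    alive = []
    for _ in cells:
        u = draws.take()
        alive.append(u >= kill_rate)
    out.random_deaths = alive.count(False)

    # (b) stress kill, one uniform per surviving stressed cell in order
    for i, c in enumerate(cells):
        if alive[i] and states_t[c.env] == STRESS:
            u = draws.take()
            if not (u < survival(c.protection)):
                alive[i] = False
                out.stress_deaths += 1

    survivors = [
        OCell(c.basal, c.increase, c.decrease, c.memdist, c.protection, c.env)
        for i, c in enumerate(cells)
        if alive[i]
    ]
    if not survivors:
        out.extinct = True
        return out

    # (c) protection update
    produced = []
    for c in survivors:
        old = c.protection
        alert = states_t[c.env] in (WARNING, STRESS)
        p = old + (c.increase if alert else 0.0) - c.decrease
        p = min(max(p, 0.0), 1.0)
        p = max(p, c.basal)
        c.protection = p
        produced.append(max(p - old, 0.0))

    # (d) reproduction back to capacity
    n_off = capacity - len(survivors)
    out.births = n_off
    daughters: list[OCell] = []
    if n_off > 0:
        weights = [cost(c.protection, q) for c, q in zip(survivors, produced)]
        total = sum(weights)
        if total <= 0.0:
            weights = [1.0] * len(survivors)
            total = float(len(survivors))
        cum = []
        acc = 0.0
        for w in weights:
            acc += w
            cum.append(acc)
        u_parents = [draws.take() for _ in range(n_off)]
        if migration_mode == "random":
            u_envs = [draws.take() for _ in range(n_off)]
        elif migration_mode == "always_leave" and n_envs > 2:
            u_envs = [draws.take() for _ in range(n_off)]
        else:
            u_envs = [None] * n_off
        for j in range(n_off):
            x = u_parents[j] * cum[-1]
            pi = 0
            while pi < len(cum) and cum[pi] <= x:
                pi += 1
            pi = min(pi, len(survivors) - 1)
            parent = survivors[pi]
            m = 0.5 if split_mode == "fixed_half" else parent.memdist
            d = daughter_share(parent.protection, m)
            parent.protection = parent.protection - d
            if migration_mode == "random":
                env = min(int(u_envs[j] * n_envs), n_envs - 1)
            elif migration_mode == "always_leave":
                if n_envs == 2:
                    env = 1 - parent.env
                else:
                    k = min(int(u_envs[j] * (n_envs - 1)), n_envs - 2)
                    env = k + (1 if k >= parent.env else 0)
            else:  # stay / always_stay
                env = parent.env
            daughters.append(
                OCell(
                    parent.basal, parent.increase, parent.decrease,
                    parent.memdist, d, env,
                )
            )

    new_cells = survivors + daughters

    # (e) mutation: all decision draws, then all trait draws, then all values
    decisions = [draws.take() for _ in new_cells]
    mutants = [i for i, u in enumerate(decisions) if u < mutation_rate]
    trait_draws = [draws.take() for _ in mutants]
    value_draws = [draws.take() for _ in mutants]
    for i, ut, uv in zip(mutants, trait_draws, value_draws):
        trait = min(int(ut * 4), 3)
        c = new_cells[i]
        if trait == 0:
            c.basal = mutate_value(c.basal, uv, mutation_kernel)
        elif trait == 1:
            c.increase = mutate_value(c.increase, uv, mutation_kernel)
        elif trait == 2:
            c.decrease = mutate_value(c.decrease, uv, mutation_kernel)
        else:
            c.memdist = mutate_value(c.memdist, uv, mutation_kernel)

    out.cells = new_cells
    return out
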