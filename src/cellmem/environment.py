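"""Stochastic favorable / warning / stress environments.

An environment is a time-ordered sequence of one-step periods, each in one of
three states: FAVORABLE, WARNING (a sub-lethal cue) or STRESS (a lethal
challenge whose mortality depends on a cell's protection level).  Two regimes
are supported:

noninformative
    Warnings and stresses fire independently at per-step probabilities
    ``p_warning`` (default 0.5%) and ``p_stress`` (default 0.4%), except that
    a warning may never immediately follow a stress nor vice versa; the
    disallowed successor's probability mass falls back to FAVORABLE, which
    keeps the marginal event rates close to nominal.  A warning carries no
    information about future stress.

informative
    Warnings fire at ``p_warning``; each warning schedules a stress with
    probability ``p_follow`` (default 80%).  While a stress is pending the
    visible state is FAVORABLE and each step switches to STRESS with
    probability ``switch_rate`` (default 0.2), i.e. the warning-to-stress
    delay is geometric with mean ``1/switch_rate`` = 5 steps — the
    discrete-time analog of an exponential delay with rate 0.2.  No new
    warning fires while a stress is pending, so each warning is paired with
    at most one stress.  With the defaults the marginal stress rate is
    ~0.8 x 0.5% = 0.4%, matching the noninformative regime.

Stream discipline (relevant for recorded-stream tests): the noninformative
generator consumes exactly one uniform per step; the informative generator
consumes one uniform per step plus one extra uniform on each WARNING step
(the stress-scheduling draw).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from enum import IntEnum
from pathlib import Path

import numpy as np

from .errors import ParameterError
from .streams import RandomStream, UniformStream, derive_seeds

__all__ = [
    "EnvState",
    "EnvironmentParams",
    "EnvironmentSequence",
    "EnvironmentSet",
    "EnvironmentSummary",
    "generate_noninformative",
    "generate_informative",
    "generate_sequence",
    "make_environment_set",
    "empirical_summary",
]

REGIMES = ("noninformative", "informative")


class EnvState(IntEnum):
    """One-step environmental state."""

    FAVORABLE = 0
    WARNING = 1
    STRESS = 2


#: single-letter codes used in delimited-text export
STATE_CODES = {EnvState.FAVORABLE: "F", EnvState.WARNING: "W", EnvState.STRESS: "S"}
CODE_STATES = {v: k for k, v in STATE_CODES.items()}


@dataclass
class EnvironmentParams:
    """Parameters of one environment regime.

    Parameters
    ----------
    regime:
        ``"noninformative"`` or ``"informative"``.
    p_warning:
        Per-step probability of a warning period (both regimes).
    p_stress:
        Per-step probability of a stress period (noninformative regime only;
        in the informative regime stresses arise only from warnings).
    p_follow:
        Probability that a warning schedules a stress (informative only).
    switch_rate:
        Per-step probability that a pending stress fires (informative only);
        the geometric-delay analog of an exponential rate.
    n_steps, n_envs:
        Sequence length and number of mutually independent environments.
    """

    regime: str = "noninformative"
    p_warning: float = 0.005
    p_stress: float = 0.004
    p_follow: float = 0.8
    switch_rate: float = 0.2
    n_steps: int = 100_000
    n_envs: int = 1

    def __post_init__(self) -> None:
        if self.regime not in REGIMES:
            raise ParameterError(f"unknown regime {self.regime!r}; use one of {REGIMES}")
        for name in ("p_warning", "p_stress", "p_follow", "switch_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ParameterError(f"{name}={v} must be a probability in [0, 1]")
        if self.p_warning + self.p_stress > 1.0:
            raise ParameterError(
                f"p_warning + p_stress = {self.p_warning + self.p_stress} exceeds 1"
            )
        if int(self.n_steps) < 1:
            raise ParameterError(f"n_steps={self.n_steps} must be >= 1")
        if int(self.n_envs) < 1:
            raise ParameterError(f"n_envs={self.n_envs} must be >= 1")
        self.n_steps = int(self.n_steps)
        self.n_envs = int(self.n_envs)

    def to_dict(self) -> dict:
        return {
            "regime": self.regime,
            "p_warning": self.p_warning,
            "p_stress": self.p_stress,
            "p_follow": self.p_follow,
            "switch_rate": self.switch_rate,
            "n_steps": self.n_steps,
            "n_envs": self.n_envs,
        }


@dataclass
class EnvironmentSequence:
    """A realized state sequence plus the parameters and seed that made it."""

    states: np.ndarray  # int8 array of EnvState values, length n_steps
    params: EnvironmentParams
    seed: int | None = None

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=np.int8)
        if self.states.ndim != 1:
            raise ParameterError("states must be one-dimensional")

    def __len__(self) -> int:
        return int(self.states.size)

    # -- delimited-text round trip -------------------------------------
    def to_csv(self, path, sidecar: bool = True) -> None:
        """Write ``step,state`` rows (F/W/S codes) plus a JSON sidecar."""
        path = Path(path)
        codes = np.array(["F", "W", "S"])
        with open(path, "w") as fh:
            fh.write("step,state\n")
            for t, s in enumerate(codes[self.states]):
                fh.write(f"{t},{s}\n")
        if sidecar:
            meta = {"params": self.params.to_dict(), "seed": self.seed}
            Path(str(path) + ".json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def from_csv(cls, path) -> "EnvironmentSequence":
        path = Path(path)
        lines = path.read_text().strip().splitlines()[1:]
        states = np.array(
            [int(CODE_STATES[row.split(",")[1]]) for row in lines], dtype=np.int8
        )
        sidecar = Path(str(path) + ".json")
        params, seed = None, None
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
            params = EnvironmentParams(**meta["params"])
            seed = meta["seed"]
        if params is None:
            params = EnvironmentParams(n_steps=len(states))
        return cls(states=states, params=params, seed=seed)


@dataclass
class EnvironmentSet:
    """``n_envs`` mutually independent environment sequences."""

    sequences: list[EnvironmentSequence]
    seeds: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.sequences:
            raise ParameterError("environment set needs at least one sequence")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) != 1:
            raise ParameterError("all sequences in a set must have equal length")
        self._matrix: np.ndarray | None = None

    @property
    def n_envs(self) -> int:
        return len(self.sequences)

    @property
    def n_steps(self) -> int:
        return len(self.sequences[0])

    @property
    def state_matrix(self) -> np.ndarray:
        """(n_envs, n_steps) int8 matrix of states, built lazily."""
        if self._matrix is None:
            self._matrix = np.stack([s.states for s in self.sequences])
        return self._matrix


def generate_noninformative(
    params: EnvironmentParams, rand_stream: UniformStream, seed: int | None = None
) -> EnvironmentSequence:
    """Generate a noninformative sequence (independent warnings and stresses).

    One uniform ``u`` is consumed per step: ``u < p_warning`` proposes
    WARNING, ``p_warning <= u < p_warning + p_stress`` proposes STRESS,
    otherwise FAVORABLE.  A proposal adjacent to its forbidden predecessor
    (stress after warning or warning after stress) collapses to FAVORABLE.
    """
    if params.regime != "noninformative":
        raise ParameterError("generate_noninformative requires regime='noninformative'")
    pw, ps = params.p_warning, params.p_stress
    states = np.empty(params.n_steps, dtype=np.int8)
    prev = EnvState.FAVORABLE
    for t in range(params.n_steps):
        u = rand_stream.uniform()
        if u < pw:
            s = EnvState.WARNING if prev != EnvState.STRESS else EnvState.FAVORABLE
        elif u < pw + ps:
            s = EnvState.STRESS if prev != EnvState.WARNING else EnvState.FAVORABLE
        else:
            s = EnvState.FAVORABLE
        states[t] = s
        prev = s
    return EnvironmentSequence(states=states, params=params, seed=seed)


def generate_informative(
    params: EnvironmentParams, rand_stream: UniformStream, seed: int | None = None
) -> EnvironmentSequence:
    """Generate an informative sequence (warnings predict stress).

    Stream discipline: one uniform per step; on a WARNING step one extra
    uniform decides whether a stress becomes pending.
    """
    if params.regime != "informative":
        raise ParameterError("generate_informative requires regime='informative'")
    pw, pf, sw = params.p_warning, params.p_follow, params.switch_rate
    states = np.empty(params.n_steps, dtype=np.int8)
    pending = False
    for t in range(params.n_steps):
        u = rand_stream.uniform()
        if pending:
            if u < sw:
                s = EnvState.STRESS
                pending = False
            else:
                s = EnvState.FAVORABLE
        elif u < pw:
            s = EnvState.WARNING
            if rand_stream.uniform() < pf:
                pending = True
        else:
            s = EnvState.FAVORABLE
        states[t] = s
    return EnvironmentSequence(states=states, params=params, seed=seed)


def generate_sequence(params: EnvironmentParams, seed: int) -> EnvironmentSequence:
    """Generate one sequence of the regime named in ``params`` from a seed."""
    stream = RandomStream(seed)
    if params.regime == "noninformative":
        return generate_noninformative(params, stream, seed=seed)
    return generate_informative(params, stream, seed=seed)


def make_environment_set(params: EnvironmentParams, base_seed: int) -> EnvironmentSet:
    """Build ``params.n_envs`` independent sequences.

    Each sequence gets its own stream, deterministically derived from
    ``base_seed``, so sequences are correlated within themselves (in the
    informative regime) but not between each other.
    """
    seeds = derive_seeds(base_seed, params.n_envs)
    sequences = [generate_sequence(params, s) for s in seeds]
    return EnvironmentSet(sequences=sequences, seeds=seeds)


@dataclass
class EnvironmentSummary:
    """Empirical statistics of one sequence.

    ``stress_after_warning`` is the fraction of warnings followed by a stress
    before the next warning (``None`` when no warning has a defined successor
    window); ``delays`` holds the warning-to-stress distances in steps for the
    successful pairs.
    """

    n_steps: int
    frequencies: dict[str, float]
    n_warnings: int
    stress_after_warning: float | None
    delays: np.ndarray
    mean_delay: float | None


def empirical_summary(seq: EnvironmentSequence) -> EnvironmentSummary:
    """Summarize state frequencies and warning→stress coupling of a sequence.

    A warning's successor window runs to the next warning (or the end of the
    sequence).  The trailing warning counts only if a stress occurs in its
    window; otherwise its outcome is censored and it is excluded from the
    conditional fraction rather than counted as a failure.
    """
    states = seq.states
    n = states.size
    if n == 0:
        raise ParameterError("empirical_summary requires a non-empty sequence")
    freqs = {
        "favorable": float(np.mean(states == EnvState.FAVORABLE)),
        "warning": float(np.mean(states == EnvState.WARNING)),
        "stress": float(np.mean(states == EnvState.STRESS)),
    }
    warn_idx = np.flatnonzero(states == EnvState.WARNING)
    stress_idx = np.flatnonzero(states == EnvState.STRESS)
    successes = 0
    evaluated = 0
    delays: list[int] = []
    for i, w in enumerate(warn_idx):
        end = warn_idx[i + 1] if i + 1 < warn_idx.size else n
        pos = np.searchsorted(stress_idx, w + 1)
        hit = pos < stress_idx.size and stress_idx[pos] < end
        censored = (i + 1 == warn_idx.size) and not hit
        if censored:
            continue
        evaluated += 1
        if hit:
            successes += 1
            delays.append(int(stress_idx[pos] - w))
    frac = successes / evaluated if evaluated else None
    delays_arr = np.asarray(delays, dtype=int)
    mean_delay = float(delays_arr.mean()) if delays_arr.size else None
    return EnvironmentSummary(
        n_steps=n,
        frequencies=freqs,
        n_warnings=int(warn_idx.size),
        stress_after_warning=frac,
        delays=delays_arr,
        mean_delay=mean_delay,
    )


def with_n_steps(params: EnvironmentParams, n_steps: int) -> EnvironmentParams:
    """Copy of ``params`` with a different sequence length."""
    return replace(params, n_steps=int(n_steps))
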