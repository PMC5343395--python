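"""Replicate-level experiments and summary statistics.

The headline quantities of a simulation campaign are, per evolvable trait:

* a trajectory envelope — the min / median / max of the per-run population
  mean at every recorded step across replicates;
* per-replicate final population means, their grand mean and standard error
  (standard deviation of the replicate means over sqrt(n_replicates));
* pooled final trait distributions, and a bimodality classification of
  replicate means into low / intermediate / high (used for traits like the
  memory distribution factor that evolve to an extreme per population without
  converging across populations).

A one-at-a-time sensitivity sweep reruns the base experiment changing a
single parameter per cell.

Two named experiment profiles are shipped: ``full`` is the reference scale
(10'000 cells, 100'000 steps, 20 replicates); ``desk`` keeps the full
population size — selection on the evolvable traits is weak relative to drift
in much smaller populations — but stops at 60'000 steps with 5 replicates,
which is past the horizon where the trait trajectories settle.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError, ParameterError
from .evolution import SimulationParams, SimulationResult, params_with, run_simulation
from .population import TRAIT_NAMES
from .streams import derive_seeds

__all__ = [
    "PROFILES",
    "ReplicateSummary",
    "BimodalityReport",
    "SweepSpec",
    "run_replicates",
    "bimodality_report",
    "run_sweep",
    "write_summary",
]

SUMMARY_COLUMNS = tuple(TRAIT_NAMES) + ("protection",)

PROFILES = {
    "desk": {"capacity": 10_000, "n_steps": 60_000, "n_replicates": 5,
             "record_every": 500},
    "full": {"capacity": 10_000, "n_steps": 100_000, "n_replicates": 20,
             "record_every": 100},
}


@dataclass
class ReplicateSummary:
    """Cross-replicate summary of one experiment."""

    params: SimulationParams
    seeds: list[int]
    n_replicates: int
    n_extinct: int
    envelope: pd.DataFrame          # step, trait, min, median, max
    trajectories: pd.DataFrame      # step, replicate, trait, mean
    final_means: pd.DataFrame       # one row per surviving replicate
    grand_means: dict[str, float]
    standard_errors: dict[str, float]
    final_populations: list[pd.DataFrame] = field(default_factory=list)


def run_replicates(
    params: SimulationParams,
    n_replicates: int = 20,
    base_seed: int | None = None,
    keep_final_populations: bool = True,
) -> ReplicateSummary:
    """Run ``n_replicates`` independent simulations and summarize them.

    Replicate seeds derive deterministically from ``base_seed`` (default:
    ``params.seed``).  Extinct replicates are excluded from every summary and
    counted in ``n_extinct``.
    """
    if n_replicates < 1:
        raise ParameterError(f"n_replicates={n_replicates} must be >= 1")
    if base_seed is None:
        base_seed = params.seed
    seeds = derive_seeds(base_seed, n_replicates)

    results: list[SimulationResult] = []
    for s in seeds:
        results.append(run_simulation(params_with(params, seed=s)))

    survived = [(i, r) for i, r in enumerate(results) if not r.extinct]
    n_extinct = n_replicates - len(survived)

    traj_rows = []
    final_rows = []
    finals = []
    trait_cols = {
        "basal": "mean_basal",
        "increase": "mean_increase",
        "decrease": "mean_decrease",
        "memdist": "mean_memdist",
        "protection": "mean_protection",
    }
    for i, r in survived:
        for trait, col in trait_cols.items():
            traj_rows.append(
                pd.DataFrame(
                    {
                        "step": r.trajectory["step"],
                        "replicate": i,
                        "trait": trait,
                        "mean": r.trajectory[col],
                    }
                )
            )
        fm = r.final_trait_means()
        fm["replicate"] = i
        final_rows.append(fm)
        if keep_final_populations:
            finals.append(r.final_population.to_frame())

    trajectories = (
        pd.concat(traj_rows, ignore_index=True)
        if traj_rows
        else pd.DataFrame(columns=["step", "replicate", "trait", "mean"])
    )
    if not trajectories.empty:
        envelope = (
            trajectories.groupby(["step", "trait"])["mean"]
            .agg(["min", "median", "max"])
            .reset_index()
        )
    else:
        envelope = pd.DataFrame(columns=["step", "trait", "min", "median", "max"])

    final_means = pd.DataFrame(final_rows)
    grand, ses = {}, {}
    for col in SUMMARY_COLUMNS:
        if final_means.empty:
            grand[col], ses[col] = float("nan"), float("nan")
            continue
        vals = final_means[col].to_numpy(dtype=float)
        grand[col] = float(vals.mean())
        ses[col] = (
            float(vals.std(ddof=1) / np.sqrt(vals.size)) if vals.size > 1 else float("nan")
        )

    return ReplicateSummary(
        params=params,
        seeds=seeds,
        n_replicates=n_replicates,
        n_extinct=n_extinct,
        envelope=envelope,
        trajectories=trajectories,
        final_means=final_means,
        grand_means=grand,
        standard_errors=ses,
        final_populations=finals,
    )


@dataclass
class BimodalityReport:
    """Classification of replicate means into low / intermediate / high."""

    trait: str
    low_cut: float
    high_cut: float
    classifications: list[str]
    counts: dict[str, int]

    @property
    def majority_extreme(self) -> bool:
        extreme = self.counts["low"] + self.counts["high"]
        return extreme > len(self.classifications) / 2


def bimodality_report(
    summary: ReplicateSummary,
    trait: str = "memdist",
    low_cut: float = 0.2,
    high_cut: float = 0.8,
) -> BimodalityReport:
    """Classify each replicate by its final population-mean trait value."""
    if not (0.0 < low_cut < high_cut < 1.0):
        raise ParameterError(
            f"cuts must satisfy 0 < low_cut < high_cut < 1, got {low_cut}, {high_cut}"
        )
    if trait not in SUMMARY_COLUMNS:
        raise ParameterError(f"unknown trait {trait!r}")
    vals = summary.final_means[trait].to_numpy(dtype=float)
    classes = [
        "low" if v < low_cut else "high" if v > high_cut else "intermediate"
        for v in vals
    ]
    counts = {c: classes.count(c) for c in ("low", "intermediate", "high")}
    return BimodalityReport(
        trait=trait,
        low_cut=low_cut,
        high_cut=high_cut,
        classifications=classes,
        counts=counts,
    )


# ---------------------------------------------------------------------------
# one-at-a-time sensitivity sweep
# ---------------------------------------------------------------------------

#: accepted axis names -> canonical parameter keys understood by params_with
PARAMETER_ALIASES = {
    "random_kill_rate": "random_kill_rate",
    "rndKill": "random_kill_rate",
    "mutation_rate": "mutation_rate",
    "mutRate": "mutation_rate",
    "mutation_kernel": "mutation_kernel",
    "switch_rate": "switch_rate",
    "lambda": "switch_rate",
    "n_envs": "n_envs",
    "numEnv": "n_envs",
    "migration_mode": "migration_mode",
    "split_mode": "split_mode",
    "p_warning": "p_warning",
    "p_stress": "p_stress",
    "p_follow": "p_follow",
    "capacity": "capacity",
    "n_steps": "n_steps",
    "regime": "regime",
}


@dataclass
class SweepSpec:
    """One-at-a-time sweep: each axis varies a single parameter off ``base``."""

    base: SimulationParams
    axes: list[tuple[str, list]] = field(default_factory=list)
    n_replicates: int = 5
    base_seed: int = 0

    def __post_init__(self) -> None:
        for name, values in self.axes:
            if name not in PARAMETER_ALIASES:
                raise ConfigError(
                    f"unknown sweep parameter {name!r}; "
                    f"known: {sorted(PARAMETER_ALIASES)}"
                )
            if not list(values):
                raise ConfigError(f"sweep axis {name!r} has no values")


def run_sweep(spec: SweepSpec) -> pd.DataFrame:
    """Run the base cell plus one cell per (parameter, value).

    Returns a long table with one row per (parameter, value, trait) holding
    the grand mean and standard error across replicates, plus the extinction
    count and the cell's seed so any cell can be rerun independently.
    """
    cells: list[tuple[str, object, SimulationParams]] = [("base", "", spec.base)]
    for name, values in spec.axes:
        key = PARAMETER_ALIASES[name]
        for v in values:
            cells.append((name, v, params_with(spec.base, **{key: v})))

    cell_seeds = derive_seeds(spec.base_seed, len(cells))
    rows = []
    for (name, value, params), seed in zip(cells, cell_seeds):
        summary = run_replicates(
            params, spec.n_replicates, base_seed=seed, keep_final_populations=False
        )
        for trait in SUMMARY_COLUMNS:
            rows.append(
                {
                    "parameter": name,
                    "value": value,
                    "trait": trait,
                    "mean": summary.grand_means[trait],
                    "se": summary.standard_errors[trait],
                    "n_extinct": summary.n_extinct,
                    "cell_seed": seed,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# output writers
# ---------------------------------------------------------------------------

def write_summary(summary: ReplicateSummary, outdir) -> dict[str, Path]:
    """Write trajectories.csv, envelope.csv, final_traits.csv, summary.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    paths["trajectories"] = outdir / "trajectories.csv"
    summary.trajectories.to_csv(paths["trajectories"], index=False)

    paths["envelope"] = outdir / "envelope.csv"
    summary.envelope.to_csv(paths["envelope"], index=False)

    paths["final_traits"] = outdir / "final_traits.csv"
    if summary.final_populations:
        frames = []
        for rep, df in zip(summary.final_means["replicate"], summary.final_populations):
            df = df.copy()
            df.insert(0, "cell", np.arange(len(df)))
            df.insert(0, "replicate", rep)
            frames.append(df)
        pd.concat(frames, ignore_index=True).to_csv(paths["final_traits"], index=False)
    else:
        summary.final_means.to_csv(paths["final_traits"], index=False)

    paths["summary"] = outdir / "summary.json"
    payload = {
        "n_replicates": summary.n_replicates,
        "n_extinct": summary.n_extinct,
        "seeds": summary.seeds,
        "grand_means": summary.grand_means,
        "standard_errors": summary.standard_errors,
        "final_means": summary.final_means.to_dict(orient="records"),
    }
    paths["summary"].write_text(json.dumps(payload, indent=2))
    return paths
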