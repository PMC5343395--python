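# Methods

## Model overview

`cellmem` is a discrete-time, individual-based model of a bacterial
population evolving under stochastic stress.  A cell is a protection level
`p ∈ [0,1]` (phenotype; the cell's memory state), four heritable traits
(`basal`, `increase`, `decrease`, `memdist`, each in `[0,1]`), and an index
into a set of environments.  The population lives at a hard carrying
capacity (default 10 000 cells): deaths free room, reproduction refills it
exactly, so generations overlap and selection acts through both differential
death and differential recruitment into freed slots.

### Environments

Environments are i.i.d.-seeded sequences of one-step periods in three
states.  Two regimes:

* **noninformative** — per step, warning with probability `p_warning`
  (default 0.005) and stress with `p_stress` (0.004), independent, except
  that warning and stress may not be adjacent in either order (the
  disallowed successor's probability mass collapses to favorable, which
  preserves the marginal rates to within ~0.5 % relative).
* **informative** — warnings fire at `p_warning`; each schedules a stress
  with probability `p_follow` (0.8).  While a stress is pending the visible
  state is favorable and the stress fires per step with probability
  `switch_rate` (0.2): a geometric delay with mean 5 steps, the discrete
  analog of an exponential delay with rate 0.2.  No new warning fires while
  a stress is pending, so warnings pair with at most one stress.  Marginal
  stress frequency is then 0.8 × 0.5 % ≈ 0.4 %, matching the noninformative
  regime, so the two regimes differ only in the *order* of events, i.e. in
  the information a warning carries.

Each period occupies exactly one time step — the simplest reading of the
point-event pictures the regimes are drawn from.  With several environments
(`n_envs` > 1) each sequence comes from an independently derived stream, so
periods are correlated within but not between environments.

### Life cycle (one step, in order)

1. random kill with probability `random_kill_rate` (0.05);
2. protection-dependent stress kill, survival `s(p)`;
3. protection update
   `p ← max(basal, clamp₀¹(p + increase·alert − decrease))`, where `alert`
   is true on warning and stress steps.  Increase and decrease apply in the
   same step (the decay also runs during alerts); the basal floor applies
   every step, so after a division that halves `p`, a high-basal cell
   regenerates — and pays for — `basal − p` of protection;
4. reproduction to capacity: parents sampled with replacement with
   probability ∝ `w(p, produced)`; weights are computed once from the
   post-update state.  Each sampled parent divides; a parent sampled `k`
   times divides sequentially from its already-reduced level.  The daughter
   receives the share `m·p` (`m = 0.5` under the fixed split, the parent's
   `memdist` under the evolvable split), the mother keeps the remainder and
   stays in her environment; the daughter's environment follows the
   migration mode (`stay`, `random` = uniform over all environments, which
   generalizes the 50 % leave-chance of the two-environment case,
   `always_leave`, `always_stay`).  If every weight is zero, sampling is
   uniform;
5. mutation: each cell with probability `mutation_rate` (0.001) has one of
   its four traits, chosen uniformly, perturbed.  The default kernel is a
   **local step**: the trait moves by a uniform step in `[-0.2, 0.2]`,
   reflected at the boundaries, so mutations have small effect and adaptation
   proceeds as a hill-climbing walk; the reflected walk has Uniform(0,1) as
   its stationary law, so unselected traits still drift toward a uniform
   distribution.  A `resample` kernel (redraw from U(0,1)) is available; it
   maximizes exploration per mutation but imposes a heavy mutation load near
   boundary optima and makes multi-trait transitions founder-limited.  The
   step kernel is the default because the study's own sensitivity behavior —
   a tenfold lower mutation rate converging to the same endpoints, only more
   slowly — is the signature of gradient-driven (local-kernel) adaptation,
   not of rare-jump dynamics.  `memdist` mutates regardless of the split
   mode; under the fixed split it is then a neutrally drifting marker — a
   useful internal control.

Extinction (no survivor after step 2) halts the run gracefully and is
flagged in the result; replicate summaries exclude extinct runs and report
their count.

### Functional forms

The curves linking protection to survival and reproduction are configured,
monotonicity-validated maps (a non-monotone form is rejected at load time).
Defaults, chosen from first principles rather than fitted:

* **Survival** `s(p) = p^(3/2)` (`"power15"`).  Convexity is load-bearing:
  for any *linear* survival curve the expected number of offspring surviving
  a stress is invariant to how protection is split at division
  (`s(αp) + s((1−α)p) = p` for all α), making the memory distribution
  factor quasi-neutral — asymmetric segregation of memory can only be
  adaptive when protection has accelerating returns.  The curvature is kept
  moderate because a steeper curve (the quadratic) makes survival at a high
  constitutive protection level so reliable that populations in informative
  environments lock into the constitutive state as a metastable local
  optimum instead of evolving the inducible memory; the 3/2 power is the
  half-integer exponent between those two regimes.  `quadratic`, `identity`
  and `sqrt` remain available.
* **Reproduction weight** `w = 1 − produced` (`"production"`), where
  `produced = max(0, p_new − p_old)` is the protection synthesized this
  step, including basal regeneration after division.  Cells pay for
  *producing* protection, not for carrying it.  A weight on the maintained
  level (`"level"`: `w = 1 − p`) makes constitutive protection
  prohibitively expensive — an invasion analysis puts the evolutionarily
  stable basal level near `p_stress·(1/random_kill_rate)·…` ≈ 0.07, and
  simulations confirm basal protection collapses — whereas under the
  production cost the fecundity penalty of maintaining a basal floor is one
  regeneration of `basal/2` per division (≈ 0.00125·basal per step),
  far below the survival benefit, so constitutive protection can evolve
  where stress is unpredictable.  `"level"`, `"level_production"` and
  `"constant"` (for neutral-drift controls) are selectable.

### Randomness

All stochastic kernels consume only uniform variates, in a fixed, documented
order (see the `cellmem.evolution` module docstring).  A master seed derives
independent streams (via `numpy.random.SeedSequence`) for the environment
set, the population initialization and the per-step loop, so the environment
realization never depends on population events.  Because the draw order is
part of the contract, a recorded list of uniforms can replay a step exactly;
the test suite exploits this with a scalar, loop-based oracle implementation
that must agree with the vectorized step bit for bit on small populations.

Division is conserving to the last bit: the larger share is computed by
multiplication and the smaller as the remainder, which is exact by the
Sterbenz lemma, so `mother + daughter == parent` holds exactly for every
split factor.

## Parameters

| parameter | default | meaning |
| --- | --- | --- |
| `capacity` | 10 000 | carrying capacity (cells) |
| `n_steps` | 100 000 | simulation length (steps) |
| `random_kill_rate` | 0.05 | per-cell per-step random mortality |
| `mutation_rate` | 0.001 | per-cell per-step mutation probability |
| `p_warning` | 0.005 | warning frequency (per step) |
| `p_stress` | 0.004 | stress frequency (noninformative regime) |
| `p_follow` | 0.8 | warning→stress coupling (informative) |
| `switch_rate` | 0.2 | per-step pending→stress switch probability |
| `mutation_kernel` | `step` | local reflected step vs full resample |
| `split_mode` | `fixed_half` | protection split at division |
| `migration_mode` | `stay`/`random` | daughter placement (by `n_envs`) |
| `survival_form` | `quadratic` | stress survival curve |
| `cost_form` | `production` | reproduction-weight curve |

Two named profiles bundle experiment scales: `full` (capacity 10 000,
100 000 steps, 20 replicates — the reference scale) and `desk` (capacity
10 000, 60 000 steps, 5 replicates).  The desk profile keeps the full
population size because selection on the memory traits is weak enough that
populations of a few thousand cells are drift-dominated (trait means
fluctuate by ±0.3 over tens of thousands of steps at capacity 2 000); it
shortens the horizon instead, to just past the point where the trajectories
settle — in exploratory full-capacity runs the informative regime's
transition from constitutive to inducible protection occurred between
~12 000 and ~55 000 steps.

## What the experiments show

* **Noninformative regime** (fixed split): basal protection converges to
  ≈ 0.95–0.97 (mutation load keeps it off the boundary), increase and
  decrease drift — constitutive protection, no memory.
* **Informative regime**: protection increase converges high (≈ 0.94),
  basal low (≈ 0.10–0.2), decrease near zero — protection is formed at the
  warning (a cellular memory) and decays mainly by dilution at division.
  The transition from the transient constitutive state to the inducible
  genotype is the slowest process in the study; occasional replicates take
  most of the 100 000-step horizon.
* **Two environments, evolvable split, migrating daughters**: selection
  favors mothers keeping the memory.  In head-to-head competition (no
  mutation) an `m = 0` genotype displaces both `m = 0.5` and `m = 1` within
  ~10 000–30 000 steps, and the evolutionary runs converge to a
  population-mean `memdist` of ≈ 0.1.  A minority of replicates first
  commit to the daughter-biased extreme (`m ≈ 0.9`; locally stable because
  moving toward an even split is penalized by the convex survival curve) and
  cross to the mother-biased optimum only around 110 000–130 000 steps,
  which is why this experiment runs a slightly longer horizon.
* **One environment, evolvable split (control)**: within single populations
  the split factor moves to an extreme — either direction — because
  concentrating protection in one of the two cells emerging from division
  beats splitting it under the convex survival curve (a bet-hedging
  asymmetry), with no cross-replicate agreement on the direction.
* **Sensitivity (one-at-a-time)**: daughters forced to stay remove the
  mother/daughter asymmetry and with it the low convergence of `memdist`;
  lowering `random_kill_rate` to 0.01 starves the population of reproductive
  slots and leaves constitutive basal protection dominant in all regimes;
  these directional effects are asserted in the test suite at reduced scale.

## What the synthetic environments do not capture

Environments are a three-state point process with single-step events: no
spatial structure, no graded stress intensities, no event durations, no
density feedback.  Cells have no cell-cycle structure, age, or molecular
mechanism (protection is a single abstract number).  Passing tests therefore
demonstrate the evolutionary logic of memory under these stylized
conditions, not quantitative predictions for any real organism.

## Numerical choices and degenerate inputs

* Trait and protection values are clamped to `[0,1]` after every update;
  division is exactly conserving (above).
* Reproduction weights are renormalized among survivors each step; an
  all-zero weight vector falls back to uniform sampling.
* A sequence with zero warnings reports the stress-after-warning fraction as
  undefined (`None`), never as zero; a trailing warning whose window is cut
  off by the end of the sequence is censored and excluded.
* Parents sampled several times in one step divide sequentially from their
  updated protection; weights are not recomputed within the reproduction
  phase (sampling is with replacement from the phase-start weights).
* Replicate standard errors use the standard deviation of replicate means
  over √n; a single replicate reports `NaN`.
* Trajectories are thinned (`record_every`, default 100) to bound output;
  final populations are always recorded at full resolution.

## Known limitations

* The survival and cost curves and the mutation kernel are principled
  defaults, not measurements; endpoint values (especially the memory
  distribution factor) depend on their shapes.  Under the `resample` kernel,
  for instance, the mutation load keeps the two-environment memory
  distribution factor near 0.35 instead of ≈ 0.1.
* Evolutionary outcomes at population sizes much below ~10 000 cells are
  drift-dominated; the shipped profiles deliberately keep the full capacity
  and scale down only the horizon and replicate count.
* Waiting times for the constitutive→inducible transition (informative
  regime) and for crossing from the daughter-biased to the mother-biased
  extreme (two environments) are stochastic; single replicates can lag the
  horizons above.
* Runs are single-threaded; a full-profile replicate set
  (20 × 100 000 steps × 10 000 cells) takes on the order of ten minutes
  (the default production-cost life cycle runs through compiled kernels;
  other cost forms use the plain vectorized path and are a few times
  slower).
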