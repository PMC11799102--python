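"""Exact continuous-time stochastic simulation of the rescue process.

Each type-``i`` cell divides at rate ``lambda_i = 1 + s(n, i)`` and dies at
rate 1, independently.  On division, the daughter pair is drawn from the
replication mode's division kernel; on division of a fully wild-type cell a
mutation occurs with probability ``u * n`` (at most one per division), giving
a ``{1, 0}`` daughter pair under regular replication or a head-start daughter
pair (urn amplification then segregation) under random replication.  The
simulation is the exact direct (event-by-event) method — no tau-leaping —
with per-type aggregated rates; mutant cells are tagged by the mutation event
that founded their lineage so the first *successful* rescue mutation can be
identified afterwards.
"""

from __future__ import annotations

import bisect
import math
import random as _random
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from .model_core import FitnessModel
from .segregation import MODES, conditional_single_mutation_pmf, pair_kernel, segregation_split_pmf

__all__ = [
    "SimulationConfig",
    "Trajectory",
    "simulate_trajectory",
    "growth_slope",
    "ReplicateSummary",
    "replicate_experiment",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulated rescue experiment.

    ``u`` is the per-locus mutation probability per plasmid replication and
    ``N0`` the initial wild-type population.  When the analytic input is only
    the product ``u * N0``, the default split ``u = uN0 / 1000, N0 = 1000``
    mirrors a large declining population with rare mutations.  ``t_max`` is
    the horizon in mean-lifespan units; ``population_cap`` stops (and flags)
    runs whose rescued population has grown past the point of interest;
    ``event_cap`` guards against runaway event loops.
    """

    model: FitnessModel
    mode: str = "regular"
    u: float = 1e-4
    N0: int = 1000
    seed: int = 0
    t_max: float = 60.0
    grid_dt: float = 1.0
    population_cap: int = 10**6
    event_cap: int = 10**8
    recurrent_mutation: bool = False

    def __post_init__(self):
        if self.mode not in MODES:
            raise ValueError(f"unknown replication mode {self.mode!r}")
        if not 0.0 <= self.u * self.model.n <= 1.0:
            raise ValueError(
                f"u*n = {self.u * self.model.n} must be a probability in [0, 1]")
        if self.N0 < 1 or int(self.N0) != self.N0:
            raise ValueError(f"N0 must be a positive integer, got {self.N0}")
        if self.t_max <= 0 or self.grid_dt <= 0:
            raise ValueError("t_max and grid_dt must be positive")

    @classmethod
    def from_product(cls, model: FitnessModel, mode: str, uN0: float,
                     N0: int = 1000, **kw) -> "SimulationConfig":
        """Build a config from the product ``u * N0`` with the default split."""
        return cls(model=model, mode=mode, u=uN0 / N0, N0=N0, **kw)


@dataclass
class Trajectory:
    """One simulated population trajectory, recorded on a fixed time grid."""

    times: np.ndarray
    counts: np.ndarray  # (len(times), n+1) cells per type
    outcome: str  # "extinct", "surviving", or "capped" (still alive at cap)
    stop_time: float  # when the event loop stopped; grid points after this
    # hold the frozen final snapshot (exact for extinct runs, stale for capped)
    extinction_time: Optional[float]
    mutation_times: List[float]
    first_successful_mutation_time: Optional[float]
    n_events: int
    truncated: bool = False

    @property
    def total(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def mutant_carrying(self) -> np.ndarray:
        return self.counts[:, 1:].sum(axis=1)


def _mutation_pair_sampler(n: int, mode: str):
    """Cumulative distribution over daughter pairs given a single mutation."""
    if mode == "regular":
        return [(1.0, (1, 0))]
    pairs = []
    cum = 0.0
    for m, pm in conditional_single_mutation_pmf(n).items():
        for (j, k), ps in segregation_split_pmf(n, m).items():
            cum += float(pm) * float(ps)
            pairs.append((cum, (j, k)))
    # normalize tail against float rounding
    pairs[-1] = (1.0, pairs[-1][1])
    return pairs


def simulate_trajectory(config: SimulationConfig) -> Trajectory:
    """Run one exact Gillespie realization of the rescue process.

    The population is partitioned into lineages: lineage 0 is the wild-type
    pool (all fully wild-type cells), and each mutation event founds a new
    lineage holding its mutant-carrying descendants.  Cells that segregate
    back to fully wild type rejoin the pool.  Identical seeds give identical
    trajectories.
    """
    model, mode = config.model, config.mode
    n = model.n
    rng = _random.Random(config.seed)

    lam = [model.birth_rate(i) for i in range(n + 1)]
    kern = pair_kernel(n, mode)
    pair_cum: List[List[Tuple[float, Tuple[int, int]]]] = []
    for i in range(n + 1):
        items = sorted(kern.pairs(i).items())
        cum = 0.0
        lst = []
        for (j, k), p in items:
            cum += float(p)
            lst.append((cum, (j, k)))
        lst[-1] = (1.0, lst[-1][1])
        pair_cum.append(lst)
    mut_pairs = _mutation_pair_sampler(n, mode)
    u_div = config.u * n  # per-division mutation probability of a type-0 cell

    # counts[lineage][type]; lineage 0 = wild-type pool
    counts: Dict[int, List[int]] = {0: [0] * (n + 1)}
    counts[0][0] = int(config.N0)
    lineage_birth: Dict[int, float] = {}
    next_lineage = 1

    t = 0.0
    n_events = 0
    grid_times = np.arange(0.0, config.t_max + 0.5 * config.grid_dt, config.grid_dt)
    grid_counts = np.zeros((len(grid_times), n + 1), dtype=np.int64)
    gi = 0
    mutation_times: List[float] = []
    outcome = "surviving"
    extinction_time = None
    truncated = False

    def record_until(t_now: float):
        nonlocal gi
        while gi < len(grid_times) and grid_times[gi] <= t_now:
            snap = np.zeros(n + 1, dtype=np.int64)
            for vec in counts.values():
                snap += np.asarray(vec)
            grid_counts[gi] = snap
            gi += 1

    record_until(0.0)

    stop_time = config.t_max
    while True:
        total_rate = 0.0
        weights = []
        keys = []
        for lin, vec in counts.items():
            for i in range(n + 1):
                c = vec[i]
                if c:
                    w = c * (lam[i] + 1.0)
                    total_rate += w
                    weights.append(total_rate)
                    keys.append((lin, i))
        total_pop = sum(sum(v) for v in counts.values())
        if total_pop == 0:
            outcome = "extinct"
            extinction_time = t
            stop_time = t
            record_until(config.t_max)
            break
        if total_pop >= config.population_cap:
            outcome = "capped"
            stop_time = t
            record_until(config.t_max)
            break
        if n_events >= config.event_cap:
            truncated = True
            stop_time = t
            record_until(config.t_max)
            break

        t += rng.expovariate(total_rate)
        if t >= config.t_max:
            record_until(config.t_max)
            break
        record_until(t)
        n_events += 1

        r = rng.random() * total_rate
        idx = bisect.bisect_left(weights, r)
        lin, i = keys[idx]
        # division with probability lam/(lam+1), death otherwise
        if rng.random() * (lam[i] + 1.0) < lam[i]:
            counts[lin][i] -= 1
            mutated = (i == 0 and lin == 0 and u_div > 0.0
                       and rng.random() < u_div)
            if not mutated and config.recurrent_mutation and 0 < i < n:
                # sensitivity-analysis option: mutation at any wild-type copy
                # replication, applied to one daughter after segregation
                mutated_recurrent = rng.random() < config.u * (n - i)
            else:
                mutated_recurrent = False
            if mutated:
                r2 = rng.random()
                j, k = next(pair for c, pair in mut_pairs if r2 <= c)
                mutation_times.append(t)
                new_lin = next_lineage
                next_lineage += 1
                lineage_birth[new_lin] = t
                counts.setdefault(new_lin, [0] * (n + 1))
                for d in (j, k):
                    target = new_lin if d >= 1 else 0
                    counts[target][d] += 1
            else:
                r2 = rng.random()
                j, k = next(pair for c, pair in pair_cum[i] if r2 <= c)
                if mutated_recurrent:
                    if j < n:
                        j += 1
                    elif k < n:
                        k += 1
                for d in (j, k):
                    target = lin if d >= 1 else 0
                    counts[target][d] += 1
            # drop emptied mutant lineages lazily
            if lin != 0 and not any(counts[lin]):
                del counts[lin]
        else:
            counts[lin][i] -= 1
            if lin != 0 and not any(counts[lin]):
                del counts[lin]

    first_success = None
    if outcome in ("surviving", "capped"):
        alive = [lin for lin, vec in counts.items()
                 if lin != 0 and sum(vec[1:]) > 0]
        if alive:
            first_success = min(lineage_birth[lin] for lin in alive)
    return Trajectory(times=grid_times, counts=grid_counts, outcome=outcome,
                      stop_time=stop_time, extinction_time=extinction_time,
                      mutation_times=mutation_times,
                      first_successful_mutation_time=first_success,
                      n_events=n_events, truncated=truncated)


def growth_slope(traj: Trajectory, low: int = 300,
                 min_fold: float = 4.0) -> Optional[float]:
    """Late-time exponential growth rate of the mutant-carrying population.

    Two-point log-slope between the first grid sample with at least ``low``
    mutant-carrying cells and the last live sample (grid points after
    ``stop_time`` repeat a frozen snapshot and are excluded).  Returns ``None``
    when the trajectory offers no window of at least ``min_fold``-fold growth,
    which keeps the estimate out of the stochastic small-number regime.
    """
    live = traj.times <= traj.stop_time
    mc = traj.mutant_carrying[live].astype(float)
    times = traj.times[live]
    idx_lo = np.nonzero(mc >= low)[0]
    if idx_lo.size == 0:
        return None
    i1 = int(idx_lo[0])
    i2 = int(np.argmax(mc))
    if i2 <= i1 or mc[i2] < min_fold * mc[i1]:
        return None
    return float(math.log(mc[i2] / mc[i1]) / (times[i2] - times[i1]))


@dataclass
class ReplicateSummary:
    """Aggregate of many independent rescue simulations."""

    config: SimulationConfig
    n_reps: int
    outcomes: List[str]
    survival_fraction: float
    survival_stderr: float
    survivor_mean: Optional[np.ndarray]  # mean total-population curve of survivors
    times: np.ndarray
    first_success_times: List[float]
    mean_first_success_time: Optional[float]
    trajectories: Optional[List[Trajectory]] = field(default=None, repr=False)


def replicate_experiment(config: SimulationConfig, n_reps: int,
                         *, keep_trajectories: bool = False) -> ReplicateSummary:
    """Run ``n_reps`` independent replicates with seeds derived from
    ``config.seed`` and summarize survival, the survivor-conditioned mean
    population curve, and the first-successful-mutation times.

    A replicate counts as surviving if its population is alive at ``t_max``
    (including runs stopped early at the population cap, which are certainly
    alive).  With zero survivors the survivor-conditioned quantities are
    reported as ``None``.
    """
    if n_reps < 1:
        raise ValueError(f"n_reps must be >= 1, got {n_reps}")
    ss = np.random.SeedSequence(config.seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n_reps)]
    outcomes = []
    curves = []
    first_times = []
    trajs = [] if keep_trajectories else None
    times = None
    for seed in seeds:
        cfg = SimulationConfig(model=config.model, mode=config.mode,
                               u=config.u, N0=config.N0, seed=seed,
                               t_max=config.t_max, grid_dt=config.grid_dt,
                               population_cap=config.population_cap,
                               event_cap=config.event_cap,
                               recurrent_mutation=config.recurrent_mutation)
        traj = simulate_trajectory(cfg)
        outcomes.append(traj.outcome)
        times = traj.times
        if traj.outcome in ("surviving", "capped"):
            curves.append(traj.total)
            if traj.first_successful_mutation_time is not None:
                first_times.append(traj.first_successful_mutation_time)
        if keep_trajectories:
            trajs.append(traj)
    k = sum(1 for o in outcomes if o in ("surviving", "capped"))
    frac = k / n_reps
    se = math.sqrt(frac * (1.0 - frac) / n_reps)
    survivor_mean = (np.mean(np.stack(curves), axis=0) if curves else None)
    mean_first = (float(np.mean(first_times)) if first_times else None)
    return ReplicateSummary(config=config, n_reps=n_reps, outcomes=outcomes,
                            survival_fraction=frac, survival_stderr=se,
                            survivor_mean=survivor_mean, times=times,
                            first_success_times=first_times,
                            mean_first_success_time=mean_first,
                            trajectories=trajs)
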