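"""Extinction and establishment probabilities of the mutant lineage.

The fate of the descendants of a single cell is governed by a multitype
branching process over the cell types ``i = 0..n`` (number of mutant plasmid
copies).  Viewed in discrete time, a type-``i`` cell leaves either zero
daughters (probability ``1 - rho_i``) or a daughter pair drawn from the
division kernel (probability ``rho_i = lambda_i / (lambda_i + mu_i)``).  The
extinction probabilities ``Q_0..Q_n`` are the least fixed point of the
offspring generating function

    f_i(z) = (1 - rho_i) + rho_i * sum_{ {j,k} } P(i -> {j,k}) z_j z_k,

reached by iterating from the zero vector.  The establishment probability of
a new mutation is ``1 - Q_1`` under regular replication; under random
replication the first mutant copy may be amplified by the urn before the cell
divides, so establishment averages ``Q_j Q_k`` over the head-start
distribution of the first division.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .model_core import FitnessModel, reproduction_probability
from .segregation import (
    MODES,
    conditional_single_mutation_pmf,
    pair_kernel,
    segregation_split_pmf,
)

__all__ = [
    "ExtinctionSolution",
    "solve_offspring_fixed_point",
    "generating_function",
    "extinction_probabilities",
    "establishment_regular",
    "establishment_random",
    "establishment_probability",
    "MonteCarloResult",
    "monte_carlo_establishment",
]

#: components of Q closer to 1 than this are snapped to exactly 1, and
#: establishment probabilities below it are reported as exactly 0, so that
#: "establishment is impossible" is an exact statement.  At the critical
#: threshold the fixed point is a double root at 1, which double precision
#: can only localize to ~sqrt(machine epsilon) ~ 1e-8; the snap must sit
#: above that floor
SNAP_TOL = 1e-7


@dataclass(frozen=True)
class ExtinctionSolution:
    """Least fixed point of the offspring generating function.

    Attributes
    ----------
    model : FitnessModel
    mode : str
    Q : numpy.ndarray
        Extinction probabilities ``Q_0..Q_n`` (snapped to 1 within tolerance).
    iterations : int
        Number of fixed-point sweeps performed.
    residual : float
        Final sup-norm residual ``max_i |f_i(Q) - Q_i|``.
    """

    model: FitnessModel
    mode: str
    Q: np.ndarray
    iterations: int
    residual: float


class ConvergenceError(RuntimeError):
    """Fixed-point iteration failed to reach the requested tolerance."""


def _flatten_kernel(model: FitnessModel, mode: str):
    """Flatten the pair kernel into index arrays so one sweep of the
    generating function is a handful of vectorized operations."""
    n = model.n
    kern = pair_kernel(n, mode)
    I, J, K, W = [], [], [], []
    for i in range(n + 1):
        for (j, k), p in kern.pairs(i).items():
            I.append(i)
            J.append(j)
            K.append(k)
            W.append(float(p))
    rho = np.array([reproduction_probability(model, i) for i in range(n + 1)])
    return (np.array(I), np.array(J), np.array(K), np.array(W), rho)


def generating_function(model: FitnessModel, mode: str = "regular"):
    """Return the offspring generating function ``f(z)`` as a callable on
    length-``n+1`` vectors (useful for inspecting the raw iteration)."""
    n = model.n
    I, J, K, W, rho = _flatten_kernel(model, mode)
    dead = 1.0 - rho

    def f(z):
        z = np.asarray(z, dtype=float)
        acc = np.bincount(I, weights=W * z[J] * z[K], minlength=n + 1)
        return dead + rho * acc

    return f


def solve_offspring_fixed_point(
    I: np.ndarray,
    J: np.ndarray,
    K: np.ndarray,
    W: np.ndarray,
    rho: np.ndarray,
    *,
    tol: float = 1e-12,
    max_iter: int = 10**6,
    accelerate: bool = True,
):
    """Least fixed point of a quadratic offspring generating function.

    The system is ``f_t(z) = (1 - rho_t) + rho_t * sum W z_J z_K`` with the
    sum over the flattened kernel entries whose parent index ``I`` equals
    ``t``.  Iterating ``z <- f(z)`` from ``z = 0`` gives componentwise
    nondecreasing iterates converging to the least fixed point (the
    extinction probabilities), but the contraction rate approaches 1 near
    the critical threshold.  By default plain sweeps are therefore
    interleaved with Newton steps on ``z - f(z) = 0``: for monotone
    polynomial systems Newton from the sub-solution region converges to the
    least fixed point, and each step is safeguarded — it is rejected if it
    overshoots above 1 by more than a snap margin (the all-ones vector is
    always a root, and clipping onto it would defeat the residual test) or
    fails to reduce the residual.  ``residual`` is the sup-norm of
    ``f(z) - z`` at return; the distance to the true fixed point is driven
    to ~1e-13 even at near-critical parameters.

    Returns ``(z, iterations, residual)``; raises :class:`ConvergenceError`
    if the residual is still above ``tol`` after ``max_iter`` sweeps.
    """
    m = rho.size
    dead = 1.0 - rho

    def sweep(z):
        acc = np.bincount(I, weights=W * z[J] * z[K], minlength=m)
        return dead + rho * acc

    def newton_step(z):
        A = np.zeros((m, m))
        np.add.at(A, (I, J), rho[I] * W * z[K])
        np.add.at(A, (I, K), rho[I] * W * z[J])
        g = sweep(z) - z
        try:
            return np.linalg.solve(np.eye(m) - A, g)
        except np.linalg.LinAlgError:
            return None

    z = np.zeros(m)
    iterations = 0
    residual = np.inf
    while iterations < max_iter:
        for _ in range(10):
            z = sweep(z)
            iterations += 1
        z_next = sweep(z)
        residual = float(np.max(np.abs(z_next - z)))
        z = z_next
        iterations += 1
        if residual < tol:
            break
        if accelerate:
            dz = newton_step(z)
            if dz is not None:
                overshoot = float(np.max(z + dz - 1.0, initial=0.0))
                zn = np.clip(z + dz, 0.0, 1.0)
                res_n = float(np.max(np.abs(sweep(zn) - zn)))
                if overshoot <= SNAP_TOL and res_n < residual:
                    z, residual = zn, res_n
                    if residual < tol:
                        break
    if residual >= tol:
        raise ConvergenceError(
            f"extinction fixed point did not converge in {iterations} sweeps "
            f"(residual {residual:.3e} > tol {tol:.3e})"
        )
    if accelerate:
        # near an almost-double root (parameters close to the critical
        # threshold) the residual underestimates the remaining error by a
        # factor 1/(1-r); polish with Newton until the step itself — a
        # direct estimate of the distance to the root — is negligible.
        # With residual < tol the iterate is within ~1e-5 of the least
        # fixed point, so larger steps indicate a hop to a different root
        # and abort the polish.
        for _ in range(80):
            dz = newton_step(z)
            if dz is None:
                break
            step = float(np.max(np.abs(dz)))
            if step > 1e-5:
                break
            if float(np.max(z + dz - 1.0, initial=0.0)) > SNAP_TOL:
                break
            z = np.clip(z + dz, 0.0, 1.0)
            if step < 1e-13:
                break
        residual = min(residual, float(np.max(np.abs(sweep(z) - z))))
    return z, iterations, residual


def extinction_probabilities(
    model: FitnessModel,
    mode: str = "regular",
    *,
    tol: float = 1e-12,
    max_iter: int = 10**6,
    accelerate: bool = True,
) -> ExtinctionSolution:
    """Solve for the extinction probabilities ``Q_0..Q_n``.

    Components within :data:`SNAP_TOL` of 1 are snapped to exactly 1, so the
    critical-threshold statements ("establishment is impossible") are exact.

    Raises
    ------
    ConvergenceError
        If the residual is still above ``tol`` after ``max_iter`` sweeps.
    """
    if mode not in MODES:
        raise ValueError(f"unknown replication mode {mode!r}; expected one of {MODES}")
    I, J, K, W, rho = _flatten_kernel(model, mode)
    z, iterations, residual = solve_offspring_fixed_point(
        I, J, K, W, rho, tol=tol, max_iter=max_iter, accelerate=accelerate)
    Q = np.where(z > 1.0 - SNAP_TOL, 1.0, z)
    Q.setflags(write=False)
    return ExtinctionSolution(model=model, mode=mode, Q=Q, iterations=iterations,
                              residual=residual)


def establishment_regular(model: FitnessModel,
                          solution: Optional[ExtinctionSolution] = None) -> float:
    """Establishment probability ``1 - Q_1`` under regular replication.

    The new mutation appears on a single plasmid copy in one cell, so the
    lineage starts from exactly one type-1 cell.  Returns 0 for ``n = 1``
    (no heterozygote class exists).
    """
    if model.n == 1:
        return 0.0
    if solution is None:
        solution = extinction_probabilities(model, "regular")
    p = 1.0 - solution.Q[1]
    return 0.0 if p < SNAP_TOL else float(p)


def establishment_random(model: FitnessModel,
                         solution: Optional[ExtinctionSolution] = None) -> float:
    """Establishment probability under random replication.

    Conditional on a single mutation during urn replication, the mutant may
    already be present in ``m = j + k`` copies when the cell divides, split
    ``{j, k}`` between the daughters; establishment is
    ``1 - sum_m pmf(m) sum_{ {j,k} } split(j, k) Q_j Q_k``.
    """
    n = model.n
    if n == 1:
        return 0.0
    if solution is None:
        solution = extinction_probabilities(model, "random")
    Q = solution.Q
    total = 0.0
    for m, pm in conditional_single_mutation_pmf(n).items():
        inner = 0.0
        for (j, k), ps in segregation_split_pmf(n, m).items():
            inner += float(ps) * Q[j] * Q[k]
        total += float(pm) * inner
    p = 1.0 - total
    return 0.0 if p < SNAP_TOL else float(p)


def establishment_probability(model: FitnessModel, mode: str = "regular") -> float:
    """Establishment probability for the given replication mode."""
    if mode == "regular":
        return establishment_regular(model)
    if mode == "random":
        return establishment_random(model)
    raise ValueError(f"unknown replication mode {mode!r}; expected one of {MODES}")


@dataclass(frozen=True)
class MonteCarloResult:
    """Monte-Carlo establishment estimate with its binomial standard error."""

    estimate: float
    stderr: float
    reps: int
    n_established: int
    n_flagged: int


def _headstart_pairs(n: int):
    """Joint head-start distribution over daughter pairs (j, k) for a single
    mutation under random replication."""
    pairs, probs = [], []
    for m, pm in conditional_single_mutation_pmf(n).items():
        for (j, k), ps in segregation_split_pmf(n, m).items():
            pairs.append((j, k))
            probs.append(float(pm) * float(ps))
    return pairs, np.array(probs)


def monte_carlo_establishment(
    model: FitnessModel,
    mode: str,
    reps: int,
    seed: int,
    *,
    survival_threshold: int = 500,
    event_cap: int = 10**7,
) -> MonteCarloResult:
    """Estimate the establishment probability by direct lineage simulation.

    Each replicate starts from the cell(s) created by a single first mutation
    (one type-1 cell under regular replication; a head-start daughter pair
    under random replication) and runs the embedded discrete-time branching
    process generation by generation until the lineage either dies out or the
    number of living mutant-carrying cells reaches ``survival_threshold``
    (heterozygote supercriticality makes later extinction negligible).
    Wild-type (type-0) daughters are discarded: they carry no mutant copy and
    their line is certain to die out.

    Replicates whose cumulative processed-cell count exceeds ``event_cap``
    before resolution are flagged and excluded from the estimate rather than
    silently counted.
    """
    if reps < 1:
        raise ValueError(f"reps must be >= 1, got {reps}")
    if mode not in MODES:
        raise ValueError(f"unknown replication mode {mode!r}; expected one of {MODES}")
    n = model.n
    rng = np.random.default_rng(seed)
    kern = pair_kernel(n, mode)
    rho = np.array([reproduction_probability(model, i) for i in range(n + 1)])

    # per parent type: pair probabilities and the pair -> daughter-type-count map
    pair_pvals, pair_maps = [], []
    for i in range(n + 1):
        items = sorted(kern.pairs(i).items())
        pv = np.array([float(p) for _, p in items])
        amap = np.zeros((len(items), n + 1), dtype=np.int64)
        for r, ((j, k), _) in enumerate(items):
            amap[r, j] += 1
            amap[r, k] += 1
        pair_pvals.append(pv / pv.sum())
        pair_maps.append(amap)

    counts = np.zeros((reps, n + 1), dtype=np.int64)
    if mode == "regular":
        counts[:, 1] = 1
    else:
        pairs, probs = _headstart_pairs(n)
        idx = rng.choice(len(pairs), size=reps, p=probs / probs.sum())
        for r, ix in enumerate(idx):
            j, k = pairs[ix]
            if j >= 1:
                counts[r, j] += 1
            if k >= 1:
                counts[r, k] += 1

    established = np.zeros(reps, dtype=bool)
    flagged = np.zeros(reps, dtype=bool)
    events = np.zeros(reps, dtype=np.int64)
    active_idx = np.arange(reps)
    C = counts

    while active_idx.size:
        events[active_idx] += C.sum(axis=1)
        over = events[active_idx] > event_cap
        if over.any():
            flagged[active_idx[over]] = True
        newC = np.zeros_like(C)
        for i in range(1, n + 1):
            ci = C[:, i]
            if not ci.any():
                continue
            d = rng.binomial(ci, rho[i])
            if not d.any():
                continue
            draws = rng.multinomial(d, pair_pvals[i])
            newC += draws @ pair_maps[i]
        newC[:, 0] = 0
        C = newC
        alive = C.sum(axis=1)
        est_now = alive >= survival_threshold
        established[active_idx[est_now]] = True
        keep = (~est_now) & (alive > 0) & (~flagged[active_idx])
        active_idx = active_idx[keep]
        C = C[keep]

    valid = ~flagged
    n_valid = int(valid.sum())
    if n_valid == 0:
        raise ConvergenceError("all replicates hit the event cap; no estimate available")
    k_est = int(established[valid].sum())
    p = k_est / n_valid
    se = float(np.sqrt(p * (1.0 - p) / n_valid))
    return MonteCarloResult(estimate=p, stderr=se, reps=n_valid,
                            n_established=k_est, n_flagged=int(flagged.sum()))
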