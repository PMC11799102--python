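"""Expected-progeny matrix, critical thresholds, and long-run composition.

The expected-progeny matrix ``M`` has entry ``(i, j)`` equal to the expected
number of daughters with ``j`` mutant copies per type-``i`` parent:
``m_ij = 2 rho_i * marginal(i, j)``.  Under regular replication it factors as
``M = 2 R P`` with ``R = diag(rho_i)`` and ``P`` the hypergeometric
segregation marginal; the eigenvalues of ``P`` are the classical
``chi_i = 2^i C(n,i) / C(2n,i)``.  Establishment is possible exactly when the
leading eigenvalue of ``M`` exceeds 1, which under dominant fitness yields
closed-form critical thresholds on ``s_max`` (and, inverted, on ``n``), and
the leading left eigenvector of ``M`` gives the stationary distribution of
cell types in an established (growing) population.
"""

from __future__ import annotations

from math import comb, sqrt
from typing import Tuple

import numpy as np

from .model_core import FitnessModel, reproduction_probability
from .segregation import MODES, pair_kernel

__all__ = [
    "segregation_marginal_matrix",
    "progeny_matrix",
    "chi_eigenvalues",
    "critical_s_max",
    "critical_n",
    "stationary_type_distribution",
    "leading_eigenvalue",
    "rescued_growth_rate",
    "half_and_half_threshold",
]


def segregation_marginal_matrix(n: int, mode: str = "regular") -> np.ndarray:
    """The ``(n+1) x (n+1)`` marginal daughter matrix ``P``: entry ``(i, j)``
    is the probability a uniformly chosen daughter of an ``i``-parent carries
    ``j`` mutant copies.  In regular mode this is the hypergeometric matrix
    ``C(2i, j) C(2(n-i), n-j) / C(2n, n)``."""
    return np.array(pair_kernel(n, mode).marginal)


def progeny_matrix(model: FitnessModel, mode: str = "regular") -> np.ndarray:
    """Expected-progeny matrix ``m_ij = 2 rho_i * marginal(i, j)``."""
    n = model.n
    rho = np.array([reproduction_probability(model, i) for i in range(n + 1)])
    return 2.0 * rho[:, None] * segregation_marginal_matrix(n, mode)


def chi_eigenvalues(n: int) -> np.ndarray:
    """Closed-form eigenvalues ``chi_i = 2^i C(n,i) / C(2n,i)`` of the regular
    segregation marginal, ``i = 0..n`` (a nonincreasing sequence with
    ``chi_0 = chi_1 = 1``)."""
    if n < 1:
        raise ValueError(f"copy number n must be >= 1, got {n}")
    return np.array([2.0**i * comb(n, i) / comb(2 * n, i) for i in range(n + 1)])


def critical_s_max(n: int, mode: str = "regular") -> float:
    """Critical heterozygote fitness above which establishment is possible
    (dominant fitness): ``2 / (2n - 3)`` for regular replication and
    ``4n / (2n^2 - 3n - 1)`` for random replication.  The boundary itself is
    excluded (establishment requires strict inequality); for ``n < 2`` the
    threshold is infinite."""
    if mode not in MODES:
        raise ValueError(f"unknown replication mode {mode!r}; expected one of {MODES}")
    if n < 2:
        return np.inf
    if mode == "regular":
        return 2.0 / (2 * n - 3)
    return 4.0 * n / (2 * n * n - 3 * n - 1)


def critical_n(s_max: float, mode: str = "regular") -> int:
    """Smallest copy number at which establishment is possible for a given
    heterozygote fitness: ``n > 1/s_max + 3/2`` for regular replication and
    ``n > 1/s_max + 3/4 + sqrt((1/s_max + 3/4)^2 + 1/2)`` for random."""
    if s_max <= 0:
        raise ValueError(f"s_max must be positive, got {s_max}")
    if mode not in MODES:
        raise ValueError(f"unknown replication mode {mode!r}; expected one of {MODES}")
    inv = 1.0 / s_max
    if mode == "regular":
        bound = inv + 1.5
    else:
        bound = inv + 0.75 + sqrt((inv + 0.75) ** 2 + 0.5)
    n = int(np.floor(bound)) + 1
    # guard against floating-point landing exactly on the open boundary
    if n <= bound:
        n += 1
    return max(n, 2)


def critical_s_max_empirical(n: int, s_min: float = -0.1, mode: str = "regular",
                             *, tol: float = 1e-4, bracket=(0.01, 16.0)) -> float:
    """Locate the establishment threshold by bisection on the branching
    solver (dominant fitness): the smallest ``s_max`` at which the
    fixed-point establishment probability becomes positive.

    Independent of the closed-form thresholds; useful as a numerical
    cross-check of them.
    """
    from .branching import establishment_probability

    lo, hi = bracket

    def positive(s):
        model = FitnessModel(n=n, kind="dominant", s_min=s_min, s_max=s)
        return establishment_probability(model, mode) > 0.0

    if positive(lo):
        raise ValueError(f"bracket lower end {lo} is already supercritical")
    if not positive(hi):
        raise ValueError(f"bracket upper end {hi} is still subcritical")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if positive(mid):
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


def leading_eigenvalue(model: FitnessModel, mode: str = "regular") -> float:
    """Largest eigenvalue (spectral radius) of the expected-progeny matrix."""
    M = progeny_matrix(model, mode)
    return float(np.max(np.abs(np.linalg.eigvals(M))))


def stationary_type_distribution(model: FitnessModel, mode: str = "regular") -> np.ndarray:
    """Long-run distribution of cell types in an established population.

    The normalized leading *left* eigenvector of ``M``.  Defined only when the
    process is supercritical (leading eigenvalue > 1); a subcritical model
    goes extinct with probability one and has no stationary composition.
    """
    M = progeny_matrix(model, mode)
    vals, vecs = np.linalg.eig(M.T)
    order = np.argsort(-vals.real)
    lead = order[0]
    if vals[lead].real <= 1.0 + 1e-12:
        raise ValueError(
            "subcritical model (leading eigenvalue "
            f"{vals[lead].real:.6f} <= 1): extinction is certain and no "
            "stationary type distribution exists"
        )
    v = vecs[:, lead].real
    if v.sum() < 0:
        v = -v
    if (v < -1e-10).any():
        raise RuntimeError("leading left eigenvector is not nonnegative")
    v = np.clip(v, 0.0, None)
    return v / v.sum()


def rescued_growth_rate(n: int, s_max: float, mode: str = "regular") -> float:
    """Long-run exponential growth rate of a rescued population under dominant
    fitness: ``(1 + s_max)(2 chi - 1) - 1`` with ``chi`` the largest
    segregation eigenvalue below 1 — ``2(n-1)/(2n-1)`` for regular and
    ``(n-1)(2n+1) / ((n+1)(2n-1))`` for random replication."""
    if n < 2:
        raise ValueError(f"copy number n must be >= 2, got {n}")
    if s_max <= 0:
        raise ValueError(f"s_max must be positive, got {s_max}")
    if mode == "regular":
        chi = 2.0 * (n - 1) / (2 * n - 1)
    elif mode == "random":
        chi = (n - 1) * (2 * n + 1) / ((n + 1) * (2 * n - 1))
    else:
        raise ValueError(f"unknown replication mode {mode!r}; expected one of {MODES}")
    return (1.0 + s_max) * (2.0 * chi - 1.0) - 1.0


def half_and_half_threshold(n: int) -> float:
    """Critical ``s_max`` in the simplified model that treats every
    heterozygote as a balanced half-and-half cell: ``1 / (2^(n-2) - 1)``.

    This comparison model overestimates heterozygote stability, so for
    ``n > 3`` its threshold is weaker (smaller) than the exact regular-mode
    threshold.  Undefined for ``n <= 2``.
    """
    if n < 3:
        raise ValueError(f"half-and-half comparison threshold requires n >= 3, got {n}")
    return 1.0 / (2.0 ** (n - 2) - 1.0)


def dominant_eigenvalue_branches(model: FitnessModel, mode: str = "regular") -> Tuple[float, float, str]:
    """The two candidate leading eigenvalues of ``M`` under dominant fitness.

    Returns ``(2 rho_hom, heterozygote branch, which)`` where ``which`` names
    the dominant one.  The homozygote branch ``2 rho_hom`` is always < 1
    (``s_min < 0``) and is therefore irrelevant to the establishment
    criterion, but near-critical models may have it numerically on top.
    """
    from .model_core import rho_het, rho_hom

    hom = 2.0 * rho_hom(model.s_min)
    n = model.n
    if mode == "regular":
        chi = 2.0 * (n - 1) / (2 * n - 1) if n >= 2 else 1.0
    else:
        chi = (n - 1) * (2 * n + 1) / ((n + 1) * (2 * n - 1)) if n >= 2 else 1.0
    het = 2.0 * rho_het(model.s_max) * chi
    which = "homozygote" if hom > het else "heterozygote"
    return hom, het, which
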