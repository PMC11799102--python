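"""Division-outcome kernels for regular and random plasmid replication.

At host cell division the ``n`` plasmid copies are first replicated to ``2n``
and then segregated, ``n`` to each daughter.  ``P(i -> {j, k})`` denotes the
probability that a parent with ``i`` mutant copies produces the unordered pair
of daughters with ``j`` and ``k`` mutant copies.

Two replication modes are supported (after the classical taxonomy of
copy-number control models):

* **regular** — every copy is replicated exactly once, so the post-replication
  pool holds exactly ``2i`` mutant copies; segregation is a hypergeometric
  split of the ``2n`` pool.
* **random** — copies to replicate are drawn uniformly with replacement from
  the growing pool (a Polya urn) until ``2n`` copies exist, then the pool is
  split hypergeometrically.  The urn's rich-get-richer dynamics make
  unbalanced daughters more likely than under regular replication.

Probabilities are computed in exact rational arithmetic for ``n <= 30`` (so
small-``n`` fractions such as 2/3 and 5/9 are reproduced bit-exactly after
conversion) and in floating point above.  Kernels are cached per ``(n, mode)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from functools import lru_cache
from math import comb
from typing import Dict, Tuple

import numpy as np

__all__ = [
    "PairKernel",
    "pair_kernel",
    "regular_pair_probs",
    "random_pair_probs",
    "polya_copy_pmf",
    "conditional_single_mutation_pmf",
    "segregation_split_pmf",
]

MODES = ("regular", "random")

#: exact rational arithmetic below this copy number, floats above
EXACT_N_MAX = 30


def _binom(a: int, b: int):
    """Binomial coefficient with the conventions the urn pmf requires:
    C(-1, 0) = 1 and C(a, b) = 0 whenever b < 0 or b > a >= 0 or a < 0
    otherwise."""
    if a == -1 and b == 0:
        return 1
    if a < 0 or b < 0 or b > a:
        return 0
    return comb(a, b)


def _check_range(n: int, i: int) -> None:
    if n < 1:
        raise ValueError(f"copy number n must be >= 1, got {n}")
    if not 0 <= i <= n:
        raise ValueError(f"mutant count i={i} out of range [0, {n}]")


def _maybe_float(d: dict, n: int) -> dict:
    if n > EXACT_N_MAX:
        return {key: float(v) for key, v in d.items()}
    return d


def regular_pair_probs(n: int, i: int) -> Dict[Tuple[int, int], Fraction]:
    """Unordered daughter-pair distribution under regular replication.

    Returns a mapping ``{(j, k): p}`` with ``j <= k``; nonzero only on the
    diagonal ``j + k = 2i`` (mutant copies are conserved exactly).  The factor
    2 for distinguishable daughters (``j != k``) is included in ``p``.
    """
    _check_range(n, i)
    denom = _binom(2 * n, n)
    out: Dict[Tuple[int, int], Fraction] = {}
    for j in range(0, i + 1):
        k = 2 * i - j
        if k > n or k < j:
            continue
        w = _binom(2 * i, j) * _binom(2 * (n - i), n - j)
        if w == 0:
            continue
        p = Fraction(w, denom)
        out[(j, k)] = p if j == k else 2 * p
    return _maybe_float(out, n)


def polya_copy_pmf(n: int, i: int) -> Dict[int, Fraction]:
    """Pmf of the number of mutant copies among ``2n`` after Polya-urn
    replication starting from ``i`` mutant copies out of ``n``.

    ``pmf(m) = C(2n-m-1, n-m+i) C(m-1, m-i) / C(2n-1, n)`` with the convention
    ``C(-1, 0) = 1`` (which makes ``i = 0`` and ``i = n`` exact point masses).
    """
    _check_range(n, i)
    denom = _binom(2 * n - 1, n)
    out: Dict[int, Fraction] = {}
    for m in range(0, 2 * n + 1):
        w = _binom(2 * n - m - 1, n - m + i) * _binom(m - 1, m - i)
        if w:
            out[m] = Fraction(w, denom)
    return _maybe_float(out, n)


def segregation_split_pmf(n: int, m: int) -> Dict[Tuple[int, int], Fraction]:
    """Hypergeometric split of ``m`` mutant copies (of ``2n`` total) into an
    unordered daughter pair ``{j, k}`` with ``j + k = m``."""
    if n < 1:
        raise ValueError(f"copy number n must be >= 1, got {n}")
    if not 0 <= m <= 2 * n:
        raise ValueError(f"post-replication mutant count m={m} out of range [0, {2 * n}]")
    denom = _binom(2 * n, n)
    out: Dict[Tuple[int, int], Fraction] = {}
    for j in range(0, m // 2 + 1):
        k = m - j
        if k > n:
            continue
        w = _binom(m, j) * _binom(2 * n - m, n - j)
        if w == 0:
            continue
        p = Fraction(w, denom)
        out[(j, k)] = p if j == k else 2 * p
    return _maybe_float(out, n)


def random_pair_probs(n: int, i: int) -> Dict[Tuple[int, int], Fraction]:
    """Unordered daughter-pair distribution under random (Polya-urn)
    replication: the urn copy pmf composed with the hypergeometric split."""
    _check_range(n, i)
    copy_pmf = polya_copy_pmf(n, i)
    out: Dict[Tuple[int, int], Fraction] = {}
    for m, pm in copy_pmf.items():
        for pair, ps in segregation_split_pmf(n, m).items():
            out[pair] = out.get(pair, 0) + pm * ps
    return out


def conditional_single_mutation_pmf(n: int) -> Dict[int, Fraction]:
    """Pmf of the total mutant copies ``m`` after replication, conditional on
    exactly one mutation occurring during Polya-urn replication of a
    wild-type cell.

    The mutation arises on a single new copy at a uniformly random point of
    the replication sequence and may itself be replicated before the pool
    reaches ``2n``; hence the "head start" ``m`` ranges over ``1..n``:

    ``pmf(m) = (2n + (n-1) m) / (n m (m+1)) * C(n, m) / C(2n-1, m)``.
    """
    if n < 1:
        raise ValueError(f"copy number n must be >= 1, got {n}")
    denom_exact = n <= EXACT_N_MAX
    out: Dict[int, Fraction] = {}
    for m in range(1, n + 1):
        num = (2 * n + (n - 1) * m) * _binom(n, m)
        den = n * m * (m + 1) * _binom(2 * n - 1, m)
        p = Fraction(num, den) if denom_exact else num / den
        out[m] = p
    return out


@dataclass(frozen=True)
class PairKernel:
    """Complete division kernel for one ``(n, mode)``.

    Attributes
    ----------
    n : int
        Copy number.
    mode : str
        ``"regular"`` or ``"random"``.
    pair_probs : tuple of dict
        ``pair_probs[i]`` maps unordered ``(j, k)`` (``j <= k``) to its
        probability, for a parent with ``i`` mutant copies.
    marginal : numpy.ndarray
        ``(n+1) x (n+1)`` row-stochastic matrix: entry ``(i, j)`` is the
        probability that a uniformly chosen daughter of an ``i``-parent has
        ``j`` mutant copies.
    """

    n: int
    mode: str
    pair_probs: tuple
    marginal: np.ndarray

    def pairs(self, i: int):
        _check_range(self.n, i)
        return self.pair_probs[i]


@lru_cache(maxsize=None)
def pair_kernel(n: int, mode: str) -> PairKernel:
    """Build (and cache) the full kernel for ``(n, mode)``."""
    if mode not in MODES:
        raise ValueError(f"unknown replication mode {mode!r}; expected one of {MODES}")
    fn = regular_pair_probs if mode == "regular" else random_pair_probs
    pair_probs = tuple(dict(fn(n, i)) for i in range(n + 1))
    marginal = np.zeros((n + 1, n + 1))
    for i, dist in enumerate(pair_probs):
        for (j, k), p in dist.items():
            pf = float(p)
            # each daughter of the unordered pair is chosen with prob 1/2
            marginal[i, j] += 0.5 * pf
            marginal[i, k] += 0.5 * pf
    marginal.setflags(write=False)
    return PairKernel(n=n, mode=mode, pair_probs=pair_probs, marginal=marginal)


def kernel_dataframe(n: int, mode: str):
    """Tidy table of the pair kernel (columns: n, mode, i, j, k, probability)."""
    import pandas as pd

    kern = pair_kernel(n, mode)
    rows = []
    for i in range(n + 1):
        for (j, k), p in sorted(kern.pairs(i).items()):
            rows.append({"n": n, "mode": mode, "i": i, "j": j, "k": k,
                         "probability": float(p)})
    return pd.DataFrame(rows)
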