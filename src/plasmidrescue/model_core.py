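"""Cell types, fitness functions, and birth/death rates.

A bacterial cell carries ``n`` copies of a plasmid; ``i`` of them bear the
mutant allele.  The net (Malthusian) growth rate of a cell with ``i`` mutant
copies is ``s(n, i)``: its division rate is ``lambda_i = 1 + s(n, i)`` and its
death rate is fixed at ``mu_i = 1``, so time is measured in units of the mean
cell lifespan.  Both homozygote classes (``i = 0`` and ``i = n``) must decline
(``s < 0``); only heterozygous cells can sustain the population.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

__all__ = [
    "FitnessModel",
    "dominant_fitness",
    "peaked_fitness",
    "reproduction_probability",
    "rho_hom",
    "rho_het",
    "rescale_time",
]

_KINDS = ("dominant", "peaked", "custom")


def dominant_fitness(n: int, i: int, s_min: float, s_max: float) -> float:
    """Dominant fitness: a single copy of either allele confers its full effect.

    Heterozygotes of any composition get ``s_max``; both homozygotes get
    ``s_min``.

    Parameters
    ----------
    n : int
        Plasmid copy number (>= 1).
    i : int
        Number of mutant plasmid copies, ``0 <= i <= n``.
    s_min : float
        Homozygote net growth rate, must be negative.
    s_max : float
        Heterozygote net growth rate, must be positive.
    """
    _check_args(n, i, s_min, s_max)
    return s_min if i == 0 or i == n else s_max


def peaked_fitness(n: int, i: int, s_min: float, s_max: float) -> float:
    """Peaked fitness: linear interpolation peaking at the balanced heterozygote.

    ``s(n, i) = s_max - (2 (s_max - s_min) / n) |i - n/2|``: maximal at an exact
    half-and-half plasmid mixture, declining linearly to ``s_min`` at either
    homozygote.  For odd ``n`` the half-integer ``|i - n/2|`` is evaluated
    exactly.
    """
    _check_args(n, i, s_min, s_max)
    return s_max - (2.0 * (s_max - s_min) / n) * abs(i - n / 2.0)


def _check_args(n: int, i: int, s_min: float, s_max: float) -> None:
    if n < 1:
        raise ValueError(f"copy number n must be >= 1, got {n}")
    if not 0 <= i <= n:
        raise ValueError(f"mutant count i={i} out of range [0, {n}]")
    if not s_min < 0:
        raise ValueError(f"s_min must be negative, got {s_min}")
    if not s_max > 0:
        raise ValueError(f"s_max must be positive, got {s_max}")


@dataclass(frozen=True)
class FitnessModel:
    """Copy number, fitness function, and per-type birth/death rates.

    Attributes
    ----------
    n : int
        Plasmid copy number per cell.
    kind : str
        One of ``"dominant"``, ``"peaked"``, ``"custom"``.
    s_min, s_max : float
        Parameters of the built-in fitness functions (ignored for custom
        tables except for validation bookkeeping).
    custom_table : sequence of float, optional
        Explicit table ``s(n, i)`` for ``i = 0..n`` (kind ``"custom"``).

    Every fitness model must satisfy ``s(n, 0) < 0`` and ``s(n, n) < 0``
    (declining homozygotes) and ``s(n, i) > -1`` for all ``i`` (nonnegative
    birth rate ``lambda_i = 1 + s``).
    """

    n: int
    kind: str = "dominant"
    s_min: float = -0.1
    s_max: float = 1.0
    custom_table: Optional[Sequence[float]] = None
    _table: tuple = field(init=False, repr=False, compare=False, default=())

    def __post_init__(self):
        if self.kind not in _KINDS:
            raise ValueError(f"unknown fitness kind {self.kind!r}; expected one of {_KINDS}")
        if self.n < 1:
            raise ValueError(f"copy number n must be >= 1, got {self.n}")
        if self.kind == "custom":
            if self.custom_table is None:
                raise ValueError("custom fitness requires a table of n+1 growth rates")
            table = tuple(float(x) for x in self.custom_table)
            if len(table) != self.n + 1:
                raise ValueError(
                    f"custom table must have n+1={self.n + 1} entries, got {len(table)}"
                )
        else:
            fn = dominant_fitness if self.kind == "dominant" else peaked_fitness
            table = tuple(fn(self.n, i, self.s_min, self.s_max) for i in range(self.n + 1))
        if not (table[0] < 0 and table[-1] < 0):
            raise ValueError(
                "both homozygote classes must decline: require s(n,0) < 0 and s(n,n) < 0, "
                f"got s(n,0)={table[0]}, s(n,n)={table[-1]}"
            )
        if min(table) <= -1.0:
            raise ValueError(
                f"net growth rates must exceed -1 (birth rate 1+s >= 0); min is {min(table)}"
            )
        object.__setattr__(self, "_table", table)

    def s(self, i: int) -> float:
        """Net growth rate of a cell with ``i`` mutant plasmids."""
        if not 0 <= i <= self.n:
            raise ValueError(f"mutant count i={i} out of range [0, {self.n}]")
        return self._table[i]

    def birth_rate(self, i: int) -> float:
        """Division rate ``lambda_i = 1 + s(n, i)``."""
        return 1.0 + self.s(i)

    @property
    def death_rate(self) -> float:
        """Death rate ``mu_i``, fixed at 1 (sets the time unit)."""
        return 1.0

    def growth_rates(self) -> tuple:
        """The full table ``s(n, 0..n)``."""
        return self._table


def reproduction_probability(model: FitnessModel, i: int) -> float:
    """Probability ``rho_i = lambda_i / (lambda_i + mu_i)`` that a cell divides
    before it dies."""
    lam = model.birth_rate(i)
    return lam / (lam + 1.0)


def rho_hom(s_min: float) -> float:
    """Reproduction probability of a homozygote, ``(1+s_min)/(2+s_min)``."""
    if not -1 < s_min < 0:
        raise ValueError(f"s_min must lie in (-1, 0), got {s_min}")
    return (1.0 + s_min) / (2.0 + s_min)


def rho_het(s_max: float) -> float:
    """Reproduction probability of a heterozygote under dominant fitness,
    ``(1+s_max)/(2+s_max)``."""
    if not s_max > 0:
        raise ValueError(f"s_max must be positive, got {s_max}")
    return (1.0 + s_max) / (2.0 + s_max)


def rescale_time(t: float, mu: float) -> float:
    """Convert a time measured in mean-lifespan units to a death rate ``mu != 1``.

    All results are computed with ``mu_i = 1``; for a general death rate the
    same process unfolds with time multiplied by ``1/mu`` (and growth rates
    interpreted per mean lifespan), so ``t`` lifespans correspond to ``t / mu``
    external time units.
    """
    if mu <= 0:
        raise ValueError(f"death rate must be positive, got {mu}")
    return t / mu
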