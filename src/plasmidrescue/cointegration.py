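"""Plasmid cointegration: fusion of plasmids into multimers.

Two plasmids can fuse into a cointegrate; the resulting m-mer carries m
copies of the replication/copy-number control system and hence counts m-fold
against the copy number ``n``.  Fusion of plasmids with *different* alleles
locks heterozygosity into a single molecule that segregation can no longer
separate; fusion of like plasmids merely reduces the number of independently
segregating units.  This module extends the regular-replication,
dominant-fitness model with a per-cell-cycle fusion probability ``kappa``
(no cointegrate resolution, at most one fusion per cycle, mutations arising
only in all-monomer cells).

A cell type is the multiset of its plasmid molecules, each molecule a
multiset over the two alleles A (wild type) and B (mutant); it is written
like ``(AA)(B)(AB)``.  A molecule is represented as a pair ``(a, b)`` of
allele counts and a cell type as the canonically sorted tuple of its
molecules.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from functools import lru_cache
from itertools import product
from math import comb
from typing import Dict, Tuple

import numpy as np

from .branching import SNAP_TOL, solve_offspring_fixed_point
from .model_core import rho_het, rho_hom

__all__ = [
    "CointegrateCellType",
    "CointegrationConfig",
    "enumerate_cell_types",
    "fusion_transition_probs",
    "division_probs",
    "cointegrate_extinction",
    "cointegrate_establishment",
    "kappa_infinity_establishment",
]

Molecule = Tuple[int, int]  # (a, b) allele counts, a + b >= 1

#: state-space enumeration refuses larger n unless explicitly overridden
DEFAULT_N_CAP = 8


def _mol_key(mol: Molecule):
    # size first, then A-rich before B-rich within a size class
    a, b = mol
    return (a + b, b, a)


@dataclass(frozen=True)
class CointegrateCellType:
    """A cell's plasmid complement: a canonical multiset of molecules.

    ``molecules`` is a tuple of ``(a, b)`` allele-count pairs sorted by
    (size, composition); two types are equal exactly when their canonical
    forms are equal.  The total allele-bearing units sum to the copy
    number ``n``.
    """

    molecules: Tuple[Molecule, ...]

    def __post_init__(self):
        if not self.molecules:
            raise ValueError("a cell type must contain at least one molecule")
        for a, b in self.molecules:
            if a < 0 or b < 0 or a + b < 1:
                raise ValueError(f"invalid molecule ({a}, {b}): allele counts must be "
                                 "nonnegative and each molecule nonempty")
        canon = tuple(sorted(self.molecules, key=_mol_key))
        object.__setattr__(self, "molecules", canon)

    @property
    def n(self) -> int:
        """Total copy-number units (each m-mer counts m times)."""
        return sum(a + b for a, b in self.molecules)

    @property
    def n_molecules(self) -> int:
        return len(self.molecules)

    @property
    def allele_counts(self) -> Tuple[int, int]:
        """Total (A, B) allele counts, irrespective of molecule structure."""
        return (sum(a for a, _ in self.molecules), sum(b for _, b in self.molecules))

    @property
    def is_heterozygous(self) -> bool:
        a, b = self.allele_counts
        return a > 0 and b > 0

    def label(self) -> str:
        """Human-readable form like ``(AA)(B)(AB)``."""
        return "".join("(" + "A" * a + "B" * b + ")" for a, b in self.molecules)

    @classmethod
    def from_label(cls, label: str) -> "CointegrateCellType":
        """Parse a ``(AA)(B)(AB)``-style label."""
        mols = []
        for part in label.replace(")", ")|").split("|"):
            part = part.strip()
            if not part:
                continue
            if not (part.startswith("(") and part.endswith(")")):
                raise ValueError(f"malformed molecule {part!r} in {label!r}")
            inner = part[1:-1]
            if set(inner) - {"A", "B"} or not inner:
                raise ValueError(f"malformed molecule {part!r} in {label!r}")
            mols.append((inner.count("A"), inner.count("B")))
        return cls(tuple(mols))

    @classmethod
    def all_monomers(cls, n_a: int, n_b: int) -> "CointegrateCellType":
        """The all-monomer type with ``n_a`` A-plasmids and ``n_b`` B-plasmids."""
        return cls(((1, 0),) * n_a + ((0, 1),) * n_b)


@dataclass(frozen=True)
class CointegrationConfig:
    """Parameters of the cointegration model.

    ``kappa`` is the per-cell-cycle fusion probability; ``math.inf`` selects
    the limiting model in which the first mutation is immediately followed by
    fusion of all plasmids into one multimer.  Fitness is the dominant
    function of the allele counts only.
    """

    n: int
    s_min: float = -0.1
    s_max: float = 1.0
    kappa: float = 0.0

    def __post_init__(self):
        if self.n < 1:
            raise ValueError(f"copy number n must be >= 1, got {self.n}")
        if not -1 < self.s_min < 0:
            raise ValueError(f"s_min must lie in (-1, 0), got {self.s_min}")
        if self.s_max <= 0:
            raise ValueError(f"s_max must be positive, got {self.s_max}")
        if not (math.isinf(self.kappa) or 0.0 <= self.kappa <= 1.0):
            raise ValueError(f"kappa must lie in [0, 1] or be inf, got {self.kappa}")

    def rho(self, cell: CointegrateCellType) -> float:
        return rho_het(self.s_max) if cell.is_heterozygous else rho_hom(self.s_min)


@lru_cache(maxsize=None)
def enumerate_cell_types(n: int, cap: int = DEFAULT_N_CAP) -> Tuple[CointegrateCellType, ...]:
    """All distinct cell types at copy number ``n``: multisets of nonempty
    allele-multisets with unit totals summing to ``n``.

    The state space grows combinatorially, so enumeration refuses ``n`` above
    ``cap`` unless a larger cap is passed explicitly.
    """
    if n < 1:
        raise ValueError(f"copy number n must be >= 1, got {n}")
    if n > cap:
        raise ValueError(
            f"state-space enumeration for n={n} exceeds the cap ({cap}); "
            "pass a larger cap explicitly to override"
        )
    molecules = sorted(
        ((a, m - a) for m in range(1, n + 1) for a in range(m + 1)),
        key=_mol_key,
    )

    types = []

    def extend(prefix, start, remaining):
        if remaining == 0:
            types.append(CointegrateCellType(tuple(prefix)))
            return
        for idx in range(start, len(molecules)):
            mol = molecules[idx]
            size = mol[0] + mol[1]
            if size > remaining:
                continue
            prefix.append(mol)
            extend(prefix, idx, remaining - size)
            prefix.pop()

    extend([], 0, n)
    return tuple(types)


def fusion_transition_probs(cell: CointegrateCellType) -> Dict[CointegrateCellType, Fraction]:
    """Distribution over cell types after one fusion event.

    Conditional on a fusion occurring, a uniformly random unordered pair of
    the cell's molecules is concatenated into one.  Single-molecule types
    return an empty distribution (no pair exists; their per-cycle fusion
    probability is 0).
    """
    mols = cell.molecules
    M = len(mols)
    if M < 2:
        return {}
    total_pairs = comb(M, 2)
    out: Dict[CointegrateCellType, Fraction] = {}
    # pairs of positions; molecules with equal composition are interchangeable
    counts: Dict[Molecule, int] = {}
    for mol in mols:
        counts[mol] = counts.get(mol, 0) + 1
    species = sorted(counts, key=_mol_key)
    for si in range(len(species)):
        for sj in range(si, len(species)):
            s, t = species[si], species[sj]
            npairs = comb(counts[s], 2) if si == sj else counts[s] * counts[t]
            if npairs == 0:
                continue
            rest = list(mols)
            rest.remove(s)
            rest.remove(t)
            fused = (s[0] + t[0], s[1] + t[1])
            new = CointegrateCellType(tuple(rest) + (fused,))
            out[new] = out.get(new, Fraction(0)) + Fraction(npairs, total_pairs)
    return out


@lru_cache(maxsize=None)
def division_probs(
    cell: CointegrateCellType,
) -> Dict[Tuple[CointegrateCellType, CointegrateCellType], Fraction]:
    """Distribution over unordered daughter-type pairs at division.

    Every molecule is duplicated (regular replication), giving two labeled
    copies of each; the ``2M`` labeled molecules are then split uniformly at
    random over all assortments in which each daughter receives exactly ``n``
    copy-number units.  Assortments violating the unit constraint are
    impossible; e.g. an ``(AAA)(B)`` parent can only produce daughters
    identical to itself.
    """
    n = cell.n
    counts: Dict[Molecule, int] = {}
    for mol in cell.molecules:
        counts[mol] = counts.get(mol, 0) + 1
    species = sorted(counts, key=_mol_key)
    dup = [2 * counts[s] for s in species]
    sizes = [s[0] + s[1] for s in species]

    weighted: Dict[Tuple[CointegrateCellType, CointegrateCellType], int] = {}
    total = 0
    for take in product(*(range(d + 1) for d in dup)):
        if sum(t * s for t, s in zip(take, sizes)) != n:
            continue
        ways = 1
        for t, d in zip(take, dup):
            ways *= comb(d, t)
        d1 = []
        d2 = []
        for s, t, d in zip(species, take, dup):
            d1.extend([s] * t)
            d2.extend([s] * (d - t))
        pair = tuple(sorted(
            (CointegrateCellType(tuple(d1)), CointegrateCellType(tuple(d2))),
            key=lambda c: c.molecules,
        ))
        weighted[pair] = weighted.get(pair, 0) + ways
        total += ways
    if total == 0:
        raise RuntimeError(f"no valid division split for {cell.label()}")
    return {pair: Fraction(w, total) for pair, w in weighted.items()}


@dataclass(frozen=True)
class CointegrateExtinction:
    """Extinction probabilities over the full cointegrate state space."""

    config: CointegrationConfig
    types: Tuple[CointegrateCellType, ...]
    Q: np.ndarray
    iterations: int
    residual: float

    def __getitem__(self, cell: CointegrateCellType) -> float:
        return float(self.Q[self.types.index(cell)])


def cointegrate_extinction(config: CointegrationConfig, *,
                           cap: int = DEFAULT_N_CAP,
                           tol: float = 1e-12,
                           max_iter: int = 10**6) -> CointegrateExtinction:
    """Least-fixed-point extinction probabilities for every cell type.

    Within one cell cycle a multi-molecule cell first fuses a molecule pair
    with probability ``kappa`` (single-molecule cells cannot fuse), then
    divides by the regular-replication split; the extinction recursion mixes
    the fused and unfused division kernels accordingly.
    """
    if math.isinf(config.kappa):
        raise ValueError("kappa=inf has no finite-state recursion; use "
                         "kappa_infinity_establishment")
    types = enumerate_cell_types(config.n, cap=cap)
    index = {t: ix for ix, t in enumerate(types)}
    kappa = config.kappa

    I, J, K, W = [], [], [], []
    rho = np.zeros(len(types))
    for ix, cell in enumerate(types):
        rho[ix] = config.rho(cell)
        eff: Dict[Tuple[int, int], float] = {}

        def add(pairs: dict, weight: float):
            for (b, c), p in pairs.items():
                key = (index[b], index[c])
                eff[key] = eff.get(key, 0.0) + weight * float(p)

        fusion = fusion_transition_probs(cell)
        k_a = kappa if fusion else 0.0
        if k_a > 0.0:
            for fused_type, pf in fusion.items():
                add(division_probs(fused_type), k_a * float(pf))
        if k_a < 1.0 or not fusion:
            add(division_probs(cell), 1.0 - k_a)
        for (b, c), p in eff.items():
            I.append(ix)
            J.append(b)
            K.append(c)
            W.append(p)

    z, iterations, residual = solve_offspring_fixed_point(
        np.array(I), np.array(J), np.array(K), np.array(W), rho,
        tol=tol, max_iter=max_iter)
    Q = np.where(z > 1.0 - SNAP_TOL, 1.0, z)
    Q.setflags(write=False)
    return CointegrateExtinction(config=config, types=types, Q=Q,
                                 iterations=iterations, residual=residual)


def cointegrate_establishment(config: CointegrationConfig, *,
                              cap: int = DEFAULT_N_CAP) -> float:
    """Establishment probability of a new mutation under cointegration.

    The mutation first appears in an all-monomer cell with a single mutant
    plasmid, so establishment is ``1 - Q`` of the ``(A)^(n-1)(B)`` type.
    With ``kappa = inf`` the closed-form single-multimer limit is returned.
    """
    if config.n < 2:
        return 0.0
    if math.isinf(config.kappa):
        return kappa_infinity_establishment(config)
    sol = cointegrate_extinction(config, cap=cap)
    founder = CointegrateCellType.all_monomers(config.n - 1, 1)
    p = 1.0 - sol[founder]
    return 0.0 if p < SNAP_TOL else float(p)


def kappa_infinity_establishment(config: CointegrationConfig) -> float:
    """Theoretical maximum establishment probability: the mutation is
    immediately followed by fusion of all plasmids into one heterozygous
    multimer, whose lineage is a single-type binary branching process with
    establishment probability ``s_max / (1 + s_max)``."""
    if config.n < 2:
        return 0.0
    return config.s_max / (1.0 + config.s_max)
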