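"""Cointegrate state space, fusion/division kernels, and establishment."""

from fractions import Fraction
from itertools import product

import math
import pytest

from plasmidrescue.branching import establishment_regular
from plasmidrescue.cointegration import (
    CointegrateCellType,
    CointegrationConfig,
    cointegrate_establishment,
    cointegrate_extinction,
    division_probs,
    enumerate_cell_types,
    fusion_transition_probs,
    kappa_infinity_establishment,
)
from plasmidrescue.model_core import FitnessModel
from plasmidrescue.segregation import regular_pair_probs

T = CointegrateCellType.from_label


def oracle_count_types(n):
    """Independent enumeration: integer partitions of n crossed with allele
    assignments, deduplicated as multisets."""

    def partitions(total, max_part):
        if total == 0:
            yield ()
            return
        for part in range(min(total, max_part), 0, -1):
            for rest in partitions(total - part, part):
                yield (part,) + rest

    seen = set()
    for shape in partitions(n, n):
        for alleles in product(*(range(m + 1) for m in shape)):
            mols = tuple(sorted((a, m - a) for m, a in zip(shape, alleles)))
            seen.add(mols)
    return len(seen)


class TestEnumeration:
    def test_n1(self):
        labels = {t.label() for t in enumerate_cell_types(1)}
        assert labels == {"(A)", "(B)"}

    def test_n2_exhaustive(self):
        labels = {t.label() for t in enumerate_cell_types(2)}
        assert labels == {"(A)(A)", "(A)(B)", "(B)(B)", "(AA)", "(AB)", "(BB)"}

    @pytest.mark.parametrize("n", range(1, 7))
    def test_count_matches_partition_oracle(self, n):
        assert len(enumerate_cell_types(n)) == oracle_count_types(n)

    def test_no_duplicates(self):
        types = enumerate_cell_types(5)
        assert len(types) == len(set(types))

    def test_unit_totals(self):
        assert all(t.n == 6 for t in enumerate_cell_types(6))

    def test_cap_enforced(self):
        with pytest.raises(ValueError, match="cap"):
            enumerate_cell_types(9)
        assert len(enumerate_cell_types(9, cap=9)) > 0


class TestCanonicalForm:
    def test_order_insensitive(self):
        assert T("(AB)(A)(B)") == T("(B)(A)(AB)")

    def test_label_round_trip(self):
        for label in ["(A)(A)(B)", "(AAB)(B)", "(AABB)"]:
            assert T(label).label() == label or \
                CointegrateCellType.from_label(T(label).label()) == T(label)

    def test_allele_counts(self):
        assert T("(AA)(B)(AB)").allele_counts == (3, 2)

    def test_empty_molecule_rejected(self):
        with pytest.raises(ValueError):
            CointegrateCellType(((0, 0), (1, 1)))


class TestFusion:
    def test_printed_examples(self):
        dist = fusion_transition_probs(T("(A)(A)(B)"))
        assert dist == {T("(A)(AB)"): Fraction(2, 3), T("(AA)(B)"): Fraction(1, 3)}

    def test_no_resolution(self):
        # fusion only: (AA)(A)(B) can never split the dimer
        dist = fusion_transition_probs(T("(AA)(A)(B)"))
        assert T("(A)(A)(AB)") not in dist

    def test_single_molecule_cannot_fuse(self):
        assert fusion_transition_probs(T("(AABB)")) == {}

    @pytest.mark.parametrize("n", range(2, 6))
    def test_normalization_and_allele_conservation(self, n):
        for cell in enumerate_cell_types(n):
            dist = fusion_transition_probs(cell)
            if cell.n_molecules < 2:
                assert dist == {}
                continue
            assert sum(dist.values()) == 1
            for new, _ in dist.items():
                assert new.allele_counts == cell.allele_counts
                assert new.n_molecules == cell.n_molecules - 1


class TestDivision:
    def test_constrained_multimer_breeds_true(self):
        dist = division_probs(T("(AAA)(B)"))
        assert dist == {(T("(AAA)(B)"), T("(AAA)(B)")): Fraction(1)}

    def test_single_full_multimer_breeds_true(self):
        dist = division_probs(T("(AABB)"))
        assert dist == {(T("(AABB)"), T("(AABB)")): Fraction(1)}

    @pytest.mark.parametrize("n", range(2, 6))
    def test_all_monomer_cells_reproduce_base_kernel(self, n):
        """An all-monomer parent's daughter mutant counts follow the regular
        replication kernel exactly."""
        for i in range(n + 1):
            parent = CointegrateCellType.all_monomers(n - i, i)
            dist = {}
            for (d1, d2), p in division_probs(parent).items():
                j, k = d1.allele_counts[1], d2.allele_counts[1]
                pair = (min(j, k), max(j, k))
                dist[pair] = dist.get(pair, Fraction(0)) + p
            assert dist == regular_pair_probs(n, i)

    @pytest.mark.parametrize("n", range(1, 7))
    def test_normalization_and_joint_allele_conservation(self, n):
        for cell in enumerate_cell_types(n):
            dist = division_probs(cell)
            assert sum(dist.values()) == 1
            a, b = cell.allele_counts
            for (d1, d2), _ in dist.items():
                assert d1.n == d2.n == n
                assert (d1.allele_counts[0] + d2.allele_counts[0],
                        d1.allele_counts[1] + d2.allele_counts[1]) == (2 * a, 2 * b)


class TestExtinctionAndEstablishment:
    def test_homozygous_types_go_extinct(self):
        cfg = CointegrationConfig(n=3, s_max=2.0, kappa=0.5)
        sol = cointegrate_extinction(cfg)
        for cell in sol.types:
            a, b = cell.allele_counts
            if a == 0 or b == 0:
                assert sol[cell] == 1.0

    def test_kappa_zero_reduces_to_base_model(self):
        for n, s_max in [(3, 2.0), (4, 1.0), (5, 0.8)]:
            cfg = CointegrationConfig(n=n, s_max=s_max, kappa=0.0)
            base = establishment_regular(FitnessModel(n=n, s_max=s_max, s_min=-0.1))
            assert abs(cointegrate_establishment(cfg) - base) < 1e-10

    def test_no_threshold_for_positive_kappa(self):
        # n=2, s_max=1 is below the Theorem-1 threshold (2), yet fusion makes
        # establishment possible
        assert cointegrate_establishment(
            CointegrationConfig(n=2, s_max=1.0, kappa=0.0)) == 0.0
        p = cointegrate_establishment(CointegrationConfig(n=2, s_max=1.0, kappa=1.0))
        assert p > 0.0

    def test_monotone_in_kappa(self):
        kappas = [0.0, 1e-3, 1e-2, 1e-1, 1.0]
        vals = [cointegrate_establishment(CointegrationConfig(n=4, s_max=1.0, kappa=k))
                for k in kappas]
        assert all(b >= a - 1e-12 for a, b in zip(vals, vals[1:]))

    def test_kappa_infinity_closed_form(self):
        cfg = CointegrationConfig(n=4, s_max=1.0, kappa=math.inf)
        assert kappa_infinity_establishment(cfg) == pytest.approx(0.5)
        assert cointegrate_establishment(cfg) == pytest.approx(0.5)

    def test_kappa_infinity_matches_single_multimer_solver(self):
        # the closed form equals 1 - Q of the full heterozygous multimer in
        # the finite-kappa state space (single-molecule types cannot fuse)
        cfg = CointegrationConfig(n=3, s_max=2.0, kappa=0.3)
        sol = cointegrate_extinction(cfg)
        multimer = T("(AAB)")
        assert 1.0 - sol[multimer] == pytest.approx(
            kappa_infinity_establishment(cfg), abs=1e-10)

    def test_kappa_infinity_is_upper_bound(self):
        for kappa in (0.0, 0.1, 1.0):
            cfg = CointegrationConfig(n=4, s_max=1.0, kappa=kappa)
            assert cointegrate_establishment(cfg) <= \
                kappa_infinity_establishment(cfg) + 1e-12

    def test_n1_cannot_establish(self):
        assert cointegrate_establishment(CointegrationConfig(n=1, kappa=0.5)) == 0.0

    def test_invalid_kappa_rejected(self):
        with pytest.raises(ValueError, match="kappa"):
            CointegrationConfig(n=3, kappa=1.5)
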