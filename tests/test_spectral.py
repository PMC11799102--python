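"""Expected-progeny matrix, eigenvalues, thresholds, stationary composition."""

import math

import numpy as np
import pytest

from plasmidrescue.branching import establishment_probability
from plasmidrescue.model_core import FitnessModel, reproduction_probability, rho_het, rho_hom
from plasmidrescue.spectral import (
    chi_eigenvalues,
    critical_n,
    critical_s_max,
    critical_s_max_empirical,
    half_and_half_threshold,
    leading_eigenvalue,
    progeny_matrix,
    rescued_growth_rate,
    segregation_marginal_matrix,
    stationary_type_distribution,
)


class TestProgenyMatrix:
    def test_factorization_M_equals_2RP(self):
        for mode in ("regular", "random"):
            m = FitnessModel(n=5, s_max=1.0)
            rho = np.diag([reproduction_probability(m, i) for i in range(6)])
            P = segregation_marginal_matrix(5, mode)
            assert np.allclose(progeny_matrix(m, mode), 2 * rho @ P, atol=1e-14)

    def test_row_sums_are_two_rho(self):
        m = FitnessModel(n=6, s_max=2.0, s_min=-0.2)
        for mode in ("regular", "random"):
            M = progeny_matrix(m, mode)
            expected = [2 * reproduction_probability(m, i) for i in range(7)]
            assert np.allclose(M.sum(axis=1), expected, atol=1e-12)

    def test_homozygote_rows_are_diagonal(self):
        m = FitnessModel(n=4, s_max=1.0, s_min=-0.1)
        for mode in ("regular", "random"):
            M = progeny_matrix(m, mode)
            hom = 2 * rho_hom(-0.1)
            for row in (0, 4):
                assert M[row, row] == pytest.approx(hom, abs=1e-12)
                off = np.delete(M[row], row)
                assert np.allclose(off, 0.0, atol=1e-14)

    def test_heterozygote_row_n2_closed_form(self):
        # 2 rho_het * (1/6, 2/3, 1/6) with s_max = 4
        m = FitnessModel(n=2, s_max=4.0)
        M = progeny_matrix(m, "regular")
        assert M[1] == pytest.approx([5 / 18, 10 / 9, 5 / 18], abs=1e-12)


class TestChiEigenvalues:
    def test_first_two_are_one(self):
        for n in range(2, 11):
            chi = chi_eigenvalues(n)
            assert chi[0] == 1.0 and chi[1] == 1.0

    def test_chi2_closed_form(self):
        assert chi_eigenvalues(4)[2] == pytest.approx(6 / 7, abs=1e-14)

    def test_nonincreasing(self):
        for n in (3, 7, 12):
            chi = chi_eigenvalues(n)
            assert np.all(np.diff(chi) <= 1e-14)

    @pytest.mark.parametrize("n", range(2, 11))
    def test_matches_dense_eigensolver(self, n):
        P = segregation_marginal_matrix(n, "regular")
        numeric = np.sort(np.linalg.eigvals(P).real)[::-1]
        assert np.allclose(numeric, chi_eigenvalues(n), atol=1e-10)


class TestThresholds:
    def test_regular_n2(self):
        # heterozygote division rate 1 + s_max must exceed 3
        assert critical_s_max(2, "regular") == 2.0

    def test_random_n3(self):
        assert critical_s_max(3, "random") == pytest.approx(1.5)

    def test_random_exceeds_regular(self):
        for n in range(2, 30):
            assert critical_s_max(n, "random") > critical_s_max(n, "regular")

    def test_single_copy_threshold_infinite(self):
        assert math.isinf(critical_s_max(1, "regular"))

    def test_critical_n_examples(self):
        assert critical_n(1.0, "regular") == 3   # smallest integer > 2.5
        assert critical_n(1.0, "random") == 4    # smallest integer > ~3.62

    @pytest.mark.parametrize("mode", ["regular", "random"])
    @pytest.mark.parametrize("s_max", [0.3, 1.0, 3.0])
    def test_critical_n_consistent_with_solver(self, mode, s_max):
        n_c = critical_n(s_max, mode)
        above = establishment_probability(FitnessModel(n=n_c, s_max=s_max), mode)
        assert above > 0.0
        if n_c > 2:
            below = establishment_probability(FitnessModel(n=n_c - 1, s_max=s_max), mode)
            assert below == 0.0

    @pytest.mark.parametrize("mode", ["regular", "random"])
    @pytest.mark.parametrize("n", [2, 5, 9])
    def test_eigenvalue_sign_flips_at_threshold(self, mode, n):
        s_c = critical_s_max(n, mode)
        eps = 1e-6
        below = leading_eigenvalue(FitnessModel(n=n, s_max=s_c * (1 - eps)), mode)
        above = leading_eigenvalue(FitnessModel(n=n, s_max=s_c * (1 + eps)), mode)
        assert below <= 1.0 + 1e-9 <= above + 2e-6

    def test_bisection_against_closed_form(self):
        # the full n = 2..10 sweep runs in the acceptance suite
        for mode in ("regular", "random"):
            emp = critical_s_max_empirical(3, mode=mode)
            assert emp == pytest.approx(critical_s_max(3, mode), abs=1e-4)

    def test_establishment_zero_iff_subcritical(self):
        for mode in ("regular", "random"):
            for n in (2, 4, 6):
                for s_max in (0.2, 0.6, 1.5, 3.0):
                    m = FitnessModel(n=n, s_max=s_max)
                    p = establishment_probability(m, mode)
                    lead = leading_eigenvalue(m, mode)
                    assert (p == 0.0) == (lead <= 1.0 + 1e-9)


class TestLeadingEigenvalue:
    def test_dominant_closed_form(self):
        for n in (2, 4, 8):
            for s_max in (0.5, 1.0, 4.0):
                m = FitnessModel(n=n, s_max=s_max, s_min=-0.1)
                het = 2 * rho_het(s_max) * 2 * (n - 1) / (2 * n - 1)
                expected = max(2 * rho_hom(-0.1), het)
                assert leading_eigenvalue(m, "regular") == pytest.approx(expected,
                                                                         abs=1e-10)

    def test_random_interior_column_sums(self):
        # the all-ones vector is a left eigenvector of the interior block of
        # M / (2 rho_het), so every column sums to its eigenvalue
        for n in range(2, 11):
            m = FitnessModel(n=n, s_max=1.0)
            M = progeny_matrix(m, "random")
            B = M[1:n, :][:, 1:n] / (2 * rho_het(1.0))
            expected = (n - 1) * (2 * n + 1) / ((n + 1) * (2 * n - 1))
            assert np.allclose(B.sum(axis=0), expected, atol=1e-12)


class TestStationaryDistribution:
    def test_random_dominant_heterozygotes_uniform(self):
        m = FitnessModel(n=6, s_max=1.0, s_min=-0.1)
        dist = stationary_type_distribution(m, "random")
        interior = dist[1:6]
        assert np.allclose(interior, interior[0], atol=1e-10)

    def test_symmetric_under_allele_relabeling(self):
        for mode in ("regular", "random"):
            m = FitnessModel(n=4, s_max=1.0, s_min=-0.1)
            dist = stationary_type_distribution(m, mode)
            assert np.allclose(dist, dist[::-1], atol=1e-10)

    def test_normalized_and_nonnegative(self):
        m = FitnessModel(n=5, kind="peaked", s_max=2.0, s_min=-0.1)
        dist = stationary_type_distribution(m, "regular")
        assert np.all(dist >= 0)
        assert dist.sum() == pytest.approx(1.0, abs=1e-12)

    def test_subcritical_model_has_no_distribution(self):
        # n=4, random, peaked at the published parameters is subcritical
        m = FitnessModel(n=4, kind="peaked", s_max=1.0, s_min=-0.1)
        with pytest.raises(ValueError, match="subcritical"):
            stationary_type_distribution(m, "random")


class TestRescuedGrowthRate:
    def test_regular_n2_below_threshold_is_negative(self):
        assert rescued_growth_rate(2, 1.0, "regular") == pytest.approx(-1 / 3)

    @pytest.mark.parametrize("mode", ["regular", "random"])
    def test_positive_iff_above_threshold(self, mode):
        for n in range(2, 12):
            s_c = critical_s_max(n, mode)
            if math.isfinite(s_c):
                assert rescued_growth_rate(n, s_c * 1.001, mode) > 0
                assert rescued_growth_rate(n, s_c * 0.999, mode) < 0

    def test_matches_progeny_eigenvalue_shift(self):
        # continuous-time growth rate = (1+s_max)(2 chi - 1) - 1 equals the
        # leading eigenvalue of Lambda (2P - I) - D computed numerically
        n, s_max = 5, 1.0
        m = FitnessModel(n=n, s_max=s_max, s_min=-0.1)
        for mode in ("regular", "random"):
            P = segregation_marginal_matrix(n, mode)
            lam = np.diag([m.birth_rate(i) for i in range(n + 1)])
            G = lam @ (2 * P - np.eye(n + 1)) - np.eye(n + 1)
            lead = np.max(np.linalg.eigvals(G).real)
            assert rescued_growth_rate(n, s_max, mode) == pytest.approx(lead,
                                                                        abs=1e-10)


class TestHalfAndHalfComparison:
    def test_value_n4(self):
        assert half_and_half_threshold(4) == pytest.approx(1 / 3)

    def test_boundary_n3_equals_one(self):
        assert half_and_half_threshold(3) == 1.0

    def test_weaker_than_exact_threshold_for_n_above_3(self):
        for n in range(4, 15):
            assert half_and_half_threshold(n) < critical_s_max(n, "regular")

    def test_rejects_small_n(self):
        with pytest.raises(ValueError):
            half_and_half_threshold(2)
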