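"""UNREST construction, uniformization and the codon lift."""

import numpy as np
import pytest

import fourfold as ff
from fourfold.mutation import (
    BETA_ORDER,
    CODONS_61,
    CODONS_64,
    NucleotideTransitionMatrix,
    RateMatrix,
    coefficients_from_beta,
    matrix_summary,
    product_codon_measure,
)

PIS = [
    (0.25, 0.25, 0.25, 0.25),
    (0.19, 0.69, 0.05, 0.07),
    (0.41, 0.41, 0.09, 0.09),
    (0.05, 0.08, 0.22, 0.65),
]


@pytest.fixture(params=PIS, ids=["uniform", "Trich", "ATeq", "Crich"])
def pi(request):
    return ff.NucleotideDistribution(request.param)


class TestConstraintSystem:
    def test_shape_and_nullspace_dimension(self, pi):
        V = ff.constraint_matrix(pi)
        assert V.shape == (3, 12)
        B = ff.nullspace_basis(V)
        assert B.shape == (12, 9)
        assert np.max(np.abs(V @ B)) < 1e-10

    def test_uniform_pi_entries(self, uniform_pi):
        """For uniform pi every nonzero entry of V is +/- 0.25."""
        V = ff.constraint_matrix(uniform_pi)
        nz = V[V != 0]
        assert set(np.round(np.abs(nz), 12)) == {0.25}
        # each balance row touches 3 outflow and 3 inflow rates
        assert all((row != 0).sum() == 6 for row in V)

    def test_basis_roundtrip_projection(self, pi, rng):
        """Projecting a feasible rate vector onto the basis recovers it."""
        B = ff.nullspace_basis(ff.constraint_matrix(pi))
        coeffs = ff.sample_coefficients(B, pi, rng)
        rebuilt = coefficients_from_beta(coeffs.beta, B, pi)
        assert np.allclose(rebuilt.beta, coeffs.beta, atol=1e-10)

    def test_basis_is_deterministic(self, pi):
        B1 = ff.nullspace_basis(ff.constraint_matrix(pi))
        B2 = ff.nullspace_basis(ff.constraint_matrix(pi))
        assert np.array_equal(B1, B2)

    def test_reference_beta_satisfies_constraints(self, reference_matrix):
        """The packaged maximizing matrix, read back as rates, sits in the
        null space of the constraint system built from its own pi."""
        P = reference_matrix
        beta = np.array(
            [P.probs["ATGC".index(x), "ATGC".index(y)] for x, y in BETA_ORDER]
        )
        V = ff.constraint_matrix(P.pi)
        assert np.max(np.abs(V @ beta)) < 1e-8


class TestSampling:
    def test_all_rates_positive_and_unit_norm(self, pi, rng):
        B = ff.nullspace_basis(ff.constraint_matrix(pi))
        coeffs = ff.sample_coefficients(B, pi, rng)
        assert np.all(coeffs.beta > 0)
        assert np.linalg.norm(coeffs.beta) == pytest.approx(1.0)

    def test_seeded_draws_are_reproducible(self, pi):
        B = ff.nullspace_basis(ff.constraint_matrix(pi))
        a = ff.sample_coefficients(B, pi, np.random.default_rng(7))
        b = ff.sample_coefficients(B, pi, np.random.default_rng(7))
        assert np.array_equal(a.beta, b.beta)


class TestRateMatrixAndUniformization:
    def test_rows_sum_to_zero_and_stationarity(self, pi, rng):
        B = ff.nullspace_basis(ff.constraint_matrix(pi))
        for _ in range(20):
            Q = ff.build_rate_matrix(ff.sample_coefficients(B, pi, rng))
            assert np.max(np.abs(Q.rates.sum(axis=1))) < 1e-10
            assert np.max(np.abs(pi.as_array() @ Q.rates)) < 1e-8

    def test_equal_rates_give_uniform_stationary(self, uniform_pi):
        B = ff.nullspace_basis(ff.constraint_matrix(uniform_pi))
        beta = np.full(12, 1.0)
        Q = ff.build_rate_matrix(coefficients_from_beta(beta, B, uniform_pi))
        P = ff.uniformize(Q)
        assert np.allclose(ff.stationary(P.probs), 0.25)

    def test_uniformization_closed_form(self, uniform_pi):
        """All rates 1: q = 12, off-diagonals 1/12, diagonals 3/4."""
        Q = RateMatrix(np.full((4, 4), 1.0) - np.eye(4) * 4.0, uniform_pi)
        P = ff.uniformize(Q)
        assert P.uniformization_rate == pytest.approx(12.0)
        off = P.probs[~np.eye(4, dtype=bool)]
        assert np.allclose(off, 1 / 12)
        assert np.allclose(np.diag(P.probs), 0.75)

    def test_diagonal_sum_is_three(self, pi, rng):
        """Off-diagonal mass of the uniformized matrix sums to exactly one."""
        B = ff.nullspace_basis(ff.constraint_matrix(pi))
        P = ff.uniformize(ff.build_rate_matrix(ff.sample_coefficients(B, pi, rng)))
        assert np.trace(P.probs) == pytest.approx(3.0, abs=1e-12)

    def test_uniformization_preserves_stationary(self, pi, rng):
        B = ff.nullspace_basis(ff.constraint_matrix(pi))
        Q = ff.build_rate_matrix(ff.sample_coefficients(B, pi, rng))
        P = ff.uniformize(Q)
        assert np.allclose(ff.stationary(P.probs), pi.as_array(), atol=1e-8)

    def test_scale_invariance(self, pi, rng):
        """beta and 2 beta uniformize to the same transition matrix."""
        B = ff.nullspace_basis(ff.constraint_matrix(pi))
        coeffs = ff.sample_coefficients(B, pi, rng)
        P1 = ff.uniformize(ff.build_rate_matrix(coeffs))
        doubled = coefficients_from_beta(2 * coeffs.beta, B, pi)
        P2 = ff.uniformize(ff.build_rate_matrix(doubled))
        assert np.allclose(P1.probs, P2.probs, atol=1e-12)


class TestStationarySolver:
    def test_reference_matrix_stationary_vector(self, reference_matrix):
        """The packaged maximizing matrix has pi = (0.19, 0.69, 0.05, 0.07)
        to two decimals."""
        pi = ff.stationary(reference_matrix.probs)
        assert np.allclose(np.round(pi, 2), [0.19, 0.69, 0.05, 0.07])

    def test_identity_matrix_rejected(self):
        with pytest.raises(ValueError, match="reducible|multiplicity"):
            ff.stationary(np.eye(4))

    def test_symmetric_matrix_gives_uniform(self, rng):
        A = rng.random((5, 5))
        M = (A + A.T) / 2
        M = M / M.sum(axis=1, keepdims=True)
        # make exactly symmetric AND stochastic: use a doubly stochastic mix
        M = 0.5 * np.eye(5) + 0.5 * np.full((5, 5), 1 / 5)
        assert np.allclose(ff.stationary(M), 0.2)


class TestCodonLift:
    def test_single_change_entries_and_zeros(self, skewed_pi, rng):
        B = ff.nullspace_basis(ff.constraint_matrix(skewed_pi))
        P = ff.uniformize(ff.build_rate_matrix(ff.sample_coefficients(B, skewed_pi, rng)))
        M = ff.codon_matrix(P)
        states = M.state_labels
        i, j = states.index("AAA"), states.index("AAT")
        assert M.probs[i, j] == pytest.approx(P.probs[0, 1] / 3)
        k = states.index("TTA")
        assert M.probs[i, k] == 0.0
        assert np.max(np.abs(M.probs.sum(axis=1) - 1)) < 1e-12

    def test_uniform_nucleotide_matrix_gives_1_12(self, uniform_pi):
        P = NucleotideTransitionMatrix(np.full((4, 4), 0.25), 3.0, uniform_pi)
        M = ff.codon_matrix(P)
        row = M.probs[M.state_labels.index("AAA")]
        nonzero = row[row > 0]
        # 9 single-change neighbours at 1/12 each, diagonal 1/4
        assert np.isclose(sorted(nonzero)[-1], 0.25)
        assert np.allclose(sorted(nonzero)[:-1], 1 / 12)

    def test_product_measure_is_stationary(self, pi, rng):
        """On the full 64-codon space pi_cod is the product measure, so the
        within-family third-position relative frequencies equal pi."""
        B = ff.nullspace_basis(ff.constraint_matrix(pi))
        P = ff.uniformize(ff.build_rate_matrix(ff.sample_coefficients(B, pi, rng)))
        M = ff.codon_matrix(P, "64-all")
        expected = product_codon_measure(pi, M.state_labels)
        assert np.allclose(M.pi_cod, expected, atol=1e-9)
        idx = {c: i for i, c in enumerate(M.state_labels)}
        for prefix in ("GG", "GT", "AC", "GC", "CC"):
            mass = np.array([M.pi_cod[idx[prefix + n]] for n in "ATGC"])
            assert np.allclose(mass / mass.sum(), pi.as_array(), atol=1e-9)

    def test_sense_restriction_is_reflecting_not_product(self, skewed_pi, rng):
        """Dropping the stop codons from the mutation chain folds the
        would-be stop flux back into the diagonal, so the 61-state chain's
        stationary vector is close to, but not exactly, the restricted
        product measure.  (The SL selection chain built on this space is
        still exact: selection, not mutation, removes the stops.)"""
        B = ff.nullspace_basis(ff.constraint_matrix(skewed_pi))
        P = ff.uniformize(ff.build_rate_matrix(ff.sample_coefficients(B, skewed_pi, rng)))
        M = ff.codon_matrix(P, "61-sense")
        expected = product_codon_measure(skewed_pi, M.state_labels)
        assert np.max(np.abs(M.pi_cod - expected)) < 0.05
        assert np.max(np.abs(M.probs.sum(axis=1) - 1)) < 1e-12


class TestReversibleConstruction:
    def test_detailed_balance(self, pi, rng):
        r = rng.uniform(0.5, 2.0, size=6)
        P = ff.reversible_transition_matrix(pi, r)
        p = pi.as_array()
        flux = p[:, None] * P.probs
        assert np.allclose(flux, flux.T, atol=1e-12)

    def test_stationary_matches_pi(self, pi, rng):
        P = ff.reversible_transition_matrix(pi, rng.uniform(0.5, 2.0, size=6))
        assert np.allclose(ff.stationary(P.probs), pi.as_array(), atol=1e-8)


class TestMatrixSummary:
    def test_symmetric_matrix_has_zero_dev_rev(self, uniform_pi):
        P = NucleotideTransitionMatrix(np.full((4, 4), 0.25), 3.0, uniform_pi)
        s = matrix_summary(P)
        assert s.dev_rev == 0.0
        assert s.titv_ratio == pytest.approx(0.5)

    def test_dev_rev_hand_computed(self, reference_matrix):
        """Dev_rev of the packaged matrix, against a hand loop over the six
        unordered pairs."""
        P = reference_matrix.probs
        expected = sum(
            abs(P[i, j] - P[j, i]) for i in range(4) for j in range(i + 1, 4)
        )
        assert matrix_summary(reference_matrix).dev_rev == pytest.approx(expected)
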