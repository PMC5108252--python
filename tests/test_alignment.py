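"""Vector correlations, eigenvector extraction, permutation alignment tests,
and directional variance."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from selscape.alignment import (
    alignment_permutation_test,
    directional_variance,
    min_eigenvector,
    random_direction_average,
    taxon_mean_permutation_test,
    vector_correlation,
)
from selscape.matrices import TaxonSummary

from conftest import make_trait_matrix

M_MAX = np.array([0.128, -0.686, 0.716])


class TestVectorCorrelation:
    def test_parallel_and_orthogonal(self):
        assert vector_correlation([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)
        assert vector_correlation([1, 0], [0, 1]) == pytest.approx(0.0)

    def test_published_p_alignment(self, published_P):
        rho = vector_correlation(M_MAX, min_eigenvector(published_P))
        assert rho == pytest.approx(0.78, abs=0.01)

    def test_published_d_alignment(self, published_D):
        rho = vector_correlation(M_MAX, min_eigenvector(published_D))
        assert rho == pytest.approx(0.82, abs=0.01)

    @given(
        s1=st.floats(0.1, 10),
        s2=st.floats(0.1, 10),
        flip=st.sampled_from([1.0, -1.0]),
    )
    @settings(max_examples=30, deadline=None)
    def test_scale_and_sign_invariance(self, s1, s2, flip):
        a = np.array([0.3, -0.5, 0.8])
        b = np.array([1.0, 0.2, -0.4])
        assert vector_correlation(a * s1 * flip, b * s2) == pytest.approx(
            vector_correlation(a, b), abs=1e-10
        )

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            vector_correlation([0, 0], [1, 0])


class TestMinEigenvector:
    def test_diagonal_matrix(self):
        v = min_eigenvector(np.diag([3.0, 2.0, 1.0]))
        np.testing.assert_allclose(v, [0, 0, 1], atol=1e-12)

    def test_identity_warns_degenerate(self):
        with pytest.warns(UserWarning, match="degenerate"):
            min_eigenvector(np.eye(3))

    def test_against_characteristic_polynomial_solver(
        self, published_P, published_D, published_gamma, brute_force_eigh_3x3
    ):
        for M in (published_P.matrix, published_D.matrix,
                  published_gamma.gamma):
            roots, vecs = brute_force_eigh_3x3(M)
            v = min_eigenvector(M)
            assert vector_correlation(v, vecs[0]) == pytest.approx(
                1.0, abs=1e-8
            )
            v_max = min_eigenvector(M, which="max")
            assert vector_correlation(v_max, vecs[-1]) == pytest.approx(
                1.0, abs=1e-8
            )


def _anisotropic_sample(rng, n=100):
    # the low-variance direction (1,-1,0)/sqrt(2) comes from a strong
    # correlation, which the within-trait shuffle destroys; marginal
    # variances alone carry no alignment signal under this null
    cov = np.array([[1.0, 0.95, 0.0], [0.95, 1.0, 0.0], [0.0, 0.0, 1.0]])
    return rng.multivariate_normal(np.zeros(3), cov, size=n)


P_MIN_TRUE = np.array([1.0, -1.0, 0.0]) / np.sqrt(2)


class TestAlignmentPermutationTest:
    def test_power_with_true_p_min_reference(self):
        rng = np.random.default_rng(15)
        X = make_trait_matrix(_anisotropic_sample(rng))
        res = alignment_permutation_test(
            X, reference=P_MIN_TRUE, which="min", n_perm=2000, seed=5
        )
        assert res.rho > 0.95
        assert res.p_value < 0.01

    def test_counting_floor(self):
        rng = np.random.default_rng(16)
        X = make_trait_matrix(_anisotropic_sample(rng))
        res = alignment_permutation_test(
            X, reference=P_MIN_TRUE, which="min", n_perm=99, seed=5
        )
        assert res.p_value == pytest.approx(1 / 100)

    def test_rho_recomputable_from_stored_vectors(self):
        rng = np.random.default_rng(18)
        X = make_trait_matrix(_anisotropic_sample(rng))
        res = alignment_permutation_test(
            X, reference=[0.1, 0.4, 0.9], n_perm=19, seed=0
        )
        assert res.rho == pytest.approx(
            vector_correlation(res.reference_vector, res.target_vector),
            abs=1e-12,
        )

    def test_null_p_values_roughly_uniform(self):
        # spherical data + random reference: permutation p-values should be
        # close to uniform across replicates
        n_reps, n_perm = 200, 199
        pvals = np.empty(n_reps)
        for rep in range(n_reps):
            rng = np.random.default_rng(1000 + rep)
            X = make_trait_matrix(rng.normal(size=(50, 3)))
            ref = rng.normal(size=3)
            res = alignment_permutation_test(
                X, ref, which="min", n_perm=n_perm, seed=rep
            )
            pvals[rep] = res.p_value
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01


class TestTaxonMeanPermutationTest:
    def test_published_rho_d(self, taxon_table, reference_means):
        res = taxon_mean_permutation_test(
            taxon_table, M_MAX, reference_means, n_perm=99, seed=1
        )
        assert res.rho == pytest.approx(0.82, abs=0.01)

    def test_identical_taxa_rejected(self, reference_means):
        taxa = [
            TaxonSummary(taxon=f"t{i}", n=5, means=reference_means,
                         sds=np.zeros(3))
            for i in range(4)
        ]
        with pytest.raises(ValueError, match="identical"):
            taxon_mean_permutation_test(
                taxa, M_MAX, reference_means, n_perm=9, seed=0
            )

    def test_planted_alignment_detected_on_synthetic_divergence(self):
        # taxa diverging everywhere except along the reference direction:
        # d_min aligns with it and the column-shuffle null rarely does
        rng = np.random.default_rng(77)
        ref = np.array([1.0, 1.0, 1.0]) / np.sqrt(3)
        Q = np.linalg.qr(np.column_stack([ref, np.eye(3)[:, :2]]))[0]
        D_true = Q @ np.diag([1e-4, 0.3, 0.2]) @ Q.T
        means = rng.multivariate_normal(np.full(3, 5.0), D_true, size=40)
        taxa = [
            TaxonSummary(taxon=f"t{i}", n=6, means=m, sds=np.zeros(3))
            for i, m in enumerate(means)
        ]
        res = taxon_mean_permutation_test(
            taxa, ref, np.full(3, 5.0), n_perm=499, seed=3
        )
        assert res.rho > 0.95
        assert res.p_value < 0.05


class TestDirectionalVariance:
    def test_identity_any_unit_direction(self, rng):
        m = rng.normal(size=4)
        m /= np.linalg.norm(m)
        assert directional_variance(np.eye(4), m) == pytest.approx(1.0)

    def test_published_e_values(self, published_P, published_D,
                                published_vectors):
        vec = {k: v / np.linalg.norm(v) for k, v in published_vectors.items()}
        assert directional_variance(published_P, vec["m_max"]) == pytest.approx(
            0.011, abs=0.001
        )
        assert directional_variance(published_D, vec["m_max"]) == pytest.approx(
            0.014, abs=0.001
        )
        assert directional_variance(published_P, vec["m1"]) == pytest.approx(
            0.015, abs=0.001
        )
        assert directional_variance(published_D, vec["m2"]) == pytest.approx(
            0.032, abs=0.001
        )

    def test_against_double_loop_oracle(self, published_P, published_vectors):
        m = published_vectors["m1"]
        m = m / np.linalg.norm(m)
        A = published_P.matrix
        total = 0.0
        for i in range(3):
            for j in range(3):
                total += m[i] * A[i, j] * m[j]
        assert directional_variance(published_P, m) == pytest.approx(
            total, abs=1e-14
        )

    def test_eigenbasis_sums_to_trace(self, published_D):
        _, vecs = np.linalg.eigh(published_D.matrix)
        total = sum(
            directional_variance(published_D, vecs[:, i]) for i in range(3)
        )
        assert total == pytest.approx(np.trace(published_D.matrix), abs=1e-12)

    def test_non_unit_direction_renormalized_with_warning(self):
        with pytest.warns(UserWarning, match="renormalized"):
            e = directional_variance(np.eye(2), [2.0, 0.0])
        assert e == pytest.approx(1.0)


class TestRandomDirectionAverage:
    def test_identity_matrix_mean_exactly_one(self):
        mean_e, sd_e = random_direction_average(np.eye(3), k=100, seed=0)
        assert mean_e == pytest.approx(1.0, abs=1e-12)
        assert sd_e < 1e-12

    def test_published_average_e(self, published_P):
        mean_e, _ = random_direction_average(published_P, k=1000, seed=42)
        assert 0.010 <= round(mean_e, 3) <= 0.011

    def test_seed_reproducibility(self, published_D):
        a = random_direction_average(published_D, k=500, seed=7)
        b = random_direction_average(published_D, k=500, seed=7)
        assert a == b
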