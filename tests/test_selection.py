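"""Selection-gradient regression, canonical rotation, permutation nulls."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from selscape.core import variance_standardize
from selscape.selection import (
    GradientEstimates,
    SelectionSurface,
    canonical_analysis,
    eigenvalue_permutation_test,
    estimate_beta,
    estimate_gamma,
    mean_standardize_gradients,
    relative_fitness,
)

from conftest import make_trait_matrix


def _std(values):
    return variance_standardize(make_trait_matrix(values))


class TestRelativeFitness:
    @pytest.mark.parametrize(
        "w,expected",
        [([1, 1, 1], [1, 1, 1]), ([0, 2], [0, 2]), ([2, 4, 6], [0.5, 1.0, 1.5])],
    )
    def test_values(self, w, expected):
        np.testing.assert_allclose(relative_fitness(w), expected)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            relative_fitness([0.0, 0.0])


class TestEstimateBeta:
    def test_constant_fitness_gives_zero_beta(self, rng):
        Z = _std(rng.normal(size=(30, 3)))
        g = estimate_beta(Z, np.ones(30))
        np.testing.assert_allclose(g.beta, 0.0, atol=1e-12)

    def test_exact_linear_truth(self, rng):
        Z = _std(rng.normal(size=(50, 3)))
        w = 1.0 + 0.3 * Z.values[:, 0]
        g = estimate_beta(Z, w)
        np.testing.assert_allclose(g.beta, [0.3, 0, 0], atol=1e-12)

    def test_df_conventions(self, rng):
        Z = _std(rng.normal(size=(44, 3)))
        g = estimate_beta(Z, relative_fitness(rng.poisson(1.0, 44) + 0.01))
        assert g.fit_stats["linear"]["df"] == (3, 40)

    def test_simulation_recovery_within_three_se(self):
        rng = np.random.default_rng(5)
        n = 10_000
        beta_true = np.array([0.1, -0.2, 0.05])
        Z = _std(rng.normal(size=(n, 3)))
        w = 1.0 + Z.values @ beta_true + rng.normal(0, 0.5, n)
        g = estimate_beta(Z, w)
        assert np.all(np.abs(g.beta - beta_true) < 3 * g.beta_se)


class TestEstimateGamma:
    def test_constant_fitness_gives_zero_gamma(self, rng):
        Z = _std(rng.normal(size=(40, 3)))
        g = estimate_gamma(Z, np.ones(40))
        np.testing.assert_allclose(g.gamma, 0.0, atol=1e-12)

    def test_exact_quadratic_truth_machine_precision(self, rng):
        G = np.array([[0.2, 0.1, 0.0], [0.1, -0.4, 0.15], [0.0, 0.15, -0.1]])
        Z = _std(rng.normal(size=(60, 3)))
        w = 1.0 + 0.5 * np.einsum("ij,jk,ik->i", Z.values, G, Z.values)
        g = estimate_gamma(Z, w, double_quadratic=True)
        np.testing.assert_allclose(g.gamma, G, atol=1e-10)

    def test_doubling_flag(self, rng):
        G = np.diag([0.4, -0.2, 0.1])
        Z = _std(rng.normal(size=(60, 3)))
        w = 1.0 + 0.5 * np.einsum("ij,jk,ik->i", Z.values, G, Z.values)
        g_raw = estimate_gamma(Z, w, double_quadratic=False)
        np.testing.assert_allclose(np.diag(g_raw.gamma), np.diag(G) / 2,
                                   atol=1e-10)

    def test_insufficient_n_states_minimum(self):
        Z = _std(np.random.default_rng(0).normal(size=(9, 3)))
        with pytest.raises(ValueError, match="10"):
            estimate_gamma(Z, np.ones(9))

    def test_gaussian_surface_recovery_vs_analytic(self):
        """γ̂ matches the closed-form projection of a Gaussian surface.

        For z ~ N(0,R) and w ∝ exp(−½(z−θ)'Ω⁻¹(z−θ)) the quadratic
        regression estimates β = R⁻¹μ*, γ = R⁻¹(Σ*−R+μ*μ*')R⁻¹ with
        Σ* = (R⁻¹+Ω⁻¹)⁻¹ and μ* = Σ*Ω⁻¹θ (the Lande–Arnold identities).
        """
        from selscape.simulate import SimulationConfig, simulate_selection_sample

        cfg = SimulationConfig(
            n_individuals=5000,
            fitness_model="gaussian_surface",
            fitness_noise="poisson",
            mean_count=2.0,
        )
        X, w = simulate_selection_sample(cfg, seed=42)
        Z = variance_standardize(X)
        g = estimate_gamma(Z, relative_fitness(w))
        sd = np.sqrt(np.diag(cfg.P_true))
        R = cfg.P_true / np.outer(sd, sd)
        Rinv = np.linalg.inv(R)
        C = np.linalg.inv(cfg.width_matrix)
        Sig = np.linalg.inv(Rinv + C)
        mu = Sig @ (C @ cfg.optimum)
        gamma_an = Rinv @ (Sig - R + np.outer(mu, mu)) @ Rinv
        assert np.all(np.abs(g.gamma - gamma_an) < 3 * g.gamma_se)


class TestCanonicalAnalysis:
    def test_published_gamma_reproduces_published_axes(self, published_gamma):
        can = canonical_analysis(published_gamma)
        np.testing.assert_allclose(
            can.lambdas, [0.181, -0.094, -0.522], atol=0.002
        )
        m3 = can.m_vectors[2]
        target = np.array([0.111, -0.803, 0.585])
        m3_aligned = m3 * np.sign(m3 @ target)
        np.testing.assert_allclose(m3_aligned, target, atol=0.01)
        assert can.m_max_index == 2
        # trace conservation against the printed diagonal
        assert can.lambdas.sum() == pytest.approx(
            np.trace(published_gamma.gamma), abs=1e-10
        )

    def test_identity_gamma(self):
        g = GradientEstimates(
            beta=np.array([0.1, 0.2, 0.3]),
            beta_se=np.zeros(3),
            gamma=np.eye(3),
            gamma_se=np.zeros((3, 3)),
            trait_labels=("a", "b", "c"),
        )
        can = canonical_analysis(g)
        np.testing.assert_allclose(can.lambdas, 1.0)
        assert can.m_max_index is None
        # thetas are the rotation of beta: norms agree
        assert np.linalg.norm(can.thetas) == pytest.approx(
            np.linalg.norm(g.beta)
        )

    @given(a=st.floats(-1, 1), b=st.floats(0.05, 1))
    @settings(max_examples=25, deadline=None)
    def test_two_by_two_closed_form(self, a, b):
        g = GradientEstimates(
            beta=np.zeros(2),
            beta_se=np.zeros(2),
            gamma=np.array([[a, b], [b, a]]),
            gamma_se=np.zeros((2, 2)),
            trait_labels=("x", "y"),
        )
        can = canonical_analysis(g)
        np.testing.assert_allclose(
            sorted(can.lambdas), sorted([a + b, a - b]), atol=1e-12
        )
        for v in can.m_vectors:
            np.testing.assert_allclose(np.abs(v), [2**-0.5] * 2, atol=1e-12)

    def test_rotation_invariance_of_eigenvalues(self, rng, published_gamma):
        A = rng.normal(size=(3, 3))
        Q, _ = np.linalg.qr(A)
        rotated = GradientEstimates(
            beta=Q @ published_gamma.beta,
            beta_se=np.zeros(3),
            gamma=Q @ published_gamma.gamma @ Q.T,
            gamma_se=np.zeros((3, 3)),
            trait_labels=("a", "b", "c"),
        )
        np.testing.assert_allclose(
            canonical_analysis(rotated).lambdas,
            canonical_analysis(published_gamma).lambdas,
            atol=1e-10,
        )


class TestEigenvaluePermutationTest:
    def test_counting_formula_most_extreme(self):
        # strong planted curvature: the observed extreme eigenvalue beats
        # every permuted one, so p hits the (1+0)/(n_perm+1) floor
        rng = np.random.default_rng(3)
        Z = _std(rng.normal(size=(300, 3)))
        w = np.maximum(0, 1 - 0.5 * Z.values[:, 1] ** 2)
        _, pvals = eigenvalue_permutation_test(Z, w, n_perm=19, seed=1)
        assert pvals[-1] == pytest.approx(1 / 20)

    def test_reproducible_and_row_relabel_invariant(self):
        rng = np.random.default_rng(8)
        vals = rng.normal(size=(60, 3))
        w = rng.poisson(1.0, 60) + 0.01
        Z = _std(vals)
        obs1, p1 = eigenvalue_permutation_test(Z, w, n_perm=99, seed=11)
        obs2, p2 = eigenvalue_permutation_test(Z, w, n_perm=99, seed=11)
        np.testing.assert_array_equal(p1, p2)
        # relabeling individuals jointly leaves observed eigenvalues fixed
        perm = rng.permutation(60)
        obs3, _ = eigenvalue_permutation_test(
            _std(vals[perm]), w[perm], n_perm=5, seed=11
        )
        np.testing.assert_allclose(obs1, obs3, atol=1e-10)

    def test_power_under_strong_stabilizing_selection(self):
        # planted λ=-0.5 at n=500: the most negative axis should be
        # detected in the vast majority of replicates
        G = np.diag([0.0, 0.0, -0.5])
        hits = 0
        n_reps = 20
        for rep in range(n_reps):
            rng = np.random.default_rng(100 + rep)
            Z = _std(rng.normal(size=(500, 3)))
            w_exp = np.maximum(
                0, 1 + 0.5 * np.einsum("ij,jk,ik->i", Z.values, G, Z.values)
            )
            w = rng.poisson(w_exp).astype(float)
            _, pvals = eigenvalue_permutation_test(
                Z, w, n_perm=99, seed=rep
            )
            if pvals[-1] < 0.05:
                hits += 1
        assert hits >= 0.8 * n_reps


class TestMeanStandardizeGradients:
    def test_unit_cv_leaves_gradients_unchanged(self, published_gamma):
        g = mean_standardize_gradients(
            published_gamma, means=[2.0, 2.0, 2.0], sds=[2.0, 2.0, 2.0]
        )
        np.testing.assert_allclose(g.gamma, published_gamma.gamma)

    def test_single_trait_hand_value(self):
        g = GradientEstimates(
            beta=np.array([0.2, 0.0]),
            beta_se=np.zeros(2),
            gamma=np.zeros((2, 2)),
            gamma_se=np.zeros((2, 2)),
            trait_labels=("a", "b"),
        )
        out = mean_standardize_gradients(g, means=[2.0, 1.0], sds=[0.5, 1.0])
        assert out.beta[0] == pytest.approx(0.8)

    def test_round_trip(self, published_gamma):
        means = np.array([3.1, 236.1, 213.4])
        sds = np.array([0.2, 19.5, 38.1])
        cv = sds / means
        g_mu = mean_standardize_gradients(published_gamma, means, sds)
        # invert: multiply back by CVs
        back = g_mu.gamma * np.outer(cv, cv)
        np.testing.assert_allclose(back, published_gamma.gamma, atol=1e-12)


class TestSelectionSurfaceModel:
    def test_fit_and_summary_round_trip(self):
        rng = np.random.default_rng(21)
        vals = rng.multivariate_normal(
            [3.1, 236, 213], np.diag([0.04, 380, 1450]), size=44
        )
        w = rng.poisson(1.0, size=44).astype(float)
        model = SelectionSurface(w, vals, trait_labels=("PN", "MD", "ML"))
        res = model.fit()
        assert res.gamma.shape == (3, 3)
        text = res.summary()
        assert "m_max" in text or "lambda" in text
        # mean-standardized conversion runs off the recorded scaling
        g_mu = res.mean_standardized()
        assert g_mu.scale_tag == "mean_standardized"
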