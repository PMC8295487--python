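import math

import numpy as np
import pytest

from ddnf import (
    ActivationSpec,
    ConnectivityTensor,
    DiscretizationParams,
    FieldState,
    LayerArchitecture,
    ModelSpec,
    StimulusSpec,
    build_jacobian,
    mu_multilayer,
    mu_single_layer,
    simulate,
    spectral_radius_classify,
    transfer_matrix_det,
    tridiagonal_eigenvalues,
    two_layer_stability,
)
from ddnf.exceptions import ConfigurationError, ThresholdSingularityError
from ddnf.fixtures import fixture_with_fixed_point
from ddnf.stability import stability_report

from conftest import finite_difference_jacobian, small_model

ALPHA_08 = math.exp(-0.8)


class TestBuildJacobian:
    def test_heaviside_off_threshold_equilibrium_gives_pure_leak(
        self, sec35_heaviside_model
    ):
        model = sec35_heaviside_model
        v_star = model.uniform_state(-0.5)
        A = build_jacobian(model, v_star)
        np.testing.assert_array_equal(A, ALPHA_08 * np.eye(200))

    def test_heaviside_on_threshold_rejected(self, sec35_heaviside_model):
        v_star = sec35_heaviside_model.uniform_state(0.0)
        with pytest.raises(ThresholdSingularityError):
            build_jacobian(sec35_heaviside_model, v_star)

    def test_scalar_model_closed_form(self):
        # L = 1, M = 1, |Omega| = 1: A = [alpha + (1-alpha) w G'(v*)]
        disc = DiscretizationParams(h=0.8, a=0.0, b=1.0)
        arch = LayerArchitecture(sizes=(1,), positions=(np.array([0.5]),))
        w = 1.7
        model = ModelSpec(
            architecture=arch,
            discretization=disc,
            connectivity=ConnectivityTensor(
                layer_sizes=(1,), blocks={(0, 0): np.array([[w]])}
            ),
            activation=ActivationSpec(family="sigmoid", theta=2.0),
            stimulus=StimulusSpec(nu=0.0, form="zero"),
        )
        v = 0.4
        from ddnf import activation_derivative

        gprime = activation_derivative(model.activation, v)
        A = build_jacobian(model, FieldState(V=np.array([[v]])))
        expected = ALPHA_08 + (1 - ALPHA_08) * w * gprime
        assert A[0, 0] == pytest.approx(expected, rel=1e-14)
        fd = finite_difference_jacobian(model, FieldState(V=np.array([[v]])))
        assert A[0, 0] == pytest.approx(fd[0, 0], rel=1e-6)

    def test_non_adjacent_layer_blocks_are_zero(self):
        model = small_model(seed=7, n_layers=3, max_size=4)
        sizes = model.architecture.sizes
        v_star = model.uniform_state(0.1)
        A = build_jacobian(model, v_star)
        off = np.cumsum((0,) + sizes)
        block_13 = A[off[0] : off[1], off[2] : off[3]]
        block_31 = A[off[2] : off[3], off[0] : off[1]]
        assert np.all(block_13 == 0.0) and np.all(block_31 == 0.0)

    @pytest.mark.parametrize("seed", range(50))
    def test_matches_finite_difference_oracle_on_random_models(self, seed):
        """Analytic Jacobian vs central differences on seeded sigmoid models."""
        rng = np.random.default_rng(seed)
        n_layers = int(rng.integers(1, 4))
        model = small_model(seed=seed, n_layers=n_layers, max_size=5)
        V = model.uniform_state(0.0).V
        for k, m in enumerate(model.architecture.sizes):
            V[k, :m] = rng.uniform(-1.0, 1.0, size=m)
        v_star = FieldState(V=V)
        A = build_jacobian(model, v_star)
        fd = finite_difference_jacobian(model, v_star)
        np.testing.assert_allclose(A, fd, rtol=1e-6, atol=1e-8)


class TestMuSingleLayer:
    def test_zero_weights_give_zero_mu(self):
        disc = DiscretizationParams(h=0.8, a=0.0, b=2.0)
        arch = LayerArchitecture(sizes=(2,), positions=(np.array([0.5, 1.5]),))
        model = ModelSpec(
            architecture=arch,
            discretization=disc,
            connectivity=ConnectivityTensor(
                layer_sizes=(2,), blocks={(0, 0): np.zeros((2, 2))}
            ),
            activation=ActivationSpec(family="sigmoid", theta=1.0),
            stimulus=StimulusSpec(nu=0.0, form="zero"),
        )
        mu = mu_single_layer(model, model.uniform_state(0.3))
        np.testing.assert_array_equal(mu, [0.0, 0.0])

    def test_mu_is_domain_size_times_gain_row_mean(self):
        """mu_i = |Omega| * mean_j of W_ij G'(V_j*): rows scaled by 2/M here."""
        disc = DiscretizationParams(h=0.8, a=0.0, b=2.0)
        arch = LayerArchitecture(sizes=(2,), positions=(np.array([0.5, 1.5]),))
        # choose weights so that the gain-weighted rows sum to 0.3 and 0.8
        theta = 2.0
        from ddnf import activation_derivative

        v_star = 0.1
        gp = activation_derivative(ActivationSpec(family="sigmoid", theta=theta), v_star)
        W = np.array([[0.1, 0.2], [0.5, 0.3]]) / gp
        model = ModelSpec(
            architecture=arch,
            discretization=disc,
            connectivity=ConnectivityTensor(layer_sizes=(2,), blocks={(0, 0): W}),
            activation=ActivationSpec(family="sigmoid", theta=theta),
            stimulus=StimulusSpec(nu=0.0, form="zero"),
        )
        mu = mu_single_layer(model, model.uniform_state(v_star))
        np.testing.assert_allclose(mu, [2.0 * 0.3 / 2, 2.0 * 0.8 / 2], rtol=1e-12)

    def test_multilayer_model_rejected(self):
        model = small_model(seed=3, n_layers=2)
        with pytest.raises(ConfigurationError):
            mu_single_layer(model, model.uniform_state(0.0))

    @pytest.mark.parametrize("seed", range(10))
    def test_row_criterion_bounds_the_infinity_norm(self, seed):
        """||A||_inf <= alpha + (1 - alpha) max|mu_i| on random single layers."""
        rng = np.random.default_rng(100 + seed)
        model = small_model(seed=100 + seed, n_layers=1, max_size=6)
        V = model.uniform_state(0.0).V
        V[0, : model.architecture.sizes[0]] = rng.uniform(-1, 1, model.architecture.sizes[0])
        v_star = FieldState(V=V)
        mu = mu_single_layer(model, v_star)
        A = build_jacobian(model, v_star)
        alpha = model.discretization.alpha
        norm_inf = np.max(np.sum(np.abs(A), axis=1))
        assert norm_inf <= alpha + (1 - alpha) * np.max(np.abs(mu)) + 1e-12


class TestSpectralRadiusClassify:
    def test_pure_leak_matrix_is_stable(self):
        rho, verdict = spectral_radius_classify(ALPHA_08 * np.eye(5))
        assert rho == pytest.approx(ALPHA_08, rel=1e-12)
        assert verdict == "stable"

    def test_identity_is_inconclusive(self):
        rho, verdict = spectral_radius_classify(np.eye(3))
        assert rho == 1.0
        assert verdict == "inconclusive"

    def test_nilpotent_matrix_is_stable(self):
        rho, verdict = spectral_radius_classify(np.array([[0.0, 2.0], [0.0, 0.0]]))
        assert rho == 0.0
        assert verdict == "stable"

    def test_expanding_matrix_is_unstable(self):
        _, verdict = spectral_radius_classify(np.diag([1.5, 0.2]))
        assert verdict == "unstable"


class TestTridiagonalEigenvalues:
    def test_single_site_chain(self):
        np.testing.assert_allclose(tridiagonal_eigenvalues(2.5, 1.0, 3.0, 1), [2.5])

    def test_vanishing_hopping_gives_flat_spectrum(self):
        np.testing.assert_array_equal(tridiagonal_eigenvalues(1.2, 0.0, 5.0, 4), [1.2] * 4)

    def test_symmetric_three_site_chain(self):
        lam = np.sort(tridiagonal_eigenvalues(2.0, 1.0, 1.0, 3))
        np.testing.assert_allclose(lam, [2 - math.sqrt(2), 2.0, 2 + math.sqrt(2)], atol=1e-12)

    def test_mixed_sign_hopping_rejected(self):
        with pytest.raises(ConfigurationError):
            tridiagonal_eigenvalues(1.0, 1.0, -1.0, 4)

    @pytest.mark.parametrize("seed", range(100))
    def test_matches_dense_eigensolver(self, seed):
        """Dense oracle via the similarity-symmetrized chain.

        D A D^-1 with D = diag((c/b)^(k/2)) is symmetric tridiagonal with
        hopping sqrt(bc) and the same spectrum; the nonsymmetric matrix
        itself has wildly ill-conditioned eigenvalues when b and c are far
        apart, so the symmetric form is the numerically faithful oracle.
        """
        rng = np.random.default_rng(seed)
        L = int(rng.integers(1, 51))
        a = rng.normal()
        b, c = rng.uniform(0, 2, size=2) * rng.choice([1.0, -1.0])  # same sign
        hop = math.sqrt(b * c)
        A_sym = a * np.eye(L) + hop * np.eye(L, k=1) + hop * np.eye(L, k=-1)
        dense = np.sort(np.linalg.eigvalsh(A_sym))
        closed = np.sort(tridiagonal_eigenvalues(a, b, c, L))
        np.testing.assert_allclose(closed, dense, atol=1e-10)


class TestMuMultilayer:
    def test_single_layer_reduction(self):
        disc = DiscretizationParams(h=0.8, a=0.0, b=1.0)
        res = mu_multilayer(disc, K0=0.5, K1=0.0, K2=0.0, L=1)
        assert res.mu[0] == pytest.approx(ALPHA_08 + (1 - ALPHA_08) * 0.5, rel=1e-14)

    def test_decoupled_chain_is_pure_leak(self):
        disc = DiscretizationParams(h=0.8, a=-1.0, b=1.0)
        res = mu_multilayer(disc, K0=0.0, K1=0.0, K2=0.0, L=5)
        np.testing.assert_allclose(res.mu, ALPHA_08)
        assert res.stable_flag

    def test_matches_dense_spectrum_of_assembled_chain(self):
        """mu_k are the eigenvalues of the tridiagonal chain with the stated
        diagonal a and hoppings b = a|Omega|K2, c = a|Omega|K1."""
        disc = DiscretizationParams(h=0.8, a=0.0, b=1.0)
        K0, K1, K2, L = 0.5, 0.1, 0.1, 4
        res = mu_multilayer(disc, K0, K1, K2, L)
        A = res.a * np.eye(L) + res.b * np.eye(L, k=1) + res.c * np.eye(L, k=-1)
        dense = np.sort(np.linalg.eigvals(A).real)
        np.testing.assert_allclose(np.sort(res.mu), dense, atol=1e-12)

    def test_supremum_bound_dominates_every_chain_length(self):
        disc = DiscretizationParams(h=0.5, a=0.0, b=1.5)
        for L in (1, 2, 5, 20, 100):
            res = mu_multilayer(disc, K0=0.4, K1=0.2, K2=0.3, L=L)
            assert res.max_abs_mu <= res.sup_bound + 1e-12

    def test_negative_rates_warn(self):
        disc = DiscretizationParams(h=0.5, a=0.0, b=1.0)
        with pytest.warns(UserWarning):
            mu_multilayer(disc, K0=-0.2, K1=0.1, K2=0.1, L=3)


def dense_chain(a, b, c, b_L=None, c_0=None):
    L = len(a)
    A = np.diag(a) + np.diag(b, 1) + np.diag(c, -1)
    if b_L is not None:
        A[L - 1, 0] += b_L
        A[0, L - 1] += c_0
    return A


class TestTransferMatrixDet:
    def test_single_site(self):
        assert transfer_matrix_det([3.0], [], [], lam=0.7) == pytest.approx(2.3)

    @pytest.mark.parametrize("seed", range(100))
    def test_open_chain_matches_dense_determinant(self, seed):
        rng = np.random.default_rng(seed)
        L = int(rng.integers(1, 13))
        a = rng.normal(size=L)
        b = rng.normal(size=L - 1)
        c = rng.normal(size=L - 1)
        lam = rng.normal()
        dense = np.linalg.det(dense_chain(a, b, c) - lam * np.eye(L))
        tm = transfer_matrix_det(a, b, c, lam)
        np.testing.assert_allclose(tm, dense, rtol=1e-8, atol=1e-10)

    @pytest.mark.parametrize("seed", range(100))
    def test_closed_chain_matches_dense_determinant(self, seed):
        rng = np.random.default_rng(1000 + seed)
        L = int(rng.integers(3, 13))
        a = rng.normal(size=L)
        b = rng.normal(size=L - 1)
        c = rng.normal(size=L - 1)
        b_L, c_0, lam = rng.normal(size=3)
        dense = np.linalg.det(dense_chain(a, b, c, b_L, c_0) - lam * np.eye(L))
        tm = transfer_matrix_det(a, b, c, lam, closed=True, b_L=b_L, c_0=c_0)
        np.testing.assert_allclose(tm, dense, rtol=1e-8, atol=1e-10)

    def test_ten_site_ring_with_uniform_weights(self):
        """Ring of 10 sites: a = 4, b = 3, c = 5, corners c0 = 7, b10 = 10."""
        L = 10
        a = np.full(L, 4.0)
        b = np.full(L - 1, 3.0)
        c = np.full(L - 1, 5.0)
        dense = np.linalg.det(dense_chain(a, b, c, 10.0, 7.0))
        tm = transfer_matrix_det(a, b, c, lam=0.0, closed=True, b_L=10.0, c_0=7.0)
        np.testing.assert_allclose(tm, dense, rtol=1e-8)
        assert tm == pytest.approx(-15417734.0, rel=1e-9)


class TestTwoLayerStability:
    def disc(self, h=0.8, om=1.0):
        return DiscretizationParams(h=h, a=0.0, b=om)

    def test_decoupled_layers_have_unit_theta(self):
        report = two_layer_stability(self.disc(), 0.3, 0.2, 0.0, 0.5)
        assert report.details["theta"] == 1.0
        assert not report.theorem_flags["printed_sufficient"]

    def test_fully_disconnected_system_is_stable_pure_leak(self):
        report = two_layer_stability(self.disc(), 0.0, 0.0, 0.0, 0.0)
        np.testing.assert_allclose(report.adjacency, ALPHA_08 * np.eye(2))
        assert report.rho == pytest.approx(ALPHA_08, rel=1e-12)
        assert report.classification == "stable"

    @pytest.mark.parametrize("seed", range(5))
    def test_exact_conditions_match_eigenvalues_and_det_trace(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(200):
            h = float(rng.uniform(0.1, 2.0))
            om = float(rng.uniform(0.5, 3.0))
            Ks = rng.uniform(0.0, 1.5 / om, size=4)
            report = two_layer_stability(self.disc(h, om), *Ks)
            eig_stable = bool(np.max(np.abs(report.eigenvalues)) < 1.0)
            assert report.theorem_flags["two_layer_conditions"] == eig_stable
            assert report.theorem_flags["det_trace"] == eig_stable

    @pytest.mark.parametrize("seed", range(5))
    def test_printed_conditions_are_sufficient_for_stability(self, seed):
        """The compact (theta, mu, discriminant) test never passes an unstable
        equilibrium, though it can reject stable ones."""
        rng = np.random.default_rng(50 + seed)
        for _ in range(200):
            h = float(rng.uniform(0.1, 2.0))
            om = float(rng.uniform(0.5, 3.0))
            Ks = rng.uniform(0.0, 1.5 / om, size=4)
            report = two_layer_stability(self.disc(h, om), *Ks)
            if report.theorem_flags["printed_sufficient"]:
                assert np.max(np.abs(report.eigenvalues)) < 1.0


class TestStabilityDynamicsConsistency:
    @pytest.mark.parametrize("seed", range(5))
    def test_stable_equilibria_reabsorb_small_perturbations(self, seed):
        model, v_star = fixture_with_fixed_point(seed, "stable")
        rng = np.random.default_rng(10_000 + seed)
        V = v_star.V.copy()
        m = model.architecture.sizes[0]
        pert = rng.uniform(-1.0, 1.0, size=m)
        V[0, :m] += 1e-3 * pert / np.max(np.abs(pert))
        traj = simulate(model, FieldState(V=V), 500)
        final_err = np.max(np.abs(traj.final().V - v_star.V))
        assert final_err < 1e-6

    @pytest.mark.parametrize("seed", range(5))
    def test_unstable_equilibria_amplify_small_perturbations(self, seed):
        model, v_star = fixture_with_fixed_point(seed, "unstable")
        rng = np.random.default_rng(20_000 + seed)
        V = v_star.V.copy()
        m = model.architecture.sizes[0]
        pert = rng.uniform(-1.0, 1.0, size=m)
        V[0, :m] += 1e-3 * pert / np.max(np.abs(pert))
        traj = simulate(model, FieldState(V=V), 500)
        err = np.max(np.abs(traj.values - v_star.V[None]), axis=(1, 2))
        assert np.max(err) >= 1e-2


class TestStabilityReport:
    def test_heaviside_report_on_standard_model(self, sec35_heaviside_model):
        model = sec35_heaviside_model
        traj = simulate(model, model.uniform_state(-1.5), 100)
        report = stability_report(model, traj.final())
        assert report.classification == "stable"
        assert report.rho == pytest.approx(ALPHA_08, rel=1e-12)
        assert report.theorem_flags["single_layer_mu"]
        np.testing.assert_array_equal(report.mu_single, np.zeros(200))
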