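"""Multivariate inference/learning and the layered hierarchy."""

import numpy as np
import numpy.linalg as la
import pytest
from scipy import stats

from predcoding import (
    ConfigurationError,
    Hierarchy,
    HierState,
    LayerParams,
    MultivariateModel,
    NonlinearMap,
    ScalarCircuitState,
    ScalarGenerativeModel,
    circuit_derivatives,
    floor_covariance,
    grad_theta,
    hier_derivatives,
    hier_parameter_gradients,
    learn_multivariate,
    mv_grad_phi,
    mv_infer_phi,
    mv_negative_free_energy,
    mv_parameter_gradients,
    negative_free_energy,
    parameter_gradients,
    simulate_hierarchy,
)
from predcoding.runtime import finite_diff_gradient

from conftest import random_spd


def _random_model(rng, n_feat=2, n_obs=2, h="identity"):
    return MultivariateModel(
        v_p=rng.normal(size=n_feat),
        Sigma_p=random_spd(rng, n_feat),
        Theta=rng.normal(size=(n_obs, n_feat)),
        Sigma_u=random_spd(rng, n_obs),
        h=NonlinearMap(h),
    )


def gls_posterior_mode(hier: Hierarchy, u: np.ndarray) -> list[np.ndarray]:
    """Normal-equations solution for a linear (h=identity) hierarchy.

    Independent oracle: minimizes the joint Gaussian quadratic over the
    unclamped levels by assembling and solving the full linear system.
    """
    sizes = hier.sizes
    free = sizes[1:]
    offs = np.concatenate([[0], np.cumsum(free)])
    n = offs[-1]
    A = np.zeros((n, n))
    b = np.zeros(n)
    precisions = [la.inv(l.Sigma) for l in hier.layers] + [la.inv(hier.Sigma_top)]
    # residual r_i = phi_i − Θ_i φ_{i+1} couples levels i and i+1
    for i, layer in enumerate(hier.layers):
        P = precisions[i]
        Th = layer.Theta
        if i == 0:
            A[offs[0]:offs[1], offs[0]:offs[1]] += Th.T @ P @ Th
            b[offs[0]:offs[1]] += Th.T @ P @ u
        else:
            lo, this = (offs[i - 1], offs[i]), (offs[i], offs[i + 1])
            A[lo[0]:lo[1], lo[0]:lo[1]] += P
            A[lo[0]:lo[1], this[0]:this[1]] += -P @ Th
            A[this[0]:this[1], lo[0]:lo[1]] += -Th.T @ P
            A[this[0]:this[1], this[0]:this[1]] += Th.T @ P @ Th
    Ptop = precisions[-1]
    A[offs[-2]:offs[-1], offs[-2]:offs[-1]] += Ptop
    b[offs[-2]:offs[-1]] += Ptop @ hier.v_p_top
    z = la.solve(A, b)
    return [z[offs[i]:offs[i + 1]] for i in range(len(free))]


class TestMultivariateFreeEnergy:
    def test_dimension_one_reduces_to_scalar(self, size_model, observed_intensity):
        mv = MultivariateModel(
            v_p=[size_model.v_p], Sigma_p=[[1.0]], Theta=[[1.0]], Sigma_u=[[1.0]],
            h=NonlinearMap("square"),
        )
        for phi in (0.5, 1.6, 3.0):
            assert mv_negative_free_energy(mv, [observed_intensity], [phi]) == pytest.approx(
                negative_free_energy(size_model, observed_intensity, phi), rel=1e-12
            )

    def test_value_at_perfect_prediction(self):
        rng = np.random.default_rng(2)
        model = _random_model(rng)
        u = model.g(model.v_p)
        sign_p, ld_p = la.slogdet(model.Sigma_p)
        sign_u, ld_u = la.slogdet(model.Sigma_u)
        expected = 0.5 * (-ld_p - ld_u) - 0.5 * 4 * np.log(2 * np.pi)
        assert mv_negative_free_energy(model, u, model.v_p) == pytest.approx(expected)

    def test_matches_multivariate_normal_log_densities(self):
        # independent oracle: scipy's multivariate normal log-pdf
        rng = np.random.default_rng(7)
        model = _random_model(rng, h="square")
        u = rng.normal(size=2)
        phi = rng.normal(size=2)
        expected = stats.multivariate_normal(model.v_p, model.Sigma_p).logpdf(phi) + stats.multivariate_normal(
            model.g(phi), model.Sigma_u
        ).logpdf(u)
        assert mv_negative_free_energy(model, u, phi) == pytest.approx(expected, rel=1e-12)


class TestMultivariateGradient:
    @pytest.mark.parametrize("h", ["identity", "square"])
    @pytest.mark.parametrize("n", [2, 3])
    def test_matches_finite_differences(self, h, n):
        rng = np.random.default_rng(n * 10 + len(h))
        model = _random_model(rng, n_feat=n, n_obs=n, h=h)
        u = rng.normal(size=n)
        phi = rng.normal(size=n)
        fd = finite_diff_gradient(lambda p: mv_negative_free_energy(model, u, p), phi)
        assert np.allclose(mv_grad_phi(model, u, phi), fd, rtol=1e-6, atol=1e-7)

    def test_matches_explicit_jacobian_assembly(self):
        # build the 2x2 Jacobian entry-by-entry: entry (j, i) = theta_ji h'(phi_i)
        rng = np.random.default_rng(3)
        model = _random_model(rng, h="square")
        u = rng.normal(size=2)
        phi = rng.normal(size=2)
        hp = model.h.derivative(phi)
        jac = model.Theta * hp[None, :]
        eps_p = la.solve(model.Sigma_p, phi - model.v_p)
        eps_u = la.solve(model.Sigma_u, u - model.g(phi))
        assert np.allclose(mv_grad_phi(model, u, phi), -eps_p + jac.T @ eps_u)

    def test_zero_at_prior_mean_with_perfect_observation(self):
        rng = np.random.default_rng(4)
        model = _random_model(rng, h="square")
        u = model.g(model.v_p)
        assert np.allclose(mv_grad_phi(model, u, model.v_p), 0.0, atol=1e-12)

    def test_gradient_ascent_reaches_stationary_point(self):
        rng = np.random.default_rng(5)
        model = _random_model(rng, h="identity")
        u = rng.normal(size=2)
        _, traj = mv_infer_phi(model, u, dt=0.01, T=30.0)
        assert np.allclose(mv_grad_phi(model, u, traj[-1]), 0.0, atol=1e-8)


class TestMultivariateParameterGradients:
    def test_dimension_one_reduces_to_scalar_rules(self):
        scalar = ScalarGenerativeModel(1.0, 2.0, 1.5, NonlinearMap("theta_h", theta=0.8, h_kind="square"))
        mv = MultivariateModel(
            v_p=[1.0], Sigma_p=[[2.0]], Theta=[[0.8]], Sigma_u=[[1.5]], h=NonlinearMap("square")
        )
        u, phi = 2.0, 1.2
        grads = mv_parameter_gradients(mv, [u], [phi])
        eps_p = (phi - scalar.v_p) / scalar.Sigma_p
        eps_u = (u - scalar.g(phi)) / scalar.Sigma_u
        dv, dsp, dsu = parameter_gradients(scalar, eps_p, eps_u)
        assert grads["v_p"][0] == pytest.approx(dv)
        assert grads["Sigma_p"][0, 0] == pytest.approx(dsp)
        assert grads["Sigma_u"][0, 0] == pytest.approx(dsu)
        assert grads["Theta"][0, 0] == pytest.approx(grad_theta(eps_u, phi, scalar.g))

    def test_sigma_gradients_match_symmetric_finite_differences(self):
        rng = np.random.default_rng(6)
        model = _random_model(rng, h="square")
        u = rng.normal(size=2)
        phi = rng.normal(size=2)
        grads = mv_parameter_gradients(model, u, phi)
        for name in ("Sigma_p", "Sigma_u"):
            fd = finite_diff_gradient(
                lambda S, name=name: mv_negative_free_energy(
                    MultivariateModel(
                        model.v_p,
                        S if name == "Sigma_p" else model.Sigma_p,
                        model.Theta,
                        S if name == "Sigma_u" else model.Sigma_u,
                        model.h,
                    ),
                    u,
                    phi,
                ),
                getattr(model, name),
                1e-5,
                symmetric=True,
            )
            assert np.allclose(grads[name], fd, atol=1e-5)

    def test_theta_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(8)
        model = _random_model(rng, h="square")
        u = rng.normal(size=2)
        phi = rng.normal(size=2)
        fd = finite_diff_gradient(
            lambda Th: mv_negative_free_energy(
                MultivariateModel(model.v_p, model.Sigma_p, Th, model.Sigma_u, model.h), u, phi
            ),
            model.Theta,
        )
        assert np.allclose(mv_parameter_gradients(model, u, phi)["Theta"], fd, rtol=1e-6, atol=1e-7)

    def test_sigma_updates_are_exactly_symmetric(self):
        rng = np.random.default_rng(9)
        model = _random_model(rng)
        grads = mv_parameter_gradients(model, rng.normal(size=2), rng.normal(size=2))
        assert np.array_equal(grads["Sigma_p"], grads["Sigma_p"].T)
        assert np.array_equal(grads["Sigma_u"], grads["Sigma_u"].T)


class TestFloorCovariance:
    def test_eigenvalues_clipped_and_symmetric(self):
        rng = np.random.default_rng(10)
        S = random_spd(rng, 3, jitter=0.01) * 0.1  # eigenvalues well below 1
        out = floor_covariance(S, 1.0)
        assert np.allclose(out, out.T)
        assert np.min(la.eigvalsh(out)) >= 1.0 - 1e-12

    def test_matrix_above_floor_unchanged(self):
        S = np.array([[2.0, 0.3], [0.3, 1.5]])
        assert np.allclose(floor_covariance(S, 1.0), S, atol=1e-12)


class TestHierarchy:
    def scalar_stack(self):
        # two scalar levels linked by g(v) = v^2 with unit weights: identical
        # to the three-node scalar circuit
        layer = LayerParams(Theta=[[1.0]], Sigma=[[1.0]], h=NonlinearMap("square"))
        return Hierarchy(layers=(layer,), v_p_top=[3.0], Sigma_top=[[1.0]])

    def test_two_scalar_levels_reduce_to_scalar_circuit(self, size_model):
        hier = self.scalar_stack()
        u, phi, eps_p, eps_u = 2.0, 1.4, 0.3, -0.2
        state = HierState(phi=[np.array([u]), np.array([phi])],
                          eps=[np.array([eps_u]), np.array([eps_p])])
        dphi, deps = hier_derivatives(hier, state)
        s = ScalarCircuitState(phi=phi, eps_p=eps_p, eps_u=eps_u)
        dphi_s, deps_p_s, deps_u_s = circuit_derivatives(size_model, u, s)
        assert dphi[0] == pytest.approx(0.0)  # sensory level clamped
        assert dphi[1][0] == pytest.approx(dphi_s)
        assert deps[0][0] == pytest.approx(deps_u_s)
        assert deps[1][0] == pytest.approx(deps_p_s)

    def test_error_derivatives_vanish_at_precision_weighted_fixed_point(self):
        rng = np.random.default_rng(11)
        sizes = (3, 2, 2)
        layers = tuple(
            LayerParams(Theta=rng.normal(size=(sizes[i], sizes[i + 1])),
                        Sigma=random_spd(rng, sizes[i]))
            for i in range(2)
        )
        hier = Hierarchy(layers=layers, v_p_top=rng.normal(size=2), Sigma_top=random_spd(rng, 2))
        phi = [rng.normal(size=n) for n in sizes]
        eps = [
            la.solve(layers[0].Sigma, phi[0] - layers[0].predict(phi[1])),
            la.solve(layers[1].Sigma, phi[1] - layers[1].predict(phi[2])),
            la.solve(hier.Sigma_top, phi[2] - hier.v_p_top),
        ]
        _, deps = hier_derivatives(hier, HierState(phi=phi, eps=eps))
        for d in deps:
            assert np.allclose(d, 0.0, atol=1e-12)

    def test_perfectly_predicted_input_keeps_errors_silent(self):
        rng = np.random.default_rng(12)
        layers = (
            LayerParams(Theta=rng.normal(size=(2, 2)), Sigma=np.eye(2)),
            LayerParams(Theta=rng.normal(size=(2, 2)), Sigma=np.eye(2)),
        )
        hier = Hierarchy(layers=layers, v_p_top=rng.normal(size=2), Sigma_top=np.eye(2))
        u = hier.predicted_means(np.zeros(2))  # top-down chain from the prior
        u = layers[0].predict(layers[1].predict(hier.v_p_top))
        _, states = simulate_hierarchy(hier, u, dt=0.01, T=3.0)
        for eps in states[-1].eps:
            assert np.allclose(eps, 0.0, atol=1e-12)
        assert np.allclose(states[-1].phi[2], hier.v_p_top, atol=1e-12)

    @pytest.mark.parametrize("sizes", [(2, 2, 2), (4, 3, 2), (4, 4, 4)])
    def test_linear_hierarchy_matches_normal_equations(self, sizes):
        rng = np.random.default_rng(sum(sizes))
        layers = tuple(
            LayerParams(Theta=rng.normal(size=(sizes[i], sizes[i + 1])),
                        Sigma=random_spd(rng, sizes[i], jitter=1.0))
            for i in range(len(sizes) - 1)
        )
        hier = Hierarchy(
            layers=layers, v_p_top=rng.normal(size=sizes[-1]),
            Sigma_top=random_spd(rng, sizes[-1], jitter=1.0),
        )
        u = rng.normal(size=sizes[0])
        _, states = simulate_hierarchy(hier, u, dt=0.01, T=300.0)
        oracle = gls_posterior_mode(hier, u)
        for level, expected in enumerate(oracle, start=1):
            assert np.allclose(states[-1].phi[level], expected, atol=1e-6)

    def test_two_level_converged_state_matches_gradient_route(self):
        rng = np.random.default_rng(13)
        model = _random_model(rng, h="identity")
        hier = Hierarchy(
            layers=(LayerParams(Theta=model.Theta, Sigma=model.Sigma_u, h=model.h),),
            v_p_top=model.v_p, Sigma_top=model.Sigma_p,
        )
        u = rng.normal(size=2)
        _, states = simulate_hierarchy(hier, u, dt=0.01, T=60.0)
        _, traj = mv_infer_phi(model, u, dt=0.01, T=60.0)
        assert np.allclose(states[-1].phi[1], traj[-1], atol=1e-6)

    def test_hier_parameter_gradients_match_two_level_rules(self):
        rng = np.random.default_rng(14)
        model = _random_model(rng, h="square")
        hier = Hierarchy(
            layers=(LayerParams(Theta=model.Theta, Sigma=model.Sigma_u, h=model.h),),
            v_p_top=model.v_p, Sigma_top=model.Sigma_p,
        )
        u = rng.normal(size=2)
        phi = rng.normal(size=2)
        eps_u = la.solve(model.Sigma_u, u - model.g(phi))
        eps_p = la.solve(model.Sigma_p, phi - model.v_p)
        state = HierState(phi=[u, phi], eps=[eps_u, eps_p])
        grads = hier_parameter_gradients(hier, state)
        mv_grads = mv_parameter_gradients(model, u, phi)
        assert np.allclose(grads[0]["Sigma"], mv_grads["Sigma_u"])
        assert np.allclose(grads[0]["Theta"], mv_grads["Theta"])
        assert np.allclose(grads[1]["v_p"], mv_grads["v_p"])
        assert np.allclose(grads[1]["Sigma"], mv_grads["Sigma_p"])

    def test_dimension_mismatch_raises(self):
        layer = LayerParams(Theta=np.ones((2, 2)), Sigma=np.eye(2))
        with pytest.raises(ConfigurationError):
            Hierarchy(layers=(layer,), v_p_top=np.zeros(3), Sigma_top=np.eye(3))
        hier = Hierarchy(layers=(layer,), v_p_top=np.zeros(2), Sigma_top=np.eye(2))
        bad = HierState(phi=[np.zeros(2)], eps=[np.zeros(2)])
        with pytest.raises(ConfigurationError):
            hier_derivatives(hier, bad)


class TestWeightLearning:
    def test_orthogonal_features_are_reconstructed_after_training(self):
        # two features mixed by orthogonal columns plus low observation
        # noise; after per-trial Hebbian weight learning the network should
        # reconstruct its inputs from the inferred features
        rng = np.random.default_rng(15)
        Theta_true = np.array([[1.0, 1.0], [1.0, -1.0]])
        n_trials = 5000
        feats = rng.normal(size=(n_trials, 2))
        us = feats @ Theta_true.T + rng.normal(size=(n_trials, 2)) * np.sqrt(0.1)
        model0 = MultivariateModel(
            v_p=np.zeros(2), Sigma_p=np.eye(2),
            Theta=rng.normal(size=(2, 2)) * 0.5, Sigma_u=0.1 * np.eye(2),
            h=NonlinearMap("identity"),
        )
        trained, hist = learn_multivariate(model0, us, alpha_theta=0.002, dt=0.02, T=2.0)
        assert np.mean(hist["reconstruction_error"][-500:]) < 0.10
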