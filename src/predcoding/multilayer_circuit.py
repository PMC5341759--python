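"""Multivariate and hierarchical predictive-coding networks.

The scalar model generalizes to vectors of features with multivariate
Gaussian priors and observation noise, observation map g(ϕ̄, Θ) = Θh(ϕ̄)
(features combine linearly after an element-wise nonlinearity), and then to
a stack of layers in which each layer's activity is the mean of the one
below: p(v̄_i | v̄_{i+1}) = N(Θ_i h(v̄_{i+1}), Σ_i).  Layer 1 is the sensory
input and is clamped; the top layer closes the chain with a fixed Gaussian
prior.

Inference integrates the node dynamics

    dϕ̄_i/dt = −ε̄_i + h'(ϕ̄_i) ∘ Θ_{i−1}ᵀ ε̄_{i−1}
    dε̄_i/dt = ϕ̄_i − Θ_i h(ϕ̄_{i+1}) − Σ_i ε̄_i

whose ε fixed points are the precision-weighted prediction errors
Σ_i⁻¹(ϕ̄_i − Θ_i h(ϕ̄_{i+1})).  Learning uses the matrix generalizations of
the scalar Hebbian rules: ΔΣ_i ∝ ½(ε̄_i ε̄_iᵀ − Σ_i⁻¹) and
ΔΘ_i ∝ ε̄_i h(ϕ̄_{i+1})ᵀ.  The Σ⁻¹ appearing in the Σ rule is computed
directly here; the interneuron circuit in
:mod:`predcoding.local_plasticity` removes it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import cached_property

import numpy as np

from .errors import ConfigurationError, InvalidParameterError
from .generative_models import NonlinearMap, _LOG_2PI
from .runtime import DEFAULT_DT, OVERFLOW_GUARD, TrialStream, euler_integrate

__all__ = [
    "MultivariateModel",
    "LayerParams",
    "Hierarchy",
    "HierState",
    "mv_negative_free_energy",
    "mv_grad_phi",
    "mv_errors",
    "mv_infer_phi",
    "mv_parameter_gradients",
    "learn_multivariate",
    "hier_derivatives",
    "simulate_hierarchy",
    "hier_parameter_gradients",
    "floor_covariance",
]


def _check_spd(name: str, S: np.ndarray) -> np.ndarray:
    S = np.atleast_2d(np.asarray(S, dtype=float))
    if S.shape[0] != S.shape[1]:
        raise ConfigurationError(f"{name} must be square, got shape {S.shape}")
    if not np.allclose(S, S.T, atol=1e-10):
        raise ConfigurationError(f"{name} must be symmetric")
    return S


def _sym_inv(S: np.ndarray) -> np.ndarray:
    """Exactly symmetric inverse of a symmetric matrix (so that Σ-gradient
    updates preserve symmetry to the last bit)."""
    inv = np.linalg.inv(S)
    return 0.5 * (inv + inv.T)


def floor_covariance(S: np.ndarray, floor: float = 1.0) -> np.ndarray:
    """Clip eigenvalues of a symmetric matrix at ``floor`` and re-symmetrize.

    Matrix analogue of the scalar variance floor: keeps every direction of
    the learned covariance at least as uncertain as the floor, so error-node
    relaxation never becomes arbitrarily slow or divergent.
    """
    S = 0.5 * (S + S.T)
    w, V = np.linalg.eigh(S)
    w = np.maximum(w, floor)
    out = (V * w) @ V.T
    return 0.5 * (out + out.T)


@dataclass(frozen=True)
class MultivariateModel:
    """Two-level multivariate model: prior N(v_p, Sigma_p) over features,
    observations N(Θh(ϕ̄), Sigma_u)."""

    v_p: np.ndarray
    Sigma_p: np.ndarray
    Theta: np.ndarray
    Sigma_u: np.ndarray
    h: NonlinearMap = field(default_factory=lambda: NonlinearMap("identity"))

    def __post_init__(self):
        v_p = np.atleast_1d(np.asarray(self.v_p, dtype=float))
        Theta = np.atleast_2d(np.asarray(self.Theta, dtype=float))
        Sigma_p = _check_spd("Sigma_p", self.Sigma_p)
        Sigma_u = _check_spd("Sigma_u", self.Sigma_u)
        if Sigma_p.shape[0] != v_p.size:
            raise ConfigurationError("Sigma_p does not match v_p")
        if Theta.shape[1] != v_p.size:
            raise ConfigurationError("Theta columns must match the feature dimension")
        if Sigma_u.shape[0] != Theta.shape[0]:
            raise ConfigurationError("Sigma_u must match the observation dimension")
        object.__setattr__(self, "v_p", v_p)
        object.__setattr__(self, "Theta", Theta)
        object.__setattr__(self, "Sigma_p", Sigma_p)
        object.__setattr__(self, "Sigma_u", Sigma_u)

    @property
    def n_features(self) -> int:
        return self.v_p.size

    @property
    def n_obs(self) -> int:
        return self.Theta.shape[0]

    @cached_property
    def Sigma_p_inv(self) -> np.ndarray:
        return _sym_inv(self.Sigma_p)

    @cached_property
    def Sigma_u_inv(self) -> np.ndarray:
        return _sym_inv(self.Sigma_u)

    def g(self, phi: np.ndarray) -> np.ndarray:
        return self.Theta @ np.atleast_1d(self.h(phi))


def mv_errors(model: MultivariateModel, u: np.ndarray, phi: np.ndarray):
    """Fixed-point prediction errors ε̄_p = Σ_p⁻¹(ϕ̄−v̄_p), ε̄_u = Σ_u⁻¹(ū−Θh(ϕ̄))."""
    u = np.atleast_1d(np.asarray(u, dtype=float))
    phi = np.atleast_1d(np.asarray(phi, dtype=float))
    eps_p = model.Sigma_p_inv @ (phi - model.v_p)
    eps_u = model.Sigma_u_inv @ (u - model.g(phi))
    return eps_p, eps_u


def mv_negative_free_energy(model: MultivariateModel, u, phi) -> float:
    """F = ln p(ϕ̄) + ln p(ū|ϕ̄) for the multivariate Gaussian model."""
    u = np.atleast_1d(np.asarray(u, dtype=float))
    phi = np.atleast_1d(np.asarray(phi, dtype=float))
    dp = phi - model.v_p
    du = u - model.g(phi)
    sign_p, logdet_p = np.linalg.slogdet(model.Sigma_p)
    sign_u, logdet_u = np.linalg.slogdet(model.Sigma_u)
    if sign_p <= 0 or sign_u <= 0:
        raise np.linalg.LinAlgError("covariance matrices must be positive definite")
    quad = (
        -logdet_p
        - dp @ np.linalg.solve(model.Sigma_p, dp)
        - logdet_u
        - du @ np.linalg.solve(model.Sigma_u, du)
    )
    n = model.n_features + model.n_obs
    return float(0.5 * quad - 0.5 * n * _LOG_2PI)


def mv_grad_phi(model: MultivariateModel, u, phi) -> np.ndarray:
    """∂F/∂ϕ̄ = −ε̄_p + h'(ϕ̄) ∘ (Θᵀ ε̄_u)."""
    phi = np.atleast_1d(np.asarray(phi, dtype=float))
    eps_p, eps_u = mv_errors(model, u, phi)
    return -eps_p + np.atleast_1d(model.h.derivative(phi)) * (model.Theta.T @ eps_u)


def mv_infer_phi(
    model: MultivariateModel,
    u,
    phi0=None,
    dt: float = DEFAULT_DT,
    T: float = 5.0,
    *,
    overflow_guard: float = OVERFLOW_GUARD,
):
    """Euler gradient ascent of F over ϕ̄; returns (t, trajectory)."""
    phi0 = model.v_p if phi0 is None else np.atleast_1d(np.asarray(phi0, dtype=float))
    return euler_integrate(
        lambda _t, y: mv_grad_phi(model, u, y), phi0, dt, T, overflow_guard=overflow_guard
    )


def mv_parameter_gradients(model: MultivariateModel, u, phi):
    """Gradients of F with respect to v̄_p, Σ_p, Σ_u and Θ at converged ϕ̄.

    Returns a dict with keys ``v_p``, ``Sigma_p``, ``Sigma_u``, ``Theta``:
    ε̄_p, ½(ε̄_pε̄_pᵀ−Σ_p⁻¹), ½(ε̄_uε̄_uᵀ−Σ_u⁻¹) and ε̄_u h(ϕ̄)ᵀ.
    """
    phi = np.atleast_1d(np.asarray(phi, dtype=float))
    eps_p, eps_u = mv_errors(model, u, phi)
    return {
        "v_p": eps_p,
        "Sigma_p": 0.5 * (np.outer(eps_p, eps_p) - model.Sigma_p_inv),
        "Sigma_u": 0.5 * (np.outer(eps_u, eps_u) - model.Sigma_u_inv),
        "Theta": np.outer(eps_u, np.atleast_1d(model.h(phi))),
    }


def learn_multivariate(
    model: MultivariateModel,
    trials: TrialStream | np.ndarray,
    *,
    alpha_theta: float = 0.01,
    alpha_sigma: float = 0.0,
    alpha_vp: float = 0.0,
    dt: float = DEFAULT_DT,
    T: float = 5.0,
    variance_floor: float = 1.0,
) -> tuple[MultivariateModel, dict]:
    """Per-trial learning for the two-level multivariate model.

    Each trial: infer ϕ̄ by gradient ascent, then step the requested
    parameters along their Hebbian gradients.  Σ updates are re-symmetrized
    and eigenvalue-floored.  Returns the trained model and a history dict
    with per-trial ϕ̄ and reconstruction errors ‖ū−Θh(ϕ̄)‖/‖ū‖.
    """
    us = trials.draw() if isinstance(trials, TrialStream) else np.asarray(trials, dtype=float)
    if us.ndim == 1:
        us = us[:, None]
    phis = np.empty((us.shape[0], model.n_features))
    recon = np.empty(us.shape[0])
    current = model
    for k, u in enumerate(us):
        _, traj = mv_infer_phi(current, u, dt=dt, T=T)
        phi = traj[-1]
        phis[k] = phi
        pred = current.g(phi)
        recon[k] = np.linalg.norm(u - pred) / max(np.linalg.norm(u), 1e-12)
        grads = mv_parameter_gradients(current, u, phi)
        updates = {}
        if alpha_vp:
            updates["v_p"] = current.v_p + alpha_vp * grads["v_p"]
        if alpha_theta:
            updates["Theta"] = current.Theta + alpha_theta * grads["Theta"]
        if alpha_sigma:
            updates["Sigma_p"] = floor_covariance(
                current.Sigma_p + alpha_sigma * grads["Sigma_p"], variance_floor
            )
            updates["Sigma_u"] = floor_covariance(
                current.Sigma_u + alpha_sigma * grads["Sigma_u"], variance_floor
            )
        if updates:
            current = replace(current, **updates)
    return current, {"phi": phis, "reconstruction_error": recon}


# ---------------------------------------------------------------------------
# hierarchy
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LayerParams:
    """Generative parameters for one level: layer i (below) is predicted from
    layer i+1 via Θ h(·) with residual covariance Σ (n_below × n_below)."""

    Theta: np.ndarray
    Sigma: np.ndarray
    h: NonlinearMap = field(default_factory=lambda: NonlinearMap("identity"))

    def __post_init__(self):
        Theta = np.atleast_2d(np.asarray(self.Theta, dtype=float))
        Sigma = _check_spd("Sigma", self.Sigma)
        if Sigma.shape[0] != Theta.shape[0]:
            raise ConfigurationError(
                f"Sigma (n={Sigma.shape[0]}) must match Theta rows (n={Theta.shape[0]})"
            )
        object.__setattr__(self, "Theta", Theta)
        object.__setattr__(self, "Sigma", Sigma)

    @property
    def n_below(self) -> int:
        return self.Theta.shape[0]

    @property
    def n_above(self) -> int:
        return self.Theta.shape[1]

    def predict(self, phi_above: np.ndarray) -> np.ndarray:
        return self.Theta @ np.atleast_1d(self.h(phi_above))


@dataclass(frozen=True)
class Hierarchy:
    """Stack of layers closed by a fixed Gaussian prior on the top layer.

    ``layers[i]`` links layer i+2 (above) to layer i+1 (below), bottom-up;
    layer 1 is the sensory input.
    """

    layers: tuple[LayerParams, ...]
    v_p_top: np.ndarray
    Sigma_top: np.ndarray

    def __post_init__(self):
        layers = tuple(self.layers)
        if not layers:
            raise ConfigurationError("hierarchy needs at least one layer of parameters")
        v_p_top = np.atleast_1d(np.asarray(self.v_p_top, dtype=float))
        Sigma_top = _check_spd("Sigma_top", self.Sigma_top)
        if Sigma_top.shape[0] != v_p_top.size:
            raise ConfigurationError("Sigma_top must match v_p_top")
        if layers[-1].n_above != v_p_top.size:
            raise ConfigurationError("top prior dimension must match the top layer")
        for lo, hi in zip(layers[:-1], layers[1:]):
            if lo.n_above != hi.n_below:
                raise ConfigurationError("adjacent layers have inconsistent dimensions")
        object.__setattr__(self, "layers", layers)
        object.__setattr__(self, "v_p_top", v_p_top)
        object.__setattr__(self, "Sigma_top", Sigma_top)

    @property
    def n_levels(self) -> int:
        return len(self.layers) + 1

    @property
    def sizes(self) -> tuple[int, ...]:
        return tuple(l.n_below for l in self.layers) + (self.v_p_top.size,)

    def predicted_means(self, u: np.ndarray) -> list[np.ndarray]:
        """Top-down predicted mean of every level (used to initialize ϕ̄)."""
        phis = [None] * self.n_levels
        phis[-1] = self.v_p_top.copy()
        for i in range(self.n_levels - 2, -1, -1):
            phis[i] = self.layers[i].predict(phis[i + 1])
        phis[0] = np.atleast_1d(np.asarray(u, dtype=float)).copy()
        return phis


@dataclass
class HierState:
    """Per-level activities; ``phi[0]`` is clamped to the observation."""

    phi: list[np.ndarray]
    eps: list[np.ndarray]

    def pack(self) -> np.ndarray:
        return np.concatenate([*self.phi, *self.eps])

    @classmethod
    def unpack(cls, y: np.ndarray, sizes: tuple[int, ...]) -> "HierState":
        parts = np.split(y, np.cumsum(np.array(sizes + sizes))[:-1])
        n = len(sizes)
        return cls(phi=list(parts[:n]), eps=list(parts[n:]))


def hier_derivatives(hier: Hierarchy, state: HierState):
    """Right-hand sides of the hierarchical node dynamics.

    Level-1 ϕ̄ is clamped to the observation (zero derivative); the top
    level's prediction error is driven by the fixed prior (v_p_top,
    Sigma_top).
    """
    L = hier.n_levels
    if len(state.phi) != L or len(state.eps) != L:
        raise ConfigurationError(f"state must carry {L} levels of phi and eps")
    dphi = [np.zeros_like(state.phi[0])]
    for i in range(1, L):
        layer_below = hier.layers[i - 1]  # links level i+1 (this) to level i (below)
        bottom_up = np.atleast_1d(layer_below.h.derivative(state.phi[i])) * (
            layer_below.Theta.T @ state.eps[i - 1]
        )
        dphi.append(-state.eps[i] + bottom_up)
    deps = []
    for i in range(L):
        if i < L - 1:
            pred = hier.layers[i].predict(state.phi[i + 1])
            Sigma = hier.layers[i].Sigma
        else:
            pred = hier.v_p_top
            Sigma = hier.Sigma_top
        deps.append(state.phi[i] - pred - Sigma @ state.eps[i])
    return dphi, deps


def simulate_hierarchy(
    hier: Hierarchy,
    u,
    dt: float = DEFAULT_DT,
    T: float = 5.0,
    *,
    state0: HierState | None = None,
    overflow_guard: float = OVERFLOW_GUARD,
):
    """Euler simulation of the full hierarchy for observation ū.

    ϕ̄ start at the top-down predicted means and ε̄ at zero unless ``state0``
    is given.  Returns ``(t, states)`` with one :class:`HierState` per step.
    """
    sizes = hier.sizes
    if state0 is None:
        phis = hier.predicted_means(u)
        state0 = HierState(phi=phis, eps=[np.zeros(n) for n in sizes])

    def deriv(_t, y):
        s = HierState.unpack(y, sizes)
        dphi, deps = hier_derivatives(hier, s)
        return np.concatenate([*dphi, *deps])

    t, traj = euler_integrate(deriv, state0.pack(), dt, T, overflow_guard=overflow_guard)
    states = [HierState.unpack(row, sizes) for row in traj]
    return t, states


def hier_parameter_gradients(hier: Hierarchy, state: HierState):
    """Per-layer Hebbian gradients at a converged state.

    Returns a list (bottom-up) of dicts with ``Sigma`` = ½(ε̄_iε̄_iᵀ−Σ_i⁻¹)
    and ``Theta`` = ε̄_i h(ϕ̄_{i+1})ᵀ, plus a final dict for the top prior
    (``v_p`` = ε̄_top, ``Sigma`` for Σ_top).
    """
    grads = []
    for i, layer in enumerate(hier.layers):
        eps = state.eps[i]
        grads.append(
            {
                "Sigma": 0.5 * (np.outer(eps, eps) - _sym_inv(layer.Sigma)),
                "Theta": np.outer(eps, np.atleast_1d(layer.h(state.phi[i + 1]))),
            }
        )
    eps_top = state.eps[-1]
    grads.append(
        {
            "v_p": eps_top,
            "Sigma": 0.5 * (np.outer(eps_top, eps_top) - _sym_inv(hier.Sigma_top)),
        }
    )
    return grads
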