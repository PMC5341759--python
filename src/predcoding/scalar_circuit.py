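"""Scalar free-energy inference and learning.

Two routes compute the most likely feature value ϕ for a
:class:`~predcoding.generative_models.ScalarGenerativeModel`:

* plain gradient ascent on the negative free energy F = ln p(u, ϕ)
  (:func:`infer_phi_gradient`), and
* a three-node neural circuit in which prediction-error nodes ε_p and ε_u
  relax to the precision-weighted errors (ϕ−v_p)/Σ_p and (u−g(ϕ))/Σ_u while
  ϕ integrates their feedback (:func:`simulate_circuit`).

Both converge to the same fixed point; the circuit gets there more slowly
because the coupled excitatory/inhibitory loop rings before settling.

All model parameters (v_p, Σ_p, Σ_u and, for parameterized observation maps,
the gain θ) are learnable by Hebbian rules: each gradient of F is a product
of activities available at the synapse (:func:`parameter_gradients`,
:func:`grad_theta`).  Estimated variances are floored at 1 so the error-node
dynamics stay well conditioned.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InvalidParameterError
from .generative_models import NonlinearMap, ScalarGenerativeModel, _LOG_2PI
from .runtime import DEFAULT_DT, DEFAULT_T, OVERFLOW_GUARD, TrialStream, euler_integrate

__all__ = [
    "ScalarCircuitState",
    "LearningRates",
    "VARIANCE_FLOOR",
    "negative_free_energy",
    "grad_F_phi",
    "infer_phi_gradient",
    "circuit_derivatives",
    "theta_circuit_derivatives",
    "simulate_circuit",
    "parameter_gradients",
    "parameter_gradients_from_phi",
    "grad_theta",
    "learn_parameters",
]

#: minimum admissible estimated variance (keeps ε-node relaxation stable)
VARIANCE_FLOOR = 1.0


@dataclass
class ScalarCircuitState:
    """Activities of the three-node circuit at time t."""

    phi: float
    eps_p: float = 0.0
    eps_u: float = 0.0
    t: float = 0.0

    def as_array(self) -> np.ndarray:
        return np.array([self.phi, self.eps_p, self.eps_u], dtype=float)

    @classmethod
    def from_array(cls, y: np.ndarray, t: float = 0.0) -> "ScalarCircuitState":
        return cls(phi=float(y[0]), eps_p=float(y[1]), eps_u=float(y[2]), t=t)


@dataclass(frozen=True)
class LearningRates:
    """Per-trial step sizes for parameter learning (zero disables a rule)."""

    alpha_vp: float = 0.01
    alpha_sigma: float = 0.01
    alpha_theta: float = 0.01

    def __post_init__(self):
        for name in ("alpha_vp", "alpha_sigma", "alpha_theta"):
            if getattr(self, name) < 0:
                raise InvalidParameterError(f"{name} must be non-negative")


def negative_free_energy(model: ScalarGenerativeModel, u: float, phi: float) -> float:
    """F(ϕ) = ln p(ϕ) + ln p(u|ϕ), constants retained so F = ln p(u, ϕ)."""
    quad = (
        -np.log(model.Sigma_p)
        - (phi - model.v_p) ** 2 / model.Sigma_p
        - np.log(model.Sigma_u)
        - (u - model.g(phi)) ** 2 / model.Sigma_u
    )
    return float(0.5 * quad - _LOG_2PI)


def grad_F_phi(model: ScalarGenerativeModel, u: float, phi: float) -> float:
    """∂F/∂ϕ = (v_p−ϕ)/Σ_p + (u−g(ϕ))·g'(ϕ)/Σ_u."""
    return float(
        (model.v_p - phi) / model.Sigma_p
        + (u - model.g(phi)) * model.g.derivative(phi) / model.Sigma_u
    )


def infer_phi_gradient(
    model: ScalarGenerativeModel,
    u: float,
    phi0: float | None = None,
    dt: float = DEFAULT_DT,
    T: float = DEFAULT_T,
    *,
    overflow_guard: float = OVERFLOW_GUARD,
):
    """Euler gradient ascent ϕ(t+Δt) = ϕ(t) + Δt·∂F/∂ϕ.

    Starts at the prior mean when ``phi0`` is omitted.  Returns ``(t, phi)``
    trajectory arrays.
    """
    if phi0 is None:
        phi0 = model.v_p
    t, traj = euler_integrate(
        lambda _t, y: np.array([grad_F_phi(model, u, float(y[0]))]),
        np.array([phi0], dtype=float),
        dt,
        T,
        overflow_guard=overflow_guard,
    )
    return t, traj[:, 0]


def circuit_derivatives(
    model: ScalarGenerativeModel, u: float, s: ScalarCircuitState
) -> tuple[float, float, float]:
    """Node dynamics of the three-node circuit.

    dϕ/dt  = ε_u·g'(ϕ) − ε_p
    dε_p/dt = ϕ − v_p − Σ_p·ε_p
    dε_u/dt = u − g(ϕ) − Σ_u·ε_u
    """
    dphi = s.eps_u * model.g.derivative(s.phi) - s.eps_p
    deps_p = s.phi - model.v_p - model.Sigma_p * s.eps_p
    deps_u = u - model.g(s.phi) - model.Sigma_u * s.eps_u
    return float(dphi), float(deps_p), float(deps_u)


def theta_circuit_derivatives(
    model: ScalarGenerativeModel, u: float, s: ScalarCircuitState
) -> tuple[float, float, float]:
    """Circuit dynamics for parameterized observation maps g(v,θ).

    For g = θv the ϕ node receives θ·ε_u; for g = θh(v) it receives
    θ·ε_u·h'(ϕ) (a modulatory pathway).  The error-node equations are the
    generic ones with the corresponding prediction θϕ or θh(ϕ).
    """
    if model.g.kind not in ("linear_theta", "theta_h"):
        raise ConfigurationError(
            f"theta circuit requires g.kind 'linear_theta' or 'theta_h', got {model.g.kind!r}"
        )
    # both cases reduce to eps_u * dg/dphi − eps_p with the right g
    return circuit_derivatives(model, u, s)


def simulate_circuit(
    model: ScalarGenerativeModel,
    u: float,
    s0: ScalarCircuitState | None = None,
    dt: float = DEFAULT_DT,
    T: float = DEFAULT_T,
    *,
    overflow_guard: float = OVERFLOW_GUARD,
) -> pd.DataFrame:
    """Euler simulation of the three-node circuit.

    Defaults to the standard initialization ϕ = v_p, ε_p = ε_u = 0.  Returns
    a DataFrame with columns (t, phi, eps_p, eps_u).
    """
    if s0 is None:
        s0 = ScalarCircuitState(phi=model.v_p)
    deriv_fn = theta_circuit_derivatives if model.g.kind in ("linear_theta", "theta_h") else circuit_derivatives

    def deriv(t, y):
        return np.array(deriv_fn(model, u, ScalarCircuitState.from_array(y, t)))

    t, traj = euler_integrate(deriv, s0.as_array(), dt, T, overflow_guard=overflow_guard)
    return pd.DataFrame({"t": t, "phi": traj[:, 0], "eps_p": traj[:, 1], "eps_u": traj[:, 2]})


def parameter_gradients(
    model: ScalarGenerativeModel, eps_p: float, eps_u: float
) -> tuple[float, float, float]:
    """Hebbian parameter gradients from error-node activities.

    ∂F/∂v_p = ε_p, ∂F/∂Σ_p = ½(ε_p²−1/Σ_p), ∂F/∂Σ_u = ½(ε_u²−1/Σ_u).
    """
    dv_p = eps_p
    dSigma_p = 0.5 * (eps_p**2 - 1.0 / model.Sigma_p)
    dSigma_u = 0.5 * (eps_u**2 - 1.0 / model.Sigma_u)
    return float(dv_p), float(dSigma_p), float(dSigma_u)


def parameter_gradients_from_phi(
    model: ScalarGenerativeModel, u: float, phi: float
) -> tuple[float, float, float]:
    """Same gradients written directly in terms of (ϕ, u).

    Equals :func:`parameter_gradients` when ε_p, ε_u sit at their fixed
    points (ϕ−v_p)/Σ_p and (u−g(ϕ))/Σ_u.
    """
    dv_p = (phi - model.v_p) / model.Sigma_p
    dSigma_p = 0.5 * ((phi - model.v_p) ** 2 / model.Sigma_p**2 - 1.0 / model.Sigma_p)
    dSigma_u = 0.5 * ((u - model.g(phi)) ** 2 / model.Sigma_u**2 - 1.0 / model.Sigma_u)
    return float(dv_p), float(dSigma_p), float(dSigma_u)


def grad_theta(eps_u: float, phi: float, g: NonlinearMap) -> float:
    """∂F/∂θ: ε_u·ϕ for g = θv, ε_u·h(ϕ) for g = θh(ϕ)."""
    if g.kind == "linear_theta":
        return float(eps_u * phi)
    if g.kind == "theta_h":
        return float(eps_u * g.h(phi))
    raise ConfigurationError(f"theta gradient requires a parameterized map, got g.kind={g.kind!r}")


def learn_parameters(
    model: ScalarGenerativeModel,
    trials: TrialStream | np.ndarray,
    rates: LearningRates = LearningRates(),
    dt: float = DEFAULT_DT,
    T: float = DEFAULT_T,
    *,
    learn_theta: bool = False,
    variance_floor: float = VARIANCE_FLOOR,
) -> pd.DataFrame:
    """Per-trial Hebbian learning of v_p, Σ_p, Σ_u (and optionally θ).

    Each trial presents one observation u, runs the three-node circuit for
    ``T`` time units (the operational meaning of convergence here), applies
    the gradients of F at the final activities scaled by the learning rates,
    and clips the variances at ``variance_floor``.  Returns one row per
    trial with the post-update parameters and the inferred ϕ.
    """
    us = trials.draw()[:, 0] if isinstance(trials, TrialStream) else np.asarray(trials, dtype=float)
    if us.size == 0:
        raise InvalidParameterError("trial stream is empty")
    rows = []
    current = model
    for k, u in enumerate(us):
        traj = simulate_circuit(current, float(u), dt=dt, T=T)
        phi = float(traj["phi"].iloc[-1])
        eps_p = float(traj["eps_p"].iloc[-1])
        eps_u = float(traj["eps_u"].iloc[-1])
        dv_p, dS_p, dS_u = parameter_gradients(current, eps_p, eps_u)
        v_p = current.v_p + rates.alpha_vp * dv_p
        Sigma_p = max(current.Sigma_p + rates.alpha_sigma * dS_p, variance_floor)
        Sigma_u = max(current.Sigma_u + rates.alpha_sigma * dS_u, variance_floor)
        g = current.g
        if learn_theta:
            g = g.with_theta(g.theta + rates.alpha_theta * grad_theta(eps_u, phi, g))
        current = ScalarGenerativeModel(v_p=v_p, Sigma_p=Sigma_p, Sigma_u=Sigma_u, g=g)
        rows.append(
            {"trial": k, "u": float(u), "phi": phi, "v_p": v_p,
             "Sigma_p": Sigma_p, "Sigma_u": Sigma_u, "theta": g.theta}
        )
    return pd.DataFrame(rows)
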