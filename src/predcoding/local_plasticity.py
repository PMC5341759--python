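"""Prediction-error units with inhibitory interneurons: learning variances
and covariances with strictly local Hebbian plasticity.

The covariance update ½(ε̄ε̄ᵀ − Σ⁻¹) of :mod:`predcoding.multilayer_circuit`
requires a matrix inverse, so a synapse would need to know weights it does
not touch.  Pairing each prediction-error node ε with an inhibitory
interneuron e removes the inverse.  With drive d̄ = ϕ̄_i − g_i(ϕ̄_{i+1}) held
(quasi-)constant, the dynamics

    dε̄/dt = d̄ − ē
    dē/dt = Σε̄ − ē

have the fixed point ε̄* = Σ⁻¹d̄, ē* = d̄ — exactly the precision-weighted
prediction error — and the connection weights learn with the purely local
Hebbian rule ΔΣ = α(ε̄ēᵀ − I), whose stochastic fixed point is the drive
covariance ⟨d̄d̄ᵀ⟩.  The fixed point is always stable for positive-definite
Σ: the linearized system matrix [[0, −I], [Σ, −I]] has negative-real-part
eigenvalues (scalar case: trace −1, determinant Σ).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InstabilityError, InvalidParameterError
from .runtime import DEFAULT_DT, DEFAULT_T_INNER, OVERFLOW_GUARD, TrialStream, euler_integrate

__all__ = [
    "ErrorUnitState",
    "StabilityResult",
    "error_unit_derivatives",
    "error_unit_fixed_point",
    "simulate_error_unit",
    "stability_analysis",
    "local_sigma_update",
    "run_variance_learning",
]


@dataclass
class ErrorUnitState:
    """Activities of paired error/interneuron populations and their weights."""

    eps: np.ndarray
    e: np.ndarray
    Sigma: np.ndarray

    def __post_init__(self):
        self.eps = np.atleast_1d(np.asarray(self.eps, dtype=float))
        self.e = np.atleast_1d(np.asarray(self.e, dtype=float))
        self.Sigma = np.atleast_2d(np.asarray(self.Sigma, dtype=float))
        if self.eps.shape != self.e.shape:
            raise ConfigurationError("eps and e must have the same length")
        if self.Sigma.shape != (self.eps.size, self.eps.size):
            raise ConfigurationError("Sigma must be square and match eps")


def error_unit_derivatives(s: ErrorUnitState, drive) -> tuple[np.ndarray, np.ndarray]:
    """dε̄/dt = drive − ē, dē/dt = Σε̄ − ē."""
    drive = np.atleast_1d(np.asarray(drive, dtype=float))
    if drive.shape != s.eps.shape:
        raise ConfigurationError("drive must match the unit dimension")
    return drive - s.e, s.Sigma @ s.eps - s.e


def error_unit_fixed_point(Sigma, drive) -> tuple[np.ndarray, np.ndarray]:
    """Algebraic fixed point (ε̄*, ē*) = (Σ⁻¹·drive, drive)."""
    Sigma = np.atleast_2d(np.asarray(Sigma, dtype=float))
    drive = np.atleast_1d(np.asarray(drive, dtype=float))
    return np.linalg.solve(Sigma, drive), drive.copy()


def simulate_error_unit(
    Sigma,
    drive,
    eps0=None,
    e0=None,
    dt: float = DEFAULT_DT,
    T: float = DEFAULT_T_INNER,
    *,
    overflow_guard: float = OVERFLOW_GUARD,
) -> pd.DataFrame:
    """Explicit Euler simulation of one error/interneuron pair (vector-valued).

    Returns a DataFrame with t and per-component eps/e columns.
    """
    Sigma = np.atleast_2d(np.asarray(Sigma, dtype=float))
    drive = np.atleast_1d(np.asarray(drive, dtype=float))
    d = drive.size
    eps0 = np.zeros(d) if eps0 is None else np.atleast_1d(np.asarray(eps0, dtype=float))
    e0 = np.zeros(d) if e0 is None else np.atleast_1d(np.asarray(e0, dtype=float))

    def deriv(_t, y):
        deps, de = error_unit_derivatives(ErrorUnitState(y[:d], y[d:], Sigma), drive)
        return np.concatenate([deps, de])

    t, traj = euler_integrate(deriv, np.concatenate([eps0, e0]), dt, T, overflow_guard=overflow_guard)
    cols = {"t": t}
    for i in range(d):
        cols[f"eps_{i}"] = traj[:, i]
        cols[f"e_{i}"] = traj[:, d + i]
    return pd.DataFrame(cols)


@dataclass(frozen=True)
class StabilityResult:
    """Linear stability of the (ε̄, ē) dynamics around their fixed point."""

    matrix: np.ndarray
    eigenvalues: np.ndarray
    trace: float
    determinant: float
    stable: bool


def stability_analysis(Sigma) -> StabilityResult:
    """Linearized system matrix [[0, −I], [Σ, −I]] and its spectrum.

    For scalar Σ this is the 2×2 matrix with trace −1 and determinant Σ;
    both eigenvalues then have negative real part whenever Σ > 0.
    """
    Sigma = np.atleast_2d(np.asarray(Sigma, dtype=float))
    d = Sigma.shape[0]
    A = np.block([[np.zeros((d, d)), -np.eye(d)], [Sigma, -np.eye(d)]])
    eig = np.linalg.eigvals(A)
    return StabilityResult(
        matrix=A,
        eigenvalues=eig,
        trace=float(np.trace(A)),
        determinant=float(np.linalg.det(A)),
        stable=bool(np.all(eig.real < 0)),
    )


def local_sigma_update(s: ErrorUnitState, alpha: float, *, floor: float = 1.0) -> np.ndarray:
    """One Hebbian step ΔΣ = α(ε̄ēᵀ − I), floored and re-symmetrized.

    The update reads only the pre/post-synaptic activities (ε_i, e_j); no
    matrix inverse appears anywhere in this learning path.  The identity
    subtraction makes the diagonal decay toward ⟨ε_i e_i⟩ = 1 and leaves
    off-diagonal targets at the raw covariances.  The instantaneous outer
    product is not symmetric, so the result is re-symmetrized (its
    expectation is symmetric); eigenvalues are clipped at ``floor``.
    """
    if not alpha >= 0:
        raise InvalidParameterError(f"alpha must be non-negative, got {alpha}")
    d = s.eps.size
    Sigma = s.Sigma + alpha * (np.outer(s.eps, s.e) - np.eye(d))
    if d == 1:
        return np.array([[max(float(Sigma[0, 0]), floor)]])
    from .multilayer_circuit import floor_covariance

    return floor_covariance(Sigma, floor)


def _euler_final_state(Sigma: np.ndarray, drive: np.ndarray, dt: float, T: float) -> np.ndarray:
    """Final Euler state of the linear (ε̄, ē) system from zero initial state.

    The Euler recursion x_{k+1} = (I + dt·A)x_k + dt·b is affine, so the
    state after N = round(T/dt) steps is available in closed form,
    x_N = (Σ_{j<N} M^j)·dt·b = −A⁻¹(I − M^N)·b with M = I + dt·A.  This is
    algebraically identical to stepping the loop (verified in the tests) and
    keeps multi-thousand-trial learning runs fast.
    """
    d = drive.size
    A = np.block([[np.zeros((d, d)), -np.eye(d)], [Sigma, -np.eye(d)]])
    b = np.concatenate([drive, np.zeros(d)])
    M = np.eye(2 * d) + dt * A
    N = int(round(T / dt))
    MN = np.linalg.matrix_power(M, N)
    return np.linalg.solve(-A, (np.eye(2 * d) - MN) @ b)


def run_variance_learning(
    trials: TrialStream | np.ndarray,
    Sigma0=1.0,
    alpha: float = 0.01,
    T_inner: float = DEFAULT_T_INNER,
    dt: float = DEFAULT_DT,
    *,
    floor: float = 1.0,
    overflow_guard: float = OVERFLOW_GUARD,
) -> np.ndarray:
    """Trial-by-trial variance/covariance learning in the interneuron circuit.

    Per trial: hold the drive constant, integrate the (ε̄, ē) dynamics from
    rest for ``T_inner`` time units with step ``dt`` (Euler; evaluated in
    closed form since the system is linear), then apply the local Hebbian
    update with learning rate ``alpha``.  Returns the per-trial Σ after each
    update, shape (n_trials, d, d).
    """
    drives = trials.draw() if isinstance(trials, TrialStream) else np.asarray(trials, dtype=float)
    if drives.ndim == 1:
        drives = drives[:, None]
    n_trials, d = drives.shape
    Sigma = np.atleast_2d(np.asarray(Sigma0, dtype=float)).copy()
    if Sigma.shape != (d, d):
        raise ConfigurationError(f"Sigma0 must be {d}x{d}, got {Sigma.shape}")
    out = np.empty((n_trials, d, d))
    for k in range(n_trials):
        x = _euler_final_state(Sigma, drives[k], dt, T_inner)
        if not np.all(np.abs(x) <= overflow_guard):
            raise InstabilityError(
                f"error-unit dynamics exceeded the overflow guard on trial {k} (dt={dt})",
                step=k,
                dt=dt,
            )
        state = ErrorUnitState(eps=x[:d], e=x[d:], Sigma=Sigma)
        Sigma = local_sigma_update(state, alpha, floor=floor)
        out[k] = Sigma
    return out
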