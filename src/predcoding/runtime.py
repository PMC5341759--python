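"""Shared simulation engineering: explicit Euler integration, seeded
synthetic trial streams, and the finite-difference gradient oracle used to
verify every analytic gradient in the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, InstabilityError, InvalidParameterError

__all__ = [
    "DEFAULT_DT",
    "DEFAULT_T",
    "DEFAULT_T_INNER",
    "OVERFLOW_GUARD",
    "SimulationConfig",
    "TrialStream",
    "euler_integrate",
    "generate_trials",
    "finite_diff_gradient",
]

DEFAULT_DT = 0.01
DEFAULT_T = 5.0
DEFAULT_T_INNER = 20.0
OVERFLOW_GUARD = 1e8


@dataclass(frozen=True)
class SimulationConfig:
    """Integration settings shared by the circuit simulations."""

    dt: float = DEFAULT_DT
    T: float = DEFAULT_T
    T_inner: float = DEFAULT_T_INNER
    overflow_guard: float = OVERFLOW_GUARD
    output_path: str | None = None

    def __post_init__(self):
        if not self.dt > 0:
            raise InvalidParameterError(f"dt must be positive, got {self.dt}")
        if self.dt > min(self.T, self.T_inner):
            raise InvalidParameterError(
                f"dt={self.dt} exceeds the integration horizon min(T, T_inner)="
                f"{min(self.T, self.T_inner)}"
            )


def euler_integrate(deriv, y0, dt: float, T: float, *, overflow_guard: float = OVERFLOW_GUARD):
    """Fixed-step explicit Euler integration of ``dy/dt = deriv(t, y)``.

    Returns ``(t, traj)`` where ``t`` has ``round(T/dt) + 1`` entries
    (including t=0 and the final step) and ``traj[k]`` is the state at
    ``t[k]``.  Raises :class:`InstabilityError` (naming the offending step
    and dt) as soon as any state component exceeds ``overflow_guard`` in
    magnitude.
    """
    if not dt > 0:
        raise InvalidParameterError(f"dt must be positive, got {dt}")
    if dt > T:
        raise InvalidParameterError(f"dt={dt} exceeds horizon T={T}")
    n_steps = int(round(T / dt))
    y = np.array(y0, dtype=float)
    t = dt * np.arange(n_steps + 1)
    traj = np.empty((n_steps + 1,) + y.shape)
    traj[0] = y
    for k in range(n_steps):
        y = y + dt * np.asarray(deriv(t[k], y), dtype=float)
        if not np.all(np.abs(y) <= overflow_guard):
            raise InstabilityError(
                f"trajectory exceeded overflow guard {overflow_guard:g} at step {k + 1} "
                f"(t={t[k + 1]:g}, dt={dt}); reduce dt or check the dynamics",
                step=k + 1,
                dt=dt,
            )
        traj[k + 1] = y
    return t, traj


@dataclass(frozen=True)
class TrialStream:
    """Seeded stream of synthetic per-trial drives.

    Each trial draws an input from N(mean, cov) and subtracts the (constant)
    top-down prediction ``g_pred``, producing the drive seen by a
    prediction-error unit.  With ``g_pred = 0`` the stream returns the raw
    draws, which is how observation sequences for learning experiments are
    produced.
    """

    seed: int
    n_trials: int
    mean: np.ndarray | float = 0.0
    cov: np.ndarray | float = 1.0
    g_pred: np.ndarray | float = 0.0
    dim: int = field(default=0)  # 0 -> inferred from mean

    def __post_init__(self):
        if self.n_trials <= 0:
            raise InvalidParameterError(f"n_trials must be positive, got {self.n_trials}")
        mean = np.atleast_1d(np.asarray(self.mean, dtype=float))
        dim = self.dim or mean.size
        if mean.size == 1 and dim > 1:
            mean = np.full(dim, mean[0])
        if mean.size != dim:
            raise ConfigurationError(f"mean has size {mean.size}, expected {dim}")
        cov = np.asarray(self.cov, dtype=float)
        if cov.ndim == 0:
            cov = float(cov) * np.eye(dim)
        if cov.shape != (dim, dim):
            raise ConfigurationError(f"cov has shape {cov.shape}, expected {(dim, dim)}")
        if not np.allclose(cov, cov.T):
            raise ConfigurationError("cov must be symmetric")
        if np.min(np.linalg.eigvalsh(cov)) < -1e-10:
            raise ConfigurationError("cov must be positive semi-definite")
        g_pred = np.atleast_1d(np.asarray(self.g_pred, dtype=float))
        if g_pred.size == 1 and dim > 1:
            g_pred = np.full(dim, g_pred[0])
        if g_pred.size != dim:
            raise ConfigurationError(f"g_pred has size {g_pred.size}, expected {dim}")
        object.__setattr__(self, "mean", mean)
        object.__setattr__(self, "cov", cov)
        object.__setattr__(self, "g_pred", g_pred)
        object.__setattr__(self, "dim", dim)

    @property
    def scalar(self) -> bool:
        return self.dim == 1

    def draw(self) -> np.ndarray:
        """All drives as an (n_trials, dim) array."""
        return generate_trials(self)


def generate_trials(stream: TrialStream) -> np.ndarray:
    """Drives for every trial: draws from N(mean, cov) minus g_pred.

    Reproducible given the stream's seed; returns shape (n_trials, dim).
    """
    rng = np.random.default_rng(stream.seed)
    chol = np.linalg.cholesky(stream.cov + 1e-15 * np.eye(stream.dim))
    z = rng.standard_normal((stream.n_trials, stream.dim))
    draws = stream.mean + z @ chol.T
    return draws - stream.g_pred


def finite_diff_gradient(fn, point, step: float = 1e-6, *, symmetric: bool = False):
    """Central finite-difference gradient of a scalar function.

    ``point`` may be a scalar, vector or matrix; the result has the same
    shape.  With ``symmetric=True`` (matrix arguments only) entries (i, j)
    and (j, i) are perturbed together and the difference quotient divided by
    the number of perturbed entries, which for a function of a symmetric
    matrix reproduces the element-wise gradient convention used by the
    analytic covariance rules.
    """
    if not step > 0:
        raise InvalidParameterError(f"step must be positive, got {step}")
    x = np.asarray(point, dtype=float)
    if x.ndim == 0:
        return (fn(float(x) + step) - fn(float(x) - step)) / (2.0 * step)
    grad = np.empty_like(x)
    if symmetric:
        if x.ndim != 2 or x.shape[0] != x.shape[1]:
            raise ConfigurationError("symmetric perturbation requires a square matrix argument")
        n = x.shape[0]
        for i in range(n):
            for j in range(i, n):
                pert = np.zeros_like(x)
                pert[i, j] = step
                pert[j, i] = step
                count = 1 if i == j else 2
                g = (fn(x + pert) - fn(x - pert)) / (2.0 * step * count)
                grad[i, j] = g
                grad[j, i] = g
        return grad
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        idx = it.multi_index
        xp = x.copy()
        xm = x.copy()
        xp[idx] += step
        xm[idx] -= step
        grad[idx] = (fn(xp) - fn(xm)) / (2.0 * step)
    return grad
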