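"""Gaussian generative models of a scalar sensory feature and their exact
grid-based posterior.

The model describes an observer inferring a hidden feature ``v`` (e.g. the
size of an object) from a noisy scalar observation ``u`` (e.g. perceived
light intensity).  The prior is ``v ~ N(v_p, Sigma_p)`` and the likelihood is
``u | v ~ N(g(v), Sigma_u)`` for a (possibly nonlinear) observation map
``g``.  Because ``g`` may be nonlinear, the posterior ``p(v|u)`` generally
has no standard form; :func:`exact_posterior` evaluates it on a uniform grid
and normalizes numerically, providing the exact reference against which the
circuit-based approximate inference elsewhere in the package is checked.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DegeneratePosteriorError, InvalidParameterError

__all__ = [
    "NonlinearMap",
    "ScalarGenerativeModel",
    "PosteriorGrid",
    "normal_density",
    "log_normal_density",
    "observation_map",
    "observation_map_derivative",
    "exact_posterior",
    "posterior_argmax",
]

_LOG_2PI = float(np.log(2.0 * np.pi))

#: observation-map kinds understood by :class:`NonlinearMap`
_KINDS = ("square", "identity", "linear_theta", "theta_h")
_H_KINDS = ("square", "identity")


@dataclass(frozen=True)
class NonlinearMap:
    """Observation map ``g`` (or inner nonlinearity ``h``) with its derivative.

    Parameters
    ----------
    kind:
        ``"square"``    -> g(v) = v**2
        ``"identity"``  -> g(v) = v
        ``"linear_theta"`` -> g(v) = theta * v
        ``"theta_h"``   -> g(v) = theta * h(v), with ``h`` selected by `h_kind`
    theta:
        Gain parameter; only used by ``linear_theta`` and ``theta_h``.
    h_kind:
        Inner nonlinearity for ``theta_h`` (``"square"`` or ``"identity"``).
    """

    kind: str = "square"
    theta: float = 1.0
    h_kind: str = "square"

    def __post_init__(self):
        if self.kind not in _KINDS:
            raise ConfigurationError(f"unknown map kind {self.kind!r}; expected one of {_KINDS}")
        if self.h_kind not in _H_KINDS:
            raise ConfigurationError(f"unknown h kind {self.h_kind!r}; expected one of {_H_KINDS}")

    # --- inner nonlinearity h --------------------------------------------
    def h(self, v):
        v = np.asarray(v, dtype=float)
        out = v * v if self.h_kind == "square" else v
        return out if out.ndim else float(out)

    def h_prime(self, v):
        v = np.asarray(v, dtype=float)
        out = 2.0 * v if self.h_kind == "square" else np.ones_like(v)
        return out if out.ndim else float(out)

    # --- the map itself ---------------------------------------------------
    def __call__(self, v):
        v = np.asarray(v, dtype=float)
        if self.kind == "square":
            out = v * v
        elif self.kind == "identity":
            out = v + 0.0
        elif self.kind == "linear_theta":
            out = self.theta * v
        else:  # theta_h
            out = self.theta * np.asarray(self.h(v), dtype=float)
        return out if out.ndim else float(out)

    def derivative(self, v):
        v = np.asarray(v, dtype=float)
        if self.kind == "square":
            out = 2.0 * v
        elif self.kind == "identity":
            out = np.ones_like(v)
        elif self.kind == "linear_theta":
            out = np.full_like(v, self.theta)
        else:  # theta_h
            out = self.theta * np.asarray(self.h_prime(v), dtype=float)
        return out if out.ndim else float(out)

    def with_theta(self, theta: float) -> "NonlinearMap":
        return NonlinearMap(self.kind, float(theta), self.h_kind)


@dataclass(frozen=True)
class ScalarGenerativeModel:
    """Scalar Gaussian generative model: prior N(v_p, Sigma_p), likelihood
    N(g(v), Sigma_u)."""

    v_p: float
    Sigma_p: float
    Sigma_u: float
    g: NonlinearMap = field(default_factory=NonlinearMap)

    def __post_init__(self):
        if not self.Sigma_p > 0:
            raise InvalidParameterError(f"Sigma_p must be positive, got {self.Sigma_p}")
        if not self.Sigma_u > 0:
            raise InvalidParameterError(f"Sigma_u must be positive, got {self.Sigma_u}")

    def log_prior(self, v):
        return log_normal_density(v, self.v_p, self.Sigma_p)

    def log_likelihood(self, u, v):
        return log_normal_density(u, self.g(v), self.Sigma_u)

    def replace(self, **kwargs) -> "ScalarGenerativeModel":
        fields = {"v_p": self.v_p, "Sigma_p": self.Sigma_p, "Sigma_u": self.Sigma_u, "g": self.g}
        fields.update(kwargs)
        return ScalarGenerativeModel(**fields)


@dataclass(frozen=True)
class PosteriorGrid:
    """Exact posterior evaluated on a uniform grid.

    ``density`` integrates (trapezoidally) to 1 over ``grid``; ``normalizer``
    is the numerical estimate of the model evidence p(u).
    """

    grid: np.ndarray
    density: np.ndarray
    normalizer: float

    def __iter__(self) -> Iterator[tuple[float, float]]:
        return zip(self.grid, self.density)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"v": self.grid, "posterior_density": self.density})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def normal_density(x, mu, sigma2):
    """Density of N(mu, sigma2) at x; sigma2 is a variance."""
    return np.exp(log_normal_density(x, mu, sigma2))


def log_normal_density(x, mu, sigma2):
    """Log-density of N(mu, sigma2) at x, computed directly for stability."""
    sigma2 = np.asarray(sigma2, dtype=float)
    if np.any(sigma2 <= 0):
        raise InvalidParameterError(f"variance must be positive, got {sigma2}")
    x = np.asarray(x, dtype=float)
    mu = np.asarray(mu, dtype=float)
    with np.errstate(over="ignore"):  # -> -inf log-density, handled downstream
        out = -0.5 * (_LOG_2PI + np.log(sigma2) + (x - mu) ** 2 / sigma2)
    return out if out.ndim else float(out)


def observation_map(g: NonlinearMap, v):
    """Evaluate the observation map g(v)."""
    return g(v)


def observation_map_derivative(g: NonlinearMap, v):
    """Evaluate g'(v)."""
    return g.derivative(v)


def make_grid(lo: float, hi: float, step: float) -> np.ndarray:
    """Uniform grid inclusive of both endpoints."""
    if not step > 0:
        raise InvalidParameterError(f"grid_step must be positive, got {step}")
    if not lo < hi:
        raise InvalidParameterError(f"grid_lo must be below grid_hi, got [{lo}, {hi}]")
    n = int(round((hi - lo) / step))
    return lo + step * np.arange(n + 1)


def exact_posterior(
    model: ScalarGenerativeModel,
    u: float,
    grid_lo: float = 0.01,
    grid_hi: float = 5.0,
    grid_step: float = 0.01,
) -> PosteriorGrid:
    """Exact posterior p(v|u) on a uniform grid, normalized numerically.

    The unnormalized log-posterior ln p(v) + ln p(u|v) is evaluated on the
    grid, shifted by its maximum before exponentiation (the likelihood can
    underflow over most of the grid for nonlinear g), and normalized with the
    trapezoidal rule.  The returned ``normalizer`` is the corresponding
    estimate of p(u).
    """
    grid = make_grid(grid_lo, grid_hi, grid_step)
    log_w = model.log_prior(grid) + model.log_likelihood(u, grid)
    m = np.max(log_w)
    if not np.isfinite(m):
        raise DegeneratePosteriorError("unnormalized posterior underflowed everywhere on the grid")
    w = np.exp(log_w - m)
    z_shifted = np.trapezoid(w, grid)
    if z_shifted <= 0:
        raise DegeneratePosteriorError("posterior normalizer is numerically zero")
    normalizer = float(np.exp(m) * z_shifted)
    return PosteriorGrid(grid=grid, density=w / z_shifted, normalizer=normalizer)


def posterior_argmax(post: PosteriorGrid) -> float:
    """Grid value with maximal posterior density (ties -> smallest value)."""
    if len(post.density) == 0:
        raise InvalidParameterError("posterior density is empty")
    return float(post.grid[int(np.argmax(post.density))])
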