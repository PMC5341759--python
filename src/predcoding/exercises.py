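"""Canned worked examples (five standard simulations).

Each runner uses the standard parameter set of the running example — prior
N(3, 1) over the feature, observation noise variance 1, observation map
g(v) = v², observed intensity u = 2 — or, for the variance-learning
exercise, drives from N(5, 2) with the correct top-down prediction 5.
Results are returned as a dict and optionally written as CSV + JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .generative_models import (
    NonlinearMap,
    ScalarGenerativeModel,
    exact_posterior,
    posterior_argmax,
)
from .local_plasticity import run_variance_learning
from .multilayer_circuit import MultivariateModel, mv_grad_phi, mv_negative_free_energy, mv_parameter_gradients
from .runtime import SimulationConfig, TrialStream, finite_diff_gradient
from .scalar_circuit import grad_F_phi, infer_phi_gradient, negative_free_energy, simulate_circuit

__all__ = ["EXERCISE_MODEL", "EXERCISE_U", "run_exercise"]

#: the package's running example: size prior N(3, 1), intensity noise 1, g(v)=v²
EXERCISE_MODEL = ScalarGenerativeModel(v_p=3.0, Sigma_p=1.0, Sigma_u=1.0, g=NonlinearMap("square"))
EXERCISE_U = 2.0


def _write(out_dir, name, df: pd.DataFrame | None, summary: dict) -> None:
    if out_dir is None:
        return
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if df is not None:
        df.to_csv(out_dir / f"{name}.csv", index=False)
    with open(out_dir / f"{name}_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=float)


def run_exercise(
    exercise_id: int,
    config: SimulationConfig | None = None,
    *,
    seed: int = 0,
    out_dir=None,
) -> dict:
    """Run one of the five worked simulations; returns its summary dict.

    When ``out_dir`` is given, writes ``exercise<k>.csv`` (posterior or
    trajectory) and ``exercise<k>_summary.json``.
    """
    cfg = config or SimulationConfig()
    model, u = EXERCISE_MODEL, EXERCISE_U
    if exercise_id == 1:
        post = exact_posterior(model, u, 0.01, 5.0, 0.01)
        summary = {
            "argmax": posterior_argmax(post),
            "normalizer": post.normalizer,
            "config": {"grid": [0.01, 5.0, 0.01], "u": u},
        }
        _write(out_dir, "exercise1", post.to_frame(), summary)
        return summary
    if exercise_id == 2:
        t, phi = infer_phi_gradient(model, u, dt=cfg.dt, T=cfg.T)
        summary = {"phi_final": float(phi[-1]), "config": {"dt": cfg.dt, "T": cfg.T, "phi0": model.v_p}}
        _write(out_dir, "exercise2", pd.DataFrame({"t": t, "phi": phi}), summary)
        return summary
    if exercise_id == 3:
        traj = simulate_circuit(model, u, dt=cfg.dt, T=cfg.T)
        summary = {
            "phi_final": float(traj["phi"].iloc[-1]),
            "eps_p_final": float(traj["eps_p"].iloc[-1]),
            "eps_u_final": float(traj["eps_u"].iloc[-1]),
            "config": {"dt": cfg.dt, "T": cfg.T},
        }
        _write(out_dir, "exercise3", traj, summary)
        return summary
    if exercise_id == 4:
        summary = _gradient_check_suite(seed)
        _write(out_dir, "exercise4", None, summary)
        return summary
    if exercise_id == 5:
        stream = TrialStream(seed=seed, n_trials=1000, mean=5.0, cov=2.0, g_pred=5.0)
        sigmas = run_variance_learning(stream, Sigma0=1.0, alpha=0.01, T_inner=cfg.T_inner, dt=cfg.dt)
        trace = sigmas[:, 0, 0]
        summary = {
            "sigma_final": float(trace[-1]),
            "sigma_trailing_mean": float(np.mean(trace[-200:])),
            "generating_variance": 2.0,
            "config": {"alpha": 0.01, "T_inner": cfg.T_inner, "dt": cfg.dt, "n_trials": 1000, "seed": seed},
        }
        _write(out_dir, "exercise5", pd.DataFrame({"trial": np.arange(len(trace)), "Sigma": trace}), summary)
        return summary
    raise ConfigurationError(f"exercise id must be 1..5, got {exercise_id}")


def _gradient_check_suite(seed: int) -> dict:
    """Verify every analytic gradient against central finite differences."""
    rng = np.random.default_rng(seed)
    report: dict[str, float] = {}

    # vector rule d(x^T x)/dx = 2x
    x = rng.normal(size=4)
    report["xTx_rule"] = float(
        np.max(np.abs(finite_diff_gradient(lambda z: z @ z, x) - 2 * x))
    )
    # matrix rule d ln|A| / dA = A^{-1} on a random SPD matrix
    B = rng.normal(size=(3, 3))
    A = B @ B.T + 3 * np.eye(3)
    report["logdet_rule"] = float(
        np.max(np.abs(
            finite_diff_gradient(lambda M: np.linalg.slogdet(M)[1], A, 1e-5)
            - np.linalg.inv(A)
        ))
    )
    # matrix rule d(x^T A^{-1} x)/dA = -(A^{-1}x)(A^{-1}x)^T
    v = rng.normal(size=3)
    Ainv_v = np.linalg.solve(A, v)
    report["quad_inverse_rule"] = float(
        np.max(np.abs(
            finite_diff_gradient(lambda M: v @ np.linalg.solve(M, v), A, 1e-5)
            + np.outer(Ainv_v, Ainv_v)
        ))
    )
    # scalar free-energy gradient
    phi = float(rng.uniform(0.5, 3.0))
    report["scalar_grad_phi"] = float(
        abs(
            finite_diff_gradient(lambda p: negative_free_energy(EXERCISE_MODEL, EXERCISE_U, p), phi)
            - grad_F_phi(EXERCISE_MODEL, EXERCISE_U, phi)
        )
    )
    # multivariate gradients on a random 2-feature instance
    model = MultivariateModel(
        v_p=rng.normal(size=2),
        Sigma_p=np.eye(2) * 1.5,
        Theta=rng.normal(size=(2, 2)),
        Sigma_u=np.eye(2) * 2.0,
        h=NonlinearMap("identity"),
    )
    u_vec = rng.normal(size=2)
    phi_vec = rng.normal(size=2)
    report["mv_grad_phi"] = float(
        np.max(np.abs(
            finite_diff_gradient(lambda p: mv_negative_free_energy(model, u_vec, p), phi_vec)
            - mv_grad_phi(model, u_vec, phi_vec)
        ))
    )
    grads = mv_parameter_gradients(model, u_vec, phi_vec)
    report["mv_grad_theta"] = float(
        np.max(np.abs(
            finite_diff_gradient(
                lambda Th: mv_negative_free_energy(
                    MultivariateModel(model.v_p, model.Sigma_p, Th, model.Sigma_u, model.h),
                    u_vec, phi_vec,
                ),
                model.Theta,
            )
            - grads["Theta"]
        ))
    )
    report["max_abs_error"] = max(report.values())
    report["seed"] = seed
    return report
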