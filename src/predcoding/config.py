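"""Model-specification files.

Two formats are understood, both parsed with YAML (a flat ``key: value``
file is valid YAML):

* scalar model — flat keys ``v_p``, ``sigma_p``, ``sigma_u``, ``g.kind``,
  ``g.theta``, ``g.h_kind``;
* layer stack — a ``layers`` list (bottom-up), each entry with ``theta``
  (inline matrix or path to a headerless CSV), ``sigma`` (matrix, CSV path,
  or scalar for isotropic), optional ``h`` (``identity``/``square``), and a
  ``top`` entry with ``v_p`` and ``sigma``.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import yaml

from .errors import ConfigurationError
from .generative_models import NonlinearMap, ScalarGenerativeModel
from .multilayer_circuit import Hierarchy, LayerParams

__all__ = ["load_scalar_model", "load_hierarchy", "scalar_model_to_dict"]


def _load_yaml(path) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ConfigurationError(f"config {path} must be a mapping")
    return data


def load_scalar_model(path) -> ScalarGenerativeModel:
    data = _load_yaml(path)
    g = NonlinearMap(
        kind=str(data.get("g.kind", "square")),
        theta=float(data.get("g.theta", 1.0)),
        h_kind=str(data.get("g.h_kind", "square")),
    )
    try:
        return ScalarGenerativeModel(
            v_p=float(data["v_p"]),
            Sigma_p=float(data["sigma_p"]),
            Sigma_u=float(data["sigma_u"]),
            g=g,
        )
    except KeyError as exc:
        raise ConfigurationError(f"scalar model config is missing key {exc}") from exc


def scalar_model_to_dict(model: ScalarGenerativeModel) -> dict:
    return {
        "v_p": model.v_p,
        "sigma_p": model.Sigma_p,
        "sigma_u": model.Sigma_u,
        "g.kind": model.g.kind,
        "g.theta": model.g.theta,
        "g.h_kind": model.g.h_kind,
    }


def _matrix(entry, base: Path, *, size: int | None = None) -> np.ndarray:
    if isinstance(entry, str):
        return np.atleast_2d(np.loadtxt(base / entry, delimiter=",", ndmin=2))
    arr = np.asarray(entry, dtype=float)
    if arr.ndim == 0:
        if size is None:
            raise ConfigurationError("scalar matrix entry needs a known size")
        return float(arr) * np.eye(size)
    return np.atleast_2d(arr)


def load_hierarchy(path) -> Hierarchy:
    path = Path(path)
    data = _load_yaml(path)
    base = path.parent
    try:
        raw_layers = data["layers"]
        top = data["top"]
    except KeyError as exc:
        raise ConfigurationError(f"hierarchy config is missing key {exc}") from exc
    layers = []
    for entry in raw_layers:
        Theta = _matrix(entry["theta"], base)
        Sigma = _matrix(entry.get("sigma", 1.0), base, size=Theta.shape[0])
        h = NonlinearMap(str(entry.get("h", "identity")))
        layers.append(LayerParams(Theta=Theta, Sigma=Sigma, h=h))
    v_p_top = np.atleast_1d(np.asarray(top["v_p"], dtype=float))
    Sigma_top = _matrix(top.get("sigma", 1.0), base, size=v_p_top.size)
    return Hierarchy(layers=tuple(layers), v_p_top=v_p_top, Sigma_top=Sigma_top)
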