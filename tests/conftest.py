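import numpy as np
import pytest

from predcoding import NonlinearMap, ScalarGenerativeModel


@pytest.fixture
def size_model() -> ScalarGenerativeModel:
    """The running example: size prior N(3, 1), intensity noise 1, g(v)=v²."""
    return ScalarGenerativeModel(v_p=3.0, Sigma_p=1.0, Sigma_u=1.0, g=NonlinearMap("square"))


@pytest.fixture
def observed_intensity() -> float:
    return 2.0


@pytest.fixture
def map_root(size_model, observed_intensity) -> float:
    """Root of dF/dϕ = 0 for the running example, found independently.

    For g(v)=v² the stationarity condition (v_p−ϕ) + (u−ϕ²)·2ϕ = 0 is the
    cubic 3 + 3ϕ − 2ϕ³ = 0; its real root is the MAP value.
    """
    roots = np.roots([-2.0, 0.0, 3.0, 3.0])
    real = [r.real for r in roots if abs(r.imag) < 1e-12]
    assert len(real) == 1
    return float(real[0])


def random_spd(rng: np.random.Generator, n: int, jitter: float = 0.5) -> np.ndarray:
    """Random symmetric positive-definite matrix."""
    B = rng.normal(size=(n, n))
    return B @ B.T + jitter * np.eye(n)
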