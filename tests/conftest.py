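import numpy as np
import pytest

from twas_knockoff.simulate import SimConfig, simulate_study


def random_correlation(rng: np.random.Generator, d: int) -> np.ndarray:
    """A random well-conditioned correlation matrix."""
    A = rng.standard_normal((d, d + 5))
    S = A @ A.T / (d + 5)
    dg = np.sqrt(np.diag(S))
    return S / np.outer(dg, dg)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def small_study():
    """One mid-signal synthetic study reused across oracle tests."""
    cfg = SimConfig(n=5000, D=60, h2=0.3, eta=0.2, seed=11)
    return simulate_study(cfg, np.random.default_rng(11))
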