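import numpy as np
import pandas as pd
import pytest

from cgmtap.config import FilterConfig, prepare_kinship
from cgmtap.envs import env_covariance
from cgmtap.simulate import pinned_fixture


@pytest.fixture(scope="session")
def pinned():
    """The pinned small synthetic MET (40 varieties × 6 environments)."""
    return pinned_fixture()


@pytest.fixture(scope="session")
def pinned_kinship(pinned):
    _, K = prepare_kinship(pinned.markers, FilterConfig())
    return K


@pytest.fixture(scope="session")
def pinned_W(pinned):
    return env_covariance(pinned.omega)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_psd_kinship(n, rng, ids=None):
    from cgmtap.markers import KinshipMatrix

    A = rng.standard_normal((n, max(2 * n, 50)))
    A = A - A.mean(axis=1, keepdims=True)
    K = A @ A.T / A.shape[1]
    K = K / np.diag(K).mean()
    return KinshipMatrix(0.5 * (K + K.T), ids or [f"V{i}" for i in range(n)], 1.0)


def small_met(rng, n=12, E=4, alpha=None, sigma=0.3):
    """A tiny generic MET table for mixed-model unit tests."""
    vids = [f"V{i}" for i in range(n)]
    eids = [f"E{j}" for j in range(E)]
    hd = 100 + 8 * rng.standard_normal((n, E))
    alpha = np.zeros(E) if alpha is None else np.asarray(alpha)
    mu = rng.standard_normal(E)
    gy = (mu + alpha * (hd - hd.mean()) / hd.std()
          + rng.standard_normal((n, 1)) + sigma * rng.standard_normal((n, E)))
    rec = pd.DataFrame({
        "variety_id": np.repeat(vids, E),
        "env_id": np.tile(eids, n),
        "gy": gy.reshape(-1),
        "hd": hd.reshape(-1),
    })
    return rec
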