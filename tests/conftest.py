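import numpy as np
import pytest

from vmgcaps import vbgmm


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def three_cluster_data():
    """300 points from 3 well-separated (separation 8) unit 2-D Gaussians."""
    gen = np.random.default_rng(7)
    centers = np.array([[0.0, 0.0], [8.0, 0.0], [0.0, 8.0]])
    pts = np.vstack([gen.normal(c, 1.0, size=(100, 2)) for c in centers])
    labels = np.repeat(np.arange(3), 100)
    return pts, labels, centers


def diag_priors(D, K=2, alpha0=None, mu0=None):
    return vbgmm.PriorHyperparams(
        alpha0=(1.0 / K) if alpha0 is None else alpha0, beta0=1.0,
        mu0=np.zeros(D) if mu0 is None else mu0,
        W0=np.ones(D), nu0=float(D + 1))
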