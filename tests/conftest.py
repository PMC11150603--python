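import numpy as np
import pytest

from gammapac import GammaGlmModel, design_matrix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def draw_glm_data(rng, w, alpha, T, K=None):
    """Sample (y, theta) from the gamma GLM with the given parameters."""
    w = np.asarray(w, dtype=float)
    K = (w.size - 1) // 2 if K is None else K
    theta = rng.uniform(-np.pi, np.pi, T)
    L = design_matrix(theta, K).matrix @ w
    y = rng.gamma(alpha, np.exp(L) / alpha)
    return y, theta


@pytest.fixture
def known_k1_model():
    """A fixed K=1 model used across information-measure tests."""
    return GammaGlmModel(K=1, w=np.array([0.0, 0.5, 0.0]), alpha=4.0,
                        nll=0.0, T=0)


@pytest.fixture
def intercept_model():
    return GammaGlmModel(K=0, w=np.array([0.3]), alpha=2.5, nll=0.0, T=0)
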