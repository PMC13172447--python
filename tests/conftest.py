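import numpy as np
import pytest

import voroslice as vs


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_pattern():
    """Fifty uniform seeds in a 100-window (fast geometry checks)."""
    return vs.sample_uniform(50, 100.0, rng_seed=7)


@pytest.fixture
def tiny_pattern():
    """Twenty seeds in a 32-window (fast rendering / training checks)."""
    return vs.sample_uniform(20, 32.0, rng_seed=3)


@pytest.fixture(scope="session")
def disc64():
    """Double-precision discriminator for gradient checks (session-cached)."""
    return vs.build_discriminator(vs.DiscriminatorConfig(dtype=np.float64), rng_seed=0)


def brute_force_periodic_distance(x, y, L):
    """Explicit minimum over all 27 translates of y (independent oracle)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    best = np.inf
    for vx in (-L, 0.0, L):
        for vy in (-L, 0.0, L):
            for vz in (-L, 0.0, L):
                best = min(best, np.linalg.norm(x - (y + np.array([vx, vy, vz]))))
    return best
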