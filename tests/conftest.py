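import numpy as np
import pytest

from bagol.data import LocalizationSet


@pytest.fixture
def tiny_locs():
    """Three localizations with distinct precisions and frames."""
    return LocalizationSet(
        x=np.array([0.0, 1.5, 8.0]),
        y=np.array([0.0, 0.5, 0.2]),
        sigma_x=np.array([1.0, 1.2, 0.9]),
        sigma_y=np.array([1.1, 1.0, 0.8]),
        frame=np.array([0, 5, 9]),
        photons=np.array([1000.0, 800.0, 1200.0]),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_cluster(center, n, sigma, rng, frame_span=100):
    """Localizations scattered around one emitter with equal precisions."""
    x = rng.normal(center[0], sigma, n)
    y = rng.normal(center[1], sigma, n)
    s = np.full(n, sigma)
    frames = rng.integers(0, frame_span, n)
    return LocalizationSet(x, y, s, s.copy(), frames)


@pytest.fixture
def cluster_factory(rng):
    def factory(centers, n_per, sigma):
        sets = [make_cluster(c, n_per, sigma, rng) for c in np.atleast_2d(centers)]
        return LocalizationSet(
            np.concatenate([s.x for s in sets]),
            np.concatenate([s.y for s in sets]),
            np.concatenate([s.sigma_x for s in sets]),
            np.concatenate([s.sigma_y for s in sets]),
            np.concatenate([s.frame for s in sets]),
        )

    return factory
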