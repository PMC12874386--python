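import numpy as np
import pytest

from writhekit.chain import ChainCoordinates
from writhekit.fixtures import (
    FixtureSpec,
    canonical_curves,
    chiral_chain_ensemble,
    helical_fragment,
    two_state_polymer,
)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def helix_chain():
    """Single-frame helical Cα fragment (20 beads, negative writhe)."""
    return ChainCoordinates(helical_fragment(20)[None])


@pytest.fixture(scope="session")
def random_chains(rng):
    """Small ensemble of self-avoiding-ish random chains (5 frames, 12 beads)."""
    frames = []
    for _ in range(5):
        steps = rng.normal(size=(11, 3))
        steps /= np.linalg.norm(steps, axis=1, keepdims=True)
        frames.append(np.concatenate([[np.zeros(3)], np.cumsum(3.8 * steps, 0)]))
    return ChainCoordinates(np.array(frames))


@pytest.fixture(scope="session")
def chiral_ensemble():
    spec = FixtureSpec(n_atoms=10, n_frames=400, seed=3, handedness_bias=0.8)
    return chiral_chain_ensemble(spec)


@pytest.fixture(scope="session")
def switching_polymer():
    spec = FixtureSpec(n_atoms=10, n_frames=6000, seed=5, k12=0.02, k21=0.02)
    return two_state_polymer(spec)


def random_rotation(rng):
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q
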