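import numpy as np
import pytest

import spinereg as sr


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def phantom():
    """One deterministic single-vertebra phantom, shared across tests."""
    return sr.make_phantom(seed=7, n_points=2500)


@pytest.fixture(scope="session")
def small_pair():
    """One small cross-source registration pair, shared across tests."""
    return sr.make_pair(sr.PairSpec(seed=11, n_preop=4000, overlap_target=0.03))


def random_rigid(rng) -> sr.RigidTransform:
    from spinereg.transforms import random_rotation
    return sr.RigidTransform(random_rotation(rng), rng.uniform(-50, 50, 3))
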