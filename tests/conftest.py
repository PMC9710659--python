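import numpy as np
import pytest

from geosec.graph_builder import featurize
from geosec.synthetic_data import SegmentSpec, build_backbone


@pytest.fixture(scope="session")
def helix():
    """Ideal 10-residue alpha helix (phi=-57, psi=-47, no jitter)."""
    return build_backbone([SegmentSpec("alpha", 10)], seed=0)


@pytest.fixture(scope="session")
def mixed():
    """Helix-coil-strand chain with exact labels."""
    segments = [
        SegmentSpec("alpha", 8),
        SegmentSpec("coil", 4),
        SegmentSpec("beta", 6),
    ]
    return build_backbone(segments, seed=1)


@pytest.fixture(scope="session")
def mixed_graph(mixed):
    s, _ = mixed
    return featurize(s)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
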