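import numpy as np
import pandas as pd
import pytest

from neckconn.model import Skeleton
from neckconn.synthgen import generate, tiny_config


@pytest.fixture(scope="session")
def tiny_bundle():
    """One tiny synthetic bundle shared across tests (seed fixed)."""
    return generate(tiny_config(seed=1))


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def make_skeleton(xyz, parents):
    """Build a Skeleton from coordinates and 0-based parent indices (-1 root)."""
    xyz = np.asarray(xyz, float)
    parents = np.asarray(parents, int)
    nodes = pd.DataFrame(
        {
            "node_id": np.arange(1, len(xyz) + 1),
            "structure": 0,
            "x": xyz[:, 0],
            "y": xyz[:, 1],
            "z": xyz[:, 2],
            "radius": -1.0,
            "parent_id": np.where(parents < 0, -1, parents + 1),
        }
    )
    return Skeleton(nodes)


@pytest.fixture()
def chain_skeleton():
    """10 nodes equally spaced along x, 1 um apart."""
    xyz = np.column_stack([np.arange(10) * 1000.0, np.zeros(10), np.zeros(10)])
    return make_skeleton(xyz, np.arange(-1, 9))
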