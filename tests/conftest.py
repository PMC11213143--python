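import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

import prospector as pr


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def path3():
    """Path graph 0-1-2."""
    return pr.build_sequence_graph(3, 1)


@pytest.fixture
def path3_sprite(path3):
    """The worked three-vertex example: concepts [1, 1, 2] on a path."""
    return pr.Sprite(topology=path3, concepts=[1, 1, 2], K=3)


@pytest.fixture(scope="session")
def small_study():
    """A small but non-trivial fitted study reused across tests.

    30 data/class on a 12x12 grid, easy signal; fits the reference
    fold-change head once per session.
    """
    cfg = pr.SynthConfig(
        n_class0=30, n_class1=30, seed=77,
        graph_params={"rows": 12, "cols": 12, "connectivity": 8},
    )
    train = [d.graph for d in pr.generate_dataset(cfg)]
    fitted = pr.fit_prospector(train, K=5, r=1, seed=77, pool_size=3000)
    test_cfg = pr.SynthConfig(
        n_class0=0, n_class1=10, seed=78,
        graph_params={"rows": 12, "cols": 12, "connectivity": 8},
    )
    test = [d.graph for d in pr.generate_dataset(test_cfg)]
    return {"cfg": cfg, "train": train, "fitted": fitted, "test": test}
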