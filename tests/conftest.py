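import numpy as np
import pytest

from qwlink import Network, karate_fixture


def make_random_network(rng: np.random.Generator, n: int, p: float) -> Network:
    """Small Erdős–Rényi instance built directly (independent of qwlink.datasets)."""
    edges = {
        (j, k)
        for j in range(n)
        for k in range(j + 1, n)
        if rng.random() < p
    }
    return Network(node_labels=list(range(n)), edges=edges)


@pytest.fixture
def path3() -> Network:
    """Path graph 0–1–2: the worked example used throughout."""
    return Network(node_labels=[0, 1, 2], edges={(0, 1), (1, 2)})


@pytest.fixture
def triangle() -> Network:
    return Network(node_labels=[0, 1, 2], edges={(0, 1), (1, 2), (0, 2)})


@pytest.fixture(scope="session")
def karate() -> Network:
    return karate_fixture()
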