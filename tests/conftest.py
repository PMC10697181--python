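import numpy as np
import pytest

from wconn.core import Parcellation, WeightedConnectome
from wconn.synth import GeneratorConfig, simulate_cohort


@pytest.fixture(scope="session")
def cohort():
    """One default-scale synthetic cohort shared across the suite."""
    return simulate_cohort(GeneratorConfig(seed=1))


@pytest.fixture(scope="session")
def cohort_cfg():
    return GeneratorConfig(seed=1)


@pytest.fixture
def toy_parcellation():
    """Four nodes, two modules, unit-ish volumes."""
    return Parcellation(
        node_ids=["a", "b", "c", "d"],
        labels=["A", "B", "C", "D"],
        module=np.array(["VIS", "VIS", "DMN", "DMN"], dtype=object),
        volume=np.array([1.0, 2.0, 1.0, 4.0]),
        coords=np.array([[0, 0, 0], [10, 0, 0], [0, 10, 0], [10, 10, 0]], dtype=float),
    )


def random_weighted_net(rng, n, density=0.5, connected=True):
    """Small random weighted graph for oracle comparisons."""
    while True:
        iu, ju = np.triu_indices(n, k=1)
        present = rng.random(len(iu)) < density
        w = np.zeros((n, n))
        vals = rng.uniform(0.1, 2.0, size=int(present.sum()))
        w[iu[present], ju[present]] = vals
        w += w.T
        net = WeightedConnectome("COMMIT", "test", w)
        if not connected:
            return net
        # simple BFS connectivity check
        adj = w != 0
        seen = {0}
        stack = [0]
        while stack:
            u = stack.pop()
            for v in np.flatnonzero(adj[u]):
                if v not in seen:
                    seen.add(int(v))
                    stack.append(int(v))
        if len(seen) == n and present.sum() >= 2:
            return net
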