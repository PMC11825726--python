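import numpy as np
import pytest

from lccnet import (
    GroundTruthNetwork,
    HopfParams,
    generate_network,
    simulate_hopf,
)


@pytest.fixture(scope="session")
def short_hopf_run():
    """A small coupled Hopf run shared by estimator tests (6 nodes, 2 s)."""
    net = generate_network(6, 0.15, seed=5)
    params = HopfParams(n_steps=20_000)
    ts = simulate_hopf(params, net, seed=5)
    return net, params, ts


def make_network(weights: np.ndarray, distances: np.ndarray | None = None,
                 p: float = 0.0, seed: int = 0) -> GroundTruthNetwork:
    """Hand-built network helper for constructed-topology tests."""
    weights = np.asarray(weights, dtype=float)
    n = weights.shape[0]
    if distances is None:
        distances = np.where(weights != 0, 5.0, 0.0)
    return GroundTruthNetwork(
        weights=weights,
        distances_mm=np.asarray(distances, dtype=float),
        n_nodes=n,
        p=p,
        seed=seed,
    )
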