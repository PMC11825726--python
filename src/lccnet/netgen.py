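"""Ground-truth directed random networks with distance-based transmission delays.

Networks are directed Erdos-Renyi digraphs: every ordered off-diagonal pair
(i, j) independently receives a connection with probability ``p``, so the
expected edge count is ``p * N * (N - 1)`` and reciprocal pairs occur with
probability ``p**2``.  Wherever a connection exists, a Euclidean distance is
drawn uniformly on (0, d_max] mm; together with a constant signal speed this
yields the transmission-delay matrix consumed by the Hopf simulator.

Orientation convention (used consistently by every module): ``weights[i, j]``
is the strength of the directed connection *from node j into node i*, i.e.
row i collects the inputs of node i.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "GroundTruthNetwork",
    "generate_gt_connectivity",
    "generate_distances",
    "generate_network",
    "delays_from_distances",
]

#: sub-stream indices spawned from the master seed
_STREAM_TOPOLOGY, _STREAM_WEIGHTS, _STREAM_DISTANCES = 0, 1, 2


@dataclass
class GroundTruthNetwork:
    """A directed weighted ground-truth network plus pairwise distances.

    Attributes
    ----------
    weights
        Square array; ``weights[i, j]`` is the strength of the connection
        j -> i.  Diagonal is zero, entries are non-negative.
    distances_mm
        Square array of distances in millimetres; zero wherever ``weights``
        is zero, positive elsewhere.
    n_nodes, p, seed
        Size, connection probability and master seed used for generation.
    """

    weights: np.ndarray
    distances_mm: np.ndarray
    n_nodes: int
    p: float
    seed: int

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.distances_mm = np.asarray(self.distances_mm, dtype=float)
        n = self.n_nodes
        if self.weights.shape != (n, n) or self.distances_mm.shape != (n, n):
            raise ValueError(
                f"weights/distances must be {n}x{n}, got "
                f"{self.weights.shape} and {self.distances_mm.shape}"
            )

    @property
    def n_edges(self) -> int:
        """Realized number of directed connections."""
        return int(np.count_nonzero(self.weights))


def _substream(seed: int, index: int) -> np.random.Generator:
    children = np.random.SeedSequence(seed).spawn(3)
    return np.random.default_rng(children[index])


def generate_gt_connectivity(
    n_nodes: int,
    p: float,
    weight_scheme: str = "uniform01",
    seed: int = 0,
) -> GroundTruthNetwork:
    """Generate a directed random ground-truth connectivity matrix.

    Each ordered off-diagonal pair independently receives a connection with
    probability ``p``.  Under ``weight_scheme='uniform01'`` nonzero weights
    are drawn uniformly on (0, 1]; under ``'binary'`` they are 1.  Distances
    are left at zero; fill them with :func:`generate_distances`.
    """
    if not isinstance(n_nodes, (int, np.integer)) or n_nodes < 2:
        raise ValueError(f"n_nodes must be an integer >= 2, got {n_nodes!r}")
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p must lie in [0, 1], got {p!r}")
    if weight_scheme not in ("binary", "uniform01"):
        raise ValueError(f"unknown weight_scheme {weight_scheme!r}")

    rng_topo = _substream(seed, _STREAM_TOPOLOGY)
    rng_w = _substream(seed, _STREAM_WEIGHTS)

    adj = rng_topo.random((n_nodes, n_nodes)) < p
    np.fill_diagonal(adj, False)
    if weight_scheme == "uniform01":
        # 1 - U[0,1) lies in (0, 1] so no connection gets weight exactly 0
        weights = np.where(adj, 1.0 - rng_w.random((n_nodes, n_nodes)), 0.0)
    else:
        weights = adj.astype(float)

    return GroundTruthNetwork(
        weights=weights,
        distances_mm=np.zeros((n_nodes, n_nodes)),
        n_nodes=int(n_nodes),
        p=float(p),
        seed=int(seed),
    )


def generate_distances(
    net: GroundTruthNetwork,
    d_max_mm: float = 10.0,
    seed: int | None = None,
) -> GroundTruthNetwork:
    """Fill pairwise distances, Uniform(0, d_max_mm] at every connection.

    Distances for a reciprocal pair (i, j) and (j, i) are drawn
    independently.  With ``seed=None`` the distance sub-stream of the
    network's own master seed is used, so ``generate_network`` is
    reproducible from a single seed.
    """
    if d_max_mm <= 0:
        raise ValueError(f"d_max_mm must be positive, got {d_max_mm!r}")
    rng = _substream(net.seed if seed is None else seed, _STREAM_DISTANCES)
    mask = net.weights != 0
    dist = np.where(mask, d_max_mm * (1.0 - rng.random(net.weights.shape)), 0.0)
    return replace(net, distances_mm=dist)


def generate_network(
    n_nodes: int,
    p: float,
    weight_scheme: str = "uniform01",
    d_max_mm: float = 10.0,
    seed: int = 0,
) -> GroundTruthNetwork:
    """Convenience: connectivity plus distances from one master seed."""
    net = generate_gt_connectivity(n_nodes, p, weight_scheme=weight_scheme, seed=seed)
    return generate_distances(net, d_max_mm=d_max_mm)


def delays_from_distances(
    net: GroundTruthNetwork, v_signal: float = 1.0
) -> np.ndarray:
    """Transmission delays in ms: ``tau_ij = distance_ij / v_signal``.

    At the defaults (distances U(0,10) mm, v_signal = 1 mm/ms) delays are
    uniformly distributed on (0, 10] ms.
    """
    if v_signal <= 0:
        raise ValueError(f"v_signal must be positive, got {v_signal!r}")
    return net.distances_mm / v_signal
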