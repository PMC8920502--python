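"""Self-organizing-map discretization and the Markov transition network.

A rectangular SOM (default 12 x 12) vector-quantizes the recorded cell
states into micro-clusters; consecutive-frame hops between best-matching
units define a row-stochastic transition matrix (self-transitions included,
probabilities below a prune threshold reset to zero without renormalizing),
and edges are weighted by -log p so Dijkstra shortest paths between the
epithelial and mesenchymal neuron communities trace the most probable
transition corridors.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from numba import njit

from .io import TrajectoryEnsemble

__all__ = [
    "SelfOrganizingMap",
    "TransitionNetwork",
    "PathSummary",
    "train_som",
    "build_transition_network",
    "shortest_transition_paths",
]

logger = logging.getLogger(__name__)


@njit(cache=True)
def _som_train(data, codebook, order, rows, cols, radius, std, lr0, lr1):
    n_samples = order.shape[0]
    n_units = codebook.shape[0]
    for t in range(n_samples):
        x = data[order[t]]
        lr = lr0 + (lr1 - lr0) * t / max(n_samples - 1, 1)
        # best-matching unit, ties to the lowest linear index
        best = 0
        best_d = 1e300
        for u in range(n_units):
            dist = 0.0
            for j in range(x.shape[0]):
                diff = codebook[u, j] - x[j]
                dist += diff * diff
            if dist < best_d:
                best_d = dist
                best = u
        br, bc = best // cols, best % cols
        for u in range(n_units):
            gr, gc = u // cols, u % cols
            gd2 = (gr - br) ** 2 + (gc - bc) ** 2
            if gd2 > radius * radius:
                continue
            h = lr * np.exp(-gd2 / (2.0 * std * std))
            for j in range(x.shape[0]):
                codebook[u, j] += h * (x[j] - codebook[u, j])


@dataclass
class SelfOrganizingMap:
    """A trained SOM: codebook of shape (rows*cols, d), row-major grid."""

    grid_shape: tuple[int, int]
    codebook: np.ndarray
    metadata: dict = field(default_factory=dict)

    @property
    def n_units(self) -> int:
        return self.grid_shape[0] * self.grid_shape[1]

    def bmu(self, points: np.ndarray) -> np.ndarray:
        """Best-matching unit per point (argmin distance, first index wins)."""
        points = np.atleast_2d(np.asarray(points, float))
        d2 = np.sum((points[:, None, :] - self.codebook[None]) ** 2, axis=2)
        return np.argmin(d2, axis=1)


def train_som(
    points: np.ndarray,
    grid: tuple[int, int] = (12, 12),
    epochs: int = 50,
    radius: float = 1.0,
    std: float = 1.0,
    seed: int = 0,
    learning_rate: tuple[float, float] = (0.5, 0.01),
) -> SelfOrganizingMap:
    """Train an online SOM on a point cloud.

    The codebook is initialized from a random sample of the data and updated
    sample-by-sample with a Gaussian grid neighborhood of standard deviation
    ``std`` truncated at ``radius``; the learning rate decays linearly over
    all presentations.  Fixed seed and input order give identical models.
    """
    points = np.atleast_2d(np.asarray(points, float))
    n, d = points.shape
    if n == 0:
        raise ValueError("cannot train a SOM on empty data")
    n_units = grid[0] * grid[1]
    if n < n_units:
        warnings.warn(
            f"only {n} points for {n_units} neurons; codebook will be sparse",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    init_idx = rng.choice(n, size=n_units, replace=n < n_units)
    codebook = points[init_idx].copy()
    if epochs > 0:
        order = np.concatenate([rng.permutation(n) for _ in range(epochs)])
        _som_train(
            np.ascontiguousarray(points),
            codebook,
            order,
            grid[0],
            grid[1],
            float(radius),
            float(std),
            float(learning_rate[0]),
            float(learning_rate[1]),
        )
    meta = dict(
        epochs=epochs, radius=radius, std=std, seed=seed,
        learning_rate=learning_rate, n_points=n,
    )
    return SelfOrganizingMap(tuple(grid), codebook, meta)


@dataclass
class TransitionNetwork:
    """Pruned row-stochastic transition matrix over SOM micro-states.

    ``P[i, j]`` is the one-frame transition probability (self-transitions
    included); pruned entries are exactly zero and rows are not renormalized
    afterwards unless requested.  ``zero_rows`` lists states with no
    outgoing hops.
    """

    P: np.ndarray
    zero_rows: list[int] = field(default_factory=list)
    E_states: list[int] = field(default_factory=list)
    M_states: list[int] = field(default_factory=list)

    @property
    def n_states(self) -> int:
        return self.P.shape[0]

    def weights(self) -> dict[tuple[int, int], float]:
        """Edge weights -log p over surviving edges only."""
        ii, jj = np.nonzero(self.P)
        return {(int(i), int(j)): float(-np.log(self.P[i, j])) for i, j in zip(ii, jj)}

    def to_graph(self) -> nx.DiGraph:
        G = nx.DiGraph()
        G.add_nodes_from(range(self.n_states))
        for (i, j), w in self.weights().items():
            G.add_edge(i, j, weight=w, probability=float(self.P[i, j]))
        return G

    def to_edge_table(self):
        import pandas as pd

        rows = [
            (i, j, float(self.P[i, j]), w) for (i, j), w in sorted(self.weights().items())
        ]
        return pd.DataFrame(rows, columns=["source", "target", "probability", "weight"])


def build_transition_network(
    ensemble: TrajectoryEnsemble,
    som: SelfOrganizingMap,
    prune: float = 0.01,
    renormalize: bool = False,
) -> TransitionNetwork:
    """Count consecutive-frame BMU hops into a pruned transition matrix."""
    n = som.n_units
    counts = np.zeros((n, n))
    for tr in ensemble:
        states = som.bmu(tr.X)
        np.add.at(counts, (states[:-1], states[1:]), 1.0)
    out = counts.sum(axis=1)
    zero_rows = [int(i) for i in np.flatnonzero(out == 0)]
    if zero_rows:
        logger.info("%d states have no outgoing hops", len(zero_rows))
    P = np.divide(counts, out[:, None], out=np.zeros_like(counts), where=out[:, None] > 0)
    P[P < prune] = 0.0
    if renormalize:
        rowsum = P.sum(axis=1)
        P = np.divide(P, rowsum[:, None], out=P, where=rowsum[:, None] > 0)
    return TransitionNetwork(P, zero_rows)


@dataclass
class PathSummary:
    """Shortest E->M paths plus node and edge usage tallies."""

    paths: list[list[int]]
    node_counts: np.ndarray
    edge_counts: dict[tuple[int, int], int]

    @property
    def n_paths(self) -> int:
        return len(self.paths)


def shortest_transition_paths(
    net: TransitionNetwork,
    som: SelfOrganizingMap,
    E_center: np.ndarray,
    M_center: np.ndarray,
    radius: float = 0.7,
) -> PathSummary:
    """Dijkstra shortest path for every (E-neuron, M-neuron) pair.

    Communities are the neurons whose codebook vector lies within ``radius``
    of the respective center.  Equal-weight ties resolve to the
    lexicographically smallest node sequence; unreachable pairs are skipped
    with a log entry.
    """
    E_center = np.asarray(E_center, float)
    M_center = np.asarray(M_center, float)
    dE = np.linalg.norm(som.codebook - E_center, axis=1)
    dM = np.linalg.norm(som.codebook - M_center, axis=1)
    E_states = [int(i) for i in np.flatnonzero(dE <= radius)]
    M_states = [int(i) for i in np.flatnonzero(dM <= radius)]
    if not E_states or not M_states:
        raise ValueError(
            f"empty community: {len(E_states)} E neurons, {len(M_states)} M neurons "
            f"within radius {radius}"
        )
    net.E_states, net.M_states = E_states, M_states

    G = net.to_graph()
    paths = []
    for e in E_states:
        for m in M_states:
            try:
                candidates = list(nx.all_shortest_paths(G, e, m, weight="weight"))
            except nx.NetworkXNoPath:
                logger.info("no path from neuron %d to neuron %d", e, m)
                continue
            paths.append(min(candidates))
    node_counts = np.zeros(net.n_states, dtype=int)
    edge_counts: dict[tuple[int, int], int] = {}
    for p in paths:
        for u in p:
            node_counts[u] += 1
        for u, v in zip(p[:-1], p[1:]):
            edge_counts[(u, v)] = edge_counts.get((u, v), 0) + 1
    return PathSummary(paths, node_counts, edge_counts)
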