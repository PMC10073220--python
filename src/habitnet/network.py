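"""Generate the behavioral network from a Q-matrix and measure its structure.

Each response is a node.  For every node i, ``edges_per_node`` distinct
targets are sampled without replacement from a softmax over beta_n * Q[i, j]
(j != i, beta_n = 50 by default), and the union over nodes forms an
undirected simple graph — so every node has at least ``edges_per_node``
edges by construction and self-loops never occur.

The default softmax uses the positive sign, which concentrates edges on
high-Q targets; the negative-sign variant (which cannot form a hub) is kept
behind ``SoftmaxSign.AS_PRINTED_NEGATIVE`` for auditability.

Hypothetical Q-matrices for the structure sweep expand a Q-vector
(q_operant, q_other, ..., q_other) to a matrix.  The default expansion is
row replication, Q[i, j] = q_j; the literal outer product Q[i, j] = q_i*q_j
is available but produces off-row differences of order q_other * q_operant,
far too weak to concentrate edges at beta_n = 50.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import networkx as nx
import numpy as np

from .qlearn import QMatrix

__all__ = [
    "SoftmaxSign",
    "NetworkParams",
    "BehavioralNetwork",
    "NetworkMetrics",
    "edge_probabilities",
    "build_network",
    "hypothetical_q",
    "network_metrics",
]


class SoftmaxSign(str, Enum):
    POSITIVE = "POSITIVE"
    AS_PRINTED_NEGATIVE = "AS_PRINTED_NEGATIVE"


@dataclass(frozen=True)
class NetworkParams:
    beta_n: float = 50.0
    edges_per_node: int = 2
    sign: SoftmaxSign = SoftmaxSign.POSITIVE

    def __post_init__(self) -> None:
        if self.beta_n <= 0:
            raise ValueError("beta_n must be > 0")
        if self.edges_per_node < 1:
            raise ValueError("edges_per_node must be >= 1")


@dataclass
class BehavioralNetwork:
    """Undirected simple graph over responses, with operant node labels."""

    graph: nx.Graph
    operant_ids: tuple[int, ...] = (0,)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    def min_degree(self) -> int:
        return min(d for _, d in self.graph.degree())

    def to_edgelist(self, path) -> None:
        with open(path, "w") as fh:
            for u, v in sorted(self.graph.edges()):
                fh.write(f"{u} {v}\n")


def edge_probabilities(
    Q: QMatrix,
    i: int,
    beta_n: float = 50.0,
    sign: SoftmaxSign = SoftmaxSign.POSITIVE,
) -> np.ndarray:
    """Edge-attachment probabilities from node i over targets j != i.

    Returns a length-N vector with p[i] = 0 that sums to 1, computed as a
    max-shifted softmax of sign * beta_n * Q[i, j] excluding the diagonal
    (the traversal model cannot use self-transitions).
    """
    n = Q.n_responses
    if n < 3:
        raise ValueError("need at least 3 nodes to place 2 edges without self-loops")
    s = 1.0 if sign is SoftmaxSign.POSITIVE else -1.0
    logits = s * beta_n * Q.values[i].astype(float)
    mask = np.ones(n, dtype=bool)
    mask[i] = False
    z = np.zeros(n)
    z[mask] = np.exp(logits[mask] - logits[mask].max())
    return z / z.sum()


def build_network(
    Q: QMatrix,
    params: NetworkParams,
    operant_ids: tuple[int, ...],
    rng: np.random.Generator,
) -> BehavioralNetwork:
    """Sample ``edges_per_node`` targets per node; union as undirected graph."""
    n = Q.n_responses
    if n <= params.edges_per_node:
        raise ValueError("n_responses must exceed edges_per_node")
    g = nx.Graph()
    g.add_nodes_from(range(n))
    for i in range(n):
        p = edge_probabilities(Q, i, params.beta_n, params.sign)
        targets = rng.choice(n, size=params.edges_per_node, replace=False, p=p)
        g.add_edges_from((i, int(j)) for j in targets)
    return BehavioralNetwork(graph=g, operant_ids=tuple(operant_ids))


def hypothetical_q(
    q_operant: float,
    q_other: float = 0.001,
    n_responses: int = 50,
    expansion: str = "replicate",
) -> QMatrix:
    """Q-matrix from the vector (q_operant, q_other, ..., q_other).

    ``expansion="replicate"`` (default) repeats the vector as every row,
    Q[i, j] = q_j; ``expansion="outer"`` is the literal outer product
    Q[i, j] = q_i * q_j.
    """
    if not 0.0 <= q_operant <= 1.0 or not 0.0 <= q_other <= 1.0:
        raise ValueError("q values must be in [0, 1]")
    vec = np.full(n_responses, q_other)
    vec[0] = q_operant
    if expansion == "replicate":
        values = np.tile(vec, (n_responses, 1))
    elif expansion == "outer":
        values = np.outer(vec, vec)
    else:
        raise ValueError(f"unknown expansion {expansion!r}")
    return QMatrix(values)


@dataclass(frozen=True)
class NetworkMetrics:
    degree: int
    betweenness: float
    avg_path_length: float
    connected: bool


def network_metrics(net: BehavioralNetwork, operant: int) -> NetworkMetrics:
    """Operant degree, normalized betweenness, and mean shortest-path length.

    On a disconnected graph the average path length is computed on the
    largest connected component and the result is flagged.
    """
    g = net.graph
    if g.number_of_nodes() == 0:
        raise ValueError("empty graph")
    degree = int(g.degree(operant))
    betweenness = float(nx.betweenness_centrality(g, normalized=True)[operant])
    connected = nx.is_connected(g)
    component = g if connected else g.subgraph(max(nx.connected_components(g), key=len))
    if component.number_of_nodes() < 2:
        apl = 0.0
    else:
        apl = float(nx.average_shortest_path_length(component))
    return NetworkMetrics(degree, betweenness, apl, connected)
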