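"""Graph channel: stacked graph-isomorphism-network (GIN) layers.

Each layer updates node v as MLP((1 + eps) * h_v + sum of neighbour
features), followed by node-level batch normalisation and ReLU.  The sum
aggregator makes the network as discriminative as the 1-Weisfeiler-Lehman
test.  The graph-level representation concatenates per-layer sum readouts
and projects them through a linear layer with ReLU and dropout; the last
layer's node features are retained for cross-attention and for
gradient-based atom attribution.

Graphs are processed as stacked node matrices with integer segment ids, so
a batch of disjoint graphs is exactly equivalent to encoding them one at a
time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from . import autograd as ag
from .autograd import Tensor
from .nn import BatchNorm1d, Dropout, Linear, Module

logger = logging.getLogger(__name__)


def neighbor_sum(x: Tensor, edge_index: np.ndarray, num_nodes: int) -> Tensor:
    """Sum of neighbour feature rows for every node (isolated nodes get zero)."""
    edge_index = np.asarray(edge_index, dtype=np.int64)
    if edge_index.size == 0:
        return Tensor(np.zeros((num_nodes, x.shape[1])))
    src, dst = edge_index
    return ag.segment_sum(ag.take(x, src), dst, num_nodes)


def gin_aggregate(x: Tensor, edge_index: np.ndarray, eps: Tensor, mlp) -> Tensor:
    """MLP((1 + eps) * own features + neighbour sum)."""
    n = x.shape[0]
    agg = (Tensor(1.0) + eps) * x + neighbor_sum(x, edge_index, n)
    return mlp(agg)


def sum_readout(node_features: Tensor, graph_ids: np.ndarray, num_graphs: int) -> Tensor:
    """Per-graph sum of node vectors -> (num_graphs, C)."""
    graph_ids = np.asarray(graph_ids, dtype=np.int64)
    if graph_ids.shape[0] != node_features.shape[0]:
        raise ValueError("every node needs exactly one graph assignment")
    if graph_ids.size and (graph_ids.min() < 0 or graph_ids.max() >= num_graphs):
        raise ValueError("graph id out of range (orphan node)")
    return ag.segment_sum(node_features, graph_ids, num_graphs)


class GINMLP(Module):
    """Two-layer perceptron used inside each GIN aggregation."""

    def __init__(self, in_dim: int, hidden: int, out_dim: int, rng: np.random.Generator):
        super().__init__()
        self.fc1 = Linear(in_dim, hidden, rng)
        self.fc2 = Linear(hidden, out_dim, rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.fc2(ag.relu(self.fc1(x)))


class GINLayer(Module):
    def __init__(self, in_dim: int, hidden: int, out_dim: int, rng: np.random.Generator):
        super().__init__()
        self.eps = Tensor(0.0, requires_grad=True)  # learnable, initialised at 0
        self.mlp = GINMLP(in_dim, hidden, out_dim, rng)
        self.bn = BatchNorm1d(out_dim)

    def forward(self, x: Tensor, edge_index: np.ndarray) -> Tensor:
        h = gin_aggregate(x, edge_index, self.eps, self.mlp)
        return ag.relu(self.bn(h))


@dataclass
class GraphRepresentation:
    per_layer: list  # node feature Tensors, one per GIN layer
    graph_vector: Tensor  # (num_graphs, out_dim)

    @property
    def node_features_last(self) -> Tensor:
        """Last-layer node features F, the attribution target."""
        return self.per_layer[-1]


class GraphEncoder(Module):
    """Stack of GIN layers with concatenated per-layer sum readouts."""

    def __init__(self, in_dim: int, hidden: int, depth: int, out_dim: int,
                 dropout: float, rng: np.random.Generator):
        super().__init__()
        if not 3 <= depth <= 7:
            logger.warning("GIN depth %d is outside the studied range [3, 7]", depth)
        if depth < 1:
            raise ValueError("depth must be >= 1")
        self.layers = [
            GINLayer(in_dim if k == 0 else hidden, hidden, hidden, rng)
            for k in range(depth)
        ]
        self.project = Linear(depth * hidden, out_dim, rng)
        self.dropout = Dropout(dropout, rng)
        self.out_dim = out_dim
        self.hidden = hidden

    def forward(self, node_features, edge_index: np.ndarray,
                graph_ids: np.ndarray, num_graphs: int) -> GraphRepresentation:
        if not isinstance(node_features, Tensor):
            node_features = Tensor(node_features)
        if node_features.shape[0] == 0:
            raise ValueError("cannot encode an empty graph")
        h = node_features
        per_layer = []
        readouts = []
        for layer in self.layers:
            h = layer(h, edge_index)
            per_layer.append(h)
            readouts.append(sum_readout(h, graph_ids, num_graphs))
        concat = ag.concat(readouts, axis=1)
        vec = self.dropout(ag.relu(self.project(concat)))
        return GraphRepresentation(per_layer=per_layer, graph_vector=vec)
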