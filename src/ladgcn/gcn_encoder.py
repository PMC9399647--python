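"""Graph-convolutional encoder of the cell graph.

Each layer propagates node features through the self-looped
symmetrically normalized adjacency, H <- sigma(A_norm H W); a
permutation-invariant readout (mean by default) followed by a linear
map yields the fixed-width cell-graph embedding h_c.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np

from . import autodiff as ad
from .cell_graph import CellGraph

__all__ = ["GCNConfig", "gcn_layer", "GCNEncoder"]

logger = logging.getLogger(__name__)

_ACTIVATIONS = {"relu": ad.relu, "tanh": ad.tanh, "identity": lambda t: t}
_NP_ACTIVATIONS = {
    "relu": lambda x: np.maximum(x, 0.0),
    "tanh": np.tanh,
    "identity": lambda x: x,
}


@dataclasses.dataclass(frozen=True)
class GCNConfig:
    """layer_widths[0] is the input feature width; the rest are hidden widths."""

    layer_widths: tuple[int, ...] = (24, 32, 32)
    activation: str = "relu"
    readout: str = "mean"
    embed_dim: int = 32
    seed: int = 0

    def __post_init__(self):
        if len(self.layer_widths) < 2 or any(w < 1 for w in self.layer_widths):
            raise ValueError("need >= 1 layer with positive widths")
        if self.readout not in ("mean", "sum", "max"):
            raise ValueError("readout must be mean, sum or max")


def gcn_layer(H: np.ndarray, a_norm: np.ndarray, W: np.ndarray, activation: str = "relu") -> np.ndarray:
    """One propagation step sigma(A_norm @ H @ W) on plain arrays."""
    H = np.asarray(H, dtype=np.float64)
    a_norm = np.asarray(a_norm, dtype=np.float64)
    W = np.asarray(W, dtype=np.float64)
    if a_norm.shape != (H.shape[0], H.shape[0]) or W.shape[0] != H.shape[1]:
        raise ValueError("shape mismatch between H, A_norm and W")
    return _NP_ACTIVATIONS[activation](a_norm @ H @ W)


class GCNEncoder:
    """Stacked graph convolutions + readout producing h_c."""

    def __init__(self, config: GCNConfig | None = None):
        self.config = config or GCNConfig()
        rng = np.random.default_rng(self.config.seed)
        widths = self.config.layer_widths
        self.weights = [
            ad.parameter(ad.glorot_uniform(rng, (widths[i], widths[i + 1])))
            for i in range(len(widths) - 1)
        ]
        self.w_out = ad.parameter(ad.glorot_uniform(rng, (widths[-1], self.config.embed_dim)))
        self.b_out = ad.parameter(np.zeros(self.config.embed_dim))

    @property
    def parameters(self) -> list[ad.Tensor]:
        return [*self.weights, self.w_out, self.b_out]

    def encode(self, graph_or_anorm, node_features: np.ndarray | None = None) -> ad.Tensor:
        """Embed one graph into a (1, embed_dim) tensor.

        Accepts a CellGraph or an (a_norm, node_features) pair.  An empty
        graph (m = 0) maps to the zero embedding so nucleus-free tiles do
        not crash the pipeline.
        """
        if isinstance(graph_or_anorm, CellGraph):
            a_norm, feats = graph_or_anorm.a_norm, graph_or_anorm.node_features
        else:
            a_norm, feats = graph_or_anorm, node_features
        feats = np.asarray(feats, dtype=np.float64)
        if feats.shape[0] == 0:
            logger.warning("empty cell graph: returning zero embedding")
            return ad.constant(np.zeros((1, self.config.embed_dim)))
        act = _ACTIVATIONS[self.config.activation]
        h = ad.constant(feats)
        a_t = ad.constant(np.asarray(a_norm, dtype=np.float64))
        for w in self.weights:
            h = act(ad.matmul(ad.matmul(a_t, h), w))
        if self.config.readout == "mean":
            pooled = ad.mean(h, axis=0, keepdims=True)
        elif self.config.readout == "sum":
            pooled = ad.tsum(h, axis=0, keepdims=True)
        else:
            pooled = ad.tmax(h, axis=0, keepdims=True)
        return ad.linear(pooled, self.w_out, self.b_out)

    def encode_batch(self, graphs: list) -> ad.Tensor:
        """Stack per-graph embeddings into a (B, embed_dim) tensor."""
        return ad.concat([self.encode(g) for g in graphs], axis=0)
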