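"""Gated Kronecker-product fusion of the cell-graph and semantic embeddings.

Each branch embedding h_m (m in {c, s}) is projected through
ReLU(W_m h_m) to a common width; a gating attention score
z_m = sigmoid(W_{cs->m} [h_c, h_s]) scales the projection elementwise;
the gated vectors are fused by the outer (Kronecker) product and a
single fully connected layer produces class logits trained with the
standard cross-entropy loss.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from . import autodiff as ad

__all__ = ["FusionConfig", "FusionHead", "kronecker_fuse", "cross_entropy"]


@dataclasses.dataclass(frozen=True)
class FusionConfig:
    proj_dim: int = 32
    n_classes: int = 3
    append_one: bool = False  # append-1 bilinear variant preserving unimodal terms
    seed: int = 0

    def __post_init__(self):
        if self.proj_dim < 1 or self.n_classes < 2:
            raise ValueError("need proj_dim >= 1 and n_classes >= 2")


def kronecker_fuse(h_c, h_s):
    """Outer-product fusion, flattened row-major.

    1-D NumPy vectors give a 1-D vector of length p*q; batched autodiff
    tensors of shape (B, p) and (B, q) give a (B, p*q) tensor.
    """
    if isinstance(h_c, ad.Tensor) or isinstance(h_s, ad.Tensor):
        return ad.outer_rows(h_c, h_s)
    h_c = np.asarray(h_c, dtype=np.float64)
    h_s = np.asarray(h_s, dtype=np.float64)
    if h_c.ndim == 1 and h_s.ndim == 1:
        return np.outer(h_c, h_s).reshape(-1)
    return (h_c[:, :, None] * h_s[:, None, :]).reshape(h_c.shape[0], -1)


def cross_entropy(batch_probs: np.ndarray, batch_labels: np.ndarray) -> float:
    """Batch-mean cross-entropy -log q[true class], clamped at q >= 1e-12."""
    probs = np.atleast_2d(np.asarray(batch_probs, dtype=np.float64))
    labels = np.atleast_1d(np.asarray(batch_labels))
    if labels.ndim == 2:  # one-hot
        labels = labels.argmax(axis=1)
    labels = labels.astype(np.int64)
    if labels.min() < 0 or labels.max() >= probs.shape[1]:
        raise ValueError("label outside class range")
    q = np.clip(probs[np.arange(probs.shape[0]), labels], 1e-12, None)
    return float(-np.log(q).mean())


class FusionHead:
    """Projection + gating + Kronecker fusion + linear classifier."""

    def __init__(self, dim_c: int, dim_s: int, config: FusionConfig | None = None):
        self.config = config or FusionConfig()
        self.dim_c, self.dim_s = int(dim_c), int(dim_s)
        p = self.config.proj_dim
        rng = np.random.default_rng(self.config.seed)
        cat = self.dim_c + self.dim_s
        self.w_c = ad.parameter(ad.glorot_uniform(rng, (self.dim_c, p)))
        self.b_c = ad.parameter(np.zeros(p))
        self.w_s = ad.parameter(ad.glorot_uniform(rng, (self.dim_s, p)))
        self.b_s = ad.parameter(np.zeros(p))
        self.w_gate_c = ad.parameter(ad.glorot_uniform(rng, (cat, p)))
        self.b_gate_c = ad.parameter(np.zeros(p))
        self.w_gate_s = ad.parameter(ad.glorot_uniform(rng, (cat, p)))
        self.b_gate_s = ad.parameter(np.zeros(p))
        fused_dim = (p + 1) ** 2 if self.config.append_one else p * p
        self.w_cls = ad.parameter(ad.glorot_uniform(rng, (fused_dim, self.config.n_classes)))
        self.b_cls = ad.parameter(np.zeros(self.config.n_classes))

    @property
    def parameters(self) -> list[ad.Tensor]:
        return [
            self.w_c, self.b_c, self.w_s, self.b_s,
            self.w_gate_c, self.b_gate_c, self.w_gate_s, self.b_gate_s,
            self.w_cls, self.b_cls,
        ]

    def gate(self, h_c, h_s, force_z: float | None = None):
        """Gated projections of both modalities.

        Returns ``(h_c_gated, h_s_gated)`` of shape (B, proj_dim).
        ``force_z`` overrides both gate vectors with a constant (used to
        verify the open/closed-gate identities).
        """
        h_c = h_c if isinstance(h_c, ad.Tensor) else ad.constant(np.atleast_2d(h_c))
        h_s = h_s if isinstance(h_s, ad.Tensor) else ad.constant(np.atleast_2d(h_s))
        proj_c = ad.relu(ad.linear(h_c, self.w_c, self.b_c))
        proj_s = ad.relu(ad.linear(h_s, self.w_s, self.b_s))
        if force_z is not None:
            z = ad.constant(np.full((1, self.config.proj_dim), float(force_z)))
            return ad.mul(z, proj_c), ad.mul(z, proj_s)
        cat = ad.concat([h_c, h_s], axis=1)
        z_c = ad.sigmoid(ad.linear(cat, self.w_gate_c, self.b_gate_c))
        z_s = ad.sigmoid(ad.linear(cat, self.w_gate_s, self.b_gate_s))
        return ad.mul(z_c, proj_c), ad.mul(z_s, proj_s)

    def fuse(self, gated_c: ad.Tensor, gated_s: ad.Tensor) -> ad.Tensor:
        if self.config.append_one:
            ones = ad.constant(np.ones((gated_c.shape[0], 1)))
            gated_c = ad.concat([gated_c, ones], axis=1)
            gated_s = ad.concat([gated_s, ones], axis=1)
        return kronecker_fuse(gated_c, gated_s)

    def classify(self, h_fusion: ad.Tensor) -> ad.Tensor:
        """Single fully connected layer producing class logits."""
        h = h_fusion if isinstance(h_fusion, ad.Tensor) else ad.constant(np.atleast_2d(h_fusion))
        return ad.linear(h, self.w_cls, self.b_cls)

    def forward(self, h_c, h_s, force_z: float | None = None) -> ad.Tensor:
        gated_c, gated_s = self.gate(h_c, h_s, force_z=force_z)
        return self.classify(self.fuse(gated_c, gated_s))
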