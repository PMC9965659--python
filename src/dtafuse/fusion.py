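"""Drug-protein interaction: cross-multi-head attention, decoupling, fusion.

Two cross-attention blocks share the protein sequence features as keys and
values: one queries with the drug's SMILES-sequence features, the other
with its graph-node features.  The head-averaged attention maps are
decoupled into per-position drug weights (row means) and per-position
protein weights (column means of the stacked maps); the weighted
representations are global-max-pooled and concatenated into the
interaction vector, which a four-layer perceptron maps to the scalar
affinity.

Row/column sums of the maps are implemented as means over unmasked
positions: any positive rescaling of the weights is absorbed by the
trained head, and means are stable across sequence lengths.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autograd as ag
from .autograd import Tensor
from .nn import Dropout, Linear, Module
from .sequence_encoder import FeatureMap, masked_max_pool


def scaled_dot_attention(q: Tensor, k: Tensor, v: Tensor, scale: float,
                         key_mask: np.ndarray | None = None) -> tuple[Tensor, Tensor]:
    """Softmax(Q K^T / scale) V with masked keys receiving zero mass.

    Returns (output, attention map); map rows sum to 1 over unmasked keys.
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    if k.shape[-2] != v.shape[-2]:
        raise ValueError("K and V must have equal key counts")
    logits = ag.matmul(q, ag.transpose(k, *range(k.ndim - 2), k.ndim - 1, k.ndim - 2))
    logits = logits * Tensor(1.0 / scale)
    if key_mask is not None:
        key_mask = np.asarray(key_mask, dtype=bool)
        if not key_mask.any(axis=-1).all():
            raise ValueError("a query has every key masked")
        expanded = np.broadcast_to(
            key_mask[..., None, :] if key_mask.ndim == logits.ndim - 1 else key_mask,
            logits.shape,
        )
        logits = ag.masked_fill(logits, ~expanded, -1e30)
    attn = ag.softmax(logits, axis=-1)
    return ag.matmul(attn, v), attn


class CrossAttentionBlock(Module):
    """One cross-multi-head attention block (drug queries, protein keys/values).

    The input projection is shared between keys and values (and, within the
    sequence branch, with the queries), mirroring the single projection
    matrix per branch; per-head query/key/value projections and the output
    projection are separate.  The logit scale is sqrt(d_in / h) where d_in
    is the query branch's input channel width (``scale_mode='input'``), or
    the conventional sqrt(d_head) (``scale_mode='head'``).
    """

    def __init__(self, query_dim: int, kv_dim: int, attn_dim: int, heads: int,
                 dropout: float, rng: np.random.Generator,
                 scale_mode: str = "input"):
        super().__init__()
        if attn_dim % heads != 0:
            raise ValueError(f"head count {heads} must divide attention width {attn_dim}")
        if scale_mode not in ("input", "head"):
            raise ValueError("scale_mode must be 'input' or 'head'")
        self.heads = heads
        self.attn_dim = attn_dim
        self.head_dim = attn_dim // heads
        self.scale = np.sqrt(query_dim / heads) if scale_mode == "input" else np.sqrt(self.head_dim)
        self.q_in = Linear(query_dim, attn_dim, rng)
        self.kv_in = Linear(kv_dim, attn_dim, rng)
        self.w_q = Linear(attn_dim, attn_dim, rng, bias=False)
        self.w_k = Linear(attn_dim, attn_dim, rng, bias=False)
        self.w_v = Linear(attn_dim, attn_dim, rng, bias=False)
        self.w_o = Linear(attn_dim, attn_dim, rng)
        self.dropout = Dropout(dropout, rng)

    def _split_heads(self, x: Tensor) -> Tensor:
        b, length, _ = x.shape
        return ag.transpose(x.reshape(b, length, self.heads, self.head_dim), 0, 2, 1, 3)

    def forward(self, query_fm: FeatureMap, kv_fm: FeatureMap,
                return_output: bool = True) -> tuple[Tensor | None, Tensor]:
        """Returns (projected output (B, Lq, attn_dim), head-averaged map (B, Lq, Lk)).

        With ``return_output=False`` the value path is skipped and only the
        attention map is produced (the fusion stage consumes the maps, not
        the value-weighted outputs).
        """
        q = ag.relu(self.q_in(query_fm.values))
        kv = ag.relu(self.kv_in(kv_fm.values))  # keys and values share the projection
        qh = self._split_heads(self.w_q(q))
        kh = self._split_heads(self.w_k(kv))
        vh = self._split_heads(self.w_v(kv)) if return_output else qh  # placeholder
        key_mask = np.broadcast_to(
            kv_fm.mask[:, None, None, :], (qh.shape[0], self.heads, 1, kv_fm.mask.shape[1])
        )
        if return_output:
            out_h, attn_h = scaled_dot_attention(qh, kh, vh, self.scale, key_mask=key_mask)
            b, _, lq, _ = out_h.shape
            merged = ag.transpose(out_h, 0, 2, 1, 3).reshape(b, lq, self.attn_dim)
            out = self.dropout(self.w_o(merged))
        else:
            logits = ag.matmul(qh, ag.transpose(kh, 0, 1, 3, 2)) * Tensor(1.0 / self.scale)
            expanded = np.broadcast_to(key_mask, logits.shape)
            attn_h = ag.softmax(ag.masked_fill(logits, ~expanded, -1e30), axis=-1)
            out = None
        return out, attn_h.mean(axis=1)


def decouple_attention(a1: Tensor, a2: Tensor, mask_d1: np.ndarray,
                       mask_d2: np.ndarray, mask_p: np.ndarray):
    """Split attention maps into drug weights (row means) and a protein weight.

    alpha_d1 / alpha_d2 are per-position row means of A1 / A2 over unmasked
    protein columns; alpha_p is the per-column mean of the drug-axis stack
    [A1; A2] over unmasked drug rows.  All weights are nonnegative.
    """
    if a1.shape[-1] != a2.shape[-1]:
        raise ValueError("attention maps must share the protein axis length")
    p_valid = Tensor(mask_p[:, None, :].astype(float))
    p_count = Tensor(mask_p.sum(axis=1, keepdims=True).astype(float))
    alpha_d1 = (a1 * p_valid).sum(axis=2) / p_count
    alpha_d2 = (a2 * p_valid).sum(axis=2) / p_count

    stacked = ag.concat([a1, a2], axis=1)  # (B, Ld1 + Ld2, Lp)
    d_mask = np.concatenate([mask_d1, mask_d2], axis=1)
    d_valid = Tensor(d_mask[:, :, None].astype(float))
    d_count = Tensor(d_mask.sum(axis=1, keepdims=True).astype(float))
    alpha_p = (stacked * d_valid).sum(axis=1) / d_count
    return alpha_d1, alpha_d2, alpha_p


def fuse(alpha_d1: Tensor, drug_seq: FeatureMap, alpha_d2: Tensor,
         drug_nodes: FeatureMap, alpha_p: Tensor, protein_seq: FeatureMap) -> Tensor:
    """Interaction vector: concat of masked max pools of the reweighted maps.

    The trailing global average pool of the original formulation acts on an
    already-pooled vector (window 1) and is therefore the identity.
    """
    seg1 = masked_max_pool(
        FeatureMap(drug_seq.values * alpha_d1.reshape(*alpha_d1.shape, 1), drug_seq.mask)
    )
    seg2 = masked_max_pool(
        FeatureMap(drug_nodes.values * alpha_d2.reshape(*alpha_d2.shape, 1), drug_nodes.mask)
    )
    seg3 = masked_max_pool(
        FeatureMap(protein_seq.values * alpha_p.reshape(*alpha_p.shape, 1), protein_seq.mask)
    )
    return ag.concat([seg1, seg2, seg3], axis=1)


class RegressionHead(Module):
    """Four affine layers; ReLU + dropout after each hidden layer."""

    def __init__(self, in_dim: int, hidden, dropout: float, rng: np.random.Generator):
        super().__init__()
        if len(hidden) != 3:
            raise ValueError("the head expects three hidden widths (four affine layers)")
        dims = [in_dim, *hidden]
        self.hidden_layers = [Linear(dims[i], dims[i + 1], rng) for i in range(3)]
        self.out = Linear(dims[-1], 1, rng)
        self.dropouts = [Dropout(dropout, rng) for _ in range(3)]

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[-1] != self.hidden_layers[0].weight.shape[0]:
            raise ValueError(
                f"input width {x.shape[-1]} does not match head width "
                f"{self.hidden_layers[0].weight.shape[0]}"
            )
        for layer, drop in zip(self.hidden_layers, self.dropouts):
            x = drop(ag.relu(layer(x)))
        return self.out(x).reshape(x.shape[0])


def predict_affinity(i_dp: Tensor, head: RegressionHead) -> Tensor:
    """Scalar affinity per pair; deterministic when the head is in eval mode."""
    return head(i_dp)


@dataclass
class AttentionDecomposition:
    """Cross-attention maps, decoupled weights and the fused vector."""

    a1: Tensor  # (B, Ld, Lp) head-averaged SMILES->protein map
    a2: Tensor  # (B, Atoms, Lp) head-averaged graph->protein map
    alpha_d1: Tensor
    alpha_d2: Tensor
    alpha_p: Tensor
    i_dp: Tensor
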