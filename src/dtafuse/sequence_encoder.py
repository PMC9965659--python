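"""Sequence channel: embedding, 1-D convolutions and squeeze-and-excitation.

A squeeze-and-excitation (SE) block computes per-channel statistics by
average pooling (squeeze), passes them through a two-layer gating
bottleneck with reduction ratio r (excite), and rescales each channel of
the convolutional feature map by its gate in (0, 1).  The encoder stacks
[convolution -> SE] blocks and exposes both the position-resolved feature
map (consumed by the cross-attention fusion) and its global-max-pooled
vector.

Padding positions (code 0) carry zero embeddings, are re-zeroed after each
convolution, and are excluded from channel statistics and pooling, so
appending padding to a sequence never changes the outputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autograd as ag
from .autograd import Tensor
from .featurization import EncodedSequence
from .nn import Conv1d, Dropout, Embedding, Linear, Module


@dataclass
class FeatureMap:
    """Batched position x channel features plus a valid-position mask."""

    values: Tensor  # (B, L, C)
    mask: np.ndarray  # (B, L) bool

    @property
    def length(self) -> int:
        return self.values.shape[1]

    @property
    def channels(self) -> int:
        return self.values.shape[2]


def embed(seq, table: Embedding) -> FeatureMap:
    """Row-wise embedding lookup; pad positions map to zero and are masked."""
    if isinstance(seq, EncodedSequence):
        codes = seq.codes[None, :]
    else:
        codes = np.atleast_2d(np.asarray(seq, dtype=np.int64))
    return FeatureMap(values=table(codes), mask=codes != 0)


def masked_max_pool(fm: FeatureMap) -> Tensor:
    """Global max pool over valid positions -> (B, C)."""
    if not fm.mask.any(axis=1).all():
        raise ValueError("cannot pool a map with no unmasked positions")
    filled = ag.masked_fill(fm.values, ~fm.mask[:, :, None], -np.inf)
    return filled.max(axis=1)


def se_squeeze(fm: FeatureMap) -> Tensor:
    """Per-channel mean over (valid) positions -> (B, C)."""
    if fm.length < 1 or not fm.mask.any(axis=1).all():
        raise ValueError("cannot squeeze an empty feature map")
    counts = fm.mask.sum(axis=1, keepdims=True).astype(float)  # (B, 1)
    masked = fm.values * Tensor(fm.mask[:, :, None].astype(float))
    return masked.sum(axis=1) / Tensor(counts)


class SEParams(Module):
    """The two gating weight matrices of an SE block (no biases)."""

    def __init__(self, channels: int, reduction: int, rng: np.random.Generator):
        super().__init__()
        if channels % reduction != 0:
            raise ValueError(
                f"reduction ratio {reduction} must divide channel count {channels}"
            )
        self.reduction = reduction
        bound = 1.0 / np.sqrt(channels)
        self.w1 = Tensor(rng.uniform(-bound, bound, (channels, channels // reduction)),
                         requires_grad=True)
        bound2 = 1.0 / np.sqrt(channels // reduction)
        self.w2 = Tensor(rng.uniform(-bound2, bound2, (channels // reduction, channels)),
                         requires_grad=True)


def se_excite(z: Tensor, params: SEParams) -> Tensor:
    """Gate s = sigmoid(W2 relu(W1 z)); every component lies in (0, 1)."""
    if z.shape[-1] != params.w1.shape[0]:
        raise ValueError(
            f"channel count {z.shape[-1]} does not match gate width {params.w1.shape[0]}"
        )
    return ag.sigmoid(ag.relu(z @ params.w1) @ params.w2)


def se_reweight(fm: FeatureMap, s: Tensor) -> FeatureMap:
    """Scale channel c of the map by gate s_c; the mask is unchanged."""
    if s.shape[-1] != fm.channels:
        raise ValueError(
            f"gate width {s.shape[-1]} does not match channel count {fm.channels}"
        )
    gated = fm.values * s.reshape(s.shape[0], 1, s.shape[-1])
    return FeatureMap(values=gated, mask=fm.mask)


class SEBlock(Module):
    def __init__(self, channels: int, reduction: int, rng: np.random.Generator):
        super().__init__()
        self.params = SEParams(channels, reduction, rng)

    def forward(self, fm: FeatureMap) -> FeatureMap:
        return se_reweight(fm, se_excite(se_squeeze(fm), self.params))


class SequenceEncoder(Module):
    """Stack of [1-D convolution -> SE block] layers over embedded sequences."""

    def __init__(self, vocab_size: int, embedding_dim: int, filters, kernel_size: int,
                 reduction: int, dropout: float, rng: np.random.Generator):
        super().__init__()
        self.embedding = Embedding(vocab_size + 1, embedding_dim, rng)
        self.kernel_size = kernel_size
        self.convs = []
        self.se_blocks = []
        prev = embedding_dim
        for f in filters:
            self.convs.append(Conv1d(prev, f, kernel_size, rng))
            self.se_blocks.append(SEBlock(f, reduction, rng))
            prev = f
        self.out_channels = prev
        self.dropout = Dropout(dropout, rng)

    def forward(self, codes: np.ndarray) -> tuple[FeatureMap, Tensor]:
        """Encode integer codes -> (length-resolved map, global-max-pooled vector)."""
        codes = np.atleast_2d(np.asarray(codes, dtype=np.int64))
        if not (codes != 0).any(axis=1).all():
            raise ValueError("a sequence in the batch has no valid positions")
        fm = embed(codes, self.embedding)
        mask_f = Tensor(fm.mask[:, :, None].astype(float))
        for conv, se in zip(self.convs, self.se_blocks):
            x = ag.relu(conv(fm.values))
            # convolution bias leaks into pad positions; re-zero them so the
            # map stays invariant to appended padding
            fm = FeatureMap(values=x * mask_f, mask=fm.mask)
            fm = se(fm)
        fm = FeatureMap(values=self.dropout(fm.values) * mask_f, mask=fm.mask)
        return fm, masked_max_pool(fm)
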