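"""The full three-channel affinity model and batch preparation.

Channels: (1) SMILES sequence -> embedding -> conv/SE stack; (2) protein
sequence likewise; (3) drug molecular graph -> GIN stack.  Two
cross-multi-head attention blocks (SMILES->protein, graph-nodes->protein)
are decoupled into position weights, fused into the interaction vector and
regressed to a scalar affinity.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from . import autograd as ag
from .autograd import Tensor
from .data import AffinityRecord
from .featurization import (
    ATOM_FEATURE_DIM,
    MolecularGraph,
    default_protein_dictionary,
    default_smiles_dictionary,
    encode_sequence,
    smiles_to_graph,
)
from .fusion import (
    AttentionDecomposition,
    CrossAttentionBlock,
    RegressionHead,
    decouple_attention,
    fuse,
)
from .graph_encoder import GraphEncoder
from .nn import Module
from .sequence_encoder import FeatureMap, SequenceEncoder


@dataclass
class ModelConfig:
    """Hyperparameters of the three-channel model.

    Defaults follow the benchmark configuration (embedding 128, three SE
    layers, eight heads, [1024, 1024, 512] head widths, dropout 0.2); the
    desk-scale synthetic preset shrinks every width.
    """

    max_smiles_len: int = 100
    max_protein_len: int = 1000
    embedding_dim: int = 128
    smiles_filters: tuple = (16, 32, 48)
    protein_filters: tuple = (16, 32, 48)
    smiles_kernel: int = 4
    protein_kernel: int = 8
    se_reduction: int = 16
    gin_depth: int = 5
    gin_hidden: int = 128
    gin_out: int = 128
    attn_dim: int = 128
    heads: int = 8
    mlp_hidden: tuple = (1024, 1024, 512)
    dropout: float = 0.2
    scale_mode: str = "input"
    seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        for key in ("smiles_filters", "protein_filters", "mlp_hidden"):
            d[key] = list(d[key])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        for key in ("smiles_filters", "protein_filters", "mlp_hidden"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class PreparedRecord:
    """Featurised triplet ready for collation."""

    drug_codes: np.ndarray
    protein_codes: np.ndarray
    graph: MolecularGraph
    affinity: float
    smiles: str
    protein: str


def prepare_record(record: AffinityRecord, config: ModelConfig,
                   smiles_dict=None, protein_dict=None) -> PreparedRecord:
    smiles_dict = smiles_dict or default_smiles_dictionary()
    protein_dict = protein_dict or default_protein_dictionary()
    return PreparedRecord(
        drug_codes=encode_sequence(record.smiles, smiles_dict, config.max_smiles_len).codes,
        protein_codes=encode_sequence(record.protein, protein_dict,
                                      config.max_protein_len).codes,
        graph=smiles_to_graph(record.smiles),
        affinity=record.affinity,
        smiles=record.smiles,
        protein=record.protein,
    )


def prepare_dataset(records, config: ModelConfig) -> list[PreparedRecord]:
    smiles_dict = default_smiles_dictionary()
    protein_dict = default_protein_dictionary()
    return [prepare_record(r, config, smiles_dict, protein_dict) for r in records]


@dataclass
class Batch:
    drug_codes: np.ndarray  # (B, Ld)
    protein_codes: np.ndarray  # (B, Lp)
    node_features: np.ndarray  # (N_total, ATOM_FEATURE_DIM)
    edge_index: np.ndarray  # (2, 2E) directed expansion across the batch
    graph_ids: np.ndarray  # (N_total,)
    node_pad_index: np.ndarray  # (B, A_max) rows into the padded node stack
    node_mask: np.ndarray  # (B, A_max)
    labels: np.ndarray  # (B,)

    @property
    def size(self) -> int:
        return self.drug_codes.shape[0]


def collate(prepared: list[PreparedRecord], indices=None) -> Batch:
    """Stack records into one batch; graphs become a single stacked node set."""
    items = [prepared[i] for i in indices] if indices is not None else list(prepared)
    if not items:
        raise ValueError("cannot collate an empty batch")
    counts = [it.graph.num_nodes for it in items]
    offsets = np.concatenate([[0], np.cumsum(counts)])
    n_total = int(offsets[-1])
    a_max = max(counts)
    edge_blocks = []
    graph_ids = np.empty(n_total, dtype=np.int64)
    pad_index = np.full((len(items), a_max), n_total, dtype=np.int64)  # n_total = zero row
    node_mask = np.zeros((len(items), a_max), dtype=bool)
    for b, it in enumerate(items):
        graph_ids[offsets[b]: offsets[b + 1]] = b
        pad_index[b, : counts[b]] = np.arange(offsets[b], offsets[b + 1])
        node_mask[b, : counts[b]] = True
        ei = it.graph.edge_index()
        if ei.size:
            edge_blocks.append(ei + offsets[b])
    return Batch(
        drug_codes=np.stack([it.drug_codes for it in items]),
        protein_codes=np.stack([it.protein_codes for it in items]),
        node_features=np.concatenate([it.graph.node_features for it in items]),
        edge_index=(np.concatenate(edge_blocks, axis=1) if edge_blocks
                    else np.zeros((2, 0), dtype=np.int64)),
        graph_ids=graph_ids,
        node_pad_index=pad_index,
        node_mask=node_mask,
        labels=np.asarray([it.affinity for it in items], dtype=np.float64),
    )


@dataclass
class ModelOutput:
    affinity: Tensor  # (B,)
    decomposition: AttentionDecomposition
    gin_node_features: Tensor  # (N_total, gin_hidden) last-layer stacked nodes
    graph_vector: Tensor
    graph_ids: np.ndarray


class DTAModel(Module):
    """Three-channel drug-target affinity regressor."""

    def __init__(self, config: ModelConfig):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(config.seed)
        smiles_vocab = len(default_smiles_dictionary().mapping)
        protein_vocab = len(default_protein_dictionary().mapping)
        self.drug_encoder = SequenceEncoder(
            smiles_vocab, config.embedding_dim, config.smiles_filters,
            config.smiles_kernel, config.se_reduction, config.dropout, rng)
        self.protein_encoder = SequenceEncoder(
            protein_vocab, config.embedding_dim, config.protein_filters,
            config.protein_kernel, config.se_reduction, config.dropout, rng)
        self.graph_encoder = GraphEncoder(
            ATOM_FEATURE_DIM, config.gin_hidden, config.gin_depth,
            config.gin_out, config.dropout, rng)
        l_c = self.drug_encoder.out_channels
        l_g = config.gin_hidden
        self.seq_attention = CrossAttentionBlock(
            l_c, self.protein_encoder.out_channels, config.attn_dim, config.heads,
            config.dropout, rng, scale_mode=config.scale_mode)
        self.graph_attention = CrossAttentionBlock(
            l_g, self.protein_encoder.out_channels, config.attn_dim, config.heads,
            config.dropout, rng, scale_mode=config.scale_mode)
        self.head = RegressionHead(
            l_c + l_g + self.protein_encoder.out_channels,
            list(config.mlp_hidden), config.dropout, rng)

    def forward(self, batch: Batch) -> ModelOutput:
        drug_fm, _ = self.drug_encoder(batch.drug_codes)
        prot_fm, _ = self.protein_encoder(batch.protein_codes)
        graph_rep = self.graph_encoder(
            batch.node_features, batch.edge_index, batch.graph_ids, batch.size)

        # pad the stacked node features to (B, A_max, C) for attention
        nodes = graph_rep.node_features_last
        zero_row = Tensor(np.zeros((1, nodes.shape[1])))
        padded = ag.take(ag.concat([nodes, zero_row], axis=0), batch.node_pad_index)
        node_fm = FeatureMap(values=padded, mask=batch.node_mask)

        _, a1 = self.seq_attention(drug_fm, prot_fm, return_output=False)
        _, a2 = self.graph_attention(node_fm, prot_fm, return_output=False)
        alpha_d1, alpha_d2, alpha_p = decouple_attention(
            a1, a2, drug_fm.mask, node_fm.mask, prot_fm.mask)
        i_dp = fuse(alpha_d1, drug_fm, alpha_d2, node_fm, alpha_p, prot_fm)
        affinity = self.head(i_dp)
        return ModelOutput(
            affinity=affinity,
            decomposition=AttentionDecomposition(
                a1=a1, a2=a2, alpha_d1=alpha_d1, alpha_d2=alpha_d2,
                alpha_p=alpha_p, i_dp=i_dp),
            gin_node_features=nodes,
            graph_vector=graph_rep.graph_vector,
            graph_ids=batch.graph_ids,
        )

    def predict(self, prepared: list[PreparedRecord], batch_size: int = 128) -> np.ndarray:
        """Deterministic predictions in evaluation mode."""
        was_training = self.training
        self.eval()
        out = np.empty(len(prepared))
        try:
            with ag.no_grad():
                for start in range(0, len(prepared), batch_size):
                    batch = collate(prepared, range(start, min(start + batch_size, len(prepared))))
                    out[start: start + batch.size] = self.forward(batch).affinity.data
        finally:
            self.train(was_training)
        return out
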