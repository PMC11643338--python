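"""Message-passing molecular encoders with activity-cliff-aware outputs.

Four backbones are provided — GCN (mean aggregation), GAT (multi-head
attention, head outputs averaged), GIN (trainable ε, two-layer update
network) and PNA (aggregators mean/min/max/sum/std × scalers identity/
amplification/attenuation; the default backbone).  The convolution
stack follows channel sizes (64, 128, 256, 512) with batch
normalization after each layer and no dropout by default; a global max
pooling (GMP) readout takes the per-channel maximum over a molecule's
nodes, and the pooled vector is both the molecule's latent
representation f (fed to the triplet soft-margin loss) and the input to
a pyramid dense head (256, 128, 32 → 1) producing the activity
prediction.  The latent dimensionality always equals the last
convolution channel.

GAT and PNA receive self-loop edges (with zero bond features) so that
single-atom molecules still aggregate; GCN includes the central node in
its mean; GIN and PNA consume bond features through a learned edge
projection, plain GCN ignores them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .mol_graph_io import ATOM_FEATURE_DIM, BOND_FEATURE_DIM, GraphBatch
from .nn.modules import BatchNorm1d, Linear, Module
from .nn.tensor import (
    Tensor,
    concat,
    gather_rows,
    segment_max,
    segment_mean,
    segment_min,
    segment_sum,
)

__all__ = [
    "EncoderConfig",
    "Encoder",
    "PairClassifier",
    "build_encoder",
    "build_pair_classifier",
    "forward",
    "global_max_pool",
]

_PNA_AGGREGATORS = ("mean", "min", "max", "sum", "std")
_PNA_SCALERS = ("identity", "amplification", "attenuation")


@dataclass
class EncoderConfig:
    """Architecture hyperparameters of the molecular encoder."""

    backbone: str = "pna"
    conv_channels: tuple[int, ...] = (64, 128, 256, 512)
    head_widths: tuple[int, ...] = (256, 128, 32)
    batch_norm: bool = True
    dropout: float = 0.0
    gat_heads: int = 4
    pna_aggregators: tuple[str, ...] = _PNA_AGGREGATORS
    pna_scalers: tuple[str, ...] = _PNA_SCALERS
    task: str = "regression"

    def __post_init__(self):
        if self.backbone not in ("gcn", "gat", "gin", "pna"):
            raise ValueError(f"unknown backbone {self.backbone!r}")
        if len(self.conv_channels) == 0:
            raise ValueError("conv_channels must be nonempty")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be a probability < 1")
        if self.task not in ("regression", "pair_classification"):
            raise ValueError(f"unknown task {self.task!r}")

    @property
    def latent_dim(self) -> int:
        return self.conv_channels[-1]


def _add_self_loops(edge_index: np.ndarray, edge_attr: Tensor, n_nodes: int):
    loops = np.arange(n_nodes, dtype=np.int64)
    ei = np.concatenate([edge_index, np.stack([loops, loops])], axis=1)
    ea = concat([edge_attr, Tensor(np.zeros((n_nodes, edge_attr.data.shape[1])))])
    return ei, ea


class GCNLayer(Module):
    """Mean aggregation over the neighborhood including the node itself."""

    def __init__(self, in_dim: int, out_dim: int, edge_dim: int, rng):
        self.lin = Linear(in_dim, out_dim, rng)

    def __call__(self, x, edge_index, edge_attr, n_nodes):
        src, dst = edge_index
        agg = segment_sum(gather_rows(x, src), dst, n_nodes) + x
        deg = (np.bincount(dst, minlength=n_nodes) + 1.0)[:, None]
        return self.lin(agg / Tensor(deg))


class GINLayer(Module):
    """Sum aggregation with trainable ε and a 2-layer update network;
    bond features enter additively through a linear projection."""

    def __init__(self, in_dim: int, out_dim: int, edge_dim: int, rng):
        self.eps = Tensor(0.0, requires_grad=True)
        self.edge_lin = Linear(edge_dim, in_dim, rng)
        self.mlp1 = Linear(in_dim, out_dim, rng)
        self.mlp2 = Linear(out_dim, out_dim, rng)

    def __call__(self, x, edge_index, edge_attr, n_nodes):
        src, dst = edge_index
        if edge_index.shape[1] > 0:
            msg = (gather_rows(x, src) + self.edge_lin(edge_attr)).relu()
            agg = segment_sum(msg, dst, n_nodes)
        else:
            agg = Tensor(np.zeros_like(x.data))
        h = x * (self.eps + 1.0) + agg
        return self.mlp2(self.mlp1(h).relu())


class GATLayer(Module):
    """Multi-head attention over incoming edges; head outputs averaged."""

    def __init__(self, in_dim: int, out_dim: int, edge_dim: int, rng, heads: int = 4):
        self.heads = heads
        self.proj = [Linear(in_dim, out_dim, rng) for _ in range(heads)]
        self.edge_proj = [Linear(edge_dim, out_dim, rng) for _ in range(heads)]
        self.att_src = [
            Tensor(rng.normal(0, 0.1, size=(out_dim,)), requires_grad=True)
            for _ in range(heads)
        ]
        self.att_dst = [
            Tensor(rng.normal(0, 0.1, size=(out_dim,)), requires_grad=True)
            for _ in range(heads)
        ]
        self.bias = Tensor(np.zeros(out_dim), requires_grad=True)

    def __call__(self, x, edge_index, edge_attr, n_nodes):
        edge_index, edge_attr = _add_self_loops(edge_index, edge_attr, n_nodes)
        src, dst = edge_index
        head_outputs = []
        for h in range(self.heads):
            hx = self.proj[h](x)
            he = self.edge_proj[h](edge_attr)
            msg = gather_rows(hx, src) + he
            score = (msg * self.att_src[h]).sum(axis=1) + (
                gather_rows(hx, dst) * self.att_dst[h]
            ).sum(axis=1)
            score = score.leaky_relu(0.2)
            # softmax over the incoming edges of each destination node
            score_max = segment_max(score.reshape(-1, 1), dst, n_nodes)
            shifted = (score - gather_rows(score_max, dst).reshape(-1)).exp()
            denom = segment_sum(shifted.reshape(-1, 1), dst, n_nodes)
            alpha = shifted / gather_rows(denom, dst).reshape(-1)
            weighted = msg * alpha.reshape(-1, 1)
            head_outputs.append(segment_sum(weighted, dst, n_nodes))
        out = head_outputs[0]
        for ho in head_outputs[1:]:
            out = out + ho
        return out / float(self.heads) + self.bias


class PNALayer(Module):
    """Principal neighborhood aggregation with degree scalers.

    Messages are ReLU(W[x_src ‖ e]); each aggregator output is rescaled
    by the identity / amplification / attenuation degree scalers with
    normalizer δ (mean log-degree of the reference data), concatenated
    with the node's own features and projected to the output width.
    """

    def __init__(
        self,
        in_dim: int,
        out_dim: int,
        edge_dim: int,
        rng,
        aggregators=_PNA_AGGREGATORS,
        scalers=_PNA_SCALERS,
    ):
        self.aggregators = tuple(aggregators)
        self.scalers = tuple(scalers)
        self.msg_lin = Linear(in_dim + edge_dim, in_dim, rng)
        post_in = in_dim * (1 + len(self.aggregators) * len(self.scalers))
        self.post = Linear(post_in, out_dim, rng)
        self.delta: Optional[float] = None  # frozen on first forward if unset

    def __call__(self, x, edge_index, edge_attr, n_nodes):
        edge_index, edge_attr = _add_self_loops(edge_index, edge_attr, n_nodes)
        src, dst = edge_index
        deg = np.bincount(dst, minlength=n_nodes).astype(np.float64)
        if self.delta is None:
            self.delta = float(np.mean(np.log(deg + 1.0)))
        msg = self.msg_lin(concat([gather_rows(x, src), edge_attr], axis=1)).relu()
        aggregated = {
            "mean": lambda: segment_mean(msg, dst, n_nodes),
            "min": lambda: segment_min(msg, dst, n_nodes),
            "max": lambda: segment_max(msg, dst, n_nodes),
            "sum": lambda: segment_sum(msg, dst, n_nodes),
            "std": lambda: (
                segment_mean(msg**2, dst, n_nodes)
                - segment_mean(msg, dst, n_nodes) ** 2
            )
            .relu()
            .sqrt(),
        }
        log_deg = np.log(deg + 1.0)[:, None]
        scale = {
            "identity": np.ones_like(log_deg),
            "amplification": log_deg / self.delta,
            "attenuation": np.where(log_deg > 0, self.delta / np.maximum(log_deg, 1e-12), 0.0),
        }
        blocks = [x]
        for agg_name in self.aggregators:
            agg = aggregated[agg_name]()
            for scaler_name in self.scalers:
                blocks.append(agg * Tensor(scale[scaler_name]))
        return self.post(concat(blocks, axis=1))


_LAYER_TYPES = {"gcn": GCNLayer, "gin": GINLayer, "gat": GATLayer, "pna": PNALayer}


class Encoder(Module):
    """Graph convolution stack + GMP readout + pyramid prediction head."""

    def __init__(
        self,
        config: EncoderConfig,
        node_dim: int = ATOM_FEATURE_DIM,
        edge_dim: int = BOND_FEATURE_DIM,
        seed: int = 0,
    ):
        rng = np.random.default_rng(seed)
        self.config = config
        self.node_dim = node_dim
        self.edge_dim = edge_dim
        self.convs: list[Module] = []
        self.norms: list[Module] = []
        in_dim = node_dim
        for out_dim in config.conv_channels:
            if config.backbone == "gat":
                layer = GATLayer(in_dim, out_dim, edge_dim, rng, heads=config.gat_heads)
            elif config.backbone == "pna":
                layer = PNALayer(
                    in_dim,
                    out_dim,
                    edge_dim,
                    rng,
                    aggregators=config.pna_aggregators,
                    scalers=config.pna_scalers,
                )
            else:
                layer = _LAYER_TYPES[config.backbone](in_dim, out_dim, edge_dim, rng)
            self.convs.append(layer)
            if config.batch_norm:
                self.norms.append(BatchNorm1d(out_dim))
            in_dim = out_dim
        self.head: list[Linear] = []
        width = config.latent_dim
        for w in config.head_widths:
            self.head.append(Linear(width, w, rng))
            width = w
        self.head_out = Linear(width, 1, rng)
        self._dropout_rng = np.random.default_rng(seed + 1)

    # -- forward ---------------------------------------------------------

    def encode(self, batch: GraphBatch, training: bool = False) -> Tensor:
        """Latent matrix f: the GMP readout of the conv stack."""
        x = Tensor(batch.node_features)
        edge_attr = Tensor(batch.edge_features)
        for i, conv in enumerate(self.convs):
            x = conv(x, batch.edge_index, edge_attr, batch.node_features.shape[0])
            if self.config.batch_norm:
                x = self.norms[i](x, training)
            x = x.relu()
        if (batch.node_counts == 0).any():
            raise ValueError("molecule with zero nodes in batch")
        return segment_max(x, batch.node_graph, batch.n_graphs)

    def predict_from_latent(self, latent: Tensor, training: bool = False) -> Tensor:
        h = latent
        for lin in self.head:
            h = lin(h).relu()
            if training and self.config.dropout > 0:
                keep = (
                    self._dropout_rng.random(h.data.shape) >= self.config.dropout
                ).astype(np.float64)
                h = h * Tensor(keep / (1.0 - self.config.dropout))
        return self.head_out(h).reshape(-1)

    def __call__(self, batch: GraphBatch, training: bool = False):
        latent = self.encode(batch, training=training)
        pred = self.predict_from_latent(latent, training=training)
        return pred, latent


class PairClassifier(Module):
    """Shared trunk encoding both molecules of an MMP; the two latents
    are concatenated and mapped to a single cliff logit."""

    def __init__(
        self,
        config: EncoderConfig,
        node_dim: int = ATOM_FEATURE_DIM,
        edge_dim: int = BOND_FEATURE_DIM,
        seed: int = 0,
    ):
        self.trunk = Encoder(config, node_dim, edge_dim, seed=seed)
        rng = np.random.default_rng(seed + 2)
        width = 2 * config.latent_dim
        self.head: list[Linear] = []
        for w in config.head_widths:
            self.head.append(Linear(width, w, rng))
            width = w
        self.head_out = Linear(width, 1, rng)

    def __call__(self, batch_a: GraphBatch, batch_b: GraphBatch, training: bool = False):
        lat_a = self.trunk.encode(batch_a, training=training)
        lat_b = self.trunk.encode(batch_b, training=training)
        h = concat([lat_a, lat_b], axis=1)
        for lin in self.head:
            h = lin(h).relu()
        logits = self.head_out(h).reshape(-1)
        return logits, lat_a, lat_b


def build_encoder(
    config: EncoderConfig,
    node_dim: int = ATOM_FEATURE_DIM,
    edge_dim: int = BOND_FEATURE_DIM,
    seed: int = 0,
) -> Encoder:
    """Construct an encoder with seeded, reproducible initialization."""
    return Encoder(config, node_dim=node_dim, edge_dim=edge_dim, seed=seed)


def build_pair_classifier(
    config: EncoderConfig,
    node_dim: int = ATOM_FEATURE_DIM,
    edge_dim: int = BOND_FEATURE_DIM,
    seed: int = 0,
) -> PairClassifier:
    return PairClassifier(config, node_dim=node_dim, edge_dim=edge_dim, seed=seed)


def forward(encoder: Encoder, batch: GraphBatch):
    """Evaluation-mode forward pass returning NumPy arrays.

    Returns ``(predictions, latents)`` with shapes [n_molecules] and
    [n_molecules × d_latent]; the latents are the pooled vectors taken
    after global max pooling and before the dense head.
    """
    pred, latent = encoder(batch, training=False)
    return pred.data.copy(), latent.data.copy()


def global_max_pool(node_features: np.ndarray, membership: np.ndarray) -> np.ndarray:
    """Per-molecule, per-channel maximum over node features."""
    node_features = np.asarray(node_features, dtype=np.float64)
    membership = np.asarray(membership, dtype=np.int64)
    if node_features.shape[0] != membership.shape[0]:
        raise ValueError("membership must cover all nodes")
    n_graphs = int(membership.max()) + 1 if membership.size else 0
    counts = np.bincount(membership, minlength=n_graphs)
    if n_graphs == 0 or (counts == 0).any():
        raise ValueError("every molecule must have at least one node")
    out = np.full((n_graphs, node_features.shape[1]), -np.inf)
    np.maximum.at(out, membership, node_features)
    return out
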