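"""Ternary-extended E(3)-equivariant graph matching encoder.

Alternates intra-graph message passing with ternary inter-graph attention
over M layers, updating SE(3)-invariant latent embeddings and
SE(3)-equivariant coordinates for the three entity graphs (protein1,
ligand, protein2).  Each node's coordinate update moves along unit
directions to its own-graph neighbours with invariant scalar magnitudes,
which makes the output coordinates equivariant under independent rigid
motions of each graph while the embeddings and attention coefficients stay
invariant.

The two protein graphs are processed by the same parameters (weight
sharing) so the network is symmetric under exchanging protein1/protein2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor, concatenate, softmax
from .errors import ContractError, NumericError
from .featurize import LIGAND_FEATURE_DIM, GeometricGraph
from .nn import MLP, Embedding, Linear, Module, glorot
from .structures_io import AA_INDEX


@dataclass
class EncoderConfig:
    n_layers: int = 5
    hidden_dim: int = 64
    beta: float = 0.5
    share_protein_weights: bool = True
    epsilon: float = 1e-8
    constraint_mode: str = "clip"  # off | clip | ligand-distance-projection
    clip_cap: float = 5.0          # max displacement norm per node per layer (A)
    edge_feature_dim: int = 18

    def __post_init__(self):
        if self.n_layers < 1 or self.hidden_dim < 1:
            raise ContractError("n_layers and hidden_dim must be >= 1")
        if not 0.0 <= self.beta <= 1.0:
            raise ContractError("beta must lie in [0, 1]")
        if self.constraint_mode not in ("off", "clip", "ligand-distance-projection"):
            raise ContractError(f"unknown constraint mode {self.constraint_mode!r}")


@dataclass
class EncoderState:
    """Final-layer latent embeddings and coordinates for the three graphs."""

    h: dict[str, Tensor]        # entity kind -> (n, hidden)
    x: dict[str, Tensor]        # entity kind -> (n, 3)
    layers_x: list[dict[str, Tensor]] = field(default_factory=list)


# ---------------------------------------------------------------------------
# The four primitive operations of one encoder layer
# ---------------------------------------------------------------------------

def _mean_agg_matrix(edge_index: np.ndarray, n_nodes: int) -> np.ndarray:
    """(n, E) matrix averaging edge values into their target nodes.

    Nodes with no incoming edge get an all-zero row (mean-of-empty = 0).
    """
    E = edge_index.shape[1]
    A = np.zeros((n_nodes, E))
    if E:
        counts = np.bincount(edge_index[1], minlength=n_nodes).astype(float)
        counts[counts == 0] = 1.0
        A[edge_index[1], np.arange(E)] = 1.0 / counts[edge_index[1]]
    return A


def _sum_agg_matrix(edge_index: np.ndarray, n_nodes: int) -> np.ndarray:
    E = edge_index.shape[1]
    A = np.zeros((n_nodes, E))
    if E:
        A[edge_index[1], np.arange(E)] = 1.0
    return A


def intra_messages(h: Tensor, x: Tensor, edge_index: np.ndarray,
                   edge_features: np.ndarray, phi_e) -> tuple[Tensor, Tensor]:
    """Per-edge messages and their per-node mean aggregate.

    ``m_{j->i} = phi_e(h_i, h_j, ||x_i - x_j||^2, f_{j->i})`` over the
    graph's own edges; ``m_i`` is the arithmetic mean over in-neighbours
    (zero vector for nodes without in-edges).
    """
    n = h.shape[0]
    if edge_index.size == 0:
        m_edge = Tensor(np.zeros((0, 1)))
        probe = phi_e(h[np.array([0])], h[np.array([0])],
                      Tensor(np.zeros((1, 1))), Tensor(np.zeros((1, edge_features.shape[1]
                                                                 if edge_features.ndim == 2 else 0))))
        return m_edge, Tensor(np.zeros((n, probe.shape[-1])))
    src, dst = edge_index
    diff = x[dst] - x[src]
    d2 = (diff ** 2).sum(axis=-1, keepdims=True)
    m_edge = phi_e(h[dst], h[src], d2, Tensor(edge_features))
    agg = Tensor(_mean_agg_matrix(edge_index, n))
    m_node = agg @ m_edge
    return m_edge, m_node


def inter_attention(h_recv: Tensor, h_send: Tensor, phi_q, phi_k,
                    W: Tensor) -> tuple[Tensor, Tensor]:
    """Cross-graph softmax attention over the union of the other graphs' nodes.

    Returns the row-stochastic coefficient matrix ``a`` and the aggregate
    ``mu_i = sum_j a_{j->i} W h_j``.
    """
    logits = phi_q(h_recv) @ phi_k(h_send).T
    a = softmax(logits, axis=-1)
    mu = a @ (h_send @ W)
    return a, mu


def update_coordinates(x: Tensor, m_edge: Tensor, edge_index: np.ndarray, phi_x,
                       epsilon: float = 1e-8, constraint: str = "off",
                       clip_cap: float = 5.0,
                       bonds: np.ndarray | None = None,
                       bond_lengths: np.ndarray | None = None) -> Tensor:
    """Equivariant coordinate update along own-graph edge directions.

    ``x_i <- Psi(x_i + sum_j (x_i - x_j)/||x_i - x_j|| * phi_x(m_{j->i}))``
    with an epsilon-guarded direction for coincident points.  ``Psi`` is the
    geometric constraint: displacement-norm clipping, iterative projection of
    ligand bonded distances toward the reference conformer, or identity.
    """
    n = x.shape[0]
    if edge_index.size == 0:
        return x
    src, dst = edge_index
    diff = x[dst] - x[src]
    d2 = (diff ** 2).sum(axis=-1, keepdims=True)
    direction = diff * ((d2 + epsilon ** 2) ** -0.5)
    step = phi_x(m_edge)  # (E, 1) invariant scalar
    disp_edge = direction * step
    S = Tensor(_sum_agg_matrix(edge_index, n)) @ disp_edge
    if constraint == "clip":
        norm = ((S ** 2).sum(axis=-1, keepdims=True) + epsilon ** 2) ** 0.5
        factor = clip_cap * ad.maximum_const(norm, clip_cap) ** -1.0
        S = S * factor
    x_new = x + S
    if constraint == "ligand-distance-projection" and bonds is not None and len(bonds):
        # Relaxation sweeps pulling each bonded pair halfway toward the
        # reference conformer's bond length (equivariant: moves along the
        # bond direction by an invariant amount).
        bi = np.asarray(bonds, int)
        ref = Tensor(np.asarray(bond_lengths, float).reshape(-1, 1))
        scatter_i = Tensor(_scatter_matrix(bi[:, 0], n))
        scatter_j = Tensor(_scatter_matrix(bi[:, 1], n))
        for _ in range(3):
            d = x_new[bi[:, 1]] - x_new[bi[:, 0]]
            length = ((d ** 2).sum(axis=-1, keepdims=True) + epsilon ** 2) ** 0.5
            corr = d * ((length - ref) / length) * 0.5
            x_new = x_new + scatter_i @ corr - scatter_j @ corr
    return x_new


def _scatter_matrix(indices: np.ndarray, n: int) -> np.ndarray:
    M = np.zeros((n, len(indices)))
    M[indices, np.arange(len(indices))] = 1.0
    return M


def update_features(h: Tensor, m_node: Tensor, mu: Tensor, f: Tensor, phi_h,
                    beta: float) -> Tensor:
    """Convex interpolation ``(1 - beta) h + beta phi_h(h, m, mu, f)``."""
    return h * (1.0 - beta) + phi_h(h, m_node, mu, f) * beta


# ---------------------------------------------------------------------------
# Layer and full encoder modules
# ---------------------------------------------------------------------------

class _EntityLayerParams(Module):
    """phi_e / phi_x / phi_h for one entity class (ligand or protein)."""

    def __init__(self, rng, hidden: int, edge_dim: int):
        self.phi_e = MLP(rng, 2 * hidden + 1 + edge_dim, hidden, hidden)
        self.phi_x = MLP(rng, hidden, hidden, 1)
        self.phi_h = MLP(rng, 4 * hidden, hidden, hidden)

    def phi_e_call(self, hd, hs, d2, fe):
        return self.phi_e(hd, hs, d2, fe)


class EncoderLayer(Module):
    def __init__(self, rng, config: EncoderConfig):
        h, e = config.hidden_dim, config.edge_feature_dim
        self.lig = _EntityLayerParams(rng, h, e)
        self.prot = _EntityLayerParams(rng, h, e)
        self.phi_q = Linear(rng, h, h)
        self.phi_k = Linear(rng, h, h)
        self.W = Tensor(glorot(rng, h, h), requires_grad=True)
        self.config = config

    def _params_for(self, kind: str) -> _EntityLayerParams:
        return self.lig if kind == "lig" else self.prot

    def forward(self, graphs: dict[str, GeometricGraph], h: dict[str, Tensor],
                x: dict[str, Tensor], f0: dict[str, Tensor],
                update_coords: bool = True) -> tuple[dict[str, Tensor], dict[str, Tensor]]:
        cfg = self.config
        kinds = ("lig", "p1", "p2")
        m_edges, m_nodes, mus = {}, {}, {}
        for kind in kinds:
            g = graphs[kind]
            params = self._params_for(kind)
            m_edges[kind], m_nodes[kind] = intra_messages(
                h[kind], x[kind], g.edge_index, g.edge_features, params.phi_e_call)
        for kind in kinds:
            others = [k for k in kinds if k != kind]
            h_send = concatenate([h[k] for k in others], axis=0)
            _, mus[kind] = inter_attention(h[kind], h_send, self.phi_q, self.phi_k, self.W)
        new_h, new_x = {}, {}
        for kind in kinds:
            g = graphs[kind]
            params = self._params_for(kind)
            if update_coords:
                bonds = g.meta.get("bonds") if kind == "lig" else None
                bond_lengths = g.meta.get("bond_lengths") if kind == "lig" else None
                constraint = cfg.constraint_mode
                if constraint == "ligand-distance-projection" and kind != "lig":
                    constraint = "clip"
                new_x[kind] = update_coordinates(
                    x[kind], m_edges[kind], g.edge_index, params.phi_x,
                    epsilon=cfg.epsilon, constraint=constraint, clip_cap=cfg.clip_cap,
                    bonds=bonds, bond_lengths=bond_lengths)
            else:
                new_x[kind] = x[kind]
            new_h[kind] = update_features(h[kind], m_nodes[kind], mus[kind],
                                          f0[kind], params.phi_h, cfg.beta)
        return new_h, new_x


class TernaryEncoder(Module):
    """M alternating intra/inter message-passing layers over the three graphs."""

    def __init__(self, config: EncoderConfig, rng: np.random.Generator):
        self.config = config
        h = config.hidden_dim
        self.lig_in = Linear(rng, LIGAND_FEATURE_DIM, h)
        self.aa_embed = Embedding(rng, len(AA_INDEX), h)
        self.pocket_embed = Tensor(np.zeros(h), requires_grad=True)
        self.layers = [EncoderLayer(rng, config) for _ in range(config.n_layers)]
        if config.share_protein_weights:
            # p1 and p2 share parameters by construction: a single `prot`
            # parameter set per layer serves both graphs.
            pass

    def initial_embeddings(self, graphs: dict[str, GeometricGraph]) -> dict[str, Tensor]:
        out = {}
        for kind, g in graphs.items():
            if kind == "lig":
                feats = np.asarray(g.node_features, float)
                # Scale chemistry counts into a sane numeric range.
                h0 = self.lig_in(Tensor(feats / 10.0))
            else:
                h0 = self.aa_embed(np.asarray(g.node_features, int))
            if g.pocket_mask is not None and g.pocket_mask.any():
                mask = Tensor(np.asarray(g.pocket_mask, float).reshape(-1, 1))
                h0 = h0 + mask * self.pocket_embed.reshape(1, -1)
            out[kind] = h0
        return out

    def forward(self, g_p1: GeometricGraph, g_lig: GeometricGraph,
                g_p2: GeometricGraph) -> EncoderState:
        graphs = {"lig": g_lig, "p1": g_p1, "p2": g_p2}
        f0 = self.initial_embeddings(graphs)
        h = dict(f0)
        x = {kind: Tensor(np.asarray(g.coords, float)) for kind, g in graphs.items()}
        layers_x = []
        for li, layer in enumerate(self.layers):
            h, x = layer.forward(graphs, h, x, f0)
            for kind in ("lig", "p1", "p2"):
                if not np.isfinite(x[kind].data).all() or not np.isfinite(h[kind].data).all():
                    raise NumericError(f"non-finite value in encoder layer {li} ({kind})")
            layers_x.append(dict(x))
        return EncoderState(h=h, x=x, layers_x=layers_x)


def encode_ternary(g_p1: GeometricGraph, g_lig: GeometricGraph, g_p2: GeometricGraph,
                   encoder: TernaryEncoder) -> EncoderState:
    """Run the full encoder; final ligand coordinates are the predicted conformation."""
    return encoder.forward(g_p1, g_lig, g_p2)
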