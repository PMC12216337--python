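"""Prompt-based pocket points decoder (PPPD).

Learned pocket-point queries attend over the encoder's final node
embeddings (tagged with graph-identity embeddings) through N attention
layers; each pocket point is then read out as an attention-weighted convex
combination of one graph's node coordinates, which makes the points
SE(3)-equivariant with their source graph while the whole attention stack
sees no coordinates and is therefore invariant.

Two operating modes:

* ``mgd`` — all four pocket-point query blocks plus the PAE query are
  active; the four point sets are predicted.
* ``protac`` — only the PAE query runs through the decoder; the pocket
  point sets are taken from the unbound structures (protein side) and from
  the encoder's predicted ligand coordinates at the anchor/warhead atom
  indices (ligand side).

The PAE (predicted aligned error, in A) is a single non-negative scalar
used to rank multi-conformer predictions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, concatenate, softmax, softplus
from .errors import ContractError
from .nn import MLP, Linear, Module
from .encoder import EncoderState


@dataclass
class DecoderConfig:
    n_layers: int = 3
    n_heads: int = 1
    n_pocket_points: int = 8   # K: points per pocket set
    hidden_dim: int = 64       # d: must match the encoder hidden dim

    def __post_init__(self):
        if self.n_layers < 1:
            raise ContractError("decoder needs at least one layer")
        if self.n_pocket_points < 3:
            raise ContractError("rigid alignment needs >= 3 pocket points")
        if self.hidden_dim % self.n_heads != 0:
            raise ContractError("hidden_dim must be divisible by n_heads")


@dataclass
class UnboundPockets:
    """Protac-mode pocket inputs with index-aligned correspondences.

    ``anchor_indices``/``warhead_indices`` select ligand atoms;
    ``p1_points``/``p2_points`` are the matching pocket coordinates on the
    E3 ligase (frame of p1) and on the POI (frame of the unbound p2 input),
    row-aligned with the respective index lists.
    """

    anchor_indices: np.ndarray
    warhead_indices: np.ndarray
    p1_points: np.ndarray
    p2_points: np.ndarray

    def __post_init__(self):
        self.anchor_indices = np.asarray(self.anchor_indices, int)
        self.warhead_indices = np.asarray(self.warhead_indices, int)
        self.p1_points = np.asarray(self.p1_points, float)
        self.p2_points = np.asarray(self.p2_points, float)
        if self.p1_points.shape != (len(self.anchor_indices), 3):
            raise ContractError("p1_points must align with anchor_indices")
        if self.p2_points.shape != (len(self.warhead_indices), 3):
            raise ContractError("p2_points must align with warhead_indices")


@dataclass
class PocketPrediction:
    """Pocket point sets and PAE for one forward pass.

    mgd mode populates the four predicted sets (pair 1: ``p_lig`` with
    ``p_p1_lig``; pair 2: ``p_p2`` with ``p_p1_p2``).  protac mode populates
    ``p_p1``/``p_p2`` (from the unbound inputs) and ``p_lig_p1``/``p_lig_p2``
    (encoder ligand coordinates at the anchor/warhead indices).  Entries are
    ``Tensor`` during training and may be plain arrays at inference.
    """

    mode: str
    pae: Tensor
    p_lig: Tensor | None = None
    p_p1_lig: Tensor | None = None
    p_p2: Tensor | None = None
    p_p1_p2: Tensor | None = None
    p_p1: np.ndarray | None = None
    p_lig_p1: Tensor | None = None
    p_lig_p2: Tensor | None = None


class AttentionBlock(Module):
    """Single Attn(Q, K, V) = a(Q, K) W V block with optional multi-head."""

    def __init__(self, rng, dim: int, n_heads: int = 1):
        self.n_heads = n_heads
        self.dim = dim
        self.phi_q = Linear(rng, dim, dim)
        self.phi_k = Linear(rng, dim, dim)
        self.W = Linear(rng, dim, dim)

    def attention_matrix(self, Q: Tensor, K: Tensor) -> Tensor:
        """Head-averaged row-stochastic attention matrix a(Q, K)."""
        if self.n_heads == 1:
            logits = self.phi_q(Q) @ self.phi_k(K).T
            return softmax(logits, axis=-1)
        H, dh = self.n_heads, self.dim // self.n_heads
        q = self.phi_q(Q).reshape(-1, H, dh).transpose(1, 0, 2)
        k = self.phi_k(K).reshape(-1, H, dh).transpose(1, 2, 0)
        a = softmax(q @ k, axis=-1)        # (H, nq, nk)
        return a.sum(axis=0) * (1.0 / H)

    def __call__(self, Q: Tensor, K: Tensor, V: Tensor) -> Tensor:
        if self.n_heads == 1:
            return self.attention_matrix(Q, K) @ self.W(V)
        H, dh = self.n_heads, self.dim // self.n_heads
        q = self.phi_q(Q).reshape(-1, H, dh).transpose(1, 0, 2)
        k = self.phi_k(K).reshape(-1, H, dh).transpose(1, 2, 0)
        a = softmax(q @ k, axis=-1)
        v = self.W(V).reshape(-1, H, dh).transpose(1, 0, 2)
        out = (a @ v).transpose(1, 0, 2).reshape(-1, self.dim)
        return out


class FeedForward(Module):
    """phi of Eqs. (11)/(13): two-layer feed-forward with residual."""

    def __init__(self, rng, dim: int):
        self.mlp = MLP(rng, dim, dim, dim)

    def __call__(self, x: Tensor) -> Tensor:
        return x + self.mlp(x)


class DecoderLayer(Module):
    def __init__(self, rng, config: DecoderConfig):
        d, H = config.hidden_dim, config.n_heads
        self.self_attn = AttentionBlock(rng, d, H)
        self.cross_attn = AttentionBlock(rng, d, H)
        self.back_attn = AttentionBlock(rng, d, H)
        self.phi = FeedForward(rng, d)

    def forward(self, Q: Tensor, Hm: Tensor) -> tuple[Tensor, Tensor]:
        # Residual connections around every attention step: pure soft
        # attention is an averaging operator, and without the skip paths
        # the pocket-point queries collapse onto a single row (a symmetric
        # fixed point gradient descent cannot leave).
        Q = Q + self.self_attn(Q, Q, Q)
        Qp = self.phi(Q + self.cross_attn(Q, Hm, Hm))
        Hp = Hm + self.back_attn(Hm, Qp, Qp)
        return Qp, Hp


class PocketDecoder(Module):
    def __init__(self, config: DecoderConfig, rng: np.random.Generator):
        self.config = config
        d, K = config.hidden_dim, config.n_pocket_points
        scale = 1.0 / np.sqrt(d)
        self.q_lig = Tensor(rng.normal(0, scale, (K, d)), requires_grad=True)
        self.q_p1_lig = Tensor(rng.normal(0, scale, (K, d)), requires_grad=True)
        self.q_p2 = Tensor(rng.normal(0, scale, (K, d)), requires_grad=True)
        self.q_p1_p2 = Tensor(rng.normal(0, scale, (K, d)), requires_grad=True)
        self.q_pae = Tensor(rng.normal(0, scale, (1, d)), requires_grad=True)
        self.e_lig = Tensor(rng.normal(0, scale, (1, d)), requires_grad=True)
        self.e_p1 = Tensor(rng.normal(0, scale, (1, d)), requires_grad=True)
        self.e_p2 = Tensor(rng.normal(0, scale, (1, d)), requires_grad=True)
        self.layers = [DecoderLayer(rng, config) for _ in range(config.n_layers)]
        self.readout_attn = AttentionBlock(rng, d, config.n_heads)
        self.readout_phi = FeedForward(rng, d)
        # One extraction attention per pocket set: each set needs its own
        # attention geometry over its source graph.
        self.extract_attns = [AttentionBlock(rng, d, 1) for _ in range(4)]
        self.pae_head = MLP(rng, d, d, 1)

    # -- building blocks ------------------------------------------------------
    def keyed_embeddings(self, state: EncoderState) -> tuple[Tensor, dict[str, int]]:
        """Concatenate node embeddings, each summed with its graph-identity tag."""
        parts = [state.h["lig"] + self.e_lig, state.h["p1"] + self.e_p1,
                 state.h["p2"] + self.e_p2]
        sizes = {k: state.h[k].shape[0] for k in ("lig", "p1", "p2")}
        return concatenate(parts, axis=0), sizes

    def run_layers(self, Q: Tensor, Hm: Tensor) -> tuple[Tensor, Tensor]:
        for layer in self.layers:
            Q, Hm = layer.forward(Q, Hm)
        Qpp = self.readout_phi(Q + self.readout_attn(Q, Hm, Hm))
        return Qpp, Hm

    def extract_pocket_points(self, Q_block: Tensor, H_block: Tensor,
                              X_block: Tensor, which: int = 0) -> Tensor:
        """Pocket points as convex combinations of one graph's coordinates."""
        a = self.extract_attns[which].attention_matrix(Q_block, H_block)
        return a @ X_block

    def predict_pae(self, q_row: Tensor) -> Tensor:
        """Non-negative scalar confidence (A) from the decoded PAE query row."""
        return softplus(self.pae_head(q_row)).sum()

    # -- full decode ----------------------------------------------------------
    def decode(self, mode: str, state: EncoderState,
               unbound: UnboundPockets | None = None) -> PocketPrediction:
        K = self.config.n_pocket_points
        if mode == "mgd":
            Q = concatenate([self.q_lig, self.q_p1_lig, self.q_p2, self.q_p1_p2,
                             self.q_pae], axis=0)
            Hm, sizes = self.keyed_embeddings(state)
            Qpp, Hp = self.run_layers(Q, Hm)
            # Unfold Q'' into the four K-row blocks + the PAE row, and H' into
            # the three graphs' node blocks.
            q_lig, q_p1_lig = Qpp[0:K], Qpp[K:2 * K]
            q_p2, q_p1_p2 = Qpp[2 * K:3 * K], Qpp[3 * K:4 * K]
            q_pae = Qpp[4 * K:4 * K + 1]
            n_lig, n_p1 = sizes["lig"], sizes["p1"]
            h_lig = Hp[0:n_lig]
            h_p1 = Hp[n_lig:n_lig + n_p1]
            h_p2 = Hp[n_lig + n_p1:]
            return PocketPrediction(
                mode="mgd",
                pae=self.predict_pae(q_pae),
                p_lig=self.extract_pocket_points(q_lig, h_lig, state.x["lig"], 0),
                p_p1_lig=self.extract_pocket_points(q_p1_lig, h_p1, state.x["p1"], 1),
                p_p2=self.extract_pocket_points(q_p2, h_p2, state.x["p2"], 2),
                p_p1_p2=self.extract_pocket_points(q_p1_p2, h_p1, state.x["p1"], 3),
            )
        if mode == "protac":
            if unbound is None:
                raise ContractError("protac mode requires unbound pocket point sets")
            Hm, _ = self.keyed_embeddings(state)
            Qpp, _ = self.run_layers(self.q_pae, Hm)
            lig_x = state.x["lig"]
            return PocketPrediction(
                mode="protac",
                pae=self.predict_pae(Qpp[0:1]),
                p_p1=unbound.p1_points,
                p_p2=unbound.p2_points,
                p_lig_p1=lig_x[unbound.anchor_indices],
                p_lig_p2=lig_x[unbound.warhead_indices],
            )
        raise ContractError(f"unknown mode {mode!r}")


class NaivePocketDecoder(Module):
    """Ablation baseline: pocket points from top-attended encoder nodes.

    Scores every node with a learned linear map of its final embedding and
    emits, per pocket set, the coordinates of the K highest-scoring nodes of
    the source graph (softmax-weighted so the op stays differentiable).
    """

    def __init__(self, config: DecoderConfig, rng: np.random.Generator):
        self.config = config
        d, K = config.hidden_dim, config.n_pocket_points
        self.scorers = [Linear(rng, d, K) for _ in range(4)]
        self.pae_head = MLP(rng, d, d, 1)

    def decode(self, mode: str, state: EncoderState,
               unbound: UnboundPockets | None = None) -> PocketPrediction:
        if mode != "mgd":
            raise ContractError("naive decoder supports mgd mode only")

        def points(scorer, kind):
            w = softmax(scorer(state.h[kind]).T, axis=-1)  # (K, n)
            return w @ state.x[kind]

        pooled = concatenate([state.h[k].mean(axis=0, keepdims=True)
                              for k in ("lig", "p1", "p2")], axis=0).mean(axis=0, keepdims=True)
        return PocketPrediction(
            mode="mgd",
            pae=softplus(self.pae_head(pooled)).sum(),
            p_lig=points(self.scorers[0], "lig"),
            p_p1_lig=points(self.scorers[1], "p1"),
            p_p2=points(self.scorers[2], "p2"),
            p_p1_p2=points(self.scorers[3], "p1"),
        )
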