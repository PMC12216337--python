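"""Encoder layer primitives against hand evaluation; equivariance contracts."""

from dataclasses import replace

import numpy as np
import pytest

from ternadock.autodiff import Tensor
from ternadock.encoder import (EncoderConfig, TernaryEncoder, encode_ternary,
                               inter_attention, intra_messages,
                               update_coordinates, update_features)
from ternadock.featurize import FeaturizerConfig, build_ligand_graph, build_protein_graph
from ternadock.geometry import random_rigid_transform
from ternadock.nn import Linear
from ternadock.training import TernaryModel


def _graphs(record, feat_config):
    return {
        "lig": build_ligand_graph(record.ligand, feat_config),
        "p1": build_protein_graph(record.p1, feat_config, kind="p1"),
        "p2": build_protein_graph(record.p2, feat_config, kind="p2"),
    }


class TestPrimitives:
    def test_isolated_node_gets_zero_mean_message(self):
        h = Tensor(np.ones((3, 4)))
        x = Tensor(np.zeros((3, 3)))
        edges = np.array([[1], [2]])  # only node 2 receives
        phi = lambda hd, hs, d2, fe: hd  # constant stub
        _, m = intra_messages(h, x, edges, np.zeros((1, 2)), phi)
        assert np.allclose(m.data[0], 0.0)
        assert np.allclose(m.data[1], 0.0)
        assert np.allclose(m.data[2], 1.0)

    def test_three_node_path_mean_matches_hand_computation(self):
        # stub phi returns the sender embedding; node 1 receives from 0 and 2.
        h = Tensor(np.array([[1.0], [10.0], [5.0]]))
        x = Tensor(np.array([[0.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0]]))
        edges = np.array([[0, 2, 1, 1], [1, 1, 0, 2]])
        phi = lambda hd, hs, d2, fe: hs
        _, m = intra_messages(h, x, edges, np.zeros((4, 2)), phi)
        assert m.data[1] == pytest.approx((1.0 + 5.0) / 2)
        assert m.data[0] == pytest.approx(10.0)
        assert m.data[2] == pytest.approx(10.0)

    def test_attention_weights_from_closed_form_logits(self):
        # two senders with logits (0, ln 3) -> weights (0.25, 0.75)
        h_recv = Tensor(np.array([[1.0]]))
        h_send = Tensor(np.array([[0.0], [np.log(3.0)]]))
        ident = lambda t: t
        W = Tensor(np.array([[2.0]]))
        a, mu = inter_attention(h_recv, h_send, ident, ident, W)
        assert np.allclose(a.data, [[0.25, 0.75]])
        assert mu.data[0, 0] == pytest.approx(0.25 * 0.0 + 0.75 * np.log(3.0) * 2.0)

    def test_attention_rows_always_sum_to_one(self):
        rng = np.random.default_rng(0)
        h_recv = Tensor(rng.normal(size=(5, 8)))
        h_send = Tensor(rng.normal(size=(9, 8)))
        lin_q = Linear(rng, 8, 8)
        lin_k = Linear(rng, 8, 8)
        a, _ = inter_attention(h_recv, h_send, lin_q, lin_k,
                               Tensor(np.eye(8)))
        assert np.allclose(a.data.sum(axis=1), 1.0)

    def test_coordinate_update_zero_phi_is_identity(self):
        x = Tensor(np.array([[0.0, 0, 0], [2.0, 0, 0]]))
        edges = np.array([[0, 1], [1, 0]])
        m = Tensor(np.ones((2, 4)))
        zero_col = lambda m_: m_.sum(axis=-1, keepdims=True) * 0.0
        out = update_coordinates(x, m, edges, zero_col, constraint="off")
        assert np.allclose(out.data, x.data)

    def test_two_nodes_on_axis_move_apart_by_phi_scalar(self):
        x = Tensor(np.array([[0.0, 0, 0], [2.0, 0, 0]]))
        edges = np.array([[0, 1], [1, 0]])
        m = Tensor(np.ones((2, 1)))
        s = 0.3
        out = update_coordinates(x, m, edges, lambda m_: m_ * 0.0 + s,
                                 constraint="off")
        # each node moves away from its neighbor along x by s
        assert out.data[0, 0] == pytest.approx(-s)
        assert out.data[1, 0] == pytest.approx(2.0 + s)

    def test_clip_constraint_bounds_displacement(self):
        x = Tensor(np.array([[0.0, 0, 0], [2.0, 0, 0]]))
        edges = np.array([[0, 1], [1, 0]])
        m = Tensor(np.ones((2, 1)))
        out = update_coordinates(x, m, edges, lambda m_: m_ * 0.0 + 100.0,
                                 constraint="clip", clip_cap=1.5)
        assert np.abs(out.data - x.data).max() <= 1.5 + 1e-9

    @pytest.mark.parametrize("beta,factor", [(0.0, 1.0), (1.0, 2.0), (0.5, 1.5)])
    def test_feature_interpolation(self, beta, factor):
        h = Tensor(np.full((3, 2), 4.0))
        stub = lambda *args: args[0] * 2.0  # phi_h returns 2h
        out = update_features(h, h, h, h, stub, beta)
        assert np.allclose(out.data, 4.0 * factor)


class TestFullEncoder:
    def _active_model(self, seed=1):
        model = TernaryModel.build(EncoderConfig(n_layers=2, hidden_dim=16),
                                   __import__("ternadock.decoder", fromlist=["DecoderConfig"]).DecoderConfig(
                                       n_layers=1, hidden_dim=16), seed=seed)
        return model

    def test_global_rigid_transform_equivariance(self, complex_and_truth,
                                                 tiny_model, feat_config):
        record, _ = complex_and_truth
        graphs = _graphs(record, feat_config)
        state = encode_ternary(graphs["p1"], graphs["lig"], graphs["p2"],
                               tiny_model.encoder)
        tr = random_rigid_transform(np.random.default_rng(5))
        moved = {k: replace(g, coords=tr.apply(g.coords)) for k, g in graphs.items()}
        state2 = encode_ternary(moved["p1"], moved["lig"], moved["p2"],
                                tiny_model.encoder)
        for kind in graphs:
            scale = max(1.0, np.abs(state.x[kind].data).max())
            assert np.abs(state2.x[kind].data
                          - tr.apply(state.x[kind].data)).max() / scale < 1e-4
            assert np.abs(state2.h[kind].data - state.h[kind].data).max() < 1e-8

    def test_independent_per_graph_equivariance(self, complex_and_truth,
                                                tiny_model, feat_config):
        record, _ = complex_and_truth
        graphs = _graphs(record, feat_config)
        state = encode_ternary(graphs["p1"], graphs["lig"], graphs["p2"],
                               tiny_model.encoder)
        rng = np.random.default_rng(6)
        trs = {k: random_rigid_transform(rng) for k in graphs}
        moved = {k: replace(g, coords=trs[k].apply(g.coords))
                 for k, g in graphs.items()}
        state2 = encode_ternary(moved["p1"], moved["lig"], moved["p2"],
                                tiny_model.encoder)
        for kind in graphs:
            scale = max(1.0, np.abs(state.x[kind].data).max())
            assert np.abs(state2.x[kind].data
                          - trs[kind].apply(state.x[kind].data)).max() / scale < 1e-4
            assert np.abs(state2.h[kind].data - state.h[kind].data).max() < 1e-8

    def test_protein_weight_sharing_exposes_same_parameter_objects(self, tiny_model):
        for layer in tiny_model.encoder.layers:
            assert layer._params_for("p1") is layer._params_for("p2")
            assert layer._params_for("lig") is not layer._params_for("p1")

    def test_zeroed_mlps_make_encoder_identity_on_coordinates(
            self, complex_and_truth, feat_config):
        record, _ = complex_and_truth
        model = TernaryModel.build(
            EncoderConfig(n_layers=2, hidden_dim=16),
            __import__("ternadock.decoder", fromlist=["DecoderConfig"]).DecoderConfig(
                n_layers=1, hidden_dim=16), seed=3)
        model.encoder.zero_all()
        graphs = _graphs(record, feat_config)
        state = encode_ternary(graphs["p1"], graphs["lig"], graphs["p2"],
                               model.encoder)
        for kind in graphs:
            assert np.allclose(state.x[kind].data, graphs[kind].coords)

    def test_permutation_equivariance_of_protein_nodes(self, complex_and_truth,
                                                       tiny_model, feat_config):
        record, _ = complex_and_truth
        graphs = _graphs(record, feat_config)
        state = encode_ternary(graphs["p1"], graphs["lig"], graphs["p2"],
                               tiny_model.encoder)
        rng = np.random.default_rng(9)
        perm = rng.permutation(graphs["p2"].n_nodes)
        g2 = graphs["p2"]
        remap = np.argsort(perm)  # old index -> new position
        permuted = replace(
            g2,
            node_features=g2.node_features[perm],
            coords=g2.coords[perm],
            edge_index=remap[g2.edge_index],
            edge_features=g2.edge_features,
        )
        state2 = encode_ternary(graphs["p1"], graphs["lig"], permuted,
                                tiny_model.encoder)
        assert np.allclose(state2.x["p2"].data, state.x["p2"].data[perm], atol=1e-8)
        assert np.allclose(state2.h["p2"].data, state.h["p2"].data[perm], atol=1e-8)
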