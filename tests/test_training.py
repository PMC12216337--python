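"""Loss-term correctness (oracles + closed forms) and training-loop behavior."""

import itertools

import numpy as np
import pytest

from ternadock.autodiff import Tensor
from ternadock.decoder import DecoderConfig
from ternadock.encoder import EncoderConfig
from ternadock.errors import ContractError
from ternadock.geometry import random_rigid_transform, rmsd
from ternadock.nn import Adam
from ternadock.training import (TernaryModel, TrainConfig, forward_losses,
                                intersection_loss, kabsch_aligned_loss,
                                ligand_coord_loss, ot_pocket_loss, pae_loss,
                                paired_ot_loss, total_loss, train_overfit,
                                training_step, _conformer_pool)


class TestLigandLosses:
    def test_zero_at_truth_and_closed_form_offset(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(9, 3))
        assert float(ligand_coord_loss(x, x).data) == 0.0
        off = x + np.array([1.0, 0.0, 0.0])
        assert float(ligand_coord_loss(off, x).data) == pytest.approx(1.0)

    def test_monotone_in_offset_magnitude(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(6, 3))
        vals = [float(ligand_coord_loss(x + d, x).data) for d in (0.5, 1.0, 2.0)]
        assert vals[0] < vals[1] < vals[2]

    def test_shape_mismatch_raises(self):
        with pytest.raises(ContractError):
            ligand_coord_loss(np.zeros((3, 3)), np.zeros((4, 3)))

    def test_kabsch_loss_invariant_to_rigid_motion_of_pred(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(8, 3)) * 4
        tr = random_rigid_transform(rng)
        assert float(kabsch_aligned_loss(tr.apply(x), x).data) < 1e-16

    def test_kabsch_loss_never_exceeds_coord_loss(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            x = rng.normal(size=(7, 3)) * 3
            y = x + rng.normal(size=(7, 3))
            assert float(kabsch_aligned_loss(y, x).data) <= \
                float(ligand_coord_loss(y, x).data) + 1e-12

    def test_kabsch_loss_matches_rotation_grid_oracle(self):
        from test_geometry import brute_force_rotation_rmsd
        rng = np.random.default_rng(4)
        x = rng.normal(size=(5, 3)) * 3
        y = x.copy()
        y[0] += [1.0, -0.5, 0.2]
        exact = float(kabsch_aligned_loss(y, x).data)
        grid = brute_force_rotation_rmsd(y, x, step_deg=2.0) ** 2 * 1.0
        assert grid >= exact - 1e-9
        assert grid - exact < 0.05 * max(0.1, exact)


class TestOTLosses:
    def test_zero_for_identical_and_permuted_sets(self):
        rng = np.random.default_rng(5)
        pts = rng.normal(size=(6, 3))
        assert float(ot_pocket_loss(pts, pts).data) == 0.0
        perm = rng.permutation(6)
        assert float(ot_pocket_loss(pts[perm], pts).data) < 1e-18

    def test_two_point_toy_matches_enumeration(self):
        pred = np.array([[0.0, 0, 0], [1.0, 0, 0]])
        true = np.array([[1.0, 0, 0], [0.0, 0, 1.0]])
        # matchings: identity cost (1 + 2)/2, swap cost (1 + 0)/2 = 0.5
        assert float(ot_pocket_loss(pred, true).data) == pytest.approx(0.5)

    @pytest.mark.parametrize("k", [3, 4, 5, 6])
    def test_matches_exhaustive_assignment_oracle(self, k):
        rng = np.random.default_rng(k)
        pred = rng.normal(size=(k, 3))
        true = rng.normal(size=(k, 3))
        got = float(ot_pocket_loss(pred, true).data)
        best = min(
            np.mean([((pred[i] - true[p[i]]) ** 2).sum() for i in range(k)])
            for p in itertools.permutations(range(k)))
        assert got == pytest.approx(best)

    def test_size_mismatch_raises(self):
        with pytest.raises(ContractError):
            ot_pocket_loss(np.zeros((3, 3)), np.zeros((4, 3)))

    def test_paired_ot_uses_one_consistent_assignment(self):
        # pred_a prefers the identity matching, pred_b the swap; the joint
        # assignment picks one matching for both rather than the per-set optima
        ta = np.array([[0.0, 0, 0], [10.0, 0, 0]])
        tb = np.array([[0.0, 5, 0], [10.0, 5, 0]])
        pred_a = ta.copy()                      # identity perfect for a
        pred_b = tb[::-1].copy()                # swap perfect for b
        joint = float(paired_ot_loss(pred_a, pred_b, ta, tb).data)
        sep = (float(ot_pocket_loss(pred_a, ta).data)
               + float(ot_pocket_loss(pred_b, tb).data))
        assert joint >= sep
        assert joint == pytest.approx(100.0)  # one of the two must pay the swap


class TestIntersectionAndPAE:
    def test_separated_entities_have_zero_penalty(self):
        a = np.zeros((4, 3))
        b = np.zeros((5, 3)) + 100.0
        assert float(intersection_loss(a, b, 4.0).data) == 0.0

    def test_single_pair_at_half_clearance_closed_form(self):
        c = 4.0
        a = np.zeros((1, 3))
        b = np.array([[c / 2, 0.0, 0.0]])
        assert float(intersection_loss(a, b, c).data) == pytest.approx((c / 2) ** 2)

    def test_non_increasing_as_entities_separate(self):
        rng = np.random.default_rng(6)
        a = rng.normal(size=(5, 3))
        b = rng.normal(size=(5, 3))
        vals = [float(intersection_loss(a, b + np.array([d, 0, 0]), 4.0).data)
                for d in (0.0, 2.0, 5.0, 10.0)]
        assert all(x >= y for x, y in zip(vals, vals[1:]))

    def test_pae_loss_closed_forms(self):
        p2 = np.zeros((6, 3))
        off = p2 + np.array([1.0, 0, 0])   # RMSD exactly 1
        assert float(pae_loss(Tensor(np.array(1.0)), off, p2).data) == pytest.approx(0.0)
        assert float(pae_loss(Tensor(np.array(2.0)), p2, p2).data) == pytest.approx(2.0)
        assert float(pae_loss(Tensor(np.array(0.25)), off, p2).data) == pytest.approx(0.75)


class TestTotalAndStep:
    def test_total_is_exact_sum_of_terms(self):
        terms = {k: Tensor(np.array(v)) for k, v in zip(
            ("l_lig", "l_kabsch_lig", "l_ot1", "l_ot2", "l_intersection", "l_pae"),
            (1.0, 0.5, 0.25, 0.125, 2.0, 0.1))}
        total, breakdown = total_loss(terms)
        assert float(total.data) == pytest.approx(4.0 - 0.025)
        assert breakdown.total == pytest.approx(float(total.data))

    def test_gradient_reaches_encoder_and_decoder(self, complex_and_truth,
                                                  tiny_model):
        record, gt = complex_and_truth
        cfg = TrainConfig(steps=1, swap_probability=0.0)
        total, _ = forward_losses(tiny_model, record, gt, cfg,
                                  np.random.default_rng(0), mode="mgd",
                                  pool=_conformer_pool(record, 1))
        total.backward()
        enc_norm = sum(float((p.grad ** 2).sum())
                       for p in tiny_model.encoder.parameters()
                       if p.grad is not None)
        dec_norm = sum(float((p.grad ** 2).sum())
                       for p in tiny_model.decoder.parameters()
                       if p.grad is not None)
        assert enc_norm > 0
        assert dec_norm > 0

    def test_same_seed_reproduces_loss_trajectory(self, complex_and_truth):
        record, gt = complex_and_truth
        histories = []
        for _ in range(2):
            model = TernaryModel.build(EncoderConfig(n_layers=1, hidden_dim=8),
                                       DecoderConfig(n_layers=1, hidden_dim=8,
                                                     n_pocket_points=4), seed=2)
            cfg = TrainConfig(steps=5, seed=3, learning_rate=1e-3)
            histories.append([h.total for h in train_overfit(model, record, gt, cfg)])
        assert histories[0] == histories[1]

    def test_swap_probability_zero_never_exchanges_proteins(self, complex_and_truth,
                                                            monkeypatch):
        record, gt = complex_and_truth
        import ternadock.training as T
        calls = []
        orig = T._oriented

        def spy(record_, gt_, swapped):
            calls.append(swapped)
            return orig(record_, gt_, swapped)

        monkeypatch.setattr(T, "_oriented", spy)
        model = TernaryModel.build(EncoderConfig(n_layers=1, hidden_dim=8),
                                   DecoderConfig(n_layers=1, hidden_dim=8,
                                                 n_pocket_points=4), seed=4)
        cfg = TrainConfig(steps=6, swap_probability=0.0, learning_rate=1e-3)
        train_overfit(model, record, gt, cfg)
        assert calls and not any(calls)


@pytest.mark.slow
class TestTinyOverfit:
    def test_loss_reduction_and_interface_recovery(self, complex_and_truth):
        from ternadock.training import train_overfit_best_of, _safe_kabsch
        from ternadock.featurize import (FeaturizerConfig, build_ligand_graph,
                                         build_protein_graph)
        record, gt = complex_and_truth
        cfg = TrainConfig(learning_rate=5e-3, steps=500, seed=17,
                          swap_probability=0.0, lr_halflife_steps=150,
                          average_from_step=350)
        model, history = train_overfit_best_of(
            record, gt, EncoderConfig(n_layers=2, hidden_dim=16),
            DecoderConfig(n_layers=1, hidden_dim=16), cfg, n_restarts=3)
        first = history[0].total
        last = np.mean([h.total for h in history[-20:]])
        assert last < 0.1 * first

        fc = FeaturizerConfig()
        center = gt.native_p1_ca.mean(axis=0)
        p1_n = gt.native_p1_ca - center
        p2_nat = gt.native_p2_ca - center
        rng = np.random.default_rng(99)
        trl = random_rigid_transform(rng, 5.0)
        trp = random_rigid_transform(rng, 5.0)
        state = model.encoder.forward(
            build_protein_graph(record.p1.with_coords(p1_n), fc, "p1"),
            build_ligand_graph(record.ligand.with_coords(
                trl.apply(gt.native_lig - gt.native_lig.mean(axis=0))), fc),
            build_protein_graph(record.p2.with_coords(trp.apply(p2_nat)), fc, "p2"))
        pk = model.decoder.decode("mgd", state)
        tr2 = _safe_kabsch(pk.p_p2.data, pk.p_p1_p2.data)
        p2_assembled = tr2.apply(trp.apply(p2_nat))
        iface = gt.p2_interface_residues
        assert rmsd(p2_assembled[iface], p2_nat[iface]) < 1.0
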