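"""Soft partitions, reconstruction, discriminators and the JSD objective."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from submdta._autograd import Parameter, Tensor
from submdta.graph_encoder import encode_graph_batch, graph_readout
from submdta.mol_io import smiles_to_graph
from submdta.substructure_contrast import (PretrainConfig, PretrainModel,
                                           compute_assignment,
                                           cosine_similarity,
                                           discriminator_score, jsd_mi,
                                           pretrain, pretrain_step,
                                           reconstruct_batch, split_soft,
                                           subgraph_readout)
from submdta._autograd import Adam


class TestAssignment:
    def test_zero_projection_gives_uniform_split(self, rng):
        nodes = rng.normal(size=(5, 4))
        A = compute_assignment(nodes, np.zeros((4, 2))).A
        assert np.allclose(A.data, 0.5)

    def test_single_node_logits_one_zero(self):
        # node features [1, 0] with identity projection -> softmax(1, 0)
        A = compute_assignment(np.array([[1.0, 0.0]]), np.eye(2)).A
        assert np.allclose(A.data, [[0.7311, 0.2689]], atol=1e-4)

    def test_rows_sum_to_one(self, rng):
        nodes = rng.normal(size=(9, 6))
        A = compute_assignment(nodes, rng.normal(size=(6, 2))).A
        assert np.allclose(A.data.sum(axis=1), 1.0, atol=1e-6)

    def test_width_mismatch_rejected(self):
        with pytest.raises(ValueError, match="width"):
            compute_assignment(np.ones((3, 4)), np.ones((5, 2)))


class TestSplitSoft:
    @pytest.mark.parametrize("T,expected_S", [(0, 1), (1, 2), (2, 4)])
    def test_mask_count_is_two_to_the_T(self, T, expected_S, rng):
        nodes = rng.normal(size=(6, 4))
        Ws = [rng.normal(size=(4, 2)) for _ in range(2 ** T)]
        part = split_soft(nodes, T, Ws)
        assert part.S == expected_S

    def test_zero_rounds_single_full_mask(self, rng):
        part = split_soft(rng.normal(size=(4, 3)), 0, [])
        assert np.allclose(part.masks[0].data, 1.0)

    @pytest.mark.parametrize("T", [1, 2, 3])
    def test_per_node_masks_sum_to_one(self, T, rng):
        nodes = rng.normal(size=(8, 5))
        Ws = [rng.normal(size=(5, 2)) for _ in range(2 ** T - 1)]
        part = split_soft(nodes, T, Ws)
        total = sum(m.data for m in part.masks)
        assert np.allclose(total, 1.0, atol=1e-6)

    def test_negative_rounds_rejected(self, rng):
        with pytest.raises(ValueError):
            split_soft(rng.normal(size=(3, 2)), -1, [])

    def test_hard_masks_are_binary_partition(self, rng):
        nodes = rng.normal(size=(7, 4))
        Ws = [rng.normal(size=(4, 2))]
        part = split_soft(nodes, 1, Ws, hard=True)
        stacked = np.stack([m.data for m in part.masks])
        assert set(np.unique(stacked)) <= {0.0, 1.0}
        assert np.allclose(stacked.sum(axis=0), 1.0)


class TestSubgraphReadout:
    def test_full_mask_equals_graph_readout(self, rng):
        m = rng.normal(size=(5, 3))
        assert np.allclose(subgraph_readout(m, np.ones(5)).data,
                           graph_readout(m).data)

    def test_zero_mask_gives_zero(self, rng):
        assert np.allclose(subgraph_readout(rng.normal(size=(4, 3)),
                                            np.zeros(4)).data, 0.0)

    def test_complementary_masks_sum_to_full_readout(self, rng):
        m = rng.normal(size=(6, 4))
        mask = rng.uniform(size=6)
        total = subgraph_readout(m, mask).data + subgraph_readout(m, 1 - mask).data
        assert np.allclose(total, graph_readout(m).data, atol=1e-12)

    def test_length_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            subgraph_readout(rng.normal(size=(4, 3)), np.ones(5))


class TestCosineSimilarity:
    def test_identical_vectors(self):
        assert cosine_similarity([1.0, 2.0], [1.0, 2.0]) == pytest.approx(1.0)

    def test_orthogonal_vectors(self):
        assert cosine_similarity([1.0, 0.0], [0.0, 3.0]) == pytest.approx(0.0)

    def test_forty_five_degrees(self):
        assert cosine_similarity([1.0, 0.0], [1.0, 1.0]) == pytest.approx(0.7071, abs=1e-4)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            cosine_similarity([0.0, 0.0], [1.0, 0.0])


class TestReconstructBatch:
    def test_identical_graphs_reproduce_kernel_aggregation(self):
        subs = [Tensor(np.array([1.0, 2.0])), Tensor(np.array([3.0, -1.0]))]
        batch = [list(subs), list(subs)]  # two identical graphs
        kernel = np.array([0.5, 2.0])
        recon = reconstruct_batch(batch, kernel)
        expected = 0.5 * subs[0].data + 2.0 * subs[1].data
        for r in recon:
            assert np.allclose(r.embedding.data, expected, atol=1e-12)

    def test_half_of_two_slots_replaced(self, rng):
        batch = [[Tensor(rng.normal(size=4)) for _ in range(2)] for _ in range(3)]
        for r in reconstruct_batch(batch, np.ones(2)):
            assert len(r.replaced_indices) == 1  # ceil(2/2)

    def test_engineered_near_duplicate_selected_as_donor(self):
        e = np.eye(4)
        batch = [
            [Tensor(e[0]), Tensor(e[1])],
            [Tensor(e[2]), Tensor(e[0] + 0.01 * e[3])],  # near-duplicate of (0,0)
            [Tensor(e[3]), Tensor(-e[2])],
        ]
        recon = reconstruct_batch(batch, np.ones(2))
        # graph 1's most cross-similar slot is slot 1, whose best donor is (0, 0)
        assert recon[1].replaced_indices == (1,)
        assert recon[1].donor_ids == ((0, 0),)

    def test_donor_never_self(self, rng):
        batch = [[Tensor(rng.normal(size=3)) for _ in range(4)] for _ in range(4)]
        for g, r in enumerate(reconstruct_batch(batch, np.ones(4))):
            assert all(dg != g for dg, _ in r.donor_ids)

    def test_singleton_batch_rejected(self, rng):
        with pytest.raises(ValueError):
            reconstruct_batch([[Tensor(rng.normal(size=3))]], np.ones(1))


class TestDiscriminator:
    def test_zero_form_scores_zero(self, rng):
        s = discriminator_score(rng.normal(size=5), rng.normal(size=5),
                                np.zeros((5, 5)))
        assert s.item() == 0.0

    def test_identity_form_is_dot_product(self, rng):
        u, v = rng.normal(size=5), rng.normal(size=5)
        assert discriminator_score(u, v, np.eye(5)).item() == pytest.approx(u @ v)

    def test_basis_vectors_select_matrix_entry(self, rng):
        omega = rng.normal(size=(4, 4))
        e1, e2 = np.eye(4)[0], np.eye(4)[1]
        assert discriminator_score(e1, e2, omega).item() == pytest.approx(omega[0, 1])

    def test_dimension_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            discriminator_score(np.ones(3), np.ones(4), np.eye(4))


class TestJsdMi:
    def test_zero_scores_give_minus_two_log_two(self):
        assert jsd_mi([0.0], [0.0]).item() == pytest.approx(-2 * np.log(2))

    def test_saturated_scores_approach_zero(self):
        assert abs(jsd_mi([40.0], [-40.0]).item()) < 1e-10

    def test_empty_lists_rejected(self):
        with pytest.raises(ValueError):
            jsd_mi([], [0.0])
        with pytest.raises(ValueError):
            jsd_mi([0.0], [])

    @given(st.lists(st.floats(-30, 30), min_size=1, max_size=6),
           st.lists(st.floats(-30, 30), min_size=1, max_size=6))
    @settings(max_examples=60, deadline=None)
    def test_always_negative(self, pos, neg):
        assert jsd_mi(pos, neg).item() < 0

    def test_monotone_in_scores(self, rng):
        pos = rng.normal(size=4).tolist()
        neg = rng.normal(size=4).tolist()
        base = jsd_mi(pos, neg).item()
        bumped = list(pos)
        bumped[2] += 0.5
        assert jsd_mi(bumped, neg).item() > base  # increasing in positives
        dropped = list(neg)
        dropped[1] += 0.5
        assert jsd_mi(pos, dropped).item() < base  # decreasing in negatives


def _tiny_model(seed=0, **kw):
    cfg = PretrainConfig(hidden_dim=12, n_layers=2, T=1, batch_size=8,
                         epochs=2, seed=seed, **kw)
    return PretrainModel(cfg), cfg


class TestPretrainStep:
    def test_subgraph_only_flag(self, fixture_molecules):
        model, cfg = _tiny_model(loss_graph=False)
        opt = Adam(model.parameters(), lr=1e-3)
        res = pretrain_step(fixture_molecules[:6], model, opt)
        assert res.mi_reconstructed is None
        assert res.loss == pytest.approx(-res.mi_subgraph)

    def test_mi_terms_nonpositive(self, fixture_molecules):
        model, _ = _tiny_model()
        opt = Adam(model.parameters(), lr=1e-3)
        res = pretrain_step(fixture_molecules[:6], model, opt)
        assert res.mi_subgraph <= 0 and res.mi_reconstructed <= 0
        assert res.loss == pytest.approx(-(res.mi_subgraph + res.mi_reconstructed))

    def test_both_flags_disabled_rejected(self):
        with pytest.raises(ValueError):
            PretrainModel(PretrainConfig(loss_subgraph=False, loss_graph=False))

    def test_singleton_batch_rejected(self, fixture_molecules):
        model, _ = _tiny_model()
        opt = Adam(model.parameters(), lr=1e-3)
        with pytest.raises(ValueError):
            pretrain_step(fixture_molecules[:1], model, opt)

    def test_loss_gradient_reaches_first_layer(self, fixture_molecules):
        """Finite-difference spot check on one first-layer encoder weight."""
        graphs = [smiles_to_graph(s) for s in fixture_molecules[:4]]

        def loss_value(model):
            nodes, pool = encode_graph_batch(graphs, model.encoder, training=True)
            hg = Tensor(pool) @ nodes
            part = split_soft(nodes, model.config.T, model.split_Ws)
            sub = Tensor(pool) @ (nodes * part.masks[0].reshape(-1, 1))
            scores = (hg @ model.disc_subgraph) @ sub.T
            idx = np.arange(len(graphs))
            pos = scores[idx, idx]
            neg = scores[np.where(~np.eye(4, dtype=bool))]
            return -jsd_mi(pos, neg)

        model, _ = _tiny_model()
        loss = loss_value(model)
        loss.backward()
        w = model.encoder.mlps[0].W1
        analytic = w.grad[0, 0]
        assert analytic != 0.0
        eps = 1e-6
        w.data[0, 0] += eps
        hi = loss_value(model).item()
        w.data[0, 0] -= 2 * eps
        lo = loss_value(model).item()
        w.data[0, 0] += eps
        assert analytic == pytest.approx((hi - lo) / (2 * eps), rel=1e-3)


class TestPretrainLoop:
    def test_deterministic_under_seed(self, fixture_molecules):
        mols = fixture_molecules[:40]
        cfg = PretrainConfig(hidden_dim=12, n_layers=2, T=1, batch_size=16,
                             epochs=2, seed=3)
        _, h1 = pretrain(mols, cfg)
        _, h2 = pretrain(mols, cfg)
        assert h1 == h2

    def test_partition_conservation_through_training(self, fixture_molecules):
        """Sum of soft subgraph readouts equals the graph readout even after
        the projections have been trained."""
        mols = fixture_molecules[:30]
        cfg = PretrainConfig(hidden_dim=12, n_layers=2, T=2, batch_size=16,
                             epochs=2, seed=1)
        model, _ = pretrain(mols, cfg)
        graphs = [smiles_to_graph(s) for s in mols[:10]]
        nodes, pool = encode_graph_batch(graphs, model.encoder, training=False)
        part = split_soft(nodes, 2, model.split_Ws)
        full = pool @ nodes.data
        parts = sum(pool @ (nodes.data * m.data[:, None]) for m in part.masks)
        assert np.allclose(parts, full, atol=1e-5)
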