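"""Spatial head: each stage against scalar-loop oracles, plus structural invariants."""

import numpy as np
import pytest

from histomorph.nn import Tensor
from histomorph.spatial_head import (
    SpatialHead,
    build_topology,
    sinusoidal_encoding,
)
from histomorph.backbone import grid_coords


# ---------------------------------------------------------------------------
# scalar-loop reference implementation (independent oracle)
# ---------------------------------------------------------------------------

def oracle_masked_softmax(s, mask):
    n = s.shape[0]
    out = np.zeros_like(s)
    for i in range(n):
        sup = [j for j in range(n) if mask[i, j] > 0]
        if not sup:
            continue
        m = max(s[i, j] for j in sup)
        exps = {j: np.exp(s[i, j] - m) for j in sup}
        z = sum(exps.values())
        for j in sup:
            out[i, j] = exps[j] / z
    return out


def oracle_head(head: SpatialHead, fused, coords):
    """Brute-force scalar-loop evaluation of the whole head on one image."""
    n, _ = fused.shape
    d = head.dim
    pe = sinusoidal_encoding(coords, d)
    e = pe @ head.wp.weight.data
    h = fused @ head.wf.weight.data + e  # h^(0)

    # structure estimation, once
    q = h @ head.struct_wq.weight.data
    k = h @ head.struct_wk.weight.data
    s = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            s[i, j] = sum(q[i, t] * k[j, t] for t in range(d)) / np.sqrt(d)
    topo = build_topology(coords, head.radius)
    a_adj = oracle_masked_softmax(s, topo.adjacent)
    a_non = oracle_masked_softmax(s, topo.nonadjacent)
    lam = head.lam
    a_hat = lam * a_adj + (1 - lam) * a_non

    for layer in range(head.depth):
        ql = h @ head.layer_wq[layer].weight.data
        kl = h @ head.layer_wk[layer].weight.data
        vl = h @ head.layer_wv[layer].weight.data
        h_half = np.zeros((n, d))
        for i in range(n):
            logits = [sum(ql[i, t] * kl[j, t] for t in range(d)) / np.sqrt(d)
                      for j in range(n)]
            m = max(logits)
            ex = [np.exp(v - m) for v in logits]
            z = sum(ex)
            for j in range(n):
                h_half[i] += a_hat[i, j] * (ex[j] / z) * vl[j]
        h_next = np.zeros((n, d))
        for i in range(n):
            agg = np.zeros(d)
            for j in range(n):
                agg += a_hat[i, j] * h_half[j]
            h_next[i] = np.maximum(agg @ head.layer_wg[layer].weight.data, 0.0) + h[i]
        h = h_next

    gates = np.array([head.u.data @ np.tanh(h[i] @ head.wa.weight.data)
                      for i in range(n)])
    ex = np.exp(gates - gates.max())
    a = ex / ex.sum()
    z = sum(a[i] * h[i] for i in range(n))
    logits = z @ head.classifier.weight.data + head.classifier.bias.data
    ex = np.exp(logits - logits.max())
    return ex / ex.sum(), a_adj, a_non, a_hat, a, z


# ---------------------------------------------------------------------------
# stage-level tests
# ---------------------------------------------------------------------------

class TestPositions:
    def test_identical_coords_identical_embeddings(self):
        head = SpatialHead(4, dim=8, seed=0)
        coords = np.array([[2, 3], [2, 3], [1, 1]])
        e = head.embed_positions(coords).numpy()
        np.testing.assert_array_equal(e[0], e[1])
        assert not np.allclose(e[0], e[2])

    def test_sinusoidal_origin_closed_form(self):
        pe = sinusoidal_encoding(np.array([[0, 0]]), 16)[0]
        # layout: [sin(row) cos(row) sin(col) cos(col)] blocks
        sin_idx = np.r_[0:4, 8:12]
        cos_idx = np.r_[4:8, 12:16]
        np.testing.assert_array_equal(pe[sin_idx], 0.0)
        np.testing.assert_array_equal(pe[cos_idx], 1.0)

    def test_absolute_encoding_changes_under_translation(self):
        head = SpatialHead(4, dim=8, seed=0)
        coords = grid_coords(2, 2)
        a = head.embed_positions(coords).numpy()
        b = head.embed_positions(coords + 3).numpy()
        assert np.abs(a - b).max() > 1e-6

    def test_learnable_mode_and_unknown_mode(self):
        head = SpatialHead(4, dim=8, pe="learnable", seed=0)
        e = head.embed_positions(grid_coords(2, 2)).numpy()
        assert e.shape == (4, 8)
        with pytest.raises(ValueError, match="positional encoding"):
            SpatialHead(4, dim=8, pe="fourier")


class TestInitNodes:
    def test_zero_embedding_identity_projection(self, rng):
        head = SpatialHead(8, dim=8, seed=0)
        head.wp.weight.data[...] = 0.0
        head.wf.weight.data = np.eye(8)
        f = rng.normal(size=(4, 8))
        h0 = head.init_nodes(Tensor(f[None]), grid_coords(2, 2)).numpy()[0]
        np.testing.assert_allclose(h0, f, atol=1e-12)

    def test_zero_features_give_embeddings(self):
        head = SpatialHead(4, dim=8, seed=0)
        coords = grid_coords(2, 2)
        h0 = head.init_nodes(Tensor(np.zeros((1, 4, 4))), coords).numpy()[0]
        np.testing.assert_allclose(h0, head.embed_positions(coords).numpy(), atol=1e-12)

    def test_matches_scalar_recomputation(self, rng):
        head = SpatialHead(3, dim=8, seed=1)
        f = rng.normal(size=(4, 3))
        coords = grid_coords(2, 2)
        h0 = head.init_nodes(Tensor(f[None]), coords).numpy()[0]
        pe = sinusoidal_encoding(coords, 8)
        for i in range(4):
            expected = f[i] @ head.wf.weight.data + pe[i] @ head.wp.weight.data
            np.testing.assert_allclose(h0[i], expected, atol=1e-12)


class TestTopology:
    def test_2x2_radius_1_brute_force(self):
        coords = grid_coords(2, 2)
        topo = build_topology(coords, 1.0)
        for i in range(4):
            for j in range(4):
                d = np.linalg.norm(coords[i] - coords[j])
                assert topo.adjacent[i, j] == (1.0 if d <= 1.0 else 0.0)
                assert topo.nonadjacent[i, j] == 1.0 - topo.adjacent[i, j]
        # each token: itself + 2 orthogonal neighbours (diagonal sqrt(2) > 1)
        np.testing.assert_array_equal(topo.adjacent.sum(axis=1), [3, 3, 3, 3])

    def test_radius_beyond_diameter_empties_nonadjacent(self):
        topo = build_topology(grid_coords(3, 3), radius=10.0)
        assert np.all(topo.nonadjacent == 0.0)

    def test_single_token(self):
        topo = build_topology(np.array([[0, 0]]), 1.5)
        np.testing.assert_array_equal(topo.adjacent, [[1.0]])
        np.testing.assert_array_equal(topo.nonadjacent, [[0.0]])

    def test_complement_identity_exact(self):
        topo = build_topology(grid_coords(4, 5), 1.5)
        np.testing.assert_array_equal(topo.adjacent + topo.nonadjacent,
                                      np.ones((20, 20)))
        np.testing.assert_array_equal(topo.adjacent, topo.adjacent.T)
        np.testing.assert_array_equal(np.diag(topo.adjacent), np.ones(20))


class TestStructure:
    def test_zero_states_zero_scores(self):
        head = SpatialHead(4, dim=8, seed=0)
        s = head.similarity_scores(Tensor(np.zeros((1, 5, 8)))).numpy()[0]
        np.testing.assert_array_equal(s, np.zeros((5, 5)))

    def test_orthonormal_rows_identity_projections(self):
        d = 4
        head = SpatialHead(4, dim=d, seed=0)
        head.struct_wq.weight.data = np.eye(d)
        head.struct_wk.weight.data = np.eye(d)
        h0 = np.eye(d)  # orthonormal rows
        s = head.similarity_scores(Tensor(h0[None])).numpy()[0]
        np.testing.assert_allclose(s, np.eye(d) / np.sqrt(d), atol=1e-12)

    def test_scores_match_triple_loop(self, rng):
        head = SpatialHead(4, dim=8, seed=2)
        h0 = rng.normal(size=(5, 8))
        s = head.similarity_scores(Tensor(h0[None])).numpy()[0]
        q = h0 @ head.struct_wq.weight.data
        k = h0 @ head.struct_wk.weight.data
        for i in range(5):
            for j in range(5):
                expected = sum(q[i, t] * k[j, t] for t in range(8)) / np.sqrt(8)
                assert s[i, j] == pytest.approx(expected, rel=1e-12)

    def test_masked_normalization_against_brute_force(self, rng):
        from histomorph.nn import masked_softmax

        coords = grid_coords(2, 3)
        topo = build_topology(coords, 1.0)
        s = rng.normal(size=(6, 6))
        got_adj = masked_softmax(Tensor(s), topo.adjacent).numpy()
        got_non = masked_softmax(Tensor(s), topo.nonadjacent).numpy()
        np.testing.assert_allclose(got_adj, oracle_masked_softmax(s, topo.adjacent),
                                   atol=1e-12)
        np.testing.assert_allclose(got_non, oracle_masked_softmax(s, topo.nonadjacent),
                                   atol=1e-12)

    def test_uniform_scores_give_uniform_support(self):
        from histomorph.nn import masked_softmax

        topo = build_topology(grid_coords(2, 2), 1.0)
        s = np.zeros((4, 4))
        out = masked_softmax(Tensor(s), topo.adjacent).numpy()
        for i in range(4):
            k = topo.adjacent[i].sum()
            np.testing.assert_allclose(out[i][topo.adjacent[i] > 0], 1.0 / k)

    def test_single_token_nonadjacent_all_zero_no_nan(self):
        from histomorph.nn import masked_softmax

        out = masked_softmax(Tensor(np.array([[3.0]])), np.array([[0.0]])).numpy()
        assert np.array_equal(out, [[0.0]])

    def test_lambda_fusion_boundaries_and_row_sums(self, rng):
        head = SpatialHead(4, dim=8, seed=3)
        coords = grid_coords(3, 4)
        topo = build_topology(coords, 1.5)
        h0 = head.init_nodes(Tensor(rng.normal(size=(1, 12, 4))), coords)
        for logit, expect in [(40.0, "adj"), (-40.0, "non")]:
            head.lambda_logit.data[:] = logit
            a_hat = head.estimate_structure(h0, topo).numpy()[0]
            s = head.similarity_scores(h0).numpy()[0]
            ref = oracle_masked_softmax(s, topo.adjacent if expect == "adj"
                                        else topo.nonadjacent)
            np.testing.assert_allclose(a_hat, ref, atol=1e-10)
        head.lambda_logit.data[:] = 0.37
        a_hat = head.estimate_structure(h0, topo).numpy()[0]
        # both supports nonempty on every row of a 3x4 grid with r=1.5
        np.testing.assert_allclose(a_hat.sum(axis=1), 1.0, atol=1e-6)

    def test_mask_complement_zeroing_exact(self, rng):
        from histomorph.nn import masked_softmax

        coords = grid_coords(3, 3)
        topo = build_topology(coords, 1.0)
        s = rng.normal(size=(9, 9))
        a_adj = masked_softmax(Tensor(s), topo.adjacent).numpy()
        a_non = masked_softmax(Tensor(s), topo.nonadjacent).numpy()
        assert np.all(a_adj * topo.nonadjacent == 0.0)
        assert np.all(a_non * topo.adjacent == 0.0)


class TestLayers:
    def test_single_node_layer(self, rng):
        head = SpatialHead(4, dim=4, depth=1, seed=0)
        h = rng.normal(size=(1, 1, 4))
        a_hat = Tensor(np.array([[[0.7]]]))
        out = head.update_layer(Tensor(h), a_hat, 0).numpy()[0]
        v = h[0] @ head.layer_wv[0].weight.data
        h_half = 0.7 * v  # inner softmax over one node equals 1
        expected = np.maximum((0.7 * h_half) @ head.layer_wg[0].weight.data, 0) + h[0]
        np.testing.assert_allclose(out, expected, atol=1e-12)

    def test_zero_structure_annihilates_attention(self, rng):
        head = SpatialHead(4, dim=4, depth=1, seed=1)
        h = rng.normal(size=(1, 5, 4))
        out = head.update_layer(Tensor(h), Tensor(np.zeros((1, 5, 5))), 0).numpy()[0]
        np.testing.assert_allclose(out, h[0], atol=1e-12)  # relu(0) + residual

    def test_zero_graph_weight_residual_identity(self, rng):
        head = SpatialHead(4, dim=4, depth=1, seed=2)
        head.layer_wg[0].weight.data[...] = 0.0
        h = rng.normal(size=(1, 5, 4))
        a_hat = Tensor(rng.uniform(size=(1, 5, 5)))
        out = head.update_layer(Tensor(h), a_hat, 0).numpy()[0]
        np.testing.assert_allclose(out, h[0], atol=1e-12)


class TestReadout:
    def test_identical_states_uniform_attention(self):
        head = SpatialHead(4, dim=6, seed=0)
        h = np.tile(np.arange(6.0), (5, 1))
        a, z = head.attend_readout(Tensor(h[None]))
        np.testing.assert_allclose(a.numpy()[0], 0.2, atol=1e-12)
        np.testing.assert_allclose(z.numpy()[0], h[0], atol=1e-12)

    def test_single_node(self, rng):
        head = SpatialHead(4, dim=6, seed=1)
        h = rng.normal(size=(1, 1, 6))
        a, z = head.attend_readout(Tensor(h))
        np.testing.assert_allclose(a.numpy()[0], [1.0])
        np.testing.assert_allclose(z.numpy()[0], h[0, 0], atol=1e-12)

    def test_convexity_of_pooled_state(self, rng):
        head = SpatialHead(4, dim=6, seed=2)
        h = rng.normal(size=(1, 8, 6))
        a, z = head.attend_readout(Tensor(h))
        a, z = a.numpy()[0], z.numpy()[0]
        assert np.all(a >= 0) and a.sum() == pytest.approx(1.0, abs=1e-6)
        np.testing.assert_allclose(z, a @ h[0], atol=1e-12)
        assert np.all(z >= h[0].min(axis=0) - 1e-12)
        assert np.all(z <= h[0].max(axis=0) + 1e-12)


class TestClassify:
    def test_softmax_closed_forms(self):
        head = SpatialHead(4, dim=4, seed=0)
        head.classifier.weight.data[...] = 0.0
        head.classifier.bias.data[...] = 0.0
        pred = head.head_forward(np.zeros((4, 4)), grid_coords(2, 2))
        np.testing.assert_allclose(pred.probabilities, [0.5, 0.5], atol=1e-12)

        head.classifier.bias.data[:] = [1.0, -1.0]
        pred = head.head_forward(np.zeros((4, 4)), grid_coords(2, 2))
        e2 = np.exp(2.0)
        np.testing.assert_allclose(pred.probabilities,
                                   [e2 / (e2 + 1), 1 / (e2 + 1)], atol=1e-12)

        head.classifier.bias.data[:] = [60.0, -60.0]
        pred = head.head_forward(np.zeros((4, 4)), grid_coords(2, 2))
        np.testing.assert_allclose(pred.probabilities, [1.0, 0.0], atol=1e-20)


# ---------------------------------------------------------------------------
# whole-head properties
# ---------------------------------------------------------------------------

class TestHeadForward:
    @pytest.mark.parametrize("gh,gw", [(1, 1), (2, 2), (3, 4), (4, 4)])
    def test_full_equivalence_with_scalar_oracle(self, rng, gh, gw):
        """Vectorised head == brute-force scalar loops for all N <= 16."""
        head = SpatialHead(5, dim=8, depth=2, seed=gh * 10 + gw)
        head.lambda_logit.data[:] = rng.normal()
        fused = rng.normal(size=(gh * gw, 5))
        coords = grid_coords(gh, gw)
        pred = head.head_forward(fused, coords, return_intermediates=True)
        probs, a_adj, a_non, a_hat, a, z = oracle_head(head, fused, coords)
        np.testing.assert_allclose(pred.probabilities, probs, rtol=1e-5, atol=1e-10)
        np.testing.assert_allclose(pred.structure.norm_adj, a_adj, rtol=1e-5, atol=1e-10)
        np.testing.assert_allclose(pred.structure.norm_non, a_non, rtol=1e-5, atol=1e-10)
        np.testing.assert_allclose(pred.structure.fused, a_hat, rtol=1e-5, atol=1e-10)
        np.testing.assert_allclose(pred.readout.attention, a, rtol=1e-5, atol=1e-10)

    def test_probabilities_sum_to_one(self, rng):
        head = SpatialHead(6, dim=8, seed=0)
        pred = head.head_forward(rng.normal(size=(9, 6)), grid_coords(3, 3))
        assert pred.probabilities.sum() == pytest.approx(1.0, abs=1e-6)
        assert np.all(pred.probabilities >= 0)

    def test_permutation_consistency(self, rng):
        """Token row order is irrelevant: structure derives from coords."""
        head = SpatialHead(6, dim=8, depth=2, seed=4)
        fused = rng.normal(size=(12, 6))
        coords = grid_coords(3, 4)
        base = head.head_forward(fused, coords).probabilities
        perm = rng.permutation(12)
        permuted = head.head_forward(fused[perm], coords[perm]).probabilities
        np.testing.assert_allclose(permuted, base, atol=1e-5)

    def test_depth_one_equals_manual_composition(self, rng):
        head = SpatialHead(5, dim=8, depth=1, seed=6)
        fused = rng.normal(size=(4, 5))
        coords = grid_coords(2, 2)
        pred = head.head_forward(fused, coords)

        topo = build_topology(coords, head.radius)
        h = head.init_nodes(Tensor(fused[None]), coords)
        a_hat = head.estimate_structure(h, topo)
        h = head.update_layer(h, a_hat, 0)
        _, z = head.attend_readout(h)
        from histomorph.nn import softmax

        manual = softmax(head.classifier(z), axis=-1).numpy()[0]
        np.testing.assert_allclose(pred.probabilities, manual, atol=1e-10)

    def test_renormalized_variant_row_stochastic_effective_attention(self, rng):
        head = SpatialHead(5, dim=8, depth=1, renormalize=True, seed=7)
        pred = head.head_forward(rng.normal(size=(9, 5)), grid_coords(3, 3))
        assert pred.probabilities.sum() == pytest.approx(1.0, abs=1e-6)

    def test_all_parameters_receive_gradient(self, rng):
        head = SpatialHead(5, dim=8, depth=2, seed=8)
        fused = Tensor(rng.normal(size=(1, 9, 5)))
        probs = head(fused, grid_coords(3, 3))
        loss = -(probs[:, 1] + 1e-9).log().sum()
        loss.backward()
        for name, p in head.named_parameters():
            assert p.grad is not None, name
            assert np.abs(p.grad).max() > 0, name
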