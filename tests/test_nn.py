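"""Network core: closed-form loss values, dense step-by-step oracles for
the graph layers, a finite-difference check of every hand-written gradient,
and the negative-edge sampling contract."""

import numpy as np
import pytest

from stmask import nn
from stmask.graph import build_knn_graph


@pytest.fixture
def small_graph():
    return build_knn_graph(np.random.default_rng(1).normal(size=(6, 2)), k=2)


def perturbed_state(n_features, seed=1, **dims):
    """Small random model whose weights are pushed away from the symmetric
    init so oracle comparisons are non-trivial."""
    state = nn.init_model(n_features, seed=seed, **dims)
    p_rng = np.random.default_rng(seed + 100)
    for k, v in state.params.items():
        state.params[k] = (v + 0.2 * p_rng.normal(size=v.shape)).astype(v.dtype)
    for k in state.buffers:
        state.buffers[k] = (
            state.buffers[k] + 0.1 * np.abs(p_rng.normal(size=state.buffers[k].shape))
        ).astype(np.float32)
    return state


def dense_encode_oracle(X, A_hat, state):
    """Step-by-step dense evaluation of the encoder in inference mode."""
    p, b = state.params, state.buffers
    A = np.asarray(A_hat.todense())
    U1 = A @ (X @ p["Wg0"])
    xhat = (U1 - b["bn_g_mean"]) / np.sqrt(b["bn_g_var"] + nn.BN_EPS)
    B1 = p["bn_g_gamma"] * xhat + p["bn_g_beta"]
    P1 = np.where(B1 > 0, B1, float(p["prelu_g"]) * B1)
    return A @ (P1 @ p["Wg1"])


def dense_decode_oracle(Ht, A_hat, state):
    p, b = state.params, state.buffers
    A = np.asarray(A_hat.todense())
    U = Ht @ p["Wd0"]
    xhat = (U - b["bn_d_mean"]) / np.sqrt(b["bn_d_var"] + nn.BN_EPS)
    B = p["bn_d_gamma"] * xhat + p["bn_d_beta"]
    P = np.where(B > 0, B, float(p["prelu_d"]) * B)
    return A @ (P @ p["Wd1"])


class TestEncodeDecode:
    def test_zero_input_zero_output(self, small_graph):
        state = nn.init_model(5, seed=0)
        H = nn.encode(np.zeros((6, 5)), small_graph.norm_operator, state)
        np.testing.assert_array_equal(H, 0)

    def test_edgeless_graph_zero_output(self, rng):
        import scipy.sparse as sp
        from stmask.graph import graph_from_adjacency

        g = graph_from_adjacency(sp.csr_matrix((4, 4)))
        state = perturbed_state(3)
        H = nn.encode(rng.normal(size=(4, 3)), g.norm_operator, state)
        np.testing.assert_array_equal(H, 0)
        Z = nn.decode(rng.normal(size=(4, 256)), g.norm_operator, state)
        np.testing.assert_array_equal(Z, 0)

    def test_encode_matches_dense_oracle(self, small_graph, rng):
        state = perturbed_state(4, enc_hidden=8, latent=5)
        X = rng.normal(size=(6, 4)).astype(np.float32)
        H = nn.encode(X, small_graph.norm_operator, state, training=False)
        np.testing.assert_allclose(
            H, dense_encode_oracle(X, small_graph.norm_operator, state), atol=1e-5
        )

    def test_decode_matches_dense_oracle(self, small_graph, rng):
        state = perturbed_state(4, latent=5, dec_hidden=7)
        Ht = rng.normal(size=(6, 5)).astype(np.float32)
        Z = nn.decode(Ht, small_graph.norm_operator, state, training=False)
        np.testing.assert_allclose(
            Z, dense_decode_oracle(Ht, small_graph.norm_operator, state), atol=1e-5
        )

    def test_shape_errors_name_the_layer(self, small_graph, rng):
        state = nn.init_model(4)
        with pytest.raises(ValueError, match="Wg0"):
            nn.encode(rng.normal(size=(6, 9)), small_graph.norm_operator, state)
        with pytest.raises(ValueError, match="Wd0"):
            nn.decode(rng.normal(size=(6, 9)), small_graph.norm_operator, state)


class TestRemask:
    def test_cases(self, rng):
        H = rng.normal(size=(4, 3))
        token = np.full(3, -1.0)
        np.testing.assert_array_equal(nn.remask(H, np.array([], int), token), H)
        assert np.all(nn.remask(H, np.arange(4), token) == -1.0)
        out = nn.remask(H, np.array([2]), token)
        np.testing.assert_array_equal(out[[0, 1, 3]], H[[0, 1, 3]])
        assert np.all(out[2] == -1.0)


class TestSCE:
    def test_positive_scaling_gives_zero(self, rng):
        X = rng.normal(size=(5, 4))
        Z = 3.0 * X
        assert nn.sce_loss(X, Z, np.arange(5)) == pytest.approx(0.0, abs=1e-12)

    def test_antipodal_rows(self, rng):
        X = rng.normal(size=(3, 4))
        assert nn.sce_loss(X, -X, np.arange(3), gamma=2) == pytest.approx(4.0)

    def test_orthogonal_rows(self):
        X = np.array([[1.0, 0.0]])
        Z = np.array([[0.0, 1.0]])
        assert nn.sce_loss(X, Z, np.array([0]), gamma=2) == pytest.approx(1.0)

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError):
            nn.sce_loss(np.ones((2, 2)), np.ones((2, 2)), np.array([], int))

    def test_range(self, rng):
        for _ in range(20):
            X, Z = rng.normal(size=(6, 3)), rng.normal(size=(6, 3))
            val = nn.sce_loss(X, Z, np.arange(6), gamma=2)
            assert 0.0 <= val <= 4.0 and np.isfinite(val)


class TestDiscriminator:
    def test_zero_path_gives_half(self):
        state = nn.init_model(4, latent=4, disc_hidden=3)
        state.params["w2"][:] = 0.0  # b1 = b2 = 0 by init
        assert nn.discriminate(np.ones(4), np.zeros(4), state) == pytest.approx(0.5)

    def test_symmetry(self, rng):
        state = perturbed_state(4, latent=6, disc_hidden=5)
        for _ in range(10):
            hi, hj = rng.normal(size=6), rng.normal(size=6)
            assert nn.discriminate(hi, hj, state) == pytest.approx(
                nn.discriminate(hj, hi, state), rel=1e-6
            )

    def test_matches_scalar_loop_oracle(self, rng):
        state = perturbed_state(4, latent=5, disc_hidden=4)
        p = state.params
        hi, hj = rng.normal(size=5), rng.normal(size=5)
        m = [hi[t] * hj[t] for t in range(5)]
        hidden = []
        for q in range(4):
            acc = p["b1"][q]
            for t in range(5):
                acc += m[t] * p["W1"][t, q]
            hidden.append(max(acc, 0.0))
        s = float(p["b2"])
        for q in range(4):
            s += hidden[q] * p["w2"][q]
        expected = 1.0 / (1.0 + np.exp(-s))
        assert nn.discriminate(hi, hj, state) == pytest.approx(expected, abs=1e-6)


class TestNegativeSampling:
    def test_empty_positives(self, small_graph):
        neg = nn.sample_negative_edges(
            np.empty((0, 2), int), 6, small_graph.neighbor_sets(), seed=0
        )
        assert neg.shape == (0, 2)

    def test_counts_and_exclusion(self):
        g = build_knn_graph(np.random.default_rng(0).uniform(size=(100, 2)), k=4)
        pos = g.edges[:30]
        neigh = g.neighbor_sets()
        neg = nn.sample_negative_edges(pos, 100, neigh, seed=1)
        pos_counts = np.bincount(pos.ravel(), minlength=100)
        neg_counts = np.bincount(neg[:, 0], minlength=100)
        np.testing.assert_array_equal(neg_counts, pos_counts)
        for i, j in neg:
            assert j not in neigh[i] and j != i

    def test_saturated_node_skipped(self):
        import scipy.sparse as sp
        from stmask.graph import graph_from_adjacency

        A = np.ones((4, 4)) - np.eye(4)  # complete graph: empty pools
        g = graph_from_adjacency(sp.csr_matrix(A))
        with pytest.warns(UserWarning, match="adjacent to every"):
            neg = nn.sample_negative_edges(g.edges, 4, g.neighbor_sets(), seed=0)
        assert neg.shape == (0, 2)

    def test_partner_distribution_uniform(self, small_graph):
        # enumerate one node's candidate pool; over many draws each
        # candidate appears equally often (chi-square tolerance)
        neigh = small_graph.neighbor_sets()
        pos = small_graph.edges[:2]
        node = int(pos[0][0])
        pool = [v for v in range(6) if v != node and v not in neigh[node]]
        s_rng = np.random.default_rng(7)
        hits = {v: 0 for v in pool}
        draws = 2000
        for _ in range(draws):
            neg = nn.sample_negative_edges(pos, 6, neigh, rng=s_rng)
            for i, j in neg:
                if i == node:
                    hits[j] += 1
        counts = np.array(list(hits.values()), float)
        expected = counts.sum() / len(pool)
        chi2 = ((counts - expected) ** 2 / expected).sum()
        # df = len(pool)-1 <= 5; 99.9th percentile of chi2_5 ~ 20.5
        assert chi2 < 21


class TestNCE:
    def test_half_probability_identity(self, small_graph, rng):
        state = nn.init_model(4, latent=8, disc_hidden=4)
        state.params["w2"][:] = 0.0  # D == 0.5 everywhere
        H = rng.normal(size=(6, 8)).astype(np.float32)
        es = nn.EdgeSets(pos=small_graph.edges[:3], neg=small_graph.edges[3:5],
                         per_node_counts=None)
        assert nn.nce_loss(H, es, state) == pytest.approx(2 * np.log(2), rel=1e-6)

    def test_crafted_probabilities_give_two(self):
        # one positive with D = 1/e and one negative with D = 1 - 1/e
        state = nn.init_model(4, latent=4, disc_hidden=4)
        p = state.params
        p["W1"][:] = 0.0
        p["W1"][0, 0] = 1.0
        p["w2"][:] = 0.0
        p["w2"][0] = 1.0
        s = -np.log(np.e - 1)
        p["b2"] = np.array(s, dtype=np.float32)
        H = np.zeros((4, 4), dtype=np.float32)
        H[1, 0] = 1.0
        H[2, 0] = H[3, 0] = np.sqrt(-2 * s)
        es = nn.EdgeSets(pos=np.array([[0, 1]]), neg=np.array([[2, 3]]),
                         per_node_counts=None)
        assert nn.nce_loss(H, es, state) == pytest.approx(2.0, rel=1e-5)

    def test_empty_positive_set_raises(self, rng):
        state = nn.init_model(4, latent=4)
        es = nn.EdgeSets(pos=np.empty((0, 2), int), neg=np.array([[0, 1]]),
                         per_node_counts=None)
        with pytest.raises(ValueError, match="edge mask"):
            nn.nce_loss(rng.normal(size=(4, 4)), es, state)


class TestTotalLoss:
    @pytest.mark.parametrize(
        "sce,nce,lam,expected", [(5.0, 9.0, 0.0, 5.0), (5.0, 9.0, 1.0, 9.0),
                                 (1.0, 2.0, 0.7, 1.7)]
    )
    def test_values(self, sce, nce, lam, expected):
        assert nn.total_loss(sce, nce, lam) == pytest.approx(expected)

    def test_invalid_lambda(self):
        with pytest.raises(ValueError):
            nn.total_loss(1.0, 1.0, 1.2)


def test_all_gradients_match_finite_differences(monkeypatch, small_graph):
    """Every hand-written gradient (both channels, all parameter groups)
    agrees with a central finite difference in float64."""
    monkeypatch.setattr(nn, "DTYPE", np.float64)
    g = small_graph
    g_rng = np.random.default_rng(0)
    X = g_rng.normal(size=(6, 5))
    state = nn.init_model(5, seed=1, enc_hidden=7, latent=6, dec_hidden=5,
                          disc_hidden=4)
    for k in state.params:
        state.params[k] = state.params[k].astype(np.float64)
        state.params[k] += 0.1 * g_rng.normal(size=state.params[k].shape)
    state.buffers = {k: v.astype(np.float64) for k, v in state.buffers.items()}
    vm = np.array([1, 4])
    pos = g.edges[:3]
    neg = np.array([[0, 5], [2, 4], [3, 5]])
    A = g.norm_operator
    es = nn.EdgeSets(pos=pos, neg=neg, per_node_counts=None)

    def forward(st, want_grads=False):
        st2 = nn.ModelState(params=st.params,
                            buffers={k: v.copy() for k, v in st.buffers.items()},
                            dims=st.dims)
        grads = st2.zero_grads()
        Xm = X.copy()
        Xm[vm] = st2.params["x_token"]
        H, c1 = nn.encode(Xm, A, st2, training=True, return_cache=True)
        Ht = nn.remask(H, vm, st2.params["h_token"])
        Z, cd = nn.decode(Ht, A, st2, training=True, return_cache=True)
        H2, c2 = nn.encode(X, A, st2, training=True, return_cache=True)
        if not want_grads:
            return 0.3 * nn.sce_loss(X, Z, vm) + 0.7 * nn.nce_loss(H2, es, st2)
        _, dZ = nn.sce_loss_grad(X, Z, vm)
        _, dH2 = nn.nce_loss_grad(H2, es, st2, grads)
        for key in nn.ModelState.DISC_KEYS:
            grads[key] *= 0.7
        dHt = nn.decode_backward(0.3 * dZ, cd, st2, grads)
        grads["h_token"] += dHt[vm].sum(0)
        dHt2 = dHt.copy()
        dHt2[vm] = 0
        dXin = nn.encode_backward(dHt2, c1, st2, grads)
        grads["x_token"] += dXin[vm].sum(0)
        nn.encode_backward(0.7 * dH2, c2, st2, grads)
        return grads

    grads = forward(state, want_grads=True)
    eps = 1e-6
    for key in state.params:
        flat = state.params[key].reshape(-1)
        # probe a subset of entries on large arrays to keep the test quick
        probe = range(flat.size) if flat.size <= 12 else range(0, flat.size, flat.size // 10)
        for idx in probe:
            orig = flat[idx]
            flat[idx] = orig + eps
            lp = forward(state)
            flat[idx] = orig - eps
            lm = forward(state)
            flat[idx] = orig
            gnum = (lp - lm) / (2 * eps)
            gana = grads[key].reshape(-1)[idx]
            assert gnum == pytest.approx(gana, rel=1e-4, abs=1e-7), key


def test_state_save_load_roundtrip(tmp_path):
    state = perturbed_state(5)
    state.save(tmp_path / "ckpt.npz")
    back = nn.ModelState.load(tmp_path / "ckpt.npz")
    assert back.dims == state.dims
    for k in state.params:
        np.testing.assert_array_equal(back.params[k], state.params[k])
    for k in state.buffers:
        np.testing.assert_array_equal(back.buffers[k], state.buffers[k])
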