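"""Graph attention encoder: forward oracle, gradients, invariants."""

import math

import numpy as np
import pytest

from gatmda.gat import (
    GraphAttentionEncoder,
    _layer_forward,
    _loss_and_grads,
    aggregate_head,
    attention_logits,
    multi_head_forward,
    normalize_attention,
)
from gatmda.synthetic import SynthConfig, generate_bundle
from gatmda.linear_features import (
    disease_linear_features,
    mirna_linear_features,
    stack_features,
)
from gatmda.evaluation import roc_auc


def lrelu(x, slope):
    return np.where(np.asarray(x) >= 0, x, slope * np.asarray(x))


def random_graph(rng, n_mi, n_dis, p=0.4):
    """Random bipartite mask (with self-loops) and global-index edges."""
    N = n_mi + n_dis
    md = rng.random((n_mi, n_dis)) < p
    if not md.any():
        md[0, 0] = True
    edges = np.argwhere(md)
    edges = np.column_stack([edges[:, 0], n_mi + edges[:, 1]])
    mask = np.eye(N, dtype=bool)
    mask[edges[:, 0], edges[:, 1]] = True
    mask[edges[:, 1], edges[:, 0]] = True
    return mask, edges


def oracle_forward(Ws, as_, F, mask, slope):
    """Per-node, per-head python-loop evaluation of the attention layer."""
    N = F.shape[0]
    K = len(Ws)
    d_out = Ws[0].shape[0]
    out = np.zeros((N, d_out))
    for i in range(N):
        acc = np.zeros(d_out)
        for k in range(K):
            h = F @ Ws[k].T
            nbrs = [t for t in range(N) if mask[i, t]]
            logits = []
            for t in nbrs:
                z = as_[k] @ np.concatenate([h[i], h[t]])
                logits.append(z if z >= 0 else slope * z)
            logits = np.asarray(logits)
            ex = np.exp(logits - logits.max())
            theta = ex / ex.sum()
            acc += sum(th * h[t] for th, t in zip(theta, nbrs))
        out[i] = lrelu(acc / K, slope)
    return out


class TestBuildingBlocks:
    def test_zero_attention_vector_gives_zero_logit(self):
        rng = np.random.default_rng(0)
        W = rng.normal(size=(3, 4))
        assert attention_logits(W, np.zeros(6), rng.normal(size=4), rng.normal(size=4)) == 0.0

    def test_leaky_relu_slope_on_both_signs(self):
        W = np.eye(1)
        f_i, f_j = np.array([2.0]), np.array([1.0])
        a_pos = np.array([1.0, 1.0])
        assert attention_logits(W, a_pos, f_i, f_j, 0.2) == pytest.approx(3.0)
        assert attention_logits(W, -a_pos, f_i, f_j, 0.2) == pytest.approx(-0.6)

    def test_logit_matches_hand_dot_product(self):
        rng = np.random.default_rng(1)
        W = rng.normal(size=(2, 3))
        a = rng.normal(size=4)
        f_i, f_j = rng.normal(size=3), rng.normal(size=3)
        z = a[:2] @ (W @ f_i) + a[2:] @ (W @ f_j)
        want = z if z >= 0 else 0.2 * z
        assert attention_logits(W, a, f_i, f_j, 0.2) == pytest.approx(want, abs=1e-12)

    def test_softmax_single_neighbor(self):
        np.testing.assert_allclose(normalize_attention([3.7]), [1.0])

    def test_softmax_equal_logits(self):
        np.testing.assert_allclose(normalize_attention([1.0] * 4), [0.25] * 4)

    def test_softmax_closed_form(self):
        np.testing.assert_allclose(
            normalize_attention([0.0, math.log(3)]), [0.25, 0.75], atol=1e-12)

    def test_softmax_empty_neighborhood_rejected(self):
        with pytest.raises(ValueError, match="empty neighborhood"):
            normalize_attention([])

    def test_aggregate_single_neighbor(self):
        rng = np.random.default_rng(2)
        W = rng.normal(size=(3, 2))
        feats = rng.normal(size=(4, 2))
        got = aggregate_head(W, feats, np.array([1]), np.array([1.0]), 0.2)
        np.testing.assert_allclose(got, lrelu(W @ feats[1], 0.2), atol=1e-12)

    def test_aggregate_zero_features(self):
        W = np.ones((2, 3))
        feats = np.zeros((5, 3))
        got = aggregate_head(W, feats, np.array([0, 2]), np.array([0.5, 0.5]))
        np.testing.assert_array_equal(got, 0.0)


class TestMultiHeadForward:
    @pytest.mark.parametrize("seed", range(8))
    def test_dense_matches_edge_list_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n_mi, n_dis = rng.integers(2, 10), rng.integers(2, 10)
        mask, _ = random_graph(rng, n_mi, n_dis)
        F = rng.normal(size=(n_mi + n_dis, 5))
        K = int(rng.integers(1, 4))
        Ws = [rng.normal(size=(3, 5)) for _ in range(K)]
        as_ = [rng.normal(size=6) for _ in range(K)]
        got = multi_head_forward(Ws, as_, F, mask, 0.2)
        want = oracle_forward(Ws, as_, F, mask, 0.2)
        np.testing.assert_allclose(got, want, atol=1e-10)

    def test_identical_heads_equal_single_head(self):
        rng = np.random.default_rng(3)
        mask, _ = random_graph(rng, 4, 3)
        F = rng.normal(size=(7, 4))
        W, a = rng.normal(size=(2, 4)), rng.normal(size=4)
        single = multi_head_forward([W], [a], F, mask)
        four = multi_head_forward([W] * 4, [a] * 4, F, mask)
        np.testing.assert_allclose(single, four, atol=1e-12)

    def test_zero_second_head_halves_preactivation(self):
        rng = np.random.default_rng(4)
        mask, _ = random_graph(rng, 3, 3)
        F = rng.normal(size=(6, 4))
        W1, a1 = rng.normal(size=(2, 4)), rng.normal(size=4)
        W2, a2 = np.zeros((2, 4)), np.zeros(4)
        cache = {}
        _layer_forward(F, mask, [W1], [a1], 0.2, cache=cache)
        want = lrelu(cache["P"] / 2.0, 0.2)  # head 2 contributes zero pre-activation
        got = multi_head_forward([W1, W2], [a1, a2], F, mask, 0.2)
        np.testing.assert_allclose(got, want, atol=1e-12)

    def test_output_shape(self):
        rng = np.random.default_rng(5)
        mask, _ = random_graph(rng, 6, 4)
        F = rng.normal(size=(10, 7))
        out = multi_head_forward([rng.normal(size=(3, 7))], [rng.normal(size=6)], F, mask)
        assert out.shape == (10, 3)

    def test_attention_rows_sum_to_one(self):
        rng = np.random.default_rng(6)
        mask, _ = random_graph(rng, 8, 6)
        F = rng.normal(size=(14, 5))
        cache = {}
        _layer_forward(F, mask, [rng.normal(size=(3, 5))], [rng.normal(size=6)],
                       0.2, cache=cache)
        for _, _, A, _ in cache["per_head"]:
            np.testing.assert_allclose(A.sum(axis=1), 1.0, atol=1e-6)
            assert np.all(A[~mask] == 0)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(7)
        mask, _ = random_graph(rng, 5, 5)
        F = rng.normal(size=(10, 4))
        Ws = [rng.normal(size=(3, 4)) for _ in range(2)]
        as_ = [rng.normal(size=6) for _ in range(2)]
        base = multi_head_forward(Ws, as_, F, mask)
        perm = rng.permutation(10)
        permuted = multi_head_forward(Ws, as_, F[perm], mask[np.ix_(perm, perm)])
        np.testing.assert_allclose(permuted, base[perm], atol=1e-10)


class TestGradients:
    @pytest.mark.parametrize("two_layer", [False, True])
    def test_analytic_gradients_match_finite_differences(self, two_layer):
        rng = np.random.default_rng(11)
        mask, edges = random_graph(rng, 3, 3, p=0.6)
        F = rng.normal(size=(6, 4))
        dims = [(4, 3), (3, 2)] if two_layer else [(4, 2)]
        layers = [([rng.normal(size=(dd, di)) * 0.5 for _ in range(2)],
                   [rng.normal(size=2 * dd) * 0.5 for _ in range(2)])
                  for di, dd in dims]
        relation = rng.normal(size=dims[-1][1]) * 0.5 + 1.0
        pairs = np.vstack([edges, [[0, 5], [2, 4]]])
        y = np.concatenate([np.ones(len(edges)), np.zeros(2)])

        _, grads, _ = _loss_and_grads(F, mask, layers, relation, pairs, y, 0.2)
        flat = [p for Ws, as_ in layers for p in (*Ws, *as_)] + [relation]

        def loss_of(params):
            it = iter(params)
            lay = [([next(it) for _ in Ws], [next(it) for _ in as_]) for Ws, as_ in layers]
            rel = next(it)
            return _loss_and_grads(F, mask, lay, rel, pairs, y, 0.2)[0]

        eps = 1e-6
        for pi, (param, grad) in enumerate(zip(flat, grads)):
            it = np.nditer(param, flags=["multi_index"])
            checked = 0
            while not it.finished and checked < 5:
                idx = it.multi_index
                bump = [p.copy() for p in flat]
                bump[pi][idx] += eps
                up = loss_of(bump)
                bump[pi][idx] -= 2 * eps
                down = loss_of(bump)
                fd = (up - down) / (2 * eps)
                denom = max(abs(fd), abs(grad[idx]), 1e-8)
                assert abs(fd - grad[idx]) / denom < 1e-4, (pi, idx, fd, grad[idx])
                checked += 1
                it.iternext()


class TestTraining:
    def _small_inputs(self, seed=0):
        rng = np.random.default_rng(seed)
        _, edges = random_graph(rng, 8, 6, p=0.3)
        F = rng.normal(size=(14, 5))
        return F, edges

    def test_fit_is_deterministic_given_seed(self):
        F, edges = self._small_inputs()
        e1 = GraphAttentionEncoder(out_dim=4, epochs=30, seed=5).fit_transform(F, edges, 8)
        e2 = GraphAttentionEncoder(out_dim=4, epochs=30, seed=5).fit_transform(F, edges, 8)
        np.testing.assert_array_equal(e1, e2)

    def test_different_seeds_differ(self):
        F, edges = self._small_inputs()
        e1 = GraphAttentionEncoder(out_dim=4, epochs=10, seed=0).fit_transform(F, edges, 8)
        e2 = GraphAttentionEncoder(out_dim=4, epochs=10, seed=1).fit_transform(F, edges, 8)
        assert not np.allclose(e1, e2)

    def test_no_edges_rejected(self):
        with pytest.raises(ValueError, match="no edges"):
            GraphAttentionEncoder().fit(np.zeros((4, 3)), np.empty((0, 2)))

    def test_training_reduces_loss(self):
        F, edges = self._small_inputs(3)
        enc = GraphAttentionEncoder(out_dim=4, epochs=60, dropout=0.0, seed=2)
        enc.fit(F, edges, 8)
        assert np.mean(enc.loss_history_[-5:]) < enc.loss_history_[0]

    def test_heldout_link_auc_on_planted_blocks(self):
        cfg = SynthConfig(m=60, n=40, l=12, n_blocks=2, p_in=0.3, p_out=0.01,
                          lnc_signal=0.4, lnc_noise=0.02, sim_noise_frac=0.1,
                          propensity_sigma=0.3, seed=1)
        bundle, _ = generate_bundle(cfg)
        m = bundle.m
        F = stack_features(mirna_linear_features(bundle.fs, bundle.ml),
                           disease_linear_features(bundle.ds, bundle.dl))
        pos = np.argwhere(bundle.md.values == 1)
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(pos))
        n_test = len(pos) // 5
        test, train = pos[perm[:n_test]], pos[perm[n_test:]]
        edges = np.column_stack([train[:, 0], m + train[:, 1]])
        enc = GraphAttentionEncoder(seed=0)
        emb = enc.fit_transform(F, edges, n_mirnas=m)
        neg = np.argwhere(bundle.md.values == 0)
        neg = neg[rng.choice(len(neg), 1500, replace=False)]
        def score(p):
            return (emb[p[:, 0]] * enc.relation_ * emb[m + p[:, 1]]).sum(axis=1)
        scores = np.concatenate([score(test), score(neg)])
        labels = np.concatenate([np.ones(len(test)), np.zeros(len(neg))])
        assert roc_auc(scores, labels) >= 0.8
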