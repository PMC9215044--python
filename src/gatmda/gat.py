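"""Multi-head graph attention encoder for the bipartite association graph.

One attention layer maps the linear features F in R^{(m+n) x l} to
non-linear embeddings F' in R^{(m+n) x l'}:

    e_ij   = LeakyReLU_beta( a^T [W f_i || W f_j] )       (per head)
    theta  = softmax of e over each node's neighborhood
    f'_i   = LeakyReLU_beta( (1/K) sum_k sum_{t in N_i} theta^k_it W^k f_t )

Heads are *averaged* before the activation, not concatenated.  Self-loops
are added so every node (including ones isolated by cross-validation
masking) has a non-empty neighborhood for the softmax.

The encoder is trained self-supervised on link prediction: an inner-product
decoder sigmoid(<f'_i, f'_j>) over miRNA-disease pairs with binary
cross-entropy on the observed edges against an equal number of uniformly
resampled non-edges per epoch.  The implementation is pure NumPy with
analytic gradients (verified against central finite differences in the test
suite) and Adam updates; everything random flows from a single seed.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from .datatypes import FeatureMatrix

__all__ = [
    "GraphAttentionEncoder",
    "attention_logits",
    "normalize_attention",
    "aggregate_head",
    "multi_head_forward",
    "train_encoder",
]


def _leaky(x: np.ndarray, slope: float) -> np.ndarray:
    return np.where(x >= 0, x, slope * x)


def _leaky_grad(x: np.ndarray, slope: float) -> np.ndarray:
    return np.where(x >= 0, 1.0, slope)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


# ---------------------------------------------------------------------------
# Functional pieces (the unit-testable building blocks of the layer)
# ---------------------------------------------------------------------------

def attention_logits(W: np.ndarray, a: np.ndarray, f_i: np.ndarray, f_j: np.ndarray,
                     leaky_slope: float = 0.2) -> float:
    """Raw attention coefficient e_ij for one ordered node pair."""
    h_i, h_j = W @ f_i, W @ f_j
    return float(_leaky(np.array(a @ np.concatenate([h_i, h_j])), leaky_slope))


def normalize_attention(logits: np.ndarray) -> np.ndarray:
    """Softmax over one neighborhood (shift-invariant, numerically safe)."""
    logits = np.asarray(logits, dtype=float)
    if logits.size == 0:
        raise ValueError("empty neighborhood: softmax undefined")
    z = np.exp(logits - logits.max())
    return z / z.sum()


def aggregate_head(W: np.ndarray, features: np.ndarray, neighbors: np.ndarray,
                   theta: np.ndarray, leaky_slope: float = 0.2) -> np.ndarray:
    """sigma( sum_t theta_t W f_t ) for one node and one head."""
    pre = (theta[:, None] * (features[neighbors] @ W.T)).sum(axis=0)
    return _leaky(pre, leaky_slope)


def _layer_forward(F: np.ndarray, mask: np.ndarray, Ws: list[np.ndarray],
                   as_: list[np.ndarray], slope: float,
                   drop_att=None, drop_in=None, cache: dict | None = None) -> np.ndarray:
    """Dense masked forward of one averaged multi-head attention layer.

    ``mask`` is the (N, N) boolean neighborhood matrix (self-loops included).
    ``drop_att``/``drop_in`` are optional inverted-dropout multiplier
    matrices applied to attention coefficients and input features during
    training.  If ``cache`` is given, intermediates needed by the backward
    pass are stored in it.
    """
    K = len(Ws)
    N = F.shape[0]
    Fin = F * drop_in if drop_in is not None else F
    P = np.zeros((N, Ws[0].shape[0]))
    per_head = []
    neg_inf = -1e30
    for k in range(K):
        H = Fin @ Ws[k].T
        d = Ws[k].shape[0]
        s = H @ as_[k][:d]
        t = H @ as_[k][d:]
        E = s[:, None] + t[None, :]
        eL = _leaky(E, slope)
        logits = np.where(mask, eL, neg_inf)
        logits = logits - logits.max(axis=1, keepdims=True)
        ex = np.exp(logits) * mask
        A = ex / ex.sum(axis=1, keepdims=True)
        A_used = A * drop_att[k] if drop_att is not None else A
        Z = A_used @ H
        P += Z
        per_head.append((H, E, A, A_used))
    P /= K
    out = _leaky(P, slope)
    if cache is not None:
        cache.update(Fin=Fin, per_head=per_head, P=P, out=out)
    return out


def _layer_backward(dOut: np.ndarray, F: np.ndarray, mask: np.ndarray,
                    Ws, as_, slope: float, cache: dict,
                    drop_att=None, drop_in=None):
    """Gradients of one layer w.r.t. its parameters and its input."""
    K = len(Ws)
    Fin = cache["Fin"]
    dP = dOut * _leaky_grad(cache["P"], slope) / K
    dWs, das = [], []
    dFin = np.zeros_like(Fin)
    for k in range(K):
        H, E, A, A_used = cache["per_head"][k]
        d = Ws[k].shape[0]
        a_src, a_dst = as_[k][:d], as_[k][d:]
        dZ = dP
        dA_used = dZ @ H.T
        dH = A_used.T @ dZ
        dA = dA_used * drop_att[k] if drop_att is not None else dA_used
        # softmax backward, row-wise over the masked neighborhood
        dE_L = A * (dA - (A * dA).sum(axis=1, keepdims=True))
        dE = dE_L * _leaky_grad(E, slope) * mask
        ds = dE.sum(axis=1)
        dt = dE.sum(axis=0)
        dH += ds[:, None] * a_src[None, :] + dt[:, None] * a_dst[None, :]
        da = np.concatenate([H.T @ ds, H.T @ dt])
        dWs.append(dH.T @ Fin)
        das.append(da)
        dFin += dH @ Ws[k]
    dF = dFin * drop_in if drop_in is not None else dFin
    return dWs, das, dF


def multi_head_forward(Ws, as_, features: np.ndarray, mask: np.ndarray,
                       leaky_slope: float = 0.2) -> np.ndarray:
    """Inference-mode forward pass (no dropout) of the averaged-head layer."""
    return _layer_forward(np.asarray(features, float), np.asarray(mask, bool),
                          [np.asarray(W, float) for W in Ws],
                          [np.asarray(a, float) for a in as_], leaky_slope)


def _loss_and_grads(F, mask, layers, relation, pairs, y, slope, drops=None):
    """Decoder BCE loss and analytic gradients of all parameters.

    Returns (loss, grads, embedding) where ``grads`` is ordered like the
    flat parameter list: per layer all Ws then all attention vectors,
    followed by the relation vector.
    """
    caches: list[dict] = []
    x = F
    for li, (Ws, as_) in enumerate(layers):
        cache: dict = {}
        da, di = (drops[li] if drops is not None else (None, None))
        x = _layer_forward(x, mask, Ws, as_, slope, drop_att=da, drop_in=di, cache=cache)
        caches.append(cache)
    emb = x

    ei, ej = emb[pairs[:, 0]], emb[pairs[:, 1]]
    z = (ei * relation * ej).sum(axis=1)
    p = _sigmoid(z)
    eps = 1e-12
    loss = -np.mean(y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps))

    dz = (p - y) / len(y)
    dRel = (dz[:, None] * ei * ej).sum(axis=0)
    dEmb = np.zeros_like(emb)
    np.add.at(dEmb, pairs[:, 0], dz[:, None] * (relation * ej))
    np.add.at(dEmb, pairs[:, 1], dz[:, None] * (relation * ei))

    dX = dEmb
    layer_grads = []
    xs = [F] + [c["out"] for c in caches[:-1]]
    for li in range(len(layers) - 1, -1, -1):
        Ws, as_ = layers[li]
        da, di = (drops[li] if drops is not None else (None, None))
        dWs, das, dX = _layer_backward(dX, xs[li], mask, Ws, as_, slope,
                                       caches[li], drop_att=da, drop_in=di)
        layer_grads.insert(0, (dWs, das))
    grads: list[np.ndarray] = []
    for dWs, das in layer_grads:
        grads.extend([*dWs, *das])
    grads.append(dRel)
    return loss, grads, emb


class _Adam:
    def __init__(self, params: list[np.ndarray], lr: float, weight_decay: float):
        self.params = params
        self.lr, self.wd = lr, weight_decay
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            g = g + self.wd * p
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + eps)


class GraphAttentionEncoder(BaseEstimator):
    """Self-supervised graph attention embedding of the association graph.

    Parameters
    ----------
    out_dim : embedding dimension l' (default 40).
    n_heads : number of attention heads r averaged per layer (default 4).
    dropout : dropout rate alpha on input features and attention
        coefficients during training (default 0.2).
    leaky_slope : negative slope beta of every LeakyReLU (default 0.2);
        a single beta parameterizes both the attention activation and the
        aggregation activation.
    hidden_units : width s of the optional first attention layer of the
        two-layer variant (default 68); unused unless ``two_layer=True``.
    two_layer : enable the hidden attention layer (default False; the
        written model is a single layer).
    epochs, learning_rate, weight_decay : Adam training controls.
    seed : controls initialization, dropout and negative sampling.

    Attributes (after ``fit``)
    --------------------------
    embedding_ : (m+n, out_dim) array F'.
    weights_ : list of per-layer (W, a) parameter lists.
    loss_history_ : per-epoch training loss.
    """

    def __init__(self, out_dim: int = 40, n_heads: int = 4, dropout: float = 0.2,
                 leaky_slope: float = 0.2, hidden_units: int = 68,
                 two_layer: bool = False, epochs: int = 200,
                 learning_rate: float = 1e-2, weight_decay: float = 5e-4,
                 neg_per_pos: int = 1, seed: int = 0):
        self.out_dim = out_dim
        self.n_heads = n_heads
        self.dropout = dropout
        self.leaky_slope = leaky_slope
        self.hidden_units = hidden_units
        self.two_layer = two_layer
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.weight_decay = weight_decay
        self.neg_per_pos = neg_per_pos
        self.seed = seed

    # -- helpers -----------------------------------------------------------

    def _init_params(self, rng: np.random.Generator, dims: list[tuple[int, int]]):
        layers = []
        for d_in, d_out in dims:
            Ws, as_ = [], []
            for _ in range(self.n_heads):
                lim_w = np.sqrt(6.0 / (d_in + d_out))
                Ws.append(rng.uniform(-lim_w, lim_w, size=(d_out, d_in)))
                lim_a = np.sqrt(6.0 / (2 * d_out + 1))
                as_.append(rng.uniform(-lim_a, lim_a, size=2 * d_out))
            layers.append((Ws, as_))
        return layers

    def _mask(self, n_nodes: int, edges: np.ndarray) -> np.ndarray:
        mask = np.eye(n_nodes, dtype=bool)
        if len(edges):
            mask[edges[:, 0], edges[:, 1]] = True
            mask[edges[:, 1], edges[:, 0]] = True
        return mask

    def _forward(self, F, mask, layers, caches=None, drops=None):
        x = F
        for li, (Ws, as_) in enumerate(layers):
            cache = {} if caches is not None else None
            da, di = (drops[li] if drops is not None else (None, None))
            x = _layer_forward(x, mask, Ws, as_, self.leaky_slope,
                              drop_att=da, drop_in=di, cache=cache)
            if caches is not None:
                caches.append(cache)
        return x

    # -- estimator API -----------------------------------------------------

    def fit(self, features, edges, n_mirnas: int | None = None):
        """Train on the bipartite graph.

        Parameters
        ----------
        features : (m+n, l) array or FeatureMatrix — the stacked linear
            features in canonical node order (miRNAs then diseases).
        edges : (n_edges, 2) int array of (miRNA node index, disease node
            index) pairs in *global* node indexing; these define both the
            attention neighborhoods and the positive decoder examples.
        n_mirnas : m; inferred as ``min(disease indices)`` if omitted.
        """
        F = features.values if isinstance(features, FeatureMatrix) else np.asarray(features, float)
        edges = np.asarray(edges, dtype=int)
        if edges.size == 0:
            raise ValueError("the association graph has no edges; nothing to train on")
        if (edges[:, 0] >= edges[:, 1]).any():
            raise ValueError("edges must be (miRNA index, disease index) with miRNA first")
        N = F.shape[0]
        m = int(n_mirnas) if n_mirnas is not None else int(edges[:, 1].min())
        n = N - m
        rng = np.random.default_rng(self.seed)
        mask = self._mask(N, edges)

        dims = ([(F.shape[1], self.hidden_units), (self.hidden_units, self.out_dim)]
                if self.two_layer else [(F.shape[1], self.out_dim)])
        layers = self._init_params(rng, dims)
        # DistMult-style decoder: learnable per-dimension relation weights
        relation = np.ones(self.out_dim)
        flat = [p for Ws, as_ in layers for p in (*Ws, *as_)] + [relation]
        opt = _Adam(flat, self.learning_rate, self.weight_decay)

        pos_set = {(int(i), int(j)) for i, j in edges}
        n_pos = len(edges)
        if len(pos_set) >= m * n:
            raise ValueError("graph is complete bipartite; no negative pairs to sample")
        keep = 1.0 - self.dropout
        self.loss_history_ = []
        for _ in range(self.epochs):
            # uniformly resampled non-edge miRNA-disease pairs
            n_neg = self.neg_per_pos * n_pos
            neg = []
            while len(neg) < n_neg:
                i = int(rng.integers(0, m))
                j = int(m + rng.integers(0, n))
                if (i, j) not in pos_set:
                    neg.append((i, j))
            neg = np.asarray(neg)
            pairs = np.vstack([edges, neg])
            y = np.concatenate([np.ones(n_pos), np.zeros(n_neg)])

            drops = None
            if self.dropout > 0:
                drops = []
                for Ws, _ in layers:
                    da = [(rng.random((N, N)) < keep) / keep for _ in Ws]
                    di = (rng.random((N, Ws[0].shape[1])) < keep) / keep
                    drops.append((da, di))
            loss, grads, _ = _loss_and_grads(F, mask, layers, relation, pairs, y,
                                             self.leaky_slope, drops=drops)
            self.loss_history_.append(float(loss))
            opt.step(grads)

        self.n_nodes_ = N
        self.n_mirnas_ = m
        self.weights_ = layers
        self.relation_ = relation
        self.mask_ = mask
        self.embedding_ = self._forward(F, mask, layers)
        return self

    def transform(self, features=None, edges=None) -> np.ndarray:
        """Embeddings for the training graph, or a forward pass on new inputs."""
        if features is None:
            return self.embedding_
        F = features.values if isinstance(features, FeatureMatrix) else np.asarray(features, float)
        mask = self._mask(F.shape[0], np.asarray(edges, int)) if edges is not None else self.mask_
        return self._forward(F, mask, self.weights_)

    def fit_transform(self, features, edges, n_mirnas: int | None = None) -> np.ndarray:
        return self.fit(features, edges, n_mirnas).embedding_


def train_encoder(features: FeatureMatrix, edges: np.ndarray, n_mirnas: int,
                  **params) -> tuple[FeatureMatrix, FeatureMatrix, GraphAttentionEncoder]:
    """Convenience wrapper: train and split F' into miRNA and disease blocks."""
    enc = GraphAttentionEncoder(**params)
    emb = enc.fit_transform(features, edges, n_mirnas)
    ids = list(features.node_ids)
    fm = FeatureMatrix(emb[:n_mirnas], ids[:n_mirnas], "nonlinear")
    fd = FeatureMatrix(emb[n_mirnas:], ids[n_mirnas:], "nonlinear")
    return fm, fd, enc
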