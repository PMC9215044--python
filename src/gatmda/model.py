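"""End-to-end association predictor.

``GATMDA`` wires the stages together: linear features from the similarity
and lncRNA-profile matrices, non-linear features from the graph attention
encoder trained on the (training-fold) association graph, concatenation
into pair vectors, and a random forest producing association scores.

``feature_mode`` selects what the classifier sees, which is also the axis
of the ablation study:

* ``full``       — [F, F'] (linear + attention embedding), the default
* ``linear``     — F only (no encoder is trained)
* ``nonlinear``  — F' only
* ``linear_svd`` — F plus a rank-l' truncated-SVD factorization of the
  training association matrix in place of F'
* ``linear_deepwalk`` — F plus skip-gram-style random-walk embeddings of
  the bipartite graph in place of F' (walk co-occurrence PPMI, factorized
  by truncated SVD)
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from .classifier import PairClassifier, score_all_pairs
from .datatypes import Bundle, FeatureMatrix, ScoreMatrix
from .fusion import fuse_node_features, pair_features
from .gat import GraphAttentionEncoder
from .linear_features import (
    disease_linear_features,
    mirna_linear_features,
    scale_features,
    stack_features,
)

__all__ = ["GATMDA"]


def _svd_embedding(md: np.ndarray, dim: int) -> tuple[np.ndarray, np.ndarray]:
    """Rank-``dim`` SVD factorization of the association matrix: rows
    embed miRNAs, columns embed diseases (singular values split evenly)."""
    U, S, Vt = np.linalg.svd(md.astype(float), full_matrices=False)
    k = min(dim, len(S))
    root = np.sqrt(S[:k])
    mi = U[:, :k] * root
    dis = Vt[:k].T * root
    if k < dim:  # pad so downstream dimensions stay fixed
        mi = np.hstack([mi, np.zeros((mi.shape[0], dim - k))])
        dis = np.hstack([dis, np.zeros((dis.shape[0], dim - k))])
    return mi, dis


def _deepwalk_embedding(md: np.ndarray, dim: int, rng: np.random.Generator,
                        walk_length: int = 10, walks_per_node: int = 10,
                        window: int = 5) -> tuple[np.ndarray, np.ndarray]:
    """Random-walk embeddings of the bipartite graph.

    Walk co-occurrences within the window are accumulated into a matrix
    whose positive PMI is factorized by truncated SVD — the standard
    closed-form stand-in for skip-gram training on walk corpora.
    """
    m, n = md.shape
    N = m + n
    adj: list[np.ndarray] = []
    for i in range(m):
        adj.append(m + np.flatnonzero(md[i]))
    for j in range(n):
        adj.append(np.flatnonzero(md[:, j]))
    C = np.zeros((N, N))
    for _ in range(walks_per_node):
        for start in range(N):
            walk = [start]
            for _ in range(walk_length - 1):
                nbrs = adj[walk[-1]]
                if len(nbrs) == 0:
                    break
                walk.append(int(nbrs[rng.integers(len(nbrs))]))
            for a in range(len(walk)):
                for b in range(a + 1, min(a + window + 1, len(walk))):
                    C[walk[a], walk[b]] += 1
                    C[walk[b], walk[a]] += 1
    total = C.sum()
    if total == 0:
        return np.zeros((m, dim)), np.zeros((n, dim))
    row = C.sum(axis=1, keepdims=True)
    row[row == 0] = 1.0
    with np.errstate(divide="ignore"):
        pmi = np.log(C * total / (row @ row.T))
    pmi[~np.isfinite(pmi)] = 0.0
    pmi = np.maximum(pmi, 0.0)
    U, S, _ = np.linalg.svd(pmi, full_matrices=False)
    k = min(dim, len(S))
    emb = U[:, :k] * np.sqrt(S[:k])
    if k < dim:
        emb = np.hstack([emb, np.zeros((N, dim - k))])
    return emb[:m], emb[m:]


class GATMDA(BaseEstimator):
    """Full linear + graph-attention + random-forest association predictor.

    The constructor mirrors the tuned operating point: attention dropout
    alpha=0.2, LeakyReLU slope beta=0.2, hidden width s=68 (two-layer
    variant only), embedding dimension l'=40, r=4 heads, and a 350-tree
    forest.  ``negatives`` controls the training negative set drawn from the
    unlabeled pairs: ``sampled_kto1`` (default; ``neg_ratio`` sampled
    negatives per positive, leaving the bulk of unlabeled pairs unseen so
    evaluation can rank pairs the forest never trained on),
    ``sampled_1to1``, or ``all``.
    """

    def __init__(self, feature_mode: str = "full", feature_scaling: str = "none",
                 out_dim: int = 40, n_heads: int = 4, dropout: float = 0.2,
                 leaky_slope: float = 0.2, hidden_units: int = 68,
                 two_layer: bool = False, epochs: int = 200,
                 learning_rate: float = 1e-2, weight_decay: float = 5e-4,
                 n_trees: int = 350, features_per_split="sqrt",
                 bootstrap: bool = True, hard_vote: bool = False,
                 negatives: str = "sampled_kto1", neg_ratio: int = 10, seed: int = 0):
        self.feature_mode = feature_mode
        self.feature_scaling = feature_scaling
        self.out_dim = out_dim
        self.n_heads = n_heads
        self.dropout = dropout
        self.leaky_slope = leaky_slope
        self.hidden_units = hidden_units
        self.two_layer = two_layer
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.weight_decay = weight_decay
        self.n_trees = n_trees
        self.features_per_split = features_per_split
        self.bootstrap = bootstrap
        self.hard_vote = hard_vote
        self.negatives = negatives
        self.neg_ratio = neg_ratio
        self.seed = seed

    def _node_features(self, bundle: Bundle, train_mask: np.ndarray,
                       rng: np.random.Generator):
        m = bundle.m
        fm = scale_features(mirna_linear_features(bundle.fs, bundle.ml), self.feature_scaling)
        fd = scale_features(disease_linear_features(bundle.ds, bundle.dl), self.feature_scaling)
        self.encoder_ = None
        mode = self.feature_mode
        if mode == "linear":
            return fm, fd
        if mode in ("full", "nonlinear"):
            stacked = stack_features(fm, fd)
            pos = np.argwhere(train_mask)
            edges = np.column_stack([pos[:, 0], m + pos[:, 1]])
            enc = GraphAttentionEncoder(
                out_dim=self.out_dim, n_heads=self.n_heads, dropout=self.dropout,
                leaky_slope=self.leaky_slope, hidden_units=self.hidden_units,
                two_layer=self.two_layer, epochs=self.epochs,
                learning_rate=self.learning_rate, weight_decay=self.weight_decay,
                seed=int(rng.integers(2**31)),
            )
            emb = enc.fit_transform(stacked, edges, n_mirnas=m)
            self.encoder_ = enc
            fpm = FeatureMatrix(emb[:m], bundle.mirna_ids, "nonlinear")
            fpd = FeatureMatrix(emb[m:], bundle.disease_ids, "nonlinear")
            if mode == "nonlinear":
                return fpm, fpd
            return fuse_node_features(fm, fpm), fuse_node_features(fd, fpd)
        if mode == "linear_svd":
            mi, dis = _svd_embedding(train_mask.astype(float), self.out_dim)
        elif mode == "linear_deepwalk":
            mi, dis = _deepwalk_embedding(train_mask.astype(np.int8), self.out_dim, rng)
        else:
            raise ValueError(f"unknown feature_mode {self.feature_mode!r}")
        fpm = FeatureMatrix(mi, bundle.mirna_ids, "nonlinear")
        fpd = FeatureMatrix(dis, bundle.disease_ids, "nonlinear")
        return fuse_node_features(fm, fpm), fuse_node_features(fd, fpd)

    def fit(self, bundle: Bundle, train_mask: np.ndarray | None = None,
            exclude_from_negatives: np.ndarray | None = None):
        """Train on the given positive mask (default: all of MD).

        ``train_mask`` is a boolean m x n matrix of the positives available
        for training (both the graph and the classifier).  Pairs flagged in
        ``exclude_from_negatives`` (e.g. held-out test positives) are kept
        out of the training negatives as well, so they never reach the
        forest in any role.
        """
        md = bundle.md.values.astype(bool)
        train_mask = md if train_mask is None else np.asarray(train_mask, bool)
        if train_mask.shape != md.shape:
            raise ValueError("train_mask shape does not match MD")
        rng = np.random.default_rng(np.random.SeedSequence(self.seed))
        mi_fused, dis_fused = self._node_features(bundle, train_mask, rng)

        pos = np.argwhere(train_mask)
        neg_pool = ~train_mask
        if exclude_from_negatives is not None:
            neg_pool &= ~np.asarray(exclude_from_negatives, bool)
        neg = np.argwhere(neg_pool)
        if self.negatives == "all":
            pass
        elif self.negatives in ("sampled_1to1", "sampled_kto1"):
            ratio = 1 if self.negatives == "sampled_1to1" else self.neg_ratio
            want = min(len(neg), ratio * len(pos))
            neg = neg[rng.choice(len(neg), size=want, replace=False)]
        else:
            raise ValueError(f"unknown negatives mode {self.negatives!r}")

        pairs = np.vstack([pos, neg])
        y = np.concatenate([np.ones(len(pos), int), np.zeros(len(neg), int)])
        X = pair_features(mi_fused, dis_fused, pairs)
        clf = PairClassifier(
            n_trees=self.n_trees, features_per_split=self.features_per_split,
            bootstrap=self.bootstrap, hard_vote=self.hard_vote,
            seed=int(rng.integers(2**31)),
        )
        clf.fit(X, y)

        self.bundle_ = bundle
        self.classifier_ = clf
        self.mi_fused_ = mi_fused
        self.dis_fused_ = dis_fused
        self.train_mask_ = train_mask
        self.train_pairs_ = pairs
        self.train_pair_set_ = {(int(i), int(j)) for i, j in pairs}
        return self

    def predict_pairs(self, pairs) -> np.ndarray:
        """Scores for (miRNA index, disease index) pairs."""
        X = pair_features(self.mi_fused_, self.dis_fused_, pairs)
        return self.classifier_.predict_score(X)

    def predict_scores(self) -> ScoreMatrix:
        """Score matrix over all m x n pairs; training positives are flagged."""
        return score_all_pairs(self.classifier_, self.mi_fused_, self.dis_fused_,
                               known_mask=self.train_mask_)
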