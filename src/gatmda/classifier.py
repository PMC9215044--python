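"""Random-forest scoring of miRNA-disease pair features.

M decision trees (default 350) are each grown on a bootstrap resample of
the N training pairs, considering a random subset of k feature dimensions
per split (default sqrt of the pair dimension).  A pair's score is the
fraction of trees voting "associated" (hard vote) or the forest-averaged
positive class probability (soft vote, the default — it yields smoother
rankings for top-k candidate lists).
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier

from .datatypes import FeatureMatrix, ScoreMatrix
from .fusion import iter_pair_blocks

__all__ = ["PairClassifier", "score_all_pairs"]


class PairClassifier(BaseEstimator, ClassifierMixin):
    """Random forest over fused pair features.

    Parameters
    ----------
    n_trees : number of trees M (default 350).
    features_per_split : "sqrt" or an integer k of feature dimensions
        considered at each split.
    bootstrap : grow each tree on an N-sized resample (default True).
    hard_vote : score by majority-vote fraction instead of averaged leaf
        class probabilities.
    seed : forest randomness.
    """

    def __init__(self, n_trees: int = 350, features_per_split="sqrt",
                 bootstrap: bool = True, hard_vote: bool = False, seed: int = 0):
        self.n_trees = n_trees
        self.features_per_split = features_per_split
        self.bootstrap = bootstrap
        self.hard_vote = hard_vote
        self.seed = seed

    def fit(self, X, y):
        X = np.asarray(X, float)
        y = np.asarray(y)
        if len(np.unique(y)) < 2:
            raise ValueError("training pairs contain a single class; need both labels")
        self.forest_ = RandomForestClassifier(
            n_estimators=self.n_trees,
            max_features=self.features_per_split,
            bootstrap=self.bootstrap,
            random_state=self.seed,
            n_jobs=1,
        )
        self.forest_.fit(X, y)
        self.n_features_in_ = X.shape[1]
        self.classes_ = self.forest_.classes_
        return self

    def predict_score(self, X) -> np.ndarray:
        """Association score in [0, 1] per pair."""
        X = np.asarray(X, float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"pair features have {X.shape[1]} dims, forest trained on {self.n_features_in_}"
            )
        if self.hard_vote:
            pos = self.classes_.tolist().index(1)
            votes = np.stack([
                (tree.predict(X) == self.classes_[pos]) for tree in self.forest_.estimators_
            ])
            return votes.mean(axis=0)
        pos = self.classes_.tolist().index(1)
        return self.forest_.predict_proba(X)[:, pos]

    def predict(self, X, threshold: float = 0.5) -> np.ndarray:
        return (self.predict_score(X) >= threshold).astype(int)


def score_all_pairs(
    clf: PairClassifier,
    mi_fused: FeatureMatrix,
    dis_fused: FeatureMatrix,
    known_mask: np.ndarray | None = None,
    block_size: int = 50_000,
) -> ScoreMatrix:
    """Score every miRNA x disease pair, blockwise to bound memory."""
    m, n = mi_fused.n_nodes, dis_fused.n_nodes
    values = np.empty((m, n))
    for block, X in iter_pair_blocks(mi_fused, dis_fused, block_size):
        values[block[:, 0], block[:, 1]] = clf.predict_score(X)
    return ScoreMatrix(values, list(mi_fused.node_ids), list(dis_fused.node_ids), known_mask)
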