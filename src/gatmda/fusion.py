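"""Fusion of linear and non-linear features into node and pair vectors.

Node fusion is plain concatenation, [F, F'] per node (dim l + l').  A
miRNA-disease pair (i, j) is represented by the fixed-order concatenation

    [f_m_i, f'_m_i, f_d_j, f'_d_j]   in R^{2 (l + l')}

i.e. the fused miRNA vector followed by the fused disease vector.  This
order is part of the trained-model contract; tests pin it.
"""

from __future__ import annotations

from typing import Iterator, Sequence

import numpy as np

from .datatypes import FeatureMatrix

__all__ = ["fuse_node_features", "pair_features", "iter_pair_blocks"]


def fuse_node_features(linear: FeatureMatrix, nonlinear: FeatureMatrix) -> FeatureMatrix:
    """[F, F'] per node; both inputs must share the node set and order."""
    if list(linear.node_ids) != list(nonlinear.node_ids):
        raise ValueError("linear and non-linear features are over different node orders")
    return FeatureMatrix(
        np.hstack([linear.values, nonlinear.values]), list(linear.node_ids), "fused"
    )


def pair_features(
    mi_fused: FeatureMatrix,
    dis_fused: FeatureMatrix,
    pairs: Sequence[tuple[int, int]] | np.ndarray,
) -> np.ndarray:
    """Feature vectors for (miRNA index, disease index) pairs, input order kept."""
    pairs = np.asarray(pairs, dtype=int).reshape(-1, 2)
    if pairs.size and (
        pairs[:, 0].min() < 0 or pairs[:, 0].max() >= mi_fused.n_nodes
        or pairs[:, 1].min() < 0 or pairs[:, 1].max() >= dis_fused.n_nodes
    ):
        raise IndexError("pair index out of range")
    return np.hstack([mi_fused.values[pairs[:, 0]], dis_fused.values[pairs[:, 1]]])


def iter_pair_blocks(
    mi_fused: FeatureMatrix, dis_fused: FeatureMatrix, block_size: int = 50_000
) -> Iterator[tuple[np.ndarray, np.ndarray]]:
    """All m x n pairs in row-major blocks: yields (pairs, features).

    Lazily bounds memory when scoring the full grid.
    """
    m, n = mi_fused.n_nodes, dis_fused.n_nodes
    all_pairs = np.indices((m, n)).reshape(2, -1).T
    for start in range(0, len(all_pairs), block_size):
        block = all_pairs[start : start + block_size]
        yield block, pair_features(mi_fused, dis_fused, block)
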