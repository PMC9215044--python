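"""Linear node features: similarity matrices times lncRNA association profiles.

Each miRNA's linear feature is its similarity-weighted miRNA-lncRNA profile
(F_m = FS @ ML) and each disease's is its similarity-weighted
disease-lncRNA profile (F_d = D_s @ DL); both live in R^l where l is the
number of lncRNAs.  Stacking miRNAs over diseases gives the (m+n) x l
initial feature matrix of the heterogeneous graph.
"""

from __future__ import annotations

import numpy as np

from .datatypes import AssociationMatrix, FeatureMatrix, SimilarityMatrix

__all__ = [
    "mirna_linear_features",
    "disease_linear_features",
    "stack_features",
    "unstack_features",
    "scale_features",
]


def mirna_linear_features(fs: SimilarityMatrix, ml: AssociationMatrix) -> FeatureMatrix:
    """F_m = FS @ ML, one l-dimensional row per miRNA."""
    if list(fs.ids) != list(ml.row_ids):
        raise ValueError("FS and ML miRNA identifiers are not aligned")
    return FeatureMatrix(fs.values @ ml.values, list(fs.ids), "linear")


def disease_linear_features(ds: SimilarityMatrix, dl: AssociationMatrix) -> FeatureMatrix:
    """F_d = D_s @ DL, one l-dimensional row per disease."""
    if list(ds.ids) != list(dl.row_ids):
        raise ValueError("Ds and DL disease identifiers are not aligned")
    return FeatureMatrix(ds.values @ dl.values, list(ds.ids), "linear")


def stack_features(fm: FeatureMatrix, fd: FeatureMatrix) -> FeatureMatrix:
    """F = [F_m; F_d]: miRNA rows first, then disease rows."""
    if fm.dim != fd.dim:
        raise ValueError(f"feature dimension mismatch: {fm.dim} vs {fd.dim}")
    values = np.vstack([fm.values, fd.values])
    return FeatureMatrix(values, list(fm.node_ids) + list(fd.node_ids), fm.feature_kind)


def unstack_features(f: FeatureMatrix, m: int) -> tuple[FeatureMatrix, FeatureMatrix]:
    """Split a stacked matrix back into (miRNA block, disease block)."""
    return (
        FeatureMatrix(f.values[:m], list(f.node_ids)[:m], f.feature_kind),
        FeatureMatrix(f.values[m:], list(f.node_ids)[m:], f.feature_kind),
    )


def scale_features(f: FeatureMatrix, mode: str = "none") -> FeatureMatrix:
    """Optional feature scaling; the pipeline default applies none."""
    if mode == "none":
        return f
    v = f.values
    if mode == "l2_row":
        norms = np.linalg.norm(v, axis=1, keepdims=True)
        norms[norms == 0] = 1.0
        v = v / norms
    elif mode == "zscore":
        sd = v.std(axis=0, keepdims=True)
        sd[sd == 0] = 1.0
        v = (v - v.mean(axis=0, keepdims=True)) / sd
    else:
        raise ValueError(f"unknown scaling mode {mode!r}")
    return FeatureMatrix(v, list(f.node_ids), f.feature_kind)
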