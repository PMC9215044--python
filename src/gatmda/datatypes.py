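"""Core containers for the heterogeneous miRNA-disease-lncRNA dataset.

All matrices carry explicit identifier lists so that alignment across files
is checked rather than assumed.  The canonical node order for the
heterogeneous graph is miRNAs first (indices ``0..m-1``) then diseases
(``m..m+n-1``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

__all__ = [
    "AssociationMatrix",
    "SimilarityMatrix",
    "DiseaseDAG",
    "FeatureMatrix",
    "ScoreMatrix",
    "Bundle",
]

_SYM_TOL = 1e-9


def _check_unique(ids: Sequence[str], axis: str) -> list[str]:
    ids = [str(x) for x in ids]
    if len(set(ids)) != len(ids):
        seen, dups = set(), []
        for x in ids:
            if x in seen:
                dups.append(x)
            seen.add(x)
        raise ValueError(f"duplicate {axis} identifiers: {sorted(set(dups))[:5]}")
    return ids


@dataclass
class AssociationMatrix:
    """Binary bipartite adjacency (MD, ML or DL) with named axes."""

    values: np.ndarray
    row_ids: Sequence[str]
    col_ids: Sequence[str]
    kind: str = "miRNA-disease"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("association matrix must be 2-D")
        uniq = np.unique(self.values)
        if not np.isin(uniq, (0, 1)).all():
            bad = uniq[~np.isin(uniq, (0, 1))]
            raise ValueError(f"association entries must be 0/1, found {bad[:5]}")
        self.values = self.values.astype(np.int8)
        self.row_ids = _check_unique(self.row_ids, "row")
        self.col_ids = _check_unique(self.col_ids, "column")
        if self.values.shape != (len(self.row_ids), len(self.col_ids)):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"({len(self.row_ids)}, {len(self.col_ids)}) identifiers"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def density(self) -> float:
        return float(self.values.mean())

    def reindex(self, row_ids: Sequence[str], col_ids: Sequence[str]) -> "AssociationMatrix":
        ri = [self.row_ids.index(r) for r in row_ids]
        ci = [self.col_ids.index(c) for c in col_ids]
        return AssociationMatrix(self.values[np.ix_(ri, ci)], list(row_ids), list(col_ids), self.kind)


@dataclass
class SimilarityMatrix:
    """Square symmetric similarity with entries in [0, 1] and unit diagonal."""

    values: np.ndarray
    ids: Sequence[str]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("similarity matrix must be square")
        if not np.allclose(v, v.T, atol=_SYM_TOL):
            raise ValueError("similarity matrix is not symmetric within 1e-9")
        if v.min() < -1e-9 or v.max() > 1 + 1e-9:
            raise ValueError(
                f"similarity entries outside [0, 1]: min={v.min():.3g} max={v.max():.3g}"
            )
        np.fill_diagonal(v, 1.0)
        self.values = np.clip(v, 0.0, 1.0)
        self.ids = _check_unique(self.ids, "similarity")
        if len(self.ids) != v.shape[0]:
            raise ValueError("identifier count does not match matrix size")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def reindex(self, ids: Sequence[str]) -> "SimilarityMatrix":
        idx = [self.ids.index(i) for i in ids]
        return SimilarityMatrix(self.values[np.ix_(idx, idx)], list(ids))


class DiseaseDAG:
    """Directed acyclic graph of disease terms (edges run parent -> child).

    ``disease_to_terms`` maps each disease to one or more term positions; a
    disease occupying several positions is treated as the union of the
    ancestor closures of its positions.
    """

    def __init__(
        self,
        edges: Iterable[tuple[str, str]],
        disease_to_terms: Mapping[str, Sequence[str]],
        terms: Sequence[str] | None = None,
    ) -> None:
        self.graph = nx.DiGraph()
        if terms is not None:
            self.graph.add_nodes_from(str(t) for t in terms)
        self.graph.add_edges_from((str(p), str(c)) for p, c in edges)
        if not nx.is_directed_acyclic_graph(self.graph):
            cycle = nx.find_cycle(self.graph)
            raise ValueError(f"DAG contains a cycle: {cycle}")
        self.disease_to_terms: dict[str, tuple[str, ...]] = {}
        for dis, ts in disease_to_terms.items():
            ts = (ts,) if isinstance(ts, str) else tuple(str(t) for t in ts)
            missing = [t for t in ts if t not in self.graph]
            if missing:
                raise ValueError(f"disease {dis!r} maps to unknown term(s) {missing}")
            if not ts:
                raise ValueError(f"disease {dis!r} maps to no terms")
            self.disease_to_terms[str(dis)] = ts

    @property
    def terms(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def edges(self) -> list[tuple[str, str]]:
        return list(self.graph.edges)

    @property
    def diseases(self) -> list[str]:
        return list(self.disease_to_terms)

    def ancestors(self, term: str) -> set[str]:
        return nx.ancestors(self.graph, term)

    def term_set(self, disease: str) -> set[str]:
        """T(D): the disease's own term position(s) plus all their ancestors."""
        if disease not in self.disease_to_terms:
            raise KeyError(f"disease {disease!r} is not mapped in the DAG")
        out: set[str] = set()
        for t in self.disease_to_terms[disease]:
            out.add(t)
            out |= nx.ancestors(self.graph, t)
        return out

    def children(self, term: str) -> set[str]:
        return set(self.graph.successors(term))


@dataclass
class FeatureMatrix:
    """Per-node real feature vectors aligned with an explicit node order."""

    values: np.ndarray
    node_ids: Sequence[str]
    feature_kind: str = "linear"  # linear | nonlinear | fused

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("feature matrix must be 2-D")
        self.node_ids = _check_unique(self.node_ids, "node")
        if len(self.node_ids) != self.values.shape[0]:
            raise ValueError("node identifier count does not match row count")

    @property
    def dim(self) -> int:
        return self.values.shape[1]

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]


@dataclass
class ScoreMatrix:
    """All-pairs miRNA x disease association scores in [0, 1]."""

    values: np.ndarray
    row_ids: Sequence[str]
    col_ids: Sequence[str]
    known_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.min() < 0 or self.values.max() > 1:
            raise ValueError("scores must lie in [0, 1]")
        if self.known_mask is not None:
            self.known_mask = np.asarray(self.known_mask).astype(bool)
            if self.known_mask.shape != self.values.shape:
                raise ValueError("known_mask shape mismatch")

    def top_k(self, disease: str, k: int = 50, exclude_known: bool = True):
        """Ranked miRNA candidates for one disease.

        Ties are broken by miRNA identifier so candidate lists are stable.
        Returns a list of (rank, mirna, score, known_flag).
        """
        j = list(self.col_ids).index(disease)
        known = self.known_mask[:, j] if self.known_mask is not None else np.zeros(len(self.row_ids), bool)
        order = sorted(
            range(len(self.row_ids)),
            key=lambda i: (-self.values[i, j], self.row_ids[i]),
        )
        out = []
        for i in order:
            if exclude_known and known[i]:
                continue
            out.append((len(out) + 1, self.row_ids[i], float(self.values[i, j]), bool(known[i])))
            if len(out) == k:
                break
        return out


@dataclass
class Bundle:
    """Aligned dataset: all matrices share one canonical identifier order."""

    md: AssociationMatrix
    ml: AssociationMatrix
    dl: AssociationMatrix
    fs: SimilarityMatrix
    ds: SimilarityMatrix
    dag: DiseaseDAG | None = None
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.md.row_ids != self.ml.row_ids or self.md.row_ids != self.fs.ids:
            raise ValueError("miRNA identifier order differs across MD/ML/FS")
        if self.md.col_ids != self.dl.row_ids or self.md.col_ids != self.ds.ids:
            raise ValueError("disease identifier order differs across MD/DL/Ds")
        if self.ml.col_ids != self.dl.col_ids:
            raise ValueError("lncRNA identifier order differs between ML and DL")

    @property
    def m(self) -> int:
        return len(self.md.row_ids)

    @property
    def n(self) -> int:
        return len(self.md.col_ids)

    @property
    def l(self) -> int:
        return len(self.ml.col_ids)

    @property
    def mirna_ids(self) -> list[str]:
        return list(self.md.row_ids)

    @property
    def disease_ids(self) -> list[str]:
        return list(self.md.col_ids)

    @property
    def lncrna_ids(self) -> list[str]:
        return list(self.ml.col_ids)

    def positive_pairs(self) -> np.ndarray:
        """(n_pos, 2) array of (miRNA index, disease index) for MD == 1."""
        return np.argwhere(self.md.values == 1)
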