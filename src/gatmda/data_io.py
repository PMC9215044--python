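"""Readers and writers for the plain-text exchange formats.

Edge lists are header-less TSV (row_id, col_id[, weight in {0,1}]); dense
matrices are CSV with a header row of column identifiers and the row
identifier in the first column.  DAGs are a TSV of (parent, child) term
pairs plus a TSV mapping (disease_id, term_id).
"""

from __future__ import annotations

import os
from typing import Sequence

import numpy as np
import pandas as pd

from .datatypes import AssociationMatrix, Bundle, DiseaseDAG, SimilarityMatrix

__all__ = [
    "read_association_matrix",
    "write_association_matrix",
    "read_similarity_matrix",
    "write_similarity_matrix",
    "read_dag",
    "align_datasets",
]

_ASYM_TOL = 1e-6


def _norm(s: str, normalize: bool) -> str:
    return s.strip().lower() if normalize else s


def read_association_matrix(
    path: str,
    format: str = "edge-list",
    row_ids: Sequence[str] | None = None,
    col_ids: Sequence[str] | None = None,
    kind: str = "miRNA-disease",
    normalize_ids: bool = False,
) -> AssociationMatrix:
    """Read a binary association matrix.

    For edge lists, identifiers default to order of first appearance unless
    explicit ``row_ids``/``col_ids`` are supplied (needed to represent
    all-zero rows/columns).  Missing pairs are 0.
    """
    if format == "dense":
        df = pd.read_csv(path, index_col=0)
        rows = [_norm(str(r), normalize_ids) for r in df.index]
        cols = [_norm(str(c), normalize_ids) for c in df.columns]
        return AssociationMatrix(df.to_numpy(), rows, cols, kind)
    if format != "edge-list":
        raise ValueError(f"unknown format {format!r}")

    edges: dict[tuple[str, str], int] = {}
    seen_rows: list[str] = []
    seen_cols: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) not in (2, 3):
                raise ValueError(f"{path}:{lineno}: expected 2-3 TSV fields, got {len(parts)}")
            r, c = _norm(parts[0], normalize_ids), _norm(parts[1], normalize_ids)
            if not r or not c:
                raise ValueError(f"{path}:{lineno}: empty identifier")
            if len(parts) == 3:
                try:
                    w = float(parts[2])
                except ValueError:
                    raise ValueError(f"{path}:{lineno}: non-numeric weight {parts[2]!r}") from None
                if w not in (0.0, 1.0):
                    raise ValueError(f"{path}:{lineno}: non-binary weight {w}")
                w = int(w)
            else:
                w = 1
            key = (r, c)
            if key in edges and edges[key] != w:
                raise ValueError(f"{path}:{lineno}: duplicate edge {key} with conflicting value")
            edges[key] = w
            if r not in seen_rows:
                seen_rows.append(r)
            if c not in seen_cols:
                seen_cols.append(c)

    rows = list(row_ids) if row_ids is not None else seen_rows
    cols = list(col_ids) if col_ids is not None else seen_cols
    if normalize_ids:
        rows = [_norm(r, True) for r in rows]
        cols = [_norm(c, True) for c in cols]
    ridx = {r: i for i, r in enumerate(rows)}
    cidx = {c: i for i, c in enumerate(cols)}
    values = np.zeros((len(rows), len(cols)), dtype=np.int8)
    for (r, c), w in edges.items():
        if r not in ridx:
            raise ValueError(f"edge row identifier {r!r} not in declared row_ids")
        if c not in cidx:
            raise ValueError(f"edge column identifier {c!r} not in declared col_ids")
        values[ridx[r], cidx[c]] = w
    return AssociationMatrix(values, rows, cols, kind)


def write_association_matrix(mat: AssociationMatrix, path: str, format: str = "dense") -> None:
    if format == "dense":
        pd.DataFrame(mat.values, index=list(mat.row_ids), columns=list(mat.col_ids)).to_csv(path)
    elif format == "edge-list":
        with open(path, "w") as fh:
            for i, j in np.argwhere(mat.values == 1):
                fh.write(f"{mat.row_ids[i]}\t{mat.col_ids[j]}\n")
    else:
        raise ValueError(f"unknown format {format!r}")


def read_similarity_matrix(path: str, normalize_ids: bool = False) -> SimilarityMatrix:
    """Read a dense CSV similarity matrix.

    Asymmetry up to 1e-6 is repaired by averaging with the transpose;
    anything larger is an error.  The diagonal is forced to 1.
    """
    df = pd.read_csv(path, index_col=0)
    rows = [_norm(str(r), normalize_ids) for r in df.index]
    cols = [_norm(str(c), normalize_ids) for c in df.columns]
    if rows != cols:
        raise ValueError(f"{path}: row and column identifiers disagree")
    v = df.to_numpy(dtype=float)
    asym = np.abs(v - v.T).max() if v.size else 0.0
    if asym > _ASYM_TOL:
        raise ValueError(f"{path}: asymmetry {asym:.3g} exceeds {_ASYM_TOL}")
    v = (v + v.T) / 2.0
    if v.size and (v.min() < -_ASYM_TOL or v.max() > 1 + _ASYM_TOL):
        raise ValueError(f"{path}: entries outside [0, 1]")
    v = np.clip(v, 0.0, 1.0)
    np.fill_diagonal(v, 1.0)
    return SimilarityMatrix(v, rows)


def write_similarity_matrix(sim: SimilarityMatrix, path: str) -> None:
    pd.DataFrame(sim.values, index=list(sim.ids), columns=list(sim.ids)).to_csv(path)


def read_dag(dag_path: str, map_path: str, normalize_ids: bool = False) -> DiseaseDAG:
    """Read a disease DAG: (parent, child) TSV plus (disease, term) TSV."""
    edges = []
    with open(dag_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{dag_path}:{lineno}: expected 2 TSV fields")
            edges.append((_norm(parts[0], normalize_ids), _norm(parts[1], normalize_ids)))
    mapping: dict[str, list[str]] = {}
    with open(map_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{map_path}:{lineno}: expected 2 TSV fields")
            d, t = _norm(parts[0], normalize_ids), _norm(parts[1], normalize_ids)
            mapping.setdefault(d, []).append(t)
    return DiseaseDAG(edges, mapping)


def write_dag(dag: DiseaseDAG, dag_path: str, map_path: str) -> None:
    with open(dag_path, "w") as fh:
        for p, c in dag.edges:
            fh.write(f"{p}\t{c}\n")
    with open(map_path, "w") as fh:
        for d, ts in dag.disease_to_terms.items():
            for t in ts:
                fh.write(f"{d}\t{t}\n")


def _ordered_intersection(order: Sequence[str], *others: Sequence[str]) -> list[str]:
    keep = set(order)
    for o in others:
        keep &= set(o)
    return [x for x in order if x in keep]


def align_datasets(
    md: AssociationMatrix,
    ml: AssociationMatrix,
    dl: AssociationMatrix,
    fs: SimilarityMatrix,
    ds: SimilarityMatrix,
    dag: DiseaseDAG | None = None,
) -> Bundle:
    """Reindex all matrices to the intersection of identifiers per axis.

    The canonical order is MD's row order for miRNAs, MD's column order for
    diseases, and ML's column order for lncRNAs.  Idempotent on an already
    aligned bundle.
    """
    mirnas = _ordered_intersection(md.row_ids, ml.row_ids, fs.ids)
    diseases = _ordered_intersection(md.col_ids, dl.row_ids, ds.ids)
    lncrnas = _ordered_intersection(ml.col_ids, dl.col_ids)
    for name, ids in (("miRNA", mirnas), ("disease", diseases), ("lncRNA", lncrnas)):
        if not ids:
            raise ValueError(f"empty {name} identifier intersection")
    return Bundle(
        md=md.reindex(mirnas, diseases),
        ml=ml.reindex(mirnas, lncrnas),
        dl=dl.reindex(diseases, lncrnas),
        fs=fs.reindex(mirnas),
        ds=ds.reindex(diseases),
        dag=dag,
    )


def write_bundle(bundle: Bundle, outdir: str) -> dict[str, str]:
    """Write a full aligned bundle in the exchange formats; returns paths."""
    os.makedirs(outdir, exist_ok=True)
    paths = {
        "md": os.path.join(outdir, "MD.tsv"),
        "ml": os.path.join(outdir, "ML.tsv"),
        "dl": os.path.join(outdir, "DL.tsv"),
        "fs": os.path.join(outdir, "FS.csv"),
        "ds": os.path.join(outdir, "Ds.csv"),
    }
    write_association_matrix(bundle.md, paths["md"], "edge-list")
    write_association_matrix(bundle.ml, paths["ml"], "edge-list")
    write_association_matrix(bundle.dl, paths["dl"], "edge-list")
    write_similarity_matrix(bundle.fs, paths["fs"])
    write_similarity_matrix(bundle.ds, paths["ds"])
    for axis, ids in (("mirnas", bundle.mirna_ids), ("diseases", bundle.disease_ids), ("lncrnas", bundle.lncrna_ids)):
        p = os.path.join(outdir, f"{axis}.txt")
        with open(p, "w") as fh:
            fh.write("\n".join(ids) + "\n")
        paths[axis] = p
    if bundle.dag is not None:
        paths["dag"] = os.path.join(outdir, "dag.tsv")
        paths["d2t"] = os.path.join(outdir, "disease_terms.tsv")
        write_dag(bundle.dag, paths["dag"], paths["d2t"])
    return paths
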