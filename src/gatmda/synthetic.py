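"""Synthetic heterogeneous datasets with planted community structure.

The generator emulates the statistical shape of the real inputs: a sparse
binary miRNA-disease matrix (~3% density, matching the 5430/(495*383)
regime of curated association catalogues), miRNA-lncRNA and disease-lncRNA
profiles correlated with community identity, a block-consistent miRNA
functional similarity, and a toy disease DAG in which same-community
diseases sit in the same subtree, so that the DAG-derived semantic
similarity is itself block-informative.

miRNAs and diseases are partitioned into ``n_blocks`` communities;
associations appear with probability ``p_in`` within a community and
``p_out`` across.  Each community owns an equal slice of the lncRNAs as its
signature; profile entries are Bernoulli(``lnc_signal``) on the signature
and Bernoulli(``lnc_noise``) off it.

All randomness flows from one seed through named child streams, so adding
a component never shifts the draws of another.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datatypes import AssociationMatrix, Bundle, DiseaseDAG, SimilarityMatrix
from .similarity import SemanticConfig, disease_similarity_matrix

__all__ = ["SynthConfig", "generate_bundle", "generate_toy_dag",
           "generate_random_dag", "shuffle_associations"]


@dataclass
class SynthConfig:
    """Study conditions of the synthetic benchmark (defaults are *the* benchmark)."""

    m: int = 100
    n: int = 80
    l: int = 20
    n_blocks: int = 4
    p_in: float = 0.12
    p_out: float = 0.001
    lnc_signal: float = 0.12
    lnc_noise: float = 0.01
    fs_in: float = 0.6
    fs_out: float = 0.15
    fs_noise: float = 0.1
    sim_noise_frac: float = 0.3
    propensity_sigma: float = 1.2
    dag_depth: int = 3
    dag_branching: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_out < self.p_in <= 1.0:
            raise ValueError("need 0 <= p_out < p_in <= 1")


def _streams(seed: int, names: list[str]) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {name: np.random.default_rng(ss) for name, ss in zip(names, children)}


def _blocks(count: int, n_blocks: int) -> np.ndarray:
    # contiguous block labels with sizes differing by <= 1
    chunks = np.array_split(np.arange(count), n_blocks)
    return np.concatenate([np.full(len(ch), b) for b, ch in enumerate(chunks)])


def _profile(rng: np.random.Generator, blocks: np.ndarray, l: int, n_blocks: int,
             p_sig: float, p_bg: float) -> np.ndarray:
    lnc_block = _blocks(l, n_blocks)
    sig = blocks[:, None] == lnc_block[None, :]
    p = np.where(sig, p_sig, p_bg)
    return (rng.random(p.shape) < p).astype(np.int8)


def generate_bundle(cfg: SynthConfig | None = None) -> tuple[Bundle, dict]:
    """Generate an aligned bundle plus ground-truth block labels."""
    cfg = cfg or SynthConfig()
    rng = _streams(cfg.seed, ["md", "ml", "dl", "fs", "dag"])
    mi_blocks = _blocks(cfg.m, cfg.n_blocks)
    dis_blocks = _blocks(cfg.n, cfg.n_blocks)
    mirnas = [f"mir-{i:03d}" for i in range(cfg.m)]
    diseases = [f"disease-{j:03d}" for j in range(cfg.n)]
    lncrnas = [f"lnc-{k:03d}" for k in range(cfg.l)]

    within = mi_blocks[:, None] == dis_blocks[None, :]
    p = np.where(within, cfg.p_in, cfg.p_out)
    # degree heterogeneity: per-node association propensities (mean 1),
    # mimicking hub miRNAs/diseases of curated catalogues
    sig = cfg.propensity_sigma
    u = rng["md"].lognormal(-sig**2 / 2, sig, size=cfg.m)
    v = rng["md"].lognormal(-sig**2 / 2, sig, size=cfg.n)
    p = np.clip(p * u[:, None] * v[None, :], 0.0, 1.0)
    md = (rng["md"].random(p.shape) < p).astype(np.int8)

    ml = _profile(rng["ml"], mi_blocks, cfg.l, cfg.n_blocks, cfg.lnc_signal, cfg.lnc_noise)
    dl = _profile(rng["dl"], dis_blocks, cfg.l, cfg.n_blocks, cfg.lnc_signal, cfg.lnc_noise)

    base = np.where(mi_blocks[:, None] == mi_blocks[None, :], cfg.fs_in, cfg.fs_out)
    # a share of miRNAs has no informative similarity profile (novel nodes
    # with incomplete functional-similarity coverage): flat background rows
    flagged = rng["fs"].random(cfg.m) < cfg.sim_noise_frac
    base[flagged, :] = cfg.fs_out
    base[:, flagged] = cfg.fs_out
    noise = rng["fs"].normal(scale=cfg.fs_noise, size=base.shape)
    fs = np.clip((base + noise + base.T + noise.T) / 2.0, 0.0, 1.0)
    np.fill_diagonal(fs, 1.0)

    dag = _block_dag(rng["dag"], diseases, dis_blocks, cfg)
    ds = disease_similarity_matrix(dag, diseases, SemanticConfig())

    bundle = Bundle(
        md=AssociationMatrix(md, mirnas, diseases, "miRNA-disease"),
        ml=AssociationMatrix(ml, mirnas, lncrnas, "miRNA-lncRNA"),
        dl=AssociationMatrix(dl, diseases, lncrnas, "disease-lncRNA"),
        fs=SimilarityMatrix(fs, mirnas),
        ds=ds,
        dag=dag,
    )
    truth = {"mirna_blocks": mi_blocks, "disease_blocks": dis_blocks}
    return bundle, truth


def _block_dag(rng: np.random.Generator, diseases: list[str], dis_blocks: np.ndarray,
               cfg: SynthConfig) -> DiseaseDAG:
    """Rooted forest under one root: one random subtree of internal terms per
    block, with each disease's own term attached inside its block's subtree."""
    edges: list[tuple[str, str]] = []
    mapping: dict[str, list[str]] = {}
    root = "T-root"
    # diseases whose DAG placement does not reflect their association
    # community (semantic similarity misleads for them)
    misplaced = rng.random(len(diseases)) < cfg.sim_noise_frac
    placement = dis_blocks.copy()
    for j in np.flatnonzero(misplaced):
        placement[j] = rng.integers(cfg.n_blocks)
    dis_blocks = placement
    for b in range(cfg.n_blocks):
        internals = [root, f"T-b{b}"]
        edges.append((root, f"T-b{b}"))
        # grow a small random internal tree below the block anchor
        n_internal = max(1, cfg.dag_depth * cfg.dag_branching - 1)
        for t in range(n_internal):
            name = f"T-b{b}-i{t}"
            parent = internals[int(rng.integers(1, len(internals)))]
            edges.append((parent, name))
            internals.append(name)
        for j in np.flatnonzero(dis_blocks == b):
            term = f"T-{diseases[j]}"
            parent = internals[int(rng.integers(1, len(internals)))]
            edges.append((parent, term))
            mapping[diseases[j]] = [term]
    return DiseaseDAG(edges, mapping)


def shuffle_associations(bundle: Bundle, seed: int = 0) -> Bundle:
    """Null control: scatter the same number of positives uniformly over the
    grid, severing any relation between the labels and the features."""
    rng = np.random.default_rng(seed)
    md = bundle.md.values
    flat = np.zeros(md.size, dtype=np.int8)
    flat[rng.choice(md.size, size=int(md.sum()), replace=False)] = 1
    shuffled = AssociationMatrix(flat.reshape(md.shape), bundle.mirna_ids,
                                 bundle.disease_ids, bundle.md.kind)
    return Bundle(md=shuffled, ml=bundle.ml, dl=bundle.dl, fs=bundle.fs,
                  ds=bundle.ds, dag=bundle.dag)


def generate_toy_dag(depth: int, branching: int, seed: int = 0,
                     diamond: bool = False) -> DiseaseDAG:
    """Balanced rooted tree of terms with diseases mapped at the leaves.

    ``depth`` counts levels (depth 1 is a single term).  With ``diamond``,
    one extra cross edge gives some term two parents.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rng = np.random.default_rng(seed)
    levels = [["T0"]]
    edges: list[tuple[str, str]] = []
    for d in range(1, depth):
        level = []
        for parent in levels[-1]:
            for b in range(branching):
                child = f"{parent}.{b}"
                edges.append((parent, child))
                level.append(child)
        levels.append(level)
    if diamond and depth >= 3:
        # give a random deepest-level term a second parent on the level above
        target = levels[-1][int(rng.integers(len(levels[-1])))]
        own_parent = target.rsplit(".", 1)[0]
        candidates = [t for t in levels[-2] if t != own_parent]
        extra_parent = candidates[int(rng.integers(len(candidates)))]
        edges.append((extra_parent, target))
    leaves = levels[-1]
    mapping = {f"d_{leaf}": [leaf] for leaf in leaves}
    return DiseaseDAG(edges, mapping, terms=[t for lv in levels for t in lv])


def generate_random_dag(n_terms: int, seed: int = 0, edge_prob: float = 0.3,
                        n_diseases: int | None = None) -> DiseaseDAG:
    """Random DAG fixture: edges only from lower to higher index, so acyclic.

    Every term is also usable as a disease position; ``n_diseases`` of them
    (default all) are mapped as diseases, named ``d_<term>``.
    """
    rng = np.random.default_rng(seed)
    terms = [f"t{i}" for i in range(n_terms)]
    edges = [
        (terms[i], terms[j])
        for i in range(n_terms)
        for j in range(i + 1, n_terms)
        if rng.random() < edge_prob
    ]
    k = n_diseases if n_diseases is not None else n_terms
    chosen = rng.permutation(n_terms)[:k]
    mapping = {f"d_{terms[i]}": [terms[i]] for i in sorted(chosen)}
    return DiseaseDAG(edges, mapping, terms=terms)
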