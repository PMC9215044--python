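"""Disease semantic similarity over a MeSH-style DAG.

Two complementary models are computed and averaged:

* **Model 1** (Wang-style): a disease's own term contributes 1 and each
  ancestor contributes a decayed share ``delta * max(children)``, so terms
  close to the disease dominate.  Similarity of two diseases is the summed
  contribution of their shared terms relative to their total semantic
  values.

* **Model 2** (information-content style): a term's contribution is
  ``-log(number of disease DAGs containing the term / number of diseases)``,
  so rare terms are worth more regardless of depth.

Both similarities are symmetric, bounded by [0, 1], and equal 1 for a
disease against itself (model 2: whenever the two term sets coincide).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .datatypes import DiseaseDAG, SimilarityMatrix

__all__ = [
    "SemanticConfig",
    "ContributionMap",
    "contributions_model1",
    "semantic_sim_model1",
    "count_dags_per_term",
    "contributions_model2",
    "semantic_sim_model2",
    "disease_similarity_matrix",
]


@dataclass
class SemanticConfig:
    """Tunables of the semantic models.

    delta : decay factor of the ancestor contribution in model 1, in (0, 1).
        0.5 is the conventional value for this family of measures.
    log_base : "natural" or "10" for the model-2 information content.  The
        base cancels out of the model-2 similarity ratio; it is exposed only
        so intermediate contributions are auditable.
    """

    delta: float = 0.5
    log_base: str = "natural"

    def __post_init__(self) -> None:
        if not 0.0 < self.delta < 1.0:
            raise ValueError("delta must lie strictly between 0 and 1")
        if self.log_base not in ("natural", "10"):
            raise ValueError("log_base must be 'natural' or '10'")

    def _log(self, x: float) -> float:
        return math.log(x) if self.log_base == "natural" else math.log10(x)


@dataclass
class ContributionMap:
    """Per-term semantic contributions of one disease and their sum."""

    contributions: dict = field(default_factory=dict)

    @property
    def dv(self) -> float:
        return float(sum(self.contributions.values()))


def contributions_model1(dag: DiseaseDAG, disease: str, cfg: SemanticConfig) -> ContributionMap:
    """Decay-based contributions over T(disease).

    The disease's own position(s) contribute 1; every strict ancestor d
    contributes ``delta * max(contribution of children of d inside T)``.
    Terms are resolved children-first so each contribution is final when
    read.
    """
    tset = dag.term_set(disease)
    own = set(dag.disease_to_terms[disease])
    contrib: dict[str, float] = {}

    def resolve(term: str) -> float:
        if term in contrib:
            return contrib[term]
        if term in own:
            contrib[term] = 1.0
            return 1.0
        kids = dag.children(term) & tset
        # term is a strict ancestor inside T, so it has at least one child in T
        contrib[term] = cfg.delta * max(resolve(k) for k in kids)
        return contrib[term]

    for t in tset:
        resolve(t)
    return ContributionMap(contrib)


def semantic_sim_model1(dag: DiseaseDAG, d_i: str, d_j: str, cfg: SemanticConfig) -> float:
    ci = contributions_model1(dag, d_i, cfg)
    cj = contributions_model1(dag, d_j, cfg)
    return _pair_similarity(ci, cj, identical=False)


def count_dags_per_term(dag: DiseaseDAG, diseases: Sequence[str] | None = None) -> dict[str, int]:
    """For each term, the number of disease DAGs (ancestor closures) containing it."""
    diseases = list(diseases) if diseases is not None else dag.diseases
    counts: dict[str, int] = {}
    for d in diseases:
        for t in dag.term_set(d):
            counts[t] = counts.get(t, 0) + 1
    return counts


def contributions_model2(
    dag: DiseaseDAG,
    disease: str,
    cfg: SemanticConfig,
    dag_counts: Mapping[str, int],
    n_diseases: int,
) -> ContributionMap:
    """Information-content contributions: -log(count(term) / n_diseases)."""
    if n_diseases <= 0:
        raise ValueError("n_diseases must be positive")
    contrib: dict[str, float] = {}
    for t in dag.term_set(disease):
        c = dag_counts.get(t, 0)
        if c <= 0:
            raise ValueError(f"term {t!r} occurs in a disease DAG but has count 0")
        contrib[t] = -cfg._log(c / n_diseases)
    return ContributionMap(contrib)


def _pair_similarity(ci: ContributionMap, cj: ContributionMap, identical: bool) -> float:
    shared = set(ci.contributions) & set(cj.contributions)
    denom = ci.dv + cj.dv
    if denom == 0.0:
        # Possible under model 2 when every shared term occurs in all DAGs.
        warnings.warn("zero total semantic value; similarity defined as 0 (1 if identical)")
        return 1.0 if identical else 0.0
    num = sum(ci.contributions[t] + cj.contributions[t] for t in shared)
    return num / denom


def semantic_sim_model2(
    dag: DiseaseDAG,
    d_i: str,
    d_j: str,
    cfg: SemanticConfig,
    dag_counts: Mapping[str, int],
    n_diseases: int | None = None,
) -> float:
    n = n_diseases if n_diseases is not None else len(dag.diseases)
    ci = contributions_model2(dag, d_i, cfg, dag_counts, n)
    cj = contributions_model2(dag, d_j, cfg, dag_counts, n)
    return _pair_similarity(ci, cj, identical=dag.term_set(d_i) == dag.term_set(d_j))


def disease_similarity_matrix(
    dag: DiseaseDAG,
    diseases: Sequence[str] | None = None,
    cfg: SemanticConfig | None = None,
    model: str = "average",
) -> SimilarityMatrix:
    """Disease similarity D_s: by default the entrywise mean of both models.

    Contributions are computed once per disease and reused across pairs.
    ``model`` selects "model1", "model2" or "average".
    """
    cfg = cfg or SemanticConfig()
    diseases = list(diseases) if diseases is not None else dag.diseases
    n = len(diseases)
    counts = count_dags_per_term(dag, diseases)
    c1 = {d: contributions_model1(dag, d, cfg) for d in diseases}
    c2 = {d: contributions_model2(dag, d, cfg, counts, n) for d in diseases}
    tsets = {d: dag.term_set(d) for d in diseases}

    out = np.eye(n)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # degenerate zero-DV pairs already defined
        for i in range(n):
            for j in range(i + 1, n):
                di, dj = diseases[i], diseases[j]
                s1 = _pair_similarity(c1[di], c1[dj], identical=False)
                s2 = _pair_similarity(c2[di], c2[dj], identical=tsets[di] == tsets[dj])
                if model == "model1":
                    s = s1
                elif model == "model2":
                    s = s2
                elif model == "average":
                    s = (s1 + s2) / 2.0
                else:
                    raise ValueError(f"unknown model {model!r}")
                out[i, j] = out[j, i] = s
    return SimilarityMatrix(out, diseases)
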