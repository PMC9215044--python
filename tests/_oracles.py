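"""Independent reference implementations shared by the oracle test suites.

Everything here is deliberately naive (python loops, closed forms, shortest
paths) and shares no code path with the package implementation it checks.
"""

import math

import networkx as nx
import numpy as np


def contributions_model1(dag, disease, delta):
    """Closed form: delta ** (shortest descent distance to an own position)."""
    positions = set(dag.disease_to_terms[disease])
    out = {}
    for t in dag.term_set(disease):
        best = math.inf
        for p in positions:
            try:
                best = min(best, nx.shortest_path_length(dag.graph, t, p))
            except nx.NetworkXNoPath:
                continue
        assert best < math.inf
        out[t] = delta ** best
    return out


def ds1(dag, di, dj, delta):
    ci = contributions_model1(dag, di, delta)
    cj = contributions_model1(dag, dj, delta)
    shared = set(ci) & set(cj)
    return sum(ci[t] + cj[t] for t in shared) / (sum(ci.values()) + sum(cj.values()))


def ds2(dag, di, dj, n_diseases, counts):
    def contrib(d):
        return {t: -math.log(counts[t] / n_diseases) for t in dag.term_set(d)}
    ci, cj = contrib(di), contrib(dj)
    num = sum(ci[t] + cj[t] for t in set(ci) & set(cj))
    den = sum(ci.values()) + sum(cj.values())
    if den == 0:
        return 1.0 if dag.term_set(di) == dag.term_set(dj) else 0.0
    return num / den


def naive_matmul(a, b):
    out = np.zeros((a.shape[0], b.shape[1]))
    for i in range(a.shape[0]):
        for j in range(b.shape[1]):
            for k in range(a.shape[1]):
                out[i, j] += a[i, k] * b[k, j]
    return out


def gat_forward(Ws, as_, F, mask, slope):
    """Per-node edge-list evaluation of the averaged multi-head layer."""
    def lrelu(x):
        return np.where(np.asarray(x) >= 0, x, slope * np.asarray(x))

    N, K, d_out = F.shape[0], len(Ws), Ws[0].shape[0]
    out = np.zeros((N, d_out))
    for i in range(N):
        acc = np.zeros(d_out)
        for k in range(K):
            h = F @ Ws[k].T
            nbrs = [t for t in range(N) if mask[i, t]]
            logits = np.array([
                (lambda z: z if z >= 0 else slope * z)(as_[k] @ np.concatenate([h[i], h[t]]))
                for t in nbrs])
            ex = np.exp(logits - logits.max())
            theta = ex / ex.sum()
            acc += sum(th * h[t] for th, t in zip(theta, nbrs))
        out[i] = lrelu(acc / K)
    return out


def pairwise_auc(scores, labels):
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    pos, neg = scores[labels == 1], scores[labels == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))
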