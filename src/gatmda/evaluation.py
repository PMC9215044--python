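"""Cross-validated evaluation, ablations, robustness sweeps and tests.

The protocol follows the standard link-prediction recipe for association
predictors: known positives are split into five folds; for each fold the
held-out positives are removed from the graph before the encoder sees it
and from the classifier's training set in any role, then scored together
with the configured negative set (default: every unlabeled pair).  The
whole five-fold cycle is repeated with fresh splits and the repeats are
averaged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.metrics import precision_recall_curve

from .datatypes import Bundle
from .model import GATMDA

__all__ = [
    "CVPlan",
    "MetricReport",
    "make_folds",
    "roc_auc",
    "aupr_score",
    "classification_metrics",
    "run_cv",
    "ablation_suite",
    "edge_removal_sweep",
    "paired_ttest",
]

METRICS = ("auc", "aupr", "acc", "f1", "recall", "precision", "specificity")


@dataclass
class CVPlan:
    n_folds: int = 5
    n_repeats: int = 10
    seed: int = 0


@dataclass
class MetricReport:
    """Mean metrics with the per-fold values they were averaged from."""

    auc: float = 0.0
    aupr: float = 0.0
    acc: float = 0.0
    f1: float = 0.0
    recall: float = 0.0
    precision: float = 0.0
    specificity: float = 0.0
    per_fold: dict = field(default_factory=lambda: {k: [] for k in METRICS})

    def add_fold(self, values: dict) -> None:
        for k in METRICS:
            self.per_fold[k].append(float(values[k]))

    def finalize(self) -> "MetricReport":
        for k in METRICS:
            setattr(self, k, float(np.mean(self.per_fold[k])))
        return self

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in METRICS}


def make_folds(n_positives: int, n_folds: int, rng: np.random.Generator) -> np.ndarray:
    """Random fold labels 0..n_folds-1 with sizes differing by at most 1."""
    if n_positives < n_folds:
        raise ValueError(f"need at least {n_folds} positives, got {n_positives}")
    labels = np.arange(n_positives) % n_folds
    return labels[rng.permutation(n_positives)]


def roc_auc(scores, labels) -> float:
    """AUC via the rank (Mann-Whitney) formulation; ties share average rank."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels).astype(int)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("roc_auc needs both classes present")
    ranks = stats.rankdata(scores)
    u = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def aupr_score(scores, labels) -> float:
    """Area under the precision-recall staircase by trapezoidal integration."""
    prec, rec, _ = precision_recall_curve(labels, scores)
    order = np.argsort(rec)
    return float(np.trapezoid(prec[order], rec[order]))


def classification_metrics(scores, labels, threshold: float = 0.5) -> dict:
    """Threshold metrics plus the two curve areas.

    Precision and F1 are defined as 0 when their denominator is empty.
    """
    scores = np.asarray(scores, float)
    labels = np.asarray(labels).astype(int)
    pred = (scores >= threshold).astype(int)
    tp = int(((pred == 1) & (labels == 1)).sum())
    tn = int(((pred == 0) & (labels == 0)).sum())
    fp = int(((pred == 1) & (labels == 0)).sum())
    fn = int(((pred == 0) & (labels == 1)).sum())
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return {
        "auc": roc_auc(scores, labels),
        "aupr": aupr_score(scores, labels),
        "acc": (tp + tn) / len(labels),
        "f1": f1,
        "recall": recall,
        "precision": precision,
        "specificity": tn / (tn + fp) if tn + fp else 0.0,
    }


def run_cv(
    bundle: Bundle,
    plan: CVPlan | None = None,
    model_params: dict | None = None,
    exclude_mask: np.ndarray | None = None,
    threshold: float = 0.5,
    max_folds: int | None = None,
    _leak_check: bool = True,
) -> MetricReport:
    """Repeated five-fold cross-validation of the full pipeline.

    Per fold, the test positives are withheld from the encoder's graph and
    from the forest's training set; test scoring ranks the withheld
    positives against every unlabeled pair (pairs in ``exclude_mask`` are
    kept out of training in any role, e.g. deliberately removed edges).
    ``max_folds`` caps how many folds per repeat are evaluated — a cheaper
    unbiased estimate for wide seed sweeps (the split itself stays 5-fold).
    """
    plan = plan or CVPlan()
    params = dict(model_params or {})
    md = bundle.md.values.astype(bool)
    positives = np.argwhere(md)
    unlabeled = np.argwhere(~md)
    if exclude_mask is not None:
        exclude_mask = np.asarray(exclude_mask, bool)

    report = MetricReport()
    root = np.random.SeedSequence(plan.seed)
    for repeat_ss in root.spawn(plan.n_repeats):
        rng = np.random.default_rng(repeat_ss)
        folds = make_folds(len(positives), plan.n_folds, rng)
        n_eval = plan.n_folds if max_folds is None else min(max_folds, plan.n_folds)
        for f in range(n_eval):
            test_pos = positives[folds == f]
            train_pos = positives[folds != f]
            train_mask = np.zeros_like(md)
            train_mask[train_pos[:, 0], train_pos[:, 1]] = True
            test_pos_mask = np.zeros_like(md)
            test_pos_mask[test_pos[:, 0], test_pos[:, 1]] = True
            excl = test_pos_mask if exclude_mask is None else (test_pos_mask | exclude_mask)

            model = GATMDA(**{**params, "seed": int(rng.integers(2**31))})
            model.fit(bundle, train_mask=train_mask, exclude_from_negatives=excl)

            if _leak_check:
                test_set = {(int(i), int(j)) for i, j in test_pos}
                assert not (test_set & model.train_pair_set_), "test positives leaked into training"

            # score only pairs the forest never saw: held-out positives vs
            # the unlabeled pairs that were not drawn as training negatives
            trained = np.zeros_like(md)
            tp = model.train_pairs_
            trained[tp[:, 0], tp[:, 1]] = True
            eval_neg = unlabeled[~trained[unlabeled[:, 0], unlabeled[:, 1]]]
            if len(eval_neg) == 0:
                raise ValueError(
                    "no unlabeled pairs left for evaluation: the training "
                    "negative set consumed the whole pool (lower neg_ratio "
                    "or avoid negatives='all')")
            eval_pairs = np.vstack([test_pos, eval_neg])
            y = np.concatenate([np.ones(len(test_pos), int), np.zeros(len(eval_neg), int)])
            scores = model.predict_pairs(eval_pairs)
            report.add_fold(classification_metrics(scores, y, threshold))
    return report.finalize()


ABLATION_MODES = ("linear", "nonlinear", "linear_svd", "linear_deepwalk", "full")


def ablation_suite(bundle: Bundle, plan: CVPlan | None = None,
                   model_params: dict | None = None) -> dict[str, MetricReport]:
    """CV the five feature-processing variants under one plan."""
    out = {}
    for mode in ABLATION_MODES:
        params = {**(model_params or {}), "feature_mode": mode}
        out[mode] = run_cv(bundle, plan, params)
    return out


def edge_removal_sweep(bundle: Bundle, fractions, plan: CVPlan | None = None,
                       model_params: dict | None = None,
                       seed: int = 0, max_folds: int | None = None) -> dict[float, float]:
    """Mean CV AUC after deleting a share of the known positives.

    Removed positives become unlabeled: they are barred from every training
    fold (either role) but stay in the scored unknown pool, mimicking true
    associations hidden from the predictor.
    """
    from .datatypes import AssociationMatrix

    plan = plan or CVPlan()
    md = bundle.md.values.astype(bool)
    positives = np.argwhere(md)
    rng = np.random.default_rng(seed)
    out: dict[float, float] = {}
    for frac in fractions:
        if not 0.0 <= frac <= 0.5:
            raise ValueError("removal fractions must lie in [0, 0.5]")
        n_remove = int(round(frac * len(positives)))
        removed = positives[rng.choice(len(positives), size=n_remove, replace=False)] \
            if n_remove else np.empty((0, 2), int)
        reduced = md.copy()
        removed_mask = np.zeros_like(md)
        if n_remove:
            reduced[removed[:, 0], removed[:, 1]] = False
            removed_mask[removed[:, 0], removed[:, 1]] = True
        reduced_bundle = Bundle(
            md=AssociationMatrix(reduced.astype(np.int8), bundle.mirna_ids,
                                 bundle.disease_ids, bundle.md.kind),
            ml=bundle.ml, dl=bundle.dl, fs=bundle.fs, ds=bundle.ds, dag=bundle.dag,
        )
        rep = run_cv(reduced_bundle, plan, model_params, exclude_mask=removed_mask,
                     max_folds=max_folds)
        out[float(frac)] = rep.auc
    return out


def paired_ttest(per_fold_a, per_fold_b) -> float:
    """Two-sided paired t-test p-value on matched per-fold metrics."""
    a = np.asarray(per_fold_a, float)
    b = np.asarray(per_fold_b, float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("need two equal-length vectors with at least 2 entries")
    if np.var(a - b) == 0:
        raise ValueError("zero variance of paired differences; t-test undefined")
    return float(stats.ttest_rel(a, b).pvalue)
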