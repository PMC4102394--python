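"""ROC/PR metrics and the k-fold cross-validation harness.

Cross-validation follows the protocol of splitting positives and negatives
independently into ``folds`` seeded segments, holding each out in turn, and
reporting per-fold AUC with mean, standard deviation and standard error.

Pipelines expose two hooks so that expensive fold-independent work (the
kernel matrix, which does not depend on labels or fold membership) is done
once:

* ``setup(pos, neg)`` receives the full record sets;
* ``run_fold(tr_pos, tr_neg, te_pos, te_neg)`` receives per-class index
  arrays and returns scores for the held-out positives and negatives.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Protocol, Sequence

import numpy as np
from sklearn.metrics import precision_recall_curve, roc_auc_score

from .kernels import KernelMatrix, gkm_kernel_matrix, kernel_from_profiles
from .models import NBModel, nb_score_many, nb_train, train_svm
from .profiles import profiles_direct
from .seqio import SequenceRecord, extract_lmers
from .weights import (
    KernelWeights,
    estimate_kernel_coefficients,
    filter_weights,
    gkm_coefficients,
    mismatch_coefficients,
    truncate_filter,
    wildcard_coefficients,
)

__all__ = [
    "EvalResult",
    "roc_auc",
    "precision_recall",
    "cross_validate",
    "SVMPipeline",
    "NBPipeline",
    "FunctionPipeline",
]


@dataclass
class EvalResult:
    """Per-fold AUCs with summary statistics and the run configuration."""

    fold_aucs: np.ndarray
    config: dict = field(default_factory=dict)
    pr_curves: Optional[list] = None

    @property
    def mean_auc(self) -> float:
        return float(np.mean(self.fold_aucs))

    @property
    def sd_auc(self) -> float:
        return float(np.std(self.fold_aucs, ddof=1)) if len(self.fold_aucs) > 1 else 0.0

    @property
    def se_auc(self) -> float:
        return self.sd_auc / np.sqrt(len(self.fold_aucs))


def _check_two_classes(labels: np.ndarray) -> None:
    if len(np.unique(labels)) < 2:
        raise ValueError("scores for both classes are required")


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the ROC curve: P(random positive outranks random negative),
    ties counted 1/2 (midrank convention)."""
    y = np.asarray(labels)
    _check_two_classes(y)
    return float(roc_auc_score(y, np.asarray(scores, dtype=float)))


def precision_recall(scores: Sequence[float], labels: Sequence[int]):
    """Precision-recall curve as (precision, recall, thresholds).

    The threshold sweep keeps, at each recall level, the highest-precision
    point (dominated points at the same recall are dropped), so perfect
    separation yields precision 1 at every recall.  Recall is non-increasing
    as the threshold rises.
    """
    y = np.asarray(labels)
    _check_two_classes(y)
    prec, rec, thr = precision_recall_curve(y, np.asarray(scores, dtype=float))
    thr = np.append(thr, np.inf)
    # within a run of equal recall, precision rises with the threshold;
    # keep the last (best) point of each run
    keep = np.ones(len(rec), dtype=bool)
    keep[:-1] = rec[:-1] != rec[1:]
    return prec[keep], rec[keep], thr[keep]


class Pipeline(Protocol):
    def setup(self, pos: Sequence[SequenceRecord], neg: Sequence[SequenceRecord]) -> None: ...

    def run_fold(self, tr_pos, tr_neg, te_pos, te_neg) -> tuple[np.ndarray, np.ndarray]: ...


def _fold_indices(n: int, folds: int, rng: np.random.Generator) -> list[np.ndarray]:
    perm = rng.permutation(n)
    return [np.sort(part) for part in np.array_split(perm, folds)]


def cross_validate(
    pos: Sequence[SequenceRecord],
    neg: Sequence[SequenceRecord],
    folds: int,
    pipeline: Pipeline,
    seed: int = 0,
) -> EvalResult:
    """Seeded k-fold CV with independent per-class splits.

    Each fold's AUC is computed on its pooled held-out scores; no sequence
    appears in both train and test of the same fold.
    """
    if len(pos) < folds or len(neg) < folds:
        raise ValueError(f"each class needs at least {folds} members")
    rng = np.random.default_rng(seed)
    pos_folds = _fold_indices(len(pos), folds, rng)
    neg_folds = _fold_indices(len(neg), folds, rng)
    pipeline.setup(pos, neg)
    aucs = []
    for f in range(folds):
        te_pos, te_neg = pos_folds[f], neg_folds[f]
        tr_pos = np.sort(np.concatenate([pos_folds[g] for g in range(folds) if g != f]))
        tr_neg = np.sort(np.concatenate([neg_folds[g] for g in range(folds) if g != f]))
        sp, sn = pipeline.run_fold(tr_pos, tr_neg, te_pos, te_neg)
        scores = np.concatenate([sp, sn])
        labels = np.concatenate([np.ones(len(sp)), -np.ones(len(sn))])
        aucs.append(roc_auc(scores, labels))
    return EvalResult(
        fold_aucs=np.array(aucs),
        config={"folds": folds, "seed": seed, "n_pos": len(pos), "n_neg": len(neg)},
    )


def make_weights(
    variant: str,
    l: int,
    k: Optional[int] = None,
    M: Optional[int] = None,
    lam: float = 1.0,
) -> KernelWeights:
    """Coefficient family lookup used by pipelines and the CLI."""
    if variant == "gkm":
        return gkm_coefficients(l, k)
    if variant == "wildcard":
        return wildcard_coefficients(l, M, lam)
    if variant == "mismatch":
        return mismatch_coefficients(l, M)
    if variant == "estimate_full":
        return estimate_kernel_coefficients(l, k, filter_weights(l, k))
    if variant == "estimate_truncated":
        return estimate_kernel_coefficients(l, k, truncate_filter(filter_weights(l, k)))
    raise ValueError(f"unknown kernel variant {variant!r}")


class SVMPipeline:
    """SVM CV pipeline; the full normalized kernel is computed once.

    Kernel entries are pairwise, label-free quantities, so precomputing the
    full matrix and slicing per fold is exact and leak-free.  The gkm
    variant uses the subset fast path; other variants go through mismatch
    profiles.
    """

    def __init__(
        self,
        l: int,
        k: Optional[int] = None,
        variant: str = "gkm",
        C: float = 1.0,
        M: Optional[int] = None,
        lam: float = 1.0,
        m_max: Optional[int] = None,
        include_revcomp: bool = True,
    ):
        self.l, self.k, self.variant, self.C = l, k, variant, C
        self.M, self.lam, self.m_max = M, lam, m_max
        self.include_revcomp = include_revcomp
        self.weights = make_weights(variant, l, k, M, lam)

    def setup(self, pos, neg) -> None:
        recs = list(pos) + list(neg)
        self.n_pos = len(pos)
        self.lls = [extract_lmers(r, self.l, self.include_revcomp) for r in recs]
        use_fast = (
            self.variant == "gkm"
            and self.m_max is None
            and self.k is not None
        )
        if use_fast:
            self.K = gkm_kernel_matrix(self.lls, self.l, self.k)
        else:
            profs = profiles_direct(self.lls, m_max=self.m_max)
            self.K = kernel_from_profiles(
                profs, self.weights, ids=[r.id for r in recs]
            )

    def run_fold(self, tr_pos, tr_neg, te_pos, te_neg):
        tr = np.concatenate([tr_pos, tr_neg + self.n_pos])
        te = np.concatenate([te_pos, te_neg + self.n_pos])
        y = np.concatenate([np.ones(len(tr_pos)), -np.ones(len(tr_neg))]).astype(int)
        sub = KernelMatrix(
            ids_rows=[self.K.ids_rows[i] for i in tr],
            ids_cols=[self.K.ids_rows[i] for i in tr],
            values=self.K.values[np.ix_(tr, tr)],
            config=self.K.config,
            raw_diag_rows=self.K.raw_diag_rows[tr],
            raw_diag_cols=self.K.raw_diag_rows[tr],
        )
        model = train_svm(
            sub, y, [self.lls[i] for i in tr], self.weights, C=self.C
        )
        cross = self.K.values[np.ix_(te, tr)]
        scores = cross[:, model.sv_idx] @ model.sv_alpha + model.bias
        return scores[: len(te_pos)], scores[len(te_pos) :]


class NBPipeline:
    """Naive-Bayes CV pipeline (tables are rebuilt per fold)."""

    def __init__(
        self,
        l: int,
        k: Optional[int] = None,
        use_filter: bool = True,
        window: Optional[int] = None,
    ):
        self.l = l
        self.k = k if k is not None else l
        self.use_filter = use_filter
        self.window = window

    def setup(self, pos, neg) -> None:
        self.pos, self.neg = list(pos), list(neg)

    def run_fold(self, tr_pos, tr_neg, te_pos, te_neg):
        model = nb_train(
            [self.pos[i] for i in tr_pos],
            [self.neg[i] for i in tr_neg],
            self.l,
            self.k,
            use_filter=self.use_filter,
        )
        sp = nb_score_many(model, [self.pos[i] for i in te_pos], self.window)
        sn = nb_score_many(model, [self.neg[i] for i in te_neg], self.window)
        return sp, sn


class FunctionPipeline:
    """Adapter for a plain scoring function f(train_pos, train_neg, records).

    Mostly a harness-testing aid (e.g. a label-leaking scorer must yield
    AUC 1 in every fold).
    """

    def __init__(self, fn):
        self.fn = fn

    def setup(self, pos, neg) -> None:
        self.pos, self.neg = list(pos), list(neg)

    def run_fold(self, tr_pos, tr_neg, te_pos, te_neg):
        tp = [self.pos[i] for i in tr_pos]
        tn = [self.neg[i] for i in tr_neg]
        sp = np.asarray(self.fn(tp, tn, [self.pos[i] for i in te_pos]))
        sn = np.asarray(self.fn(tp, tn, [self.neg[i] for i in te_neg]))
        return sp, sn
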