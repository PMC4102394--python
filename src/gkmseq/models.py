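"""Classifiers on gapped k-mer features: precomputed-kernel SVM and
Naive-Bayes on robust l-mer count estimates.

The SVM is the standard soft-margin dual solved on the normalized kernel
matrix; a trained model is the set of support vectors (references to
training l-mer lists), their label-signed dual coefficients and a bias, and
scores a new sequence as  sum_sv alpha_sv * K(seq, sv) + b.

The Naive-Bayes classifier scores a sequence as the sum over its l-mers of
log(N_P / N_N), where N_P and N_N are the l-mer's counts in the positive
and negative training sets -- either raw counts with a 0.5 pseudo-count, or
the truncated gkm-filter estimates with a pseudo-count of half the filter's
smallest positive coefficient.  An optional window mode scores every
substring holding ``window`` consecutive l-mers and takes the maximum,
which suits single-site (CTCF-like) data; full-sequence scoring suits
multi-site (EP300-like) data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import NamedTuple, Optional, Sequence

import numpy as np
from sklearn.svm import SVC

from . import _fast
from .kernels import (
    KernelMatrix,
    cross_kernel,
    gkm_cross_matrix,
    _DENSE_COLS_MAX,
    _flatten,
    _subset_shifts,
)
from .seqio import (
    LmerList,
    SequenceRecord,
    extract_lmers,
    ordered_forward_codes,
    revcomp_code,
    unpack_code,
)
from .weights import GkmFilter, KernelWeights, filter_weights, truncate_filter

logger = logging.getLogger(__name__)

__all__ = [
    "TrainedSVM",
    "NBModel",
    "train_svm",
    "decision_scores",
    "score_all_kmers",
    "KmerScoreTable",
    "nb_train",
    "nb_score",
    "nb_score_many",
]


@dataclass
class TrainedSVM:
    """A soft-margin SVM trained on a precomputed normalized kernel."""

    train_lls: list[LmerList]
    labels: np.ndarray
    weights: KernelWeights
    sv_idx: np.ndarray  # indices of support vectors into train_lls
    sv_alpha: np.ndarray  # label-signed dual coefficients
    bias: float
    C: float
    train_raw_diag: np.ndarray
    train_decision: Optional[np.ndarray] = None

    @property
    def sv_lls(self) -> list[LmerList]:
        return [self.train_lls[i] for i in self.sv_idx]


def train_svm(
    K: KernelMatrix,
    labels: Sequence[int],
    train_lls: Sequence[LmerList],
    weights: KernelWeights,
    C: float = 1.0,
    tol: float = 1e-6,
) -> TrainedSVM:
    """Solve the soft-margin dual on a precomputed (normalized) kernel.

    Deterministic given (K, labels, C, tol).  If the solver rejects a
    non-PSD matrix (possible with truncated profiles or truncated-filter
    coefficients), the smallest ridge 1e-8*I is added and logged.
    """
    y = np.asarray(labels, dtype=np.int64)
    if not K.is_square:
        raise ValueError("training requires a square kernel matrix")
    if set(np.unique(y)) != {-1, 1}:
        raise ValueError("labels must contain both classes, coded +1/-1")
    if len(y) != len(K.ids_rows):
        raise ValueError("label count does not match kernel size")
    svc = SVC(kernel="precomputed", C=C, tol=tol)
    try:
        svc.fit(K.values, y)
    except ValueError:
        logger.warning("kernel rejected by solver; retrying with ridge 1e-8*I")
        svc.fit(K.values + 1e-8 * np.eye(len(y)), y)
    model = TrainedSVM(
        train_lls=list(train_lls),
        labels=y,
        weights=weights,
        sv_idx=svc.support_.copy(),
        sv_alpha=svc.dual_coef_[0].copy(),
        bias=float(svc.intercept_[0]),
        C=C,
        train_raw_diag=np.asarray(K.raw_diag_rows, dtype=float),
        train_decision=svc.decision_function(K.values),
    )
    return model


def decision_scores(
    model: TrainedSVM, test: Sequence[LmerList], method: str = "auto"
) -> np.ndarray:
    """Support-vector expansion scores for test sequences.

    Higher means more positive-class.  ``method`` picks the cross-kernel
    route: 'subsets' (exact, gkm only), 'profiles' (any variant), or
    'auto'.
    """
    sv = model.sv_lls
    sv_diag = model.train_raw_diag[model.sv_idx]
    w = model.weights
    use_subsets = method == "subsets" or (
        method == "auto" and w.variant == "gkm" and 4 ** int(w.k) <= _DENSE_COLS_MAX
    )
    if use_subsets:
        if w.variant != "gkm":
            raise ValueError("subset route only applies to the gkm variant")
        Kx = gkm_cross_matrix(list(test), sv, w.l, int(w.k), sv_diag)
    else:
        Kx = cross_kernel(list(test), sv, w, sv_diag)
    return Kx.values @ model.sv_alpha + model.bias


class KmerScoreTable(NamedTuple):
    """All w-mers ranked by SVM weight (descending)."""

    codes: np.ndarray  # uint64 packed w-mers
    weights: np.ndarray
    w: int

    def top(self, fraction: float) -> tuple[list[str], np.ndarray]:
        n = max(1, int(round(fraction * len(self.codes))))
        kmers = [unpack_code(int(c), self.w) for c in self.codes[:n]]
        return kmers, self.weights[:n].copy()

    def write_tsv(self, path, fraction: float = 1.0) -> None:
        kmers, wts = self.top(fraction)
        with open(path, "w") as fh:
            fh.write("#kmer\tweight\n")
            for km, wt in zip(kmers, wts):
                fh.write(f"{km}\t{wt:.10g}\n")


def _revcomp_codes_vec(codes: np.ndarray, w: int) -> np.ndarray:
    rc = np.zeros_like(codes)
    tmp = codes.copy()
    three = np.uint64(3)
    two = np.uint64(2)
    for _ in range(w):
        rc = (rc << two) | (three - (tmp & three))
        tmp = tmp >> two
    return rc


def score_all_kmers(model: TrainedSVM, w: int = 10) -> KmerScoreTable:
    """Score every w-mer as a standalone sequence (both strands), ranked.

    Used to seed de novo PWM construction.  For the gkm variant with
    w == l this runs through per-subset support-vector weight tables; the
    generic route scores w-mers as ordinary test sequences.
    """
    if w > 12:
        raise ValueError("w-mer enumeration guarded to w <= 12")
    if w < model.weights.l:
        raise ValueError(f"w={w} is shorter than the feature length l={model.weights.l}")
    codes = np.arange(4**w, dtype=np.uint64)
    rc_codes = _revcomp_codes_vec(codes, w)
    wt = model.weights
    if wt.variant == "gkm" and w == wt.l and 4 ** int(wt.k) <= _DENSE_COLS_MAX:
        l, k = wt.l, int(wt.k)
        sv = model.sv_lls
        alpha_n = model.sv_alpha / np.sqrt(model.train_raw_diag[model.sv_idx])
        flat_codes, flat_cnts, offsets = _flatten(sv)
        subs = _subset_shifts(l, k)
        tables = np.zeros((len(subs), 4**k))
        C = np.zeros((len(sv), 4**k), dtype=np.float32)
        shifts_all = np.zeros((len(subs), k), dtype=np.uint64)
        for s, shifts in enumerate(subs):
            _fast.build_masked_counts(flat_codes, flat_cnts, offsets, shifts, k, C)
            tables[s] = C.astype(np.float64).T @ alpha_n
            shifts_all[s] = shifts
        scores = (
            _fast.score_wmers_gkm(
                codes, rc_codes, tables, shifts_all, k, wt.coef[0], wt.coef
            )
            + model.bias
        )
    else:
        lls = []
        for c in codes:
            rec = SequenceRecord(f"w{int(c)}", unpack_code(int(c), w))
            lls.append(extract_lmers(rec, model.weights.l, include_revcomp=True))
        scores = decision_scores(model, lls)
    order = np.argsort(-scores, kind="stable")
    return KmerScoreTable(codes=codes[order], weights=scores[order], w=w)


# ---------------------------------------------------------------------------
# Naive Bayes on l-mer count estimates


@dataclass
class NBModel:
    """Naive-Bayes model on (estimated) l-mer counts.

    Tables hold deduplicated l-mer counts over both strands of the
    training sets; lookups are lazy, so no 4**l table is materialized.
    """

    l: int
    k: int
    use_filter: bool
    filt: Optional[GkmFilter]
    pseudo_count: float
    pos_codes: np.ndarray
    pos_cnts: np.ndarray
    neg_codes: np.ndarray
    neg_cnts: np.ndarray
    include_revcomp: bool = True

    def lookup(self, query_codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(N_P, N_N) for each query l-mer code, before pseudo-counting."""
        if self.use_filter:
            g = self.filt.g
            sup = self.filt.support
            np_ = _fast.nb_filtered_counts(
                query_codes, self.pos_codes, self.pos_cnts, g, sup, self.l
            )
            nn_ = _fast.nb_filtered_counts(
                query_codes, self.neg_codes, self.neg_cnts, g, sup, self.l
            )
            return np_, nn_
        return (
            _exact_counts(query_codes, self.pos_codes, self.pos_cnts),
            _exact_counts(query_codes, self.neg_codes, self.neg_cnts),
        )

    def log_ratios(self, query_codes: np.ndarray) -> np.ndarray:
        np_, nn_ = self.lookup(query_codes)
        pc = self.pseudo_count
        return np.log(np_ + pc) - np.log(nn_ + pc)


def _exact_counts(queries: np.ndarray, codes: np.ndarray, cnts: np.ndarray) -> np.ndarray:
    pos = np.searchsorted(codes, queries)
    pos = np.clip(pos, 0, len(codes) - 1) if len(codes) else np.zeros(len(queries), int)
    out = np.zeros(len(queries))
    if len(codes):
        hit = codes[pos] == queries
        out[hit] = cnts[pos[hit]]
    return out


def _merge_tables(lls: Sequence[LmerList]) -> tuple[np.ndarray, np.ndarray]:
    if not lls:
        return np.empty(0, np.uint64), np.empty(0, np.float64)
    codes = np.concatenate([x.codes for x in lls])
    cnts = np.concatenate([x.counts for x in lls]).astype(np.float64)
    uniq, inv = np.unique(codes, return_inverse=True)
    return uniq, np.bincount(inv, weights=cnts)


def nb_train(
    pos: Sequence[SequenceRecord],
    neg: Sequence[SequenceRecord],
    l: int,
    k: int,
    use_filter: bool = True,
    include_revcomp: bool = True,
) -> NBModel:
    """Build the NB l-mer tables from positive and negative training sets.

    Filter mode smooths counts with the truncated gkm-filter and uses half
    its smallest positive coefficient as pseudo-count; raw mode uses exact
    counts with pseudo-count 0.5.  At l = k the filter is the identity and
    the two modes coincide (the identity filter's pseudo-count is also 0.5).
    """
    if not pos or not neg:
        raise ValueError("both training sets must be non-empty")
    pos_lls = [extract_lmers(r, l, include_revcomp) for r in pos]
    neg_lls = [extract_lmers(r, l, include_revcomp) for r in neg]
    pc, filt = 0.5, None
    if use_filter:
        filt = truncate_filter(filter_weights(l, k))
        pc = filt.min_positive / 2.0
    pos_codes, pos_cnts = _merge_tables(pos_lls)
    neg_codes, neg_cnts = _merge_tables(neg_lls)
    return NBModel(
        l=l,
        k=k,
        use_filter=use_filter,
        filt=filt,
        pseudo_count=pc,
        pos_codes=pos_codes,
        pos_cnts=pos_cnts,
        neg_codes=neg_codes,
        neg_cnts=neg_cnts,
        include_revcomp=include_revcomp,
    )


def save_svm(model: TrainedSVM, path) -> None:
    """Persist a trained SVM (support vectors only) as a .npz archive."""
    import json

    sv = model.sv_lls
    offsets = np.zeros(len(sv) + 1, dtype=np.int64)
    for i, ll in enumerate(sv):
        offsets[i + 1] = offsets[i] + len(ll.codes)
    w = model.weights
    meta = {
        "variant": w.variant,
        "l": w.l,
        "k": w.k,
        "M": w.M,
        "lam": w.lam,
        "b": w.b,
        "C": model.C,
        "bias": model.bias,
        "owners": [ll.owner for ll in sv],
        "n": [ll.n for ll in sv],
        "t": sv[0].t if sv else 6,
        "include_revcomp": sv[0].include_revcomp if sv else True,
    }
    np.savez(
        path,
        codes=np.concatenate([ll.codes for ll in sv]) if sv else np.empty(0, np.uint64),
        counts=np.concatenate([ll.counts for ll in sv]) if sv else np.empty(0, np.int64),
        offsets=offsets,
        sv_alpha=model.sv_alpha,
        sv_diag=model.train_raw_diag[model.sv_idx],
        coef=w.coef,
        meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
    )


def load_svm(path) -> TrainedSVM:
    import json

    with np.load(path) as z:
        meta = json.loads(z["meta"].tobytes().decode())
        codes, counts, offsets = z["codes"], z["counts"], z["offsets"]
        sv_alpha, sv_diag, coef = z["sv_alpha"], z["sv_diag"], z["coef"]
    lls = []
    for i, owner in enumerate(meta["owners"]):
        lls.append(
            LmerList(
                owner=owner,
                l=meta["l"],
                t=meta["t"],
                codes=codes[offsets[i] : offsets[i + 1]].astype(np.uint64),
                counts=counts[offsets[i] : offsets[i + 1]].astype(np.int64),
                n=meta["n"][i],
                include_revcomp=meta["include_revcomp"],
            )
        )
    weights = KernelWeights(
        variant=meta["variant"],
        l=meta["l"],
        k=meta["k"],
        M=meta["M"],
        lam=meta["lam"],
        b=meta["b"],
        coef=coef,
    )
    labels = np.where(sv_alpha >= 0, 1, -1)
    return TrainedSVM(
        train_lls=lls,
        labels=labels,
        weights=weights,
        sv_idx=np.arange(len(lls)),
        sv_alpha=sv_alpha,
        bias=float(meta["bias"]),
        C=float(meta["C"]),
        train_raw_diag=sv_diag,
    )


def _window_scores(llrs: np.ndarray, window: Optional[int]) -> float:
    if window is None:
        return float(llrs.sum())
    if len(llrs) < window:
        raise ValueError(
            f"sequence has {len(llrs)} l-mers, fewer than window={window}"
        )
    c = np.concatenate([[0.0], np.cumsum(llrs)])
    return float((c[window:] - c[:-window]).max())


def nb_score(
    model: NBModel, seq: SequenceRecord, window: Optional[int] = None
) -> float:
    """Log-likelihood-ratio score of one sequence.

    Without a window, the sum of log(N_P/N_N) over the sequence's forward
    l-mers; with ``window`` set, the maximum such sum over all runs of
    ``window`` consecutive l-mers (substrings of length window + l - 1).
    Strand symmetry comes from the tables holding both strands.
    """
    return nb_score_many(model, [seq], window)[0]


def nb_score_many(
    model: NBModel, seqs: Sequence[SequenceRecord], window: Optional[int] = None
) -> np.ndarray:
    """Batch scorer: one table lookup pass over the union of query l-mers."""
    per_seq = [ordered_forward_codes(s, model.l) for s in seqs]
    if any(len(c) == 0 for c in per_seq):
        bad = seqs[[len(c) for c in per_seq].index(0)]
        raise ValueError(f"sequence {bad.id!r} has no valid l-mer window")
    allq = np.unique(np.concatenate(per_seq))
    llr = model.log_ratios(allq)
    out = np.empty(len(seqs))
    for i, codes in enumerate(per_seq):
        idx = np.searchsorted(allq, codes)
        out[i] = _window_scores(llr[idx], window)
    return out
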