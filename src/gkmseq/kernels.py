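"""Kernel matrices from mismatch profiles, plus explicit feature-space oracles.

The raw kernel between two sequences is sum_m coef[m] * N_m; the kernel
proper is the normalized inner product

    K(S1, S2) = K_raw(S1, S2) / sqrt(K_raw(S1, S1) * K_raw(S2, S2)),

so K(S, S) = 1.  Normalization is always applied before SVM training; raw
values stay available for diagnostics.

Three routes produce identical gkm-kernel values:

* profiles route (any coefficient family): mismatch profiles from
  :mod:`gkmseq.profiles` contracted with a coefficient vector;
* subset route (gkm only): K_raw = sum over the choose(l,k) position
  subsets of the co-occurrence counts of masked k-mers, accumulated as
  dense BLAS rank-k updates (float32 is exact here: every intermediate is
  an integer below 2**24) or sparse products when 4**k is large.  This is
  the production path for training-scale inputs;
* explicit feature vectors (small l only): the literal gapped k-mer count
  vectors of the kernel's definition, used as test oracles.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import scipy.sparse as sp
from scipy.linalg import blas as _blas

from . import _fast
from .profiles import MismatchProfile, profiles_direct
from .seqio import LmerList
from .weights import GkmFilter, KernelWeights, gkm_coefficients

__all__ = [
    "KernelMatrix",
    "kernel_from_profiles",
    "cross_kernel",
    "gapped_kmer_vector",
    "lmer_estimate_vector",
    "gkm_kernel_matrix",
    "gkm_cross_matrix",
    "write_kernel_tsv",
    "read_kernel_tsv",
]

_DENSE_COLS_MAX = 1 << 18  # switch to sparse co-occurrence above 4**k columns


@dataclass
class KernelMatrix:
    """A (cross-)kernel matrix with its feature configuration.

    For a training matrix rows == cols; for a cross matrix rows are test
    sequences and cols training sequences.  ``raw_diag_rows/cols`` hold the
    unnormalized self-similarities used for normalization.
    """

    ids_rows: list[str]
    ids_cols: list[str]
    values: np.ndarray
    config: dict = field(default_factory=dict)
    raw_diag_rows: Optional[np.ndarray] = None
    raw_diag_cols: Optional[np.ndarray] = None

    @property
    def is_square(self) -> bool:
        return self.ids_rows == self.ids_cols


def _coef_dot(counts: np.ndarray, coef: np.ndarray) -> float:
    m = min(len(counts), len(coef))
    return float(np.dot(counts[:m], coef[:m]))


def kernel_from_profiles(
    profiles: Sequence[MismatchProfile],
    weights: KernelWeights,
    normalize: bool = True,
    ids: Optional[Sequence[str]] = None,
) -> KernelMatrix:
    """Assemble a symmetric training kernel from lower-triangle profiles.

    Requires self pairs when ``normalize`` is on; a sequence with zero raw
    self-similarity (no valid l-mers) is reported by name.
    """
    n = max(p.i for p in profiles) + 1
    raw = np.zeros((n, n))
    seen_diag = np.zeros(n, dtype=bool)
    for p in profiles:
        v = _coef_dot(p.counts, weights.coef)
        raw[p.i, p.j] = v
        raw[p.j, p.i] = v
        if p.i == p.j:
            seen_diag[p.i] = True
    ids = list(ids) if ids is not None else [str(i) for i in range(n)]
    diag = np.diag(raw).copy()
    values = raw
    if normalize:
        if not seen_diag.all():
            missing = int(np.nonzero(~seen_diag)[0][0])
            raise ValueError(f"missing self pair for sequence {ids[missing]!r}")
        if (diag <= 0).any():
            bad = int(np.nonzero(diag <= 0)[0][0])
            raise ValueError(
                f"sequence {ids[bad]!r} has zero self-similarity (no valid l-mers)"
            )
        norm = np.sqrt(diag)
        values = raw / np.outer(norm, norm)
    return KernelMatrix(
        ids_rows=ids,
        ids_cols=ids,
        values=values,
        config={
            "variant": weights.variant,
            "l": weights.l,
            "k": weights.k,
            "M": weights.M,
            "lambda": weights.lam,
            "normalized": normalize,
        },
        raw_diag_rows=diag,
        raw_diag_cols=diag,
    )


def cross_kernel(
    test: Sequence[LmerList],
    train: Sequence[LmerList],
    weights: KernelWeights,
    train_diag: np.ndarray,
    m_max: Optional[int] = None,
) -> KernelMatrix:
    """Normalized test x train kernel via the profiles route.

    ``train_diag`` are the training sequences' raw self-similarities under
    the same feature configuration (the same coefficient family, l, k and
    strand convention); test self-similarities are computed here.
    """
    if len(train_diag) != len(train):
        raise ValueError("train_diag length does not match training set")
    if test and train and test[0].l != train[0].l:
        raise ValueError(
            f"feature config mismatch: test l={test[0].l}, train l={train[0].l}"
        )
    cap = m_max if m_max is not None else weights.support
    raw = np.zeros((len(test), len(train)))
    for p in profiles_direct(test, train, m_max=cap):
        raw[p.i, p.j] = _coef_dot(p.counts, weights.coef)
    test_diag = np.array(
        [
            _coef_dot(profiles_direct([t], m_max=cap)[0].counts, weights.coef)
            for t in test
        ]
    )
    if (test_diag <= 0).any():
        bad = int(np.nonzero(test_diag <= 0)[0][0])
        raise ValueError(
            f"sequence {test[bad].owner!r} has zero self-similarity (no valid l-mers)"
        )
    values = raw / np.sqrt(np.outer(test_diag, train_diag))
    return KernelMatrix(
        ids_rows=[t.owner for t in test],
        ids_cols=[t.owner for t in train],
        values=values,
        config={"variant": weights.variant, "l": weights.l, "k": weights.k},
        raw_diag_rows=test_diag,
        raw_diag_cols=np.asarray(train_diag, dtype=float),
    )


# ---------------------------------------------------------------------------
# explicit feature-space oracles (small l)


def gapped_kmer_vector(ll: LmerList, l: int, k: int) -> np.ndarray:
    """Explicit gapped k-mer count vector, index = (subset, letters).

    Total mass is n * C(l, k).  Guarded to l <= 8; this is a test oracle,
    production paths never materialize it.
    """
    if ll.l != l:
        raise ValueError(f"l-mer list has l={ll.l}, requested {l}")
    if l > 8:
        raise ValueError("gapped_kmer_vector is an oracle for l <= 8")
    subsets = list(combinations(range(l), k))
    vec = np.zeros(len(subsets) * 4**k)
    for si, pos in enumerate(subsets):
        shifts = [2 * (l - 1 - p) for p in pos]
        base = si * 4**k
        for code, cnt in zip(ll.codes, ll.counts):
            idx = 0
            for sh in shifts:
                idx = (idx << 2) | ((int(code) >> sh) & 3)
            vec[base + idx] += int(cnt)
    return vec


def lmer_estimate_vector(ll: LmerList, filt: GkmFilter) -> np.ndarray:
    """Robust l-mer count estimates for all 4**l l-mers (dense oracle).

    estimate[u] = sum_m g[m] * (number of observed l-mers at distance m
    from u).  With the full filter, the incidence matrix applied to this
    vector reproduces the observed gapped k-mer counts.  Guarded to l <= 8.
    """
    l = filt.l
    if ll.l != l:
        raise ValueError(f"l-mer list has l={ll.l}, filter has l={l}")
    if l > 8:
        raise ValueError("lmer_estimate_vector is a dense oracle for l <= 8")
    all_codes = np.arange(4**l, dtype=np.uint64)
    return _fast.nb_filtered_counts(
        all_codes, ll.codes, ll.counts, filt.g, filt.support, l
    )


# ---------------------------------------------------------------------------
# fast exact gkm path (subset decomposition)


def _flatten(lls: Sequence[LmerList]):
    offsets = np.zeros(len(lls) + 1, dtype=np.int64)
    for i, ll in enumerate(lls):
        offsets[i + 1] = offsets[i] + len(ll.codes)
    flat_codes = np.concatenate([ll.codes for ll in lls]) if lls else np.empty(0, np.uint64)
    flat_cnts = np.concatenate(
        [ll.counts.astype(np.float64) for ll in lls]
    ) if lls else np.empty(0, np.float64)
    return flat_codes, flat_cnts, offsets


def _subset_shifts(l: int, k: int) -> list[np.ndarray]:
    return [
        np.array([2 * (l - 1 - p) for p in pos], dtype=np.uint64)
        for pos in combinations(range(l), k)
    ]


def _masked_codes(flat_codes: np.ndarray, shifts: np.ndarray, k: int) -> np.ndarray:
    idx = np.zeros(len(flat_codes), dtype=np.int64)
    for j in range(k):
        idx = (idx << 2) | ((flat_codes >> shifts[j]) & np.uint64(3)).astype(np.int64)
    return idx


def _sparse_counts(flat_codes, flat_cnts, offsets, shifts, k):
    idx = _masked_codes(flat_codes, shifts, k)
    rows = np.repeat(np.arange(len(offsets) - 1), np.diff(offsets))
    uniq, col = np.unique(idx, return_inverse=True)
    return sp.csr_matrix(
        (flat_cnts, (rows, col)), shape=(len(offsets) - 1, len(uniq))
    )


def gkm_kernel_raw(lls: Sequence[LmerList], l: int, k: int) -> np.ndarray:
    """Exact raw gkm kernel matrix via the position-subset decomposition."""
    if lls and lls[0].l != l:
        raise ValueError(f"l-mer lists have l={lls[0].l}, requested {l}")
    n = len(lls)
    flat_codes, flat_cnts, offsets = _flatten(lls)
    K = np.zeros((n, n), dtype=np.float32, order="F")
    dense = 4**k <= _DENSE_COLS_MAX
    if dense:
        C = np.zeros((n, 4**k), dtype=np.float32)
        for shifts in _subset_shifts(l, k):
            _fast.build_masked_counts(flat_codes, flat_cnts, offsets, shifts, k, C)
            K = _blas.ssyrk(1.0, C, beta=1.0, c=K, trans=0, lower=1, overwrite_c=1)
        K = np.tril(K) + np.tril(K, -1).T
    else:
        Kd = np.zeros((n, n))
        for shifts in _subset_shifts(l, k):
            X = _sparse_counts(flat_codes, flat_cnts, offsets, shifts, k)
            Kd += (X @ X.T).toarray()
        return Kd
    return K.astype(np.float64)


def gkm_kernel_matrix(
    lls: Sequence[LmerList], l: int, k: int, normalize: bool = True
) -> KernelMatrix:
    """Exact normalized gkm training kernel (production path).

    Entrywise identical to the profiles route with
    :func:`gkmseq.weights.gkm_coefficients`.
    """
    raw = gkm_kernel_raw(lls, l, k)
    diag = np.diag(raw).copy()
    ids = [x.owner for x in lls]
    values = raw
    if normalize:
        if (diag <= 0).any():
            bad = int(np.nonzero(diag <= 0)[0][0])
            raise ValueError(
                f"sequence {ids[bad]!r} has zero self-similarity (no valid l-mers)"
            )
        values = raw / np.sqrt(np.outer(diag, diag))
    return KernelMatrix(
        ids_rows=ids,
        ids_cols=ids,
        values=values,
        config={"variant": "gkm", "l": l, "k": k, "normalized": normalize},
        raw_diag_rows=diag,
        raw_diag_cols=diag,
    )


def gkm_cross_matrix(
    test: Sequence[LmerList],
    train: Sequence[LmerList],
    l: int,
    k: int,
    train_diag: np.ndarray,
    normalize: bool = True,
) -> KernelMatrix:
    """Exact normalized test x train gkm kernel via the subset route."""
    ft_codes, ft_cnts, ft_off = _flatten(test)
    tr_codes, tr_cnts, tr_off = _flatten(train)
    nt, nr = len(test), len(train)
    dense = 4**k <= _DENSE_COLS_MAX
    if dense:
        K = np.zeros((nt, nr), dtype=np.float32)
        Ct = np.zeros((nt, 4**k), dtype=np.float32)
        Cr = np.zeros((nr, 4**k), dtype=np.float32)
        for shifts in _subset_shifts(l, k):
            _fast.build_masked_counts(ft_codes, ft_cnts, ft_off, shifts, k, Ct)
            _fast.build_masked_counts(tr_codes, tr_cnts, tr_off, shifts, k, Cr)
            K += Ct @ Cr.T
        raw = K.astype(np.float64)
    else:
        raw = np.zeros((nt, nr))
        for shifts in _subset_shifts(l, k):
            Xt = _masked_codes(ft_codes, shifts, k)
            Xr = _masked_codes(tr_codes, shifts, k)
            uniq = np.unique(np.concatenate([Xt, Xr]))
            st = sp.csr_matrix(
                (ft_cnts, (np.repeat(np.arange(nt), np.diff(ft_off)),
                           np.searchsorted(uniq, Xt))),
                shape=(nt, len(uniq)),
            )
            sr = sp.csr_matrix(
                (tr_cnts, (np.repeat(np.arange(nr), np.diff(tr_off)),
                           np.searchsorted(uniq, Xr))),
                shape=(nr, len(uniq)),
            )
            raw += (st @ sr.T).toarray()
    # test self-similarities via the closed-form coefficients on self profiles
    w = gkm_coefficients(l, k)
    test_diag = np.array(
        [
            _coef_dot(profiles_direct([t], m_max=l - k)[0].counts, w.coef)
            for t in test
        ]
    )
    values = raw
    if normalize:
        if (test_diag <= 0).any():
            bad = int(np.nonzero(test_diag <= 0)[0][0])
            raise ValueError(
                f"sequence {test[bad].owner!r} has zero self-similarity"
            )
        values = raw / np.sqrt(np.outer(test_diag, np.asarray(train_diag)))
    return KernelMatrix(
        ids_rows=[t.owner for t in test],
        ids_cols=[t.owner for t in train],
        values=values,
        config={"variant": "gkm", "l": l, "k": k, "normalized": normalize},
        raw_diag_rows=test_diag,
        raw_diag_cols=np.asarray(train_diag, dtype=float),
    )


# ---------------------------------------------------------------------------
# serialization


def write_kernel_tsv(km: KernelMatrix, path) -> None:
    """Headered tab-separated matrix; config echoed in a '#' comment line."""
    with open(path, "w") as fh:
        cfg = " ".join(f"{k}={v}" for k, v in km.config.items())
        fh.write(f"# gkmseq kernel {cfg}\n")
        fh.write("id\t" + "\t".join(km.ids_cols) + "\n")
        for rid, row in zip(km.ids_rows, km.values):
            fh.write(rid + "\t" + "\t".join(f"{v:.10g}" for v in row) + "\n")


def read_kernel_tsv(path) -> KernelMatrix:
    with open(path) as fh:
        header = fh.readline()
        cfg: dict = {}
        if header.startswith("#"):
            for part in header.split()[3:]:
                if "=" in part:
                    key, val = part.split("=", 1)
                    cfg[key] = val
            header = fh.readline()
        cols = header.rstrip("\n").split("\t")[1:]
        ids, rows = [], []
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            ids.append(parts[0])
            rows.append([float(x) for x in parts[1:]])
    return KernelMatrix(ids_rows=ids, ids_cols=cols, values=np.array(rows), config=cfg)
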