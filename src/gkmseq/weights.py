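"""Distance-indexed kernel coefficients and the gkm-filter.

Every kernel in this framework is a weighted sum over the mismatch profile
of a sequence pair:  K_raw(S1, S2) = sum_m coef[m] * N_m(S1, S2), where
N_m counts l-mer pairs at Hamming distance m.  This module computes the
coefficient families:

* ``gkm``:       coef[m] = C(l-m, k), the number of gapped k-mers (k
                 informative positions chosen from l) shared by two l-mers
                 at distance m;
* ``wildcard``:  coef[m] = sum_{j=m..M} lambda^j C(l-m, j-m) -- patterns with
                 j <= M wildcards matching both l-mers (wildcards must cover
                 every mismatch position), each weighted lambda^j;
* ``mismatch``:  coef[m] = size of the intersection of the two Hamming balls
                 of radius M around l-mers at distance m;
* ``estimate_full`` / ``estimate_truncated``: the linear kernel on robust
                 l-mer count estimates (the gkm-filter applied to observed
                 counts), reduced to the same distance-indexed form.

The gkm-filter g_lk(m) maps observed l-mer counts to minimum-norm l-mer
count estimates.  It is the distance profile of the projection
G = pinv(A) . A, where A is the binary incidence matrix from l-mers to
gapped k-mers.  In the Fourier (character) basis of the Hamming scheme,
G projects onto the components of degree <= k, giving the exact closed form

    g_lk(m) = b^{-l} * sum_{j=0..k} K_j(m; l, b)

with K_j the (binary-alphabet-generalised) Krawtchouk polynomial

    K_j(m) = sum_i (-1)^i (b-1)^{j-i} C(m, i) C(l-m, j-i).

All integer-valued quantities are computed with exact integer/rational
arithmetic and converted to floating point only in the final filter weights.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from itertools import combinations, product
from math import comb
from typing import Optional

import numpy as np

__all__ = [
    "KernelWeights",
    "GkmFilter",
    "gkm_coefficients",
    "wildcard_coefficients",
    "mismatch_coefficients",
    "incidence_matrix",
    "filter_weights",
    "truncate_filter",
    "estimate_kernel_coefficients",
    "spectrum_coefficients",
]

VARIANTS = ("gkm", "wildcard", "mismatch", "estimate_full", "estimate_truncated")


@dataclass(frozen=True)
class KernelWeights:
    """Coefficient vector turning a mismatch profile into a raw kernel value.

    ``coef[m]`` is the weight of an l-mer pair at Hamming distance m;
    ``coef`` has length l+1.
    """

    variant: str
    l: int
    coef: np.ndarray
    k: Optional[int] = None  # informative positions (gkm / estimate)
    M: Optional[int] = None  # max wildcards / mismatches
    lam: float = 1.0
    b: int = 4

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown kernel variant {self.variant!r}")
        if len(self.coef) != self.l + 1:
            raise ValueError("coef must have length l+1")

    @property
    def support(self) -> int:
        """Largest m with coef[m] != 0 (kernel is exact at m_max >= support)."""
        nz = np.nonzero(self.coef)[0]
        return int(nz[-1]) if len(nz) else 0


@dataclass(frozen=True)
class GkmFilter:
    """gkm-filter weights g_lk(m), full or truncated.

    ``g[m]`` weighs the contribution of an observed l-mer to the count
    estimate of an l-mer at distance m.  The truncated variant zeroes every
    entry at and beyond ``m0``, the first m with a negative weight, so that
    count estimates stay non-negative.
    """

    l: int
    k: int
    g: np.ndarray
    truncated: bool = False
    m0: Optional[int] = None  # l+1 sentinel when nothing was truncated

    @property
    def support(self) -> int:
        nz = np.nonzero(self.g)[0]
        return int(nz[-1]) if len(nz) else 0

    @property
    def min_positive(self) -> float:
        pos = self.g[self.g > 0]
        if len(pos) == 0:
            raise ValueError("filter has no positive weight")
        return float(pos.min())


def _check_lk(l: int, k: int) -> None:
    if not (1 <= k <= l):
        raise ValueError(f"require 1 <= k <= l, got l={l}, k={k}")


def gkm_coefficients(l: int, k: int) -> KernelWeights:
    """Gapped k-mer kernel coefficients h_lk(m) = C(l-m, k).

    Two l-mers at distance m share a gapped k-mer for every choice of k
    informative positions among their l-m matching positions.  At l = k this
    is the ungapped spectrum kernel.
    """
    _check_lk(l, k)
    coef = np.array([comb(l - m, k) for m in range(l + 1)], dtype=np.float64)
    return KernelWeights(variant="gkm", l=l, k=k, coef=coef)


def spectrum_coefficients(l: int) -> KernelWeights:
    """The plain l-mer (spectrum) kernel, i.e. the gkm kernel at k = l."""
    return gkm_coefficients(l, l)


def wildcard_coefficients(l: int, M: int, lam: float = 1.0) -> KernelWeights:
    """Wildcard-kernel coefficients.

    A pattern with j wildcards matches both l-mers of a pair at distance m
    iff its wildcards cover all m mismatch positions, so there are
    C(l-m, j-m) such patterns for j >= m.  Each pattern is penalised by
    lambda^j, applied once in the kernel sum.
    """
    if not (0 <= M <= l):
        raise ValueError(f"require 0 <= M <= l, got l={l}, M={M}")
    if lam <= 0:
        raise ValueError("lambda must be positive")
    coef = np.array(
        [
            sum(lam**j * comb(l - m, j - m) for j in range(m, M + 1))
            for m in range(l + 1)
        ],
        dtype=np.float64,
    )
    return KernelWeights(variant="wildcard", l=l, M=M, lam=lam, coef=coef)


def _comb0(n: int, k: int) -> int:
    """Binomial coefficient with the zero-outside-range convention."""
    if k < 0 or n < 0 or k > n:
        return 0
    return comb(n, k)


def _pair_ball_count(l: int, m: int, m1: int, m2: int, t: int, b: int) -> int:
    """Number of l-mers u at distance m1 from u1 and m2 from u2.

    u1, u2 differ at exactly m positions; t of u's mismatches with u1 fall in
    the l-m positions where u1 and u2 agree.  Out-of-range binomials are 0,
    so the triple sum over (m1, m2, t) is self-truncating.
    """
    r = m1 + m2 - 2 * t - m  # positions where u differs from both, third letter
    if r < 0:
        return 0
    base = _comb0(l - m, t) * (b - 1) ** t * _comb0(m, m1 - t) * _comb0(m1 - t, r)
    if base == 0:
        return 0
    return base * (b - 2) ** r if r > 0 else base


def mismatch_coefficients(l: int, M: int, b: int = 4) -> KernelWeights:
    """Mismatch-kernel coefficients: Hamming-ball intersection sizes.

    coef[m] = |{u : d(u, x1) <= M and d(u, x2) <= M}| for any l-mer pair
    (x1, x2) at distance m, via the closed-form triple sum over (m1, m2, t).
    """
    if not (0 <= M <= l):
        raise ValueError(f"require 0 <= M <= l, got l={l}, M={M}")
    if b < 2:
        raise ValueError("alphabet size b must be >= 2")
    coef = np.zeros(l + 1)
    for m in range(l + 1):
        total = 0
        for m1 in range(M + 1):
            for m2 in range(M + 1):
                for t in range(l + 1):
                    total += _pair_ball_count(l, m, m1, m2, t, b)
        coef[m] = total
    return KernelWeights(variant="mismatch", l=l, M=M, b=b, coef=coef)


# ---------------------------------------------------------------------------
# incidence matrix and gkm-filter


def incidence_matrix(l: int, k: int, b: int = 4) -> np.ndarray:
    """Binary matrix A: rows = gapped k-mers, columns = l-mers.

    A[i, j] = 1 iff gapped k-mer v_i (a position subset plus k letters)
    matches l-mer u_j.  Row sums are b^(l-k), column sums C(l, k).  Guarded
    to l <= 6; larger parameters must use the closed forms.
    """
    _check_lk(l, k)
    if l > 6:
        raise ValueError(
            "incidence_matrix is a small-parameter oracle (l <= 6); "
            "use filter_weights/gkm_coefficients for larger l"
        )
    n_lmers = b**l
    rows = []
    for pos in combinations(range(l), k):
        for letters in product(range(b), repeat=k):
            row = np.ones(n_lmers, dtype=np.int8)
            for p, c in zip(pos, letters):
                # digit of u at position p (positions indexed from the left)
                digits = (np.arange(n_lmers) // b ** (l - 1 - p)) % b
                row &= (digits == c).astype(np.int8)
            rows.append(row)
    return np.array(rows, dtype=np.int8)


def _krawtchouk(j: int, m: int, l: int, b: int) -> int:
    return sum(
        (-1) ** i * (b - 1) ** (j - i) * comb(m, i) * comb(l - m, j - i)
        for i in range(j + 1)
    )


def _filter_fractions(l: int, k: int, b: int) -> list[Fraction]:
    bl = Fraction(1, b**l)
    return [
        bl * sum(_krawtchouk(j, m, l, b) for j in range(k + 1)) for m in range(l + 1)
    ]


def pseudo_inverse_weights(l: int, k: int, b: int = 4) -> np.ndarray:
    """Pseudo-inverse weights w(t), t = 0..k.

    w(t) is the weight with which a gapped k-mer at distance t (counted on
    its k defined positions) contributes to an l-mer count estimate; the
    filter is g_lk(m) = sum_t C(m, t) C(l-m, k-t) w(t).  Recovered exactly
    from g_lk(m) by solving that relation's lower-triangular system at
    m = 0..k; the remaining identities (m = k+1..l) are implied and checked
    in the test suite.
    """
    _check_lk(l, k)
    g = _filter_fractions(l, k, b)
    w: list[Fraction] = []
    for m in range(k + 1):
        acc = sum(
            Fraction(comb(m, t) * comb(l - m, k - t)) * w[t] for t in range(m)
        )
        diag = comb(m, m) * comb(l - m, k - m)
        w.append((g[m] - acc) / diag)
    return np.array([float(x) for x in w])


def filter_weights(l: int, k: int, b: int = 4) -> GkmFilter:
    """The full gkm-filter g_lk(m).

    Computed as the distance profile of the projection pinv(A).A via the
    partial Krawtchouk sum (exact rational arithmetic, converted to float at
    the end).  At l = k this is the identity filter (delta at m = 0).
    """
    _check_lk(l, k)
    g = np.array([float(x) for x in _filter_fractions(l, k, b)])
    return GkmFilter(l=l, k=k, g=g, truncated=False, m0=None)


def truncate_filter(filt: GkmFilter) -> GkmFilter:
    """Zero all weights at and beyond the first negative entry.

    The minimum-norm estimate is not sign-constrained and can dip negative at
    large m; truncation trades the minimum-norm property for non-negative
    count estimates (required wherever logarithms or ratios are taken).
    Idempotent; a filter with no negative entry gets the sentinel m0 = l+1.
    """
    if filt.truncated:
        return filt
    neg = np.nonzero(filt.g < 0)[0]
    m0 = int(neg[0]) if len(neg) else filt.l + 1
    g = filt.g.copy()
    g[m0:] = 0.0
    return GkmFilter(l=filt.l, k=filt.k, g=g, truncated=True, m0=m0)


def estimate_kernel_coefficients(
    l: int, k: int, filt: Optional[GkmFilter] = None, b: int = 4
) -> KernelWeights:
    """Coefficients c_lk(m) of the kernel on l-mer count estimates.

    c_m = sum over all l-mers u of g(d(u, u1)) g(d(u, u2)) for any pair
    (u1, u2) at distance m, evaluated by the closed-form sum over
    (m1, m2, t) with the pair-ball multiplicities.  For the full filter the
    projection identity G.G = G forces c_m = g_m exactly; for a truncated
    filter the sum is evaluated as written.
    """
    if filt is None:
        filt = filter_weights(l, k, b)
    if (filt.l, filt.k) != (l, k):
        raise ValueError(
            f"filter was built for (l={filt.l}, k={filt.k}), not (l={l}, k={k})"
        )
    g = filt.g
    coef = np.zeros(l + 1)
    for m in range(l + 1):
        total = 0.0
        for m1 in range(l + 1):
            if g[m1] == 0.0:
                continue
            for m2 in range(l + 1):
                if g[m2] == 0.0:
                    continue
                s = 0
                for t in range(min(m1, l - m) + 1):
                    s += _pair_ball_count(l, m, m1, m2, t, b)
                total += g[m1] * g[m2] * s
        coef[m] = total
    variant = "estimate_truncated" if filt.truncated else "estimate_full"
    return KernelWeights(variant=variant, l=l, k=k, b=b, coef=coef)
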