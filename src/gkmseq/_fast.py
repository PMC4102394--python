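"""Low-level numba kernels shared by profiles, kernels and models.

All routines operate on l-mers packed two bits per base into uint64 codes
(first base in the high bits), as produced by :mod:`gkmseq.seqio`.
Bit-twiddling constants are kept as np.uint64 throughout: numba follows
numpy's promotion rules and a stray int64 operand would silently promote
the arithmetic to float64.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_M1 = np.uint64(0x5555555555555555)
_M2 = np.uint64(0x3333333333333333)
_M4 = np.uint64(0x0F0F0F0F0F0F0F0F)
_H01 = np.uint64(0x0101010101010101)
_U1 = np.uint64(1)
_U2 = np.uint64(2)
_U3 = np.uint64(3)
_U4 = np.uint64(4)
_U56 = np.uint64(56)


@njit(cache=True, inline="always")
def base_mismatches(a, b):
    """Hamming distance in base positions between two packed codes."""
    x = a ^ b
    y = (x | (x >> _U1)) & _M1
    y = y - ((y >> _U1) & _M1)
    y = (y & _M2) + ((y >> _U2) & _M2)
    y = (y + (y >> _U4)) & _M4
    return int((y * _H01) >> _U56)


@njit(cache=True)
def pair_profile(codes_a, cnts_a, codes_b, cnts_b, m_cap):
    """Mismatch profile between two deduplicated l-mer multisets.

    counts[m] = number of ordered l-mer pairs (one from each multiset) at
    Hamming distance m, for m <= m_cap; larger distances are dropped.
    """
    counts = np.zeros(m_cap + 1, dtype=np.int64)
    for i in range(codes_a.shape[0]):
        ca = cnts_a[i]
        ai = codes_a[i]
        for j in range(codes_b.shape[0]):
            m = base_mismatches(ai, codes_b[j])
            if m <= m_cap:
                counts[m] += ca * cnts_b[j]
    return counts


@njit(cache=True)
def build_masked_counts(flat_codes, flat_cnts, offsets, shifts, k, out):
    """Scatter per-sequence masked k-mer counts into a dense matrix.

    ``shifts[j]`` (uint64) is the bit shift of the j-th selected position;
    the masked index concatenates the k selected 2-bit fields.  ``out`` has
    shape (n_sequences, 4**k) and is zeroed here.
    """
    n = offsets.shape[0] - 1
    out[:, :] = 0.0
    for i in range(n):
        for p in range(offsets[i], offsets[i + 1]):
            code = flat_codes[p]
            idx = 0
            for j in range(k):
                idx = (idx << 2) | int((code >> shifts[j]) & _U3)
            out[i, idx] += flat_cnts[p]


@njit(cache=True)
def score_wmers_gkm(codes, rc_codes, tables, shifts_all, k, h0, hcoef):
    """Normalized SVM decision numerators for w-mers under the gkm fast path.

    ``tables[s]`` holds, for position subset s, the support-vector-weighted
    masked k-mer counts; ``shifts_all[s, j]`` (uint64) the bit shifts of the
    subset.  For w-mer u with strand multiset {u, rc(u)} the raw cross
    kernel summed over support vectors is
    sum_s tables[s][mask(u)] + tables[s][mask(rc(u))], and the w-mer's own
    raw self-similarity is 2*h0 + 2*h[d(u, rc(u))].
    """
    n = codes.shape[0]
    n_sub = tables.shape[0]
    out = np.empty(n, dtype=np.float64)
    for i in range(n):
        u = codes[i]
        ru = rc_codes[i]
        acc = 0.0
        for s in range(n_sub):
            idx = 0
            ridx = 0
            for j in range(k):
                sh = shifts_all[s, j]
                idx = (idx << 2) | int((u >> sh) & _U3)
                ridx = (ridx << 2) | int((ru >> sh) & _U3)
            acc += tables[s, idx] + tables[s, ridx]
        d = base_mismatches(u, ru)
        self_raw = 2.0 * h0 + 2.0 * hcoef[d]
        out[i] = acc / np.sqrt(self_raw)
    return out


@njit(cache=True)
def nb_filtered_brute(q_codes, t_codes, t_cnts, gtab, msup):
    """est[q] = sum_v cnt_v * gtab[d(q, v)] over table l-mers within msup."""
    Q = q_codes.shape[0]
    out = np.zeros(Q, dtype=np.float64)
    for i in range(Q):
        qi = q_codes[i]
        acc = 0.0
        for j in range(t_codes.shape[0]):
            m = base_mismatches(qi, t_codes[j])
            if m <= msup:
                acc += t_cnts[j] * gtab[m]
        out[i] = acc
    return out


@njit(cache=True)
def nb_filtered_indexed(
    q_codes,
    t_codes,
    t_cnts,
    bucket_starts,  # (B, 4**maxlen + 1) bucket offsets per block
    bucket_order,  # (B, T) table indices sorted by block key, per block
    block_shifts,  # uint64 (B,)
    block_lens,  # int64 (B,)
    gtab,
    msup,
):
    """Output-sensitive version of :func:`nb_filtered_brute`.

    The l positions are split into B blocks, each probed at radius 1: any
    pair within total distance msup <= 2B-1 has some block with at most one
    mismatch, so probing each query block's exact value plus all single-base
    substitutions finds every neighbour.  A pair is attributed to the first
    block whose block distance is <= 1, to avoid double counting.
    """
    Q = q_codes.shape[0]
    B = block_shifts.shape[0]
    out = np.zeros(Q, dtype=np.float64)
    for i in range(Q):
        qi = q_codes[i]
        acc = 0.0
        for b in range(B):
            blen = block_lens[b]
            shift = block_shifts[b]
            mask = (_U1 << np.uint64(2 * blen)) - _U1
            # np.int64 cast: numba's int() keeps uint64, and uint64 mixed
            # with a non-literal int64 promotes to float64
            qkey = np.int64((qi >> shift) & mask)
            n_probe = 1 + 3 * blen
            for pr in range(n_probe):
                if pr == 0:
                    pkey = qkey
                else:
                    pos = (pr - 1) // 3
                    alt = (pr - 1) % 3
                    cur = (qkey >> (2 * pos)) & 3
                    newb = alt if alt < cur else alt + 1
                    pkey = (qkey & ~(3 << (2 * pos))) | (newb << (2 * pos))
                lo = bucket_starts[b, pkey]
                hi = bucket_starts[b, pkey + 1]
                for ptr in range(lo, hi):
                    j = bucket_order[b, ptr]
                    tj = t_codes[j]
                    d = base_mismatches(qi, tj)
                    if d > msup:
                        continue
                    first = True
                    for bb in range(b):
                        mk2 = (_U1 << np.uint64(2 * block_lens[bb])) - _U1
                        x = ((qi ^ tj) >> block_shifts[bb]) & mk2
                        y = (x | (x >> _U1)) & _M1
                        # block distance <= 1 iff y has <= 1 bit set
                        if (y & (y - _U1)) == np.uint64(0):
                            first = False
                            break
                    if first:
                        acc += t_cnts[j] * gtab[d]
        out[i] = acc
    return out


def nb_filtered_counts(q_codes, t_codes, t_cnts, gtab, msup, l):
    """Dispatch between the brute scan and the block index.

    The index pays off when Q*T is large and the filter support msup is
    small relative to l.
    """
    Q, T = len(q_codes), len(t_codes)
    if Q == 0 or T == 0:
        return np.zeros(Q, dtype=np.float64)
    gtab = np.asarray(gtab, dtype=np.float64)
    cnts = np.asarray(t_cnts, dtype=np.float64)
    B = (msup + 2) // 2  # smallest B with 2B-1 >= msup
    if Q * T < 2e8 or B < 2 or l // B < 2:
        return nb_filtered_brute(q_codes, t_codes, cnts, gtab, msup)
    lens = np.full(B, l // B, dtype=np.int64)
    lens[: l % B] += 1
    shifts = np.empty(B, dtype=np.uint64)
    pos = l
    for b in range(B):
        pos -= int(lens[b])
        shifts[b] = np.uint64(2 * pos)
    maxlen = int(lens.max())
    starts = np.zeros((B, 4**maxlen + 1), dtype=np.int64)
    order = np.zeros((B, T), dtype=np.int64)
    for b in range(B):
        mask = np.uint64((1 << (2 * int(lens[b]))) - 1)
        keys = ((t_codes >> shifts[b]) & mask).astype(np.int64)
        order[b] = np.argsort(keys, kind="stable")
        counts = np.bincount(keys, minlength=4 ** int(lens[b]))
        starts[b, 1 : 4 ** int(lens[b]) + 1] = np.cumsum(counts)
        starts[b, 4 ** int(lens[b]) + 1 :] = starts[b, 4 ** int(lens[b])]
    return nb_filtered_indexed(
        q_codes, t_codes, cnts, starts, order, shifts, lens, gtab, msup
    )
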