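"""Mismatch profiles N_m between sequence pairs.

The mismatch profile of two sequences is the integer vector counting, for
each Hamming distance m, the number of l-mer pairs (one l-mer from each
sequence, with multiplicity) at that distance.  It is the sufficient
statistic for every kernel in this framework.

Two independent algorithms are provided and must agree exactly:

* :func:`profiles_direct` compares all unique l-mer pairs with a bitwise
  XOR and a precomputed lookup table (chunked two-bit encoding);
* :func:`profiles_tree` inserts all l-mers into a k-mer tree and computes
  every pairwise profile in one depth-first traversal, carrying at each
  node the list of same-depth nodes within ``m_max`` mismatches.  Node
  pairs whose sequence-id ranges cannot contribute to the lower triangle
  (maxID(t_i) < minID(t_j)) are pruned.

Setting ``m_max`` truncates the profile: only distances m <= m_max are
counted.  With m_max >= the coefficient support (l - k for the gkm kernel)
the truncated kernel equals the exact one.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from . import _fast
from .seqio import EncodedLmer, LmerList

__all__ = [
    "MismatchProfile",
    "count_mismatches",
    "profiles_direct",
    "profiles_tree",
    "choose_algorithm",
    "KmerTreeNode",
    "dump_profiles",
]

_XOR_TABLES: dict[int, np.ndarray] = {}


def _xor_table(t: int) -> np.ndarray:
    """Lookup table: 2t-bit XOR pattern -> number of mismatched bases."""
    tab = _XOR_TABLES.get(t)
    if tab is None:
        x = np.arange(4**t, dtype=np.uint64)
        y = (x | (x >> np.uint64(1))) & np.uint64(0x5555555555555555)
        tab = np.bitwise_count(y).astype(np.uint8)
        _XOR_TABLES[t] = tab
    return tab


def count_mismatches(u1: EncodedLmer, u2: EncodedLmer) -> int:
    """Hamming distance (in bases) between two encoded l-mers.

    Each chunk pair is XORed and the mismatch count read from a
    4**t-entry table.
    """
    if u1.l != u2.l or u1.t != u2.t:
        raise ValueError(
            f"l-mer encodings differ: (l={u1.l}, t={u1.t}) vs (l={u2.l}, t={u2.t})"
        )
    tab = _xor_table(u1.t)
    return int(sum(tab[c1 ^ c2] for c1, c2 in zip(u1.chunks, u2.chunks)))


@dataclass
class MismatchProfile:
    """Mismatch profile of one sequence pair.

    ``counts[m]`` is the number of ordered l-mer pairs at distance m for
    m <= m_max (m_max = l when untruncated); without truncation the counts
    sum to n_i * n_j.
    """

    i: int
    j: int
    counts: np.ndarray
    m_max: Optional[int] = None


def _pair_counts(a: LmerList, b: LmerList, m_cap: int) -> np.ndarray:
    return _fast.pair_profile(
        a.codes, a.counts.astype(np.int64), b.codes, b.counts.astype(np.int64), m_cap
    )


def _check_same_l(lists: Sequence[LmerList]) -> int:
    ls = {x.l for x in lists}
    if len(ls) != 1:
        raise ValueError(f"l-mer lists have mixed l: {sorted(ls)}")
    return ls.pop()


def profiles_direct(
    setA: Sequence[LmerList],
    setB: Optional[Sequence[LmerList]] = None,
    m_max: Optional[int] = None,
) -> list[MismatchProfile]:
    """All-pairs mismatch profiles by direct l-mer comparison.

    With ``setB`` given, profiles for the full A x B grid are returned
    (i indexes A, j indexes B).  With ``setB=None``, the lower triangle of
    A x A including self pairs (i >= j), which is what kernel assembly
    needs.
    """
    l = _check_same_l(list(setA) + (list(setB) if setB is not None else []))
    m_cap = l if m_max is None else min(m_max, l)
    out: list[MismatchProfile] = []
    if setB is None:
        for i, a in enumerate(setA):
            for j in range(i + 1):
                out.append(
                    MismatchProfile(i, j, _pair_counts(a, setA[j], m_cap), m_max)
                )
    else:
        for i, a in enumerate(setA):
            for j, b in enumerate(setB):
                out.append(MismatchProfile(i, j, _pair_counts(a, b, m_cap), m_max))
    return out


# ---------------------------------------------------------------------------
# k-mer tree


class KmerTreeNode:
    """Node of the l-mer tree; leaves carry (sequence index, count) lists."""

    __slots__ = ("children", "occs", "min_id", "max_id")

    def __init__(self) -> None:
        self.children: dict[int, "KmerTreeNode"] = {}
        self.occs: list[tuple[int, int]] = []
        self.min_id = 1 << 30
        self.max_id = -1

    def insert(self, code: int, l: int, seq_id: int, count: int) -> None:
        node = self
        node.min_id = min(node.min_id, seq_id)
        node.max_id = max(node.max_id, seq_id)
        for depth in range(l):
            base = (code >> (2 * (l - 1 - depth))) & 3
            child = node.children.get(base)
            if child is None:
                child = KmerTreeNode()
                node.children[base] = child
            node = child
            node.min_id = min(node.min_id, seq_id)
            node.max_id = max(node.max_id, seq_id)
        node.occs.append((seq_id, count))

    @property
    def n_leaves(self) -> int:
        if not self.children:
            return 1
        return sum(c.n_leaves for c in self.children.values())

    def leaf_strings(self, prefix: str = "") -> list[str]:
        if not self.children:
            return [prefix]
        out: list[str] = []
        for base in sorted(self.children):
            out.extend(self.children[base].leaf_strings(prefix + "ACGT"[base]))
        return out


def build_kmer_tree(seqs: Sequence[LmerList]) -> KmerTreeNode:
    l = _check_same_l(seqs)
    root = KmerTreeNode()
    for si, ll in enumerate(seqs):
        for code, cnt in zip(ll.codes, ll.counts):
            root.insert(int(code), l, si, int(cnt))
    return root


def profiles_tree(
    seqs: Sequence[LmerList], m_max: Optional[int] = None
) -> list[MismatchProfile]:
    """Lower-triangle mismatch profiles via one DFS over the k-mer tree.

    Identical to :func:`profiles_direct` restricted to m <= m_max.  Each
    visited node carries the list of same-depth nodes within m_max
    mismatches plus their running distances; at a leaf, every pointed-to
    leaf's occurrence list is combined with the leaf's own, attributing
    each ordered l-mer pair with seq_i >= seq_j exactly once.
    """
    l = _check_same_l(seqs)
    m_cap = l if m_max is None else min(m_max, l)
    n = len(seqs)
    root = build_kmer_tree(seqs)
    counts = {
        (i, j): np.zeros(m_cap + 1, dtype=np.int64)
        for i in range(n)
        for j in range(i + 1)
    }

    def dfs(node: KmerTreeNode, ptrs: list[tuple[KmerTreeNode, int]]) -> None:
        if not node.children:  # leaf at depth l
            for other, mm in ptrs:
                for si, ci in node.occs:
                    for sj, cj in other.occs:
                        if si >= sj:
                            counts[(si, sj)][mm] += ci * cj
            return
        for base, child in node.children.items():
            new_ptrs: list[tuple[KmerTreeNode, int]] = []
            for other, mm in ptrs:
                for obase, ochild in other.children.items():
                    nm = mm + (1 if base != obase else 0)
                    if nm > m_cap:
                        continue
                    if child.max_id < ochild.min_id:
                        # subtree pair can only produce seq_i < seq_j pairs,
                        # which belong to the mirrored visit
                        continue
                    new_ptrs.append((ochild, nm))
            dfs(child, new_ptrs)

    dfs(root, [(root, 0)])
    return [
        MismatchProfile(i, j, counts[(i, j)], m_max)
        for i in range(n)
        for j in range(i + 1)
    ]


def choose_algorithm(
    n_sequences: int, l: int, k: int, m_max: Optional[int] = None
) -> str:
    """Heuristic from the framework: tree when the number of allowed
    mismatches is small and the set is large, direct otherwise."""
    mm = m_max if m_max is not None else l - k
    if mm <= 4 and n_sequences > 50:
        return "tree"
    return "direct"


def dump_profiles(profiles: Sequence[MismatchProfile], path) -> None:
    """Write profiles as a tab-separated (i, j, m, count) table."""
    with open(path, "w") as fh:
        fh.write("#i\tj\tm\tcount\n")
        for p in profiles:
            for m, c in enumerate(p.counts):
                fh.write(f"{p.i}\t{p.j}\t{m}\t{int(c)}\n")
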