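"""De novo PWM construction from SVM-ranked k-mers, and PWM scoring.

A trained gapped k-mer SVM assigns a weight to every w-mer (default
w = 10).  The top fraction of that ranking is condensed into up to three
position weight matrices by an iterated greedy alignment: seed a PWM from
the single highest-weight k-mer, align every remaining top k-mer to it
(all offsets with at least half overlap, both strands), accept alignments
whose log-odds against the background clear a threshold (default 5.0 at a
genomic GC of 0.42), rebuild the PWM from the accepted k-mers with mass
exp(alpha * weight), and iterate until the assignment set stops changing.
Used k-mers are removed and the process repeats for the next PWM.

PWMs score sequences by their best log-odds match over all offsets and
both strands -- the single-PWM baseline classifier.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Optional, Sequence

import numpy as np

from .seqio import SequenceRecord, reverse_complement

__all__ = [
    "PWM",
    "pwm_best_match_score",
    "align_kmer_to_pwm",
    "build_pwms",
    "write_meme",
    "read_meme",
]

_BASES = "ACGT"
_IDX = {b: i for i, b in enumerate(_BASES)}


def background_freqs(gc: float) -> np.ndarray:
    """Position-independent background: gc/2 for G/C, (1-gc)/2 for A/T."""
    return np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])


@dataclass
class PWM:
    """Position weight matrix with background and provenance.

    ``probs[i, b]`` is the probability of base b at position i; every
    column sums to 1 and is strictly positive after pseudo-counting.
    """

    probs: np.ndarray
    gc: float = 0.42
    name: str = "pwm"
    provenance: list = field(default_factory=list)  # (kmer, weight) pairs

    @property
    def width(self) -> int:
        return self.probs.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(_BASES[i] for i in self.probs.argmax(axis=1))

    def log_odds(self) -> np.ndarray:
        return np.log(self.probs / background_freqs(self.gc))

    @property
    def max_score(self) -> float:
        return float(self.log_odds().max(axis=1).sum())


def _encode(seq: str) -> np.ndarray:
    return np.array([_IDX.get(c, -1) for c in seq.upper()], dtype=np.int64)


def _best_score_one_strand(lo: np.ndarray, enc: np.ndarray) -> float:
    w = lo.shape[0]
    best = -np.inf
    for off in range(len(enc) - w + 1):
        win = enc[off : off + w]
        if (win < 0).any():  # ambiguous base in window
            continue
        s = float(lo[np.arange(w), win].sum())
        if s > best:
            best = s
    return best


def pwm_best_match_score(pwm: PWM, seq: SequenceRecord) -> float:
    """Maximum summed log-odds over all offsets and both strands."""
    if len(seq.bases) < pwm.width:
        raise ValueError(
            f"sequence {seq.id!r} (length {len(seq.bases)}) is shorter than "
            f"PWM width {pwm.width}"
        )
    lo = pwm.log_odds()
    fwd = _best_score_one_strand(lo, _encode(seq.bases))
    rev = _best_score_one_strand(lo, _encode(reverse_complement(seq.bases)))
    best = max(fwd, rev)
    if best == -np.inf:
        raise ValueError(f"sequence {seq.id!r} has no unambiguous window")
    return best


class Alignment(NamedTuple):
    offset: int  # k-mer start relative to PWM start (may be negative)
    strand: str
    score: float


def _alignment_offsets(kmer_len: int, width: int) -> range:
    min_overlap = (kmer_len + 1) // 2  # at least half the k-mer on the PWM
    return range(-(kmer_len - min_overlap), width - min_overlap + 1)


def _align_score(lo: np.ndarray, enc: np.ndarray, offset: int) -> float:
    w = lo.shape[0]
    s = 0.0
    for i, b in enumerate(enc):
        p = offset + i
        if 0 <= p < w:
            s += lo[p, b]
    return float(s)


def align_kmer_to_pwm(
    kmer: str,
    pwm: PWM,
    threshold: float = 5.0,
    gc: Optional[float] = None,
) -> Optional[Alignment]:
    """Best (offset, strand) of a k-mer against a PWM by log-odds.

    Offsets allow partial overlap with at least half of the k-mer on the
    PWM; log-odds are summed over the overlapping positions only.  Returns
    ``None`` when the best score is below ``threshold``.  Ties prefer the
    smaller offset and the forward strand (deterministic).
    """
    bg_pwm = pwm if gc is None else PWM(pwm.probs, gc=gc, name=pwm.name)
    lo = bg_pwm.log_odds()
    best: Optional[Alignment] = None
    for strand, s in (("+", kmer), ("-", reverse_complement(kmer))):
        enc = _encode(s)
        for off in _alignment_offsets(len(kmer), pwm.width):
            sc = _align_score(lo, enc, off)
            if best is None or sc > best.score + 1e-12:
                best = Alignment(off, strand, sc)
    if best is None or best.score < threshold:
        return None
    return best


def _pwm_from_assignments(
    assignments: Sequence[tuple[str, float, int, str]],
    width: int,
    gc: float,
    alpha: float,
    name: str,
) -> PWM:
    """Accumulate exp(alpha*weight) mass into aligned columns and normalize.

    Overhanging k-mer bases are ignored; each column receives a uniform
    pseudo-count of 1% of its own mass (uniform column if empty).
    """
    mass = np.zeros((width, 4))
    prov = []
    for kmer, weight, offset, strand in assignments:
        s = kmer if strand == "+" else reverse_complement(kmer)
        m = float(np.exp(alpha * weight))
        for i, c in enumerate(s.upper()):
            p = offset + i
            if 0 <= p < width:
                mass[p, _IDX[c]] += m
        prov.append((kmer, weight))
    probs = np.empty_like(mass)
    for p in range(width):
        tot = mass[p].sum()
        if tot <= 0:
            probs[p] = 0.25
        else:
            col = mass[p] + 0.01 * tot / 4.0
            probs[p] = col / col.sum()
    return PWM(probs=probs, gc=gc, name=name, provenance=prov)


def _align_batch(
    onehot_fwd: np.ndarray,  # (n, L, 4)
    onehot_rev: np.ndarray,
    lo: np.ndarray,  # (width, 4)
    offsets: Sequence[int],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Best (score, offset, strand) of every k-mer against one PWM.

    Vectorized equivalent of :func:`align_kmer_to_pwm`; forward strand and
    smaller offsets win ties.
    """
    n, L, _ = onehot_fwd.shape
    width = lo.shape[0]
    n_off = len(offsets)
    scores = np.empty((n, 2, n_off))
    for oi, off in enumerate(offsets):
        p_lo = max(0, off)
        p_hi = min(width, off + L)
        cols = slice(p_lo, p_hi)
        kpos = slice(p_lo - off, p_hi - off)
        block = lo[cols]  # (overlap, 4)
        scores[:, 0, oi] = np.einsum("nlb,lb->n", onehot_fwd[:, kpos, :], block)
        scores[:, 1, oi] = np.einsum("nlb,lb->n", onehot_rev[:, kpos, :], block)
    flat = scores.reshape(n, -1)
    best_idx = flat.argmax(axis=1)
    best = flat[np.arange(n), best_idx]
    strand_idx, off_idx = np.divmod(best_idx, n_off)
    return best, np.asarray(offsets)[off_idx], strand_idx


def build_pwms(
    kmers: Sequence[str],
    weights: Sequence[float],
    max_pwms: int = 3,
    threshold: float = 5.0,
    gc: float = 0.42,
    alpha: float = 3.0,
    min_kmers: int = 5,
    max_iter: int = 50,
) -> list[PWM]:
    """Iterated greedy PWM construction from a ranked k-mer table.

    ``kmers``/``weights`` must already be the top fraction of the ranking;
    they are (re)sorted by descending weight with lexicographic tie-break.
    PWM width is fixed at the seed k-mer's length; overhanging aligned
    bases are ignored.  PWMs whose converged assignment holds fewer than
    ``min_kmers`` k-mers are dropped (their k-mers are still consumed).
    """
    order = sorted(range(len(kmers)), key=lambda i: (-weights[i], kmers[i]))
    kmer_list = [kmers[i] for i in order]
    weight_arr = np.asarray([weights[i] for i in order], dtype=float)
    if len(kmer_list) == 0:
        return []
    L = len(kmer_list[0])
    enc_f = np.array([_encode(k) for k in kmer_list])
    enc_r = np.array([_encode(reverse_complement(k)) for k in kmer_list])
    eye = np.eye(4)
    onehot_f = eye[enc_f]
    onehot_r = eye[enc_r]
    alive = np.ones(len(kmer_list), dtype=bool)
    pwms: list[PWM] = []
    for pi in range(max_pwms):
        idx = np.nonzero(alive)[0]
        if len(idx) == 0:
            break
        seed = idx[0]
        width = L
        offsets = list(_alignment_offsets(L, width))
        seed_assign = [(kmer_list[seed], weight_arr[seed], 0, "+")]
        pwm = _pwm_from_assignments(seed_assign, width, gc, alpha, f"pwm{pi + 1}")
        prev_key = None
        for _ in range(max_iter):
            best, off, strand = _align_batch(
                onehot_f[idx], onehot_r[idx], pwm.log_odds(), offsets
            )
            acc = best >= threshold
            if not acc.any():
                pwm = _pwm_from_assignments(seed_assign, width, gc, alpha, pwm.name)
                break
            assignments = [
                (
                    kmer_list[i],
                    weight_arr[i],
                    int(off[j]),
                    "+" if strand[j] == 0 else "-",
                )
                for j, i in enumerate(idx)
                if acc[j]
            ]
            key = tuple((a[0], a[2], a[3]) for a in assignments)
            pwm = _pwm_from_assignments(assignments, width, gc, alpha, pwm.name)
            if key == prev_key:
                break
            prev_key = key
        used = {k for k, _ in pwm.provenance}
        for j, km in enumerate(kmer_list):
            if km in used:
                alive[j] = False
        if len(pwm.provenance) >= min_kmers:
            pwms.append(pwm)
    return pwms


def pwm_alignment_correlation(pwm_a: np.ndarray, pwm_b: np.ndarray) -> float:
    """Best mean per-column Pearson correlation between two PWMs.

    Slides the narrower matrix over the wider one (both strands, at least
    half overlap) and returns the alignment with the highest mean
    column-wise Pearson r.  Used to quantify recovery of a planted motif.
    """
    a = np.asarray(pwm_a, dtype=float)
    b = np.asarray(pwm_b, dtype=float)
    if len(a) > len(b):
        a, b = b, a
    # reverse complement of a PWM: reverse rows, swap A<->T and C<->G
    a_rc = a[::-1, ::-1]
    best = -1.0
    min_ov = (len(a) + 1) // 2
    for mat in (a, a_rc):
        for off in range(-(len(a) - min_ov), len(b) - min_ov + 1):
            lo_b = max(0, off)
            hi_b = min(len(b), off + len(mat))
            cols_a = mat[lo_b - off : hi_b - off]
            cols_b = b[lo_b:hi_b]
            rs = []
            for ca, cb in zip(cols_a, cols_b):
                sa, sb = ca - ca.mean(), cb - cb.mean()
                denom = np.sqrt((sa**2).sum() * (sb**2).sum())
                rs.append(float(sa @ sb / denom) if denom > 0 else 0.0)
            if rs and float(np.mean(rs)) > best:
                best = float(np.mean(rs))
    return best


# ---------------------------------------------------------------------------
# MEME minimal format


def write_meme(pwms: Sequence[PWM], path, gc: float = 0.42) -> None:
    bg = background_freqs(gc)
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        fh.write("Background letter frequencies\n")
        fh.write(
            f"A {bg[0]:.5f} C {bg[1]:.5f} G {bg[2]:.5f} T {bg[3]:.5f}\n\n"
        )
        for pwm in pwms:
            fh.write(f"MOTIF {pwm.name}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {pwm.width} "
                f"nsites= {max(1, len(pwm.provenance))} E= 0\n"
            )
            for row in pwm.probs:
                fh.write(" ".join(f"{v:.6f}" for v in row) + "\n")
            fh.write("\n")


def read_meme(path) -> list[PWM]:
    pwms: list[PWM] = []
    gc = 0.5
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    i = 0
    while i < len(lines):
        ln = lines[i]
        if ln.startswith("Background letter frequencies"):
            parts = lines[i + 1].split()
            freq = {parts[j]: float(parts[j + 1]) for j in range(0, len(parts), 2)}
            gc = freq.get("C", 0.25) + freq.get("G", 0.25)
            i += 2
            continue
        if ln.startswith("MOTIF"):
            name = ln.split()[1] if len(ln.split()) > 1 else "pwm"
            i += 1
            while i < len(lines) and not lines[i].startswith("letter-probability"):
                i += 1
            header = lines[i].split()
            w = int(header[header.index("w=") + 1])
            rows = []
            for j in range(i + 1, i + 1 + w):
                rows.append([float(x) for x in lines[j].split()])
            pwms.append(PWM(probs=np.array(rows), gc=gc, name=name))
            i += 1 + w
            continue
        i += 1
    return pwms
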