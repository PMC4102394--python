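"""Sequence I/O, two-bit l-mer encoding and strand-symmetric l-mer extraction.

Sequences are plain DNA strings over A/C/G/T/N plus the IUPAC ambiguity
letters; lowercase marks repeat-masked bases (soft masking).  Feature
extraction case-folds, skips any window containing a non-ACGT base, and by
default appends the reverse-complement strand's l-mers so that every
downstream kernel is exactly strand symmetric.

l-mers are packed two bits per base (A=0, C=1, G=2, T=3).  The public
:class:`EncodedLmer` carries the chunked representation (``t`` bases per
integer chunk) used by the XOR/lookup-table mismatch counter; the internal
fast paths pack whole l-mers (l <= 32) into single 64-bit codes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence

import numpy as np

__all__ = [
    "SequenceRecord",
    "EncodedLmer",
    "LmerList",
    "read_fasta",
    "write_fasta",
    "reverse_complement",
    "extract_lmers",
    "encode_lmer",
    "decode_lmer",
    "pack_code",
    "unpack_code",
    "revcomp_code",
    "DEFAULT_CHUNK_WIDTH",
    "FastaFormatError",
]

DEFAULT_CHUNK_WIDTH = 6  # bases per integer chunk for the XOR lookup table

_BASES = "ACGT"
_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}

# full IUPAC nucleotide complement, both cases
_IUPAC = "ACGTUNRYSWKMBDHV"
_COMP = dict(
    zip(
        "ACGTUNRYSWKMBDHV" + "ACGTUNRYSWKMBDHV".lower(),
        "TGCAANYRSWMKVHDB" + "TGCAANYRSWMKVHDB".lower(),
    )
)
_VALID_CHARS = frozenset(_IUPAC + _IUPAC.lower())


class FastaFormatError(ValueError):
    """Malformed FASTA input (bad header or non-IUPAC character)."""


@dataclass
class SequenceRecord:
    """One DNA sequence with an identifier and an optional class label.

    ``label`` is +1/-1 for positive/negative training examples, or ``None``.
    Lowercase bases are interpreted as repeat-masked.
    """

    id: str
    bases: str
    label: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.bases:
            raise ValueError(f"sequence {self.id!r} is empty")

    def __len__(self) -> int:
        return len(self.bases)

    @property
    def repeat_fraction(self) -> float:
        """Fraction of soft-masked (lowercase) bases, in [0, 1]."""
        low = sum(1 for c in self.bases if c.islower())
        return low / len(self.bases)

    def reverse_complement(self) -> "SequenceRecord":
        return SequenceRecord(self.id, reverse_complement(self.bases), self.label)


def reverse_complement(bases: str) -> str:
    """Watson-Crick reverse complement; N -> N, per-position case preserved."""
    try:
        return "".join(_COMP[c] for c in reversed(bases))
    except KeyError as exc:
        raise ValueError(f"non-IUPAC character {exc.args[0]!r} in sequence") from None


def read_fasta(path) -> list[SequenceRecord]:
    """Read a FASTA file into records, preserving order and case.

    Raises :class:`FastaFormatError` naming the offending line for a body
    line appearing before any header, an empty header, or a non-IUPAC
    character.
    """
    records: list[SequenceRecord] = []
    name: Optional[str] = None
    parts: list[str] = []

    def _flush(lineno: int) -> None:
        if name is None:
            return
        if not parts:
            raise FastaFormatError(f"line {lineno}: record {name!r} has no sequence")
        records.append(SequenceRecord(name, "".join(parts)))

    with open(path) as fh:
        lineno = 0
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                _flush(lineno)
                name = line[1:].split()[0] if len(line) > 1 and line[1:].strip() else ""
                if not name:
                    raise FastaFormatError(f"line {lineno}: empty FASTA header")
                parts = []
            else:
                if name is None:
                    raise FastaFormatError(
                        f"line {lineno}: sequence data before any '>' header"
                    )
                bad = set(line) - _VALID_CHARS
                if bad:
                    raise FastaFormatError(
                        f"line {lineno}: non-IUPAC character {sorted(bad)[0]!r}"
                    )
                parts.append(line)
        _flush(lineno + 1)
    return records


def write_fasta(records: Sequence[SequenceRecord], path, width: int = 80) -> None:
    """Write records as FASTA, wrapping sequence bodies at ``width`` columns."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.bases), width):
                fh.write(rec.bases[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# two-bit encoding


def pack_code(lmer: str) -> int:
    """Pack an ACGT string into an integer, first base in the high bits."""
    code = 0
    for c in lmer:
        code = (code << 2) | _CODE[c]
    return code


def unpack_code(code: int, l: int) -> str:
    out = []
    for j in range(l):
        out.append(_BASES[(code >> (2 * (l - 1 - j))) & 3])
    return "".join(out)


def revcomp_code(code: int, l: int) -> int:
    """Reverse complement of a packed l-mer code."""
    rc = 0
    for _ in range(l):
        rc = (rc << 2) | (3 - (code & 3))
        code >>= 2
    return rc


@dataclass(frozen=True)
class EncodedLmer:
    """An l-mer packed into ``ceil(l/t)`` integer chunks, t bases per chunk.

    Two encodings are equal iff they spell the same base string, regardless
    of chunk width.
    """

    chunks: tuple[int, ...]
    l: int
    t: int

    def decode(self) -> str:
        out = []
        for ci, chunk in enumerate(self.chunks):
            width = min(self.t, self.l - ci * self.t)
            out.append(unpack_code(chunk, width))
        return "".join(out)

    @property
    def code(self) -> int:
        """Chunk-width-independent packed integer (first base high bits)."""
        return pack_code(self.decode())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, EncodedLmer):
            return NotImplemented
        return self.l == other.l and self.code == other.code

    def __hash__(self) -> int:
        return hash((self.l, self.code))


def encode_lmer(lmer: str, t: int = DEFAULT_CHUNK_WIDTH) -> EncodedLmer:
    """Encode an ACGT string into chunks of ``t`` bases (2 bits per base)."""
    if t < 1:
        raise ValueError("chunk width t must be >= 1")
    s = lmer.upper()
    if any(c not in _CODE for c in s):
        raise ValueError(f"l-mer {lmer!r} contains a non-ACGT base")
    chunks = tuple(pack_code(s[i : i + t]) for i in range(0, len(s), t))
    return EncodedLmer(chunks=chunks, l=len(s), t=t)


def decode_lmer(enc: EncodedLmer) -> str:
    return enc.decode()


def _code_to_chunks(code: int, l: int, t: int) -> tuple[int, ...]:
    s = unpack_code(code, l)
    return tuple(pack_code(s[i : i + t]) for i in range(0, l, t))


@dataclass
class LmerList:
    """The multiset of valid l-mers of one sequence, both strands by default.

    Stored deduplicated: ``codes[i]`` is a packed l-mer and ``counts[i]`` its
    multiplicity; ``n`` is the total number of retained windows (summed over
    strands).  With no ambiguous bases and the reverse complement included,
    ``n == 2 * (len(seq) - l + 1)``.
    """

    owner: str
    l: int
    t: int
    codes: np.ndarray  # uint64, unique, sorted
    counts: np.ndarray  # int64
    n: int = 0
    include_revcomp: bool = True

    def __post_init__(self) -> None:
        if self.n == 0:
            self.n = int(self.counts.sum())

    def as_encoded_lmers(self) -> Iterator[EncodedLmer]:
        """Iterate the multiset as :class:`EncodedLmer` (with multiplicity)."""
        for code, cnt in zip(self.codes, self.counts):
            enc = EncodedLmer(_code_to_chunks(int(code), self.l, self.t), self.l, self.t)
            for _ in range(int(cnt)):
                yield enc


def _forward_codes(bases: str, l: int) -> list[int]:
    """Packed codes of all ACGT-only windows of width l (case-folded)."""
    s = bases.upper()
    n = len(s)
    codes: list[int] = []
    mask = (1 << (2 * l)) - 1
    code = 0
    run = 0  # length of current run of ACGT bases ending here
    for ch in s:
        b = _CODE.get(ch)
        if b is None:
            run = 0
            code = 0
            continue
        code = ((code << 2) | b) & mask
        run += 1
        if run >= l:
            codes.append(code)
    return codes


def extract_lmers(
    record: SequenceRecord,
    l: int,
    include_revcomp: bool = True,
    t: int = DEFAULT_CHUNK_WIDTH,
) -> LmerList:
    """Enumerate and encode the sequence's l-mers.

    Windows containing any non-ACGT base are skipped entirely.  If
    ``include_revcomp`` the reverse-complement strand's windows are appended,
    so palindromic l-mers are counted once per strand.
    """
    if l < 1:
        raise ValueError("l must be >= 1")
    if l > len(record.bases):
        raise ValueError(
            f"l={l} exceeds length {len(record.bases)} of sequence {record.id!r}"
        )
    if l > 32:
        raise ValueError("l-mers longer than 32 bases are not supported")
    fwd = _forward_codes(record.bases, l)
    all_codes = list(fwd)
    if include_revcomp:
        all_codes.extend(revcomp_code(c, l) for c in fwd)
    if all_codes:
        codes, counts = np.unique(np.array(all_codes, dtype=np.uint64), return_counts=True)
    else:
        codes = np.empty(0, dtype=np.uint64)
        counts = np.empty(0, dtype=np.int64)
    return LmerList(
        owner=record.id,
        l=l,
        t=t,
        codes=codes,
        counts=counts.astype(np.int64),
        n=len(all_codes),
        include_revcomp=include_revcomp,
    )


def ordered_forward_codes(record: SequenceRecord, l: int) -> np.ndarray:
    """Forward-strand window codes in sequence order (valid windows only).

    Used by the Naive-Bayes windowed scorer, which needs positional order
    rather than the deduplicated multiset.
    """
    if l > len(record.bases):
        raise ValueError(
            f"l={l} exceeds length {len(record.bases)} of sequence {record.id!r}"
        )
    return np.array(_forward_codes(record.bases, l), dtype=np.uint64)
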