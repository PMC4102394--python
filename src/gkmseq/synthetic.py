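"""Synthetic planted-motif benchmarks.

The generator emulates the statistical structure of ChIP-seq peak
classification experiments: positives are random background sequences of
configurable GC content with instances of one or more PWMs planted at
random non-overlapping positions and strands; negatives are background
matched in length and pooled GC to the positives.

Two presets mirror the two regimes studied with these classifiers:

* ``ctcf_like``: one long (19 bp), high-information planted motif per
  positive -- the single-dominant-site regime where long-word features and
  PWM scanning excel;
* ``ep300_like``: three distinct short (8 bp), degenerate motifs, one to
  three instances per positive -- the combinatorial enhancer regime.

Both planted PWMs are synthetic constructions of this package (defined
below from consensus strings and per-column dominance levels); they model
motif classes, not measured binding preferences.

All randomness flows from ``SyntheticConfig.seed`` through named
per-stage generators, so a config is reproducible byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np

from .seqio import SequenceRecord

__all__ = [
    "MotifSpec",
    "SyntheticConfig",
    "sample_background",
    "plant_motifs",
    "make_benchmark",
    "ctcf_like_config",
    "ep300_like_config",
    "CTCF_LIKE_PWM",
    "EP300_LIKE_PWMS",
    "write_metadata_tsv",
]

_BASES = "ACGT"
_IDX = {b: i for i, b in enumerate(_BASES)}
# transition partner used as the runner-up base in degenerate columns
_PARTNER = {"A": "G", "G": "A", "C": "T", "T": "C"}


def pwm_from_consensus(consensus: str, dominance: Sequence[float]) -> np.ndarray:
    """Column-stochastic PWM: consensus base gets ``dominance[i]``.

    The transition partner of the consensus base receives half of the
    remainder, the other two bases a quarter each.
    """
    if len(consensus) != len(dominance):
        raise ValueError("consensus and dominance lengths differ")
    pwm = np.zeros((len(consensus), 4))
    for i, (c, d) in enumerate(zip(consensus.upper(), dominance)):
        rest = 1.0 - d
        for b in _BASES:
            if b == c:
                pwm[i, _IDX[b]] = d
            elif b == _PARTNER[c]:
                pwm[i, _IDX[b]] = rest / 2
            else:
                pwm[i, _IDX[b]] = rest / 4
    return pwm


# 19 bp, high information content, column strengths shaped like real CTCF
# matrices: most columns at 0.8-0.9 dominance spread over the whole width
# (so no sub-word is near-deterministic), weaker edges (synthetic
# CTCF-like profile).
CTCF_LIKE_PWM = pwm_from_consensus(
    "TGGCCACCAGGGGGCACTA",
    [0.50, 0.70, 0.85, 0.88, 0.82, 0.88, 0.85, 0.82, 0.88, 0.85,
     0.88, 0.82, 0.85, 0.88, 0.82, 0.70, 0.70, 0.60, 0.50],
)

# three 8 bp degenerate motifs (~8 bits each, synthetic enhancer-cofactor
# profiles) -- clearly weaker than the CTCF-like site but individually usable
EP300_LIKE_PWMS = [
    pwm_from_consensus("TGACTCAA", [0.80] * 8),
    pwm_from_consensus("CAGCTGTT", [0.80] * 8),
    pwm_from_consensus("TTTGCATA", [0.80] * 8),
]


@dataclass
class MotifSpec:
    """One planted motif: PWM, instances per positive, and a name.

    ``instances`` is an int or an inclusive (lo, hi) range sampled
    uniformly per sequence.
    """

    pwm: np.ndarray
    instances: Union[int, tuple[int, int]] = 1
    name: str = "motif"


@dataclass
class SyntheticConfig:
    n_pos: int
    n_neg: int
    length: int
    gc: float
    motifs: list[MotifSpec] = field(default_factory=list)
    seed: int = 0
    name: str = "benchmark"


def _rng_for(seed: int, stage: str) -> np.random.Generator:
    # crc32 keyed per stage: stable across processes (unlike hash())
    import zlib

    ss = np.random.SeedSequence([seed, zlib.crc32(stage.encode()) % (2**31)])
    return np.random.default_rng(ss)


def sample_background(
    n: int,
    length: int,
    gc: float,
    seed: Union[int, np.random.Generator] = 0,
    id_prefix: str = "bg",
) -> list[SequenceRecord]:
    """i.i.d. background sequences with P(G) = P(C) = gc/2."""
    if not (0 < gc < 1):
        raise ValueError(f"gc must be in (0, 1), got {gc}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    base_arr = np.frombuffer(b"ACGT", dtype="S1")
    out = []
    for i in range(n):
        draws = rng.choice(4, size=length, p=p)
        out.append(
            SequenceRecord(f"{id_prefix}_{i}", base_arr[draws].tobytes().decode())
        )
    return out


def _sample_instance(pwm: np.ndarray, rng: np.random.Generator) -> str:
    cols = [rng.choice(4, p=row / row.sum()) for row in pwm]
    return "".join(_BASES[c] for c in cols)


def _revcomp(s: str) -> str:
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    return "".join(comp[c] for c in reversed(s))


def plant_motifs(
    background: Sequence[SequenceRecord],
    motifs: Sequence[MotifSpec],
    seed: Union[int, np.random.Generator] = 0,
) -> tuple[list[SequenceRecord], list[dict]]:
    """Insert PWM instances at uniform non-overlapping positions.

    Each instance is drawn column-wise from its PWM, placed on a uniformly
    chosen strand, and overwrites the background.  Returns the modified
    records and a metadata row (id, offset, strand, motif) per instance.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out: list[SequenceRecord] = []
    meta: list[dict] = []
    for rec in background:
        seq = list(rec.bases)
        occupied: list[tuple[int, int]] = []
        for spec in motifs:
            w = spec.pwm.shape[0]
            if w > len(seq):
                raise ValueError(
                    f"motif {spec.name!r} (width {w}) does not fit length {len(seq)}"
                )
            if isinstance(spec.instances, tuple):
                n_inst = int(rng.integers(spec.instances[0], spec.instances[1] + 1))
            else:
                n_inst = int(spec.instances)
            for _ in range(n_inst):
                placed = False
                for _attempt in range(1000):
                    off = int(rng.integers(0, len(seq) - w + 1))
                    if all(off + w <= a or off >= b for a, b in occupied):
                        placed = True
                        break
                if not placed:
                    raise ValueError(
                        f"cannot place motif {spec.name!r} without overlap in "
                        f"sequence {rec.id!r}"
                    )
                inst = _sample_instance(spec.pwm, rng)
                strand = "+" if rng.random() < 0.5 else "-"
                if strand == "-":
                    inst = _revcomp(inst)
                seq[off : off + w] = list(inst)
                occupied.append((off, off + w))
                meta.append(
                    {"id": rec.id, "offset": off, "strand": strand, "motif": spec.name}
                )
        out.append(SequenceRecord(rec.id, "".join(seq), label=+1))
    return out, meta


def _pooled_gc(records: Sequence[SequenceRecord]) -> float:
    gc = total = 0
    for r in records:
        s = r.bases.upper()
        gc += s.count("G") + s.count("C")
        total += len(s)
    return gc / total


def make_benchmark(
    config: SyntheticConfig,
) -> tuple[list[SequenceRecord], list[SequenceRecord], list[dict]]:
    """Positives with planted motifs plus length/GC-matched negatives."""
    bg = sample_background(
        config.n_pos,
        config.length,
        config.gc,
        _rng_for(config.seed, "background"),
        id_prefix="pos",
    )
    pos, meta = plant_motifs(bg, config.motifs, _rng_for(config.seed, "plant"))
    neg = sample_background(
        config.n_neg,
        config.length,
        _pooled_gc(pos),
        _rng_for(config.seed, "negatives"),
        id_prefix="neg",
    )
    neg = [SequenceRecord(r.id, r.bases, label=-1) for r in neg]
    return pos, neg, meta


def ctcf_like_config(
    seed: int = 0,
    n_pos: int = 500,
    n_neg: int = 500,
    length: int = 300,
    gc: float = 0.42,
) -> SyntheticConfig:
    """One high-information 19 bp site per positive (single-site regime)."""
    return SyntheticConfig(
        n_pos=n_pos,
        n_neg=n_neg,
        length=length,
        gc=gc,
        motifs=[MotifSpec(CTCF_LIKE_PWM, 1, "ctcf_like")],
        seed=seed,
        name="ctcf_like",
    )


def ep300_like_config(
    seed: int = 0,
    n_pos: int = 500,
    n_neg: int = 500,
    length: int = 300,
    gc: float = 0.42,
) -> SyntheticConfig:
    """Three degenerate 8 bp motifs, 1-3 instances each (enhancer regime)."""
    return SyntheticConfig(
        n_pos=n_pos,
        n_neg=n_neg,
        length=length,
        gc=gc,
        motifs=[
            MotifSpec(pwm, (1, 3), f"ep300_like_{i}")
            for i, pwm in enumerate(EP300_LIKE_PWMS)
        ],
        seed=seed,
        name="ep300_like",
    )


def write_metadata_tsv(meta: Sequence[dict], path) -> None:
    with open(path, "w") as fh:
        fh.write("#id\toffset\tstrand\tmotif\n")
        for row in meta:
            fh.write(f"{row['id']}\t{row['offset']}\t{row['strand']}\t{row['motif']}\n")
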