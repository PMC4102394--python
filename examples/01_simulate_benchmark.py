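"""Generate a planted-motif benchmark and inspect what was planted.

Positives are random-background sequences with one high-information
CTCF-like site each; negatives match the positives' length and pooled GC.
"""

from gkmseq import ctcf_like_config, make_benchmark

config = ctcf_like_config(seed=0, n_pos=50, n_neg=50, length=300)
pos, neg, meta = make_benchmark(config)


def pooled_gc(records):
    s = "".join(r.bases for r in records)
    return (s.count("G") + s.count("C")) / len(s)


print(f"positives: {len(pos)} x {len(pos[0].bases)} bp, GC {pooled_gc(pos):.3f}")
print(f"negatives: {len(neg)} x {len(neg[0].bases)} bp, GC {pooled_gc(neg):.3f}")
print("first three planted instances (sequence, offset, strand):")
for row in meta[:3]:
    print(f"  {row['id']}\t{row['offset']}\t{row['strand']}")
site = meta[0]
seq = next(r for r in pos if r.id == site["id"])
print("planted region of", site["id"], "->", seq.bases[site["offset"] : site["offset"] + 19])
# The GC difference between classes is ~0.00x: classifiers cannot cheat on
# base composition and must learn the planted site itself.
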