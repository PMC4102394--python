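"""De novo PWM extraction from a trained gapped k-mer SVM.

Trains on the planted-motif benchmark, ranks all 4^10 10-mers by SVM
decision score, condenses the top 1% into up to three PWMs by iterated
greedy alignment, and compares the first PWM with the planted one.
"""

import numpy as np

from gkmseq import ctcf_like_config, make_benchmark
from gkmseq.kernels import gkm_kernel_matrix
from gkmseq.models import score_all_kmers, train_svm
from gkmseq.motifs import build_pwms, pwm_alignment_correlation, write_meme
from gkmseq.seqio import extract_lmers
from gkmseq.synthetic import CTCF_LIKE_PWM
from gkmseq.weights import gkm_coefficients

pos, neg, _ = make_benchmark(ctcf_like_config(seed=0, n_pos=200, n_neg=200))
recs = pos + neg
labels = [1] * len(pos) + [-1] * len(neg)
lls = [extract_lmers(r, 10) for r in recs]

model = train_svm(gkm_kernel_matrix(lls, 10, 6), labels, lls, gkm_coefficients(10, 6))
table = score_all_kmers(model, w=10)
kmers, weights = table.top(0.01)
print(f"top-ranked 10-mers (of {len(table.codes)}):")
for km, w in zip(kmers[:5], weights[:5]):
    print(f"  {km}  SVM score {w:+.3f}")

pwms = build_pwms(kmers, weights)
print(f"\nbuilt {len(pwms)} PWM(s):")
for p in pwms:
    print(f"  {p.name}: consensus {p.consensus}, from {len(p.provenance)} 10-mers")

planted = "".join("ACGT"[i] for i in CTCF_LIKE_PWM.argmax(axis=1))
r = pwm_alignment_correlation(pwms[0].probs, CTCF_LIKE_PWM)
print(f"\nplanted consensus: {planted}")
print(f"best-alignment mean per-column Pearson r (pwm1 vs planted): {r:.3f}")
write_meme(pwms, "motifs.meme", gc=0.42)
print("wrote motifs.meme (MEME minimal format)")
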