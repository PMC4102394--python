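# Methods

## Feature model

A sequence is represented by the counts of its gapped k-mers: all words of
length *l* with *k* informative positions (a position subset of size k plus
k letters) derived from the sequence's l-mers on both strands. Ambiguous
bases void the whole window; lowercase (repeat-masked) bases are case-folded
and used. Appending the reverse-complement strand's l-mers makes every
downstream quantity exactly strand symmetric; a palindromic l-mer is counted
once per strand. Whether the original convention counted palindromes once or
twice is not decidable from the framework's description; the double count is
the convention here and is applied consistently on both sides of every inner
product, so normalized kernels are unaffected for typical inputs.

## Kernels from mismatch profiles

The kernel is the cosine similarity of gapped k-mer count vectors. It is
computed without feature-space materialization through the mismatch profile
N_m (counts of cross-sequence l-mer pairs at Hamming distance m, a
sufficient statistic), contracted with a distance-indexed coefficient
vector. The coefficient families and their exactly-verified identities:

* gapped k-mer: h_m = C(l−m, k); h reduces to the spectrum kernel at l = k.
* wildcard: Σ_{j=m..M} λʲ C(l−m, j−m). The λ exponent convention (λ per
  wildcard, applied once in the kernel sum, not once per feature vector)
  follows the original wildcard-kernel formulation; at the benchmark setting
  λ = 1 the choice is immaterial.
* mismatch: the Hamming-ball intersection size, evaluated by the
  self-truncating triple sum over (m₁, m₂, t) with multiplicity
  C(l−m,t)(b−1)ᵗ · C(m, m₁−t) · C(m₁−t, r)(b−2)ʳ, r = m₁+m₂−2t−m.
* estimate kernel: c_m = Σ_{m₁,m₂,t} g(m₁) g(m₂) × (same multiplicity).
  For the full filter, c_m = g_m exactly (projection identity); for the
  truncated filter the sum is evaluated as written.

All integer quantities use exact integer arithmetic; binomials with
out-of-range arguments are 0, making every sum self-truncating.

## The gkm-filter

The minimum-norm l-mer count estimate is ĉ = pinv(A)·A·c, where A is the
binary incidence matrix from l-mers to gapped k-mers and c the observed
count vector. In the character (Fourier) basis of the Hamming scheme, A's
Gram matrix has eigenvalue b^{l−k} C(l−j, k−j) on the degree-j component, so
pinv(A)·A is the projection onto degrees ≤ k and its entries depend only on
the Hamming distance m:

    g_lk(m) = b^{-l} Σ_{j=0..k} K_j(m; l, b),

with K_j the Krawtchouk polynomial Σ_i (−1)ⁱ (b−1)^{j−i} C(m,i) C(l−m,j−i).
This closed form is evaluated in exact rational arithmetic and converted to
float at the end; the test suite pins it to the numerical pinv(A)·A oracle
for small (l,k) and to the equivalent binomial form g(m) = Σ_t C(m,t)
C(l−m,k−t) w(t), whose pseudo-inverse weights w(t) are recovered by a
triangular solve. The *truncated* filter zeroes g from its first negative
entry m₀ on, guaranteeing non-negative estimates at the cost of the
minimum-norm property — required wherever logs or ratios of estimates are
taken. Representative m₀ values at k=6: m₀=4 (l=12), 6 (l=16), 8 (l=20).

## Computing mismatch profiles

* **Direct**: each sequence is a deduplicated list of two-bit-packed l-mers
  with multiplicities; pairs are compared by XOR plus a 4^t-entry lookup
  table (default chunk width t = 6, configurable since the optimum is
  hardware-dependent). Distinct l-mers are compared once and weighted by
  their count product.
* **Tree**: all l-mers are inserted in a prefix tree; one depth-first
  traversal carries, per node, the list of same-depth nodes within m_max
  mismatches and their running distances. At a leaf, occurrence lists are
  combined into N_m for every sequence pair; the (minID, maxID) interval
  test prunes subtree pairs that can only produce upper-triangle entries.
  Self pairs run through the same code path (the kernel diagonal is needed
  for normalization). Setting m_max < l−k trades exactness for speed;
  m_max ≥ l−k is exact because h_m = 0 beyond the coefficient support.
* **Subset decomposition** (gkm variant only): K_raw = Σ over the C(l,k)
  position subsets of the co-occurrence matrix of masked k-mers, accumulated
  as dense float32 BLAS syrk/gemm updates when 4^k ≤ 2¹⁸ (exact: every
  intermediate is an integer < 2²⁴) and as sparse products otherwise. This
  is the production path for training-scale data; tests assert exact
  agreement of all three routes.

## Classifiers

* **SVM**: standard soft-margin dual on the precomputed normalized kernel
  (scikit-learn's SMO), C = 1.0 by default (exposed), solver tolerance
  1e−6, bias included. Truncated kernels are not guaranteed PSD; if the
  solver rejects a matrix, the smallest ridge 1e−8·I is added and logged.
  Scoring is the support-vector expansion via a test × SV cross kernel; for
  the gkm variant, ranking all 4^w w-mers (w = 10 default, guard w ≤ 12)
  uses per-subset support-vector weight tables instead of explicit cross
  kernels, which is algebraically identical.
* **Naive Bayes**: score = Σ log(N_P/N_N) over a sequence's forward-strand
  l-mers (tables hold both strands, which restores strand symmetry of the
  total). Filter mode uses truncated-filter estimates with pseudo-count
  = half the smallest positive filter coefficient; raw mode uses exact
  counts with pseudo-count 0.5. At l = k both modes coincide (the identity
  filter's pseudo-count is also 0.5). The optional window mode takes the
  maximum over runs of `window` consecutive l-mers (substrings of length
  window + l − 1); window = 15 suits single-site data, full-sequence
  scoring suits multi-site data. Counts rather than frequencies enter the
  ratio; the two differ by a constant per model that leaves AUC unchanged.
  Filter-mode lookups are lazy: a pigeonhole block index (B = ⌈(m₀+1)/2⌉
  blocks, per-block probe radius 1, first-matching-block attribution)
  enumerates exactly the training l-mers within the filter support of each
  query, verified against the brute pairwise scan.

## De novo PWMs

The top 1% of SVM-ranked 10-mers seed up to three PWMs. Each PWM starts
from the single highest-weight unused 10-mer; every remaining top 10-mer is
aligned to it over all offsets with at least half overlap and both strands,
accepted when the overlap log-odds (background: gc/2 per G/C, default
GC = 0.42) reaches 5.0, and the PWM is rebuilt each pass from all accepted
10-mers with mass exp(α·weight), α = 3.0, until the assignment set is
stable (cap 50 passes; batch update per pass — the original wording admits
batch or online, batch is deterministic). Pseudo-count: 1% of each column's
own mass, spread uniformly (uniform column if empty). Width stays at the
seed's length; overhanging bases are ignored. PWMs with fewer than 5
contributing 10-mers are dropped. PWM classification scores a sequence by
its best summed log-odds over all offsets and strands.

## Evaluation

AUC uses the midrank (ties = ½) convention; precision–recall keeps the
best-precision point per recall level. Cross-validation splits positives
and negatives independently into seeded folds; per-fold AUC is computed on
pooled held-out scores and summarized as mean, SD and SE (both reported,
since both conventions appear in practice). For SVM pipelines the full
normalized kernel is computed once and sliced per fold — kernel entries are
pairwise, label-free statistics, so this is exact and leak-free.

## Synthetic benchmark

The generator emulates ChIP-seq peak classification: i.i.d. background of
configurable GC (order-1 Markov background deliberately omitted — the
genomic null used with real data requires genome sampling, which is out of
scope), PWM instances planted at uniform non-overlapping positions and
uniform strands, and negatives matched to the positives' lengths and pooled
GC so composition alone cannot separate the classes. Presets:

* `ctcf_like`: 500+/500−, 300 bp, one 19 bp planted site. The planted PWM
  is a synthetic construction whose column-strength distribution copies
  real CTCF matrices (most columns 0.82–0.88 dominant, weak edges,
  ≈ 18 bits total; no sub-word is near-deterministic). Chosen so the preset
  reproduces the single-dominant-site regime: a PWM scan is a near-perfect
  oracle, and exact long k-mers go sparse while gapped k-mers do not.
* `ep300_like`: three distinct 8 bp degenerate motifs (0.80 dominance,
  ≈ 8 bits each), 1–3 instances per positive — the combinatorial enhancer
  regime.

What passing on this generator does *not* show: robustness to genomic
nulls (repeats, CpG islands, higher-order composition), to soft-masked
training data, or to peak-centering artifacts of real ChIP-seq sets; the
i.i.d. background makes class separation cleaner than in genomic data.

## Problem sizes and determinism

Test and acceptance runs use the preset sizes (1000 sequences of 300 bp)
with l up to 16; stochastic claims are asserted on means over three
generator seeds. All randomness flows from explicit integer seeds through
named per-stage generators (stable CRC-derived stream keys), so every
output, including FASTA files, is byte-reproducible.

## Known limitations

* l ≤ 32 (single 64-bit packing); the feature-space oracles are guarded to
  l ≤ 8 and the incidence matrix to l ≤ 6 by design.
* The dense subset path assumes 4^k ≤ 2¹⁸; beyond that the sparse or
  profile routes apply.
* Wildcard/mismatch kernels run through the profile routes only (no subset
  decomposition) — adequate at the scales where those baselines are used.
* N-containing windows are dropped rather than marginalized; heavily
  masked or gappy sequences lose features accordingly, and a sequence with
  no valid window is reported as an error by name.
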