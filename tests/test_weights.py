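"""Coefficient families against exhaustive enumeration oracles."""

from itertools import combinations, product
from math import comb

import numpy as np
import pytest

from gkmseq.weights import (
    GkmFilter,
    estimate_kernel_coefficients,
    filter_weights,
    gkm_coefficients,
    incidence_matrix,
    mismatch_coefficients,
    pseudo_inverse_weights,
    truncate_filter,
    wildcard_coefficients,
)

B = 4


def pair_at_distance(l: int, m: int) -> tuple[tuple, tuple]:
    """A canonical l-mer pair at Hamming distance m (alphabet 0..3)."""
    x1 = tuple([0] * l)
    x2 = tuple([1] * m + [0] * (l - m))
    return x1, x2


def hamming(a, b) -> int:
    return sum(x != y for x, y in zip(a, b))


# ---------------------------------------------------------------------------
# enumeration oracles


def oracle_gkm(l, k, m):
    """Count position subsets of size k avoiding all m mismatch positions."""
    x1, x2 = pair_at_distance(l, m)
    total = 0
    for pos in combinations(range(l), k):
        if all(x1[p] == x2[p] for p in pos):
            total += 1
    return total


def oracle_wildcard(l, M, m, lam=1.0):
    """Enumerate wildcard patterns (letters + '*') matching both l-mers."""
    x1, x2 = pair_at_distance(l, m)
    total = 0.0
    for pattern in product(range(B + 1), repeat=l):  # B encodes '*'
        j = sum(1 for c in pattern if c == B)
        if j > M:
            continue
        if all(c == B or c == a for c, a in zip(pattern, x1)) and all(
            c == B or c == a for c, a in zip(pattern, x2)
        ):
            total += lam**j
    return total


def oracle_mismatch(l, M, m):
    """Size of the intersection of the two radius-M Hamming balls."""
    x1, x2 = pair_at_distance(l, m)
    return sum(
        1
        for u in product(range(B), repeat=l)
        if hamming(u, x1) <= M and hamming(u, x2) <= M
    )


def oracle_estimate(l, k, g, m):
    """Brute-force sum_u g(d(u,x1)) g(d(u,x2)) over the full l-mer space."""
    x1, x2 = pair_at_distance(l, m)
    return sum(
        g[hamming(u, x1)] * g[hamming(u, x2)] for u in product(range(B), repeat=l)
    )


# ---------------------------------------------------------------------------


class TestGkmCoefficients:
    def test_small_example(self):
        # confirmed by the subset-enumeration oracle below
        assert [oracle_gkm(3, 2, m) for m in range(4)] == [3, 1, 0, 0]
        assert gkm_coefficients(3, 2).coef.tolist() == [3, 1, 0, 0]

    def test_zero_when_too_few_matches(self):
        assert gkm_coefficients(10, 6).coef[5] == 0

    def test_spectrum_special_case(self):
        coef = gkm_coefficients(4, 4).coef
        assert coef.tolist() == [1, 0, 0, 0, 0]

    @pytest.mark.parametrize("l", [2, 3, 4])
    def test_matches_enumeration(self, l):
        for k in range(1, l + 1):
            coef = gkm_coefficients(l, k).coef
            for m in range(l + 1):
                assert coef[m] == oracle_gkm(l, k, m)

    def test_monotone_in_m(self):
        coef = gkm_coefficients(8, 4).coef
        assert all(coef[m] >= coef[m + 1] for m in range(8))

    def test_invalid_k(self):
        with pytest.raises(ValueError):
            gkm_coefficients(3, 4)


class TestWildcardCoefficients:
    def test_small_example(self):
        assert [oracle_wildcard(3, 1, m) for m in range(4)] == [4, 1, 0, 0]
        assert wildcard_coefficients(3, 1).coef.tolist() == [4, 1, 0, 0]

    def test_no_wildcards_is_exact_match(self):
        assert wildcard_coefficients(5, 0).coef.tolist() == [1, 0, 0, 0, 0, 0]

    def test_one_mismatch_two_wildcards(self):
        assert wildcard_coefficients(4, 2).coef[1] == oracle_wildcard(4, 2, 1) == 4

    @pytest.mark.parametrize("l,M", [(2, 1), (3, 2), (4, 2)])
    def test_matches_enumeration(self, l, M):
        for lam in (1.0, 0.5):
            coef = wildcard_coefficients(l, M, lam).coef
            for m in range(l + 1):
                assert coef[m] == pytest.approx(oracle_wildcard(l, M, m, lam))


class TestMismatchCoefficients:
    def test_ball_examples(self):
        # enumeration first, then the closed form
        assert [oracle_mismatch(2, 1, m) for m in range(3)] == [7, 4, 2]
        assert mismatch_coefficients(2, 1).coef.tolist() == [7, 4, 2]

    @pytest.mark.parametrize("l,M", [(2, 1), (3, 1), (3, 2), (4, 2)])
    def test_matches_enumeration(self, l, M):
        coef = mismatch_coefficients(l, M).coef
        for m in range(l + 1):
            assert coef[m] == oracle_mismatch(l, M, m)


class TestIncidenceMatrix:
    def test_shape_and_margins(self):
        A = incidence_matrix(2, 1)
        assert A.shape == (8, 16)
        assert (A.sum(axis=1) == 4).all()  # b^(l-k)
        assert (A.sum(axis=0) == 2).all()  # choose(l,k)

    def test_l_equals_k_is_permutation_identity(self):
        A = incidence_matrix(2, 2)
        assert A.shape == (16, 16)
        assert (A.sum(axis=0) == 1).all() and (A.sum(axis=1) == 1).all()

    def test_counts_map(self):
        # "AAAA" l-mer counts at l=2: AA occurs 3 times
        counts = np.zeros(16)
        counts[0] = 3
        A = incidence_matrix(2, 1)
        y = A @ counts
        # gapped 1-mers "A." and ".A" each occur 3 times
        assert sorted(y[y > 0].tolist()) == [3.0, 3.0]

    def test_size_guard(self):
        with pytest.raises(ValueError):
            incidence_matrix(7, 3)


def distance_profile_of(G: np.ndarray, l: int) -> np.ndarray:
    """Average of G over entries at each Hamming distance (they must agree)."""
    codes = list(product(range(B), repeat=l))
    sums = np.zeros(l + 1)
    counts = np.zeros(l + 1)
    for i, u in enumerate(codes):
        for j, v in enumerate(codes):
            m = hamming(u, v)
            sums[m] += G[i, j]
            counts[m] += 1
    return sums / counts


class TestGkmFilter:
    def test_identity_at_l_equals_k(self):
        f = filter_weights(3, 3)
        assert f.g[0] == pytest.approx(1.0)
        assert np.allclose(f.g[1:], 0.0)

    @pytest.mark.parametrize("l,k", [(2, 1), (3, 2), (4, 2)])
    def test_matches_pseudo_inverse_oracle(self, l, k):
        A = incidence_matrix(l, k).astype(float)
        G = np.linalg.pinv(A, rcond=1e-10) @ A
        f = filter_weights(l, k)
        prof = distance_profile_of(G, l)
        assert np.abs(f.g - prof).max() < 1e-8
        # projection identities
        assert np.abs(G @ G - G).max() < 1e-8
        assert np.abs(A @ G - A).max() < 1e-8
        # entries at equal distance coincide
        codes = list(product(range(B), repeat=l))
        for i in range(0, len(codes), 7):
            for j in range(0, len(codes), 5):
                m = hamming(codes[i], codes[j])
                assert G[i, j] == pytest.approx(prof[m], abs=1e-9)

    def test_eq10_reconstruction_from_pinv_weights(self):
        # g(m) = sum_t C(m,t) C(l-m,k-t) w(t) must hold for every m
        for l, k in [(4, 2), (10, 6), (16, 6)]:
            w = pseudo_inverse_weights(l, k)
            g = filter_weights(l, k).g
            rec = [
                sum(comb(m, t) * comb(l - m, k - t) * w[t] for t in range(k + 1))
                for m in range(l + 1)
            ]
            assert np.abs(np.array(rec) - g).max() < 1e-12

    def test_goes_negative_for_long_words(self):
        g = filter_weights(20, 6).g
        assert (g < 0).any()


class TestTruncateFilter:
    def test_nothing_to_truncate(self):
        f = GkmFilter(l=3, k=3, g=np.array([1.0, 0, 0, 0]))
        t = truncate_filter(f)
        assert t.m0 == 4  # l+1 sentinel
        assert np.array_equal(t.g, f.g)

    def test_zeroes_at_and_beyond_first_negative(self):
        f = GkmFilter(l=3, k=2, g=np.array([1.0, 0.5, -0.1, 0.02]))
        t = truncate_filter(f)
        assert t.m0 == 2
        assert t.g.tolist() == [1.0, 0.5, 0.0, 0.0]
        assert (t.g >= 0).all()

    def test_idempotent(self):
        f = truncate_filter(filter_weights(4, 2))
        assert np.array_equal(truncate_filter(f).g, f.g)


class TestEstimateKernelCoefficients:
    @pytest.mark.parametrize("l,k", [(2, 1), (3, 2), (4, 2), (5, 3), (5, 2)])
    def test_full_filter_reproduces_itself(self, l, k):
        f = filter_weights(l, k)
        c = estimate_kernel_coefficients(l, k, f)
        assert np.abs(c.coef - f.g).max() < 1e-9

    def test_truncated_filter_matches_brute_force(self):
        for l, k in [(3, 2), (4, 2)]:
            t = truncate_filter(filter_weights(l, k))
            c = estimate_kernel_coefficients(l, k, t)
            for m in range(l + 1):
                assert c.coef[m] == pytest.approx(
                    oracle_estimate(l, k, t.g, m), abs=1e-9
                )

    def test_delta_filter_is_its_own_gram(self):
        f = GkmFilter(l=3, k=2, g=np.array([1.0, 0, 0, 0]))
        c = estimate_kernel_coefficients(3, 2, f)
        assert np.allclose(c.coef, [1, 0, 0, 0])

    def test_filter_parameter_mismatch(self):
        with pytest.raises(ValueError):
            estimate_kernel_coefficients(4, 2, filter_weights(3, 2))
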