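import numpy as np
import pytest

from conftest import random_records
from gkmseq._fast import nb_filtered_brute, nb_filtered_counts
from gkmseq.kernels import gkm_kernel_matrix
from gkmseq.models import (
    decision_scores,
    load_svm,
    nb_score,
    nb_score_many,
    nb_train,
    save_svm,
    score_all_kmers,
    train_svm,
)
from gkmseq.seqio import (
    SequenceRecord,
    extract_lmers,
    reverse_complement,
    unpack_code,
)
from gkmseq.weights import filter_weights, gkm_coefficients, truncate_filter


def _fit(recs, labels, l, k, C=1.0):
    lls = [extract_lmers(r, l) for r in recs]
    K = gkm_kernel_matrix(lls, l, k)
    return train_svm(K, labels, lls, gkm_coefficients(l, k), C=C), lls, K


class TestTrainSVM:
    def test_separable_toy_perfect_training_accuracy(self):
        recs = [
            SequenceRecord("p1", "AAAAAAAA"),
            SequenceRecord("p2", "AAAAAAAT"),
            SequenceRecord("n1", "CCCCCCCC"),
            SequenceRecord("n2", "CCCCCCCG"),
        ]
        model, lls, _ = _fit(recs, [1, 1, -1, -1], 4, 2)
        preds = np.sign(decision_scores(model, lls))
        assert preds.tolist() == [1, 1, -1, -1]

    def test_label_flip_negates_scores(self, small_benchmark):
        pos, neg, _ = small_benchmark
        recs = (pos + neg)[:30]
        labels = [1] * 15 + [-1] * 15
        m1, lls, K = _fit(recs, labels, 5, 3)
        m2 = train_svm(K, [-y for y in labels], lls, gkm_coefficients(5, 3))
        s1 = decision_scores(m1, lls)
        s2 = decision_scores(m2, lls)
        assert np.abs(s1 + s2).max() < 1e-6

    def test_one_class_rejected(self):
        recs = random_records(1, 4, 20)
        lls = [extract_lmers(r, 4) for r in recs]
        K = gkm_kernel_matrix(lls, 4, 2)
        with pytest.raises(ValueError):
            train_svm(K, [1, 1, 1, 1], lls, gkm_coefficients(4, 2))

    def test_duplication_invariance(self, small_benchmark):
        # with no dual coefficient at the box bound, duplicating every
        # training sequence leaves held-out decisions unchanged
        pos, neg, _ = small_benchmark
        train = pos[:10] + neg[:10]
        held = pos[10:14] + neg[10:14]
        labels = [1] * 10 + [-1] * 10
        C = 50.0
        m1, _, _ = _fit(train, labels, 6, 3, C=C)
        assert np.abs(m1.sv_alpha).max() < C * 0.999, "premise: no bound-active alpha"
        m2, _, _ = _fit(train + train, labels + labels, 6, 3, C=C)
        held_lls = [extract_lmers(r, 6) for r in held]
        assert np.abs(
            decision_scores(m1, held_lls) - decision_scores(m2, held_lls)
        ).max() < 1e-4


class TestDecisionScores:
    def test_reproduces_training_decision(self, small_gkm_model):
        model, lls, _ = small_gkm_model
        sc = decision_scores(model, lls)
        assert np.abs(sc - model.train_decision).max() < 1e-10

    def test_strand_symmetric(self, small_gkm_model, small_benchmark):
        model, _, _ = small_gkm_model
        pos, _, _ = small_benchmark
        fwd = [extract_lmers(r, 6) for r in pos[:8]]
        rev = [extract_lmers(r.reverse_complement(), 6) for r in pos[:8]]
        assert np.abs(
            decision_scores(model, fwd) - decision_scores(model, rev)
        ).max() < 1e-10

    def test_order_invariant(self, small_gkm_model):
        model, lls, _ = small_gkm_model
        sc = decision_scores(model, lls[:6])
        perm = [5, 3, 1, 0, 4, 2]
        sc_perm = decision_scores(model, [lls[i] for i in perm])
        assert np.allclose(sc_perm, sc[perm])

    def test_profiles_route_agrees(self, small_gkm_model):
        model, lls, _ = small_gkm_model
        a = decision_scores(model, lls[:5], method="subsets")
        b = decision_scores(model, lls[:5], method="profiles")
        assert np.abs(a - b).max() < 1e-10


class TestScoreAllKmers:
    def test_fast_path_matches_generic_scoring(self, small_gkm_model):
        model, _, _ = small_gkm_model
        table = score_all_kmers(model, w=6)
        by_code = dict(zip(table.codes.tolist(), table.weights.tolist()))
        lls = [
            extract_lmers(SequenceRecord(f"w{c}", unpack_code(c, 6)), 6)
            for c in range(0, 4096, 37)
        ]
        generic = decision_scores(model, lls)
        for i, c in enumerate(range(0, 4096, 37)):
            assert by_code[c] == pytest.approx(generic[i], abs=1e-9)

    def test_reverse_complement_pairs_score_equally(self, small_gkm_model):
        from gkmseq.seqio import revcomp_code

        model, _, _ = small_gkm_model
        table = score_all_kmers(model, w=6)
        by_code = dict(zip(table.codes.tolist(), table.weights.tolist()))
        rng = np.random.default_rng(0)
        for c in rng.integers(0, 4096, 50):
            assert by_code[int(c)] == pytest.approx(
                by_code[revcomp_code(int(c), 6)], abs=1e-10
            )

    def test_sorted_descending_and_top(self, small_gkm_model):
        model, _, _ = small_gkm_model
        table = score_all_kmers(model, w=6)
        assert (np.diff(table.weights) <= 1e-12).all()
        kmers, wts = table.top(0.01)
        assert len(kmers) == 41  # 1% of 4096, rounded
        assert all(len(k) == 6 for k in kmers)

    def test_w_shorter_than_l_rejected(self, small_gkm_model):
        model, _, _ = small_gkm_model
        with pytest.raises(ValueError):
            score_all_kmers(model, w=4)


class TestNaiveBayes:
    def test_identical_sets_score_zero(self):
        recs = random_records(5, 6, 30)
        model = nb_train(recs, recs, 5, 3)
        for r in recs[:3]:
            assert nb_score(model, r) == pytest.approx(0.0, abs=1e-9)

    def test_single_lmer_sequence(self):
        pos = [SequenceRecord("p", "ACGTA")]
        neg = [SequenceRecord("n", "TTTTT")]
        model = nb_train(pos, neg, 5, 3)
        from gkmseq.seqio import pack_code

        np_, nn_ = model.lookup(np.array([pack_code("ACGTA")], dtype=np.uint64))
        expected = np.log(np_[0] + model.pseudo_count) - np.log(
            nn_[0] + model.pseudo_count
        )
        assert nb_score(model, SequenceRecord("q", "ACGTA")) == pytest.approx(
            float(expected)
        )

    def test_l_equals_k_filter_reduces_to_raw_mode(self):
        pos, neg = random_records(9, 4, 25), random_records(10, 4, 25)
        mf = nb_train(pos, neg, 4, 4, use_filter=True)
        mr = nb_train(pos, neg, 4, 4, use_filter=False)
        assert mf.pseudo_count == pytest.approx(0.5)
        s1 = nb_score_many(mf, pos + neg)
        s2 = nb_score_many(mr, pos + neg)
        assert np.abs(s1 - s2).max() < 1e-9

    def test_smoothing_rationale_unseen_neighbour(self):
        # positives share one frequent 8-mer; a 1-mismatch neighbour unseen
        # in training scores positive under the filter but ~0 with raw counts
        core = "ACGTACGT"
        pos = [SequenceRecord(f"p{i}", core * 3) for i in range(3)]
        neg = [SequenceRecord(f"n{i}", "TTTTAAAATTTTAAAATTTTAAAA") for i in range(3)]
        query = SequenceRecord("q", "ACGTACGA")  # one substitution
        filt = nb_train(pos, neg, 8, 4)
        raw = nb_train(pos, neg, 8, 4, use_filter=False)
        assert nb_score(filt, query) > 0.5
        assert abs(nb_score(raw, query)) < 1e-9

    def test_windowed_score_dominates_substrings(self):
        pos, neg = random_records(21, 5, 60), random_records(22, 5, 60)
        model = nb_train(pos, neg, 6, 3)
        rng = np.random.default_rng(0)
        for r in random_records(23, 4, 60):
            full = nb_score(model, r, window=10)
            start = int(rng.integers(0, 60 - 15 - 6 + 1))
            sub = SequenceRecord("sub", r.bases[start : start + 15])
            assert full >= nb_score(model, sub, window=10) - 1e-9

    def test_monotone_in_positive_copies(self):
        pos, neg = random_records(31, 4, 40), random_records(32, 4, 40)
        target = pos[0]
        m1 = nb_train(pos, neg, 6, 3)
        m2 = nb_train(pos + [target] * 3, neg, 6, 3)
        assert nb_score(m2, target) >= nb_score(m1, target) - 1e-9

    def test_windowed_requires_enough_lmers(self):
        model = nb_train(random_records(1, 2, 20), random_records(2, 2, 20), 6, 3)
        with pytest.raises(ValueError):
            nb_score(model, SequenceRecord("s", "ACGTACGTAC"), window=10)

    def test_indexed_neighbour_search_equals_brute(self):
        rng = np.random.default_rng(42)
        q = np.unique(rng.integers(0, 4**12, 400).astype(np.uint64))
        t = np.unique(rng.integers(0, 4**12, 800).astype(np.uint64))
        cnt = rng.integers(1, 4, len(t)).astype(np.float64)
        f = truncate_filter(filter_weights(12, 6))
        brute = nb_filtered_brute(q, t, cnt, f.g, f.support)
        # force the block index regardless of problem size
        import gkmseq._fast as fast

        lens = np.full(2, 6, dtype=np.int64)
        shifts = np.array([12, 0], dtype=np.uint64)
        starts = np.zeros((2, 4**6 + 1), dtype=np.int64)
        order = np.zeros((2, len(t)), dtype=np.int64)
        for b in range(2):
            mask = np.uint64((1 << 12) - 1)
            keys = ((t >> shifts[b]) & mask).astype(np.int64)
            order[b] = np.argsort(keys, kind="stable")
            starts[b, 1:] = np.cumsum(np.bincount(keys, minlength=4**6))
        indexed = fast.nb_filtered_indexed(
            q, t, cnt, starts, order, shifts, lens, f.g, f.support
        )
        assert np.abs(indexed - brute).max() < 1e-12

    def test_strand_symmetry(self):
        pos, neg = random_records(51, 5, 40), random_records(52, 5, 40)
        model = nb_train(pos, neg, 8, 4)
        probes = random_records(53, 5, 40)
        fwd = nb_score_many(model, probes)
        rev = nb_score_many(model, [p.reverse_complement() for p in probes])
        assert np.abs(fwd - rev).max() < 1e-9


def test_svm_save_load_round_trip(small_gkm_model, tmp_path):
    model, lls, _ = small_gkm_model
    path = tmp_path / "model.npz"
    save_svm(model, path)
    back = load_svm(path)
    a = decision_scores(model, lls[:10])
    b = decision_scores(back, lls[:10])
    assert np.abs(a - b).max() < 1e-10
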