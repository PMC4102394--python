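import numpy as np
import pytest

from gkmseq.seqio import SequenceRecord, extract_lmers
from gkmseq.synthetic import ctcf_like_config, make_benchmark

BASES = "ACGT"


def random_record(rng: np.random.Generator, length: int, rec_id: str = "r") -> SequenceRecord:
    return SequenceRecord(rec_id, "".join(BASES[b] for b in rng.integers(0, 4, length)))


def random_records(seed: int, n: int, length: int) -> list[SequenceRecord]:
    rng = np.random.default_rng(seed)
    return [random_record(rng, length, f"r{i}") for i in range(n)]


@pytest.fixture(scope="session")
def small_benchmark():
    """A small planted-motif benchmark shared by model-level tests."""
    pos, neg, meta = make_benchmark(
        ctcf_like_config(seed=7, n_pos=40, n_neg=40, length=120)
    )
    return pos, neg, meta


@pytest.fixture(scope="session")
def small_gkm_model(small_benchmark):
    """A trained gkm-SVM (l=6, k=3) on the small benchmark."""
    from gkmseq.kernels import gkm_kernel_matrix
    from gkmseq.models import train_svm
    from gkmseq.weights import gkm_coefficients

    pos, neg, _ = small_benchmark
    recs = pos + neg
    labels = [1] * len(pos) + [-1] * len(neg)
    lls = [extract_lmers(r, 6) for r in recs]
    K = gkm_kernel_matrix(lls, 6, 3)
    model = train_svm(K, labels, lls, gkm_coefficients(6, 3), C=1.0)
    return model, lls, labels
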