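import warnings

import numpy as np
import pytest

from ltrstack import (
    apply_preprocess,
    default_spec,
    enumerate_kmers,
    fit_preprocess,
    generate,
    vectorize_dataset,
)

warnings.filterwarnings("ignore", category=UserWarning)


@pytest.fixture(scope="session")
def vocab_k3():
    return enumerate_kmers(1, 3)


@pytest.fixture(scope="session")
def small_dataset():
    """Small high-separation synthetic dataset (negative + 13 lineages)."""
    spec = default_spec(n_per_class=12, separation=1.0, seed=7)
    return generate(spec)


@pytest.fixture(scope="session")
def small_counts(small_dataset, vocab_k3):
    return vectorize_dataset(small_dataset, vocab_k3)


@pytest.fixture(scope="session")
def small_pca(small_counts):
    pre = fit_preprocess(small_counts)
    return pre, apply_preprocess(pre, small_counts)


@pytest.fixture()
def rng():
    return np.random.default_rng(123)


def random_dna(rng, length, alphabet="ACGT"):
    return "".join(rng.choice(list(alphabet), size=length))
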