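import numpy as np
import pytest

from mirsimbench import (
    AssociationTable,
    SimilarityMatrix,
    SyntheticConfig,
    gen_associations,
    gen_sequences,
    sequence_similarity,
)


@pytest.fixture(scope="session")
def benchmark_cfg() -> SyntheticConfig:
    """The planted benchmark: 6 families x 10 miRNAs, 20 diseases."""
    return SyntheticConfig(seed=1)


@pytest.fixture(scope="session")
def benchmark_similarity(benchmark_cfg):
    return sequence_similarity(gen_sequences(benchmark_cfg))


@pytest.fixture(scope="session")
def benchmark_associations(benchmark_cfg):
    return gen_associations(benchmark_cfg)


def make_similarity(values, ids=None) -> SimilarityMatrix:
    values = np.asarray(values, dtype=float)
    if ids is None:
        ids = tuple(f"m{i}" for i in range(values.shape[0]))
    return SimilarityMatrix(ids=tuple(ids), values=values)


def make_associations(incidence, mirna_ids=None, disease_ids=None) -> AssociationTable:
    incidence = np.asarray(incidence)
    n, d = incidence.shape
    mirna_ids = tuple(mirna_ids or (f"m{i}" for i in range(n)))
    disease_ids = tuple(disease_ids or (f"d{j}" for j in range(d)))
    pairs = frozenset(
        (mirna_ids[i], disease_ids[j])
        for i in range(n) for j in range(d) if incidence[i, j]
    )
    return AssociationTable(
        mirna_ids=mirna_ids, disease_ids=disease_ids, pairs=pairs
    )


def random_instance(rng, n_max=20, d_max=10):
    """A random aligned (similarity, association) instance."""
    n = int(rng.integers(3, n_max + 1))
    d = int(rng.integers(2, d_max + 1))
    raw = rng.random((n, n))
    values = (raw + raw.T) / 2
    np.fill_diagonal(values, 1.0)
    incidence = (rng.random((n, d)) < 0.4).astype(int)
    return make_similarity(values), make_associations(incidence)
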