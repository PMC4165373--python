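import numpy as np
import pytest

from contigclust.alignment_io import ExperimentDesign
from contigclust.readmodel import EqClassStore


@pytest.fixture
def two_cond_design() -> ExperimentDesign:
    """Two samples, one per condition."""
    return ExperimentDesign(("s1", "s2"), {}, {"s1": "A", "s2": "B"})


@pytest.fixture
def four_sample_design() -> ExperimentDesign:
    """Two conditions with two replicates each."""
    return ExperimentDesign(
        ("a1", "a2", "b1", "b2"),
        {},
        {"a1": "A", "a2": "A", "b1": "B", "b2": "B"},
    )


def make_store(n_samples: int, classes) -> EqClassStore:
    """Build a store from {contig-id iterable: counts} pairs."""
    store = EqClassStore(n_samples)
    for key, counts in classes:
        store.add(frozenset(key), counts)
    return store


def random_classes(
    rng: np.random.Generator,
    n_contigs: int,
    n_samples: int,
    n_classes: int,
    max_count: int = 50,
) -> dict[frozenset, np.ndarray]:
    """Random equivalence classes over contigs c0..c{n-1}; at least one per contig."""
    contigs = [f"c{i}" for i in range(n_contigs)]
    classes: dict[frozenset, np.ndarray] = {}
    for c in contigs:  # guarantee every contig is live
        key = frozenset([c])
        classes[key] = classes.get(key, 0) + rng.integers(1, max_count, size=n_samples)
    for _ in range(n_classes):
        size = int(rng.integers(1, n_contigs + 1))
        key = frozenset(rng.choice(contigs, size=size, replace=False).tolist())
        vec = rng.integers(0, max_count, size=n_samples)
        if vec.sum() == 0:
            vec[0] = 1
        classes[key] = classes.get(key, 0) + vec
    return {k: np.asarray(v, dtype=np.int64) for k, v in classes.items()}


def store_from_classes(classes: dict, n_samples: int) -> EqClassStore:
    store = EqClassStore(n_samples)
    for key, vec in classes.items():
        store.add(key, vec)
    return store
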