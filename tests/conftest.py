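import numpy as np
import pytest

from tfassoc import BindingMatrix, GenomicSegment, PlantedModel, simulate_binding


def random_segments(rng, n, n_chroms=3, max_pos=10_000, max_len=300):
    """Random, possibly overlapping intervals for merge/overlap tests."""
    out = []
    for _ in range(n):
        chrom = f"chr{rng.integers(1, n_chroms + 1)}"
        start = int(rng.integers(0, max_pos))
        out.append(GenomicSegment(chrom, start, start + int(rng.integers(1, max_len))))
    return out


def binary_matrix(values, ids=None):
    """BindingMatrix from a dense 0/1 array with dummy tiled segments."""
    values = np.asarray(values, dtype=np.int8)
    n = values.shape[0]
    segs = [GenomicSegment("chr1", 300 * i, 300 * i + 200) for i in range(n)]
    ids = ids or [f"s{j:02d}" for j in range(values.shape[1])]
    return BindingMatrix(segs, ids, values)


@pytest.fixture(scope="session")
def planted():
    """A planted 20-node / 30-edge copula model with its simulated matrix,
    shared across recovery tests (read-only)."""
    model = PlantedModel.random(20, 30, 2000, seed=11)
    X, truth = simulate_binding(model)
    return model, X, truth
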