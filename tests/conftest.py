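import numpy as np
import pytest

import divkit as dk


@pytest.fixture
def tiny_dataset():
    """2 samples x 3 markers on one chromosome, fully called."""
    samples = dk.make_sample_table(["f1", "f1"], ["a", "b"])
    markers = dk.make_marker_table(
        ["m1", "m2", "m3"], ["1", "1", "1"], [100, 200, 300], a1=list("AAA"), a2=list("GGG")
    )
    calls = np.array([[0, 2, 1], [1, 2, 1]], dtype=np.int8)
    return dk.GenotypeDataset(samples, markers, calls)


def random_dataset(rng, n_samples, n_markers, missing_rate=0.0, n_chroms=2):
    """Uniform-genotype random dataset (helper, not a fixture)."""
    chroms = np.sort(rng.integers(1, n_chroms + 1, size=n_markers))
    pos = np.zeros(n_markers, dtype=int)
    for c in range(1, n_chroms + 1):
        sel = chroms == c
        pos[sel] = np.sort(rng.integers(1, 10_000_000, size=sel.sum()))
        pos[sel] += np.arange(sel.sum())  # break position ties
    markers = dk.make_marker_table(
        [f"m{i}" for i in range(n_markers)], chroms.astype(str), pos
    )
    samples = dk.make_sample_table(
        ["f"] * n_samples, [f"i{k}" for k in range(n_samples)]
    )
    calls = rng.integers(0, 3, size=(n_samples, n_markers)).astype(np.int8)
    if missing_rate:
        calls[rng.random(calls.shape) < missing_rate] = dk.MISSING
    return dk.GenotypeDataset(samples, markers, calls)
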