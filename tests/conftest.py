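import numpy as np
import pytest

from probetest import ProbeMatrix, TwoGroupDesign


@pytest.fixture
def rng():
    return np.random.default_rng(20240501)


def make_matrix(values, gene_sizes=None, probe_ids=None, sample_ids=None):
    """Build a ProbeMatrix from a value array.

    ``gene_sizes`` gives the number of probes per consecutive gene
    (default: one gene holding all probes).
    """
    values = np.asarray(values, dtype=float)
    n_probes, n_samples = values.shape
    if probe_ids is None:
        probe_ids = tuple(f"p{i + 1:03d}" for i in range(n_probes))
    if sample_ids is None:
        sample_ids = tuple(f"s{i + 1:02d}" for i in range(n_samples))
    if gene_sizes is None:
        gene_sizes = [n_probes]
    assert sum(gene_sizes) == n_probes
    probe_to_gene = {}
    cursor = 0
    for g, size in enumerate(gene_sizes):
        for _ in range(size):
            probe_to_gene[probe_ids[cursor]] = f"g{g + 1:03d}"
            cursor += 1
    return ProbeMatrix(values, probe_ids, sample_ids, probe_to_gene)


def make_design(n_a, n_b, sample_ids=None):
    if sample_ids is None:
        sample_ids = tuple(f"s{i + 1:02d}" for i in range(n_a + n_b))
    return TwoGroupDesign.from_groups(sample_ids[:n_a], sample_ids[n_a:])


@pytest.fixture
def small_matrix():
    """2 genes x 3 probes each, 4 samples, positive random-ish values."""
    rng = np.random.default_rng(7)
    return make_matrix(rng.uniform(1.0, 100.0, size=(6, 4)), gene_sizes=[3, 3])
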