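import numpy as np
import pytest

from refstab.quant_io import CqTable, EfficiencyTable, SampleSheet


@pytest.fixture
def toy_cq():
    """Two genes whose Cq difference has a hand-computable SD.

    Gene A: (20, 21, 22), gene B: (25, 26, 23); the pairwise difference
    A - B is (-5, -5, -1) with sample SD sqrt(16/3) = 2.3094.
    """
    return CqTable(("A", "B"), ("s1", "s2", "s3"), [[20, 21, 22], [25, 26, 23]])


@pytest.fixture
def grouped_sheet():
    """Five groups x three replicates, mirroring a dehydration design."""
    groups = ["control", "loss20", "loss50", "loss70", "rehydration"]
    ids, glab, reps = [], [], []
    for g in groups:
        for r in (1, 2, 3):
            ids.append(f"{g}_r{r}")
            glab.append(g)
            reps.append(r)
    return SampleSheet(tuple(ids), tuple(glab), tuple(reps))


def random_cq(rng, n_genes, n_samples, low=18.0, high=32.0):
    genes = tuple(f"g{i:02d}" for i in range(n_genes))
    samples = tuple(f"s{i:02d}" for i in range(n_samples))
    return CqTable(genes, samples, rng.uniform(low, high, size=(n_genes, n_samples)))


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
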