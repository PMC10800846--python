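import numpy as np
import pandas as pd
import pytest

from microsig.containers import OtuTable
from microsig.synthetic import SimConfig, generate_dataset


def make_table(counts: np.ndarray, lines, tissues=None, otu_ids=None) -> OtuTable:
    """Build a small OtuTable by hand."""
    n, m = counts.shape
    samples = [f"S{i+1}" for i in range(n)]
    otu_ids = otu_ids or [f"O{j+1}" for j in range(m)]
    tissues = tissues or ["jejunum"] * n
    meta = pd.DataFrame(
        {"line": lines, "tissue": tissues, "replicate": range(1, n + 1)},
        index=samples,
    )
    return OtuTable(pd.DataFrame(counts, index=samples, columns=otu_ids), meta)


@pytest.fixture(scope="session")
def default_dataset():
    """One default-parameter synthetic dataset, shared across tests."""
    return generate_dataset(SimConfig(seed=1))


@pytest.fixture(scope="session")
def small_dataset():
    """A small synthetic dataset for fast pipeline-level tests."""
    cfg = SimConfig(
        n_otus=100,
        n_discriminative=8,
        n_exclusive_per_line=3,
        n_genes=300,
        n_linked_otus=2,
        n_linked_genes_per_otu=30,
        seed=7,
    )
    return cfg, generate_dataset(cfg)
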