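import numpy as np
import pandas as pd
import pytest

from gbmnoise.config import SimConfig
from gbmnoise.iodata import GeneModel


@pytest.fixture
def two_exon_gene() -> GeneModel:
    """Gene 1..1000 with exons 1..200 and 801..1000 (one intron 201..800)."""
    return GeneModel(
        gene_id="g1", chrom="Chr1", strand="+", start=1, end=1000,
        exons=[(1, 200), (801, 1000)],
    )


@pytest.fixture
def small_config() -> SimConfig:
    return SimConfig(seed=11, n_genes=150, reads_per_cell=2000)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture
def small_matrix() -> pd.DataFrame:
    """4 genes x 4 cells with known structure."""
    return pd.DataFrame(
        {
            "c1": [2.0, 0.0, 5.0, 0.0],
            "c2": [2.0, 4.0, 6.0, 0.0],
            "c3": [2.0, 0.0, 7.0, 0.0],
            "c4": [2.0, 4.0, 8.0, 0.0],
        },
        index=pd.Index(["gA", "gB", "gC", "gD"], name="gene_id"),
    )
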