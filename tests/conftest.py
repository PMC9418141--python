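import numpy as np
import pandas as pd
import pytest

from cocoreg import GeneAnnotation, make_cell_matrix, simulate_annotation


@pytest.fixture
def toy_annotation():
    """Five genes on two chromosomes with hand-placed TSSs."""
    return GeneAnnotation(pd.DataFrame({
        "gene_id": ["gA", "gB", "gC", "gD", "gE"],
        "chrom": ["chr1", "chr1", "chr1", "chr2", "chr2"],
        "tss": [100_000, 600_000, 1_400_000, 50_000, 900_000],
        "strand": ["+", "-", "+", "-", "+"],
        "biotype": ["protein_coding"] * 5,
    }))


@pytest.fixture
def toy_matrix(toy_annotation):
    """Small dense counts matrix over the toy annotation's genes."""
    rng = np.random.default_rng(42)
    X = rng.poisson(5.0, size=(5, 30))
    return make_cell_matrix(toy_annotation.gene_ids,
                            [f"c{i}" for i in range(30)], X, "counts")


@pytest.fixture
def spaced_annotation():
    """Regular 100 kb spacing, one chromosome, 30 genes."""
    return simulate_annotation(30, n_chrom=1, spacing_bp=100_000, seed=0)
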