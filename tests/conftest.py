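import numpy as np
import pandas as pd
import pytest

from polvel.genes import GeneModel


@pytest.fixture
def toy_genes():
    """Three genes, two of them overlapping on the same strand."""
    return [
        GeneModel("gA", "chr1", 100, 500, "+"),
        GeneModel("gB", "chr1", 400, 900, "+"),   # overlaps gA on [400, 500)
        GeneModel("gC", "chr1", 1000, 1500, "-"),
    ]


@pytest.fixture
def plus_gene():
    return GeneModel("gP", "chr1", 1000, 61000, "+")


@pytest.fixture
def minus_gene():
    return GeneModel("gM", "chr1", 1000, 61000, "-")


def records(rows):
    """rows: (chrom, start, end, name, strand)."""
    return pd.DataFrame(
        {
            "chrom": [r[0] for r in rows],
            "start": np.array([r[1] for r in rows], dtype=np.int64),
            "end": np.array([r[2] for r in rows], dtype=np.int64),
            "name": [r[3] for r in rows],
            "score": 0,
            "strand": [r[4] for r in rows],
        }
    )
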