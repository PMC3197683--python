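import numpy as np
import pytest

from faireatlas.io import GeneModel, Peak, PeakSet


@pytest.fixture
def toy_genes() -> list[GeneModel]:
    """Four genes on two chromosomes with simple exon structure."""
    return [
        GeneModel("g1", "chr1", "+", 10_000, 10_000, 20_000,
                  exons=((10_000, 10_200), (19_800, 20_000))),
        GeneModel("g2", "chr1", "-", 60_000, 45_000, 60_001,
                  exons=((45_000, 45_200), (59_800, 60_001))),
        GeneModel("g3", "chr1", "+", 90_000, 90_000, 95_000),
        GeneModel("g4", "chr2", "+", 30_000, 30_000, 40_000),
    ]


@pytest.fixture
def toy_peaks() -> PeakSet:
    return PeakSet(
        "day8",
        [
            Peak("chr1", 9_800, 10_300, 5.0, "p_prom"),      # center 10050, near g1 TSS
            Peak("chr1", 52_000, 52_400, 8.0, "p_distal"),   # between g2 exons
            Peak("chr1", 86_800, 87_200, 2.0, "p_upstream"), # 3 kb upstream of g3
            Peak("chr2", 500_000, 500_300, 1.0, "p_far"),
        ],
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
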