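import numpy as np
import pytest

from chromopos.genemap_io import ChipUniverse, GeneAnnotation


def make_universe(spec, chrom_sizes=None):
    """Build a ChipUniverse from (probeset, gene, chrom, start, end) tuples."""
    anns = [
        GeneAnnotation(
            chromosome=c, start=s, end=e, probeset_id=p, gene_symbol=g
        )
        for p, g, c, s, e in spec
    ]
    return ChipUniverse(anns, chrom_sizes or {})


@pytest.fixture
def small_universe():
    """Ten genes on two chromosomes with known anchors."""
    rows = []
    # chr1: genes at 0.1, 0.2, 0.3, 1.5, 3.0 Mb
    for i, pos in enumerate([100_000, 200_000, 300_000, 1_500_000, 3_000_000]):
        rows.append((f"p1_{i}", f"A{i}", "1", pos, pos + 10_000))
    # chr2: genes at 0.05, 0.25, 0.8, 2.0, 2.1 Mb
    for i, pos in enumerate([50_000, 250_000, 800_000, 2_000_000, 2_100_000]):
        rows.append((f"p2_{i}", f"B{i}", "2", pos, pos + 10_000))
    return make_universe(rows, {"1": 4_000_000, "2": 3_000_000})


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
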