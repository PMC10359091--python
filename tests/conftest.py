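import numpy as np
import pytest

from promethyl.core import Cell, ContactRecord, GenomicPosition, MethylationCall, TargetRegion
from promethyl.synthetic import fixture_small


@pytest.fixture(scope="session")
def small_dataset():
    """Deterministic tiny dataset: 2 types x 25 cells, 1 chrom, 12 promoters."""
    return fixture_small()


@pytest.fixture(scope="session")
def small_graphs(small_dataset):
    """Graphs for a handful of fixture cells (k = 10 meta-cells)."""
    from promethyl.benchmark import build_graphs, split_cells

    split = split_cells(small_dataset, seed=7)
    return split, build_graphs(small_dataset, split, k=10, kmer=4, bin_size=20_000)


def make_regions(chrom="chr1", tss_list=(10_000, 20_000, 30_000, 40_000), chrom_length=None):
    return [
        TargetRegion.from_tss(f"g{i}", chrom, tss, "+", chrom_length=chrom_length)
        for i, tss in enumerate(tss_list)
    ]


def make_cell(cell_id, contacts, cell_type=None, methylation=()):
    recs = [
        ContactRecord.make(GenomicPosition(c1, p1), GenomicPosition(c2, p2))
        for c1, p1, c2, p2 in contacts
    ]
    calls = [
        MethylationCall(GenomicPosition(c, p, s), m, t) for c, p, s, m, t in methylation
    ]
    return Cell(cell_id=cell_id, cell_type=cell_type, contacts=recs, methylation=calls)


@pytest.fixture
def toy_regions():
    return make_regions()
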