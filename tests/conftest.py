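import numpy as np
import pytest

from chromstate import GenomeLayout, GeneModel, TagTrack


@pytest.fixture
def layout():
    return GenomeLayout({"chr1": 100_000, "chr2": 50_000})


@pytest.fixture
def genes(layout):
    return [
        GeneModel(gene_id="gA", chrom="chr1", strand="+", tx_start=10_000, tx_end=16_000),
        GeneModel(gene_id="gB", chrom="chr1", strand="-", tx_start=40_000, tx_end=46_000),
        GeneModel(gene_id="gC", chrom="chr2", strand="+", tx_start=20_000, tx_end=25_000),
    ]


def make_track(layout, tags, library_size=None):
    """Build a TagTrack from {chrom: [(pos, '+'/'-'), ...]}."""
    chroms = {}
    n = 0
    for chrom, items in tags.items():
        pos = np.array([p for p, _ in items], dtype=np.int64)
        sgn = np.array([1 if s == "+" else -1 for _, s in items], dtype=np.int8)
        order = np.argsort(pos, kind="stable")
        chroms[chrom] = (pos[order], sgn[order])
        n += len(items)
    return TagTrack(layout=layout, chroms=chroms,
                    library_size=n if library_size is None else library_size)


@pytest.fixture
def track_factory():
    return make_track
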