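import numpy as np
import pytest

from lsvtools.annotation_io import GeneModel, JunctionKey, PositionalCounts, Transcript
from lsvtools.splicegraph import ReliabilityFilter, build_splice_graph


def make_counts(junction, counts, experiment="exp1", gc=None):
    return PositionalCounts(
        junction=junction,
        experiment_id=experiment,
        counts=dict(counts),
        gc_fraction=gc,
    )


@pytest.fixture
def cassette_gene():
    """Three-exon gene where transcript 2 skips the middle exon."""
    e1, e2, e3 = (100, 200), (500, 600), (900, 1000)
    return GeneModel(
        gene_id="g1",
        chrom="chr1",
        strand="+",
        transcripts=[
            Transcript("g1.t1", [e1, e2, e3]),
            Transcript("g1.t2", [e1, e3]),
        ],
    )


@pytest.fixture
def linear_gene():
    return GeneModel(
        gene_id="lin",
        chrom="chr1",
        strand="+",
        transcripts=[Transcript("lin.t1", [(0, 100), (200, 300), (400, 500)])],
    )


@pytest.fixture
def cassette_graph(cassette_gene):
    return build_splice_graph(cassette_gene, [], ReliabilityFilter())


def junction(donor_end, acceptor_start, chrom="chr1", strand="+"):
    return JunctionKey(chrom, strand, donor_end, acceptor_start)
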