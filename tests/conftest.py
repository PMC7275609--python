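import pytest

from splicemark.annotation import GeneModel, GenomicInterval


def make_gene(gene_id, chrom, strand, transcripts):
    """Build a GeneModel from {tx_id: [(start, end), ...]}."""
    model = GeneModel(gene_id, chrom, strand)
    for tx_id, exons in transcripts.items():
        model.add_transcript(
            tx_id, [GenomicInterval(chrom, s, e, strand) for s, e in exons]
        )
    return model


@pytest.fixture
def cassette_gene():
    """Three-exon gene: tx_inc includes the middle exon, tx_skip skips it."""
    return make_gene(
        "G1",
        "chr1",
        "+",
        {
            "tx_inc": [(100, 200), (300, 400), (500, 600)],
            "tx_skip": [(100, 200), (500, 600)],
        },
    )


@pytest.fixture
def toy_sam(tmp_path):
    """Toy SAM file plus its hand-computed expected count tables."""
    from splicemark.simulate import write_toy_sam

    path = tmp_path / "toy.sam"
    expected_junctions, expected_exons = write_toy_sam(path)
    return path, expected_junctions, expected_exons
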