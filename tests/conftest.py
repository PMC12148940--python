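import pytest

from neuraging.intervals import GenomicInterval, TranscriptModel
from neuraging.simulate import ImageSimParams, simulate_cell_image, simulate_gene_models


@pytest.fixture(scope="session")
def gene_models():
    """Small mixed-strand gene set reused across annotation tests."""
    return simulate_gene_models(20, exons_per_gene=5, seed=11)


@pytest.fixture(scope="session")
def default_image():
    """One simulated field at default parameters, with its truth."""
    return simulate_cell_image(ImageSimParams(seed=3))


@pytest.fixture()
def toy_model():
    """Hand-built plus-strand transcript with known element geometry.

    exons [100,200) [300,400) [500,600); CDS 150..550 =>
    5'UTR [100,150), CDS [150,200)+[300,400)+[500,550), 3'UTR [550,600),
    introns [200,300) and [400,500).
    """
    return TranscriptModel(
        transcript_id="toy_tx",
        gene_id="toy_gene",
        chrom="chrT",
        strand="+",
        exons=[
            GenomicInterval("chrT", 100, 200, "+"),
            GenomicInterval("chrT", 300, 400, "+"),
            GenomicInterval("chrT", 500, 600, "+"),
        ],
        cds_start=150,
        cds_end=550,
    )
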