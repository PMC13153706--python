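import pytest

from peptidogenomics.classify import GeneIndex
from peptidogenomics.models import GeneModel, Genome
from peptidogenomics.sixframe import build_sixframe_db
from peptidogenomics.synthetic import simulate_study

TOY_SEQ = "ATGGCCTAAGGG"


@pytest.fixture(scope="session")
def toy_genome():
    return Genome({"chr1": TOY_SEQ})


@pytest.fixture(scope="session")
def toy_db(toy_genome):
    return build_sixframe_db(toy_genome, seed=1, min_len=1)


@pytest.fixture(scope="session")
def example_gene():
    """Single-transcript '+' gene with two exons, split CDS, and both UTRs."""
    return GeneModel(
        gene_id="geneA", transcript_id="geneA.t1", chrom="chr1", strand="+",
        exons=[(100, 200), (300, 400)],
        cds=[(130, 200, 0), (300, 340, 2)],
        utr5=[(100, 130)], utr3=[(340, 400)],
    )


@pytest.fixture(scope="session")
def gene_index(example_gene):
    return GeneIndex([example_gene], chromosomes={"chr1"})


@pytest.fixture(scope="session")
def study():
    """The default synthetic study: 2 x 10 Mb, 50 genes, 2,000 peptides."""
    return simulate_study(17)


@pytest.fixture(scope="session")
def small_study():
    """A reduced study for fast end-to-end and determinism checks."""
    return simulate_study(23, chrom_length=150_000, n_genes=6, n_peptides=80)
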