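import pytest

from peptidogenomics.classify import (
    GeneIndex, classify_locus, cp_ncp_partition, locus_frame_phase, pct,
)
from peptidogenomics.models import GeneModel, LocusCategory, PeptideLocus


def _locus(start, end, strand="+", chrom="chr1"):
    return PeptideLocus(
        peptide="A" * ((end - start) // 3), chrom=chrom, strand=strand,
        frame=0, start=start, end=end,
    )


class TestLocusFramePhase:
    def test_forward(self):
        phase = locus_frame_phase(_locus(130, 145))
        assert [phase(130), phase(131), phase(133)] == [0, 1, 0]

    def test_reverse_first_base_read(self):
        phase = locus_frame_phase(_locus(0, 12, strand="-"))
        assert phase(11) == 0
        assert phase(0) == 2  # last base read completes the final codon

    def test_outside_error(self):
        phase = locus_frame_phase(_locus(130, 145))
        with pytest.raises(ValueError):
            phase(146)


class TestClassifyLocus:
    @pytest.mark.parametrize("start,end,strand,expected", [
        (133, 148, "+", LocusCategory.CP),                 # in-frame CDS
        (134, 149, "+", LocusCategory.OUT_OF_FRAME_EXON),  # phase shifted
        (133, 148, "-", LocusCategory.OUT_OF_FRAME_EXON),  # antisense to CDS
        (220, 235, "+", LocusCategory.INTRON),
        (220, 235, "-", LocusCategory.INTRON),
        (103, 124, "+", LocusCategory.UTR5),
        (352, 367, "+", LocusCategory.UTR3),
        (5000, 5015, "+", LocusCategory.INTERGENIC),
    ])
    def test_example_gene(self, gene_index, start, end, strand, expected):
        assert classify_locus(_locus(start, end, strand), gene_index) is expected

    def test_second_cds_piece_in_frame(self, gene_index):
        # second CDS piece has phase 2: codon boundaries at 302, 305, ...
        assert classify_locus(_locus(302, 317), gene_index) is LocusCategory.CP
        assert classify_locus(_locus(303, 318), gene_index) is \
            LocusCategory.OUT_OF_FRAME_EXON

    def test_boundary_straddler_uses_touch_precedence(self, gene_index):
        # spans the exon/intron boundary at 200 while touching CDS
        assert classify_locus(_locus(190, 205), gene_index) is \
            LocusCategory.OUT_OF_FRAME_EXON
        # spans the UTR3/intergenic edge at 400, touching only UTR3
        assert classify_locus(_locus(395, 410), gene_index) is LocusCategory.UTR3

    def test_unknown_chromosome_error(self, gene_index):
        with pytest.raises(ValueError, match="universe"):
            classify_locus(_locus(0, 6, chrom="chrZ"), gene_index)

    def test_minus_strand_gene_cp(self):
        model = GeneModel(
            gene_id="g", transcript_id="g.t1", chrom="c", strand="-",
            exons=[(100, 400)], cds=[(130, 340, 0)],
            utr5=[(340, 400)], utr3=[(100, 130)],
        )
        index = GeneIndex([model])
        # phase 0 on '-': codon boundaries anchored at position 339
        assert classify_locus(_locus(325, 340, strand="-", chrom="c"), index) \
            is LocusCategory.CP
        assert classify_locus(_locus(324, 339, strand="-", chrom="c"), index) \
            is LocusCategory.OUT_OF_FRAME_EXON
        assert classify_locus(_locus(325, 340, strand="+", chrom="c"), index) \
            is LocusCategory.OUT_OF_FRAME_EXON


class TestPartition:
    def test_fraction(self):
        pairs = [(LocusCategory.CP, "+")] * 3 + [(LocusCategory.INTRON, "-")] * 7
        report = cp_ncp_partition(pairs)
        assert report.ncp_pct == 70.00
        assert report.cp_pct == 30.00

    def test_strand_tally_conserved(self):
        pairs = [(LocusCategory.INTERGENIC, "+")] * 4 + \
                [(LocusCategory.INTRON, "-")] * 6
        report = cp_ncp_partition(pairs)
        assert sum(report.ncp_strand_counts.values()) == 10

    def test_category_tally_sums_to_total(self):
        pairs = [(c, "+") for c in LocusCategory] * 5
        report = cp_ncp_partition(pairs)
        assert sum(report.category_counts.values()) == report.n_total == 30
        assert report.n_cp + report.n_ncp == report.n_total


def test_pct_rounding():
    assert pct(1, 3) == 33.33
    assert pct(0, 0) == 0.0


def test_planted_category_recovery(small_study):
    """Classification of planted loci reproduces every planted category."""
    s = small_study
    index = GeneIndex(s.models, chromosomes=set(s.genome.chromosomes))
    for planted in s.truth.peptides.values():
        assert classify_locus(planted.locus, index) is planted.category


def test_cp_peptides_lie_in_spliced_cds_translation(small_study):
    """Every planted CP is a substring of its transcript's conceptual
    CDS translation (splice, then translate)."""
    from oracles import revcomp, translate
    s = small_study
    by_tx = {m.transcript_id: m for m in s.models}
    cps = [p for p in s.truth.peptides.values()
           if p.category is LocusCategory.CP]
    assert cps
    for planted in cps:
        found = False
        for m in by_tx.values():
            if m.chrom != planted.locus.chrom or m.strand != planted.locus.strand:
                continue
            pieces = [s.resolved_genome[m.chrom][cs:ce] for cs, ce, _ in m.cds]
            cds_nt = "".join(pieces)
            if m.strand == "-":
                cds_nt = revcomp(cds_nt)
            if planted.peptide in translate(cds_nt):
                found = True
                break
        assert found, planted.peptide
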