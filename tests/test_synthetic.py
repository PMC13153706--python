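import numpy as np
import pandas as pd
import pytest

from peptidogenomics import io_formats as iof
from peptidogenomics import synthetic as syn
from peptidogenomics.classify import GeneIndex, classify_locus
from peptidogenomics.models import LocusCategory
from peptidogenomics.sixframe import build_sixframe_db, resolve_genome
from peptidogenomics.tissue import classify_tissue_pattern

import oracles


class TestGenerateGenome:
    def test_deterministic(self):
        g1 = syn.generate_genome(3, n_chrom=1, lengths=[20_000])
        g2 = syn.generate_genome(3, n_chrom=1, lengths=[20_000])
        assert g1 == g2

    def test_gc_fraction_within_binomial_bounds(self):
        g = syn.generate_genome(5, n_chrom=1, lengths=[100_000], gc=0.5,
                                ambiguity_rate=0.0)
        seq = g["chr1"]
        gc = seq.count("G") + seq.count("C")
        sigma = (100_000 * 0.25) ** 0.5
        assert abs(gc - 50_000) < 3 * sigma

    def test_zero_ambiguity_has_no_n(self):
        g = syn.generate_genome(5, n_chrom=1, lengths=[20_000], ambiguity_rate=0.0)
        assert "N" not in g["chr1"]

    @pytest.mark.parametrize("kwargs", [
        {"lengths": [5_000]}, {"gc": 0.0}, {"ambiguity_rate": 0.2},
        {"lengths": [20_000, 20_000]},
    ])
    def test_invalid_parameters(self, kwargs):
        with pytest.raises(ValueError):
            syn.generate_genome(1, n_chrom=1, **kwargs)


@pytest.fixture(scope="module")
def planted():
    genome = syn.generate_genome(11, n_chrom=1, lengths=[120_000])
    return syn.plant_gene_models(genome, 12, n_genes=5)


@pytest.fixture(scope="module")
def peptidome_setup():
    genome = syn.generate_genome(21, n_chrom=1, lengths=[200_000],
                                 ambiguity_rate=0.0)
    genome, models = syn.plant_gene_models(genome, 22, n_genes=6)
    resolved = resolve_genome(genome, 23)
    db = build_sixframe_db(genome, 23, resolved=resolved)
    return resolved, models, db


class TestPlantGeneModels:
    def test_cds_translates_without_internal_stops(self, planted):
        genome, models = planted
        for m in models:
            pieces = [genome[m.chrom][s:e] for s, e, _ in m.cds]
            cds_nt = "".join(pieces)
            if m.strand == "-":
                cds_nt = oracles.revcomp(cds_nt)
            protein = oracles.translate(cds_nt)
            assert protein[0] == "M"
            assert protein[-1] == "*"
            assert "*" not in protein[:-1]

    def test_phases_match_cumulative_length(self, planted):
        _, models = planted
        for m in models:
            order = m.cds if m.strand == "+" else list(reversed(m.cds))
            cum = 0
            for s, e, phase in order:
                assert phase == (3 - cum % 3) % 3
                cum += e - s

    def test_gff3_roundtrip(self, planted, tmp_path):
        _, models = planted
        path = tmp_path / "ann.gff3"
        iof.write_gff3(models, path)
        back = {m.transcript_id: m for m in iof.read_gff3(path)}
        for m in models:
            r = back[m.transcript_id]
            assert (r.exons, r.cds, r.utr5, r.utr3) == \
                (m.exons, m.cds, m.utr5, m.utr3)

    def test_no_genes_leaves_genome_unchanged(self):
        genome = syn.generate_genome(2, n_chrom=1, lengths=[20_000])
        edited, models = syn.plant_gene_models(genome, 3, n_genes=0)
        assert models == [] and edited == genome

    def test_min_spacing_respected(self, planted):
        _, models = planted
        spans = sorted(m.span for m in models)
        for (s0, e0), (s1, e1) in zip(spans, spans[1:]):
            assert s1 - e0 >= 5_000


class TestPlantPeptidome:
    def test_truth_consistency(self, peptidome_setup):
        resolved, models, db = peptidome_setup
        rows, truth = syn.plant_peptidome(resolved, models, db, 24, n_peptides=60)
        index = GeneIndex(models, chromosomes=set(resolved.chromosomes))
        for planted in truth.peptides.values():
            loc = planted.locus
            nt = resolved[loc.chrom][loc.start:loc.end]
            if loc.strand == "-":
                nt = oracles.revcomp(nt)
            assert oracles.translate(nt) == planted.peptide
            assert classify_locus(loc, index) is planted.category

    def test_pure_cp_mix(self, peptidome_setup):
        resolved, models, db = peptidome_setup
        _, truth = syn.plant_peptidome(
            resolved, models, db, 25, n_peptides=15,
            category_mix={LocusCategory.CP: 1.0})
        assert all(p.category is LocusCategory.CP
                   for p in truth.peptides.values())

    def test_unplantable_category_names_it(self, peptidome_setup):
        resolved, _, db = peptidome_setup
        with pytest.raises(ValueError, match="intron"):
            syn.plant_peptidome(resolved, [], db, 26, n_peptides=5,
                                category_mix={LocusCategory.INTRON: 1.0})

    def test_fdr_fail_rows_flagged_out(self, peptidome_setup):
        resolved, models, db = peptidome_setup
        rows, _ = syn.plant_peptidome(resolved, models, db, 27, n_peptides=20,
                                      n_fdr_fail=5)
        table = iof.make_id_table(rows)
        assert (~table.rows["passes_fdr"]).sum() == 5

    def test_bad_length_range(self, peptidome_setup):
        resolved, models, db = peptidome_setup
        with pytest.raises(ValueError, match="length"):
            syn.plant_peptidome(resolved, models, db, 28, length_range=(3, 40))


class TestPlantTissueMatrix:
    def test_deterministic(self):
        peps = [f"PEPTIDE{i}A" for i in range(10)]
        m1, l1, r1 = syn.plant_tissue_matrix(peps, 5)
        m2, l2, r2 = syn.plant_tissue_matrix(peps, 5)
        pd.testing.assert_frame_equal(m1.means, m2.means)
        pd.testing.assert_frame_equal(l1, l2)

    def test_fold_one_unplantable(self):
        with pytest.raises(ValueError, match="fold"):
            syn.plant_tissue_matrix(["AAAAAA"], 5, fold=1)

    def test_recovery_at_default_noise(self):
        rng = np.random.default_rng(0)
        peps = list(dict.fromkeys(
            oracles.random_peptide(rng, 10) for _ in range(300)))
        matrix, labels, _ = syn.plant_tissue_matrix(
            peps, 6, class_mix={"specific": 0.4, "enhanced": 0.3, "mixed": 0.3})
        observed = classify_tissue_pattern(matrix)
        joined = observed.join(labels, lsuffix="_obs", rsuffix="_true")
        assert (joined["tissue_class_obs"] == joined["tissue_class_true"]).all()


class TestEndToEndDeterminism:
    def test_same_seed_same_study(self, tmp_path):
        kw = dict(chrom_length=60_000, n_genes=3, n_peptides=25,
                  with_support=False)
        s1 = syn.simulate_study(99, **kw)
        s2 = syn.simulate_study(99, **kw)
        assert s1.genome == s2.genome
        assert list(s1.truth.peptides) == list(s2.truth.peptides)
        pd.testing.assert_frame_equal(s1.id_rows, s2.id_rows)
        pd.testing.assert_frame_equal(s1.matrix.means, s2.matrix.means)
        p1, p2 = tmp_path / "a.fa", tmp_path / "b.fa"
        s1.db.to_fasta(p1, sidecar=False)
        s2.db.to_fasta(p2, sidecar=False)
        assert p1.read_bytes() == p2.read_bytes()

    def test_stage_seed_below_2_31(self):
        assert 0 <= syn.stage_seed(2 ** 30, 99) < 2 ** 31


def test_planted_hotspot_found_by_detection():
    """A planted 25-peptide cluster inside one 6-Mb window becomes a hotspot
    in an otherwise sparse genome."""
    from peptidogenomics import distribution as dist
    genome = syn.generate_genome(41, n_chrom=1, lengths=[12_000_000],
                                 ambiguity_rate=0.0)
    genome, models = syn.plant_gene_models(genome, 42, n_genes=4)
    resolved = resolve_genome(genome, 43)
    db = build_sixframe_db(genome, 43, resolved=resolved)
    spec = syn.HotspotSpec("chr1", 6_000_000, 12_000_000, 25)
    _, truth = syn.plant_peptidome(resolved, models, db, 44, n_peptides=5,
                                   hotspot=spec)
    loci = [p.locus for p in truth.peptides.values()]
    profile = dist.window_density(loci, resolved.lengths)
    hot = dist.detect_hotspots(profile)
    assert ("chr1", 6_000_000, 12_000_000) in {h[:3] for h in hot}
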