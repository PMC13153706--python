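import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from peptidogenomics import properties as props
from peptidogenomics.mapping import locate_peptide
from peptidogenomics.models import Genome, PeptideLocus
from peptidogenomics.sixframe import build_sixframe_db

import oracles

peptides = st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=1, max_size=30)


class TestMolecularWeight:
    def test_single_glycine(self):
        expected = props.AVERAGE_RESIDUE_MASS["G"] + props.WATER_MASS
        assert props.molecular_weight("G") == pytest.approx(expected, abs=1e-9)
        assert props.molecular_weight("G") == pytest.approx(75.067, abs=5e-3)

    def test_residue_additivity(self):
        diff = props.molecular_weight("GG") - props.molecular_weight("G")
        assert diff == pytest.approx(props.AVERAGE_RESIDUE_MASS["G"], abs=1e-9)

    def test_reported_utr5_peptide_vs_summation_oracle(self):
        pep = "ASAAEGDMEAELTR"
        oracle = sum(props.AVERAGE_RESIDUE_MASS[a] for a in pep) + props.WATER_MASS
        assert props.molecular_weight(pep) == pytest.approx(oracle, abs=1e-3)

    def test_errors(self):
        with pytest.raises(ValueError):
            props.molecular_weight("")
        with pytest.raises(ValueError):
            props.molecular_weight("AXB")

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(peptides, peptides)
    def test_concatenation_additivity(self, x, y):
        lhs = props.molecular_weight(x + y)
        rhs = props.molecular_weight(x) + props.molecular_weight(y) - props.WATER_MASS
        assert lhs == pytest.approx(rhs, abs=1e-9)


class TestIsoelectricPoint:
    def test_no_sidechain_closed_form(self):
        pka = props.DEFAULT_PKA
        expected = (pka["n_term"] + pka["c_term"]) / 2
        assert props.isoelectric_point("GG") == pytest.approx(expected, abs=1e-3)

    def test_acidic_neutral_basic_ordering(self):
        assert props.isoelectric_point("DDDD") < props.isoelectric_point("GGGG") \
            < props.isoelectric_point("KKKK")

    def test_charge_vanishes_at_pi(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            pep = oracles.random_peptide(rng, int(rng.integers(1, 31)))
            pi = props.isoelectric_point(pep)
            assert abs(props.net_charge(pep, pi)) < 1e-3

    def test_agrees_with_grid_scan(self):
        rng = np.random.default_rng(4)
        for _ in range(100):
            pep = oracles.random_peptide(rng, int(rng.integers(1, 31)))
            oracle = oracles.grid_scan_pi(pep, props.DEFAULT_PKA)
            assert abs(props.isoelectric_point(pep) - oracle) <= 2e-3


class TestHydropathy:
    def test_spleen_specific_ncp(self):
        # L,P,W,W,P,W,W hydrophobic vs K hydrophilic
        assert props.hydropathy_counts("LPWKWPWW") == (7, 1)

    def test_isoleucine_in_neither_set(self):
        assert props.hydropathy_counts("III") == (0, 0)

    def test_empty_error(self):
        with pytest.raises(ValueError):
            props.hydropathy_counts("")

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(peptides)
    def test_conservation(self, pep):
        n_phobic, n_philic = props.hydropathy_counts(pep)
        assert n_phobic + n_philic + pep.count("I") == len(pep)


class TestStartCodon:
    def test_toy_loci(self, toy_genome, toy_db):
        ma = PeptideLocus("MA", "chr1", "+", 0, 0, 6)
        wpk = PeptideLocus("WPK", "chr1", "+", 1, 1, 10)
        plgh = PeptideLocus("PLGH", "chr1", "-", 0, 0, 12)
        assert props.start_codon(ma, toy_genome, toy_db) == ("ATG", True)
        assert props.start_codon(wpk, toy_genome, toy_db) == ("TGG", False)
        assert props.start_codon(plgh, toy_genome, toy_db) == ("CCC", False)

    def test_digest_mismatch_error(self, toy_db):
        other = Genome({"chr1": "ATGGCCTAAGGA"})
        locus = PeptideLocus("MA", "chr1", "+", 0, 0, 6)
        with pytest.raises(ValueError, match="digest"):
            props.start_codon(locus, other, toy_db)

    def test_consistent_with_mapping(self):
        rng = np.random.default_rng(8)
        seq = oracles.random_genome_string(rng, 600)
        genome = Genome({"c": seq})
        db = build_sixframe_db(genome, seed=1, min_len=4)
        seg = db.segments[0]
        (locus,) = [l for l in locate_peptide(seg.aa_seq, db)
                    if (l.start, l.end) == (seg.start, seg.end)]
        codon, is_aug = props.start_codon(locus, genome, db)
        assert oracles.CODON_TABLE[codon] == seg.aa_seq[0]
        assert is_aug == (codon == "ATG")


class TestPercentIdentity:
    def test_indolicidin_similarity(self):
        assert props.percent_identity("LPWKWPWW", "ILPWKWPWWPWRR") == 61.54

    def test_identity_and_disjoint(self):
        assert props.percent_identity("WWWW", "WWWW") == 100.00
        assert props.percent_identity("AAAA", "CCCC") == 0.00

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(peptides, peptides)
    def test_symmetric_and_bounded(self, a, b):
        v = props.percent_identity(a, b)
        assert v == props.percent_identity(b, a)
        assert 0.0 <= v <= 100.0


def test_properties_table_columns(toy_genome, toy_db):
    loci = {"MA": PeptideLocus("MA", "chr1", "+", 0, 0, 6)}
    table = props.properties_table(loci, genome=toy_genome, db=toy_db)
    row = table.iloc[0]
    assert row["length"] == 2 and row["is_aug"]
    assert row["n_hydrophobic"] == 2  # M and A
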