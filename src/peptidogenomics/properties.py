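"""Physicochemical characterization of identified peptides.

Molecular weight from average residue masses, isoelectric point by
bisection of the Henderson-Hasselbalch net-charge equation, the fixed
8-hydrophobic / 11-hydrophilic residue split used throughout the study
(isoleucine belongs to neither set), genomic start-codon readout, and
ungapped percent identity against reference peptides.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .models import STANDARD_AA, Genome, PeptideLocus
from .sixframe import TranslationDB, extract_locus_nt

#: Average (isotope-weighted) residue masses in Da, conventional values.
AVERAGE_RESIDUE_MASS = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886, "C": 103.1388,
    "E": 129.1155, "Q": 128.1307, "G": 57.0519, "H": 137.1411, "I": 113.1594,
    "L": 113.1594, "K": 128.1741, "M": 131.1926, "F": 147.1766, "P": 97.1167,
    "S": 87.0782, "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}

WATER_MASS = 18.0153

#: Bjellqvist-style pKa values (the table conventional for 2-D gel pI work).
DEFAULT_PKA = {
    "n_term": 7.50, "c_term": 3.55,
    "D": 4.05, "E": 4.45, "C": 9.00, "Y": 10.00,
    "H": 5.98, "K": 10.00, "R": 12.00,
}

_POSITIVE_SIDE = ("H", "K", "R")
_NEGATIVE_SIDE = ("D", "E", "C", "Y")


@dataclass
class ResidueTables:
    """The mass, pKa, and hydropathy tables the property calculations use."""

    masses: dict[str, float] = field(default_factory=lambda: dict(AVERAGE_RESIDUE_MASS))
    water: float = WATER_MASS
    pka: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_PKA))
    hydrophobic: frozenset = frozenset("GAVLPMFW")
    hydrophilic: frozenset = frozenset("STYCNQDERKH")

    def __post_init__(self):
        if self.hydrophobic & self.hydrophilic:
            raise ValueError("hydrophobic and hydrophilic sets overlap")


DEFAULT_TABLES = ResidueTables()


def _check_peptide(peptide: str) -> str:
    peptide = peptide.upper()
    if not peptide:
        raise ValueError("empty peptide")
    bad = set(peptide) - STANDARD_AA
    if bad:
        raise ValueError(f"nonstandard residues {sorted(bad)} in {peptide!r}")
    return peptide


def molecular_weight(peptide: str, tables: ResidueTables = DEFAULT_TABLES) -> float:
    """Average molecular weight in Da: residue masses plus one water."""
    peptide = _check_peptide(peptide)
    return sum(tables.masses[aa] for aa in peptide) + tables.water


def net_charge(peptide: str, ph: float, tables: ResidueTables = DEFAULT_TABLES) -> float:
    """Henderson-Hasselbalch net charge at a given pH."""
    peptide = _check_peptide(peptide)
    pka = tables.pka
    charge = 1.0 / (1.0 + 10.0 ** (ph - pka["n_term"]))
    charge -= 1.0 / (1.0 + 10.0 ** (pka["c_term"] - ph))
    for aa in _POSITIVE_SIDE:
        n = peptide.count(aa)
        if n:
            charge += n / (1.0 + 10.0 ** (ph - pka[aa]))
    for aa in _NEGATIVE_SIDE:
        n = peptide.count(aa)
        if n:
            charge -= n / (1.0 + 10.0 ** (pka[aa] - ph))
    return charge


def isoelectric_point(
    peptide: str, tables: ResidueTables = DEFAULT_TABLES, tol: float = 1e-6
) -> float:
    """The pH at which the net charge is zero, by bisection on [0, 14].

    Net charge is strictly decreasing in pH, so plain bisection converges;
    the tolerance is on the pH axis.
    """
    peptide = _check_peptide(peptide)
    lo, hi = 0.0, 14.0
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if net_charge(peptide, mid, tables) > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def hydropathy_counts(
    peptide: str, tables: ResidueTables = DEFAULT_TABLES
) -> tuple[int, int]:
    """(hydrophobic, hydrophilic) residue counts against the fixed sets.

    Ile is in neither set, so the two counts plus the Ile count equal the
    peptide length.
    """
    peptide = _check_peptide(peptide)
    n_phobic = sum(aa in tables.hydrophobic for aa in peptide)
    n_philic = sum(aa in tables.hydrophilic for aa in peptide)
    return n_phobic, n_philic


def start_codon(
    locus: PeptideLocus, genome: Genome, db: TranslationDB | None = None
) -> tuple[str, bool]:
    """First codon of the locus on its reading strand, and whether it is ATG.

    ``genome`` must be the ambiguity-resolved genome the database was built
    from; passing the database enables a digest check.
    """
    if db is not None and db.genome_digest and genome.digest() != db.genome_digest:
        raise ValueError("genome digest does not match the database provenance")
    nt = extract_locus_nt(genome, locus.chrom, locus.strand, locus.start, locus.end)
    codon = nt[:3]
    return codon, codon == "ATG"


def percent_identity(peptide: str, reference: str) -> float:
    """Best ungapped containment identity, normalized by the longer sequence.

    The shorter sequence slides over the longer; the best position-wise
    match count is divided by the longer length, as a percentage rounded
    to two decimals.
    """
    a = _check_peptide(peptide)
    b = _check_peptide(reference)
    short, long_ = (a, b) if len(a) <= len(b) else (b, a)
    best = 0
    for off in range(len(long_) - len(short) + 1):
        matches = sum(x == y for x, y in zip(short, long_[off:]))
        best = max(best, matches)
    return round(100.0 * best / len(long_), 2)


def properties_table(
    loci: dict[str, PeptideLocus], genome: Genome | None = None,
    db: TranslationDB | None = None, tables: ResidueTables = DEFAULT_TABLES,
) -> pd.DataFrame:
    """One row of physicochemical properties per peptide locus."""
    rows = []
    for pep, locus in loci.items():
        n_phobic, n_philic = hydropathy_counts(pep, tables)
        row = {
            "peptide": pep, "length": len(pep),
            "mw": round(molecular_weight(pep, tables), 4),
            "pi": round(isoelectric_point(pep, tables), 3),
            "n_hydrophobic": n_phobic, "n_hydrophilic": n_philic,
        }
        if genome is not None:
            codon, is_aug = start_codon(locus, genome, db)
            row["start_codon"] = codon
            row["is_aug"] = is_aug
        rows.append(row)
    return pd.DataFrame(rows)
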