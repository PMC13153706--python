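"""Core domain types shared across the pipeline.

Every interval in this package is 0-based, half-open, and expressed in
forward-strand genomic coordinates, regardless of the strand the feature
or peptide is read from.  Format readers/writers convert at the boundary.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from enum import Enum

from Bio.Data import IUPACData

#: Legal nucleotide symbols (uppercase): the four bases plus IUPAC ambiguity codes.
IUPAC_NUCLEOTIDES = frozenset(IUPACData.ambiguous_dna_letters.upper())

#: The twenty standard amino-acid letters.
STANDARD_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")


class Genome:
    """An ordered collection of named chromosome sequences.

    Sequences are stored uppercase.  Names must be unique, sequences
    non-empty, and every character a legal IUPAC nucleotide symbol.
    """

    def __init__(self, chromosomes: dict[str, str]):
        if not chromosomes:
            raise ValueError("genome has no chromosomes")
        self.chromosomes: dict[str, str] = {}
        for name, seq in chromosomes.items():
            if name in self.chromosomes:
                raise ValueError(f"duplicate chromosome name: {name!r}")
            seq = seq.upper()
            if not seq:
                raise ValueError(f"chromosome {name!r} is empty")
            bad = set(seq) - IUPAC_NUCLEOTIDES
            if bad:
                raise ValueError(
                    f"chromosome {name!r} contains illegal symbols: {sorted(bad)}"
                )
            self.chromosomes[name] = seq

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.chromosomes.items()}

    def __getitem__(self, name: str) -> str:
        return self.chromosomes[name]

    def __contains__(self, name: str) -> bool:
        return name in self.chromosomes

    def __iter__(self):
        return iter(self.chromosomes)

    def __len__(self) -> int:
        return len(self.chromosomes)

    def __eq__(self, other) -> bool:
        return isinstance(other, Genome) and self.chromosomes == other.chromosomes

    def digest(self) -> str:
        """Stable hex digest of names and sequences, for provenance checks."""
        h = hashlib.sha256()
        for name, seq in self.chromosomes.items():
            h.update(name.encode())
            h.update(b"\x00")
            h.update(seq.encode())
            h.update(b"\x01")
        return h.hexdigest()[:16]


@dataclass(frozen=True, slots=True)
class PeptideLocus:
    """An identified peptide anchored to a single genomic interval.

    ``start``/``end`` are forward-strand coordinates; for ``strand == '-'``
    the peptide is read from the reverse complement of that interval.
    ``frame`` is the reading-frame offset (0-2) on the reading strand and
    ``segment_offset`` the residue offset within the source database segment.
    """

    peptide: str
    chrom: str
    strand: str
    frame: int
    start: int
    end: int
    segment_offset: int = 0

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        if self.end - self.start != 3 * len(self.peptide):
            raise ValueError(
                f"interval [{self.start},{self.end}) does not span "
                f"3 x {len(self.peptide)} nt"
            )


class LocusCategory(Enum):
    """Genomic source category of a peptide locus.

    CP (conventional polypeptide) means in-frame, same-strand containment
    in annotated CDS; the other five categories are the non-conventional
    (NCP) sources.
    """

    CP = "CP"
    OUT_OF_FRAME_EXON = "out_of_frame_exon"
    UTR5 = "5UTR"
    UTR3 = "3UTR"
    INTRON = "intron"
    INTERGENIC = "intergenic"


#: Categories counted as non-conventional peptides.
NCP_CATEGORIES = frozenset(LocusCategory) - {LocusCategory.CP}


@dataclass
class GeneModel:
    """One transcript's structure used for CP/NCP classification.

    ``exons`` are sorted, non-overlapping intervals; ``cds`` carries GFF3
    phase per piece (bases to skip at the piece's 5' end to reach a codon
    boundary); ``introns`` are the gaps between consecutive exons.
    """

    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    cds: list[tuple[int, int, int]] = field(default_factory=list)
    utr5: list[tuple[int, int]] = field(default_factory=list)
    utr3: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        self.exons = sorted(self.exons)
        for (s0, e0), (s1, e1) in zip(self.exons, self.exons[1:]):
            if s1 < e0:
                raise ValueError(f"overlapping exons in {self.transcript_id}")
        self.cds = sorted(self.cds)
        for s, e, phase in self.cds:
            if phase not in (0, 1, 2):
                raise ValueError(f"bad CDS phase {phase!r} in {self.transcript_id}")
            if not any(xs <= s and e <= xe for xs, xe in self.exons):
                raise ValueError(f"CDS [{s},{e}) outside exons in {self.transcript_id}")

    @property
    def introns(self) -> list[tuple[int, int]]:
        return [
            (e0, s1) for (_, e0), (s1, _) in zip(self.exons, self.exons[1:]) if s1 > e0
        ]

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]
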