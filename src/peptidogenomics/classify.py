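"""CP/NCP classification of peptide loci against gene models.

A locus is a conventional peptide (CP) only if it sits entirely inside
annotated CDS of one transcript, on the annotated strand, in the annotated
reading frame.  Everything else is a non-conventional peptide (NCP), split
into out-of-frame exon, 5'UTR, 3'UTR, intron, and intergenic sources.
Conflicts across transcripts and partial overlaps resolve by the precedence
CP > out-of-frame exon > 5'UTR > 3'UTR > intron > intergenic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from intervaltree import IntervalTree

from .models import GeneModel, LocusCategory, PeptideLocus


def locus_frame_phase(locus: PeptideLocus):
    """Return f(position) -> codon phase implied by the locus's translation.

    Phase 0 marks the first base of a codon in the locus's reading
    direction; on '-' the first base read is ``end - 1``.
    """

    def phase(pos: int) -> int:
        if not (locus.start <= pos < locus.end):
            raise ValueError(f"position {pos} outside locus [{locus.start},{locus.end})")
        if locus.strand == "+":
            return (pos - locus.start) % 3
        return ((locus.end - 1) - pos) % 3

    return phase


def _contained_in_union(start: int, end: int, intervals) -> bool:
    """True iff [start,end) is covered by the (sorted, disjoint) intervals."""
    for s, e in intervals:
        if s <= start and end <= e:
            return True
    return False


def _cds_phase_ok(locus: PeptideLocus, model: GeneModel) -> bool:
    """Locus frame agrees with the annotated CDS frame at every position.

    Both frames advance one phase per base within a CDS piece, so agreement
    at the first covered base of the piece implies agreement throughout.
    """
    for s, e, phase in model.cds:
        if s <= locus.start and locus.end <= e:
            if model.strand == "+":
                return (locus.start - (s + phase)) % 3 == 0
            return ((e - 1 - phase) - (locus.end - 1)) % 3 == 0
    return False


@dataclass
class GeneIndex:
    """Interval-indexed gene models plus the chromosome universe."""

    models: list[GeneModel]
    chromosomes: set[str] = field(default_factory=set)

    def __post_init__(self):
        self.chromosomes = set(self.chromosomes)
        self.chromosomes.update(m.chrom for m in self.models)
        self._trees: dict[str, IntervalTree] = {}
        for m in self.models:
            s, e = m.span
            self._trees.setdefault(m.chrom, IntervalTree()).addi(s, e, m)

    def overlapping(self, locus: PeptideLocus) -> list[GeneModel]:
        tree = self._trees.get(locus.chrom)
        if tree is None:
            return []
        return [iv.data for iv in tree.overlap(locus.start, locus.end)]


def classify_locus(
    locus: PeptideLocus, index: GeneIndex, with_gene: bool = False
):
    """Assign the single genomic source category of a locus.

    Raises if the locus's chromosome is not part of the annotation
    universe (no way to distinguish intergenic from unannotated).
    """
    if locus.chrom not in index.chromosomes:
        raise ValueError(f"chromosome {locus.chrom!r} absent from the annotation universe")
    models = index.overlapping(locus)
    if not models:
        result = (LocusCategory.INTERGENIC, None)
        return result if with_gene else result[0]

    s, e = locus.start, locus.end
    hit: dict[LocusCategory, str] = {}
    touch: dict[LocusCategory, str] = {}

    for m in models:
        cds_iv = [(cs, ce) for cs, ce, _ in m.cds]
        overlaps_cds = any(cs < e and s < ce for cs, ce in cds_iv)
        if _contained_in_union(s, e, cds_iv) and m.strand == locus.strand \
                and _cds_phase_ok(locus, m):
            hit.setdefault(LocusCategory.CP, m.gene_id)
            continue
        if _contained_in_union(s, e, m.exons) and overlaps_cds:
            hit.setdefault(LocusCategory.OUT_OF_FRAME_EXON, m.gene_id)
        if _contained_in_union(s, e, m.utr5):
            hit.setdefault(LocusCategory.UTR5, m.gene_id)
        if _contained_in_union(s, e, m.utr3):
            hit.setdefault(LocusCategory.UTR3, m.gene_id)
        if _contained_in_union(s, e, m.introns):
            hit.setdefault(LocusCategory.INTRON, m.gene_id)
        # partial-overlap fallbacks: highest-ranked element the locus touches
        if overlaps_cds:
            touch.setdefault(LocusCategory.OUT_OF_FRAME_EXON, m.gene_id)
        if any(us < e and s < ue for us, ue in m.utr5):
            touch.setdefault(LocusCategory.UTR5, m.gene_id)
        if any(us < e and s < ue for us, ue in m.utr3):
            touch.setdefault(LocusCategory.UTR3, m.gene_id)
        if any(js < e and s < je for js, je in m.introns):
            touch.setdefault(LocusCategory.INTRON, m.gene_id)

    for cat in (LocusCategory.CP, LocusCategory.OUT_OF_FRAME_EXON,
                LocusCategory.UTR5, LocusCategory.UTR3, LocusCategory.INTRON):
        if cat in hit:
            return (cat, hit[cat]) if with_gene else cat
        if cat in touch:
            return (cat, touch[cat]) if with_gene else cat
    # overlapping a gene span but none of its elements cannot happen
    # (span = exons + introns); defensive fallback:
    result = (LocusCategory.INTERGENIC, None)
    return result if with_gene else result[0]


def classify_loci(
    loci: dict[str, PeptideLocus], index: GeneIndex
) -> pd.DataFrame:
    """Classify a peptide -> locus map into a tidy table."""
    rows = []
    for pep, locus in loci.items():
        cat, gene = classify_locus(locus, index, with_gene=True)
        rows.append({
            "peptide": pep, "chrom": locus.chrom, "start": locus.start,
            "end": locus.end, "strand": locus.strand, "frame": locus.frame,
            "category": cat.value, "gene_id": gene if gene is not None else ".",
        })
    return pd.DataFrame(
        rows, columns=["peptide", "chrom", "start", "end", "strand", "frame",
                       "category", "gene_id"],
    )


def pct(n: int, total: int, decimals: int = 2) -> float:
    """Percentage of ``n`` in ``total``, rounded to ``decimals`` places."""
    if total == 0:
        return 0.0
    return round(100.0 * n / total, decimals)


@dataclass
class PartitionReport:
    """CP/NCP split with per-category and per-strand tallies."""

    n_total: int
    n_cp: int
    n_ncp: int
    category_counts: dict[str, int]
    category_pct: dict[str, float]
    ncp_strand_counts: dict[str, int]
    cp_strand_counts: dict[str, int]

    @property
    def cp_pct(self) -> float:
        return pct(self.n_cp, self.n_total)

    @property
    def ncp_pct(self) -> float:
        return pct(self.n_ncp, self.n_total)


def cp_ncp_partition(classified) -> PartitionReport:
    """Tally a classified table (or (category, strand) pairs) into a report."""
    if isinstance(classified, pd.DataFrame):
        pairs = list(zip(classified["category"], classified["strand"]))
    else:
        pairs = [
            (c.value if isinstance(c, LocusCategory) else c, s)
            for c, s in classified
        ]
    cat_counts = {c.value: 0 for c in LocusCategory}
    ncp_strand = {"+": 0, "-": 0}
    cp_strand = {"+": 0, "-": 0}
    for cat, strand in pairs:
        cat_counts[cat] += 1
        if cat == LocusCategory.CP.value:
            cp_strand[strand] += 1
        else:
            ncp_strand[strand] += 1
    n_total = len(pairs)
    n_cp = cat_counts[LocusCategory.CP.value]
    n_ncp = n_total - n_cp
    return PartitionReport(
        n_total=n_total, n_cp=n_cp, n_ncp=n_ncp,
        category_counts=cat_counts,
        category_pct={c: pct(n, n_total) for c, n in cat_counts.items()},
        ncp_strand_counts=ncp_strand, cp_strand_counts=cp_strand,
    )
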