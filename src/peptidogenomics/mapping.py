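"""Exact-substring assignment of peptides to genomic loci.

Peptides are searched against the six-frame database segments; a hit at
residue offset ``k`` of a segment maps to a genomic interval by simple
codon arithmetic.  Matching is within-segment only, so a peptide can
never span a stop codon.  Downstream analyses keep only peptides with a
single unambiguous locus.
"""

from __future__ import annotations

import logging
from bisect import bisect_right

from .models import STANDARD_AA, PeptideLocus
from .sixframe import TranslationDB

log = logging.getLogger(__name__)

_SEP = "#"


class SegmentIndex:
    """Concatenated-text substring index over database segments.

    Segments are joined with a separator that cannot occur in a peptide,
    so a single ``str.find`` scan locates within-segment matches only.
    """

    def __init__(self, db: TranslationDB, il_equiv: bool = False):
        self.db = db
        self.il_equiv = il_equiv
        self.starts: list[int] = []
        pos = 0
        parts = []
        for seg in db.segments:
            self.starts.append(pos)
            parts.append(seg.aa_seq)
            pos += len(seg.aa_seq) + 1
        self.text = _SEP.join(parts)
        self.search_text = self.text.replace("I", "J").replace("L", "J") \
            if il_equiv else self.text

    def occurrences(self, peptide: str, limit: int | None = None) -> list[PeptideLocus]:
        """All within-segment occurrences of ``peptide`` (stop at ``limit``)."""
        query = peptide.replace("I", "J").replace("L", "J") \
            if self.il_equiv else peptide
        loci = []
        pos = self.search_text.find(query)
        while pos != -1:
            seg_i = bisect_right(self.starts, pos) - 1
            seg = self.db.segments[seg_i]
            k = pos - self.starts[seg_i]
            m = len(peptide)
            if seg.strand == "+":
                start = seg.start + 3 * k
                end = seg.start + 3 * (k + m)
            else:
                start = seg.end - 3 * (k + m)
                end = seg.end - 3 * k
            loci.append(PeptideLocus(
                peptide=seg.aa_seq[k: k + m], chrom=seg.chrom, strand=seg.strand,
                frame=seg.frame, start=start, end=end, segment_offset=k,
            ))
            if limit is not None and len(loci) >= limit:
                break
            pos = self.search_text.find(query, pos + 1)
        return loci

    def count(self, peptide: str, at_most: int = 2) -> int:
        """Occurrence count, stopping early once ``at_most`` are seen."""
        return len(self.occurrences(peptide, limit=at_most))


def _index_for(db: TranslationDB, il_equiv: bool) -> SegmentIndex:
    cache = getattr(db, "_segment_index", None)
    if cache is None or cache.il_equiv != il_equiv:
        cache = SegmentIndex(db, il_equiv=il_equiv)
        db._segment_index = cache
    return cache


def locate_peptide(
    peptide: str, db: TranslationDB, il_equiv: bool = False
) -> list[PeptideLocus]:
    """One locus per occurrence of ``peptide`` in any database segment.

    With ``il_equiv`` Ile and Leu match interchangeably (MS cannot tell
    them apart); the returned locus carries the genome-derived residues.
    """
    peptide = peptide.upper()
    if not peptide or not set(peptide) <= STANDARD_AA:
        raise ValueError(f"illegal residue in peptide {peptide!r}")
    return _index_for(db, il_equiv).occurrences(peptide)


def map_peptides(
    peptides, db: TranslationDB, il_equiv: bool = False, min_pep_len: int = 6
) -> dict[str, list[PeptideLocus]]:
    """Locate each peptide; peptides shorter than ``min_pep_len`` are skipped."""
    located: dict[str, list[PeptideLocus]] = {}
    n_short = 0
    for pep in dict.fromkeys(peptides):  # preserve order, drop duplicates
        if len(pep) < min_pep_len:
            n_short += 1
            continue
        located[pep] = locate_peptide(pep, db, il_equiv=il_equiv)
    if n_short:
        log.info("%d peptides below the minimum mapping length %d skipped",
                 n_short, min_pep_len)
    return located


def unique_locus_filter(
    located: dict[str, list[PeptideLocus]]
) -> tuple[dict[str, PeptideLocus], dict[str, int]]:
    """Partition peptides into single-locus keepers and multiplicity rejects.

    Peptides hitting zero loci appear in ``discarded`` with count 0 (an
    identified sequence absent from the database is worth a warning).
    """
    kept: dict[str, PeptideLocus] = {}
    discarded: dict[str, int] = {}
    for pep, loci in located.items():
        if len(loci) == 1:
            kept[pep] = loci[0]
        else:
            discarded[pep] = len(loci)
            if not loci:
                log.warning("peptide %s not found in the database", pep)
    return kept, discarded
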