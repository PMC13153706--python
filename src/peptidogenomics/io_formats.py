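"""Readers and writers for the formats the pipeline exchanges.

FASTA for genomes and translation databases, GFF3 for gene annotation,
BED6 for peptide loci, and TSV for peptide identification tables.  GFF3
uses 1-based inclusive coordinates on disk; everything in memory is
0-based half-open (see :mod:`peptidogenomics.models`).
"""

from __future__ import annotations

import logging
import os
import tempfile
from dataclasses import dataclass

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .models import STANDARD_AA, GeneModel, Genome, PeptideLocus

log = logging.getLogger(__name__)

ID_TABLE_COLUMNS = ["peptide", "tissue", "sample", "abundance", "score", "fdr"]


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path) -> Genome:
    """Read a genome FASTA; sequences are case-folded to uppercase."""
    chromosomes: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in chromosomes:
            raise ValueError(f"duplicate FASTA record name: {record.id!r}")
        chromosomes[record.id] = str(record.seq).upper()
    if not chromosomes:
        raise ValueError(f"no FASTA records in {path}")
    return Genome(chromosomes)


def write_fasta(genome: Genome, path, width: int = 70) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in genome.chromosomes.items()
    ]
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=width)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# GFF3

_KNOWN_FEATURES = {
    "gene", "mRNA", "transcript", "exon", "CDS",
    "five_prime_UTR", "three_prime_UTR",
}


def read_gff3(path) -> list[GeneModel]:
    """Read gene models from GFF3, grouped by transcript via Parent links.

    CDS features must carry a numeric phase.  Children must lie within
    their gene's span.  Unknown feature types are skipped with a warning.
    """
    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    unknown = {
        ft for ft in db.featuretypes() if ft not in _KNOWN_FEATURES
    }
    for ft in sorted(unknown):
        log.warning("ignoring unknown GFF3 feature type %r", ft)

    models = []
    for kind in ("mRNA", "transcript"):
        for tx in db.features_of_type(kind):
            gene_id = tx.attributes.get("Parent", [tx.id])[0]
            try:
                gene = db[gene_id]
                gene_span = (gene.start - 1, gene.end)
            except gffutils.FeatureNotFoundError:
                gene_span = None
            exons, cds, utr5, utr3 = [], [], [], []
            for child in db.children(tx.id):
                iv = (child.start - 1, child.end)
                if gene_span and not (gene_span[0] <= iv[0] and iv[1] <= gene_span[1]):
                    raise ValueError(
                        f"feature {child.featuretype} [{iv[0]},{iv[1]}) not contained "
                        f"in gene {gene_id} span {gene_span}"
                    )
                if child.featuretype == "exon":
                    exons.append(iv)
                elif child.featuretype == "CDS":
                    if child.frame not in ("0", "1", "2"):
                        raise ValueError(
                            f"CDS of {tx.id} lacks a phase (got {child.frame!r})"
                        )
                    cds.append((iv[0], iv[1], int(child.frame)))
                elif child.featuretype == "five_prime_UTR":
                    utr5.append(iv)
                elif child.featuretype == "three_prime_UTR":
                    utr3.append(iv)
            if not exons:
                log.warning("transcript %s has no exons; skipped", tx.id)
                continue
            models.append(GeneModel(
                gene_id=gene_id, transcript_id=tx.id, chrom=tx.seqid,
                strand=tx.strand, exons=exons, cds=cds, utr5=utr5, utr3=utr3,
            ))
    return models


def write_gff3(models: list[GeneModel], path) -> None:
    """Write gene models as GFF3 (gene + mRNA + exon/CDS/UTR features)."""
    lines = ["##gff-version 3"]
    by_gene: dict[str, list[GeneModel]] = {}
    for m in models:
        by_gene.setdefault(m.gene_id, []).append(m)
    for gene_id, txs in by_gene.items():
        chrom = txs[0].chrom
        strand = txs[0].strand
        gs = min(m.span[0] for m in txs)
        ge = max(m.span[1] for m in txs)
        lines.append(
            f"{chrom}\tpepgen\tgene\t{gs + 1}\t{ge}\t.\t{strand}\t.\tID={gene_id}"
        )
        for m in txs:
            s, e = m.span
            lines.append(
                f"{chrom}\tpepgen\tmRNA\t{s + 1}\t{e}\t.\t{strand}\t.\t"
                f"ID={m.transcript_id};Parent={gene_id}"
            )
            for xs, xe in m.exons:
                lines.append(
                    f"{chrom}\tpepgen\texon\t{xs + 1}\t{xe}\t.\t{strand}\t.\t"
                    f"Parent={m.transcript_id}"
                )
            for cs, ce, phase in m.cds:
                lines.append(
                    f"{chrom}\tpepgen\tCDS\t{cs + 1}\t{ce}\t.\t{strand}\t{phase}\t"
                    f"Parent={m.transcript_id}"
                )
            for us, ue in m.utr5:
                lines.append(
                    f"{chrom}\tpepgen\tfive_prime_UTR\t{us + 1}\t{ue}\t.\t{strand}\t.\t"
                    f"Parent={m.transcript_id}"
                )
            for us, ue in m.utr3:
                lines.append(
                    f"{chrom}\tpepgen\tthree_prime_UTR\t{us + 1}\t{ue}\t.\t{strand}\t.\t"
                    f"Parent={m.transcript_id}"
                )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# BED6

def write_bed(loci: list[PeptideLocus], path) -> None:
    """Write peptide loci as BED6, sorted by (chrom, start)."""
    rows = sorted(loci, key=lambda l: (l.chrom, l.start))
    with open(path, "w") as fh:
        for l in rows:
            fh.write(f"{l.chrom}\t{l.start}\t{l.end}\t{l.peptide}\t0\t{l.strand}\n")


def read_bed(path) -> list[PeptideLocus]:
    """Read BED6 peptide loci written by :func:`write_bed`.

    The frame is reconstructed from the coordinates (reading offset of the
    interval start on the reading strand is not recoverable from BED alone,
    so frame is set to start mod 3 on '+' and 0 on '-'); mapping output that
    must preserve frames uses the TSV report instead.
    """
    loci = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            chrom, start, end, name, _score, strand = line.rstrip("\n").split("\t")[:6]
            loci.append(PeptideLocus(
                peptide=name, chrom=chrom, strand=strand,
                frame=int(start) % 3 if strand == "+" else 0,
                start=int(start), end=int(end),
            ))
    return loci


# ---------------------------------------------------------------------------
# Identification tables

@dataclass
class IdentificationTable:
    """Peptide identification rows with an FDR pass/fail flag.

    ``rows`` holds every input row plus a boolean ``passes_fdr`` column;
    ``kept`` is the view used downstream (strict ``fdr < threshold``).
    """

    rows: pd.DataFrame
    fdr_threshold: float = 0.05

    @property
    def kept(self) -> pd.DataFrame:
        return self.rows[self.rows["passes_fdr"]]

    @property
    def peptides(self) -> list[str]:
        return sorted(self.kept["peptide"].unique())


def make_id_table(df: pd.DataFrame, fdr_threshold: float = 0.05) -> IdentificationTable:
    """Validate a raw identification DataFrame and apply the FDR flag."""
    missing = [c for c in ID_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"identification table missing columns: {missing}")
    df = df[ID_TABLE_COLUMNS].copy()
    df["peptide"] = df["peptide"].astype(str).str.upper()
    bad = df.loc[~df["peptide"].map(lambda p: bool(p) and set(p) <= STANDARD_AA), "peptide"]
    if len(bad):
        raise ValueError(f"illegal residue in peptide {bad.iloc[0]!r}")
    for col in ("abundance", "score", "fdr"):
        df[col] = pd.to_numeric(df[col], errors="raise")
    if (df["abundance"] < 0).any():
        raise ValueError("negative abundance")
    if ((df["fdr"] < 0) | (df["fdr"] > 1)).any():
        raise ValueError("fdr outside [0,1]")
    df["passes_fdr"] = df["fdr"] < fdr_threshold
    n_fail = int((~df["passes_fdr"]).sum())
    if n_fail:
        log.info("%d identification rows excluded at FDR >= %g", n_fail, fdr_threshold)
    return IdentificationTable(rows=df, fdr_threshold=fdr_threshold)


def read_id_table(path, fdr_threshold: float = 0.05) -> IdentificationTable:
    """Read a TSV identification table (peptide/tissue/sample/abundance/score/fdr)."""
    df = pd.read_csv(path, sep="\t")
    return make_id_table(df, fdr_threshold=fdr_threshold)


def write_id_table(table: IdentificationTable | pd.DataFrame, path) -> None:
    df = table.rows if isinstance(table, IdentificationTable) else table
    df[ID_TABLE_COLUMNS].to_csv(path, sep="\t", index=False)


# round-trip helper used by tests and the GFF3 round-trip invariant
def gff3_roundtrip(models: list[GeneModel]) -> list[GeneModel]:
    with tempfile.NamedTemporaryFile("w", suffix=".gff3", delete=False) as fh:
        path = fh.name
    try:
        write_gff3(models, path)
        return read_gff3(path)
    finally:
        os.unlink(path)
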