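"""Coordinate-tracked six-frame translation of a genome.

The database is the set of maximal stop-free codon runs ("segments") of at
least ``min_len`` residues, for every chromosome x strand x frame.  Each
segment records the forward-strand genomic interval it was read from, so a
peptide hit inside a segment maps back to an exact genomic locus.

Ambiguous nucleotides are resolved to concrete bases before translation by
a per-position deterministic random draw, so the same (genome, seed) pair
always yields the same database.
"""

from __future__ import annotations

import json
import random
import re
import zlib
from dataclasses import dataclass, field

import numpy as np
from Bio.Data import CodonTable, IUPACData

from .models import Genome

_RUN_RE = re.compile(r"[^*]+")

_COMPLEMENT = str.maketrans("ACGTMRWSYKVHDBN", "TGCAKYWSRMBDHVN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# fast vectorized codon translation (standard genetic code, '*' for stops)
_BASE_INDEX = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _BASE_INDEX[ord(_b)] = _i

_CODON_AA = np.zeros(64, dtype=np.uint8)
_table = CodonTable.unambiguous_dna_by_id[1]
for _c0 in "ACGT":
    for _c1 in "ACGT":
        for _c2 in "ACGT":
            _codon = _c0 + _c1 + _c2
            _idx = ("ACGT".index(_c0) * 16 + "ACGT".index(_c1) * 4
                    + "ACGT".index(_c2))
            _aa = "*" if _codon in _table.stop_codons else _table.forward_table[_codon]
            _CODON_AA[_idx] = ord(_aa)


def translate_codons(seq: str) -> str:
    """Translate an ACGT string codon-by-codon; trailing partial codon dropped."""
    n = len(seq) // 3
    if n == 0:
        return ""
    arr = _BASE_INDEX[np.frombuffer(seq[: 3 * n].encode(), dtype=np.uint8)]
    if arr.max(initial=0) > 3:
        raise ValueError("sequence contains unresolved non-ACGT symbols")
    codons = arr.reshape(-1, 3)
    idx = codons[:, 0] * 16 + codons[:, 1] * 4 + codons[:, 2]
    return _CODON_AA[idx].tobytes().decode("ascii")


# ---------------------------------------------------------------------------
# Ambiguity resolution

_AMBIG = {
    sym.upper(): sorted(bases.upper())
    for sym, bases in IUPACData.ambiguous_dna_values.items()
}


def resolve_ambiguity(sequence: str, seed: int, chrom: str = "") -> str:
    """Replace every ambiguity symbol by a random base it denotes.

    The draw at each position uses a generator seeded from
    (seed, chrom, position), so the result depends only on the inputs and
    single positions can be re-resolved independently.
    """
    sequence = sequence.upper()
    chrom_key = zlib.crc32(chrom.encode())
    out = list(sequence)
    for pos, ch in enumerate(sequence):
        if ch in "ACGT":
            continue
        try:
            choices = _AMBIG[ch]
        except KeyError:
            raise ValueError(f"symbol {ch!r} at position {pos} is not IUPAC")
        if len(choices) == 1:
            out[pos] = choices[0]
            continue
        rng = random.Random((seed << 34) ^ (chrom_key << 2) ^ pos)
        out[pos] = rng.choice(choices)
    return "".join(out)


def resolve_genome(genome: Genome, seed: int) -> Genome:
    """Resolve every chromosome's ambiguity codes; returns a new Genome."""
    return Genome({
        name: resolve_ambiguity(seq, seed, chrom=name)
        for name, seq in genome.chromosomes.items()
    })


# ---------------------------------------------------------------------------
# Segments and database

@dataclass(frozen=True, slots=True)
class SixFrameSegment:
    """One maximal stop-free translation run with its genomic interval."""

    chrom: str
    strand: str
    frame: int
    start: int
    end: int
    aa_seq: str

    def __post_init__(self):
        if self.end - self.start != 3 * len(self.aa_seq):
            raise ValueError("interval length is not 3 x residue count")
        if "*" in self.aa_seq or not self.aa_seq:
            raise ValueError("segment sequence must be non-empty and stop-free")

    @property
    def header(self) -> str:
        return f"{self.chrom}|{self.strand}|{self.frame}|{self.start}|{self.end}"


def translate_frame(
    chrom_seq: str, chrom_name: str, strand: str, frame: int, min_len: int
) -> list[SixFrameSegment]:
    """Translate one strand/frame of a resolved chromosome into segments.

    On '-' the reverse complement is read; segment coordinates are mapped
    back to forward-strand intervals (end-anchored reversal).
    """
    if strand not in "+-":
        raise ValueError(f"bad strand {strand!r}")
    if frame not in (0, 1, 2):
        raise ValueError(f"bad frame {frame!r}")
    length = len(chrom_seq)
    reading = chrom_seq if strand == "+" else reverse_complement(chrom_seq)
    protein = translate_codons(reading[frame:])
    segments = []
    for m in _RUN_RE.finditer(protein):
        if m.end() - m.start() < min_len:
            continue
        # nt interval in reading-strand coordinates
        r_start = frame + 3 * m.start()
        r_end = frame + 3 * m.end()
        if strand == "+":
            start, end = r_start, r_end
        else:
            start, end = length - r_end, length - r_start
        segments.append(SixFrameSegment(
            chrom=chrom_name, strand=strand, frame=frame,
            start=start, end=end, aa_seq=m.group(),
        ))
    return segments


@dataclass
class TranslationDB:
    """A six-frame translation database with provenance metadata."""

    segments: list[SixFrameSegment]
    genome_digest: str
    seed: int
    min_len: int
    resolved_genome: Genome | None = field(default=None, repr=False, compare=False)

    def __len__(self) -> int:
        return len(self.segments)

    def to_fasta(self, path, sidecar: bool = True) -> None:
        with open(path, "w") as fh:
            for seg in self.segments:
                fh.write(f">{seg.header}\n{seg.aa_seq}\n")
        if sidecar:
            meta = {
                "genome_digest": self.genome_digest,
                "seed": self.seed,
                "min_len": self.min_len,
                "n_segments": len(self.segments),
            }
            with open(str(path) + ".json", "w") as fh:
                json.dump(meta, fh, indent=1)

    @classmethod
    def from_fasta(cls, path) -> "TranslationDB":
        segments = []
        header = None
        chunks: list[str] = []

        def flush():
            if header is None:
                return
            chrom, strand, frame, start, end = header.split("|")
            segments.append(SixFrameSegment(
                chrom=chrom, strand=strand, frame=int(frame),
                start=int(start), end=int(end), aa_seq="".join(chunks),
            ))

        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if line.startswith(">"):
                    flush()
                    header = line[1:]
                    chunks = []
                elif line:
                    chunks.append(line)
            flush()
        try:
            with open(str(path) + ".json") as fh:
                meta = json.load(fh)
        except FileNotFoundError:
            meta = {"genome_digest": "", "seed": -1, "min_len": 0}
        return cls(
            segments=segments, genome_digest=meta["genome_digest"],
            seed=meta["seed"], min_len=meta["min_len"],
        )


def build_sixframe_db(
    genome: Genome, seed: int, min_len: int = 5, resolved: Genome | None = None
) -> TranslationDB:
    """Build the six-frame database for a genome.

    If ``resolved`` is given it must be the ambiguity-resolved version of
    ``genome`` (same seed); otherwise it is computed here.  The resolved
    genome is kept on the returned database so locus re-extraction and
    start-codon readout see exactly the sequence that was translated.
    """
    if resolved is None:
        resolved = resolve_genome(genome, seed)
    segments = []
    for name, seq in resolved.chromosomes.items():
        for strand in "+-":
            for frame in (0, 1, 2):
                segments.extend(translate_frame(seq, name, strand, frame, min_len))
    return TranslationDB(
        segments=segments, genome_digest=resolved.digest(), seed=seed,
        min_len=min_len, resolved_genome=resolved,
    )


def extract_locus_nt(genome: Genome, chrom: str, strand: str, start: int, end: int) -> str:
    """The nucleotide sequence read at a locus (reverse-complemented on '-')."""
    nt = genome[chrom][start:end]
    return nt if strand == "+" else reverse_complement(nt)
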