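"""Support of NCPs by non-coding RNA and ribosome-profiling evidence.

Transcripts (lncRNA, circRNA, Ribo-seq ORFs) are translated in silico in
the three sense-strand frames and split into stop-free runs; an NCP is
supported by a transcript class when its sequence is a contiguous
substring of any run.  Circular RNAs are doubled head-to-tail before
translation so peptides spanning the back-splice junction are findable;
the doubling itself bounds any run below two laps of the circle, which
rules out unbounded rolling-circle products.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd
from Bio import SeqIO

from .classify import pct
from .sixframe import translate_codons

log = logging.getLogger(__name__)

KINDS = ("lncRNA", "circRNA", "riboseq_orf")

#: short kind labels used in report columns
KIND_COLUMNS = {"lncRNA": "lncRNA", "circRNA": "circRNA", "riboseq_orf": "riboseq"}


@dataclass(frozen=True)
class TranscriptRecord:
    transcript_id: str
    kind: str
    sequence: str

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ValueError(f"unknown transcript kind {self.kind!r}")


def transcript_translations(record: TranscriptRecord) -> set[str]:
    """Stop-free runs from the three sense-frame translations.

    circRNA sequences are doubled before translation; runs shorter than
    one residue never arise.  Sequences under 3 nt yield an empty set.
    """
    seq = record.sequence.upper()
    if len(seq) < 3:
        log.warning("transcript %s shorter than one codon", record.transcript_id)
        return set()
    template = seq + seq if record.kind == "circRNA" else seq
    runs: set[str] = set()
    for frame in (0, 1, 2):
        protein = translate_codons(template[frame:])
        runs.update(run for run in protein.split("*") if run)
    return runs


def match_support(
    ncps, records: list[TranscriptRecord]
) -> tuple[pd.DataFrame, dict[str, int | float]]:
    """Per-NCP support flags and per-kind totals.

    The union total counts a peptide supported by several kinds once; its
    percentage of all NCPs is reported to one decimal place.
    """
    ncps = list(dict.fromkeys(ncps))
    texts: dict[str, str] = {}
    for kind in KINDS:
        runs = set()
        for rec in records:
            if rec.kind == kind:
                runs.update(transcript_translations(rec))
        texts[kind] = "#".join(sorted(runs))
    flags = pd.DataFrame(
        {
            KIND_COLUMNS[kind]: [pep in texts[kind] for pep in ncps]
            for kind in KINDS
        },
        index=pd.Index(ncps, name="peptide"),
    )
    union = flags.any(axis=1)
    totals: dict[str, int | float] = {
        f"n_{col}": int(flags[col].sum()) for col in flags.columns
    }
    totals["n_supported"] = int(union.sum())
    totals["n_ncps"] = len(ncps)
    totals["supported_pct"] = pct(int(union.sum()), len(ncps), decimals=1)
    return flags, totals


def read_transcripts(fasta_path, kinds_path) -> list[TranscriptRecord]:
    """Read transcript sequences plus a two-column TSV (transcript_id, kind)."""
    kinds = pd.read_csv(kinds_path, sep="\t")
    kind_of = dict(zip(kinds["transcript_id"], kinds["kind"]))
    records = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id not in kind_of:
            raise ValueError(f"transcript {rec.id!r} has no kind assignment")
        records.append(TranscriptRecord(rec.id, kind_of[rec.id], str(rec.seq).upper()))
    return records


def write_transcripts(records: list[TranscriptRecord], fasta_path, kinds_path) -> None:
    with open(fasta_path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.transcript_id}\n{rec.sequence}\n")
    pd.DataFrame(
        [(r.transcript_id, r.kind) for r in records],
        columns=["transcript_id", "kind"],
    ).to_csv(kinds_path, sep="\t", index=False)
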