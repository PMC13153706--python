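#!/usr/bin/env python
"""Summarize the six-frame translation database built for the study genome.

The database itself (written by 01_simulate_study.py) records, for every
stop-free translation run, its chromosome, strand, frame, and exact
genomic interval, which is what later makes peptide hits traceable to
single loci.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
from _paths import RESULTS, SCRATCH

from peptidogenomics.sixframe import TranslationDB


def main():
    db = TranslationDB.from_fasta(SCRATCH / "db.fa")
    lengths = np.array([len(s.aa_seq) for s in db.segments])
    rows = []
    for strand in "+-":
        for frame in (0, 1, 2):
            n = sum(1 for s in db.segments
                    if s.strand == strand and s.frame == frame)
            rows.append({"strand": strand, "frame": frame, "n_segments": n})
    per_frame = pd.DataFrame(rows)
    summary = pd.DataFrame([{
        "n_segments": len(db),
        "total_residues": int(lengths.sum()),
        "min_segment_len": int(lengths.min()),
        "median_segment_len": float(np.median(lengths)),
        "max_segment_len": int(lengths.max()),
        "genome_digest": db.genome_digest,
    }])
    per_frame.to_csv(RESULTS / "02_db_per_frame.tsv", sep="\t", index=False)
    summary.to_csv(RESULTS / "02_db_summary.tsv", sep="\t", index=False)
    print(summary.to_string(index=False))
    print(per_frame.to_string(index=False))


if __name__ == "__main__":
    main()
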