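#!/usr/bin/env python
"""Chromosome-scale distribution of CP and NCP loci.

Sliding-window density (6 Mb / 3 Mb), hotspot windows (count > 10),
nearest-neighbour spacing against the 100-kb cutoff, distances to
translation initiation sites, arm-normalized positions, and the
peptide-count versus chromosome-length correlation.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
from _paths import RESULTS, SCRATCH

from peptidogenomics import distribution as dist
from peptidogenomics import io_formats as iof
from peptidogenomics.models import LocusCategory, PeptideLocus


def _loci(table):
    return [
        PeptideLocus(peptide=r.peptide, chrom=r.chrom, strand=r.strand,
                     frame=int(r.frame), start=int(r.start), end=int(r.end))
        for r in table.itertuples()
    ]


def main():
    classified = pd.read_csv(SCRATCH / "classified.tsv", sep="\t")
    genome = iof.read_fasta(SCRATCH / "genome.fa")
    models = iof.read_gff3(SCRATCH / "annotation.gff3")
    lengths = genome.lengths
    conf = dist.DistributionConfig()

    rows = []
    for label, sub in (
            ("CP", classified[classified["category"] == LocusCategory.CP.value]),
            ("NCP", classified[classified["category"] != LocusCategory.CP.value])):
        loci = _loci(sub)
        profile = dist.window_density(loci, lengths, conf, label=label)
        hot = dist.detect_hotspots(profile, conf)
        distances, frac = dist.adjacent_spacing(loci, cutoff=conf.spacing_cutoff)
        tssd, tss_share, n_undef = dist.tss_distances(
            loci, models, tss_window=conf.tss_window)
        arm = dist.arm_normalized_positions(loci, lengths)
        counts = [sum(l.chrom == c for l in loci) for c in lengths]
        row = {
            "class": label, "n_loci": len(loci),
            "hotspot_windows": len(hot),
            "hotspot_regions_merged": len(dist.merge_hotspots(hot)),
            "spacing_lt_100kb_frac": round(frac, 4),
            "tss_within_700bp_share": round(tss_share, 4),
            "mean_arm_position": round(float(np.mean(arm)), 4),
        }
        if len(lengths) >= 3:
            r, p = dist.count_length_correlation(counts, list(lengths.values()))
            row.update(count_length_r=round(r, 3), count_length_p=p)
        rows.append(row)
        pd.DataFrame(
            [(c, ws, we, n) for c, wins in profile.windows.items()
             for ws, we, n in wins],
            columns=["chrom", "window_start", "window_end", "count"],
        ).to_csv(RESULTS / f"04_density_{label}.tsv", sep="\t", index=False)

    summary = pd.DataFrame(rows)
    summary.to_csv(RESULTS / "04_distribution_summary.tsv", sep="\t", index=False)
    print(summary.to_string(index=False))


if __name__ == "__main__":
    main()
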