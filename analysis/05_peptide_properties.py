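#!/usr/bin/env python
"""Physicochemical profile of CPs and NCPs and the indolicidin comparison.

Length, average molecular weight, isoelectric point, the fixed
8-hydrophobic / 11-hydrophilic residue composition, genomic start-codon
usage (AUG vs non-AUG), and the ungapped percent identity of the
spleen-specific NCP LPWKWPWW against bovine indolicidin.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
from _paths import RESULTS, SCRATCH

from peptidogenomics import io_formats as iof
from peptidogenomics.models import LocusCategory, PeptideLocus
from peptidogenomics.properties import percent_identity, properties_table

INDOLICIDIN = "ILPWKWPWWPWRR"


def main():
    classified = pd.read_csv(SCRATCH / "classified.tsv", sep="\t")
    resolved = iof.read_fasta(SCRATCH / "resolved_genome.fa")
    loci = {
        r.peptide: PeptideLocus(
            peptide=r.peptide, chrom=r.chrom, strand=r.strand,
            frame=int(r.frame), start=int(r.start), end=int(r.end))
        for r in classified.itertuples()
    }
    props = properties_table(loci, genome=resolved)
    props = props.merge(classified[["peptide", "category"]], on="peptide")
    props["is_cp"] = props["category"] == LocusCategory.CP.value
    props.to_csv(SCRATCH / "properties.tsv", sep="\t", index=False)

    rows = []
    for label, sub in (("CP", props[props["is_cp"]]),
                       ("NCP", props[~props["is_cp"]])):
        rows.append({
            "class": label, "n": len(sub),
            "mean_length": round(sub["length"].mean(), 2),
            "mean_mw_da": round(sub["mw"].mean(), 3),
            "mean_pi": round(sub["pi"].mean(), 3),
            "hydrophobic_total": int(sub["n_hydrophobic"].sum()),
            "hydrophilic_total": int(sub["n_hydrophilic"].sum()),
            "aug_start_pct": round(100 * sub["is_aug"].mean(), 2),
            "non_aug_start_pct": round(100 * (1 - sub["is_aug"].mean()), 2),
        })
    summary = pd.DataFrame(rows)
    summary.to_csv(RESULTS / "05_properties_summary.tsv", sep="\t", index=False)

    identity = percent_identity("LPWKWPWW", INDOLICIDIN)
    pd.DataFrame([{
        "peptide": "LPWKWPWW", "reference": "indolicidin",
        "percent_identity": identity,
    }]).to_csv(RESULTS / "05_indolicidin_identity.tsv", sep="\t", index=False)
    print(summary.to_string(index=False))
    print(f"LPWKWPWW vs indolicidin: {identity}% identity")


if __name__ == "__main__":
    main()
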