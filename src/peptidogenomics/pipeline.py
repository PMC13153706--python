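"""End-to-end orchestration: database -> mapping -> classification -> reports.

``run_all`` executes every stage on file inputs, logs record counts in and
out of each stage, and emits one machine-readable summary mirroring the
study's headline tables: CP/NCP counts and percentages, per-category NCP
counts, strand tallies, hotspot counts per class, spacing fractions,
start-codon usage, tissue-pattern counts, and ncRNA/Ribo-seq support.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import distribution as dist
from . import io_formats as iof
from .classify import GeneIndex, classify_loci, cp_ncp_partition, pct
from .mapping import map_peptides, unique_locus_filter
from .models import LocusCategory
from .ncrna import match_support, read_transcripts
from .properties import properties_table
from .sixframe import build_sixframe_db, resolve_genome
from .tissue import AbundanceMatrix, classify_tissue_pattern, overlap_analysis

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All stage parameters with the analysis defaults."""

    seed: int = 17
    min_len: int = 5               # minimum database segment length (residues)
    fdr_threshold: float = 0.05    # strict '<' exclusion
    il_equiv: bool = False
    min_pep_len: int = 6           # minimum peptide length for mapping
    window_size: int = 6_000_000
    step: int = 3_000_000
    hotspot_threshold: int = 10
    spacing_cutoff: int = 100_000
    tss_window: int = 700
    fold_threshold: float = 15.0

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)

    def dist_config(self) -> dist.DistributionConfig:
        return dist.DistributionConfig(
            window_size=self.window_size, step=self.step,
            hotspot_threshold=self.hotspot_threshold,
            spacing_cutoff=self.spacing_cutoff, tss_window=self.tss_window,
        )


def run_all(
    config: PipelineConfig,
    genome_path,
    gff_path,
    ids_path,
    transcripts_path=None,
    kinds_path=None,
    abundance_path=None,
    out_dir=None,
) -> dict:
    """Run every pipeline stage and return the summary report dict."""
    report: dict = {"config": config.as_dict(), "stages": {}}

    def stage(name, n_in, n_out):
        log.info("stage %s: %d in, %d out", name, n_in, n_out)
        report["stages"][name] = {"in": n_in, "out": n_out,
                                  "discarded": n_in - n_out}

    genome = iof.read_fasta(genome_path)
    models = iof.read_gff3(gff_path)
    id_table = iof.read_id_table(ids_path, fdr_threshold=config.fdr_threshold)
    stage("fdr_filter", len(id_table.rows), len(id_table.kept))

    resolved = resolve_genome(genome, config.seed)
    db = build_sixframe_db(genome, config.seed, min_len=config.min_len,
                           resolved=resolved)
    report["db"] = {"n_segments": len(db), "genome_digest": db.genome_digest}

    peptides = id_table.peptides
    located = map_peptides(peptides, db, il_equiv=config.il_equiv,
                           min_pep_len=config.min_pep_len)
    kept, discarded = unique_locus_filter(located)
    stage("unique_locus", len(peptides), len(kept))
    report["mapping"] = {
        "n_identified": len(peptides),
        "n_mapped_unique": len(kept),
        "n_multi_locus": sum(1 for n in discarded.values() if n > 1),
        "n_unmatched": sum(1 for n in discarded.values() if n == 0),
    }

    index = GeneIndex(models, chromosomes=set(genome.chromosomes))
    classified = classify_loci(kept, index)
    part = cp_ncp_partition(classified)
    report["classification"] = {
        "n_total": part.n_total, "n_cp": part.n_cp, "n_ncp": part.n_ncp,
        "cp_pct": part.cp_pct, "ncp_pct": part.ncp_pct,
        "category_counts": part.category_counts,
        "category_pct": part.category_pct,
        "ncp_strand_counts": part.ncp_strand_counts,
        "cp_strand_counts": part.cp_strand_counts,
    }

    dconf = config.dist_config()
    lengths = genome.lengths
    is_cp = classified["category"] == LocusCategory.CP.value
    loci_cp = [kept[p] for p in classified.loc[is_cp, "peptide"]]
    loci_ncp = [kept[p] for p in classified.loc[~is_cp, "peptide"]]
    report["distribution"] = {}
    for label, loci in (("CP", loci_cp), ("NCP", loci_ncp)):
        profile = dist.window_density(loci, lengths, dconf, label=label)
        hot = dist.detect_hotspots(profile, dconf)
        distances, frac = dist.adjacent_spacing(loci, cutoff=dconf.spacing_cutoff)
        entry = {
            "n_loci": len(loci),
            "n_hotspot_windows": len(hot),
            "n_hotspot_regions": len(dist.merge_hotspots(hot)),
            "spacing_fraction_below_cutoff":
                round(frac, 4) if frac == frac else None,
        }
        if len(loci) >= 3 and len(lengths) >= 3:
            counts = [sum(l.chrom == c for l in loci) for c in lengths]
            try:
                r, p = dist.count_length_correlation(counts, list(lengths.values()))
                entry["count_length_r"] = round(r, 4)
                entry["count_length_p"] = p
            except ValueError:
                pass
        report["distribution"][label] = entry

    props = properties_table(kept, genome=resolved, db=db)
    n_aug = int(props["is_aug"].sum())
    report["properties"] = {
        "mean_length": round(float(props["length"].mean()), 2),
        "mean_mw": round(float(props["mw"].mean()), 3),
        "aug_fraction": pct(n_aug, len(props)),
        "non_aug_fraction": pct(len(props) - n_aug, len(props)),
    }

    if abundance_path is not None:
        replicates = pd.read_csv(abundance_path, sep="\t")
        matrix = AbundanceMatrix.from_replicates(replicates)
        classes = classify_tissue_pattern(matrix, fold_threshold=config.fold_threshold)
        pairwise, _ = overlap_analysis(matrix.detected)
        report["tissue"] = {
            "class_counts": classes["tissue_class"].value_counts().to_dict(),
            "pairwise_overlap": pairwise.to_dict(),
        }

    if transcripts_path is not None and kinds_path is not None:
        records = read_transcripts(transcripts_path, kinds_path)
        ncp_peps = classified.loc[~is_cp, "peptide"].tolist()
        flags, totals = match_support(ncp_peps, records)
        report["support"] = totals

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        classified.to_csv(out_dir / "classified.tsv", sep="\t", index=False)
        props.to_csv(out_dir / "properties.tsv", sep="\t", index=False)
        iof.write_bed(list(kept.values()), out_dir / "loci.bed")
        with open(out_dir / "report.json", "w") as fh:
            json.dump(report, fh, indent=1, default=str)
    return report
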