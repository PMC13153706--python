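#!/usr/bin/env python
"""Generate the synthetic study: genome, gene models, peptidome, tissues.

Writes all pipeline inputs (plus the ground truth) under scratch/study/
and a one-row design summary under results/.
"""

import sys
from collections import Counter
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
from _paths import MASTER_SEED, RESULTS, SCRATCH

from peptidogenomics import io_formats as iof
from peptidogenomics.ncrna import write_transcripts
from peptidogenomics.synthetic import simulate_study


def main():
    study = simulate_study(MASTER_SEED)
    iof.write_fasta(study.genome, SCRATCH / "genome.fa")
    iof.write_fasta(study.resolved_genome, SCRATCH / "resolved_genome.fa")
    iof.write_gff3(study.models, SCRATCH / "annotation.gff3")
    iof.write_id_table(iof.make_id_table(study.id_rows), SCRATCH / "ids.tsv")
    study.replicates.to_csv(SCRATCH / "abundance.tsv", sep="\t", index=False)
    study.truth.to_json(SCRATCH / "truth.json")
    write_transcripts(study.transcripts, SCRATCH / "transcripts.fa",
                      SCRATCH / "kinds.tsv")
    study.db.to_fasta(SCRATCH / "db.fa")

    categories = Counter(p.category.value for p in study.truth.peptides.values())
    summary = pd.DataFrame([{
        "seed": MASTER_SEED,
        "n_chromosomes": len(study.genome),
        "genome_bp": sum(study.genome.lengths.values()),
        "n_genes": len(study.models),
        "n_peptides": len(study.truth.peptides),
        **{f"planted_{k}": v for k, v in sorted(categories.items())},
    }])
    summary.to_csv(RESULTS / "01_study_design.tsv", sep="\t", index=False)
    print(summary.to_string(index=False))
    print(f"\ninputs written to {SCRATCH}")


if __name__ == "__main__":
    main()
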