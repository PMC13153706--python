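"""Synthetic genomes, gene models, peptidomes, and tissue matrices.

Every generator is fully determined by its seed and records ground-truth
labels, so each pipeline stage can be tested for exact recovery without
any external data.  Defaults emulate the study conditions: a
multi-megabase multi-chromosome genome, ~50 gene models with exons, CDS
(with phase), UTRs and introns, a peptidome dominated by intergenic and
intronic sources (the observed NCP category mix at an 8% CP share), and
a six-tissue abundance matrix containing specific / enhanced / mixed
patterns around the 15-fold rule.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classify import GeneIndex, classify_locus
from .mapping import SegmentIndex, _index_for
from .models import GeneModel, Genome, LocusCategory, PeptideLocus
from .ncrna import TranscriptRecord
from .sixframe import (
    TranslationDB, build_sixframe_db, extract_locus_nt, resolve_genome,
    reverse_complement, translate_codons,
)
from .tissue import DEFAULT_TISSUES, AbundanceMatrix

log = logging.getLogger(__name__)

_STOPS = ("TAA", "TAG", "TGA")
_NONSTOP_CODONS = [
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in _STOPS
]

#: Category shares mirroring the observed NCP source mix at an 8% CP share.
DEFAULT_CATEGORY_MIX = {
    LocusCategory.CP: 0.08,
    LocusCategory.INTERGENIC: 0.92 * 0.61,
    LocusCategory.INTRON: 0.92 * 0.38,
    LocusCategory.UTR3: 0.92 * 0.006,
    LocusCategory.UTR5: 0.92 * 0.002,
    LocusCategory.OUT_OF_FRAME_EXON: 0.92 * 0.002,
}

#: Tissue-pattern shares mirroring the observed NCP class proportions.
DEFAULT_CLASS_MIX = {"specific": 0.92, "enhanced": 0.016, "mixed": 0.064}


def stage_seed(master_seed: int, stage: int) -> int:
    """Derive a per-stage seed (< 2^31) from one master seed."""
    return (master_seed * 1_000_003 + stage) % (2 ** 31)


# ---------------------------------------------------------------------------
# Genome

def generate_genome(
    seed: int, n_chrom: int = 2, lengths=None, gc: float = 0.42,
    ambiguity_rate: float = 0.001,
) -> Genome:
    """I.i.d. random genome at a given GC fraction with sparse 'N' positions."""
    if lengths is None:
        lengths = [10_000_000] * n_chrom
    lengths = list(lengths)
    if len(lengths) != n_chrom:
        raise ValueError("lengths must match n_chrom")
    if any(l < 10_000 for l in lengths):
        raise ValueError("chromosome lengths must be >= 10 kb")
    if not 0.0 < gc < 1.0:
        raise ValueError("gc must be in (0,1)")
    if not 0.0 <= ambiguity_rate <= 0.05:
        raise ValueError("ambiguity_rate must be in [0, 0.05]")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    alphabet = np.frombuffer(b"ACGT", dtype=np.uint8)
    chromosomes = {}
    for i, length in enumerate(lengths, start=1):
        idx = rng.choice(4, size=length, p=p)
        arr = alphabet[idx]
        if ambiguity_rate > 0:
            mask = rng.random(length) < ambiguity_rate
            arr[mask] = ord("N")
        chromosomes[f"chr{i}"] = arr.tobytes().decode("ascii")
    return Genome(chromosomes)


# ---------------------------------------------------------------------------
# Gene models

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def _spliced_positions(exons, strand) -> list[int]:
    """Genomic positions of the spliced transcript in transcription order."""
    pos = []
    if strand == "+":
        for s, e in exons:
            pos.extend(range(s, e))
    else:
        for s, e in reversed(exons):
            pos.extend(range(e - 1, s - 1, -1))
    return pos


def _spliced_slice_to_intervals(pos_list, a, b) -> list[tuple[int, int]]:
    """Forward-strand genomic intervals covered by spliced indices [a, b)."""
    chunk = sorted(pos_list[a:b])
    intervals = []
    run_start = prev = chunk[0]
    for p in chunk[1:]:
        if p != prev + 1:
            intervals.append((run_start, prev + 1))
            run_start = p
        prev = p
    intervals.append((run_start, prev + 1))
    return intervals


def plant_gene_models(
    genome: Genome, seed: int, n_genes: int = 50, min_intergenic: int = 5_000,
) -> tuple[Genome, list[GeneModel]]:
    """Write non-overlapping gene models into a genome.

    Each gene gets 1-4 exons, a CDS starting ATG and ending at a stop with
    no internal in-frame stops (bases overwritten as needed), flanking
    UTRs, and derived introns.  Genes are separated by at least
    ``min_intergenic`` nt of untouched intergenic sequence.
    """
    rng = np.random.default_rng(seed)
    seqs = {name: bytearray(seq.encode()) for name, seq in genome.chromosomes.items()}
    chrom_names = list(genome.chromosomes)
    total_len = sum(genome.lengths.values())
    per_chrom = {
        name: round(n_genes * genome.lengths[name] / total_len)
        for name in chrom_names
    }
    # fix rounding so counts sum to n_genes
    drift = n_genes - sum(per_chrom.values())
    per_chrom[chrom_names[0]] += drift

    models: list[GeneModel] = []
    gene_no = 0
    for chrom in chrom_names:
        length = genome.lengths[chrom]
        n_here = per_chrom[chrom]
        if n_here == 0:
            continue
        # draw gene structures first so spacing can be checked up front
        structures = []
        for _ in range(n_here):
            while True:
                n_exons = int(rng.integers(1, 5))
                exon_lens = rng.integers(150, 901, n_exons)
                intron_lens = rng.integers(200, 2001, max(n_exons - 1, 0))
                t_len = int(exon_lens.sum())
                utr5_len = int(rng.integers(60, 200))
                utr3_len = int(rng.integers(60, 200))
                cds_len = t_len - utr5_len - utr3_len
                cds_len -= cds_len % 3
                if cds_len >= 120:
                    utr3_len = t_len - utr5_len - cds_len
                    break
            structures.append((exon_lens, intron_lens, utr5_len, cds_len, utr3_len))
        spans = [
            int(ex.sum() + intr.sum()) for ex, intr, *_ in structures
        ]
        free = length - sum(spans) - (n_here + 1) * min_intergenic
        if free < 0:
            raise ValueError(f"insufficient space for {n_here} genes on {chrom}")
        weights = rng.random(n_here + 1)
        extra = (weights / weights.sum() * free).astype(int)

        cursor = 0
        for i, (exon_lens, intron_lens, utr5_len, cds_len, utr3_len) in enumerate(structures):
            cursor += min_intergenic + int(extra[i])
            gene_no += 1
            strand = "+" if rng.random() < 0.5 else "-"
            exons = []
            p = cursor
            for k, el in enumerate(exon_lens):
                exons.append((p, p + int(el)))
                p += int(el)
                if k < len(intron_lens):
                    p += int(intron_lens[k])
            cursor = p
            pos_list = _spliced_positions(exons, strand)
            n_codons = cds_len // 3 - 2  # internal codons besides start and stop
            codons = ["ATG"]
            codons += [
                _NONSTOP_CODONS[int(j)]
                for j in rng.integers(0, len(_NONSTOP_CODONS), n_codons)
            ]
            codons.append(_STOPS[int(rng.integers(0, 3))])
            cds_seq = "".join(codons)
            for j, base in enumerate(cds_seq):
                gpos = pos_list[utr5_len + j]
                seqs[chrom][gpos] = ord(base if strand == "+" else _COMP[base])
            cds_intervals = _spliced_slice_to_intervals(
                pos_list, utr5_len, utr5_len + cds_len)
            # phases in transcription order
            tx_order = cds_intervals if strand == "+" else list(reversed(cds_intervals))
            cds = []
            cum = 0
            for s, e in tx_order:
                cds.append((s, e, (3 - cum % 3) % 3))
                cum += e - s
            gid = f"gene{gene_no}"
            models.append(GeneModel(
                gene_id=gid, transcript_id=f"{gid}.t1", chrom=chrom, strand=strand,
                exons=exons, cds=sorted(cds),
                utr5=_spliced_slice_to_intervals(pos_list, 0, utr5_len),
                utr3=_spliced_slice_to_intervals(
                    pos_list, utr5_len + cds_len, len(pos_list)),
            ))
    edited = Genome({name: bytes(b).decode("ascii") for name, b in seqs.items()})
    return edited, models


# ---------------------------------------------------------------------------
# Peptidome

@dataclass
class HotspotSpec:
    """Extra intergenic peptides to place inside one density window."""

    chrom: str
    start: int
    end: int
    count: int


@dataclass
class PlantedPeptide:
    peptide: str
    category: LocusCategory
    locus: PeptideLocus
    in_hotspot: bool = False
    tissue_class: str | None = None
    defining_tissue: str | None = None
    support: tuple[str, ...] = ()


@dataclass
class SyntheticTruth:
    """Planted labels for recovery testing, plus generator provenance."""

    peptides: dict[str, PlantedPeptide]
    hotspot: HotspotSpec | None
    seed: int
    params: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        payload = {
            "seed": self.seed,
            "params": self.params,
            "hotspot": vars(self.hotspot) if self.hotspot else None,
            "peptides": {
                pep: {
                    "category": pl.category.value,
                    "chrom": pl.locus.chrom, "strand": pl.locus.strand,
                    "frame": pl.locus.frame, "start": pl.locus.start,
                    "end": pl.locus.end, "in_hotspot": pl.in_hotspot,
                    "tissue_class": pl.tissue_class,
                    "defining_tissue": pl.defining_tissue,
                    "support": list(pl.support),
                }
                for pep, pl in self.peptides.items()
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def _frame_of(strand: str, start: int, end: int, chrom_length: int) -> int:
    return start % 3 if strand == "+" else (chrom_length - end) % 3


def _intergenic_gaps(models, chrom_lengths, min_size) -> list[tuple[str, int, int]]:
    spans: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_lengths}
    for m in models:
        spans[m.chrom].append(m.span)
    gaps = []
    for chrom, length in chrom_lengths.items():
        prev = 0
        for s, e in sorted(spans[chrom]) + [(length, length)]:
            if s - prev >= min_size:
                gaps.append((chrom, prev, s))
            prev = max(prev, e)
    return gaps


def _allocate(mix: dict, n: int) -> dict:
    """Largest-remainder allocation of n items to the mix's shares."""
    total = sum(mix.values())
    if abs(total - 1.0) > 1e-6:
        raise ValueError("category mix must sum to 1")
    raw = {k: v / total * n for k, v in mix.items()}
    counts = {k: int(v) for k, v in raw.items()}
    remainder = n - sum(counts.values())
    for k in sorted(raw, key=lambda k: raw[k] - counts[k], reverse=True)[:remainder]:
        counts[k] += 1
    return counts


class _PeptidePlanter:
    """Rejection sampler for peptides of a prescribed genomic category."""

    def __init__(self, genome, models, db, rng, length_range, max_attempts=1000):
        self.genome = genome
        self.models = models
        self.db = db
        self.rng = rng
        self.min_m, self.max_m = length_range
        self.max_attempts = max_attempts
        self.index: SegmentIndex = _index_for(db, il_equiv=False)
        self.gene_index = GeneIndex(models, chromosomes=set(genome.chromosomes))
        self.cds_pieces = [
            (m, piece) for m in models for piece in m.cds
            if piece[1] - piece[0] >= 3 * self.min_m + 3
        ]
        self.utr5 = [(m, iv) for m in models for iv in m.utr5
                     if iv[1] - iv[0] >= 3 * self.min_m]
        self.utr3 = [(m, iv) for m in models for iv in m.utr3
                     if iv[1] - iv[0] >= 3 * self.min_m]
        self.introns = [(m, iv) for m in models for iv in m.introns
                        if iv[1] - iv[0] >= 3 * self.min_m]
        self.gaps = _intergenic_gaps(
            models, genome.lengths, min_size=3 * self.min_m)
        self.taken: set[str] = set()

    def _pick(self, pool, category):
        if not pool:
            raise ValueError(
                f"no genomic space to plant a {category.value} peptide")
        return pool[int(self.rng.integers(0, len(pool)))]

    def _candidate(self, category, region=None):
        """One candidate (chrom, strand, start, end) for a category, or None
        when the sampled length does not fit the sampled element."""
        rng = self.rng
        m = int(rng.integers(self.min_m, self.max_m + 1))
        if category is LocusCategory.CP or category is LocusCategory.OUT_OF_FRAME_EXON:
            model, (s, e, phase) = self._pick(self.cds_pieces, category)
            antisense = (category is LocusCategory.OUT_OF_FRAME_EXON
                         and rng.random() < 0.5)
            shift = 0
            if category is LocusCategory.OUT_OF_FRAME_EXON and not antisense:
                shift = int(rng.integers(1, 3))
            if model.strand == "+":
                first = s + phase + shift
                n_slots = (e - first) // 3 - m + 1
                if n_slots < 1:
                    return None
                j = int(rng.integers(0, n_slots))
                a = first + 3 * j
                b = a + 3 * m
            else:
                anchor = e - phase - shift  # codon-boundary end on '-'
                n_slots = (anchor - s) // 3 - m + 1
                if n_slots < 1:
                    return None
                j = int(rng.integers(0, n_slots))
                b = anchor - 3 * j
                a = b - 3 * m
            strand = model.strand
            if antisense:
                strand = "-" if strand == "+" else "+"
                # any codon alignment is fine on the antisense strand
                wiggle = int(rng.integers(0, 3))
                if a + wiggle + 3 * m <= e:
                    a, b = a + wiggle, a + wiggle + 3 * m
            return model.chrom, strand, a, b
        if category is LocusCategory.INTERGENIC:
            if region is not None:
                chrom, s, e = region
            else:
                if not self.gaps:
                    raise ValueError("no intergenic space to plant a peptide")
                chrom, s, e = self.gaps[int(rng.integers(0, len(self.gaps)))]
        else:
            pool = {LocusCategory.UTR5: self.utr5, LocusCategory.UTR3: self.utr3,
                    LocusCategory.INTRON: self.introns}[category]
            model, (s, e) = self._pick(pool, category)
            chrom = model.chrom
        m = min(m, (e - s) // 3)
        if m < self.min_m:
            return None
        strand = "+" if rng.random() < 0.5 else "-"
        a = s + int(rng.integers(0, e - s - 3 * m + 1))
        return chrom, strand, a, a + 3 * m

    def plant(self, category: LocusCategory, region=None) -> PlantedPeptide:
        for _ in range(self.max_attempts):
            cand = self._candidate(category, region=region)
            if cand is None:  # sampled length did not fit; resample
                continue
            chrom, strand, a, b = cand
            aa = translate_codons(
                extract_locus_nt(self.genome, chrom, strand, a, b))
            if "*" in aa or aa in self.taken:
                continue
            locus = PeptideLocus(
                peptide=aa, chrom=chrom, strand=strand,
                frame=_frame_of(strand, a, b, self.genome.lengths[chrom]),
                start=a, end=b,
            )
            if classify_locus(locus, self.gene_index) is not category:
                continue
            occ = self.index.occurrences(aa, limit=2)
            if len(occ) != 1:
                continue
            hit = occ[0]
            if (hit.chrom, hit.strand, hit.start, hit.end) != (chrom, strand, a, b):
                continue
            self.taken.add(aa)
            return PlantedPeptide(peptide=aa, category=category, locus=hit)
        raise ValueError(
            f"could not plant a unique {category.value} peptide "
            f"in {self.max_attempts} attempts"
        )


def plant_peptidome(
    genome: Genome, models: list[GeneModel], db: TranslationDB, seed: int,
    category_mix: dict | None = None, n_peptides: int = 2000,
    length_range: tuple[int, int] = (6, 30), hotspot: HotspotSpec | None = None,
    tissues=DEFAULT_TISSUES, n_fdr_fail: int = 10, max_attempts: int = 1000,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Plant peptides read off the genome in prescribed category proportions.

    ``genome`` must be the ambiguity-resolved genome ``db`` was built from.
    Every planted peptide is verified unique in the database (rejection
    sampling), so the full pipeline can recover it at its planted locus.
    Returns raw identification-table rows (with sub-FDR scores, plus
    ``n_fdr_fail`` deliberately failing rows) and the truth labels.
    """
    if not (6 <= length_range[0] <= length_range[1] <= 30):
        raise ValueError("peptide lengths must lie in [6, 30]")
    mix = dict(category_mix or DEFAULT_CATEGORY_MIX)
    rng = np.random.default_rng(seed)
    planter = _PeptidePlanter(genome, models, db, rng, length_range,
                              max_attempts=max_attempts)
    counts = _allocate(mix, n_peptides)
    planted: dict[str, PlantedPeptide] = {}
    for category, n in counts.items():
        for _ in range(n):
            p = planter.plant(category)
            planted[p.peptide] = p
    if hotspot is not None:
        region_gaps = [
            (c, max(s, hotspot.start), min(e, hotspot.end))
            for c, s, e in planter.gaps
            if c == hotspot.chrom and min(e, hotspot.end) - max(s, hotspot.start)
            >= 3 * length_range[0]
        ]
        if not region_gaps:
            raise ValueError("no intergenic space inside the hotspot window")
        for _ in range(hotspot.count):
            region = region_gaps[int(rng.integers(0, len(region_gaps)))]
            p = planter.plant(LocusCategory.INTERGENIC, region=region)
            p.in_hotspot = True
            planted[p.peptide] = p

    # identification rows: 1-3 tissues per peptide, lognormal intensities
    rows = []
    peps = list(planted)
    for pep in peps:
        k = int(rng.integers(1, 4))
        chosen = rng.choice(len(tissues), size=k, replace=False)
        for t in chosen:
            for rep in range(1, 4):
                rows.append({
                    "peptide": pep, "tissue": tissues[int(t)],
                    "sample": f"{tissues[int(t)]}_{rep}",
                    "abundance": float(10 ** rng.uniform(5, 7)),
                    "score": float(rng.uniform(30, 80)),
                    "fdr": float(rng.uniform(0.0, 0.049)),
                })
    for _ in range(n_fdr_fail):
        pep = peps[int(rng.integers(0, len(peps)))]
        rows.append({
            "peptide": pep, "tissue": tissues[int(rng.integers(0, len(tissues)))],
            "sample": "fdr_fail",
            "abundance": float(10 ** rng.uniform(5, 7)),
            "score": float(rng.uniform(10, 25)),
            "fdr": float(rng.uniform(0.05, 0.3)),
        })
    truth = SyntheticTruth(
        peptides=planted, hotspot=hotspot, seed=seed,
        params={"n_peptides": n_peptides, "length_range": list(length_range),
                "category_mix": {k.value: v for k, v in mix.items()}},
    )
    return pd.DataFrame(rows), truth


# ---------------------------------------------------------------------------
# Tissue matrix

def plant_tissue_matrix(
    peptides, seed: int, class_mix: dict | None = None, fold: float = 15.0,
    sigma: float = 0.2, tissues=DEFAULT_TISSUES, n_replicates: int = 3,
) -> tuple[AbundanceMatrix, pd.DataFrame, pd.DataFrame]:
    """Plant specific / enhanced / mixed abundance patterns.

    Enhanced peptides are planted at twice the fold threshold above every
    other tissue; mixed peptides keep their planted max/min ratio below
    half the threshold; log-normal noise (sigma on the natural-log scale)
    is applied per replicate.  Returns (matrix, truth labels, replicate rows).
    """
    mix = dict(class_mix or DEFAULT_CLASS_MIX)
    if fold <= 2 and mix.get("mixed", 0) > 0:
        raise ValueError("mixed patterns are not plantable at fold <= 2")
    peptides = list(dict.fromkeys(peptides))
    rng = np.random.default_rng(seed)
    counts = _allocate(mix, len(peptides))
    classes = [c for c, n in counts.items() for _ in range(n)]
    rng.shuffle(classes)

    rows = []
    labels = []

    def noisy(mean):
        return mean * np.exp(rng.normal(0.0, sigma))

    for pep, cls in zip(peptides, classes):
        base = 10 ** rng.uniform(5, 7)
        if cls == "specific":
            t = tissues[int(rng.integers(0, len(tissues)))]
            level = {tt: (base if tt == t else 0.0) for tt in tissues}
            defining = t
        elif cls == "enhanced":
            t = tissues[int(rng.integers(0, len(tissues)))]
            n_others = int(rng.integers(1, len(tissues)))
            others = [tt for tt in tissues if tt != t]
            rng.shuffle(others)
            level = {tt: 0.0 for tt in tissues}
            level[t] = base * 2 * fold
            for tt in others[:n_others]:
                level[tt] = base
            defining = t
        else:  # mixed
            k = int(rng.integers(2, len(tissues) + 1))
            chosen = list(tissues)
            rng.shuffle(chosen)
            top = max(1.01, fold / 2 * 0.8)
            level = {tt: 0.0 for tt in tissues}
            for tt in chosen[:k]:
                level[tt] = base * rng.uniform(1.0, top)
            defining = ""
        labels.append((pep, cls, defining))
        for tt in tissues:
            for rep in range(1, n_replicates + 1):
                ab = noisy(level[tt]) if level[tt] > 0 else 0.0
                rows.append({
                    "peptide": pep, "tissue": tt, "sample": f"{tt}_{rep}",
                    "abundance": float(ab),
                })
    replicates = pd.DataFrame(rows)
    matrix = AbundanceMatrix.from_replicates(replicates)
    label_df = pd.DataFrame(
        labels, columns=["peptide", "tissue_class", "defining_tissue"]
    ).set_index("peptide")
    return matrix, label_df, replicates


# ---------------------------------------------------------------------------
# Transcript support

def plant_transcript_support(
    truth: SyntheticTruth, genome: Genome, seed: int,
    n_per_kind: dict | None = None, n_decoys: int = 20,
    flank_range: tuple[int, int] = (30, 120),
) -> tuple[list[TranscriptRecord], dict[str, tuple[str, ...]], list[str]]:
    """Embed planted NCP coding sequences into synthetic transcripts.

    Linear transcripts (lncRNA, Ribo-seq ORFs) carry the peptide's genomic
    coding sequence codon-aligned between random flanks; circRNA monomers
    are rotated so the peptide spans the head-to-tail junction and is only
    recoverable in circular translation mode.  Decoys are scrambled NCP
    sequences verified absent from every transcript translation.
    """
    rng = np.random.default_rng(seed)
    ncps = [p for p in truth.peptides.values()
            if p.category is not LocusCategory.CP]
    if n_per_kind is None:
        per = max(1, min(25, len(ncps) // 3))
        n_per_kind = {"lncRNA": per, "circRNA": per, "riboseq_orf": per}
    need = sum(n_per_kind.values())
    if need > len(ncps):
        raise ValueError("not enough planted NCPs for the requested support sets")
    order = list(rng.permutation(len(ncps)))
    chosen = [ncps[i] for i in order[:need]]
    alphabet = "ACGT"

    def random_nt(n):
        return "".join(alphabet[int(i)] for i in rng.integers(0, 4, n))

    records: list[TranscriptRecord] = []
    support: dict[str, tuple[str, ...]] = {}
    pos = 0
    for kind, n in n_per_kind.items():
        for j in range(n):
            planted = chosen[pos]
            pos += 1
            loc = planted.locus
            insert = extract_locus_nt(genome, loc.chrom, loc.strand, loc.start, loc.end)
            left = random_nt(int(rng.integers(*flank_range)))
            right = random_nt(int(rng.integers(*flank_range)))
            if kind == "circRNA":
                cut = int(rng.integers(1, len(insert)))
                seq = insert[cut:] + left + insert[:cut]
            else:
                seq = left + insert + right
            records.append(TranscriptRecord(f"{kind}_{j + 1}", kind, seq))
            support[planted.peptide] = (kind,)
            planted.support = (kind,)

    # decoys: scrambled planted peptides, verified absent everywhere
    from .ncrna import transcript_translations
    all_runs = "#".join(
        run for rec in records for run in transcript_translations(rec))
    decoys = []
    pool = [p.peptide for p in ncps[need:]] or [p.peptide for p in ncps]
    while len(decoys) < n_decoys and pool:
        pep = pool[int(rng.integers(0, len(pool)))]
        for _ in range(50):
            letters = list(pep)
            rng.shuffle(letters)
            scrambled = "".join(letters)
            if scrambled not in all_runs and scrambled not in truth.peptides:
                decoys.append(scrambled)
                break
        else:
            pool.remove(pep)
    return records, support, decoys


# ---------------------------------------------------------------------------
# The whole synthetic study

@dataclass
class SyntheticStudy:
    """All inputs and truth labels of one simulated study."""

    seed: int
    genome: Genome
    resolved_genome: Genome
    models: list[GeneModel]
    db: TranslationDB
    id_rows: pd.DataFrame
    truth: SyntheticTruth
    matrix: AbundanceMatrix
    tissue_labels: pd.DataFrame
    replicates: pd.DataFrame
    transcripts: list[TranscriptRecord]
    support_truth: dict[str, tuple[str, ...]]
    decoys: list[str]


def simulate_study(
    seed: int, n_chrom: int = 2, chrom_length: int = 10_000_000,
    n_genes: int = 50, n_peptides: int = 2000, min_len: int = 5,
    gc: float = 0.42, ambiguity_rate: float = 0.001,
    category_mix: dict | None = None, hotspot: HotspotSpec | None = None,
    with_support: bool = True,
) -> SyntheticStudy:
    """Run the full generator chain from one master seed."""
    raw = generate_genome(stage_seed(seed, 1), n_chrom=n_chrom,
                          lengths=[chrom_length] * n_chrom, gc=gc,
                          ambiguity_rate=ambiguity_rate)
    genome, models = plant_gene_models(raw, stage_seed(seed, 2), n_genes=n_genes)
    resolved = resolve_genome(genome, stage_seed(seed, 3))
    db = build_sixframe_db(genome, stage_seed(seed, 3), min_len=min_len,
                           resolved=resolved)
    id_rows, truth = plant_peptidome(
        resolved, models, db, stage_seed(seed, 4),
        category_mix=category_mix, n_peptides=n_peptides, hotspot=hotspot)
    # record how to reproduce the ambiguity resolution downstream
    truth.params["master_seed"] = seed
    truth.params["db_seed"] = stage_seed(seed, 3)
    truth.params["db_min_len"] = min_len
    matrix, tissue_labels, replicates = plant_tissue_matrix(
        list(truth.peptides), stage_seed(seed, 5))
    for pep, row in tissue_labels.iterrows():
        truth.peptides[pep].tissue_class = row["tissue_class"]
        truth.peptides[pep].defining_tissue = row["defining_tissue"]
    if with_support:
        transcripts, support_truth, decoys = plant_transcript_support(
            truth, resolved, stage_seed(seed, 6))
    else:
        transcripts, support_truth, decoys = [], {}, []
    return SyntheticStudy(
        seed=seed, genome=genome, resolved_genome=resolved, models=models,
        db=db, id_rows=id_rows, truth=truth, matrix=matrix,
        tissue_labels=tissue_labels, replicates=replicates,
        transcripts=transcripts, support_truth=support_truth, decoys=decoys,
    )
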