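"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive and self-contained: a hand-written
codon table, per-codon loops, all-window scans, and grid searches.  None
of it shares code paths with the package being tested.
"""

from __future__ import annotations

import numpy as np

# hand-written standard genetic code
CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def revcomp(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


def translate(seq: str) -> str:
    return "".join(
        CODON_TABLE[seq[i:i + 3]] for i in range(0, len(seq) - len(seq) % 3, 3)
    )


def sixframe_segments(chrom_seq: str, chrom: str, min_len: int):
    """All maximal stop-free runs of >= min_len residues, with coordinates.

    Returns a set of (chrom, strand, frame, start, end, aa) tuples; '-'
    coordinates are derived from the fact that reading-strand position j
    corresponds to genomic position L-1-j.
    """
    L = len(chrom_seq)
    out = set()
    for strand in "+-":
        reading = chrom_seq if strand == "+" else revcomp(chrom_seq)
        for frame in (0, 1, 2):
            run = []
            run_start = None
            for i in range(frame, L - 2, 3):
                aa = CODON_TABLE[reading[i:i + 3]]
                if aa == "*":
                    if run and len(run) >= min_len:
                        r_start, r_end = run_start, run_start + 3 * len(run)
                        if strand == "+":
                            iv = (r_start, r_end)
                        else:
                            iv = (L - r_end, L - r_start)
                        out.add((chrom, strand, frame, iv[0], iv[1], "".join(run)))
                    run, run_start = [], None
                else:
                    if not run:
                        run_start = i
                    run.append(aa)
            if run and len(run) >= min_len:
                r_start, r_end = run_start, run_start + 3 * len(run)
                iv = (r_start, r_end) if strand == "+" else (L - r_end, L - r_start)
                out.add((chrom, strand, frame, iv[0], iv[1], "".join(run)))
    return out


def locate_all_windows(chrom_seq: str, chrom: str, peptide: str):
    """Translate every 3m-nt window on both strands; return matching loci."""
    m = len(peptide)
    L = len(chrom_seq)
    hits = set()
    for p in range(0, L - 3 * m + 1):
        window = chrom_seq[p:p + 3 * m]
        if translate(window) == peptide:
            hits.add((chrom, "+", p, p + 3 * m))
        if translate(revcomp(window)) == peptide:
            hits.add((chrom, "-", p, p + 3 * m))
    return hits


def grid_scan_pi(peptide: str, pka: dict, coarse: float = 0.01,
                 fine: float = 1e-4) -> float:
    """Isoelectric point by coarse-to-fine grid scan of |net charge|."""

    def charge(ph):
        ph = np.asarray(ph, dtype=float)
        q = 1.0 / (1.0 + 10.0 ** (ph - pka["n_term"]))
        q = q - 1.0 / (1.0 + 10.0 ** (pka["c_term"] - ph))
        for aa in "HKR":
            n = peptide.count(aa)
            if n:
                q = q + n / (1.0 + 10.0 ** (ph - pka[aa]))
        for aa in "DECY":
            n = peptide.count(aa)
            if n:
                q = q - n / (1.0 + 10.0 ** (pka[aa] - ph))
        return q

    grid = np.arange(0.0, 14.0 + coarse, coarse)
    best = grid[np.argmin(np.abs(charge(grid)))]
    grid = np.arange(max(0.0, best - 2 * coarse),
                     min(14.0, best + 2 * coarse) + fine, fine)
    return float(grid[np.argmin(np.abs(charge(grid)))])


def pearson_r(x, y) -> float:
    """Textbook product-moment correlation."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(x, y))
    vx = sum((a - mx) ** 2 for a in x)
    vy = sum((b - my) ** 2 for b in y)
    return cov / (vx ** 0.5 * vy ** 0.5)


def pairwise_overlaps(mask_rows, tissues):
    """Brute-force double loop over peptides x tissue pairs."""
    counts = {}
    for i, ti in enumerate(tissues):
        for j, tj in enumerate(tissues):
            counts[(ti, tj)] = sum(1 for row in mask_rows if row[i] and row[j])
    return counts


def random_genome_string(rng, length: int) -> str:
    return "".join("ACGT"[int(i)] for i in rng.integers(0, 4, length))


def random_peptide(rng, length: int) -> str:
    alphabet = "ACDEFGHIKLMNPQRSTVWY"
    return "".join(alphabet[int(i)] for i in rng.integers(0, 20, length))
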