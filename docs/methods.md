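# Methods

This package implements a peptidogenomic analysis chain for endogenous
peptides: instead of searching mass-spectrometry identifications against an
annotated proteome, peptides are located in a database built by conceptual
six-frame translation of the genome itself, so that peptides from
unannotated regions — intergenic space, introns, UTRs, and off-frame exonic
reading frames — are discoverable. This note records the model, the
parameter choices, the numerical conventions, and what the synthetic data
do and do not establish.

## Coordinate conventions

All intervals are 0-based, half-open, on the forward strand. GFF3 input
and output converts at the boundary (1-based inclusive on disk). A locus on
the '-' strand denotes the reverse complement of its interval; its first
base read is `end - 1`. A peptide of m residues always occupies exactly
3m nt.

## Six-frame translation database

Each chromosome is read on both strands in all three frame offsets.
Translation uses the standard genetic code only; selenocysteine and
pyrrolysine are not modelled. Codon runs are split at every stop codon
(TAA/TAG/TGA); each maximal stop-free run of at least `min_len` residues
becomes one database segment carrying its chromosome, strand, frame, and
exact genomic interval. Stops are dropped entirely — segments never contain
`*` — and translation resumes at the next codon *in the same frame*.
Restarting at the literal next nucleotide would change frame and merely
duplicate the content of the other frame tracks, so same-frame resumption
is the only segmentation that makes the six tracks non-redundant.

`min_len` defaults to 5 residues. A database-side minimum is needed to
keep the segment count bounded (one-residue runs between adjacent stops
carry no mappable information at the default 6-residue mapping minimum);
5 keeps every segment long enough to be hit by no mapped peptide length
while staying below the mapping minimum.

**Ambiguity resolution.** IUPAC ambiguity codes (N, R, Y, ...) are replaced
before translation by a uniform draw among the bases the symbol denotes.
The draw at each position is seeded from (seed, chromosome, position), so
resolution is reproducible, independent of which other positions are
ambiguous, and stable under re-resolution of a slice. The resolved genome
is cached with the database so locus re-extraction and start-codon readout
see exactly the sequence that was translated; a digest check guards
against mixing a database with a differently resolved genome.

## Peptide-to-locus assignment

Peptides are located by exact substring search over the database segments
(segments are concatenated with a separator character so one scan finds
within-segment matches only). A hit at residue offset k of a segment maps
to the genomic interval by codon arithmetic: `[seg.start + 3k,
seg.start + 3(k+m))` on '+', end-anchored on '-'. Because matching is
within-segment, a peptide can never span a stop codon — consistent with
how the database is defined.

Peptides hitting more than one locus are discarded entirely rather than
assigned at random; only single-locus peptides enter downstream analyses.
Peptides shorter than 6 residues are excluded from mapping by default —
shorter sequences are almost never unique in a database of this size — and
the exclusion is logged. An optional Ile/Leu equivalence flag exists
because MS cannot distinguish the isobaric pair, but it is off by default;
identifications are consumed as written.

Identification tables are filtered at FDR strictly below 0.05 (a row at
exactly 0.05 is excluded).

## CP/NCP classification

A locus is a **conventional peptide (CP)** iff it is fully contained in
the annotated CDS intervals of one transcript, on the annotated strand,
and its reading frame agrees with the annotated CDS phase at every covered
position. Phase agreement is checked at one position per containing CDS
piece: both the locus frame and the annotated frame advance one phase per
base within a piece, so pointwise agreement is equivalent.

Everything else is a **non-conventional peptide (NCP)** with one of five
sources, resolved across all transcripts by the precedence

    CP > out-of-frame exon > 5'UTR > 3'UTR > intron > intergenic

- *out-of-frame exon*: contained in exonic sequence overlapping CDS but
  failing the strand or phase test. Antisense-to-CDS loci fall here:
  "a different reading frame" is read to include the opposite strand.
- *5'UTR / 3'UTR / intron*: full containment in the respective element.
- *intergenic*: no overlap with any gene span (the union of transcript
  extents including UTRs and introns).

A locus straddling element boundaries takes the highest-precedence element
it touches. Because the database is unspliced, a genuine CP can only be
exon-contained; boundary-straddlers can therefore never be CP, and the
most-coding-like-first precedence is the conservative choice for the
CP/NCP split. Classification requires the locus's chromosome to belong to
the annotation universe; an unknown chromosome is an error rather than
"intergenic", since the two are not distinguishable.

## Chromosome-scale statistics

- **Density** uses a 6-Mb sliding window with a 3-Mb step. A locus counts
  in a window iff its *start* lies in it (point density, not overlap
  length). Windows are emitted until one reaches the chromosome end; the
  final window is truncated, not dropped, so short chromosomes still
  contribute.
- **Hotspots** are windows with count strictly greater than 10, reported
  per peptide class as window counts; a merged-region count is reported as
  a secondary statistic because overlapping windows can describe one dense
  area.
- **Spacing** is the start-to-start distance to the nearest same-chromosome
  neighbour; a chromosome's only locus has infinite distance and stays in
  the denominator of the below-100-kb fraction.
- **TSS distances**: the TSS here is the *translation initiation site* —
  the first base of a transcript's annotated CDS, not the transcription
  start. Each locus reports the absolute distance to the nearest TSS on
  its chromosome; loci on chromosomes without any TSS are excluded from
  the within-700-bp share and counted separately.
- **Arm-normalized position** maps a locus start p on a chromosome of
  length L to |p − L/2| / (L/2): 0 at the midpoint, 1 at either telomere;
  invariant under reflecting the chromosome.
- **Count-length correlation** is the Pearson product-moment correlation
  of per-chromosome locus counts against chromosome lengths, with the
  standard two-sided t-based p-value (scipy); it requires at least three
  chromosomes and nonzero variance.

## Physicochemical properties

- **Molecular weight** sums *average* (isotope-weighted) residue masses
  plus one water (18.0153 Da). Average rather than monoisotopic masses are
  used because the reported summaries are population means, for which
  average masses are conventional. The table is the standard one
  (G 57.0519, A 71.0788, ..., W 186.2132 Da) and is configurable.
- **Isoelectric point** solves net charge = 0 by bisection on pH ∈ [0, 14]
  to 1e-6, with Henderson–Hasselbalch terms for the termini and the D, E,
  C, Y, H, K, R side chains. The pKa set is the Bjellqvist-style table
  conventional for 2-D gel pI prediction (N-term 7.5, C-term 3.55, D 4.05,
  E 4.45, C 9.0, Y 10.0, H 5.98, K 10.0, R 12.0); it is configurable
  because published pI values depend materially on the chosen set. Net
  charge is strictly decreasing in pH, so bisection always converges.
- **Hydropathy** counts residues against the fixed sets used throughout
  the analysis: 8 hydrophobic (G, A, V, L, P, M, F, W) and 11 hydrophilic
  (S, T, Y, C, N, Q, D, E, R, K, H). Isoleucine belongs to neither set, so
  n_hydrophobic + n_hydrophilic + count(I) = length.
- **Start codon** is the first codon of the locus read on its strand from
  the resolved genome; AUG usage is reported as the fraction of loci whose
  first codon is ATG.
- **Percent identity** slides the shorter sequence over the longer without
  gaps and divides the best match count by the *longer* length. This is
  the only convention under which an 8-mer perfectly contained in a 13-mer
  scores 8/13 = 61.54%, as for the spleen-specific NCP LPWKWPWW against
  bovine indolicidin (ILPWKWPWWPWRR).

## Tissue expression patterns

A peptide is *detected* in a tissue if any replicate reports nonzero
abundance; the tissue mean is the arithmetic mean of the detected
replicates. Classes:

- **specific** — detected in exactly one tissue;
- **enhanced** — maximum tissue mean at least `fold` (default 15) times
  the *maximum* of the other detected tissues' means, boundary inclusive
  (exactly 15x qualifies);
- **mixed** — detected in several tissues but below the fold rule.

Comparing against the maximum of the other tissues is the strictest
reading of "higher than that in other tissues"; a flag switches the base
to their mean for sensitivity analysis. Pairwise tissue overlaps count
peptides detected in both members of each pair; k-tissue intersections are
computed for queried subsets.

## ncRNA and Ribo-seq support

Transcripts are translated in their three sense frames and split into
stop-free runs; an NCP is supported by a transcript class iff its sequence
is a contiguous substring of some run. Support is sequence containment,
not coordinate overlap, matching how translated Ribo-seq sequences are
compared against MS peptides; a coordinate-overlap mode would require
interval-resolved transcript models and is out of scope here.

Circular RNAs are doubled head-to-tail before translation so that runs
spanning the back-splice junction are representable. The doubling itself
bounds any run below two laps of the circle, which is what rules out
unbounded rolling-circle products; no further truncation is applied, so a
junction-spanning peptide slightly longer than one lap (e.g. MEW from the
5-nt circle ATGGA) remains representable. Union support counts a peptide
supported by several classes once.

## Synthetic data

The generator emulates the study's structure at a scale that runs on one
CPU in about a minute: by default 2 chromosomes x 10 Mb of i.i.d. sequence
at GC 0.42 with 0.1% ambiguous positions, 50 non-overlapping gene models
(1–4 exons of 150–900 nt, introns of 0.2–2 kb, UTRs of 60–200 nt, CDS of
at least 120 nt with valid start/stop, correct phases, and no internal
in-frame stops — bases are overwritten as needed), separated by at least
5 kb of intergenic space.

The planted peptidome defaults to 2,000 peptides of 6–30 residues in the
observed source mix (8% CP; the NCP remainder split 61% intergenic /
38% intron / 0.6% 3'UTR / 0.2% 5'UTR / 0.2% out-of-frame). Peptides are
read directly off the resolved genome at loci satisfying their category,
verified by the classifier, and accepted only if their sequence occurs
exactly once in the six-frame database (rejection sampling, capped at
1,000 attempts per peptide so generation always terminates). Every planted
peptide therefore satisfies the locus round-trip invariant by
construction, which is what makes exact recovery a meaningful end-to-end
test. An optional hotspot spec plants k additional intergenic peptides
inside one chosen 6-Mb window.

Tissue patterns are planted per class: specific peptides in one tissue;
enhanced at twice the fold threshold above every other detected tissue;
mixed with planted max/min ratio below half the threshold; multiplicative
log-normal noise (sigma 0.2 on the natural-log scale) per replicate. The
planted margins of 2x on either side of the threshold make label recovery
robust to that noise level. Transcript support embeds the genomic coding
sequence of selected NCPs codon-aligned between random flanks (rotated
across the junction for circRNA monomers); decoys are scrambled NCP
sequences verified absent from every transcript translation.

All stage seeds derive from one master seed by a fixed affine map modulo
2^31, so the whole study is reproducible from a single integer and each
stage is independently re-runnable.

**What the synthetic data do not emulate:** spectral noise and missed
identifications (identifications are planted as correct), homology and
repeat structure (the genome is i.i.d., so sequence uniqueness is easier
than in a real genome), alternative isoforms (one transcript per gene),
and realistic intensity distributions (log-normal with a single sigma).
Perfect recovery on these data therefore demonstrates the correctness of
the bookkeeping — coordinates, frames, phases, thresholds — not the
biological error rates of the upstream search.

## Numerical and degenerate-input conventions

Percentages in reports are rounded to two decimals (one decimal for the
support share). Counts of zero denominators report 0.0. An empty locus
list yields empty outputs, not errors; a peptide absent from the database
is recorded with multiplicity 0 and a warning. Window arithmetic for a
chromosome shorter than one window emits a single truncated window. The
bisection tolerance (1e-6 pH) is far below the 1e-3 reporting precision.

## Known limitations

- The unspliced database cannot represent peptides spanning exon–exon
  junctions; this matches the design being reproduced but undercounts
  genuine CPs from spliced transcripts.
- Multi-locus peptides are discarded, biasing against repetitive regions.
- The pI depends on the chosen pKa set; values from other tables differ
  by up to ~0.5 pH units for cysteine/tyrosine-rich peptides.
- Tissue classes are assigned from means over at most a few replicates;
  no uncertainty is propagated.
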