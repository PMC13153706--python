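"""Chromosome-scale distribution statistics for peptide loci.

Sliding-window density (6 Mb window, 3 Mb step by default), hotspot
windows (count strictly greater than 10), nearest-neighbour spacing,
distances to translation initiation sites, arm-normalized positions,
and the count-versus-chromosome-length correlation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .models import GeneModel, PeptideLocus

log = logging.getLogger(__name__)


@dataclass
class DistributionConfig:
    window_size: int = 6_000_000
    step: int = 3_000_000
    hotspot_threshold: int = 10     # hotspot iff count > threshold
    spacing_cutoff: int = 100_000   # nt
    tss_window: int = 700           # nt, reporting only

    def __post_init__(self):
        if not (self.window_size >= self.step > 0):
            raise ValueError("need window_size >= step > 0")
        if self.hotspot_threshold <= 0 or self.spacing_cutoff <= 0:
            raise ValueError("thresholds must be positive")


def sliding_windows(chrom_length: int, window: int, step: int) -> list[tuple[int, int]]:
    """Window list covering [0, chrom_length); the final window is truncated."""
    out = []
    s = 0
    while True:
        e = min(s + window, chrom_length)
        out.append((s, e))
        if s + window >= chrom_length:
            break
        s += step
    return out


@dataclass
class DensityProfile:
    """Per-chromosome window counts for one peptide class."""

    windows: dict[str, list[tuple[int, int, int]]]
    label: str = ""
    config: DistributionConfig = field(default_factory=DistributionConfig)


def window_density(
    loci, chrom_lengths: dict[str, int],
    config: DistributionConfig | None = None, label: str = "",
) -> DensityProfile:
    """Count loci per sliding window; a locus counts where its start falls."""
    config = config or DistributionConfig()
    starts_by_chrom: dict[str, list[int]] = {c: [] for c in chrom_lengths}
    for locus in loci:
        pos = locus.start if isinstance(locus, PeptideLocus) else locus[1]
        chrom = locus.chrom if isinstance(locus, PeptideLocus) else locus[0]
        if chrom not in chrom_lengths:
            raise ValueError(f"locus chromosome {chrom!r} has no known length")
        if pos >= chrom_lengths[chrom]:
            raise ValueError(f"locus at {chrom}:{pos} beyond chromosome end")
        starts_by_chrom[chrom].append(pos)
    profile = {}
    for chrom, length in chrom_lengths.items():
        starts = np.sort(np.asarray(starts_by_chrom[chrom], dtype=np.int64))
        rows = []
        for ws, we in sliding_windows(length, config.window_size, config.step):
            count = int(np.searchsorted(starts, we, side="left")
                        - np.searchsorted(starts, ws, side="left"))
            rows.append((ws, we, count))
        profile[chrom] = rows
    return DensityProfile(windows=profile, label=label, config=config)


def detect_hotspots(
    profile: DensityProfile, config: DistributionConfig | None = None
) -> list[tuple[str, int, int, int]]:
    """Windows whose count strictly exceeds the hotspot threshold."""
    config = config or profile.config
    return [
        (chrom, ws, we, count)
        for chrom, rows in profile.windows.items()
        for ws, we, count in rows
        if count > config.hotspot_threshold
    ]


def merge_hotspots(hotspots) -> list[tuple[str, int, int]]:
    """Merge overlapping hotspot windows into regions (secondary statistic)."""
    merged: list[list] = []
    for chrom, ws, we, _ in sorted(hotspots):
        if merged and merged[-1][0] == chrom and ws <= merged[-1][2]:
            merged[-1][2] = max(merged[-1][2], we)
        else:
            merged.append([chrom, ws, we])
    return [tuple(m) for m in merged]


def adjacent_spacing(loci, cutoff: int = 100_000) -> tuple[list[float], float]:
    """Start-to-start distance to the nearest same-chromosome neighbour.

    Returns one distance per locus (inf for a chromosome's only locus,
    which stays in the denominator) and the fraction below ``cutoff``.
    """
    by_chrom: dict[str, list[int]] = {}
    for locus in loci:
        by_chrom.setdefault(locus.chrom, []).append(locus.start)
    distances = []
    for starts in by_chrom.values():
        starts.sort()
        n = len(starts)
        for i, p in enumerate(starts):
            d = math.inf
            if i > 0:
                d = min(d, p - starts[i - 1])
            if i < n - 1:
                d = min(d, starts[i + 1] - p)
            distances.append(float(d))
    return distances, spacing_fraction(distances, cutoff)


def spacing_fraction(distances: list[float], cutoff: int = 100_000) -> float:
    """Share of loci with nearest-neighbour distance below the cutoff.

    Singleton loci (infinite distance) stay in the denominator.
    """
    if not distances:
        return float("nan")
    return sum(d < cutoff for d in distances) / len(distances)


def tss_positions(models: list[GeneModel]) -> dict[str, np.ndarray]:
    """Translation initiation sites: the first base of each transcript's CDS."""
    by_chrom: dict[str, list[int]] = {}
    for m in models:
        if not m.cds:
            continue
        if m.strand == "+":
            tss = min(s for s, _, _ in m.cds)
        else:
            tss = max(e for _, e, _ in m.cds) - 1
        by_chrom.setdefault(m.chrom, []).append(tss)
    return {c: np.sort(np.asarray(v)) for c, v in by_chrom.items()}


def tss_distances(
    loci, models: list[GeneModel], tss_window: int = 700
) -> tuple[list[float], float, int]:
    """Distance from each locus start to the nearest same-chromosome TSS.

    Loci on chromosomes without any TSS get ``nan`` and are excluded from
    the within-window share (their count is returned and logged).
    """
    tss = tss_positions(models)
    distances = []
    n_undefined = 0
    for locus in loci:
        sites = tss.get(locus.chrom)
        if sites is None or len(sites) == 0:
            distances.append(float("nan"))
            n_undefined += 1
            continue
        i = int(np.searchsorted(sites, locus.start))
        best = math.inf
        if i < len(sites):
            best = min(best, abs(int(sites[i]) - locus.start))
        if i > 0:
            best = min(best, abs(locus.start - int(sites[i - 1])))
        distances.append(float(best))
    if n_undefined:
        log.info("%d loci on chromosomes without a TSS", n_undefined)
    defined = [d for d in distances if not math.isnan(d)]
    share = (sum(d <= tss_window for d in defined) / len(defined)) if defined else float("nan")
    return distances, share, n_undefined


def arm_normalized_positions(loci, chrom_lengths: dict[str, int]) -> list[float]:
    """Map each locus start to [0,1]: 0 at the chromosome midpoint, 1 at an end."""
    values = []
    for locus in loci:
        length = chrom_lengths[locus.chrom]
        half = length / 2.0
        values.append(abs(locus.start - half) / half)
    return values


def count_length_correlation(counts, lengths) -> tuple[float, float]:
    """Pearson correlation of per-chromosome counts vs lengths (two-sided p)."""
    counts = np.asarray(counts, dtype=float)
    lengths = np.asarray(lengths, dtype=float)
    if len(counts) < 3:
        raise ValueError("need at least 3 chromosomes")
    if np.std(counts) == 0 or np.std(lengths) == 0:
        raise ValueError("zero variance in counts or lengths")
    r, p = stats.pearsonr(counts, lengths)
    return float(r), float(p)
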