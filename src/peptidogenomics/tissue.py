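"""Tissue expression patterns of identified peptides.

Peptides are classed from a tissue x peptide abundance matrix as
tissue-specific (detected in exactly one tissue), tissue-enhanced (mean
abundance in one tissue at least ``fold`` times that in every other
detected tissue; 15-fold by default, boundary inclusive) or mixed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from itertools import combinations

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

DEFAULT_TISSUES = ["liver", "lung", "spleen", "muscle", "intestine", "testis"]


class TissueClass(Enum):
    SPECIFIC = "specific"
    ENHANCED = "enhanced"
    MIXED = "mixed"


@dataclass
class AbundanceMatrix:
    """Peptide x tissue mean abundances plus a detection mask.

    Means are arithmetic means over the *detected* (nonzero) replicates of
    each tissue; a peptide is detected in a tissue if any replicate
    reports nonzero abundance.  Peptides absent everywhere are dropped
    with a warning.
    """

    means: pd.DataFrame
    detected: pd.DataFrame

    def __post_init__(self):
        if not self.means.index.equals(self.detected.index) or \
                list(self.means.columns) != list(self.detected.columns):
            raise ValueError("means and detection mask are not aligned")
        if (self.means.values < 0).any():
            raise ValueError("negative abundance")
        empty = ~self.detected.any(axis=1)
        if empty.any():
            log.warning("%d peptides detected in no tissue; excluded", int(empty.sum()))
            self.means = self.means[~empty]
            self.detected = self.detected[~empty]

    @property
    def tissues(self) -> list[str]:
        return list(self.means.columns)

    @classmethod
    def from_replicates(cls, df: pd.DataFrame) -> "AbundanceMatrix":
        """Build from long-format rows (peptide, tissue, sample, abundance)."""
        nz = df[df["abundance"] > 0]
        means = nz.pivot_table(index="peptide", columns="tissue",
                               values="abundance", aggfunc="mean")
        all_tissues = sorted(df["tissue"].unique())
        means = means.reindex(columns=all_tissues)
        detected = means.notna()
        return cls(means=means.fillna(0.0), detected=detected)


def classify_tissue_pattern(
    matrix: AbundanceMatrix, fold_threshold: float = 15.0, other: str = "max"
) -> pd.DataFrame:
    """Assign SPECIFIC / ENHANCED / MIXED per peptide.

    ``other`` chooses the comparison base for the enhanced rule: the
    maximum ("max", default, strictest) or the mean ("mean") of the other
    detected tissues' means.
    """
    if other not in ("max", "mean"):
        raise ValueError("other must be 'max' or 'mean'")
    rows = []
    for pep in matrix.means.index:
        det = matrix.detected.loc[pep]
        tissues = list(det[det].index)
        means = matrix.means.loc[pep, tissues]
        if len(tissues) == 1:
            rows.append((pep, TissueClass.SPECIFIC.value, tissues[0]))
            continue
        top_tissue = means.idxmax()
        others = means.drop(top_tissue)
        base = others.max() if other == "max" else others.mean()
        if means[top_tissue] >= fold_threshold * base:
            rows.append((pep, TissueClass.ENHANCED.value, top_tissue))
        else:
            rows.append((pep, TissueClass.MIXED.value, ""))
    return pd.DataFrame(rows, columns=["peptide", "tissue_class", "defining_tissue"]) \
        .set_index("peptide")


def overlap_analysis(
    detected: pd.DataFrame, subsets: list[list[str]] | None = None
) -> tuple[pd.DataFrame, dict[tuple[str, ...], int]]:
    """Pairwise tissue overlap counts plus optional k-tissue intersections.

    The symmetric matrix has per-tissue detection totals on the diagonal.
    """
    tissues = list(detected.columns)
    mask = detected.values.astype(bool)
    pairwise = pd.DataFrame(0, index=tissues, columns=tissues, dtype=int)
    for i, ti in enumerate(tissues):
        pairwise.loc[ti, ti] = int(mask[:, i].sum())
        for j in range(i + 1, len(tissues)):
            tj = tissues[j]
            n = int((mask[:, i] & mask[:, j]).sum())
            pairwise.loc[ti, tj] = n
            pairwise.loc[tj, ti] = n
    subset_counts: dict[tuple[str, ...], int] = {}
    for subset in subsets or []:
        for t in subset:
            if t not in detected.columns:
                raise ValueError(f"unknown tissue {t!r}")
        cols = [tissues.index(t) for t in subset]
        subset_counts[tuple(subset)] = int(np.all(mask[:, cols], axis=1).sum())
    return pairwise, subset_counts


def extreme_overlaps(pairwise: pd.DataFrame) -> tuple[tuple, tuple]:
    """(largest, smallest) off-diagonal overlap as ((t1, t2, n), ...)."""
    best, worst = None, None
    for ti, tj in combinations(pairwise.columns, 2):
        n = int(pairwise.loc[ti, tj])
        if best is None or n > best[2]:
            best = (ti, tj, n)
        if worst is None or n < worst[2]:
            worst = (ti, tj, n)
    return best, worst
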