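"""Simplified gene accessibility scores from a peak x cell count matrix.

A gene's accessibility score in a cell is the sum of counts of all peaks
overlapping the gene's scoring window: the gene body plus 5 kb upstream
of the transcription start site (strand-aware, clipped at the chromosome
start).  Overlap is strict half-open interval intersection, and a peak
overlapping several gene windows contributes fully to each.

This is an unweighted stand-in for distance-weighted gene-score matrices
produced by upstream ATAC toolkits; inference consumes whichever score
matrix is supplied, so a precomputed matrix is the preferred input path.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from intervaltree import IntervalTree

from .containers import CellMatrix, FormatError, GeneAnnotation, ValidationError

__all__ = ["GeneWindow", "build_gene_windows", "compute_gene_scores", "parse_peak_id"]

_PEAK_RE = re.compile(r"^(?P<chrom>[^:]+):(?P<start>\d+)-(?P<end>\d+)$")


@dataclass(frozen=True)
class GeneWindow:
    """Scoring window: gene body + fixed upstream promoter margin."""

    gene_id: str
    chrom: str
    window_start: int
    window_end: int
    strand: str

    def __post_init__(self) -> None:
        if not (0 <= self.window_start < self.window_end):
            raise ValidationError(
                f"invalid window [{self.window_start}, {self.window_end}) "
                f"for {self.gene_id}"
            )


def build_gene_windows(
    annotations: Sequence[GeneAnnotation], upstream: int = 5000
) -> list[GeneWindow]:
    """Extend each gene's interval by ``upstream`` bases past its TSS.

    '+' strand: [max(0, start - upstream), end); '-' strand:
    [start, end + upstream).  Default margin is 5 kb.
    """
    windows = []
    for ann in annotations:
        if ann.strand == "+":
            start, end = max(0, ann.start - upstream), ann.end
        else:
            start, end = ann.start, ann.end + upstream
        windows.append(GeneWindow(ann.gene_id, ann.chrom, start, end, ann.strand))
    return windows


def parse_peak_id(peak_id: str) -> tuple[str, int, int]:
    """Parse a ``chrom:start-end`` peak identifier (0-based half-open)."""
    m = _PEAK_RE.match(peak_id.strip())
    if m is None:
        raise FormatError(f"unparseable peak identifier {peak_id!r}")
    start, end = int(m["start"]), int(m["end"])
    if start >= end:
        raise FormatError(f"peak {peak_id!r}: start must be < end")
    return m["chrom"], start, end


def compute_gene_scores(
    peaks: CellMatrix,
    windows: Sequence[GeneWindow],
    peak_coords: Optional[Sequence[tuple[str, int, int]]] = None,
    normalize_per_10k: bool = False,
) -> CellMatrix:
    """Sum peak counts over each gene window.

    Parameters
    ----------
    peaks
        Peak x cell count matrix (``modality='peaks'``).  Peak locations
        are taken from ``peak_coords`` if given, otherwise parsed from
        the peak identifiers as ``chrom:start-end``.
    windows
        Gene scoring windows; genes with no overlapping peak get all-zero
        rows.
    normalize_per_10k
        Optionally rescale each cell's scores to sum to 10,000 (off by
        default; downstream pseudocell averaging and standardization
        absorb scale).
    """
    if peaks.modality != "peaks":
        raise ValidationError("compute_gene_scores expects a peaks matrix")
    if not windows:
        raise ValidationError("no gene windows supplied")
    if peak_coords is None:
        peak_coords = [parse_peak_id(p) for p in peaks.gene_ids]
    elif len(peak_coords) != peaks.n_genes:
        raise ValidationError("peak_coords length != number of peaks")

    trees: dict[str, IntervalTree] = {}
    for i, (chrom, start, end) in enumerate(peak_coords):
        trees.setdefault(chrom, IntervalTree()).addi(start, end, i)

    dense = peaks.to_dense()
    scores = np.zeros((len(windows), peaks.n_cells))
    for gi, w in enumerate(windows):
        tree = trees.get(w.chrom)
        if tree is None:
            continue
        # IntervalTree.overlap is half-open, matching our convention
        hits = sorted(iv.data for iv in tree.overlap(w.window_start, w.window_end))
        if hits:
            scores[gi] = dense[hits].sum(axis=0)

    if normalize_per_10k:
        totals = scores.sum(axis=0)
        nonzero = totals > 0
        scores[:, nonzero] *= 1e4 / totals[nonzero]

    return CellMatrix(scores, [w.gene_id for w in windows], list(peaks.cell_ids),
                      "accessibility")
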