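"""Pseudocell construction: binning pseudotime-ordered cells and averaging.

Single-nucleus RNA and ATAC measurements are sparse; averaging bins of
transcriptionally adjacent cells ("pseudocells") recovers smooth gene
trajectories.  N cells ordered by pseudotime are partitioned into n
contiguous bins whose sizes differ by at most one: the first (N mod n)
bins hold floor(N/n)+1 cells and the rest hold floor(N/n).  Pseudocell
expression x_p and accessibility y_p are the plain arithmetic means of
the member cells.

A control mode builds pseudocells by random sampling within cell-type
clusters instead of along pseudotime, used to show that pseudotime
ordering carries real signal.

Guidance: choose n so that bins hold roughly 30-40 cells; too few bins
over-smooth the trajectory, too many keep single-cell noise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .containers import CellMatrix, CellOrdering, ValidationError

log = logging.getLogger("popinfer")

__all__ = [
    "PseudocellSet",
    "bin_sizes",
    "select_root_cell",
    "make_pseudocells",
    "make_random_pseudocells",
]


def bin_sizes(n_cells: int, n_bins: int) -> np.ndarray:
    """Bin sizes for N cells in n bins: first N mod n bins get the extra cell."""
    if n_bins <= 0:
        raise ValidationError("number of bins must be positive")
    if n_bins > n_cells:
        raise ValidationError(f"cannot split {n_cells} cells into {n_bins} bins")
    base, extra = divmod(n_cells, n_bins)
    return np.array([base + 1] * extra + [base] * (n_bins - extra), dtype=int)


@dataclass
class PseudocellSet:
    """An ordered partition of cells into bins with aggregated profiles.

    ``x_p`` (expression) and ``y_p`` (accessibility) are genes x n_bins
    matrices of member-cell means; ``y_p`` is None when only expression
    was aggregated (RNA-only analyses).
    """

    bins: list[list[str]]
    x_p: np.ndarray
    y_p: Optional[np.ndarray]
    gene_ids: list[str]
    mode: str  # pseudotime_ordered | cluster_random

    @property
    def n_bins(self) -> int:
        return len(self.bins)

    @property
    def n_cells(self) -> int:
        return sum(len(b) for b in self.bins)


def select_root_cell(
    expr: CellMatrix, marker_genes: Sequence[str], rank: int = 1
) -> str:
    """Cell with the rank-th largest summed marker expression.

    Used to pick the root for upstream pseudotime algorithms, e.g. the
    cell with the highest Mecom + Mpl expression in hematopoietic data
    (rank > 1 lets the caller skip cells outside the expected cluster).
    Ties are broken by input cell order.
    """
    if not marker_genes:
        raise ValidationError("marker_genes must be non-empty")
    if not 1 <= rank <= expr.n_cells:
        raise ValidationError(f"rank {rank} out of range for {expr.n_cells} cells")
    idx = [expr.gene_index(g) for g in marker_genes]
    sums = expr.to_dense()[idx].sum(axis=0)
    # stable sort on descending value -> earliest cell wins ties
    order = np.argsort(-sums, kind="stable")
    return expr.cell_ids[order[rank - 1]]


def _aggregate(matrix: CellMatrix, bins: list[list[str]]) -> np.ndarray:
    """Mean profile per bin; contiguous-run aware via reduceat."""
    pos = {c: i for i, c in enumerate(matrix.cell_ids)}
    dense = matrix.to_dense()
    out = np.empty((matrix.n_genes, len(bins)))
    for j, members in enumerate(bins):
        cols = [pos[c] for c in members]
        out[:, j] = dense[:, cols].mean(axis=1)
    return out


def _check_cells(matrix: CellMatrix, cells: Sequence[str], what: str) -> None:
    missing = [c for c in cells if c not in set(matrix.cell_ids)]
    if missing:
        raise ValidationError(f"cells in ordering absent from {what}: {missing[:5]}")


def make_pseudocells(
    expr: CellMatrix,
    access: Optional[CellMatrix],
    ordering: CellOrdering,
    n: int,
) -> PseudocellSet:
    """Bin pseudotime-ordered cells into n pseudocells and average.

    ``access`` may be None for RNA-only analyses.  Bins are contiguous
    runs of the ordered cell sequence with the remainder rule above.
    """
    cells = ordering.cell_ids
    N = len(cells)
    sizes = bin_sizes(N, n)
    _check_cells(expr, cells, "expression matrix")
    if len(cells) != expr.n_cells:
        raise ValidationError("ordering does not cover every expression cell")
    if access is not None:
        _check_cells(access, cells, "accessibility matrix")
        if len(cells) != access.n_cells:
            raise ValidationError("ordering does not cover every accessibility cell")
        if access.gene_ids != expr.gene_ids:
            raise ValidationError("expression and accessibility gene sets differ")
    k = N / n
    if not 25 <= k <= 50:
        log.info("pseudocells hold %.1f cells on average; ~30-40 is recommended", k)

    edges = np.concatenate([[0], np.cumsum(sizes)])
    bins = [cells[edges[i]:edges[i + 1]] for i in range(n)]
    x_p = _aggregate(expr, bins)
    y_p = _aggregate(access, bins) if access is not None else None
    return PseudocellSet(bins, x_p, y_p, list(expr.gene_ids), "pseudotime_ordered")


def make_random_pseudocells(
    expr: CellMatrix,
    access: Optional[CellMatrix],
    cluster_labels: dict[str, str] | Sequence[str],
    bin_size: int,
    seed: int,
) -> PseudocellSet:
    """Control: pseudocells sampled at random within cell-type clusters.

    Within each cluster, cells are shuffled (seeded) and partitioned with
    the same remainder rule as the pseudotime mode, targeting
    ceil(cluster_size / bin_size) bins per cluster.  Aggregation is
    identical to the pseudotime mode; only bin membership differs.
    """
    cells = list(expr.cell_ids)
    if not isinstance(cluster_labels, dict):
        if len(cluster_labels) != len(cells):
            raise ValidationError("cluster_labels length != number of cells")
        cluster_labels = dict(zip(cells, cluster_labels))
    missing = [c for c in cells if c not in cluster_labels]
    if missing:
        raise ValidationError(f"cells without cluster label: {missing[:5]}")
    if bin_size <= 0:
        raise ValidationError("bin_size must be positive")

    clusters: dict[str, list[str]] = {}
    for c in cells:
        clusters.setdefault(str(cluster_labels[c]), []).append(c)
    smallest = min(len(v) for v in clusters.values())
    if bin_size > smallest:
        raise ValidationError(
            f"bin_size {bin_size} exceeds smallest cluster ({smallest} cells)"
        )

    rng = np.random.default_rng(seed)
    bins: list[list[str]] = []
    for label in sorted(clusters):
        members = clusters[label]
        if not members:
            log.warning("cluster %s has no cells; skipped", label)
            continue
        members = [members[i] for i in rng.permutation(len(members))]
        n_bins = -(-len(members) // bin_size)  # ceil
        sizes = bin_sizes(len(members), n_bins)
        edges = np.concatenate([[0], np.cumsum(sizes)])
        bins.extend(members[edges[i]:edges[i + 1]] for i in range(n_bins))

    x_p = _aggregate(expr, bins)
    y_p = _aggregate(access, bins) if access is not None else None
    return PseudocellSet(bins, x_p, y_p, list(expr.gene_ids), "cluster_random")
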