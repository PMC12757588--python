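"""Core in-memory containers shared across the package.

The central object is :class:`CellMatrix`, a named genes-by-cells matrix
holding either gene expression, gene accessibility scores, or raw peak
counts.  :class:`CellOrdering` carries the per-cell pseudotime used to
order cells along a differentiation trajectory, and :class:`RunConfig`
bundles every tunable of the inference pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import scipy.sparse as sp

MODALITIES = ("expression", "accessibility", "peaks")

__all__ = [
    "CellMatrix",
    "CellOrdering",
    "GeneAnnotation",
    "RunConfig",
    "ValidationError",
    "FormatError",
]


class ValidationError(ValueError):
    """Input violates a documented invariant (shape, sign, identifiers...)."""


class FormatError(ValueError):
    """A file could not be interpreted in its declared format."""


def _check_unique(ids: Sequence[str], what: str) -> list[str]:
    ids = [str(i).strip() for i in ids]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValidationError(f"duplicate {what}: {dupes[:5]}")
    return ids


@dataclass
class CellMatrix:
    """A genes x cells real-valued matrix with named rows and columns.

    Parameters
    ----------
    values
        Dense ndarray or scipy sparse matrix, shape (n_genes, n_cells).
        Sparse storage is intended for ``modality='peaks'``.
    gene_ids, cell_ids
        Unique row/column identifiers (whitespace-stripped, case kept:
        gene symbols are case-significant, e.g. mouse Mecom vs human MECOM).
    modality
        One of ``expression``, ``accessibility``, ``peaks``.  Accessibility
        and peak values must be non-negative.
    """

    values: np.ndarray | sp.spmatrix
    gene_ids: list[str]
    cell_ids: list[str]
    modality: str = "expression"

    def __post_init__(self) -> None:
        if self.modality not in MODALITIES:
            raise ValidationError(
                f"modality must be one of {MODALITIES}, got {self.modality!r}"
            )
        self.gene_ids = _check_unique(self.gene_ids, "gene identifiers")
        self.cell_ids = _check_unique(self.cell_ids, "cell identifiers")
        shape = self.values.shape
        if shape != (len(self.gene_ids), len(self.cell_ids)):
            raise FormatError(
                f"matrix shape {shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells"
            )
        data = self.values.data if sp.issparse(self.values) else self.values
        data = np.asarray(data)
        if data.size and not np.all(np.isfinite(data)):
            raise ValidationError("matrix contains non-finite values")
        if self.modality in ("accessibility", "peaks") and data.size and data.min() < 0:
            raise ValidationError(f"{self.modality} values must be >= 0")

    # -- convenience -------------------------------------------------------
    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def to_dense(self) -> np.ndarray:
        if sp.issparse(self.values):
            return np.asarray(self.values.todense(), dtype=float)
        return np.asarray(self.values, dtype=float)

    def gene_index(self, gene_id: str) -> int:
        try:
            return self.gene_ids.index(gene_id)
        except ValueError:
            raise ValidationError(f"gene {gene_id!r} not in matrix") from None

    def row(self, gene_id: str) -> np.ndarray:
        return self.to_dense()[self.gene_index(gene_id)]

    def reorder_cells(self, cell_ids: Sequence[str]) -> "CellMatrix":
        """Return a copy with columns permuted into the given cell order."""
        pos = {c: i for i, c in enumerate(self.cell_ids)}
        missing = [c for c in cell_ids if c not in pos]
        if missing:
            raise ValidationError(f"cells absent from matrix: {missing[:5]}")
        if len(cell_ids) != self.n_cells:
            raise ValidationError(
                f"ordering has {len(cell_ids)} cells, matrix has {self.n_cells}"
            )
        idx = [pos[c] for c in cell_ids]
        vals = self.values[:, idx] if not sp.issparse(self.values) else self.values.tocsc()[:, idx]
        return CellMatrix(vals, list(self.gene_ids), [str(c) for c in cell_ids], self.modality)


@dataclass
class CellOrdering:
    """Cells ordered along a trajectory, optionally with pseudotime values.

    When pseudotime is present the cells are stored sorted by non-decreasing
    pseudotime; ties are broken by the original input order (stable sort),
    so the ordering is deterministic.
    """

    cell_ids: list[str]
    pseudotime: Optional[np.ndarray] = None
    cluster_labels: Optional[list[str]] = None

    def __post_init__(self) -> None:
        self.cell_ids = _check_unique(self.cell_ids, "cell identifiers")
        if self.pseudotime is not None:
            self.pseudotime = np.asarray(self.pseudotime, dtype=float)
            if self.pseudotime.shape != (len(self.cell_ids),):
                raise ValidationError("pseudotime length != number of cells")
            if not np.all(np.isfinite(self.pseudotime)):
                raise ValidationError("pseudotime contains non-finite values")
            if np.any(np.diff(self.pseudotime) < 0):
                raise ValidationError(
                    "cells must be sorted by pseudotime; use from_pseudotime()"
                )
        if self.cluster_labels is not None and len(self.cluster_labels) != len(self.cell_ids):
            raise ValidationError("cluster_labels length != number of cells")

    @classmethod
    def from_pseudotime(
        cls,
        cell_ids: Sequence[str],
        pseudotime: Sequence[float],
        cluster_labels: Optional[Sequence[str]] = None,
    ) -> "CellOrdering":
        """Build an ordering by stable-sorting cells on pseudotime."""
        pt = np.asarray(pseudotime, dtype=float)
        order = np.argsort(pt, kind="stable")
        cells = [str(cell_ids[i]).strip() for i in order]
        labels = [str(cluster_labels[i]) for i in order] if cluster_labels is not None else None
        return cls(cells, pt[order], labels)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)


@dataclass(frozen=True)
class GeneAnnotation:
    """Genomic location of a gene, 0-based half-open coordinates."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(f"strand must be '+' or '-', got {self.strand!r}")
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"invalid interval [{self.start}, {self.end}) for {self.gene_id}"
            )

    @property
    def tss(self) -> int:
        """Transcription start site (strand-aware)."""
        return self.start if self.strand == "+" else self.end


def alpha_grid(alpha_max: float = 0.4, alpha_step: float = 0.001,
               include_zero: bool = False) -> np.ndarray:
    """Regular grid of the sparsity/MSE tradeoff parameter.

    The default is {0.001, 0.002, ..., 0.4}; the denser variant used for
    steeper trajectories extends to 0.6.  Including 0 only rescales the
    final weights by s/(s+1) since alpha=0 always yields an empty network.
    """
    n = int(round(alpha_max / alpha_step))
    grid = np.round(np.arange(1, n + 1) * alpha_step, 12)
    if include_zero:
        grid = np.concatenate([[0.0], grid])
    return grid


@dataclass
class RunConfig:
    """All tunables of the inference pipeline.

    Attributes
    ----------
    n_pseudocells
        Number of pseudotime bins (default 80).  Aim for roughly 30-40
        cells per pseudocell.
    alpha_max, alpha_step, include_alpha_zero
        Define the tradeoff-parameter grid averaged over (default
        {0.001,...,0.4} step 0.001).
    n_lambda
        Number of points on the LASSO regularization path (default 200).
    lambda_min_ratio
        Ratio of the smallest to the largest path penalty (default 1e-4).
    weight_threshold
        Magnitude cutoff for calling an edge from the averaged weight
        matrix (default 0.4, strict inequality).
    mode
        ``multiome`` predicts pseudocell accessibility from pseudocell
        expression; ``rna_only`` predicts expression from expression.
    exclude_self
        Drop the target's own expression from its predictor set.
    lag
        Optional shift (in pseudocells) of predictors earlier in
        pseudotime; 0 pairs same-index pseudocells (the canonical model).
    """

    n_pseudocells: int = 80
    alpha_max: float = 0.4
    alpha_step: float = 0.001
    include_alpha_zero: bool = False
    n_lambda: int = 200
    lambda_min_ratio: float = 1e-4
    weight_threshold: float = 0.4
    mode: str = "multiome"
    exclude_self: bool = True
    lag: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pseudocells <= 0:
            raise ValidationError("n_pseudocells must be positive")
        if self.n_lambda < 2:
            raise ValidationError("n_lambda must be >= 2")
        if self.mode not in ("multiome", "rna_only"):
            raise ValidationError(f"unknown mode {self.mode!r}")
        if not 0.0 <= self.weight_threshold <= 1.0:
            raise ValidationError("weight_threshold must lie in [0, 1]")
        grid = self.alphas
        if grid.size == 0 or np.any(grid < 0) or np.any(grid > 1):
            raise ValidationError("alpha grid must be non-empty within [0, 1]")
        if np.any(np.diff(grid) <= 0):
            raise ValidationError("alpha grid must be strictly increasing")

    @property
    def alphas(self) -> np.ndarray:
        return alpha_grid(self.alpha_max, self.alpha_step, self.include_alpha_zero)

    def with_updates(self, **kwargs) -> "RunConfig":
        return replace(self, **kwargs)
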