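"""The network-inference estimator: per-target LASSO ensembled over alpha.

For every target gene g, pseudocell accessibility y_p(g) (multiome mode)
or pseudocell expression x_p(g) (RNA-only mode) is regressed on the
pseudocell expression of all candidate regulators.  One regularization
path is fit per target; for each tradeoff value alpha on a grid the
gene-specific penalty is selected and the coefficients sign-binarized
into a network W_alpha in {-1, 0, +1}^{G x G}.  The final signed network
is the average W = (1/s) sum_j W_{alpha_j}, with entries in [-1, 1] and
a zero diagonal; |W| close to 1 marks an edge called consistently with a
stable sign across the whole sparsity sweep.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .containers import CellMatrix, CellOrdering, RunConfig, ValidationError
from .lasso import binarize_signed, fit_lasso_path, select_lambda_indices
from .pseudocells import PseudocellSet, make_pseudocells

log = logging.getLogger("popinfer")

__all__ = ["SignedNetwork", "PopInfer", "infer_network"]


@dataclass
class SignedNetwork:
    """Averaged signed network; rows are regulators, columns targets."""

    W: np.ndarray
    gene_ids: list[str]
    alpha_grid: np.ndarray
    alpha_networks: Optional[list[np.ndarray]] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        G = len(self.gene_ids)
        if self.W.shape != (G, G):
            raise ValidationError("W must be square over gene_ids")
        if np.any(np.abs(self.W) > 1 + 1e-12):
            raise ValidationError("W entries must lie in [-1, 1]")
        if np.any(np.diag(self.W) != 0):
            raise ValidationError("W diagonal must be zero")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.W, index=self.gene_ids, columns=self.gene_ids)

    def to_edge_list(self, tau: float = 0.0) -> pd.DataFrame:
        from .network import threshold_network

        return threshold_network(self, tau)


class PopInfer(BaseEstimator):
    """Signed, directed GRN inference from pseudocells over pseudotime.

    Parameters
    ----------
    n_pseudocells : int, default=80
        Number of pseudotime bins when fitting from single-cell matrices.
    alpha_max, alpha_step : float
        Tradeoff-parameter grid {alpha_step, 2*alpha_step, ..., alpha_max}
        averaged over; defaults give {0.001, ..., 0.4}.  Use
        ``alpha_max=0.6`` for steeper transitions where denser networks
        are tolerable.
    include_alpha_zero : bool, default=False
        Prepend alpha = 0 (always an empty network; rescales weights by
        s/(s+1) only).
    n_lambda : int, default=200
        Points on each regularization path.
    lambda_min_ratio : float, default=1e-4
        Smallest/largest path penalty ratio.
    mode : {'multiome', 'rna_only'}
        Predict accessibility from expression, or expression from
        expression.
    exclude_self : bool, default=True
        Remove the target's own expression from its predictor set (the
        network is defined only off-diagonal).
    lag : int, default=0
        Shift predictors earlier by this many pseudocells (sensitivity
        analysis only; the canonical model pairs same-index pseudocells).
    keep_alpha_networks : bool, default=False
        Retain every per-alpha signed matrix on the fitted estimator.

    Attributes
    ----------
    weights_ : ndarray of shape (G, G)
        Averaged signed network, regulators in rows, targets in columns.
    network_ : SignedNetwork
        The same network with gene labels attached.
    gene_ids_ : list of str
    degenerate_targets_ : list of str
        Targets whose response was constant (or orthogonal to all
        predictors) across pseudocells; their columns are all zero.
    """

    def __init__(
        self,
        n_pseudocells: int = 80,
        alpha_max: float = 0.4,
        alpha_step: float = 0.001,
        include_alpha_zero: bool = False,
        n_lambda: int = 200,
        lambda_min_ratio: float = 1e-4,
        mode: str = "multiome",
        exclude_self: bool = True,
        lag: int = 0,
        keep_alpha_networks: bool = False,
    ):
        self.n_pseudocells = n_pseudocells
        self.alpha_max = alpha_max
        self.alpha_step = alpha_step
        self.include_alpha_zero = include_alpha_zero
        self.n_lambda = n_lambda
        self.lambda_min_ratio = lambda_min_ratio
        self.mode = mode
        self.exclude_self = exclude_self
        self.lag = lag
        self.keep_alpha_networks = keep_alpha_networks

    # -- configuration plumbing -------------------------------------------
    @classmethod
    def from_config(cls, config: RunConfig, **overrides) -> "PopInfer":
        params = dict(
            n_pseudocells=config.n_pseudocells,
            alpha_max=config.alpha_max,
            alpha_step=config.alpha_step,
            include_alpha_zero=config.include_alpha_zero,
            n_lambda=config.n_lambda,
            lambda_min_ratio=config.lambda_min_ratio,
            mode=config.mode,
            exclude_self=config.exclude_self,
            lag=config.lag,
        )
        params.update(overrides)
        return cls(**params)

    def _alpha_grid(self) -> np.ndarray:
        from .containers import alpha_grid

        return alpha_grid(self.alpha_max, self.alpha_step, self.include_alpha_zero)

    # -- fitting -----------------------------------------------------------
    def fit(self, pseudocells: PseudocellSet, y=None) -> "PopInfer":
        """Infer the signed network from an aggregated pseudocell set."""
        pc = pseudocells
        if self.mode not in ("multiome", "rna_only"):
            raise ValidationError(f"unknown mode {self.mode!r}")
        if self.mode == "multiome" and pc.y_p is None:
            raise ValidationError("multiome mode requires pseudocell accessibility")
        n_bins = pc.x_p.shape[1]
        lag = int(self.lag)
        if lag < 0 or lag >= n_bins:
            raise ValidationError("lag must satisfy 0 <= lag < n_pseudocells")
        if n_bins - lag < 3:
            raise ValidationError("need at least 3 pseudocells after lag shift")

        genes = pc.gene_ids
        G = len(genes)
        alphas = self._alpha_grid()
        s = len(alphas)
        response = pc.y_p if self.mode == "multiome" else pc.x_p
        X_all = pc.x_p.T  # bins x genes

        W = np.zeros((G, G))
        alpha_nets = (
            [np.zeros((G, G), dtype=int) for _ in range(s)]
            if self.keep_alpha_networks
            else None
        )
        degenerate: list[str] = []
        cols = np.arange(G)
        for j in range(G):
            pred_idx = cols[cols != j] if self.exclude_self else cols
            yj = response[j, lag:] if lag else response[j]
            Xj = X_all[: n_bins - lag, pred_idx] if lag else X_all[:, pred_idx]
            path = fit_lasso_path(
                yj,
                Xj,
                n_lambda=self.n_lambda,
                lambda_min_ratio=self.lambda_min_ratio,
                target_gene=genes[j],
            )
            if path.degenerate or path.nonzero[path.lambda_mse_index] == 0:
                degenerate.append(genes[j])
                log.warning(
                    "target %s: constant/unpredictable response; column left empty",
                    genes[j],
                )
                continue
            idxs = select_lambda_indices(path, alphas)
            signs = binarize_signed(path.coefs[:, idxs])  # predictors x s
            W[pred_idx, j] = signs.mean(axis=1)
            if alpha_nets is not None:
                for a in range(s):
                    alpha_nets[a][pred_idx, j] = signs[:, a]

        np.fill_diagonal(W, 0.0)
        self.gene_ids_ = list(genes)
        self.alpha_grid_ = alphas
        self.weights_ = W
        self.degenerate_targets_ = degenerate
        self.network_ = SignedNetwork(W, list(genes), alphas, alpha_nets)
        return self

    def fit_cells(
        self,
        expr: CellMatrix,
        access: Optional[CellMatrix],
        ordering: CellOrdering,
    ) -> "PopInfer":
        """Convenience: bin single cells into pseudocells, then fit."""
        pc = make_pseudocells(expr, access, ordering, self.n_pseudocells)
        return self.fit(pc)


def infer_network(
    pc: PseudocellSet, config: RunConfig, keep_alpha_networks: bool = False
) -> SignedNetwork:
    """Functional wrapper over :class:`PopInfer` for one pseudocell set."""
    est = PopInfer.from_config(config, keep_alpha_networks=keep_alpha_networks)
    return est.fit(pc).network_
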