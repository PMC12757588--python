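"""Per-target LASSO paths and the sparsity/MSE lambda-selection rule.

For a target gene g with pseudocell response y and predictor matrix X
(pseudocell expression of candidate regulators), the model is

    min_{b0, b}  (1/n) sum_i (y_i - b0 - x_i' b)^2  +  lambda ||b||_1

solved along a geometric grid of 200 lambda values from lambda_max (the
smallest penalty with an all-zero solution) down to
lambda_max * lambda_min_ratio.  The gene-specific penalty lambda_g is
then chosen by the tradeoff rule

    lambda_g = argmin_lambda | a * MSE_l / MSE_triv
                              - (1 - a) * nnz_l / nnz_{l^MSE} |

where a in [0, 1] balances relative training error against relative
model density: a = 0 forces the empty model, a = 1 the minimum-MSE
model.  Ties go to the largest lambda (sparsest model).  Selected
coefficients are sign-binarized; magnitudes are discarded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import lasso_path

from .containers import ValidationError

__all__ = ["LassoPathResult", "fit_lasso_path", "select_lambda",
           "select_lambda_indices", "binarize_signed"]


@dataclass
class LassoPathResult:
    """Solution path of one target's penalized regression.

    Coefficients are reported on the original data scale; fitting is done
    on standardized predictors and a centered response.  ``mse`` is the
    in-sample training error on the same pseudocells (no cross-validation:
    the selection rule consumes relative, not predictive, error).
    ``degenerate`` marks paths where no predictor ever enters (constant
    response, or response orthogonal to every predictor).
    """

    target_gene: str
    lambdas: np.ndarray          # strictly decreasing, length n_lambda
    coefs: np.ndarray            # predictors x n_lambda, original scale
    intercepts: np.ndarray       # per lambda
    mse: np.ndarray              # training MSE per lambda
    nonzero: np.ndarray          # nonzero-coefficient count per lambda
    mse_trivial: float           # MSE of the intercept-only model
    lambda_mse_index: int        # first index attaining minimal mse
    degenerate: bool = False

    @property
    def n_lambda(self) -> int:
        return len(self.lambdas)


def _degenerate_path(target: str, n_lambda: int, p: int,
                     intercept: float, mse_trivial: float) -> LassoPathResult:
    lambdas = np.geomspace(1.0, 1e-4, n_lambda)
    return LassoPathResult(
        target_gene=target,
        lambdas=lambdas,
        coefs=np.zeros((p, n_lambda)),
        intercepts=np.full(n_lambda, intercept),
        mse=np.full(n_lambda, mse_trivial),
        nonzero=np.zeros(n_lambda, dtype=int),
        mse_trivial=mse_trivial,
        lambda_mse_index=0,
        degenerate=True,
    )


def fit_lasso_path(
    y: np.ndarray,
    X: np.ndarray,
    n_lambda: int = 200,
    lambda_min_ratio: float = 1e-4,
    target_gene: str = "",
    tol: float = 1e-10,
    max_iter: int = 100_000,
) -> LassoPathResult:
    """Solve the L1 path for one target over a geometric penalty grid.

    Predictors are standardized to zero mean / unit variance for fitting
    (constant predictors stay at coefficient zero); lambda_max is
    max_j |<x_j, y - ybar>| / n on the standardized data, which makes the
    first grid point's solution exactly zero.  Coefficients are mapped
    back to the original scale, which preserves their signs.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValidationError("X must be 2-D (pseudocells x predictors)")
    n, p = X.shape
    if y.shape[0] != n:
        raise ValidationError("y length != number of rows of X")
    if n < 3:
        raise ValidationError("need at least 3 pseudocells")
    if p < 1:
        raise ValidationError("need at least one predictor")
    if n_lambda < 2:
        raise ValidationError("n_lambda must be >= 2")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValidationError("non-finite values in regression inputs")

    y_mean = y.mean()
    yc = y - y_mean
    mse_trivial = float(np.mean(yc**2))
    # constant response up to float rounding: fitting would only chase
    # accumulated round-off, so return the flagged degenerate path
    if mse_trivial <= (1e-12 * max(1.0, abs(y_mean))) ** 2:
        return _degenerate_path(target_gene, n_lambda, p, y_mean, 0.0)

    x_mean = X.mean(axis=0)
    x_std = X.std(axis=0)
    constant = x_std == 0
    x_std_safe = np.where(constant, 1.0, x_std)
    Xs = (X - x_mean) / x_std_safe

    lambda_max = float(np.max(np.abs(Xs.T @ yc)) / n)
    if lambda_max <= 0.0:
        return _degenerate_path(target_gene, n_lambda, p, y_mean, mse_trivial)

    lambdas = lambda_max * lambda_min_ratio ** np.linspace(0.0, 1.0, n_lambda)
    with warnings.catch_warnings():
        # the tight tolerance trips sklearn's duality-gap warning on
        # near-noiseless responses; gaps ~1e-8 are far below anything
        # the sign-binarized selection can notice
        warnings.simplefilter("ignore", ConvergenceWarning)
        _, coefs_std, _ = lasso_path(Xs, yc, alphas=lambdas, tol=tol, max_iter=max_iter)

    resid = yc[:, None] - Xs @ coefs_std
    mse = np.mean(resid**2, axis=0)
    nonzero = np.count_nonzero(coefs_std, axis=0)
    coefs = coefs_std / x_std_safe[:, None]
    intercepts = y_mean - x_mean @ coefs
    return LassoPathResult(
        target_gene=target_gene,
        lambdas=lambdas,
        coefs=coefs,
        intercepts=intercepts,
        mse=mse,
        nonzero=nonzero,
        mse_trivial=mse_trivial,
        lambda_mse_index=int(np.argmin(mse)),
        degenerate=False,
    )


def select_lambda_indices(path: LassoPathResult, alphas: np.ndarray) -> np.ndarray:
    """Vectorized lambda selection: one path index per tradeoff value.

    Implements argmin_l |a * MSE_l/MSE_triv - (1-a) * nnz_l/nnz_{l^MSE}|
    with ties broken toward the largest lambda.  Degenerate paths (no
    predictor ever enters, so the density normalizer is undefined) return
    the trivial model for every a.
    """
    alphas = np.asarray(alphas, dtype=float)
    if np.any(alphas < 0) or np.any(alphas > 1):
        raise ValidationError("alpha values must lie in [0, 1]")
    if path.degenerate or path.nonzero[path.lambda_mse_index] == 0:
        return np.zeros(len(alphas), dtype=int)
    rel_mse = path.mse / path.mse_trivial
    rel_nnz = path.nonzero / path.nonzero[path.lambda_mse_index]
    objective = np.abs(alphas[:, None] * rel_mse[None, :]
                       - (1.0 - alphas)[:, None] * rel_nnz[None, :])
    # argmin returns the first (largest-lambda) index on exact ties
    return np.argmin(objective, axis=1)


def select_lambda(path: LassoPathResult, alpha: float) -> tuple[int, np.ndarray]:
    """Select the path point for one tradeoff value.

    Returns ``(lambda_index, coefficients)``.  a = 0 yields the empty
    model; a = 1 yields the minimum-training-MSE model.
    """
    idx = int(select_lambda_indices(path, np.array([alpha]))[0])
    return idx, path.coefs[:, idx].copy()


def binarize_signed(coefs: np.ndarray) -> np.ndarray:
    """Map coefficients to {-1, 0, +1}, keeping only their signs."""
    coefs = np.asarray(coefs, dtype=float)
    if not np.all(np.isfinite(coefs)):
        raise ValidationError("non-finite coefficients")
    return np.sign(coefs).astype(int)
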