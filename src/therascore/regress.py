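"""Removal of unwanted sources of variation from the score matrix.

Scores computed per cell inherit technical covariation with library size,
gene detection and cell-cycle status.  This module removes it in two steps:
missing entries are first imputed with a k-nearest-neighbour average, then a
per-signature linear model of the scaled scores on the chosen covariates is
fitted via QR decomposition and its residuals kept.  Residuals stay on the
signed scale (mean zero per signature) and are NOT re-rescaled; the switch
point remains the one computed at scoring time.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .datatypes import ScoreMatrix

__all__ = ["knn_impute", "design_matrix", "regress_out"]


def knn_impute(matrix: pd.DataFrame, k: int = 10) -> pd.DataFrame:
    """Replace each NaN by the mean of the k nearest cells' values.

    Distance between two cells is the Euclidean distance over their mutually
    finite signature columns.  For a missing (cell, signature) entry the k
    nearest cells *with a finite value in that signature* act as donors.
    Signatures that are NaN in every cell are dropped with a warning; a cell
    with no finite entry at all is an error.

    A matrix with no NaN is returned unchanged (as a copy).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k >= matrix.shape[0]:
        raise ValueError(f"k={k} must be smaller than the number of cells "
                         f"({matrix.shape[0]})")
    X = matrix.to_numpy(dtype=float).copy()
    finite = np.isfinite(X)
    all_nan_cols = ~finite.any(axis=0)
    if all_nan_cols.any():
        dropped = list(matrix.columns[all_nan_cols])
        warnings.warn(f"dropping signatures that are NaN in every cell: {dropped}")
        matrix = matrix.loc[:, ~all_nan_cols]
        X = X[:, ~all_nan_cols]
        finite = finite[:, ~all_nan_cols]
    if not finite.any(axis=1).all():
        bad = list(matrix.index[~finite.any(axis=1)])
        raise ValueError(f"cells with no finite score cannot be imputed: {bad[:5]}")
    if finite.all():
        return matrix.copy()

    # pairwise squared distance over mutually finite columns
    Xf = np.where(finite, X, 0.0)
    F = finite.astype(float)
    sq = Xf**2
    d2 = sq @ F.T + F @ sq.T - 2.0 * (Xf @ Xf.T)
    shared = F @ F.T
    d2 = np.where(shared > 0, np.maximum(d2, 0.0), np.inf)
    np.fill_diagonal(d2, np.inf)

    out = X.copy()
    for i in np.where(~finite.all(axis=1))[0]:
        order = np.argsort(d2[i], kind="stable")  # ties broken by cell order
        for j in np.where(~finite[i])[0]:
            donors = order[finite[order, j] & np.isfinite(d2[i, order])][:k]
            if donors.size == 0:
                raise ValueError(
                    f"no finite donor for cell {matrix.index[i]!r}, "
                    f"signature {matrix.columns[j]!r}"
                )
            out[i, j] = X[donors, j].mean()
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def design_matrix(covars: pd.DataFrame, which: list[str]) -> pd.DataFrame:
    """Intercept + numeric covariates + one-hot dummies (first level dropped)."""
    missing = [c for c in which if c not in covars.columns]
    if missing:
        raise KeyError(f"covariates not in table: {missing}")
    parts = [pd.Series(1.0, index=covars.index, name="intercept")]
    for c in which:
        col = covars[c]
        if pd.api.types.is_numeric_dtype(col):
            vals = col.astype(float)
            if not np.isfinite(vals.to_numpy()).all():
                raise ValueError(f"covariate {c!r} has non-finite values")
            parts.append(vals)
        else:
            dummies = pd.get_dummies(col, prefix=c, drop_first=True, dtype=float)
            parts.append(dummies)
    X = pd.concat(parts, axis=1)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # identify offending columns via the QR diagonal
        _, R = np.linalg.qr(X.to_numpy())
        small = np.abs(np.diag(R)) < 1e-10 * max(1.0, np.abs(np.diag(R)).max())
        names = list(X.columns[small])
        raise ValueError(f"rank-deficient design; collinear columns: {names}")
    return X


def regress_out(
    scores: ScoreMatrix,
    covars: pd.DataFrame,
    which: list[str],
    *,
    k: int = 10,
) -> ScoreMatrix:
    """Fill ``scores.residuals`` with covariate-regressed scaled scores.

    ``covars`` is a per-cell table (indexed by cell id) of numeric and/or
    categorical covariates; ``which`` names the columns to regress out.  NaN
    entries in the scaled matrix are KNN-imputed first.  Residuals are exactly
    orthogonal to every design column (QR projection) and the operation is
    idempotent.
    """
    cells = scores.cell_ids
    missing_cells = [c for c in cells if c not in covars.index]
    if missing_cells:
        raise ValueError(f"covariates missing for cells: {missing_cells[:5]}")
    Y = scores.scaled
    if not np.isfinite(Y.to_numpy()).all():
        Y = knn_impute(Y, k=k)
    X = design_matrix(covars.loc[cells], which)
    Q, _ = np.linalg.qr(X.to_numpy())
    Ym = Y.to_numpy()
    resid = Ym - Q @ (Q.T @ Ym)
    residuals = pd.DataFrame(resid, index=Y.index, columns=Y.columns)
    prov = dict(scores.provenance)
    prov["regressed_covariates"] = list(which)
    return scores.replace(residuals=residuals, provenance=prov)
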