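"""Per-cell signature scoring and the switch point.

For every (cell, signature) pair a raw enrichment is computed as the mean
expression over the signature genes present in the matrix, separately for the
UP and DN gene sets.  Raw scores are normalised to penalise cells that detect
few of the signature genes (multiplication by the detection fraction), damp
outliers (winsorisation across cells) and centre at the across-cell median so
that zero marks typical activity.  The signed net score (UP − DN) is then
rescaled to [0, 1]; the position of net = 0 on that scale is the signature's
switch point (SP): the value where cells cross from a down-regulated status to
an up-regulated one.  SP = 0 means every cell scores positive (a uniformly
sensitive population for a sensitivity signature), SP = 1 means uniformly
resistant, intermediate SPs mean a heterogeneous response.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

from .datatypes import (
    ExpressionMatrix,
    ScoreMatrix,
    SignatureCollection,
    SignatureMode,
)

logger = logging.getLogger(__name__)

__all__ = ["raw_score", "normalise_scores", "combine_and_rescale", "bc_score"]


def raw_score(expr: ExpressionMatrix, genes) -> tuple[np.ndarray, int]:
    """Mean expression per cell over the signature genes present in the matrix.

    Returns ``(scores, n_present)``.  The sum of expression is divided by the
    number of signature genes present; with no gene present every cell gets
    NaN (and a warning is emitted).
    """
    cols = expr.gene_columns(genes)
    n_present = len(cols)
    if n_present == 0:
        warnings.warn("no signature gene present in the expression matrix")
        return np.full(expr.n_cells, np.nan), 0
    return expr.values[:, cols].sum(axis=1) / n_present, n_present


def normalise_scores(
    raw: np.ndarray,
    expr: ExpressionMatrix,
    genes,
    winsor: tuple[float, float] = (1.0, 99.0),
    *,
    penalise_zeros: bool = True,
    centre: bool = True,
) -> np.ndarray:
    """Normalise raw scores against dropout and outliers.

    Three separately toggleable steps, applied across cells:

    1. multiply each cell's raw score by its detection fraction
       ``f_i = (# signature genes with expression > 0 in cell i) / n_present``,
       penalising cells with many zeroes;
    2. winsorise at the given percentiles (default 1st/99th), damping
       outlier cells;
    3. centre by subtracting the across-cell median, so a positive normalised
       score means above-typical gene-set activity.
    """
    raw = np.asarray(raw, dtype=float)
    if not np.isfinite(raw).any():
        return np.full_like(raw, np.nan)
    cols = expr.gene_columns(genes)
    v = raw.copy()
    if penalise_zeros:
        detected = (expr.values[:, cols] > 0).sum(axis=1)
        v = v * (detected / len(cols))
    if winsor is not None and tuple(winsor) != (0.0, 100.0):
        lo, hi = np.nanpercentile(v, winsor)
        v = np.clip(v, lo, hi)
    if centre:
        v = v - np.nanmedian(v)
    return v


def combine_and_rescale(
    up_norm: np.ndarray | None = None,
    dn_norm: np.ndarray | None = None,
) -> tuple[np.ndarray, float]:
    """Combine directional normalised scores and rescale to [0, 1].

    The net score is ``up − dn`` for a bidirectional signature, ``up`` alone
    or ``−dn`` alone in the unidirectional cases.  The rescale maps the
    across-cell minimum to 0 and maximum to 1; the switch point is the image
    of net = 0, clamped to [0, 1]:

    * every cell net-positive → SP = 0 (uniformly up-regulated / sensitive);
    * every cell net-negative → SP = 1 (uniformly resistant);
    * mixed signs → SP strictly between 0 and 1, and
      ``scaled > SP  ⇔  net > 0`` cell by cell.

    A constant net score carries no direction information: all cells get 0.5
    and SP = 0.5, with a warning.
    """
    if up_norm is None and dn_norm is None:
        raise ValueError("need at least one of up_norm / dn_norm")
    if up_norm is not None and dn_norm is not None:
        net = np.asarray(up_norm, float) - np.asarray(dn_norm, float)
    elif up_norm is not None:
        net = np.asarray(up_norm, float).copy()
    else:
        net = -np.asarray(dn_norm, float)

    finite = np.isfinite(net)
    if not finite.any():
        return np.full_like(net, np.nan), float("nan")
    mn = float(net[finite].min())
    mx = float(net[finite].max())
    if mx == mn:
        warnings.warn(
            "constant net score: no direction information, SP set to 0.5"
        )
        scaled = np.where(finite, 0.5, np.nan)
        return scaled, 0.5
    scaled = (net - mn) / (mx - mn)
    sp = float(np.clip((0.0 - mn) / (mx - mn), 0.0, 1.0))
    return scaled, sp


def bc_score(
    expr: ExpressionMatrix,
    collection: SignatureCollection,
    winsor: tuple[float, float] = (1.0, 99.0),
    *,
    coverage_floor: float = 0.1,
    penalise_zeros: bool = True,
    centre: bool = True,
) -> ScoreMatrix:
    """Score every cell against every signature in the collection.

    Runs :func:`raw_score` → :func:`normalise_scores` per direction and
    :func:`combine_and_rescale` per signature.  Signatures whose gene coverage
    (fraction of the gene set present in the matrix) falls below
    ``coverage_floor`` are still scored but listed in ``flagged``; a signature
    with zero coverage yields a NaN column.

    The expression matrix is expected to be preprocessed (quality-filtered,
    normalised, log scale) — that is the caller's responsibility.
    """
    if len(collection) == 0:
        raise ValueError("empty signature collection")
    n = expr.n_cells
    scaled = np.empty((n, len(collection)))
    net = np.empty((n, len(collection)))
    sps = np.empty(len(collection))
    coverage = np.empty(len(collection))
    flagged: list[str] = []

    for j, sig in enumerate(collection):
        up_norm = dn_norm = None
        n_up = n_dn = 0
        if sig.up_genes:
            raw_u, n_up = raw_score(expr, sig.up_genes)
            if n_up:
                up_norm = normalise_scores(
                    raw_u, expr, sig.up_genes, winsor,
                    penalise_zeros=penalise_zeros, centre=centre,
                )
        if sig.dn_genes:
            raw_d, n_dn = raw_score(expr, sig.dn_genes)
            if n_dn:
                dn_norm = normalise_scores(
                    raw_d, expr, sig.dn_genes, winsor,
                    penalise_zeros=penalise_zeros, centre=centre,
                )
        coverage[j] = (n_up + n_dn) / max(len(sig.genes), 1)
        if up_norm is None and dn_norm is None:
            scaled[:, j] = np.nan
            net[:, j] = np.nan
            sps[j] = np.nan
            flagged.append(sig.name)
            logger.warning("signature %s has zero gene coverage", sig.name)
            continue
        if sig.mode is SignatureMode.BIDIRECTIONAL and (
            up_norm is None or dn_norm is None
        ):
            logger.warning(
                "signature %s: one direction absent from the matrix, "
                "scored unidirectionally", sig.name,
            )
        scaled[:, j], sps[j] = combine_and_rescale(up_norm, dn_norm)
        net[:, j] = _net(up_norm, dn_norm)
        if coverage[j] < coverage_floor:
            flagged.append(sig.name)
        logger.info(
            "signature %s: coverage %.2f, switch point %.3f",
            sig.name, coverage[j], sps[j],
        )

    names = collection.names
    return ScoreMatrix(
        scaled=pd.DataFrame(scaled, index=expr.cell_ids, columns=names),
        normalised=pd.DataFrame(net, index=expr.cell_ids, columns=names),
        switch_points=pd.Series(sps, index=names, name="switch_point"),
        coverage=pd.Series(coverage, index=names, name="coverage"),
        flagged=flagged,
        provenance={
            "collection": collection.name,
            "winsor": list(winsor) if winsor is not None else None,
            "coverage_floor": coverage_floor,
            "penalise_zeros": penalise_zeros,
            "centre": centre,
        },
    )


def _net(up_norm, dn_norm) -> np.ndarray:
    if up_norm is not None and dn_norm is not None:
        return np.asarray(up_norm, float) - np.asarray(dn_norm, float)
    if up_norm is not None:
        return np.asarray(up_norm, float)
    return -np.asarray(dn_norm, float)
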