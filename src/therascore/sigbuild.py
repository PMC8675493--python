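"""Construction of drug signatures from bulk pharmacogenomic data.

Two designs are supported, mirroring the two signature families:

* **perturbation** signatures come from a control-vs-treated contrast — the
  per-gene statistic is the t-value of the treated indicator in an OLS fit;
* **sensitivity** signatures treat the drug-response AUC as a continuous
  covariate — the statistic is the t-value of the AUC slope, positive when
  the gene is higher in resistant (high-AUC) cell lines.

Tissue/site of origin enters the model as one-hot confounder dummies.  The
UP/DN gene sets are the N most up-/down-ranked genes of the statistic
(N = 250 by default).  The drug specificity score (DSS) measures how similar
a signature's induced pattern is across cell types; its extreme deciles form
the reduced drug background used to speed up scoring.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import (
    DrugSpecificity,
    ExpressionMatrix,
    GeneSignature,
    PharmacoTable,
    SignatureCollection,
    SignatureMode,
)
from .io import cut_top_bottom
from .scoring import raw_score

__all__ = [
    "SignatureBuildConfig",
    "de_statistic",
    "make_signature",
    "dss",
    "select_background",
]


@dataclass(frozen=True)
class SignatureBuildConfig:
    """Signature-cut parameters: gene-set size and minimum cohort size."""

    n_top: int = 250
    min_samples: int = 10

    def __post_init__(self) -> None:
        if self.n_top < 1:
            raise ValueError("n_top must be >= 1")
        if self.min_samples < 1:
            raise ValueError("min_samples must be >= 1")


def _ols_t(X: np.ndarray, Y: np.ndarray, term: int) -> np.ndarray:
    """t-statistic of column ``term`` from a per-gene OLS fit of Y on X."""
    n, p = X.shape
    if n <= p:
        raise ValueError(f"too few samples ({n}) for {p} design columns")
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("rank-deficient design matrix")
    Q, R = np.linalg.qr(X)
    beta = np.linalg.solve(R, Q.T @ Y)  # p × genes
    resid = Y - X @ beta
    dof = n - p
    sigma2 = (resid**2).sum(axis=0) / dof
    xtx_inv_jj = np.linalg.inv(R.T @ R)[term, term]
    se = np.sqrt(sigma2 * xtx_inv_jj)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta[term] / se
    # a gene expressed identically in every sample carries no direction: t = 0
    flat = Y.max(axis=0) == Y.min(axis=0)
    t = np.where(flat | ((se == 0) & (beta[term] == 0)), 0.0, t)
    return t


def de_statistic(
    table: PharmacoTable,
    drug: str,
    design: str = "continuous",
    cfg: SignatureBuildConfig = SignatureBuildConfig(),
) -> pd.Series:
    """Per-gene differential-expression t-statistic for one drug.

    ``design="contrast"`` fits expression on a treated indicator (rows of the
    response table with ``arm`` in {control, treated}); ``"continuous"`` fits
    on the AUC.  Confounder dummies (first level dropped) are included when
    the table carries a confounder.  Positive statistic = higher expression
    in treated / in resistant (high-AUC) samples.
    """
    resp = table.response[table.response["drug"] == drug]
    if resp.empty:
        raise ValueError(f"no response rows for drug {drug!r}")
    if design == "contrast":
        if "arm" not in resp.columns:
            raise ValueError("contrast design needs an 'arm' response column")
        resp = resp[resp["arm"].isin(["control", "treated"])]
        counts = resp["arm"].value_counts()
        if counts.get("control", 0) < 2 or counts.get("treated", 0) < 2:
            raise ValueError("contrast design needs >= 2 samples per arm")
        samples = list(resp["sample"])
        x = (resp["arm"] == "treated").to_numpy(dtype=float)
    elif design == "continuous":
        if "auc" not in resp.columns:
            raise ValueError("continuous design needs an 'auc' response column")
        resp = resp[np.isfinite(resp["auc"].to_numpy(dtype=float))]
        if len(resp) < cfg.min_samples:
            raise ValueError(
                f"continuous design needs >= {cfg.min_samples} samples with "
                f"AUC for {drug!r}, have {len(resp)}"
            )
        samples = list(resp["sample"])
        x = resp["auc"].to_numpy(dtype=float)
    else:
        raise ValueError(f"unknown design: {design!r}")

    conf = None
    if table.confounder is not None:
        conf = table.confounder.loc[samples]
        if design == "continuous":
            counts = conf.value_counts()
            singletons = list(counts.index[counts == 1])
            if singletons:
                warnings.warn(
                    f"dropping confounder levels with a single sample: "
                    f"{singletons}"
                )
                keep = ~conf.isin(singletons).to_numpy()
                samples = [s for s, k in zip(samples, keep) if k]
                x = x[keep]
                conf = conf[keep]

    expr = table.expression.to_frame().loc[samples]
    cols = [np.ones(len(samples)), x]
    if conf is not None and conf.nunique() > 1:
        dummies = pd.get_dummies(conf, drop_first=True, dtype=float)
        cols.extend(dummies[c].to_numpy() for c in dummies.columns)
    X = np.column_stack(cols)
    t = _ols_t(X, expr.to_numpy(dtype=float), term=1)
    return pd.Series(t, index=expr.columns, name=f"{drug}_t")


def make_signature(
    stats: pd.Series,
    name: str,
    cfg: SignatureBuildConfig = SignatureBuildConfig(),
    collection_tag: str = "custom",
) -> GeneSignature:
    """Bidirectional signature from the top/bottom ``n_top`` genes of a statistic.

    Ties at the cut are broken deterministically (see
    :func:`therascore.io.cut_top_bottom`); negating the statistic swaps the UP
    and DN sets exactly.
    """
    vals = stats.to_numpy(dtype=float)
    finite = vals[np.isfinite(vals)]
    if finite.size and np.all(finite == finite[0]):
        warnings.warn(
            f"all statistics equal for {name!r}: selection is the "
            f"2·n_top lexicographically extreme gene ids"
        )
    up, dn = cut_top_bottom(stats.astype(float), cfg.n_top)
    return GeneSignature(name, up, dn, SignatureMode.BIDIRECTIONAL, collection_tag)


def dss(
    collection: SignatureCollection,
    profiles: ExpressionMatrix,
    cell_types: pd.Series,
) -> DrugSpecificity:
    """Drug specificity score: cross-cell-type similarity of signature activity.

    Each signature is scored per cell-type group as the group mean of the net
    enrichment (mean UP expression − mean DN expression per profile).  The
    DSS is ``1 − mpd/max_mpd`` where ``mpd`` is the signature's mean pairwise
    absolute difference of per-type scores: identical patterns across cell
    types give DSS = 1, the most discordant signature gets 0.  The first and
    last deciles by DSS (ceil(0.1·n) signatures each, ties broken by name)
    fill ``decile_low``/``decile_high``.
    """
    cell_types = pd.Series(cell_types).reindex(profiles.cell_ids)
    if cell_types.isna().any():
        raise ValueError("cell_types must label every profile")
    groups = list(pd.unique(cell_types))
    if len(groups) < 2:
        raise ValueError("DSS needs >= 2 cell-type groups")

    per_type = np.zeros((len(groups), len(collection)))
    for j, sig in enumerate(collection):
        up = raw_score(profiles, sig.up_genes)[0] if sig.up_genes else 0.0
        dn = raw_score(profiles, sig.dn_genes)[0] if sig.dn_genes else 0.0
        net = np.asarray(up) - np.asarray(dn)
        for gi, g in enumerate(groups):
            per_type[gi, j] = np.nanmean(net[(cell_types == g).to_numpy()])

    n_g = len(groups)
    pairs = [(a, b) for a in range(n_g) for b in range(a + 1, n_g)]
    mpd = np.array(
        [
            np.mean([abs(per_type[a, j] - per_type[b, j]) for a, b in pairs])
            for j in range(len(collection))
        ]
    )
    max_mpd = mpd.max()
    dss_vals = np.ones_like(mpd) if max_mpd == 0 else 1.0 - mpd / max_mpd
    series = pd.Series(dss_vals, index=collection.names, name="dss")

    n_dec = math.ceil(0.1 * len(collection))
    order = series.to_frame().assign(name=series.index).sort_values(
        ["dss", "name"]
    )
    decile_low = set(order.index[:n_dec])
    decile_high = set(order.index[-n_dec:])
    return DrugSpecificity(series, decile_low, decile_high)


def select_background(
    spec: DrugSpecificity, collection: SignatureCollection
) -> SignatureCollection:
    """Reduced background: the DSS extreme-decile signatures, order preserved."""
    missing = [n for n in spec.background_names if n not in collection]
    if missing:
        raise KeyError(
            f"specificity scores reference signatures not in the collection: "
            f"{sorted(missing)[:5]}"
        )
    return collection.subset(
        sorted(spec.background_names), name=f"{collection.name}_background"
    )
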