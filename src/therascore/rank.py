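"""Drug prioritisation: per-group statistics, quadrants, differential ranking.

``bc_stats`` summarises every signature within every cell group (switch
point, moments, NaN fraction, residuals' mean).  ``four_squares`` classifies
signatures for one group on the residuals'-mean (x) vs switch-point (y)
plane: the bottom-right corner holds the drugs the group is most sensitive
to, the top-left the least; the centre band holds drugs the group is
differentially (in)sensitive to relative to the other groups.
``rank_differential`` orders signatures by their between-condition effect
with permutation p-values and Benjamini–Hochberg correction, and
``correlation_modules`` groups signatures whose score profiles co-vary.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.spatial.distance as ssd
from statsmodels.stats.multitest import multipletests

from .datatypes import RankTable, ScoreMatrix

__all__ = ["bc_stats", "four_squares", "rank_differential", "correlation_modules"]


def bc_stats(scores: ScoreMatrix, groups: pd.Series) -> RankTable:
    """Summary statistics for every (signature, group) pair.

    Statistics are computed on the scaled scores with NaNs excluded from the
    moments and counted in ``prop_nan``; ``residuals_mean`` is on the residual
    scale (NaN when regression has not run).  ``sd``/``variance`` use the
    n−1 denominator.
    """
    groups = pd.Series(groups)
    if list(groups.index) != scores.cell_ids:
        groups = groups.reindex(scores.cell_ids)
        if groups.isna().any():
            raise ValueError("groups do not cover all scored cells")
    rows = []
    index = []
    scaled = scores.scaled
    resid = scores.residuals
    for g in pd.unique(groups):
        mask = (groups == g).to_numpy()
        if mask.sum() == 0:
            raise ValueError(f"empty group: {g!r}")
        sub = scaled.loc[mask]
        for sig in scores.signature_names:
            x = sub[sig].to_numpy(dtype=float)
            fin = x[np.isfinite(x)]
            if fin.size:
                mean, med = float(fin.mean()), float(np.median(fin))
                sd = float(fin.std(ddof=1)) if fin.size > 1 else 0.0
                mn, mx = float(fin.min()), float(fin.max())
            else:
                mean = med = sd = mn = mx = float("nan")
            res_mean = float("nan")
            if resid is not None:
                r = resid.loc[mask, sig].to_numpy(dtype=float)
                r = r[np.isfinite(r)]
                if r.size:
                    res_mean = float(r.mean())
            rows.append(
                {
                    "switch_point": float(scores.switch_points[sig]),
                    "mean": mean,
                    "median": med,
                    "sd": sd,
                    "variance": sd**2,
                    "min": mn,
                    "max": mx,
                    "prop_nan": float(np.isnan(x).mean()),
                    "residuals_mean": res_mean,
                }
            )
            index.append((sig, g))
    table = pd.DataFrame(
        rows, index=pd.MultiIndex.from_tuples(index, names=["signature", "group"])
    )
    return RankTable(table)


def four_squares(
    table: RankTable,
    group,
    sp_cuts: tuple[float, float] = (0.1, 0.9),
    res_quantile: float = 0.9,
) -> RankTable:
    """Classify signatures for one group into prioritisation quadrants.

    With SP on the y-axis and residuals' mean on the x-axis:

    * ``bottom_right_most_sensitive``: SP ≤ ``sp_cuts[0]`` and residuals'
      mean at or above the group's ``res_quantile`` quantile;
    * ``top_left_least_sensitive``: SP ≥ ``sp_cuts[1]`` and residuals' mean
      at or below the ``1 − res_quantile`` quantile;
    * intermediate SP with an extreme residuals' mean →
      ``differentially_sensitive`` / ``differentially_insensitive``;
    * anything else → ``unclassified``.
    """
    sub = table.for_group(group)
    res = sub["residuals_mean"].to_numpy(dtype=float)
    if np.isnan(res).all():
        raise ValueError(
            "residuals_mean is missing: run regress_out before four_squares"
        )
    lo_cut, hi_cut = sp_cuts
    q_hi = float(np.nanquantile(res, res_quantile))
    q_lo = float(np.nanquantile(res, 1.0 - res_quantile))

    out = table.table.copy()
    if "quadrant" not in out.columns:
        out["quadrant"] = "unclassified"
    for sig, row in sub.iterrows():
        sp, rm = row["switch_point"], row["residuals_mean"]
        quadrant = "unclassified"
        if np.isfinite(sp) and np.isfinite(rm):
            if sp <= lo_cut and rm >= q_hi:
                quadrant = "bottom_right_most_sensitive"
            elif sp >= hi_cut and rm <= q_lo:
                quadrant = "top_left_least_sensitive"
            elif lo_cut < sp < hi_cut and rm >= q_hi:
                quadrant = "differentially_sensitive"
            elif lo_cut < sp < hi_cut and rm <= q_lo:
                quadrant = "differentially_insensitive"
        out.loc[(sig, group), "quadrant"] = quadrant
    return RankTable(out)


def rank_differential(
    scores: ScoreMatrix,
    condition: pd.Series,
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Rank signatures by differential response between two conditions.

    The effect is the difference of group means (first condition label in
    sorted order minus the second) of the residuals — or of the scaled scores,
    with a warning, when regression has not run.  Two-sided empirical
    p-values come from ``n_perm`` label permutations with the add-one
    correction ``p = (1 + #{|perm| ≥ |obs|}) / (n_perm + 1)``; BH-FDR is
    applied across signatures and rows are sorted by decreasing |effect|.
    """
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} is low; p-value resolution is poor")
    condition = pd.Series(condition).reindex(scores.cell_ids)
    if condition.isna().any():
        raise ValueError("condition labels do not cover all cells")
    levels = sorted(pd.unique(condition))
    if len(levels) != 2:
        raise ValueError(f"need exactly 2 condition labels, got {levels}")
    if scores.residuals is not None:
        V = scores.residuals.to_numpy(dtype=float)
        scale = "residuals"
    else:
        warnings.warn("no residuals present; ranking on scaled scores")
        V = scores.scaled.to_numpy(dtype=float)
        scale = "scaled"
    names = scores.signature_names
    mask = (condition == levels[0]).to_numpy()
    if mask.sum() == 0 or (~mask).sum() == 0:
        raise ValueError("both conditions must be non-empty")

    def group_diff(m: np.ndarray) -> np.ndarray:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN slices
            a = np.nanmean(V[m], axis=0)
            b = np.nanmean(V[~m], axis=0)
        return a - b

    obs = group_diff(mask)
    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(names))
    for _ in range(n_perm):
        perm = rng.permutation(mask)
        exceed += np.abs(group_diff(perm)) >= np.abs(obs) - 1e-12
    pvals = (1.0 + exceed) / (n_perm + 1.0)
    fdr = multipletests(pvals, method="fdr_bh")[1]
    out = pd.DataFrame(
        {"effect": obs, "p_value": pvals, "fdr": fdr, "scale": scale},
        index=pd.Index(names, name="signature"),
    )
    out["abs_effect"] = np.abs(out["effect"].fillna(0.0))
    out = out.sort_values(["abs_effect", "signature"], ascending=[False, True])
    return out.drop(columns="abs_effect")


def correlation_modules(
    scores: ScoreMatrix, min_abs_r: float = 0.7
) -> tuple[pd.DataFrame, pd.Series]:
    """Drug–drug score correlations and co-response modules.

    Pearson correlation of the scaled scores across cells; signatures are
    grouped by average-linkage hierarchical clustering of the distance
    ``1 − |r|`` cut at ``1 − min_abs_r``.  Constant (or NaN) columns are
    excluded with a warning.  Returns the correlation matrix and a module-id
    Series (module ids ordered by first occurrence).
    """
    scaled = scores.scaled
    if scaled.shape[1] < 2:
        raise ValueError("need at least 2 signatures for correlation modules")
    vals = scaled.to_numpy(dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        sds = np.nanstd(vals, axis=0)
    keep = np.isfinite(sds) & (sds > 0)
    if not keep.all():
        excluded = list(scaled.columns[~keep])
        warnings.warn(f"excluding constant/NaN signatures: {excluded}")
    cols = scaled.columns[keep]
    sub = scaled.loc[:, cols]
    corr = sub.corr(method="pearson")  # pairwise-complete over cells
    if len(cols) < 2:
        raise ValueError("fewer than 2 non-constant signatures remain")
    dist = 1.0 - np.abs(corr.to_numpy())
    np.fill_diagonal(dist, 0.0)
    condensed = ssd.squareform(np.maximum(dist, 0.0), checks=False)
    linkage = sch.linkage(condensed, method="average")
    raw = sch.fcluster(linkage, t=1.0 - min_abs_r, criterion="distance")
    # stable module ids: number by first appearance in column order
    seen: dict[int, int] = {}
    ids = []
    for r in raw:
        if r not in seen:
            seen[r] = len(seen)
        ids.append(seen[r])
    modules = pd.Series(ids, index=cols, name="module")
    return corr, modules
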