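"""Independent brute-force reference implementations used by the tests.

Everything here is written as straight loops over cells/signatures with no
code shared with the package internals, so that agreement between the two
routes is a meaningful check.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm_api


def brute_signature_scores(expr, signature, winsor=(1.0, 99.0)):
    """Loop re-implementation of raw → normalise → combine for one signature.

    Returns (scaled, switch_point, net).
    """
    frame = expr.to_frame()

    def norm_one(genes):
        present = [g for g in sorted(genes) if g in frame.columns]
        if not present:
            return None
        v = []
        for cell in frame.index:
            vals = [frame.at[cell, g] for g in present]
            raw = sum(vals) / len(present)
            f = sum(1 for x in vals if x > 0) / len(present)
            v.append(raw * f)
        v = np.array(v, dtype=float)
        lo, hi = np.nanpercentile(v, winsor)
        v = np.array([min(max(x, lo), hi) for x in v])
        return v - np.nanmedian(v)

    up = norm_one(signature.up_genes) if signature.up_genes else None
    dn = norm_one(signature.dn_genes) if signature.dn_genes else None
    if up is None and dn is None:
        n = len(frame.index)
        return np.full(n, np.nan), float("nan"), np.full(n, np.nan)
    if up is not None and dn is not None:
        net = up - dn
    elif up is not None:
        net = up
    else:
        net = -dn
    mn, mx = net.min(), net.max()
    if mx == mn:
        return np.full_like(net, 0.5), 0.5, net
    scaled = (net - mn) / (mx - mn)
    sp = min(max((0.0 - mn) / (mx - mn), 0.0), 1.0)
    return scaled, sp, net


def brute_stats(scaled_df, switch_points, groups, residuals_df=None):
    """Loop recomputation of the per-(signature, group) summary statistics."""
    rows = {}
    for g in pd.unique(pd.Series(groups)):
        cells = [c for c in scaled_df.index if groups[c] == g]
        for sig in scaled_df.columns:
            vals = [scaled_df.at[c, sig] for c in cells]
            fin = [v for v in vals if not np.isnan(v)]
            n = len(fin)
            mean = sum(fin) / n
            med = float(np.median(fin))
            if n > 1:
                var = sum((v - mean) ** 2 for v in fin) / (n - 1)
            else:
                var = 0.0
            res_mean = float("nan")
            if residuals_df is not None:
                r = [residuals_df.at[c, sig] for c in cells]
                r = [v for v in r if not np.isnan(v)]
                if r:
                    res_mean = sum(r) / len(r)
            rows[(sig, g)] = {
                "switch_point": switch_points[sig],
                "mean": mean,
                "median": med,
                "sd": var**0.5,
                "variance": var,
                "min": min(fin),
                "max": max(fin),
                "prop_nan": (len(vals) - n) / len(vals),
                "residuals_mean": res_mean,
            }
    return rows


def brute_knn_impute(df, k):
    """Loop KNN imputation: plain Euclidean over mutually finite columns."""
    X = df.to_numpy(dtype=float)
    n, m = X.shape
    out = X.copy()
    for i in range(n):
        missing = [j for j in range(m) if np.isnan(X[i, j])]
        if not missing:
            continue
        dists = []
        for other in range(n):
            if other == i:
                continue
            shared = [
                c for c in range(m)
                if not np.isnan(X[i, c]) and not np.isnan(X[other, c])
            ]
            if not shared:
                continue
            d = sum((X[i, c] - X[other, c]) ** 2 for c in shared) ** 0.5
            dists.append((d, other))
        dists.sort()
        for j in missing:
            donors = [o for _, o in dists if not np.isnan(X[o, j])][:k]
            out[i, j] = sum(X[o, j] for o in donors) / len(donors)
    return pd.DataFrame(out, index=df.index, columns=df.columns)


def statsmodels_residuals(scaled_df, covars, which):
    """Per-signature OLS residuals via statsmodels (independent route)."""
    parts = [pd.Series(1.0, index=covars.index, name="intercept")]
    for c in which:
        col = covars[c]
        if pd.api.types.is_numeric_dtype(col):
            parts.append(col.astype(float))
        else:
            parts.append(pd.get_dummies(col, prefix=c, drop_first=True, dtype=float))
    X = pd.concat(parts, axis=1).loc[scaled_df.index]
    resid = {}
    for sig in scaled_df.columns:
        fit = sm_api.OLS(scaled_df[sig].to_numpy(), X.to_numpy()).fit()
        resid[sig] = fit.resid
    return pd.DataFrame(resid, index=scaled_df.index)
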