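"""Drug prioritisation statistics, quadrants, differential ranking, modules."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats

import therascore as ts

from oracles import brute_stats


def _score_matrix(scaled, residuals=None, sps=None):
    scaled = pd.DataFrame(scaled)
    if sps is None:
        sps = pd.Series(0.5, index=scaled.columns, name="switch_point")
    return ts.ScoreMatrix(scaled=scaled, normalised=scaled - 0.5,
                          switch_points=sps, residuals=residuals)


# -- bc_stats -----------------------------------------------------------------


def test_constant_signature_statistics():
    scaled = pd.DataFrame({"s": [0.4] * 10}, index=[f"c{i}" for i in range(10)])
    groups = pd.Series(["g"] * 10, index=scaled.index)
    table = ts.bc_stats(_score_matrix(scaled), groups).table
    row = table.loc[("s", "g")]
    assert row["sd"] == 0.0 and row["variance"] == 0.0
    assert row["min"] == row["max"] == row["mean"] == row["median"] == 0.4


def test_prop_nan_counts_missing_cells():
    vals = [0.1] * 8 + [np.nan, np.nan]
    scaled = pd.DataFrame({"s": vals}, index=[f"c{i}" for i in range(10)])
    groups = pd.Series(["g"] * 10, index=scaled.index)
    table = ts.bc_stats(_score_matrix(scaled), groups).table
    assert table.loc[("s", "g"), "prop_nan"] == pytest.approx(0.2)


def test_empty_group_is_error(rng):
    scaled = pd.DataFrame({"s": rng.uniform(size=5)},
                          index=[f"c{i}" for i in range(5)])
    groups = pd.Series(["a"] * 5, index=scaled.index)
    with pytest.raises(ValueError, match="cover"):
        ts.bc_stats(_score_matrix(scaled),
                    pd.Series(["a"] * 4, index=scaled.index[:4]))
    assert ts.bc_stats(_score_matrix(scaled), groups)  # sanity


def test_bc_stats_matches_brute_force(rng):
    """Every statistic equals the loop oracle to 1e−12 on a random instance."""
    n = 100
    scaled = pd.DataFrame(
        rng.uniform(size=(n, 5)), index=[f"c{i}" for i in range(n)],
        columns=[f"s{j}" for j in range(5)],
    )
    scaled[scaled < 0.03] = np.nan
    residuals = pd.DataFrame(rng.normal(size=(n, 5)), index=scaled.index,
                             columns=scaled.columns)
    sps = pd.Series(rng.uniform(size=5), index=scaled.columns)
    groups = pd.Series(rng.choice(["x", "y", "z"], size=n), index=scaled.index)
    table = ts.bc_stats(_score_matrix(scaled, residuals, sps), groups).table
    expected = brute_stats(scaled, sps, groups, residuals)
    for key, row in expected.items():
        for stat, val in row.items():
            got = table.loc[key, stat]
            if np.isnan(val):
                assert np.isnan(got)
            else:
                assert got == pytest.approx(val, abs=1e-12), (key, stat)


# -- four_squares -------------------------------------------------------------


def _rank_table_for_quadrants():
    n = 20
    sigs = [f"d{i:02d}" for i in range(n)]
    res = np.linspace(-1, 1, n)
    sp = np.full(n, 0.5)
    sp[-1], res[-1] = 0.0, res.max() + 1.0   # most sensitive corner
    sp[0], res[0] = 1.0, res.min() - 1.0     # least sensitive corner
    table = pd.DataFrame(
        {
            "switch_point": sp, "mean": 0.5, "median": 0.5, "sd": 0.1,
            "variance": 0.01, "min": 0.0, "max": 1.0, "prop_nan": 0.0,
            "residuals_mean": res,
        },
        index=pd.MultiIndex.from_tuples([(s, "tc0") for s in sigs],
                                        names=["signature", "group"]),
    )
    return ts.RankTable(table)


def test_four_squares_corner_assignments():
    out = ts.four_squares(_rank_table_for_quadrants(), "tc0").table
    assert out.loc[("d19", "tc0"), "quadrant"] == "bottom_right_most_sensitive"
    assert out.loc[("d00", "tc0"), "quadrant"] == "top_left_least_sensitive"
    assert out.loc[("d10", "tc0"), "quadrant"] == "unclassified"


def test_four_squares_centre_band_uses_residual_quantiles():
    out = ts.four_squares(_rank_table_for_quadrants(), "tc0").table
    centre = out[(out["switch_point"] == 0.5)]
    hi = centre["residuals_mean"].max()
    assert out.loc[centre[centre["residuals_mean"] == hi].index[0], "quadrant"] \
        == "differentially_sensitive"


def test_four_squares_without_residuals_instructs_regression():
    table = _rank_table_for_quadrants().table.copy()
    table["residuals_mean"] = np.nan
    with pytest.raises(ValueError, match="regress"):
        ts.four_squares(ts.RankTable(table), "tc0")


def test_four_squares_invariant_to_cell_order_and_group_names(rng):
    """Permuting cells and renaming groups leaves quadrant calls unchanged."""
    n = 80
    cells = [f"c{i}" for i in range(n)]
    scaled = pd.DataFrame(rng.uniform(size=(n, 6)), index=cells,
                          columns=[f"s{j}" for j in range(6)])
    resid = pd.DataFrame(rng.normal(size=(n, 6)), index=cells,
                         columns=scaled.columns)
    sps = pd.Series(rng.uniform(size=6), index=scaled.columns)
    groups = pd.Series(rng.choice(["a", "b"], size=n), index=cells)

    t1 = ts.four_squares(
        ts.bc_stats(_score_matrix(scaled, resid, sps), groups), "a"
    ).table["quadrant"]

    perm = rng.permutation(n)
    renamed = groups.iloc[perm].map({"a": "group_one", "b": "group_two"})
    sm2 = _score_matrix(scaled.iloc[perm], resid.iloc[perm], sps)
    t2 = ts.four_squares(ts.bc_stats(sm2, renamed), "group_one").table["quadrant"]
    for sig in scaled.columns:
        assert t1.loc[(sig, "a")] == t2.loc[(sig, "group_one")]


# -- rank_differential --------------------------------------------------------


def test_planted_shift_ranks_first_with_small_fdr(rng):
    n = 200
    cells = [f"c{i}" for i in range(n)]
    cond = pd.Series(["A"] * 100 + ["B"] * 100, index=cells)
    resid = pd.DataFrame(rng.normal(size=(n, 8)), index=cells,
                         columns=[f"s{j}" for j in range(8)])
    resid.loc[cond == "A", "s3"] += 3.0
    sm = _score_matrix(pd.DataFrame(0.5, index=cells, columns=resid.columns),
                       residuals=resid)
    out = ts.rank_differential(sm, cond, n_perm=500, seed=0)
    assert out.index[0] == "s3"
    assert out.loc["s3", "fdr"] < 0.05
    assert out.loc["s3", "effect"] == pytest.approx(3.0, abs=0.5)


def test_constant_signature_has_zero_effect_p_one(rng):
    n = 40
    cells = [f"c{i}" for i in range(n)]
    cond = pd.Series(["A", "B"] * 20, index=cells)
    resid = pd.DataFrame(
        {"flat": np.full(n, 0.25), "noise": rng.normal(size=n)}, index=cells
    )
    sm = _score_matrix(pd.DataFrame(0.5, index=cells, columns=resid.columns),
                       residuals=resid)
    out = ts.rank_differential(sm, cond, n_perm=200, seed=0)
    assert out.loc["flat", "effect"] == 0.0
    assert out.loc["flat", "p_value"] == 1.0


def test_falls_back_to_scaled_scores_with_warning(rng):
    n = 30
    cells = [f"c{i}" for i in range(n)]
    cond = pd.Series(["A"] * 15 + ["B"] * 15, index=cells)
    sm = _score_matrix(pd.DataFrame(rng.uniform(size=(n, 3)), index=cells,
                                    columns=list("abc")))
    with pytest.warns(UserWarning, match="scaled"):
        out = ts.rank_differential(sm, cond, n_perm=150, seed=0)
    assert (out["scale"] == "scaled").all()


def test_null_permutation_pvalues_are_uniform():
    """200 replicates of a no-effect instance: KS does not reject uniformity
    of the permutation p-values at α = 0.01, and FDR<0.05 calls are rare."""
    rng = np.random.default_rng(99)
    pvals = []
    any_hit = 0
    n_reps = 200
    for _ in range(n_reps):
        n = 30
        cells = [f"c{i}" for i in range(n)]
        cond = pd.Series(rng.permutation(["A"] * 15 + ["B"] * 15), index=cells)
        resid = pd.DataFrame(rng.normal(size=(n, 5)), index=cells,
                             columns=[f"s{j}" for j in range(5)])
        sm = _score_matrix(
            pd.DataFrame(0.5, index=cells, columns=resid.columns),
            residuals=resid,
        )
        out = ts.rank_differential(sm, cond, n_perm=199,
                                   seed=int(rng.integers(2**31)))
        pvals.append(out.loc["s0", "p_value"])  # one fixed p per replicate: iid
        any_hit += (out["fdr"] < 0.05).any()
    ks = scipy.stats.kstest(pvals, "uniform")
    assert ks.pvalue > 0.01
    assert any_hit / n_reps <= 0.05


# -- correlation modules ------------------------------------------------------


def test_duplicated_signature_shares_module(rng):
    n = 200
    x = rng.normal(size=n)
    scaled = pd.DataFrame(
        {"a": x, "a_copy": x, "b": rng.normal(size=n)},
        index=[f"c{i}" for i in range(n)],
    )
    corr, modules = ts.correlation_modules(_score_matrix(scaled))
    assert corr.loc["a", "a_copy"] == pytest.approx(1.0)
    assert modules["a"] == modules["a_copy"]
    assert modules["a"] != modules["b"]


def test_independent_signatures_split_modules(rng):
    n = 1000
    scaled = pd.DataFrame(rng.normal(size=(n, 2)), columns=["x", "y"],
                          index=[f"c{i}" for i in range(n)])
    corr, modules = ts.correlation_modules(_score_matrix(scaled))
    assert abs(corr.loc["x", "y"]) < 0.15
    assert modules["x"] != modules["y"]


def test_shared_latent_factor_forms_one_module(rng):
    """Three signatures loading 0.9 on one factor group into one module."""
    n = 500
    factor = rng.normal(size=n)
    noise = rng.normal(size=(n, 4))
    scaled = pd.DataFrame(
        {
            "f1": 0.9 * factor + np.sqrt(1 - 0.81) * noise[:, 0],
            "f2": 0.9 * factor + np.sqrt(1 - 0.81) * noise[:, 1],
            "f3": 0.9 * factor + np.sqrt(1 - 0.81) * noise[:, 2],
            "indep": noise[:, 3],
        },
        index=[f"c{i}" for i in range(n)],
    )
    _, modules = ts.correlation_modules(_score_matrix(scaled))
    assert modules["f1"] == modules["f2"] == modules["f3"]
    assert modules["indep"] != modules["f1"]


def test_constant_column_excluded_with_warning(rng):
    scaled = pd.DataFrame(
        {"flat": np.ones(50), "x": rng.normal(size=50), "y": rng.normal(size=50)},
        index=[f"c{i}" for i in range(50)],
    )
    with pytest.warns(UserWarning, match="constant"):
        corr, modules = ts.correlation_modules(_score_matrix(scaled))
    assert "flat" not in corr.columns and "flat" not in modules.index
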