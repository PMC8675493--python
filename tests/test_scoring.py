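"""Per-cell scoring: raw means, dropout/outlier normalisation, switch points."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import therascore as ts
from therascore.scoring import combine_and_rescale, normalise_scores, raw_score

from oracles import brute_signature_scores


# -- raw_score ----------------------------------------------------------------


def test_raw_score_divides_by_present_genes(small_expr):
    """Genes absent from the matrix shrink the denominator, not the sum."""
    scores, n_present = raw_score(small_expr, {"g1", "g2", "g3", "gX"})
    assert n_present == 3
    assert scores[0] == pytest.approx((2.0 + 0.0 + 4.0) / 3)


def test_raw_score_empty_intersection_is_nan(small_expr):
    with pytest.warns(UserWarning, match="no signature gene"):
        scores, n_present = raw_score(small_expr, {"nope1", "nope2"})
    assert n_present == 0
    assert np.isnan(scores).all()


def test_raw_score_matches_brute_force_loop(random_expr, rng):
    genes = {f"g{j}" for j in rng.choice(60, size=17, replace=False)}
    scores, n = raw_score(random_expr, genes)
    frame = random_expr.to_frame()
    present = [g for g in genes if g in frame.columns]
    for i, cell in enumerate(frame.index):
        expected = sum(frame.at[cell, g] for g in present) / len(present)
        assert scores[i] == pytest.approx(expected, abs=1e-12)


# -- normalise_scores ---------------------------------------------------------


def test_zero_detection_cell_is_penalised_to_minus_median():
    """A cell expressing none of the signature genes scores 0 − median."""
    vals = np.array([[1.0, 2.0], [0.0, 0.0], [2.0, 1.0], [3.0, 1.0], [1.0, 1.0]])
    expr = ts.ExpressionMatrix(vals, [f"c{i}" for i in range(5)], ["g1", "g2"])
    raw, _ = raw_score(expr, {"g1", "g2"})
    norm = normalise_scores(raw, expr, {"g1", "g2"}, winsor=(0.0, 100.0))
    weighted = raw * np.array([1.0, 0.0, 1.0, 1.0, 1.0])
    assert norm[1] == pytest.approx(0.0 - np.median(weighted))


def test_identical_cells_normalise_to_zero():
    vals = np.tile([1.0, 2.0, 3.0], (6, 1))
    expr = ts.ExpressionMatrix(vals, [f"c{i}" for i in range(6)], ["g1", "g2", "g3"])
    raw, _ = raw_score(expr, {"g1", "g2", "g3"})
    norm = normalise_scores(raw, expr, {"g1", "g2", "g3"})
    np.testing.assert_allclose(norm, 0.0, atol=1e-15)


def test_winsor_caps_outlier_at_percentile(rng):
    """A 100× outlier ends up exactly at the pre-centring 99th percentile."""
    base = rng.uniform(1.0, 2.0, size=200)
    base[17] = 150.0
    expr = ts.ExpressionMatrix(base[:, None], [f"c{i}" for i in range(200)], ["g1"])
    raw, _ = raw_score(expr, {"g1"})
    weighted = raw * (base > 0)
    hi = np.percentile(weighted, 99)
    norm = normalise_scores(raw, expr, {"g1"}, winsor=(1.0, 99.0), centre=False)
    assert norm[17] == pytest.approx(hi)


def test_all_nan_raw_propagates():
    vals = np.ones((3, 2))
    expr = ts.ExpressionMatrix(vals, ["a", "b", "c"], ["g1", "g2"])
    norm = normalise_scores(np.full(3, np.nan), expr, {"g1"})
    assert np.isnan(norm).all()


# -- combine_and_rescale ------------------------------------------------------


@pytest.mark.parametrize(
    "net, expected_sp",
    [
        (np.array([0.3, 0.6]), 0.0),          # uniformly up-regulated
        (np.array([-1.0, -0.5, -0.2]), 1.0),  # uniformly down-regulated
        (np.array([-1.0, 1.0]), 0.5),         # symmetric mixed response
    ],
    ids=["all_positive", "all_negative", "symmetric"],
)
def test_switch_point_semantics(net, expected_sp):
    scaled, sp = combine_and_rescale(up_norm=net)
    assert sp == pytest.approx(expected_sp)
    assert scaled.min() == 0.0 and scaled.max() == 1.0


def test_symmetric_net_scales_to_unit_interval_ends():
    scaled, sp = combine_and_rescale(up_norm=np.array([-1.0, 1.0]))
    np.testing.assert_allclose(scaled, [0.0, 1.0])
    assert sp == 0.5


def test_dn_only_flips_sign():
    """For a DN-only signature high DN activity means a low net score."""
    dn = np.array([1.0, -1.0, 0.5])
    scaled, sp = combine_and_rescale(dn_norm=dn)
    expected, sp2 = combine_and_rescale(up_norm=-dn)
    np.testing.assert_allclose(scaled, expected)
    assert sp == sp2


def test_constant_net_gives_half_with_warning():
    with pytest.warns(UserWarning, match="constant net"):
        scaled, sp = combine_and_rescale(up_norm=np.array([2.0, 2.0, 2.0]))
    assert sp == 0.5
    np.testing.assert_array_equal(scaled, 0.5)


def test_all_nan_gives_nan_column():
    scaled, sp = combine_and_rescale(up_norm=np.array([np.nan, np.nan]))
    assert np.isnan(scaled).all() and np.isnan(sp)


@settings(derandomize=True, max_examples=50)
@given(
    st.lists(st.floats(-50, 50, allow_nan=False), min_size=2, max_size=40),
    st.lists(st.floats(-50, 50, allow_nan=False), min_size=2, max_size=40),
)
def test_scaled_bounds_and_sign_consistency_property(up, dn):
    """scaled ∈ [0,1]; net > 0 ⇔ scaled > SP for interior switch points."""
    n = min(len(up), len(dn))
    up_arr, dn_arr = np.array(up[:n]), np.array(dn[:n])
    import warnings as w

    with w.catch_warnings():
        w.simplefilter("ignore")
        scaled, sp = combine_and_rescale(up_arr, dn_arr)
    net = up_arr - dn_arr
    assert np.all(scaled >= 0.0) and np.all(scaled <= 1.0)
    assert 0.0 <= sp <= 1.0
    if np.allclose(net, net[0]):
        return  # degenerate: SP fixed at 0.5 by convention
    span = net.max() - net.min()
    tol = 1e-9 * span  # cells with |net| below float resolution are ambiguous
    clear = np.abs(net) > tol
    if 0.0 < sp < 1.0:
        assert np.array_equal(net[clear] > 0, scaled[clear] > sp)
    elif sp == 0.0:
        assert np.all(net >= -tol)  # no cell strictly down-regulated
    else:
        assert np.all(net <= tol)  # no cell strictly up-regulated


# -- bc_score -----------------------------------------------------------------


def test_bc_score_shape_bounds_and_invariants(random_expr, random_collection):
    sm = ts.bc_score(random_expr, random_collection)
    assert sm.scaled.shape == (200, 3)
    assert len(sm.switch_points) == 3
    sm.validate()
    # min 0 / max 1 attained per non-degenerate signature
    for sig in sm.signature_names:
        col = sm.scaled[sig].dropna()
        assert col.min() == pytest.approx(0.0)
        assert col.max() == pytest.approx(1.0)


def test_bc_score_empty_collection_is_error(random_expr):
    with pytest.raises(ValueError, match="empty"):
        ts.bc_score(random_expr, ts.SignatureCollection([], name="none"))


def test_bc_score_matches_brute_force_loop(random_expr, random_collection):
    """Full scoring pipeline equals an independent straight-loop oracle."""
    sm = ts.bc_score(random_expr, random_collection)
    for sig in random_collection:
        scaled, sp, net = brute_signature_scores(random_expr, sig)
        np.testing.assert_allclose(
            sm.scaled[sig.name].to_numpy(), scaled, atol=1e-10
        )
        np.testing.assert_allclose(
            sm.normalised[sig.name].to_numpy(), net, atol=1e-10
        )
        assert sm.switch_points[sig.name] == pytest.approx(sp, abs=1e-10)


def test_zero_coverage_signature_is_nan_and_flagged(random_expr):
    coll = ts.SignatureCollection(
        [
            ts.GeneSignature("present", {"g1", "g2"}, {"g3"}),
            ts.GeneSignature("absent", {"zz1"}, {"zz2"}),
        ]
    )
    with pytest.warns(UserWarning):
        sm = ts.bc_score(random_expr, coll)
    assert sm.scaled["absent"].isna().all()
    assert np.isnan(sm.switch_points["absent"])
    assert "absent" in sm.flagged
    assert sm.coverage["present"] == 1.0


def test_direction_antisymmetry(random_expr, random_collection):
    """Swapping UP and DN maps net → −net, SP → 1−SP, scaled → 1−scaled."""
    sig = random_collection["sigA"]
    flipped = ts.SignatureCollection([sig.flipped()])
    sm = ts.bc_score(random_expr, ts.SignatureCollection([sig]))
    sm_f = ts.bc_score(random_expr, flipped)
    np.testing.assert_allclose(
        sm_f.normalised[sig.name], -sm.normalised[sig.name], atol=1e-12
    )
    assert sm_f.switch_points[sig.name] == pytest.approx(
        1 - sm.switch_points[sig.name], abs=1e-12
    )
    np.testing.assert_allclose(
        sm_f.scaled[sig.name], 1 - sm.scaled[sig.name], atol=1e-12
    )


def test_up_gene_increase_is_monotone_in_net(rng):
    """Raising one UP gene in one cell never lowers that cell's net score."""
    vals = np.exp(rng.normal(size=(50, 20)))
    gene_ids = [f"g{j}" for j in range(20)]
    sig = ts.GeneSignature("s", frozenset(gene_ids[:6]), frozenset(gene_ids[6:12]))
    coll = ts.SignatureCollection([sig])
    base = ts.bc_score(ts.ExpressionMatrix(vals, [f"c{i}" for i in range(50)],
                                           gene_ids), coll)
    for delta in (0.1, 1.0, 10.0):
        bumped = vals.copy()
        bumped[7, 2] += delta  # g2 is an UP gene
        sm = ts.bc_score(
            ts.ExpressionMatrix(bumped, [f"c{i}" for i in range(50)], gene_ids),
            coll,
        )
        assert (
            sm.normalised["s"].iloc[7] >= base.normalised["s"].iloc[7] - 1e-12
        )


def test_planted_clone_scores_higher_on_matched_signature():
    """2σ planted effect separates clone means by > 0.2 on the scaled scale."""
    cfg = ts.SimConfig(
        n_cells=300,
        clones=(
            ts.CloneSpec(0.5, (2.0, 0.0, 0.0, 0.0, 0.0, 0.0)),
            ts.CloneSpec(0.5, (0.0,) * 6),
        ),
        seed=11,
    )
    expr, coll, truth, _ = ts.simulate(cfg)
    sm = ts.bc_score(expr, coll)
    sensitive = sm.scaled.loc[(truth == 0).to_numpy(), "sig0"].mean()
    resistant = sm.scaled.loc[(truth == 1).to_numpy(), "sig0"].mean()
    assert sensitive - resistant > 0.2
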