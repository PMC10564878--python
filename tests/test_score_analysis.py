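"""Quantile normalization, differential scores, correlation and clustering."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import biasaudit as ba


# -- quantile normalization ----------------------------------------------

def test_quantile_normalize_two_columns_worked_example():
    m = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [4.0, 5.0, 6.0]})
    out = ba.quantile_normalize(m)
    for col in out:
        np.testing.assert_allclose(np.sort(out[col]), [2.5, 3.5, 4.5])


def test_quantile_normalize_is_fixed_point_on_identical_columns():
    m = pd.DataFrame({"a": [3.0, 1.0, 2.0], "b": [3.0, 1.0, 2.0]})
    out = ba.quantile_normalize(m)
    pd.testing.assert_frame_equal(out, m)


def test_quantile_normalize_ties_get_equal_values():
    m = pd.DataFrame({"a": [1.0, 1.0, 5.0], "b": [2.0, 4.0, 6.0]})
    out = ba.quantile_normalize(m)
    # tied entries span sorted positions 1 and 2 -> mean of those row means
    mean_sorted = np.sort(m.values, axis=0).mean(axis=1)
    expected = (mean_sorted[0] + mean_sorted[1]) / 2
    assert out.loc[0, "a"] == out.loc[1, "a"] == pytest.approx(expected)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(
    st.lists(st.floats(-100, 100, allow_nan=False, width=32),
             min_size=21, max_size=21, unique=True)
)
def test_quantile_normalize_invariants(flat):
    # tie handling is covered separately; the sorted-profile identity is a
    # statement about tie-free columns
    values = np.array(flat).reshape(7, 3)
    m = pd.DataFrame(values, columns=list("abc"))
    out = ba.quantile_normalize(m)
    # all column-sorted vectors identical
    ref = np.sort(out["a"].values)
    for col in "bc":
        np.testing.assert_allclose(np.sort(out[col].values), ref, atol=1e-12)
    # rank order preserved up to ties
    for col in "abc":
        orig_rank = m[col].rank(method="average")
        new_rank = out[col].rank(method="average")
        np.testing.assert_allclose(orig_rank, new_rank)
    # idempotent
    again = ba.quantile_normalize(out)
    pd.testing.assert_frame_equal(again, out, atol=1e-12)


def test_quantile_normalize_rejects_missing_and_single_column():
    with pytest.raises(ValueError, match="missing"):
        ba.quantile_normalize(pd.DataFrame({"a": [1.0, np.nan], "b": [1.0, 2.0]}))
    with pytest.raises(ValueError, match="2 columns"):
        ba.quantile_normalize(pd.DataFrame({"a": [1.0, 2.0]}))


# -- differential scores -------------------------------------------------

def _mat(seed, nodes=8, cols=3, scale=1.0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(rng.random((nodes, cols)) * scale,
                        index=[f"n{i}" for i in range(nodes)],
                        columns=[f"c{j}" for j in range(cols)])


def test_identical_setups_give_zero_differential():
    m = _mat(0)
    table = ba.differential_scores(m, m.copy())
    np.testing.assert_allclose(table["differential"], 0.0, atol=1e-12)


def test_differential_is_antisymmetric():
    a, b = _mat(1), _mat(2)
    fwd = ba.differential_scores(a, b)
    rev = ba.differential_scores(b, a)
    np.testing.assert_allclose(fwd["differential"], -rev["differential"], atol=1e-12)


def test_control_dominated_node_gets_negative_differential():
    a, b = _mat(3), _mat(4)
    a.loc["n0"] = 0.01   # weak under real data
    b.loc["n0"] = 0.99   # strong under the control: bias-driven importance
    table = ba.differential_scores(a, b)
    assert table.loc["n0", "differential"] < 0


def test_differential_requires_shared_node_set():
    a, b = _mat(5), _mat(6)
    with pytest.raises(ValueError, match="node sets"):
        ba.differential_scores(a, b.drop(index="n0"))


def test_layer_ranks_are_per_layer():
    a, b = _mat(7), _mat(8)
    layers = pd.Series({f"n{i}": (0 if i < 4 else 1) for i in range(8)})
    table = ba.differential_scores(a, b, layers=layers)
    for _, sub in table.groupby("layer"):
        assert sorted(sub["layer_rank"]) == [1.0, 2.0, 3.0, 4.0]


# -- cross-setup correlation and clustering ------------------------------

def test_duplicate_and_negated_columns():
    m = _mat(9, nodes=10, cols=1)
    m["dup"] = m["c0"]
    m["neg"] = -m["c0"]
    corr, order, link = ba.cross_setup_correlation(m)
    assert corr.loc["c0", "dup"] == pytest.approx(1.0)
    assert corr.loc["c0", "neg"] == pytest.approx(-1.0)
    # distance 0 pair merges before anything else
    assert {order.index("c0"), order.index("dup")} in ({0, 1}, {1, 2})


def test_complete_linkage_merges_closest_pair_first():
    m = pd.DataFrame({
        "a": [1.0, 2.0, 3.0, 4.0],
        "b": [1.1, 2.0, 3.0, 4.2],
        "c": [4.0, 3.0, 2.0, 1.0],
    })
    corr, order, link = ba.cross_setup_correlation(m)
    # a and b are nearly identical -> first merge joins leaves 0 and 1
    first = sorted(int(v) for v in link[0, :2])
    assert first == [0, 1]
    assert abs(order.index("a") - order.index("b")) == 1


def test_zero_variance_column_is_rejected():
    m = _mat(10)
    m["flat"] = 1.0
    with pytest.raises(ValueError, match="zero-variance"):
        ba.cross_setup_correlation(m)


def test_newick_export_contains_all_leaves():
    m = _mat(11, nodes=12, cols=4)
    corr, order, link = ba.cross_setup_correlation(m)
    nwk = ba.linkage_to_newick(link, list(corr.columns))
    assert nwk.endswith(";")
    for leaf in corr.columns:
        assert leaf in nwk


# -- centrality correlation ----------------------------------------------

def test_constant_measure_within_layer_is_missing_not_zero():
    cent = pd.DataFrame({
        "layer": [1, 1, 1, 2, 2, 2],
        "indegree": [3, 3, 3, 1, 2, 4],
        "reachability": [4, 4, 4, 5, 7, 9],
    }, index=[f"n{i}" for i in range(6)])
    imp = pd.Series([0.5, 0.2, 0.9, 1.0, 2.0, 4.0], index=cent.index)
    out = ba.centrality_correlation(imp, cent, measures=("indegree", "reachability"))
    assert np.isnan(out.loc[1, "indegree"])
    assert np.isnan(out.loc[1, "reachability"])
    assert out.loc[2, "indegree"] == pytest.approx(1.0)


def test_importance_proportional_to_centrality_gives_r_one():
    cent = pd.DataFrame({"layer": [1] * 5, "reachability": [2, 4, 6, 8, 11]},
                        index=[f"n{i}" for i in range(5)])
    imp = pd.Series([0.2, 0.4, 0.6, 0.8, 1.1], index=cent.index)
    out = ba.centrality_correlation(imp, cent, measures=("reachability",))
    assert out.loc[1, "reachability"] == pytest.approx(1.0)


def test_random_importance_correlation_centered_at_zero():
    rng = np.random.default_rng(12)
    cent = pd.DataFrame({"layer": [1] * 30,
                         "reachability": rng.integers(2, 50, 30)},
                        index=[f"n{i}" for i in range(30)])
    imp_vals = rng.random(30)
    rs = []
    for _ in range(1000):
        perm = rng.permutation(imp_vals)
        imp = pd.Series(perm, index=cent.index)
        rs.append(ba.centrality_correlation(imp, cent,
                                            measures=("reachability",)).loc[1, "reachability"])
    assert abs(np.mean(rs)) < 0.02
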