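"""Layered-DAG validation, masks, and centrality against brute-force oracles."""

import numpy as np
import pytest

import biasaudit as ba
from biasaudit.graphkit import StructuralError

from conftest import random_layered_dag


# -- independent oracles -------------------------------------------------

def brute_reachability(dag: ba.LayeredDAG) -> dict[str, int]:
    """Transitive closure by repeated edge expansion until fixpoint."""
    anc = {n: set() for n in dag.nodes}
    changed = True
    while changed:
        changed = False
        for s, t in dag.edges:
            new = anc[s] | {s}
            if not new <= anc[t]:
                anc[t] |= new
                changed = True
    return {n: len(anc[n]) + 1 for n in dag.nodes}


def brute_betweenness(dag: ba.LayeredDAG) -> dict[str, float]:
    """Exhaustive path enumeration with fractional shortest-path counting."""
    succ = {n: [] for n in dag.nodes}
    for s, t in dag.edges:
        succ[s].append(t)

    def all_paths(s, t):
        out, stack = [], [[s]]
        while stack:
            path = stack.pop()
            if path[-1] == t:
                out.append(path)
                continue
            for nxt in succ[path[-1]]:
                stack.append(path + [nxt])
        return out

    score = dict.fromkeys(dag.nodes, 0.0)
    for s in dag.nodes:
        for t in dag.nodes:
            if s == t:
                continue
            paths = all_paths(s, t)
            if not paths:
                continue
            shortest = min(len(p) for p in paths)
            sp = [p for p in paths if len(p) == shortest]
            for p in sp:
                for v in p[1:-1]:
                    score[v] += 1.0 / len(sp)
    return score


# -- validation ----------------------------------------------------------

@pytest.mark.parametrize(
    "nodes, edges, message",
    [
        ({"a": 0, "b": 2}, (("a", "b"),), "skips layers"),
        ({"a": 0, "b": 1}, (("a", "b"), ("a", "b")), "duplicate"),
        ({"a": 0, "b": 1, "c": 1}, (("a", "b"),), "no incoming edge"),
    ],
)
def test_invalid_graphs_are_rejected(nodes, edges, message):
    with pytest.raises(StructuralError, match=message):
        ba.LayeredDAG(nodes=nodes, edges=edges)


def test_masks_transcribe_edges_and_flag_orphans():
    dag = ba.LayeredDAG(nodes={"x": 0, "y": 0, "h": 1}, edges=(("x", "h"), ("y", "h")))
    masks = ba.build_masks(dag)
    assert len(masks) == 1
    np.testing.assert_array_equal(masks[0], [[1], [1]])


def test_mask_entry_sums_equal_edge_count():
    rng = np.random.default_rng(5)
    for _ in range(10):
        dag = random_layered_dag(rng)
        masks = ba.build_masks(dag)
        assert sum(int(m.sum()) for m in masks) == len(dag.edges)


# -- centrality ----------------------------------------------------------

def test_reachability_counts_ancestors_plus_self(chain_dag):
    reach = ba.reachability(chain_dag)
    assert reach == {"a": 1, "b": 2, "c": 3}


def test_layer1_node_with_three_feature_parents_has_reachability_4():
    # three feature-type inputs (mutation, amplification, deletion) feeding one gene
    dag = ba.LayeredDAG(
        nodes={"g_mut": 0, "g_amp": 0, "g_del": 0, "g": 1},
        edges=(("g_mut", "g"), ("g_amp", "g"), ("g_del", "g")),
    )
    assert ba.reachability(dag)["g"] == 4


def test_reachability_matches_brute_force_on_random_dags():
    rng = np.random.default_rng(17)
    for _ in range(15):
        dag = random_layered_dag(rng)
        assert len(dag.nodes) <= 50
        assert ba.reachability(dag) == brute_reachability(dag)


def test_betweenness_chain_and_diamond(chain_dag, diamond_dag):
    assert ba.betweenness(chain_dag) == pytest.approx({"a": 0, "b": 1, "c": 0})
    # two shortest a->d paths, one through each middle node
    assert ba.betweenness(diamond_dag)["b"] == pytest.approx(0.5)


def test_betweenness_matches_exhaustive_enumeration():
    rng = np.random.default_rng(23)
    for _ in range(10):
        dag = random_layered_dag(rng)
        assert len(dag.nodes) <= 20
        got = ba.betweenness(dag)
        want = brute_betweenness(dag)
        for n in dag.nodes:
            assert got[n] == pytest.approx(want[n], abs=1e-9)


def test_raw_count_betweenness_counts_every_path(diamond_dag):
    raw = ba.betweenness(diamond_dag, fractional=False)
    assert raw["b"] == 1.0  # whole path counted, not sigma-fraction


def test_degree_handshake_identity():
    rng = np.random.default_rng(31)
    dag = random_layered_dag(rng, layer_sizes=[5, 6, 4])
    indeg, outdeg = ba.degrees(dag)
    assert sum(indeg.values()) == sum(outdeg.values()) == len(dag.edges)
    for src in dag.layer_nodes(0):
        assert indeg[src] == 0


def test_layer1_reachability_equals_indegree_plus_one():
    rng = np.random.default_rng(41)
    dag = random_layered_dag(rng, layer_sizes=[6, 5, 3])
    reach = ba.reachability(dag)
    indeg, _ = ba.degrees(dag)
    for n in dag.layer_nodes(1):
        assert reach[n] == indeg[n] + 1


def test_centrality_invariant_to_relabeling():
    rng = np.random.default_rng(47)
    dag = random_layered_dag(rng, layer_sizes=[4, 4, 2])
    mapping = {n: f"zz_{i}" for i, n in enumerate(sorted(dag.nodes))}
    relabeled = ba.LayeredDAG(
        nodes={mapping[n]: l for n, l in dag.nodes.items()},
        edges=tuple((mapping[s], mapping[t]) for s, t in dag.edges),
    )
    for fn in (ba.reachability, ba.betweenness):
        orig, new = fn(dag), fn(relabeled)
        for n in dag.nodes:
            assert orig[n] == pytest.approx(new[mapping[n]])


def test_centrality_table_layout(small_dag):
    table = ba.centrality_table(small_dag)
    assert list(table.columns) == ["layer", "indegree", "outdegree", "reachability", "betweenness"]
    assert (table["reachability"] >= 1).all()
    assert table["layer"].is_monotonic_increasing


# -- hierarchy file round-trip -------------------------------------------

def test_hierarchy_roundtrip_exact(tmp_path, small_dag):
    path = tmp_path / "hierarchy.tsv"
    ba.write_hierarchy(small_dag, path)
    back = ba.read_hierarchy(path)
    assert back.nodes == small_dag.nodes
    assert sorted(back.edges) == sorted(small_dag.edges)


def test_hierarchy_reader_rejects_bad_header(tmp_path):
    p = tmp_path / "h.tsv"
    p.write_text("src\tdst\tlayer\na\tb\t1\n")
    with pytest.raises(ValueError, match="header"):
        ba.read_hierarchy(p)
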