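"""Layered knowledge DAGs: validation, connectivity masks, and centrality.

A biology-inspired network is built on a strictly layered directed acyclic
graph whose layer-0 nodes are input features (e.g. per-gene mutation /
amplification / deletion indicators), whose deeper layers are biological
entities (genes, pathways), and whose edges encode known relationships.
The prediction head sits after the maximum layer and is *not* a DAG node;
all centrality measures are computed on the input and hidden nodes only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd


class StructuralError(ValueError):
    """The graph violates the strictly-layered feed-forward contract."""


@dataclass(frozen=True)
class LayeredDAG:
    """A strictly layered feed-forward DAG.

    Parameters
    ----------
    nodes
        Mapping ``node_id -> layer`` with layer 0 holding input feature
        nodes and the maximum layer adjacent to the prediction output.
    edges
        Directed ``(source_id, target_id)`` pairs; every edge must go from
        layer ``L`` to layer ``L + 1``.
    """

    nodes: dict[str, int]
    edges: tuple[tuple[str, str], ...]
    _graph: nx.DiGraph = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "edges", tuple(self.edges))
        self._validate()
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        if not nx.is_directed_acyclic_graph(g):  # implied by layering, still asserted
            raise StructuralError("graph contains a cycle")
        object.__setattr__(self, "_graph", g)

    # -- validation -----------------------------------------------------

    def _validate(self) -> None:
        if len(set(self.edges)) != len(self.edges):
            raise StructuralError("duplicate edges")
        for layer in self.nodes.values():
            if layer < 0:
                raise StructuralError("negative layer index")
        indeg: dict[str, int] = {n: 0 for n in self.nodes}
        for src, dst in self.edges:
            if src not in self.nodes or dst not in self.nodes:
                raise StructuralError(f"edge ({src!r}, {dst!r}) references unknown node")
            if self.nodes[dst] != self.nodes[src] + 1:
                raise StructuralError(
                    f"edge ({src!r}, {dst!r}) skips layers "
                    f"({self.nodes[src]} -> {self.nodes[dst]})"
                )
            indeg[dst] += 1
        for node, layer in self.nodes.items():
            if layer > 0 and indeg[node] == 0:
                raise StructuralError(f"node {node!r} in layer {layer} has no incoming edge")

    # -- structure ------------------------------------------------------

    @property
    def n_layers(self) -> int:
        return max(self.nodes.values()) + 1

    def layer_nodes(self, layer: int) -> list[str]:
        """Node ids of one layer in the canonical (lexicographic) order."""
        return sorted(n for n, l in self.nodes.items() if l == layer)

    @property
    def hidden_nodes(self) -> list[str]:
        """All non-input nodes, ordered by (layer, node id)."""
        out: list[str] = []
        for layer in range(1, self.n_layers):
            out.extend(self.layer_nodes(layer))
        return out

    def graph(self) -> nx.DiGraph:
        return self._graph.copy()


def build_masks(dag: LayeredDAG) -> list[np.ndarray]:
    """Binary connectivity masks, one per layer transition.

    ``masks[L]`` has one row per layer-``L`` node and one column per
    layer-``L+1`` node (both lexicographically ordered, matching
    :meth:`LayeredDAG.layer_nodes`); an entry is 1 iff the edge exists.
    """
    masks = []
    for layer in range(dag.n_layers - 1):
        rows = dag.layer_nodes(layer)
        cols = dag.layer_nodes(layer + 1)
        if not cols:
            raise StructuralError(f"layer {layer + 1} declared but empty")
        ridx = {n: i for i, n in enumerate(rows)}
        cidx = {n: j for j, n in enumerate(cols)}
        m = np.zeros((len(rows), len(cols)), dtype=np.int8)
        for src, dst in dag.edges:
            if dag.nodes[src] == layer:
                m[ridx[src], cidx[dst]] = 1
        if m.sum(axis=0).min(initial=1) == 0:
            bad = cols[int(np.argmin(m.sum(axis=0)))]
            raise StructuralError(f"node {bad!r} in layer {layer + 1} has no incoming edge")
        masks.append(m)
    return masks


def reachability(dag: LayeredDAG) -> dict[str, int]:
    """Number of nodes from which each node is reachable, counting itself.

    Equals ``|ancestors| + 1``; a layer-1 node with three feature-type
    predecessors therefore has reachability 4.
    """
    g = dag._graph
    return {n: len(nx.ancestors(g, n)) + 1 for n in dag.nodes}


def betweenness(dag: LayeredDAG, *, fractional: bool = True) -> dict[str, float]:
    """Directed betweenness centrality, unnormalized.

    With ``fractional=True`` (default, the igraph/networkx convention) each
    ordered pair (s, t) contributes sigma_st(v) / sigma_st for v not in
    {s, t}.  With ``fractional=False`` each shortest path through ``v``
    counts 1 regardless of how many shortest s-t paths exist (raw counts).
    """
    g = dag._graph
    if fractional:
        bc = nx.betweenness_centrality(g, normalized=False)
        return {n: float(bc[n]) for n in dag.nodes}
    counts = dict.fromkeys(dag.nodes, 0.0)
    for s in dag.nodes:
        for t in dag.nodes:
            if s == t or not nx.has_path(g, s, t):
                continue
            for path in nx.all_shortest_paths(g, s, t):
                for v in path[1:-1]:
                    counts[v] += 1.0
    return counts


def degrees(dag: LayeredDAG) -> tuple[dict[str, int], dict[str, int]]:
    """(indegree, outdegree) per node — direct neighbor counts."""
    g = dag._graph
    return (
        {n: int(g.in_degree(n)) for n in dag.nodes},
        {n: int(g.out_degree(n)) for n in dag.nodes},
    )


def centrality_table(dag: LayeredDAG) -> pd.DataFrame:
    """Per-node centrality: indegree, outdegree, reachability, betweenness.

    Rows are ordered by (layer, node_id); this is the canonical node order
    used by every downstream artifact.
    """
    indeg, outdeg = degrees(dag)
    reach = reachability(dag)
    btw = betweenness(dag)
    order = sorted(dag.nodes, key=lambda n: (dag.nodes[n], n))
    return pd.DataFrame(
        {
            "node_id": order,
            "layer": [dag.nodes[n] for n in order],
            "indegree": [indeg[n] for n in order],
            "outdegree": [outdeg[n] for n in order],
            "reachability": [reach[n] for n in order],
            "betweenness": [btw[n] for n in order],
        }
    ).set_index("node_id")


# -- hierarchy file I/O -------------------------------------------------
#
# Tab-separated, three columns: source_id, target_id, target_layer.
# Header line required; '#' starts a comment line.


def write_hierarchy(dag: LayeredDAG, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("source_id\ttarget_id\ttarget_layer\n")
        for src, dst in sorted(dag.edges, key=lambda e: (dag.nodes[e[1]], e[0], e[1])):
            fh.write(f"{src}\t{dst}\t{dag.nodes[dst]}\n")


def read_hierarchy(path) -> LayeredDAG:
    nodes: dict[str, int] = {}
    edges: list[tuple[str, str]] = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
        if header.strip().split("\t") != ["source_id", "target_id", "target_layer"]:
            raise ValueError(f"unexpected hierarchy header: {header!r}")
        for lineno, line in enumerate(fh, start=2):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(f"line {lineno}: expected 3 tab-separated fields")
            src, dst, layer_s = parts
            layer = int(layer_s)
            for node, lyr in ((src, layer - 1), (dst, layer)):
                if node in nodes and nodes[node] != lyr:
                    raise StructuralError(f"node {node!r} assigned to layers {nodes[node]} and {lyr}")
                nodes[node] = lyr
            edges.append((src, dst))
    return LayeredDAG(nodes=nodes, edges=tuple(edges))
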