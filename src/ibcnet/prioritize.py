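"""Network-based module prioritization.

Module-module eigengene correlations and per-cell-line module expression are
dichotomized at zero into a binary module/cell-line graph; a deterministic
minimum spanning tree (unit edge weights, lexicographic tie-break on node
pairs) is extracted per connected component, and the prioritized modules are
those lying on tree paths joining the target cell lines.

On an unweighted graph the MST is not unique; the lexicographic Kruskal
order makes the result canonical and input-order invariant, which is the one
convention this procedure needs to be reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd


@dataclass
class BipartiteAdjacency:
    graph: nx.Graph  # nodes carry kind="module" | "cell_line"

    @property
    def modules(self) -> list:
        return [n for n, d in self.graph.nodes(data=True) if d["kind"] == "module"]

    @property
    def cell_lines(self) -> list:
        return [n for n, d in self.graph.nodes(data=True) if d["kind"] == "cell_line"]


def build_bipartite_adjacency(
    module_correlations: pd.DataFrame,
    module_expression: pd.DataFrame,
) -> BipartiteAdjacency:
    """Binary joint graph over modules and cell lines.

    ``module_correlations`` is the modules x modules eigengene correlation
    matrix; ``module_expression`` is modules x cell lines (eigengene value of
    each module in each line). An edge exists iff the value is strictly
    positive; exact zeros yield no edge.
    """
    g = nx.Graph()
    mods = list(module_correlations.index)
    lines = list(module_expression.columns)
    g.add_nodes_from(((m, {"kind": "module"}) for m in mods))
    g.add_nodes_from(((c, {"kind": "cell_line"}) for c in lines))
    for i, a in enumerate(mods):
        for b in mods[i + 1:]:
            if module_correlations.loc[a, b] > 0:
                g.add_edge(a, b)
    for m in mods:
        for c in lines:
            if module_expression.loc[m, c] > 0:
                g.add_edge(m, c)
    return BipartiteAdjacency(graph=g)


def _canonical_mst(g: nx.Graph) -> nx.Graph:
    """Kruskal over lexicographically sorted node-pair edges (unit weights)."""
    uf = nx.utils.UnionFind(g.nodes)
    tree = nx.Graph()
    tree.add_nodes_from(g.nodes(data=True))
    edges = sorted(tuple(sorted((str(u), str(v)))) for u, v in g.edges)
    name = {str(n): n for n in g.nodes}
    for u, v in edges:
        nu, nv = name[u], name[v]
        if uf[nu] != uf[nv]:
            uf.union(nu, nv)
            tree.add_edge(nu, nv)
    return tree


def minimal_connecting_modules(
    adjacency: BipartiteAdjacency, targets: list
) -> tuple[pd.DataFrame, tuple]:
    """Minimal tree edge set and the modules connecting the target cell lines.

    Returns an edge table (u, v, on_path flag) for the spanning forest and
    the sorted tuple of modules lying on the unique tree paths between the
    targets (the Steiner subtree of the MST). All targets must share one
    connected component.
    """
    g = adjacency.graph
    missing = [t for t in targets if t not in g]
    if missing:
        raise KeyError(f"target cell lines absent from the graph: {missing}")
    components = list(nx.connected_components(g))
    comp = {n: i for i, c in enumerate(components) for n in c}
    comps = {comp[t] for t in targets}
    if len(comps) > 1:
        groups: dict = {}
        for t in targets:
            groups.setdefault(comp[t], []).append(t)
        # "isolated" = targets outside the main (largest, then most-target)
        # component
        main = max(groups, key=lambda i: (len(groups[i]), len(components[i])))
        isolated = sorted(t for i, ts in groups.items() if i != main for t in ts)
        raise ValueError(f"target cell lines not connected: isolated {isolated}")

    tree = _canonical_mst(g)
    # Steiner subtree of a tree = union of pairwise paths; anchor on one target
    on_path_edges = set()
    path_nodes = set(targets)
    t0 = targets[0]
    for t in targets[1:]:
        path = nx.shortest_path(tree, t0, t)
        path_nodes.update(path)
        on_path_edges.update(frozenset(e) for e in zip(path[:-1], path[1:]))

    kind = nx.get_node_attributes(g, "kind")
    modules = tuple(sorted(n for n in path_nodes if kind[n] == "module"))
    rows = [
        {"u": u, "v": v, "on_path": frozenset((u, v)) in on_path_edges}
        for u, v in sorted(tuple(sorted((str(a), str(b)))) for a, b in tree.edges)
    ]
    return pd.DataFrame(rows, columns=["u", "v", "on_path"]), modules
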