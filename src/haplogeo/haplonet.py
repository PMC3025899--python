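"""Pairwise mutational-step matrix and minimum spanning network (MSN).

The MSN connects observed haplotypes only: a minimum spanning tree over the
step matrix, augmented with every alternative connection whose direct
distance ties the minimax (bottleneck) path weight between its endpoints.
Ties therefore surface as loops, as in classic minimum-spanning-network
software; no median or inferred intermediate haplotypes are created —
multi-step edges simply carry their step count.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .seqio import HaplotypeTable

UNAMBIGUOUS = frozenset("ACGT")


class MissingSequencesError(ValueError):
    """Raised when an operation needs haplotype sequences but none are present."""


def step_matrix(t: HaplotypeTable) -> pd.DataFrame:
    """Symmetric haplotype × haplotype matrix of mutational step counts.

    An entry counts sites at which the two haplotypes carry differing,
    unambiguous bases (``N``-involved sites are skipped). Requires the table
    to have been built from sequence data with indel columns dropped.
    """
    if t.sequences is None:
        raise MissingSequencesError(
            "step matrix requires haplotype sequences; supply a FASTA alignment "
            "rather than a count-only table"
        )
    ids = t.haplotype_ids
    arr = np.array([list(t.sequences[h]) for h in ids], dtype="U1")
    valid = np.isin(arr, list(UNAMBIGUOUS))
    n = len(ids)
    d = np.zeros((n, n), dtype=int)
    for i in range(n - 1):
        for j in range(i + 1, n):
            both = valid[i] & valid[j]
            d[i, j] = d[j, i] = int(((arr[i] != arr[j]) & both).sum())
    return pd.DataFrame(d, index=ids, columns=ids)


@dataclass
class HaplotypeNetwork:
    """Graph on haplotypes with step-count edge weights.

    ``graph`` is an undirected networkx graph whose edges carry ``steps``
    (int) and ``edge_class`` ("mst" or "alternative"); nodes carry a
    ``counts`` dict (population → count) when counts were supplied.
    """

    graph: nx.Graph
    mst_edges: set[frozenset] = field(default_factory=set)

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    def edge_list(self) -> list[tuple[str, str, int, str]]:
        rows = []
        for u, v, data in self.graph.edges(data=True):
            a, b = sorted((u, v))
            rows.append((a, b, int(data["steps"]), data["edge_class"]))
        return sorted(rows)

    def mst_weight(self) -> int:
        return sum(
            int(self.graph.edges[tuple(e)]["steps"]) for e in self.mst_edges
        )


def _mst_max_edge_weights(tree: nx.Graph, nodes: list[str]) -> dict[frozenset, int]:
    """Maximum edge weight on the tree path between every node pair."""
    out: dict[frozenset, int] = {}
    for src in nodes:
        # DFS carrying the running max edge weight
        stack = [(src, None, 0)]
        seen = {src}
        while stack:
            node, parent, running = stack.pop()
            for nb in tree.neighbors(node):
                if nb == parent or nb in seen:
                    continue
                w = max(running, int(tree.edges[node, nb]["steps"]))
                out[frozenset((src, nb))] = w
                seen.add(nb)
                stack.append((nb, node, w))
    return out


def minimum_spanning_network(
    d: pd.DataFrame, counts: pd.DataFrame | None = None
) -> HaplotypeNetwork:
    """Build the minimum spanning network from a step matrix.

    A primary minimum spanning tree is chosen by Kruskal with deterministic
    tie-breaking (weight, then lexicographic node pair); every non-tree pair
    whose direct distance equals the bottleneck path weight between its
    endpoints in the tree is then added as an ``alternative`` edge. With the
    alternative-edge rule the emitted edge set does not depend on how MST
    ties were broken.
    """
    ids = list(d.index)
    g = nx.Graph()
    g.add_nodes_from(ids)
    if counts is not None:
        for h in ids:
            g.nodes[h]["counts"] = {
                p: int(c) for p, c in counts.loc[h].items() if c > 0
            }
    if len(ids) == 1:
        return HaplotypeNetwork(graph=g, mst_edges=set())

    edges = sorted(
        (
            (int(d.loc[u, v]), u, v)
            for i, u in enumerate(ids)
            for v in ids[i + 1 :]
        ),
        key=lambda t: (t[0], t[1], t[2]),
    )
    # Kruskal
    tree = nx.Graph()
    tree.add_nodes_from(ids)
    parent = {h: h for h in ids}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    mst_edges: set[frozenset] = set()
    for w, u, v in edges:
        ru, rv = find(u), find(v)
        if ru != rv:
            parent[ru] = rv
            tree.add_edge(u, v, steps=w)
            mst_edges.add(frozenset((u, v)))
            g.add_edge(u, v, steps=w, edge_class="mst")

    bottleneck = _mst_max_edge_weights(tree, ids)
    for w, u, v in edges:
        key = frozenset((u, v))
        if key in mst_edges:
            continue
        if w == bottleneck[key]:
            g.add_edge(u, v, steps=w, edge_class="alternative")
    return HaplotypeNetwork(graph=g, mst_edges=mst_edges)


def export_network(nw: HaplotypeNetwork, path) -> None:
    """Write the network as a TSV edge list (u, v, steps, edge_class).

    Rows are lexicographically ordered so output is deterministic. A
    single-node network produces a header-only file.
    """
    rows = nw.edge_list()
    df = pd.DataFrame(rows, columns=["u", "v", "steps", "edge_class"])
    df.to_csv(path, sep="\t", index=False)


def read_network(path) -> HaplotypeNetwork:
    """Re-read an exported edge list; node counts are not round-tripped."""
    df = pd.read_csv(path, sep="\t")
    g = nx.Graph()
    mst_edges: set[frozenset] = set()
    for _, row in df.iterrows():
        g.add_edge(
            str(row["u"]), str(row["v"]),
            steps=int(row["steps"]), edge_class=str(row["edge_class"]),
        )
        if row["edge_class"] == "mst":
            mst_edges.add(frozenset((str(row["u"]), str(row["v"]))))
    return HaplotypeNetwork(graph=g, mst_edges=mst_edges)
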