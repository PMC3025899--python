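"""K2P distances, neighbor-joining trees and nonparametric bootstrap support.

Distances use Kimura's two-parameter model with pairwise deletion of
``N``-involved sites (complete deletion available by flag). Trees are built
with the Saitou–Nei neighbor-joining agglomeration; bootstrap support for
the internal bipartitions of the full-data tree comes from resampling
alignment columns with replacement and rebuilding the NJ tree per replicate.

Trees are :class:`dendropy.Tree` objects throughout, so newick round-trips
and tree surgery use a standard library rather than a bespoke format.
"""

from __future__ import annotations

import math

import dendropy
import numpy as np
import pandas as pd

from .seqio import SequenceAlignment

PURINES = {"A", "G"}
PYRIMIDINES = {"C", "T"}


class SaturationError(ValueError):
    """Raised when K2P distances are undefined (log-domain violation)."""


class UndefinedDistanceError(ValueError):
    """Raised when NJ input contains undefined (NaN) distances."""


def k2p_distance(seq_a: str, seq_b: str) -> float:
    """Kimura two-parameter distance, substitutions per site.

    With P and Q the transition and transversion proportions over comparable
    (both unambiguous) sites: d = −½ ln((1−2P−Q)·√(1−2Q)). Returns ``nan``
    when the log argument is non-positive (saturation) and raises when no
    comparable sites exist.
    """
    n_comp = transitions = transversions = 0
    for x, y in zip(seq_a, seq_b):
        if x == "N" or y == "N" or x == "-" or y == "-":
            continue
        n_comp += 1
        if x == y:
            continue
        if (x in PURINES) == (y in PURINES):
            transitions += 1
        else:
            transversions += 1
    if n_comp == 0:
        raise SaturationError("no comparable sites between sequences")
    P = transitions / n_comp
    Q = transversions / n_comp
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0.0 or w2 <= 0.0:
        return float("nan")
    return -0.5 * math.log(w1 * math.sqrt(w2))


def k2p_matrix(
    labeled_seqs: list[tuple[str, str]], complete_deletion: bool = False
) -> pd.DataFrame:
    """Pairwise K2P distance matrix over labeled sequences.

    ``complete_deletion=True`` first removes every column with an ``N`` (or
    gap) in any sequence; the default compares per-pair comparable sites.
    """
    labels = [lab for lab, _ in labeled_seqs]
    seqs = [s for _, s in labeled_seqs]
    if complete_deletion:
        arr = np.array([list(s) for s in seqs], dtype="U1")
        keep = ~np.isin(arr, ["N", "-"]).any(axis=0)
        seqs = ["".join(row) for row in arr[:, keep]]
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n - 1):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = k2p_distance(seqs[i], seqs[j])
    return pd.DataFrame(d, index=labels, columns=labels)


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------

def neighbor_joining(d: pd.DataFrame) -> dendropy.Tree:
    """Saitou–Nei neighbor joining on a symmetric distance matrix.

    Requires ≥ 3 labels and no undefined entries. Negative branch lengths
    are clamped to 0 with the deficit shifted to the sister branch. The
    returned tree is unrooted (trifurcating seed node).
    """
    labels = list(d.index)
    if len(labels) < 3:
        raise ValueError("neighbor joining needs at least 3 labels")
    mat = d.to_numpy(dtype=float)
    if np.isnan(mat).any():
        bad = [
            (labels[i], labels[j])
            for i in range(len(labels))
            for j in range(i + 1, len(labels))
            if math.isnan(mat[i, j])
        ]
        raise UndefinedDistanceError(f"undefined distances for pairs: {bad}")

    taxa = dendropy.TaxonNamespace(labels)
    nodes: list[dendropy.Node] = []
    for lab in labels:
        node = dendropy.Node()
        node.taxon = taxa.get_taxon(lab)
        nodes.append(node)

    active = list(range(len(labels)))
    dist = {frozenset((i, j)): mat[i, j] for i in active for j in active if i < j}
    next_idx = len(labels)
    node_of = dict(enumerate(nodes))

    def D(i, j):
        return dist[frozenset((i, j))]

    while len(active) > 3:
        m = len(active)
        r = {i: sum(D(i, k) for k in active if k != i) for i in active}
        best = None
        for ai, i in enumerate(active):
            for j in active[ai + 1 :]:
                q = (m - 2) * D(i, j) - r[i] - r[j]
                key = (q, i, j)  # deterministic tie-break by creation order
                if best is None or key < best:
                    best = key
        _, i, j = best
        dij = D(i, j)
        li = 0.5 * dij + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = dij - li
        if li < 0.0:
            li, lj = 0.0, dij
        elif lj < 0.0:
            li, lj = dij, 0.0
        new = dendropy.Node()
        new.add_child(node_of[i])
        new.add_child(node_of[j])
        node_of[i].edge.length = li
        node_of[j].edge.length = lj
        node_of[next_idx] = new
        for k in active:
            if k in (i, j):
                continue
            dist[frozenset((next_idx, k))] = max(
                0.0, 0.5 * (D(i, k) + D(j, k) - dij)
            )
        active = [k for k in active if k not in (i, j)] + [next_idx]
        next_idx += 1

    # final trifurcation
    i, j, k = active
    la = 0.5 * (D(i, j) + D(i, k) - D(j, k))
    lb = 0.5 * (D(i, j) + D(j, k) - D(i, k))
    lc = 0.5 * (D(i, k) + D(j, k) - D(i, j))
    root = dendropy.Node()
    for idx, ln in ((i, la), (j, lb), (k, lc)):
        root.add_child(node_of[idx])
        node_of[idx].edge.length = max(0.0, ln)
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.seed_node = root
    tree.is_rooted = False
    return tree


def tree_bipartitions(tree: dendropy.Tree) -> set[frozenset]:
    """Non-trivial bipartitions as frozensets of leaf labels.

    Each internal edge is represented by the side of the split *not*
    containing the lexicographically first leaf label, so representation is
    rotation-independent.
    """
    leaves = sorted(lf.taxon.label for lf in tree.leaf_node_iter())
    ref = leaves[0]
    n = len(leaves)
    out: set[frozenset] = set()
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node is tree.seed_node:
            continue
        below = frozenset(lf.taxon.label for lf in node.leaf_iter())
        side = below if ref not in below else frozenset(leaves) - below
        if 2 <= len(side) <= n - 2:
            out.add(side)
    return out


def bootstrap_support(
    a: SequenceAlignment, n_reps: int = 1000, seed: int | None = None
) -> tuple[dendropy.Tree, dict]:
    """NJ tree with bootstrap support on its internal bipartitions.

    Columns are resampled with replacement per replicate; support is the
    percentage of replicate NJ trees containing each internal bipartition of
    the full-data tree. Replicates yielding an undefined K2P distance are
    dropped and counted. Returns the supported tree and a report dict with
    ``n_reps``, ``n_dropped`` and per-bipartition support.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    full = neighbor_joining(k2p_matrix(a.records))
    targets = tree_bipartitions(full)
    hits = {bp: 0 for bp in targets}
    arr = a.to_array()
    n_dropped = 0
    n_used = 0
    for _ in range(n_reps):
        cols = rng.integers(0, a.length, size=a.length)
        res = arr[:, cols]
        recs = [(sid, "".join(row)) for sid, row in zip(a.sample_ids, res)]
        dm = k2p_matrix(recs)
        if np.isnan(dm.to_numpy()).any():
            n_dropped += 1
            continue
        n_used += 1
        reps = tree_bipartitions(neighbor_joining(dm))
        for bp in targets & reps:
            hits[bp] += 1
    support = {
        bp: (100.0 * h / n_used if n_used else float("nan"))
        for bp, h in hits.items()
    }
    # annotate the full tree's internal nodes
    leaves = sorted(lf.taxon.label for lf in full.leaf_node_iter())
    ref = leaves[0]
    n = len(leaves)
    for node in full.preorder_node_iter():
        if node.is_leaf() or node is full.seed_node:
            continue
        below = frozenset(lf.taxon.label for lf in node.leaf_iter())
        side = below if ref not in below else frozenset(leaves) - below
        if side in support:
            node.label = f"{support[side]:.1f}"
    report = {"n_reps": n_reps, "n_dropped": n_dropped, "support": support}
    return full, report


# ---------------------------------------------------------------------------
# Newick I/O
# ---------------------------------------------------------------------------

def write_newick(tree: dendropy.Tree, path) -> None:
    """Write newick with branch lengths (10 significant digits) and internal
    node labels (bootstrap supports) preserved."""
    tree.write(
        path=str(path),
        schema="newick",
        suppress_rooting=True,
        real_value_format_specifier=".10g",
    )


def read_newick(path) -> dendropy.Tree:
    """Read a newick tree; malformed input raises a parse error with position."""
    try:
        return dendropy.Tree.get(
            path=str(path), schema="newick", suppress_internal_node_taxa=True
        )
    except Exception as exc:  # dendropy raises schema-specific errors
        raise ValueError(f"malformed newick in {path}: {exc}") from exc
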