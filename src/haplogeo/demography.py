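"""Deterministic skyline reconstruction of effective-size history.

Given an ultrametric genealogy with branch lengths in substitutions per
site, the classic skyline converts each inter-coalescent interval into a
piecewise-constant estimate of effective population size: with i lineages
and interval duration τ (years, via the per-site per-year rate μ),
N̂ = i(i−1)·τ / 2 (divided by the generation time when one is supplied —
otherwise the reported quantity is N·generation-time and labeled so).

The generalized skyline pools adjacent intervals until each composite group
spans at least ε, using the maximum-likelihood pooled estimator
N̂ = Σ C(i_j,2)·τ_j / (number of coalescences pooled), which reduces to the
classic skyline at ε = 0. This is a deterministic, desk-testable analogue
of MCMC-based skyline methods: it reconstructs the same piecewise trend
from a single input genealogy without posterior sampling.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np


class UltrametricityError(ValueError):
    """Raised when a tree is not ultrametric within tolerance."""


@dataclass
class CoalescentIntervals:
    """Inter-coalescent intervals from tips to root.

    ``lineage_counts`` runs n, n−1, …, 2; ``durations`` are the waiting
    times (same units as the input branch lengths) spent with that many
    lineages.
    """

    lineage_counts: list[int]
    durations: list[float]

    def __post_init__(self) -> None:
        if len(self.lineage_counts) != len(self.durations):
            raise ValueError("lineage_counts and durations must align")
        for i, nxt in zip(self.lineage_counts, self.lineage_counts[1:]):
            if nxt != i - 1:
                raise ValueError("lineage counts must decrease by 1 per coalescence")
        if any(d < 0 for d in self.durations):
            raise ValueError("durations must be non-negative")

    @property
    def total_depth(self) -> float:
        return float(sum(self.durations))


@dataclass
class SkylinePlot:
    """Piecewise-constant N(t); times in years before present, increasing
    into the past. ``generation_time=None`` means segments carry
    N × generation-time rather than N."""

    segments: list[tuple[float, float, float]]  # (t_start, t_end, N)
    mutation_rate: float
    L: int
    generation_time: float | None

    def __post_init__(self) -> None:
        prev_end = 0.0
        for t0, t1, N in self.segments:
            if abs(t0 - prev_end) > 1e-9 * max(1.0, abs(t1)):
                raise ValueError("skyline segments must be contiguous")
            if t1 < t0:
                raise ValueError("segment times must increase into the past")
            if N < 0:
                raise ValueError("N estimates must be non-negative")
            prev_end = t1

    @property
    def span_years(self) -> float:
        return self.segments[-1][1] if self.segments else 0.0


def ultrametricize_tree(tree: "dendropy.Tree") -> "dendropy.Tree":
    """Turn an additive (e.g. NJ) tree into an ultrametric genealogy.

    Midpoint-roots a copy, smooths node heights by mean path length to the
    descendant leaves (child heights clipped to their parent's, so branch
    lengths stay non-negative), and resolves any multifurcation with
    zero-length branches. This is an approximation, not a clock model: use
    it to feed skyline extraction, not to date nodes.
    """
    t = tree.clone(depth=1)
    t.reroot_at_midpoint(update_bipartitions=True)
    for node in t.postorder_node_iter():
        if node.is_leaf():
            node._h = 0.0
        else:
            node._h = float(
                np.mean(
                    [c._h + (c.edge.length or 0.0) for c in node.child_nodes()]
                )
            )
    for node in t.preorder_node_iter():
        parent = node.parent_node
        if parent is None:
            continue
        if node._h > parent._h:
            node._h = parent._h
        node.edge.length = parent._h - node._h
    t.resolve_polytomies()
    return t


def coalescent_intervals(
    tree: dendropy.Tree, rel_tol: float = 1e-6
) -> CoalescentIntervals:
    """Extract coalescent intervals from an ultrametric binary genealogy.

    Root-to-tip distances must agree within ``rel_tol`` (relative to tree
    height); negative branch lengths are rejected.
    """
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            raise ValueError("tree has a negative branch length")
    # node depths from root
    depths: dict = {}
    for node in tree.preorder_node_iter():
        parent = node.parent_node
        depths[node] = (depths[parent] if parent else 0.0) + (node.edge.length or 0.0)
    leaf_depths = [depths[lf] for lf in tree.leaf_node_iter()]
    height = max(leaf_depths)
    if height == 0.0:
        raise UltrametricityError("tree has zero height")
    if (max(leaf_depths) - min(leaf_depths)) > rel_tol * height:
        raise UltrametricityError(
            "tree is not ultrametric within tolerance; normalize tip heights "
            "(e.g. mean path length) before extracting intervals"
        )
    internal_ages = sorted(
        height - depths[nd]
        for nd in tree.preorder_internal_node_iter()
    )
    n = len(leaf_depths)
    if len(internal_ages) != n - 1:
        raise ValueError("genealogy must be binary (n−1 coalescences)")
    durations = []
    prev = 0.0
    for age in internal_ages:
        durations.append(age - prev)
        prev = age
    counts = list(range(n, 1, -1))
    return CoalescentIntervals(lineage_counts=counts, durations=durations)


def classic_skyline(
    ci: CoalescentIntervals,
    mutation_rate: float,
    L: int = 1,
    generation_time: float | None = None,
) -> SkylinePlot:
    """Classic skyline: one segment per coalescent interval.

    Branch-length durations (substitutions/site) are converted to years by
    dividing by ``mutation_rate``; the segment estimate with i lineages over
    τ years is N̂ = i(i−1)·τ/2 per generation time. Zero-duration intervals
    yield N = 0 segments that are retained.
    """
    if mutation_rate <= 0:
        raise ValueError("mutation_rate must be > 0")
    if L < 1:
        raise ValueError("L must be >= 1")
    gt = generation_time if generation_time is not None else 1.0
    segments = []
    t = 0.0
    for i, dur in zip(ci.lineage_counts, ci.durations):
        tau_years = dur / mutation_rate
        N = i * (i - 1) * tau_years / (2.0 * gt)
        segments.append((t, t + tau_years, N))
        t += tau_years
    return SkylinePlot(segments, mutation_rate, L, generation_time)


def generalized_skyline(
    ci: CoalescentIntervals,
    epsilon: float,
    mutation_rate: float = 1.0,
    L: int = 1,
    generation_time: float | None = None,
) -> SkylinePlot:
    """Generalized skyline: pool adjacent intervals until each composite
    group spans at least ε (in input branch-length units).

    The pooled estimate for a group is Σ C(i_j,2)·τ_j divided by the number
    of coalescences in the group (the constant-size MLE over the group);
    ε = 0 reduces exactly to the classic skyline. The root-adjacent group
    may remain shorter than ε.
    """
    if epsilon < 0:
        raise ValueError("epsilon must be >= 0")
    gt = generation_time if generation_time is not None else 1.0
    groups: list[list[int]] = []
    current: list[int] = []
    acc = 0.0
    for idx, dur in enumerate(ci.durations):
        current.append(idx)
        acc += dur
        if acc >= epsilon and (acc > 0 or epsilon == 0):
            groups.append(current)
            current, acc = [], 0.0
    if current:
        if groups:
            groups[-1].extend(current)  # fold short root-adjacent remainder
        else:
            groups.append(current)
    segments = []
    t = 0.0
    for grp in groups:
        dur_total = sum(ci.durations[j] for j in grp)
        weighted = sum(
            ci.lineage_counts[j] * (ci.lineage_counts[j] - 1) / 2.0
            * ci.durations[j]
            for j in grp
        )
        k = len(grp)  # coalescences pooled
        tau_years = dur_total / mutation_rate
        N = (weighted / mutation_rate) / (k * gt)
        segments.append((t, t + tau_years, N))
        t += tau_years
    return SkylinePlot(segments, mutation_rate, L, generation_time)


def skyline_table(sp: SkylinePlot):
    """Skyline as a plain table of (t_start, t_end, N) rows."""
    import pandas as pd

    label = "N" if sp.generation_time is not None else "N_times_generation_time"
    return pd.DataFrame(sp.segments, columns=["t_start", "t_end", label])
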