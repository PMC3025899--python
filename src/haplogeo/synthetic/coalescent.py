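"""Structured-coalescent generator for cpDNA-like data.

Simulates genealogies under the n-island (and related) structured
coalescent for a single non-recombining, maternally inherited locus, then
drops finite-sites mutations on the branches. Finite-sites mutation (rather
than infinite sites) is deliberate: recurrent change produces the homoplasy
and network reticulation the downstream loop-breaking rules must handle.

Scaling. Time is measured in units of N generations, where N is the
haploid (female) effective size of one deme. With k lineages in a deme,
coalescence occurs at rate C(k,2); each lineage migrates at scaled rate
M = Nm·(d−1)/d to a uniformly chosen other deme, the finite-island mapping
under which the Hudson FST of two demes has island-model expectation
FST = 1/(1 + 2Nm). Mutations fall as Poisson events at rate θL/2 per
lineage per time unit (θ = per-site scaled mutation rate, L sites); each
event hits a uniform site and redraws the base from the stationary
composition restricted to the other three bases.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from ..seqio import PopulationMap, SequenceAlignment

BASES = np.array(["A", "C", "G", "T"])

# Default composition echoes the strong A/T bias of noncoding cpDNA spacers
# (~73.6% A+T).
DEFAULT_COMPOSITION = (0.368, 0.132, 0.132, 0.368)  # A, C, G, T


@dataclass
class SimParams:
    """Parameters of the island-model generator.

    Defaults mirror the sampling design the package targets: eight demes
    with 8–10 samples each, one ~881-site non-recombining locus, strong
    differentiation (Nm = 0.25 ⇒ expected FST = 1/(1+2Nm) ≈ 0.67, inside
    the 0.2–0.9 range typical of maternally inherited markers in fragmented
    shrub populations).
    """

    n_demes: int = 8
    sample_sizes: tuple = (10, 10, 10, 10, 8, 10, 10, 9)
    Nm: float = 0.25
    theta: float = 0.005
    L: int = 881
    base_composition: tuple = DEFAULT_COMPOSITION
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_demes < 1:
            raise ValueError("n_demes must be >= 1")
        if len(self.sample_sizes) != self.n_demes:
            raise ValueError("sample_sizes must have one entry per deme")
        if any(s < 1 for s in self.sample_sizes):
            raise ValueError("sample sizes must be positive")
        if self.Nm < 0 or self.theta <= 0 or self.L < 1:
            raise ValueError("Nm must be >= 0, theta > 0 and L >= 1")
        if abs(sum(self.base_composition) - 1.0) > 1e-9:
            raise ValueError("base_composition must sum to 1")
        if any(f <= 0 for f in self.base_composition):
            raise ValueError("base frequencies must be positive")


class _Node:
    __slots__ = ("children", "branch", "deme", "label")

    def __init__(self, deme: int, label: str | None = None):
        self.children: list[_Node] = []
        self.branch = 0.0  # length to parent, coalescent units
        self.deme = deme
        self.label = label


def _structured_genealogy(
    samples_per_deme: list[int],
    migration: np.ndarray,
    rng: np.random.Generator,
    labels: list[list[str]],
    collapse_time: float | None = None,
    ancestral_scale: float = 1.0,
) -> _Node:
    """Gillespie simulation of the structured coalescent.

    ``migration[i, j]`` is the scaled per-lineage migration rate from deme i
    to deme j (backwards in time). At ``collapse_time`` (if given) all
    lineages move to deme 0 and migration stops, with coalescence rate
    scaled by 1/``ancestral_scale`` (ancestral deme of relative size
    ``ancestral_scale``).
    """
    active: list[_Node] = []
    for d, (k, labs) in enumerate(zip(samples_per_deme, labels)):
        for i in range(k):
            active.append(_Node(deme=d, label=labs[i]))
    t = 0.0
    collapsed = False
    mig = migration.copy()
    coal_scale = 1.0
    while len(active) > 1:
        by_deme: dict[int, list[_Node]] = {}
        for nd in active:
            by_deme.setdefault(nd.deme, []).append(nd)
        coal_rate = sum(
            len(v) * (len(v) - 1) / 2.0 for v in by_deme.values()
        ) / coal_scale
        mig_rate = sum(mig[nd.deme].sum() for nd in active)
        total = coal_rate + mig_rate
        if total <= 0:
            # isolated lineages that can never meet: jump to collapse
            if collapse_time is None:
                raise RuntimeError("structured coalescent cannot finish: no events possible")
            wait = math.inf
        else:
            wait = rng.exponential(1.0 / total)
        if collapse_time is not None and not collapsed and t + wait >= collapse_time:
            dt = collapse_time - t
            for nd in active:
                nd.branch += dt
                nd.deme = 0
            t = collapse_time
            mig = np.zeros_like(mig)
            coal_scale = ancestral_scale
            collapsed = True
            continue
        for nd in active:
            nd.branch += wait
        t += wait
        if rng.random() < coal_rate / total:
            # coalescence: pick a deme weighted by pair count, then a pair
            demes = [d for d, v in by_deme.items() if len(v) >= 2]
            weights = np.array(
                [len(by_deme[d]) * (len(by_deme[d]) - 1) / 2.0 for d in demes]
            )
            d = demes[rng.choice(len(demes), p=weights / weights.sum())]
            i, j = rng.choice(len(by_deme[d]), size=2, replace=False)
            a, b = by_deme[d][i], by_deme[d][j]
            parent = _Node(deme=d)
            parent.children = [a, b]
            active = [nd for nd in active if nd is not a and nd is not b]
            active.append(parent)
        else:
            rates = np.array([mig[nd.deme].sum() for nd in active])
            idx = rng.choice(len(active), p=rates / rates.sum())
            nd = active[idx]
            row = mig[nd.deme]
            nd.deme = int(rng.choice(len(row), p=row / row.sum()))
    return active[0]


def _mutate_sequences(
    root: _Node,
    theta_total_half: float,
    L: int,
    composition: np.ndarray,
    rng: np.random.Generator,
) -> dict[str, str]:
    """Drop Poisson mutations along branches; return leaf label → sequence."""
    root_seq = rng.choice(4, size=L, p=composition)
    out: dict[str, str] = {}
    stack = [(root, root_seq)]
    while stack:
        node, seq = stack.pop()
        n_mut = rng.poisson(theta_total_half * node.branch)
        if n_mut:
            seq = seq.copy()
            sites = rng.integers(0, L, size=n_mut)
            for s in sites:
                cur = seq[s]
                probs = composition.copy()
                probs[cur] = 0.0
                probs /= probs.sum()
                seq[s] = rng.choice(4, p=probs)
        if node.children:
            for ch in node.children:
                stack.append((ch, seq))
        else:
            out[node.label] = "".join(BASES[seq])
    return out


def _grid_sites(n_demes: int, positions: list[float] | None = None):
    """Deme coordinates on a latitudinal transect (~13 km spacing)."""
    if positions is None:
        positions = list(range(n_demes))
    return {
        i: (39.40 + 0.12 * positions[i], 106.80, 1100.0)
        for i in range(n_demes)
    }


def _emit(
    root: _Node,
    params_theta_half: float,
    L: int,
    composition,
    rng,
    samples_per_deme,
    deme_positions=None,
    deme_names=None,
) -> tuple[SequenceAlignment, PopulationMap]:
    comp = np.asarray(composition, dtype=float)
    seqs = _mutate_sequences(root, params_theta_half, L, comp, rng)
    names = deme_names or [f"P{i + 1}" for i in range(len(samples_per_deme))]
    records = []
    sample_to_pop = {}
    for d, k in enumerate(samples_per_deme):
        for i in range(k):
            sid = f"{names[d]}_{i + 1:02d}"
            records.append((sid, seqs[sid]))
            sample_to_pop[sid] = names[d]
    sites = _grid_sites(len(samples_per_deme), deme_positions)
    pop_to_site = {names[d]: sites[d] for d in range(len(samples_per_deme))}
    return (
        SequenceAlignment(records),
        PopulationMap(sample_to_pop=sample_to_pop, pop_to_site=pop_to_site),
    )


def _island_migration_matrix(n_demes: int, Nm: float) -> np.ndarray:
    """Per-lineage scaled migration rates for the symmetric island model.

    Total per-lineage rate M = Nm·(d−1)/d, split evenly over the other
    demes, so that Hudson FST between demes has expectation 1/(1+2Nm).
    """
    mig = np.zeros((n_demes, n_demes))
    if n_demes > 1 and Nm > 0:
        M = Nm * (n_demes - 1) / n_demes
        per_target = M / (n_demes - 1)
        mig[:] = per_target
        np.fill_diagonal(mig, 0.0)
    return mig


def simulate_island_coalescent(
    p: SimParams,
) -> tuple[SequenceAlignment, PopulationMap]:
    """Simulate one island-model dataset (alignment + population map).

    Fully reproducible from ``p.seed``: the same parameters and seed yield
    byte-identical FASTA output.
    """
    rng = np.random.default_rng(p.seed)
    names = [f"P{i + 1}" for i in range(p.n_demes)]
    labels = [
        [f"{names[d]}_{i + 1:02d}" for i in range(k)]
        for d, k in enumerate(p.sample_sizes)
    ]
    mig = _island_migration_matrix(p.n_demes, p.Nm)
    collapse = None
    if p.n_demes > 1 and p.Nm == 0:
        # isolated demes must eventually share an ancestor; 50N generations
        # is deep enough that within-deme variation is saturated relative to
        # the split
        collapse = 50.0
    root = _structured_genealogy(
        list(p.sample_sizes), mig, rng, labels, collapse_time=collapse
    )
    return _emit(
        root,
        p.theta * p.L / 2.0,
        p.L,
        p.base_composition,
        rng,
        list(p.sample_sizes),
        deme_names=names,
    )


def simulate_constant_coalescent_tree(
    n: int, N: float, seed: int | None = None
):
    """Standard Kingman coalescent genealogy for n tips, constant size N.

    Waiting time with i lineages is Exp(C(i,2)/N); branch lengths are in
    generations, the tree is ultrametric by construction. Returns a
    dendropy tree with tips ``t1..tn``.
    """
    import dendropy

    if n < 2:
        raise ValueError("need n >= 2 tips")
    if N <= 0:
        raise ValueError("N must be > 0")
    rng = np.random.default_rng(seed)
    # represent live lineages as (newick fragment, height-of-fragment-root)
    frags = [(f"t{i + 1}", 0.0) for i in range(n)]
    t = 0.0
    while len(frags) > 1:
        i_n = len(frags)
        rate = i_n * (i_n - 1) / 2.0 / N
        t += rng.exponential(1.0 / rate)
        i, j = sorted(rng.choice(i_n, size=2, replace=False))
        (fa, ha), (fb, hb) = frags[i], frags[j]
        merged = (f"({fa}:{t - ha:.10g},{fb}:{t - hb:.10g})", t)
        frags = [f for k, f in enumerate(frags) if k not in (i, j)]
        frags.append(merged)
    newick = frags[0][0] + ";"
    return dendropy.Tree.get(data=newick, schema="newick")
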