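"""Within-population and pooled diversity statistics for haploid sequence data.

Implements Nei's unbiased haplotype (gene) diversity and its sampling
variance, nucleotide diversity π (mean pairwise differences per site), and
Watterson's segregating-sites estimator of the scaled mutation rate.

The "nucleotide difference" statistic reported alongside haplotype diversity
in cpDNA surveys is implemented here as π — the default per-site nucleotide
diversity of sequence-analysis software — while the Watterson estimator is
provided separately under its own name.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .seqio import HaplotypeTable, PopulationMap, SequenceAlignment


class UndefinedStatisticError(ValueError):
    """Raised when a statistic requires more samples than provided."""


@dataclass
class DiversityStats:
    population: str
    n: int
    k: int
    S: int | None
    h: float | None
    h_sd: float | None
    pi: float | None
    theta_w: float | None


def haplotype_diversity(counts) -> float:
    """Nei's unbiased haplotype diversity h = n(1 − Σp²)/(n−1).

    ``counts`` are per-haplotype sample counts; n = Σcounts must be ≥ 2.
    h is 0 exactly when a single haplotype is present.
    """
    c = np.asarray([x for x in counts if x > 0], dtype=float)
    if c.size == 0:
        raise UndefinedStatisticError("no haplotype counts supplied")
    n = c.sum()
    if n < 2:
        raise UndefinedStatisticError(f"need n >= 2 samples, got {int(n)}")
    p = c / n
    return float(n / (n - 1.0) * (1.0 - np.sum(p**2)))


def haplotype_diversity_sd(counts) -> float:
    """Standard deviation of h from Nei's sampling-variance formula.

    V(h) = (2/(n(n−1)))·{2(n−2)[Σp³ − (Σp²)²] + Σp² − (Σp²)²}
    """
    c = np.asarray([x for x in counts if x > 0], dtype=float)
    n = c.sum()
    if n < 2:
        raise UndefinedStatisticError(f"need n >= 2 samples, got {int(n)}")
    p = c / n
    sp2 = float(np.sum(p**2))
    sp3 = float(np.sum(p**3))
    var = (2.0 / (n * (n - 1.0))) * (
        2.0 * (n - 2.0) * (sp3 - sp2**2) + sp2 - sp2**2
    )
    return math.sqrt(max(0.0, var))


def _pairwise_diff_stats(arr: np.ndarray) -> tuple[float, int]:
    """Mean per-site pairwise difference and number of pairs.

    ``arr`` is an (n, L) array of bases; sites where either member of a pair
    carries ``N`` are excluded for that pair (per-pair effective length).
    """
    n = arr.shape[0]
    total = 0.0
    pairs = 0
    valid = arr != "N"
    for i in range(n - 1):
        for j in range(i + 1, n):
            both = valid[i] & valid[j]
            eff = int(both.sum())
            if eff == 0:
                continue
            d = int(((arr[i] != arr[j]) & both).sum())
            total += d / eff
            pairs += 1
    return total, pairs


def nucleotide_diversity(a: SequenceAlignment) -> float:
    """π: mean proportion of sites differing between two random sequences.

    Requires indel columns already dropped and n ≥ 2. ``N``-bearing site
    pairs are excluded pair-by-pair.
    """
    if a.n < 2:
        raise UndefinedStatisticError("nucleotide diversity needs n >= 2")
    total, pairs = _pairwise_diff_stats(a.to_array())
    if pairs == 0:
        return 0.0
    return total / pairs


def segregating_sites(a: SequenceAlignment) -> int:
    """Number of columns with at least two distinct unambiguous bases."""
    arr = a.to_array()
    S = 0
    for col in arr.T:
        bases = {b for b in col if b != "N"}
        if len(bases) > 1:
            S += 1
    return S


def watterson_theta(S: int, n: int, L: int) -> float:
    """Watterson's per-site estimator S / a_{n-1} / L, a_k = Σ_{i=1..k} 1/i."""
    if n < 2:
        raise UndefinedStatisticError("Watterson theta needs n >= 2")
    if L < 1:
        raise ValueError("L must be >= 1")
    a_n = sum(1.0 / i for i in range(1, n))
    return S / a_n / L


def population_summary(
    t: HaplotypeTable,
    a: SequenceAlignment | None = None,
    m: PopulationMap | None = None,
) -> pd.DataFrame:
    """One diversity row per population plus a pooled ``Overall`` row.

    With sequence data (``a`` plus ``m``) the row carries n, k, S, h, h_sd,
    π and Watterson θ; from a count table alone only the frequency-based
    columns are filled. Populations with n < 2 keep their row with h fields
    set to NaN rather than being dropped.
    """
    rows = []
    seq_by_pop: dict[str, list[str]] = {}
    if a is not None and m is not None:
        for sid, seq in a.records:
            seq_by_pop.setdefault(m.population_of(sid), []).append(seq)

    def _stats_for(pop: str, counts: np.ndarray) -> DiversityStats:
        counts = counts[counts > 0]
        n = int(counts.sum())
        k = int((counts > 0).sum())
        h = h_sd = None
        if n >= 2:
            h = haplotype_diversity(counts)
            h_sd = haplotype_diversity_sd(counts)
        S = pi = theta = None
        seqs = seq_by_pop.get(pop)
        if seqs is not None and len(seqs) >= 2:
            sub = SequenceAlignment([(f"{pop}_{i}", s) for i, s in enumerate(seqs)])
            S = segregating_sites(sub)
            pi = nucleotide_diversity(sub)
            theta = watterson_theta(S, sub.n, sub.length)
        return DiversityStats(pop, n, k, S, h, h_sd, pi, theta)

    for pop in t.populations:
        rows.append(_stats_for(pop, t.counts[pop].to_numpy()))

    # pooled row over all populations
    pooled = t.pooled_counts()
    overall = _stats_for("__overall__", pooled)
    if a is not None:
        S = segregating_sites(a)
        overall.S = S
        overall.pi = nucleotide_diversity(a)
        overall.theta_w = watterson_theta(S, a.n, a.length)
    overall.population = "Overall"
    rows.append(overall)

    df = pd.DataFrame(
        [
            {
                "population": r.population,
                "n": r.n,
                "k": r.k,
                "S": r.S,
                "h": r.h,
                "h_sd": r.h_sd,
                "pi": r.pi,
                "theta_w": r.theta_w,
            }
            for r in rows
        ]
    )
    return df.set_index("population")
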