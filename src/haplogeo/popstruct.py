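"""Pairwise FST, island-model gene flow (Nm) and isolation-by-distance tests.

FST uses the Hudson–Slatkin–Maddison estimator from mean pairwise sequence
differences: FST = 1 − Hw/Hb, where Hw is the unweighted mean of the two
within-population mean pairwise difference counts and Hb the mean
between-population pairwise difference. Gene flow is deduced under the
haploid (maternal) island model FST = 1/(1 + 2Nm), so Nm = (1−FST)/(2·FST).

Isolation by distance is tested by correlating pairwise Nm against
great-circle distance, with significance from a Mantel permutation of
population identities (rows/columns permuted together); a plain regression
F-test is also reported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .seqio import PopulationMap, SequenceAlignment, great_circle_km

UNAMBIGUOUS = frozenset("ACGT")


class InsufficientDataError(ValueError):
    """Raised when fewer than the required populations/samples are available."""


def _diff_matrix(seqs_a: list[str], seqs_b: list[str]) -> np.ndarray:
    """Pairwise difference counts between two sequence sets (vectorized).

    Only sites where both bases are unambiguous (A/C/G/T) count toward a
    pair's difference total.
    """
    a = np.array([list(s) for s in seqs_a], dtype="U1")
    b = np.array([list(s) for s in seqs_b], dtype="U1")
    va = np.isin(a, list(UNAMBIGUOUS))
    vb = np.isin(b, list(UNAMBIGUOUS))
    diff = (a[:, None, :] != b[None, :, :]) & va[:, None, :] & vb[None, :, :]
    return diff.sum(axis=2)


def mean_pairwise_within(seqs: list[str]) -> float:
    """Mean pairwise difference count within a sequence set (n ≥ 2)."""
    d = _diff_matrix(seqs, seqs)
    n = len(seqs)
    iu = np.triu_indices(n, k=1)
    return float(d[iu].mean())


def mean_pairwise_between(seqs_a: list[str], seqs_b: list[str]) -> float:
    return float(_diff_matrix(seqs_a, seqs_b).mean())


def hudson_fst(seqs_a: list[str], seqs_b: list[str]) -> tuple[float, bool]:
    """Hudson FST = 1 − Hw/Hb between two sequence sets.

    Returns ``(fst, clamped)``; negative estimates are clamped to 0 with the
    flag set. When Hb = 0 (no between-population differences) the statistic
    is undefined and ``nan`` is returned.
    """
    if len(seqs_a) < 2 or len(seqs_b) < 2:
        raise InsufficientDataError("each population needs >= 2 sequences")
    hw = 0.5 * (mean_pairwise_within(seqs_a) + mean_pairwise_within(seqs_b))
    hb = mean_pairwise_between(seqs_a, seqs_b)
    if hb == 0.0:
        return float("nan"), False
    fst = 1.0 - hw / hb
    if fst < 0.0:
        return 0.0, True
    return min(fst, 1.0), False


def nm_from_fst(fst: float) -> float:
    """Island-model gene flow Nm = (1 − FST)/(2·FST).

    FST of exactly 0 implies unbounded gene flow (``inf``); FST outside
    [0, 1] is a domain error.
    """
    if math.isnan(fst):
        return float("nan")
    if fst > 1.0 or fst < 0.0:
        raise ValueError(f"FST must lie in [0, 1], got {fst}")
    if fst == 0.0:
        return float("inf")
    return (1.0 - fst) / (2.0 * fst)


@dataclass
class FstNmMatrices:
    """Symmetric pairwise FST (in [0,1]) and Nm (≥ 0, inf at FST=0) matrices."""

    populations: list[str]
    fst: pd.DataFrame
    nm: pd.DataFrame
    clamped_pairs: list[tuple[str, str]] = field(default_factory=list)
    excluded_populations: list[str] = field(default_factory=list)


def fst_nm_matrices(a: SequenceAlignment, m: PopulationMap) -> FstNmMatrices:
    """All pairwise FST/Nm values between populations with n ≥ 2.

    Populations with fewer than two samples are excluded (recorded on the
    result); fewer than two eligible populations is an error.
    """
    by_pop: dict[str, list[str]] = {}
    for sid, seq in a.records:
        by_pop.setdefault(m.population_of(sid), []).append(seq)
    order = [p for p in m.populations if p in by_pop]
    for p in by_pop:
        if p not in order:
            order.append(p)
    eligible = [p for p in order if len(by_pop[p]) >= 2]
    excluded = [p for p in order if p not in eligible]
    if len(eligible) < 2:
        raise InsufficientDataError(
            f"need >= 2 populations with >= 2 samples; eligible: {eligible}"
        )
    k = len(eligible)
    fst = np.zeros((k, k))
    nm = np.full((k, k), float("inf"))
    clamped = []
    for i in range(k - 1):
        for j in range(i + 1, k):
            f, was_clamped = hudson_fst(by_pop[eligible[i]], by_pop[eligible[j]])
            if was_clamped:
                clamped.append((eligible[i], eligible[j]))
            fst[i, j] = fst[j, i] = f
            nm[i, j] = nm[j, i] = nm_from_fst(f)
    return FstNmMatrices(
        populations=eligible,
        fst=pd.DataFrame(fst, index=eligible, columns=eligible),
        nm=pd.DataFrame(nm, index=eligible, columns=eligible),
        clamped_pairs=clamped,
        excluded_populations=excluded,
    )


def combined_table(fm: FstNmMatrices) -> pd.DataFrame:
    """Single matrix with Nm below the diagonal and FST above it."""
    pops = fm.populations
    out = pd.DataFrame("", index=pops, columns=pops, dtype=object)
    for i, p in enumerate(pops):
        for j, q in enumerate(pops):
            if i < j:
                out.loc[p, q] = f"{fm.fst.loc[p, q]:.2f}"
            elif i > j:
                v = fm.nm.loc[p, q]
                out.loc[p, q] = "inf" if math.isinf(v) else f"{v:.2f}"
    return out


@dataclass
class IbdResult:
    r: float
    p_perm: float
    n_pairs: int
    transform: str
    r_regression: float | None = None
    p_f_test: float | None = None
    n_perm: int = 0
    seed: int | None = None


def _pairwise_vectors(
    fm: FstNmMatrices, m: PopulationMap, transform: str
) -> tuple[np.ndarray, np.ndarray, list[tuple[int, int]]]:
    pops = fm.populations
    pairs = [(i, j) for i in range(len(pops)) for j in range(i + 1, len(pops))]
    nm_vals = np.array([fm.nm.iloc[i, j] for i, j in pairs])
    dist = np.array(
        [
            great_circle_km(m.site_of(pops[i]), m.site_of(pops[j]))
            for i, j in pairs
        ]
    )
    if transform == "log-distance":
        dist = np.log(dist)
    return nm_vals, dist, pairs


def ibd_test(
    fm: FstNmMatrices,
    m: PopulationMap,
    n_perm: int = 10000,
    seed: int | None = None,
    transform: str = "none",
) -> IbdResult:
    """Correlation of pairwise Nm with geographic distance, Mantel-tested.

    The Mantel permutation shuffles population identities (permuting rows
    and columns of the Nm matrix together) and recomputes the Pearson
    correlation against the fixed distance matrix; the two-sided p-value is
    the proportion of permutations with |r| ≥ |observed| (observed
    included). Pairs with infinite Nm are excluded. A plain regression
    F-test over the same (non-independent) pairs is reported alongside.
    """
    pops = fm.populations
    if len(pops) < 3:
        raise InsufficientDataError("IBD test needs >= 3 populations")
    nm_vals, dist, pairs = _pairwise_vectors(fm, m, transform)
    finite = np.isfinite(nm_vals)
    nm_f, dist_f = nm_vals[finite], dist[finite]
    if nm_f.size < 3 or np.std(nm_f) == 0 or np.std(dist_f) == 0:
        return IbdResult(float("nan"), float("nan"), int(nm_f.size), transform)
    r_obs = float(np.corrcoef(nm_f, dist_f)[0, 1])
    reg = stats.linregress(dist_f, nm_f)
    rng = np.random.default_rng(seed)
    k = len(pops)
    nm_mat = fm.nm.to_numpy()
    dist_mat = np.zeros((k, k))
    for i, j in pairs:
        d = great_circle_km(m.site_of(pops[i]), m.site_of(pops[j]))
        if transform == "log-distance":
            d = math.log(d)
        dist_mat[i, j] = dist_mat[j, i] = d
    hits = 1  # observed arrangement counts
    for _ in range(n_perm):
        perm = rng.permutation(k)
        nm_p = nm_mat[np.ix_(perm, perm)]
        x = np.array([nm_p[i, j] for i, j in pairs])
        y = np.array([dist_mat[i, j] for i, j in pairs])
        fin = np.isfinite(x)
        if fin.sum() < 3 or np.std(x[fin]) == 0:
            continue
        r_p = float(np.corrcoef(x[fin], y[fin])[0, 1])
        if abs(r_p) >= abs(r_obs) - 1e-12:
            hits += 1
    p = hits / (n_perm + 1)
    return IbdResult(
        r=r_obs,
        p_perm=p,
        n_pairs=int(nm_f.size),
        transform=transform,
        r_regression=float(reg.rvalue),
        p_f_test=float(reg.pvalue),
        n_perm=n_perm,
        seed=seed,
    )
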