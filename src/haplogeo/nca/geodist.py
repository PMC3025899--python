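"""Geographic clade statistics (Dc, Dn), permutation tests and contingency
analysis for a nesting design.

Dc (clade distance) is the count-weighted mean great-circle distance of a
clade's individuals from the clade's own geographic center; Dn (nested
clade distance) measures the same individuals from the center of the clade
one nesting level up. Centers are count-weighted centroids of unit vectors
on the sphere, renormalized — well-defined at all longitudes.

Significance comes from permuting individuals' population labels among the
member clades of each nesting clade, holding clade sizes fixed; p-values
count the observed arrangement in both numerator and denominator, so they
are never zero.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..seqio import HaplotypeTable, PopulationMap, great_circle_km
from .nesting import NestingDesign, unit_status
from ..haplonet import HaplotypeNetwork

_EPS = 1e-9


@dataclass
class CladeGeoStats:
    clade_id: str
    Dc: float
    Dn: float
    status: str | None = None
    p_small_Dc: float | None = None
    p_large_Dc: float | None = None
    p_small_Dn: float | None = None
    p_large_Dn: float | None = None


@dataclass
class InteriorTipContrast:
    nesting_clade_id: str
    it_Dc: float | None = None
    it_Dn: float | None = None
    p_small_it_Dc: float | None = None
    p_large_it_Dc: float | None = None
    p_small_it_Dn: float | None = None
    p_large_it_Dn: float | None = None


@dataclass
class ContingencyResult:
    nesting_clade_id: str
    chi_square: float | None
    p_perm: float | None
    n_perm: int
    seed: int | None
    applicable: bool = True


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------

def _unit_vectors(latlon: np.ndarray) -> np.ndarray:
    lat = np.radians(latlon[:, 0])
    lon = np.radians(latlon[:, 1])
    return np.column_stack(
        [np.cos(lat) * np.cos(lon), np.cos(lat) * np.sin(lon), np.sin(lat)]
    )


def _center_of(weights: np.ndarray, vectors: np.ndarray) -> tuple[float, float]:
    """Weighted spherical centroid as (lat, lon) in degrees."""
    v = (weights[:, None] * vectors).sum(axis=0)
    norm = np.linalg.norm(v)
    if norm == 0.0:
        # antipodal degenerate case; fall back to first weighted site
        idx = int(np.nonzero(weights)[0][0])
        v = vectors[idx]
        norm = 1.0
    v = v / norm
    lat = math.degrees(math.asin(max(-1.0, min(1.0, v[2]))))
    lon = math.degrees(math.atan2(v[1], v[0]))
    return (lat, lon)


def _weighted_mean_distance(
    weights: np.ndarray, latlon: np.ndarray, center: tuple[float, float]
) -> float:
    total = weights.sum()
    if total == 0:
        return 0.0
    d = np.array(
        [great_circle_km((la, lo), center) for la, lo in latlon]
    )
    return float((weights * d).sum() / total)


class _Geo:
    """Per-analysis cache of population order, coordinates and unit vectors."""

    def __init__(self, table: HaplotypeTable, popmap: PopulationMap):
        self.pops = list(table.populations)
        self.latlon = np.array([popmap.site_of(p) for p in self.pops])
        self.vectors = _unit_vectors(self.latlon)
        self.pop_index = {p: i for i, p in enumerate(self.pops)}

    def counts_of(self, design: NestingDesign, table: HaplotypeTable, unit: str):
        haps = design.haplotypes_of(unit)
        present = [h for h in haps if h in table.counts.index]
        w = table.counts.loc[present].sum(axis=0).to_numpy(dtype=float)
        return w

    def dc(self, w: np.ndarray) -> float:
        center = _center_of(w, self.vectors)
        return _weighted_mean_distance(w, self.latlon, center)

    def dn(self, w: np.ndarray, center: tuple[float, float]) -> float:
        return _weighted_mean_distance(w, self.latlon, center)


def clade_distances(
    design: NestingDesign, table: HaplotypeTable, popmap: PopulationMap
) -> dict[str, CladeGeoStats]:
    """Dc and Dn for every unit of the design (haplotypes and clades).

    Dn of a unit uses the geographic center of its nesting (parent) clade;
    for the total cladogram Dn = Dc by definition. A clade whose
    individuals all sit at one site has Dc = 0.
    """
    geo = _Geo(table, popmap)
    out: dict[str, CladeGeoStats] = {}
    units = [h for h in table.haplotype_ids] + [
        c.clade_id for c in design.clades
    ]
    # centers of every potential parent
    centers: dict[str, tuple[float, float]] = {}
    for c in design.clades:
        w = geo.counts_of(design, table, c.clade_id)
        centers[c.clade_id] = _center_of(w, geo.vectors)
    for unit in units:
        w = geo.counts_of(design, table, unit)
        if w.sum() == 0:
            continue
        dc = geo.dc(w)
        parent = _parent_id(design, unit)
        dn = geo.dn(w, centers[parent]) if parent else dc
        out[unit] = CladeGeoStats(clade_id=unit, Dc=dc, Dn=dn)
    return out


def _parent_id(design: NestingDesign, unit: str) -> str | None:
    try:
        return design.clade(unit).parent
    except KeyError:
        for c in design.at_level(1):
            if unit in c.members:
                return c.clade_id
        return None


# ---------------------------------------------------------------------------
# permutation tests
# ---------------------------------------------------------------------------

def _expand_pool(member_weights: list[np.ndarray]) -> tuple[np.ndarray, list[int]]:
    pool = []
    sizes = []
    for w in member_weights:
        idx = np.repeat(np.arange(len(w)), w.astype(int))
        pool.append(idx)
        sizes.append(len(idx))
    return np.concatenate(pool), sizes


def _split_counts(pool: np.ndarray, sizes: list[int], n_pops: int):
    out = []
    start = 0
    for s in sizes:
        seg = pool[start : start + s]
        out.append(np.bincount(seg, minlength=n_pops).astype(float))
        start += s
    return out


def permutation_significance(
    design: NestingDesign,
    table: HaplotypeTable,
    popmap: PopulationMap,
    n_perm: int = 10000,
    seed: int | None = None,
    network: HaplotypeNetwork | None = None,
    exhaustive: bool = False,
) -> tuple[dict[str, CladeGeoStats], dict[str, InteriorTipContrast]]:
    """Permutation p-values for Dc/Dn of every nested unit, plus
    interior-minus-tip contrasts per nesting clade.

    Within each nesting clade, individuals' population labels are permuted
    among its member clades with clade sizes held fixed; ``p_small``
    (``p_large``) is the proportion of permuted statistics ≤ (≥) the
    observed one, observed arrangement included. ``exhaustive=True``
    enumerates every ordering of the pooled labels instead of sampling
    (only sensible for tiny nesting clades). Nesting clades with a single
    member keep their statistics with p-values left as ``None``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    geo = _Geo(table, popmap)
    stats = clade_distances(design, table, popmap)
    contrasts: dict[str, InteriorTipContrast] = {}

    for parent in design.clades:
        members = parent.members
        pid = parent.clade_id
        weights = [geo.counts_of(design, table, m) for m in members]
        present = [i for i, w in enumerate(weights) if w.sum() > 0]
        members = [members[i] for i in present]
        weights = [weights[i] for i in present]
        if len(members) < 2:
            contrasts[pid] = InteriorTipContrast(nesting_clade_id=pid)
            continue
        pooled_w = np.sum(weights, axis=0)
        parent_center = _center_of(pooled_w, geo.vectors)
        sizes_w = np.array([w.sum() for w in weights])

        statuses = [
            unit_status(network, design, m) if network is not None
            else _status_lookup(design, m)
            for m in members
        ]
        tips = [i for i, s in enumerate(statuses) if s == "tip"]
        interiors = [i for i, s in enumerate(statuses) if s == "interior"]

        def member_stats(wlist):
            dcs = np.array([geo.dc(w) for w in wlist])
            dns = np.array([geo.dn(w, parent_center) for w in wlist])
            return dcs, dns

        def it_contrast(dcs, dns):
            if not tips or not interiors:
                return None, None
            wt = sizes_w
            itc = float(
                np.average(dcs[interiors], weights=wt[interiors])
                - np.average(dcs[tips], weights=wt[tips])
            )
            itn = float(
                np.average(dns[interiors], weights=wt[interiors])
                - np.average(dns[tips], weights=wt[tips])
            )
            return itc, itn

        obs_dc, obs_dn = member_stats(weights)
        obs_itc, obs_itn = it_contrast(obs_dc, obs_dn)

        pool, sizes = _expand_pool(weights)
        n_pops = len(geo.pops)
        tall = {
            "dc_small": np.zeros(len(members)),
            "dc_large": np.zeros(len(members)),
            "dn_small": np.zeros(len(members)),
            "dn_large": np.zeros(len(members)),
        }
        it_tall = {"c_small": 0, "c_large": 0, "n_small": 0, "n_large": 0}

        if exhaustive:
            perms = [np.array(p) for p in itertools.permutations(pool)]
        else:
            perms = None

        n_done = 0

        def tally(perm_pool):
            nonlocal n_done
            wlist = _split_counts(perm_pool, sizes, n_pops)
            dcs, dns = member_stats(wlist)
            tall["dc_small"] += dcs <= obs_dc + _EPS
            tall["dc_large"] += dcs >= obs_dc - _EPS
            tall["dn_small"] += dns <= obs_dn + _EPS
            tall["dn_large"] += dns >= obs_dn - _EPS
            if obs_itc is not None:
                itc, itn = it_contrast(dcs, dns)
                it_tall["c_small"] += itc <= obs_itc + _EPS
                it_tall["c_large"] += itc >= obs_itc - _EPS
                it_tall["n_small"] += itn <= obs_itn + _EPS
                it_tall["n_large"] += itn >= obs_itn - _EPS
            n_done += 1

        if exhaustive:
            for p in perms:
                tally(p)
            denom = n_done
            extra = 0
        else:
            for _ in range(n_perm):
                tally(rng.permutation(pool))
            denom = n_perm + 1
            extra = 1  # the observed arrangement

        for i, m in enumerate(members):
            s = stats[m]
            s.status = statuses[i]
            s.p_small_Dc = (tall["dc_small"][i] + extra) / denom
            s.p_large_Dc = (tall["dc_large"][i] + extra) / denom
            s.p_small_Dn = (tall["dn_small"][i] + extra) / denom
            s.p_large_Dn = (tall["dn_large"][i] + extra) / denom
        ct = InteriorTipContrast(nesting_clade_id=pid)
        if obs_itc is not None:
            ct.it_Dc, ct.it_Dn = obs_itc, obs_itn
            ct.p_small_it_Dc = (it_tall["c_small"] + extra) / denom
            ct.p_large_it_Dc = (it_tall["c_large"] + extra) / denom
            ct.p_small_it_Dn = (it_tall["n_small"] + extra) / denom
            ct.p_large_it_Dn = (it_tall["n_large"] + extra) / denom
        contrasts[pid] = ct

    return stats, contrasts


def _status_lookup(design: NestingDesign, unit: str) -> str | None:
    try:
        return design.clade(unit).status
    except KeyError:
        return None


# ---------------------------------------------------------------------------
# nested contingency analysis
# ---------------------------------------------------------------------------

def _chi_square(tableau: np.ndarray) -> float:
    rows = tableau.sum(axis=1, keepdims=True)
    cols = tableau.sum(axis=0, keepdims=True)
    total = tableau.sum()
    expected = rows @ cols / total
    mask = expected > 0
    return float(((tableau - expected)[mask] ** 2 / expected[mask]).sum())


def nested_contingency_test(
    design: NestingDesign,
    table: HaplotypeTable,
    popmap: PopulationMap | None = None,
    n_perm: int = 10000,
    seed: int | None = None,
) -> dict[str, ContingencyResult]:
    """Chi-square test of member-clade × population association per nesting
    clade, with a permutation null.

    Population labels are permuted among the nesting clade's individuals;
    p is the proportion of permuted chi-square values ≥ the observed one,
    observed included. Single-row or single-column tables are flagged
    not-applicable.
    """
    rng = np.random.default_rng(seed)
    n_pops_total = len(table.populations)
    out: dict[str, ContingencyResult] = {}
    for parent in design.clades:
        pid = parent.clade_id
        member_w = []
        for m in parent.members:
            haps = [
                h for h in design.haplotypes_of(m) if h in table.counts.index
            ]
            w = table.counts.loc[haps].sum(axis=0).to_numpy(dtype=float)
            if w.sum() > 0:
                member_w.append(w)
        if len(member_w) < 2:
            out[pid] = ContingencyResult(pid, None, None, n_perm, seed, False)
            continue
        tableau = np.vstack(member_w)
        col_mask = tableau.sum(axis=0) > 0
        tableau = tableau[:, col_mask]
        if tableau.shape[1] < 2:
            out[pid] = ContingencyResult(pid, None, None, n_perm, seed, False)
            continue
        obs = _chi_square(tableau)
        pool, sizes = _expand_pool(list(tableau))
        hits = 1
        for _ in range(n_perm):
            perm = rng.permutation(pool)
            t = np.vstack(_split_counts(perm, sizes, tableau.shape[1]))
            if _chi_square(t) >= obs - _EPS:
                hits += 1
        out[pid] = ContingencyResult(
            pid, obs, hits / (n_perm + 1), n_perm, seed, True
        )
    return out


# ---------------------------------------------------------------------------
# composition table
# ---------------------------------------------------------------------------

def clade_composition_table(
    design: NestingDesign, table: HaplotypeTable
) -> pd.DataFrame:
    """Per-clade individual counts and percentages by population.

    Mirrors the layout of nested-clade composition tables: one row per
    clade (total last), per-population counts, the clade total n and the
    percentage of all sampled individuals it holds.
    """
    n_total = table.n_total
    rows = []
    ordered = sorted(
        (c for c in design.clades if c.clade_id != "total"),
        key=lambda c: (c.level, _clade_sort_key(c.clade_id)),
    ) + [design.total]
    for c in ordered:
        haps = [h for h in design.haplotypes_of(c.clade_id) if h in table.counts.index]
        counts = table.counts.loc[haps].sum(axis=0)
        n = int(counts.sum())
        row = {"clade": c.clade_id, "n": n, "pct": round(100.0 * n / n_total, 1)}
        row.update({p: int(counts[p]) for p in table.populations})
        rows.append(row)
    return pd.DataFrame(rows).set_index("clade")


def _clade_sort_key(cid: str):
    try:
        lvl, idx = cid.split("-")
        return (int(lvl), int(idx))
    except ValueError:
        return (999, 0)
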