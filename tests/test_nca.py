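import itertools
import math

import numpy as np
import pandas as pd
import pytest

from haplogeo.haplonet import minimum_spanning_network, step_matrix
from haplogeo.nca import (
    Clade,
    NestingDesign,
    build_nesting,
    clade_composition_table,
    clade_distances,
    nested_contingency_test,
    permutation_significance,
)
from haplogeo.nca.inference import (
    CladePattern,
    apply_inference_key,
    load_inference_key,
)
from haplogeo.nca.geodist import CladeGeoStats, InteriorTipContrast
from haplogeo.nca.nesting import unit_status
from haplogeo.seqio import HaplotypeTable, PopulationMap


def _path_network(n=5):
    """Haplotypes on a mutational path: H1-H2-...-Hn, one step apart."""
    L = n + 2
    seqs = {}
    base = list("A" * L)
    for i in range(n):
        s = base.copy()
        for k in range(i):
            s[k] = "T"
        seqs[f"H{i + 1}"] = "".join(s)
    ids = list(seqs)
    t = HaplotypeTable(
        counts=pd.DataFrame({"P": [1] * n}, index=ids), sequences=seqs
    )
    return t, minimum_spanning_network(step_matrix(t), t.counts)


class TestNesting:
    def test_five_haplotype_path(self):
        # tips unite inward; the stranded middle attaches to the smaller
        # (lexicographically first on ties) adjacent clade
        _, nw = _path_network(5)
        design = build_nesting(nw)
        level1 = sorted(tuple(c.members) for c in design.at_level(1))
        assert level1 == [("H1", "H2", "H3"), ("H4", "H5")]
        assert design.total.members == ["2-1"] or len(design.at_level(2)) <= 1

    def test_single_haplotype_trivial_clade(self):
        t = HaplotypeTable(
            counts=pd.DataFrame({"P": [3]}, index=["H1"]),
            sequences={"H1": "ACGT"},
        )
        nw = minimum_spanning_network(step_matrix(t), t.counts)
        design = build_nesting(nw)
        assert [c.members for c in design.at_level(1)] == [["H1"]]

    def test_star_unites_all_tips_with_center(self):
        seqs = {"H1": "AAAAA"}
        for i in range(4):
            s = list("AAAAA")
            s[i] = "T"
            seqs[f"H{i + 2}"] = "".join(s)
        t = HaplotypeTable(
            counts=pd.DataFrame({"P": [1] * 5}, index=list(seqs)),
            sequences=seqs,
        )
        nw = minimum_spanning_network(step_matrix(t), t.counts)
        design = build_nesting(nw)
        assert [sorted(c.members) for c in design.at_level(1)] == [
            ["H1", "H2", "H3", "H4", "H5"]
        ]

    def test_every_level_partitions_haplotypes(self, rng):
        for _ in range(5):
            n = int(rng.integers(6, 16))
            seqs = {}
            while len(seqs) < n:
                s = "".join(rng.choice(list("ACGT"), size=12))
                seqs[s] = None
            seqs = {f"H{i + 1}": s for i, s in enumerate(seqs)}
            t = HaplotypeTable(
                counts=pd.DataFrame({"P": [1] * n}, index=list(seqs)),
                sequences=seqs,
            )
            nw = minimum_spanning_network(step_matrix(t), t.counts)
            design = build_nesting(nw)
            for level in design.levels():
                units = [
                    h
                    for c in design.at_level(level)
                    for h in design.haplotypes_of(c.clade_id)
                ]
                if any(c.clade_id == "total" for c in design.at_level(level)):
                    continue
                assert sorted(units) == sorted(seqs)

    def test_path_endpoints_are_tips_middle_interior(self):
        _, nw = _path_network(5)
        design = build_nesting(nw)
        # within clade (H1,H2,H3): H1 and H3 have one connection, H2 two
        assert unit_status(nw, design, "H1") == "tip"
        assert unit_status(nw, design, "H2") == "interior"

    def test_three_cycle_members_all_interior(self):
        # three haplotypes at mutual distance 1 form a loop
        seqs = {"H1": "AA", "H2": "AT", "H3": "AC"}
        t = HaplotypeTable(
            counts=pd.DataFrame({"P": [1, 1, 1]}, index=list(seqs)),
            sequences=seqs,
        )
        nw = minimum_spanning_network(step_matrix(t), t.counts)
        design = build_nesting(nw)
        assert len(design.at_level(1)) == 1
        for h in seqs:
            assert unit_status(nw, design, h) == "interior"


def _two_site_setup(dist_km=100.0):
    dlat = math.degrees(dist_km / 6371.0)
    pmap = PopulationMap(
        sample_to_pop={},
        pop_to_site={"P1": (0.0, 10.0, 0.0), "P2": (dlat, 10.0, 0.0)},
    )
    return pmap


class TestCladeDistances:
    def _design(self, counts: pd.DataFrame) -> NestingDesign:
        c1 = Clade("1-1", 1, list(counts.index), parent="total")
        total = Clade("total", 2, ["1-1"])
        return NestingDesign(clades=[c1, total])

    def test_single_population_clade_has_zero_dc(self):
        counts = pd.DataFrame({"P1": [3], "P2": [0]}, index=["H1"])
        t = HaplotypeTable(counts=counts)
        stats = clade_distances(self._design(counts), t, _two_site_setup())
        assert stats["1-1"].Dc == 0.0

    def test_equal_split_100km_gives_dc_50(self):
        counts = pd.DataFrame({"P1": [2], "P2": [2]}, index=["H1"])
        t = HaplotypeTable(counts=counts)
        stats = clade_distances(self._design(counts), t, _two_site_setup(100.0))
        assert stats["1-1"].Dc == pytest.approx(50.0, abs=0.2)

    def test_dn_equals_dc_when_nesting_clade_identical(self):
        counts = pd.DataFrame({"P1": [2], "P2": [1]}, index=["H1"])
        t = HaplotypeTable(counts=counts)
        stats = clade_distances(self._design(counts), t, _two_site_setup())
        assert stats["1-1"].Dn == pytest.approx(stats["1-1"].Dc)
        assert stats["total"].Dn == pytest.approx(stats["total"].Dc)

    def test_invariant_under_longitude_translation(self):
        counts = pd.DataFrame({"P1": [2], "P2": [3]}, index=["H1"])
        t = HaplotypeTable(counts=counts)
        base = _two_site_setup()
        shifted = PopulationMap(
            sample_to_pop={},
            pop_to_site={
                p: (lat, lon + 137.0, e)
                for p, (lat, lon, e) in base.pop_to_site.items()
            },
        )
        s1 = clade_distances(self._design(counts), t, base)
        s2 = clade_distances(self._design(counts), t, shifted)
        assert s1["1-1"].Dc == pytest.approx(s2["1-1"].Dc, abs=1e-6)


def _toy_nested():
    """Two 1-step clades of 2 individuals each over 3 populations."""
    counts = pd.DataFrame(
        {"P1": [2, 0], "P2": [0, 1], "P3": [0, 1]}, index=["HA", "HB"]
    )
    t = HaplotypeTable(counts=counts)
    design = NestingDesign(
        clades=[
            Clade("1-1", 1, ["HA"], parent="total"),
            Clade("1-2", 1, ["HB"], parent="total"),
            Clade("total", 2, ["1-1", "1-2"]),
        ]
    )
    pmap = PopulationMap(
        sample_to_pop={},
        pop_to_site={
            "P1": (39.0, 106.0, 0.0),
            "P2": (40.0, 106.5, 0.0),
            "P3": (40.5, 107.5, 0.0),
        },
    )
    return design, t, pmap


def _oracle_permutation_pvalues(design, t, pmap):
    """Independent brute force: enumerate all orderings of the pooled labels."""

    def hav(p1, p2):
        la1, lo1 = map(math.radians, p1)
        la2, lo2 = map(math.radians, p2)
        h = (
            math.sin((la2 - la1) / 2) ** 2
            + math.cos(la1) * math.cos(la2) * math.sin((lo2 - lo1) / 2) ** 2
        )
        return 2 * 6371.0 * math.asin(math.sqrt(h))

    def center(points):
        vs = []
        for lat, lon in points:
            la, lo = math.radians(lat), math.radians(lon)
            vs.append(
                (
                    math.cos(la) * math.cos(lo),
                    math.cos(la) * math.sin(lo),
                    math.sin(la),
                )
            )
        m = [sum(v[i] for v in vs) / len(vs) for i in range(3)]
        norm = math.sqrt(sum(x * x for x in m))
        m = [x / norm for x in m]
        return (
            math.degrees(math.asin(m[2])),
            math.degrees(math.atan2(m[1], m[0])),
        )

    pool = ["P1", "P1", "P2", "P3"]
    all_points = [pmap.site_of(p) for p in pool]
    total_center = center(all_points)

    def stats_for(assign):
        a_pts = [pmap.site_of(p) for p in assign[:2]]
        b_pts = [pmap.site_of(p) for p in assign[2:]]
        dc_a = sum(hav(p, center(a_pts)) for p in a_pts) / 2
        dc_b = sum(hav(p, center(b_pts)) for p in b_pts) / 2
        dn_a = sum(hav(p, total_center) for p in a_pts) / 2
        dn_b = sum(hav(p, total_center) for p in b_pts) / 2
        return dc_a, dc_b, dn_a, dn_b

    obs = stats_for(pool)
    perms = [stats_for(list(p)) for p in itertools.permutations(pool)]
    n = len(perms)
    out = {}
    for idx, key in enumerate(["dc_a", "dc_b", "dn_a", "dn_b"]):
        small = sum(1 for s in perms if s[idx] <= obs[idx] + 1e-9) / n
        large = sum(1 for s in perms if s[idx] >= obs[idx] - 1e-9) / n
        out[key] = (small, large)
    return out


class TestPermutationSignificance:
    def test_exhaustive_matches_independent_oracle(self):
        design, t, pmap = _toy_nested()
        stats, _ = permutation_significance(
            design, t, pmap, n_perm=1, exhaustive=True
        )
        oracle = _oracle_permutation_pvalues(design, t, pmap)
        assert stats["1-1"].p_small_Dc == pytest.approx(oracle["dc_a"][0])
        assert stats["1-1"].p_large_Dc == pytest.approx(oracle["dc_a"][1])
        assert stats["1-2"].p_small_Dn == pytest.approx(oracle["dn_b"][0])
        assert stats["1-2"].p_large_Dn == pytest.approx(oracle["dn_b"][1])

    def test_sampled_pvalues_approach_exhaustive(self):
        design, t, pmap = _toy_nested()
        ex, _ = permutation_significance(
            design, t, pmap, n_perm=1, exhaustive=True
        )
        mc, _ = permutation_significance(design, t, pmap, n_perm=4000, seed=5)
        assert mc["1-1"].p_small_Dc == pytest.approx(
            ex["1-1"].p_small_Dc, abs=0.05
        )

    def test_one_location_gives_all_pvalues_one(self):
        counts = pd.DataFrame({"P1": [2, 2]}, index=["HA", "HB"])
        t = HaplotypeTable(counts=counts)
        design = NestingDesign(
            clades=[
                Clade("1-1", 1, ["HA"], parent="total"),
                Clade("1-2", 1, ["HB"], parent="total"),
                Clade("total", 2, ["1-1", "1-2"]),
            ]
        )
        pmap = PopulationMap(
            sample_to_pop={}, pop_to_site={"P1": (39.0, 106.0, 0.0)}
        )
        stats, _ = permutation_significance(design, t, pmap, n_perm=200, seed=1)
        for cid in ("1-1", "1-2"):
            assert stats[cid].p_small_Dc == 1.0
            assert stats[cid].p_large_Dn == 1.0

    def test_seeded_determinism(self):
        design, t, pmap = _toy_nested()
        s1, _ = permutation_significance(design, t, pmap, n_perm=500, seed=77)
        s2, _ = permutation_significance(design, t, pmap, n_perm=500, seed=77)
        assert s1["1-1"].p_small_Dc == s2["1-1"].p_small_Dc

    def test_single_member_parent_flagged_not_applicable(self):
        counts = pd.DataFrame({"P1": [2], "P2": [1]}, index=["HA"])
        t = HaplotypeTable(counts=counts)
        design = NestingDesign(
            clades=[
                Clade("1-1", 1, ["HA"], parent="total"),
                Clade("total", 2, ["1-1"]),
            ]
        )
        pmap = _two_site_setup()
        stats, contrasts = permutation_significance(
            design, t, pmap, n_perm=100, seed=1
        )
        assert stats["1-1"].p_small_Dc is None
        assert contrasts["total"].it_Dc is None


class TestNestedContingency:
    def test_small_complete_separation_exact(self):
        # 2x2 table (3,0 / 0,3): exact permutation p = 2/C(6,3) = 0.1
        counts = pd.DataFrame({"P1": [3, 0], "P2": [0, 3]}, index=["HA", "HB"])
        t = HaplotypeTable(counts=counts)
        design = NestingDesign(
            clades=[
                Clade("1-1", 1, ["HA"], parent="total"),
                Clade("1-2", 1, ["HB"], parent="total"),
                Clade("total", 2, ["1-1", "1-2"]),
            ]
        )
        res = nested_contingency_test(design, t, n_perm=20000, seed=3)
        assert res["total"].p_perm == pytest.approx(0.1, abs=0.01)

    def test_strong_separation_significant(self):
        counts = pd.DataFrame({"P1": [10, 0], "P2": [0, 10]}, index=["HA", "HB"])
        t = HaplotypeTable(counts=counts)
        design = NestingDesign(
            clades=[
                Clade("1-1", 1, ["HA"], parent="total"),
                Clade("1-2", 1, ["HB"], parent="total"),
                Clade("total", 2, ["1-1", "1-2"]),
            ]
        )
        res = nested_contingency_test(design, t, n_perm=10000, seed=3)
        assert res["total"].p_perm <= 0.001

    def test_uniform_table_not_significant(self):
        counts = pd.DataFrame({"P1": [5, 5], "P2": [5, 5]}, index=["HA", "HB"])
        t = HaplotypeTable(counts=counts)
        design = NestingDesign(
            clades=[
                Clade("1-1", 1, ["HA"], parent="total"),
                Clade("1-2", 1, ["HB"], parent="total"),
                Clade("total", 2, ["1-1", "1-2"]),
            ]
        )
        res = nested_contingency_test(design, t, n_perm=2000, seed=3)
        assert res["total"].p_perm > 0.5

    def test_single_column_not_applicable(self):
        counts = pd.DataFrame({"P1": [3, 3]}, index=["HA", "HB"])
        t = HaplotypeTable(counts=counts)
        design = NestingDesign(
            clades=[
                Clade("1-1", 1, ["HA"], parent="total"),
                Clade("1-2", 1, ["HB"], parent="total"),
                Clade("total", 2, ["1-1", "1-2"]),
            ]
        )
        res = nested_contingency_test(design, t, n_perm=100, seed=3)
        assert not res["total"].applicable

    def test_seeded_determinism(self):
        counts = pd.DataFrame({"P1": [4, 1], "P2": [1, 4]}, index=["HA", "HB"])
        t = HaplotypeTable(counts=counts)
        design = NestingDesign(
            clades=[
                Clade("1-1", 1, ["HA"], parent="total"),
                Clade("1-2", 1, ["HB"], parent="total"),
                Clade("total", 2, ["1-1", "1-2"]),
            ]
        )
        r1 = nested_contingency_test(design, t, n_perm=500, seed=9)
        r2 = nested_contingency_test(design, t, n_perm=500, seed=9)
        assert r1["total"].p_perm == r2["total"].p_perm


def _mk_stats(cid, status, **p):
    return CladeGeoStats(
        clade_id=cid, Dc=p.get("Dc", 10.0), Dn=p.get("Dn", 10.0),
        status=status,
        p_small_Dc=p.get("p_small_Dc", 0.5),
        p_large_Dc=p.get("p_large_Dc", 0.5),
        p_small_Dn=p.get("p_small_Dn", 0.5),
        p_large_Dn=p.get("p_large_Dn", 0.5),
    )


class TestInferenceKey:
    def test_key_loads_and_enumerates_valid_conclusions(self):
        key = load_inference_key()
        assert key["start"] in key["steps"]

    def test_restricted_gene_flow_ibd_chain(self):
        # significantly small tip Dc + significantly large tip Dn, ranges
        # overlapping -> 1-2-3-4(no) -> restricted gene flow with IBD
        pat = CladePattern(
            nesting_clade_id="total",
            members=[
                _mk_stats("A", "tip", p_small_Dc=0.01, p_large_Dn=0.01),
                _mk_stats("B", "interior"),
            ],
            contrast=InteriorTipContrast("total"),
            contingency=None,
            member_pop_counts={
                "A": {"P1": 5, "P2": 1},
                "B": {"P2": 5, "P3": 5},
            },
            inter_steps=[1],
            intra_steps=[1, 1],
        )
        out = apply_inference_key(pat)
        assert out.conclusion == "restricted gene flow with isolation by distance"
        assert [s for s, _ in out.key_path] == ["1", "2", "3", "4"]
        assert out.key_path[-1] == ("4", "no")

    def test_no_significance_is_inconclusive_at_step_one(self):
        pat = CladePattern(
            nesting_clade_id="total",
            members=[_mk_stats("A", "tip"), _mk_stats("B", "interior")],
            contrast=InteriorTipContrast("total"),
            contingency=None,
            member_pop_counts={"A": {"P1": 5}, "B": {"P2": 5}},
            inter_steps=[1],
            intra_steps=[],
        )
        out = apply_inference_key(pat)
        assert out.conclusion == "inconclusive"
        assert out.key_path == [("1", "no")]

    def test_deep_disjoint_split_is_past_fragmentation(self):
        pat = CladePattern(
            nesting_clade_id="total",
            members=[
                _mk_stats("A", "tip", p_small_Dc=0.01),
                _mk_stats("B", "interior", p_small_Dc=0.2),
            ],
            contrast=InteriorTipContrast("total"),
            contingency=None,
            member_pop_counts={
                "A": {"P1": 10, "P2": 10},
                "B": {"P3": 10, "P4": 10},
            },
            inter_steps=[20],
            intra_steps=[1, 2, 1],
        )
        out = apply_inference_key(pat)
        assert out.conclusion == "past fragmentation"


class TestComposition:
    def test_reference_counts_reproduce_published_table(self, reference):
        comp = clade_composition_table(
            reference.clade_memberships, reference.haplotype_counts
        )
        expected = {
            "1-1": {"n": 10, "SZS": 10},
            "1-2": {"n": 10, "GLS": 10},
            "2-1": {"n": 20, "SZS": 10, "GLS": 10},
            "1-3": {"n": 6, "HN": 6},
            "2-2": {"n": 6, "HN": 6},
            "3-1": {"n": 26, "SZS": 10, "HN": 6, "GLS": 10},
            "1-4": {"n": 12, "HN": 2, "TST": 10},
            "1-5": {"n": 9, "HN": 2, "XD": 7},
            "2-3": {"n": 21, "HN": 4, "XD": 7, "TST": 10},
            "1-6": {"n": 11, "XD": 3, "YKBLG": 8},
            "1-7": {"n": 9, "BLG": 9},
            "2-4": {"n": 20, "XD": 3, "YKBLG": 8, "BLG": 9},
            "1-8": {"n": 10, "MSG": 10},
            "2-5": {"n": 10, "MSG": 10},
            "3-2": {"n": 51, "HN": 4, "XD": 10, "YKBLG": 8, "TST": 10,
                    "MSG": 10, "BLG": 9},
            "total": {"n": 77},
        }
        for cid, cells in expected.items():
            for col, val in cells.items():
                assert comp.loc[cid, col] == val, (cid, col)
        assert comp.loc["3-2", "pct"] == 66.2
        assert comp.loc["2-1", "pct"] == 26.0

    def test_full_clade_is_100_percent(self, reference):
        comp = clade_composition_table(
            reference.clade_memberships, reference.haplotype_counts
        )
        assert comp.loc["total", "pct"] == 100.0

    def test_singleton_percentage_arithmetic(self):
        counts = pd.DataFrame({"P1": [76, 1]}, index=["HA", "HB"])
        t = HaplotypeTable(counts=counts)
        design = NestingDesign(
            clades=[
                Clade("1-1", 1, ["HA"], parent="total"),
                Clade("1-2", 1, ["HB"], parent="total"),
                Clade("total", 2, ["1-1", "1-2"]),
            ]
        )
        comp = clade_composition_table(design, t)
        assert comp.loc["1-2", "pct"] == 1.3
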