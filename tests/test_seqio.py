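import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from haplogeo import seqio
from haplogeo.seqio import (
    AlignmentError,
    CoordinateError,
    FormatError,
    PopulationMap,
    SequenceAlignment,
    collapse_haplotypes,
    drop_indel_columns,
    great_circle_km,
    parse_dms_coordinate,
    read_fasta_alignment,
    read_haplotype_counts,
)


class TestReadFasta:
    def test_reads_records_in_order_uppercased(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(">s1\nacgtuacgta\n>s2\nACGTACGTAC\n")
        a = read_fasta_alignment(p)
        assert a.length == 10
        assert a.sample_ids == ["s1", "s2"]
        assert a.sequences[0] == "ACGTTACGTA"  # U mapped to T

    def test_unequal_lengths_names_offender(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(">s1\nACGTACGTAC\n>bad\nACGTACGTA\n")
        with pytest.raises(AlignmentError, match="bad"):
            read_fasta_alignment(p)

    def test_empty_file_is_format_error(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text("")
        with pytest.raises(FormatError):
            read_fasta_alignment(p)


class TestDropIndels:
    def test_gap_columns_removed_and_indices_kept(self):
        a = SequenceAlignment([("x", "ACGT"), ("y", "AC-T")])
        out, kept = drop_indel_columns(a)
        assert out.length == 3
        assert kept == [0, 1, 3]
        assert out.sequences == ["ACT", "ACT"]

    def test_gap_free_alignment_is_identity(self, toy_alignment):
        out, kept = drop_indel_columns(toy_alignment)
        assert kept == list(range(10))
        assert out.sequences == toy_alignment.sequences

    def test_column_count_matches_gap_scan(self, rng):
        # independent oracle: count columns containing at least one gap
        n, L = 5, 30
        arr = rng.choice(list("ACGT"), size=(n, L))
        for col in (4, 17):
            arr[rng.integers(0, n), col] = "-"
        a = SequenceAlignment(
            [(f"s{i}", "".join(arr[i])) for i in range(n)]
        )
        expected_removed = sum((arr == "-").any(axis=0))
        out, kept = drop_indel_columns(a)
        assert out.length == L - expected_removed
        assert kept == sorted(kept)

    def test_all_gap_columns_error(self):
        a = SequenceAlignment([("x", "-"), ("y", "A")])
        with pytest.raises(AlignmentError):
            drop_indel_columns(a)


class TestCollapse:
    def test_identical_sequences_share_haplotype(self, toy_alignment, toy_popmap):
        t = collapse_haplotypes(toy_alignment, toy_popmap)
        assert len(t.haplotype_ids) == 3
        assert t.pooled_counts().tolist() == [3, 1, 1]
        assert t.n_total == 5

    def test_all_distinct_gives_n_haplotypes(self, rng):
        # brute-force dedup over random distinct strings
        seqs = set()
        while len(seqs) < 10:
            seqs.add("".join(rng.choice(list("ACGT"), size=12)))
        seqs = sorted(seqs)
        a = SequenceAlignment([(f"s{i}", s) for i, s in enumerate(seqs)])
        m = PopulationMap(
            sample_to_pop={f"s{i}": "P" for i in range(10)},
            pop_to_site={"P": (0.0, 0.0, 0.0)},
        )
        t = collapse_haplotypes(a, m)
        assert len(t.haplotype_ids) == len(set(seqs))

    def test_haplotype_count_matches_string_dedup(self, rng):
        n, L = 20, 15
        base = rng.choice(list("ACGT"), size=L)
        rows = []
        for i in range(n):
            s = base.copy()
            if rng.random() < 0.6:
                s[rng.integers(0, L)] = rng.choice(list("ACGT"))
            rows.append("".join(s))
        a = SequenceAlignment([(f"s{i}", s) for i, s in enumerate(rows)])
        m = PopulationMap(
            sample_to_pop={f"s{i}": "P" for i in range(n)},
            pop_to_site={"P": (0.0, 0.0, 0.0)},
        )
        t = collapse_haplotypes(a, m)
        assert len(t.haplotype_ids) == len(set(rows))
        # total sample count preserved
        assert t.n_total == n

    def test_n_is_wildcard_for_identity(self):
        a = SequenceAlignment([("x", "ACGT"), ("y", "ACGN")])
        m = PopulationMap(
            sample_to_pop={"x": "P", "y": "P"},
            pop_to_site={"P": (0.0, 0.0, 0.0)},
        )
        t = collapse_haplotypes(a, m)
        assert len(t.haplotype_ids) == 1
        assert t.sequences["H01"] == "ACGT"  # refined representative

    def test_missing_sample_raises_mapping_error(self, toy_alignment):
        m = PopulationMap(
            sample_to_pop={"s1": "A"}, pop_to_site={"A": (0.0, 0.0, 0.0)}
        )
        with pytest.raises(KeyError):
            collapse_haplotypes(toy_alignment, m)

    def test_collapse_is_idempotent_under_reapplication(
        self, toy_alignment, toy_popmap
    ):
        a, _ = drop_indel_columns(toy_alignment)
        t1 = collapse_haplotypes(a, toy_popmap)
        hap_aln = SequenceAlignment(
            [(h, t1.sequences[h]) for h in t1.haplotype_ids]
        )
        m = PopulationMap(
            sample_to_pop={h: "P" for h in t1.haplotype_ids},
            pop_to_site={"P": (0.0, 0.0, 0.0)},
        )
        a2, _ = drop_indel_columns(hap_aln)
        t2 = collapse_haplotypes(a2, m)
        assert len(t2.haplotype_ids) == len(t1.haplotype_ids)


class TestCountTable:
    def test_reference_counts_totals(self, reference, tmp_path):
        t = reference.haplotype_counts
        assert t.n_total == 77
        assert len(t.haplotype_ids) == 38
        assert len(t.populations) == 8

    def test_single_monomorphic_row(self, tmp_path):
        p = tmp_path / "c.tsv"
        p.write_text("haplotype\tYKBLG\nH30\t8\n")
        t = read_haplotype_counts(p)
        assert t.n_total == 8
        assert t.pooled_counts().tolist() == [8]

    def test_empty_body_errors(self, tmp_path):
        p = tmp_path / "c.tsv"
        p.write_text("haplotype\tA\tB\n")
        with pytest.raises(FormatError):
            read_haplotype_counts(p)

    def test_negative_cell_errors(self, tmp_path):
        p = tmp_path / "c.tsv"
        p.write_text("haplotype\tA\nH1\t-2\n")
        with pytest.raises(FormatError):
            read_haplotype_counts(p)


class TestCoordinates:
    @pytest.mark.parametrize(
        "text,lat,lon",
        [
            ("106°49'E 39°25'N", 39 + 25 / 60, 106 + 49 / 60),
            ("0°0'E 0°0'N", 0.0, 0.0),
            ("107°03'E 40°16'N", 40 + 16 / 60, 107.05),
            ("39°25'N 106°49'E", 39 + 25 / 60, 106 + 49 / 60),  # either order
        ],
    )
    def test_dms_parse(self, text, lat, lon):
        got_lat, got_lon = parse_dms_coordinate(text)
        assert got_lat == pytest.approx(lat, abs=1e-9)
        assert got_lon == pytest.approx(lon, abs=1e-9)

    def test_minutes_over_60_rejected(self):
        with pytest.raises(CoordinateError):
            parse_dms_coordinate("106°61'E 39°25'N")

    def test_identical_points_zero_distance(self):
        assert great_circle_km((39.5, 106.8), (39.5, 106.8)) == 0.0

    def test_antipodal_half_circumference(self):
        assert great_circle_km((0, 0), (0, 180)) == pytest.approx(
            math.pi * 6371.0, abs=0.1
        )

    def test_matches_independent_haversine(self, reference):
        # second implementation of the formula, written from scratch
        def hav(p1, p2):
            la1, lo1, la2, lo2 = map(
                math.radians, (p1[0], p1[1], p2[0], p2[1])
            )
            h = (
                math.sin((la2 - la1) / 2) ** 2
                + math.cos(la1) * math.cos(la2) * math.sin((lo2 - lo1) / 2) ** 2
            )
            return 2 * 6371.0 * math.atan2(math.sqrt(h), math.sqrt(1 - h))

        szs = reference.coordinates.site_of("SZS")
        blg = reference.coordinates.site_of("BLG")
        assert great_circle_km(szs, blg) == pytest.approx(hav(szs, blg), abs=0.1)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        st.tuples(
            st.floats(-89, 89), st.floats(-179, 179),
            st.floats(-89, 89), st.floats(-179, 179),
            st.floats(-89, 89), st.floats(-179, 179),
        )
    )
    def test_symmetry_and_triangle_inequality(self, coords):
        p1, p2, p3 = (coords[0], coords[1]), (coords[2], coords[3]), (coords[4], coords[5])
        d12 = great_circle_km(p1, p2)
        d21 = great_circle_km(p2, p1)
        assert d12 == pytest.approx(d21, abs=1e-6)
        assert d12 <= great_circle_km(p1, p3) + great_circle_km(p3, p2) + 1e-6
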