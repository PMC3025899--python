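"""Packaged reference dataset from a range-wide cpDNA survey of an
endangered desert shrub: 77 individuals from eight populations, 38
haplotypes at a ~881-bp chloroplast spacer.

The fixture carries the haplotype-by-population count matrix, the sampling
site coordinates (degree–minute notation, with elevations), and the
published nested-clade memberships, so the count-only stages of the
pipeline can run — and be checked — without any sequence download.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd

from ..nca.nesting import NestingDesign
from ..seqio import HaplotypeTable, PopulationMap, parse_dms_coordinate


class FixturePackagingError(RuntimeError):
    """Raised when the packaged data fail their internal checksums."""


@dataclass
class ReferenceFixture:
    haplotype_counts: HaplotypeTable
    coordinates: PopulationMap
    clade_memberships: NestingDesign


def _data_path(name: str):
    return resources.files("haplogeo.data").joinpath(name)


def load_reference_counts() -> HaplotypeTable:
    with resources.as_file(_data_path("reference_haplotype_counts.tsv")) as p:
        df = pd.read_csv(p, sep="\t", index_col=0)
    return HaplotypeTable(counts=df.astype(int), sequences=None)


def load_reference_sites() -> PopulationMap:
    with resources.as_file(_data_path("reference_sites.tsv")) as p:
        df = pd.read_csv(p, sep="\t")
    pop_to_site = {}
    for _, row in df.iterrows():
        lat, lon = parse_dms_coordinate(str(row["coordinate"]))
        pop_to_site[str(row["population"])] = (
            lat, lon, float(row["elevation_m"])
        )
    return PopulationMap(sample_to_pop={}, pop_to_site=pop_to_site)


def load_reference_clades() -> NestingDesign:
    """Published nesting design (clade → members), statuses unassigned.

    The assignment of sequence-identical singletons to 1-step clades is
    reconstructed to match the published per-population clade totals.
    """
    from ..nca.nesting import read_clade_memberships

    with resources.as_file(_data_path("reference_clades.tsv")) as p:
        return read_clade_memberships(p)


def make_reference_fixture() -> ReferenceFixture:
    """Load and validate the packaged reference dataset.

    Checks the printed totals: 77 individuals, 38 haplotypes, 8
    populations, and clade totals (e.g. the large northern clade holds 51
    individuals). A mismatch raises :class:`FixturePackagingError`.
    """
    counts = load_reference_counts()
    sites = load_reference_sites()
    design = load_reference_clades()
    errors = []
    if counts.n_total != 77:
        errors.append(f"grand total {counts.n_total} != 77")
    if len(counts.haplotype_ids) != 38:
        errors.append(f"{len(counts.haplotype_ids)} haplotypes != 38")
    if len(counts.populations) != 8:
        errors.append(f"{len(counts.populations)} populations != 8")
    if set(counts.populations) != set(sites.populations):
        errors.append("population codes differ between counts and sites")
    expected_clade_totals = {"2-1": 20, "2-2": 6, "2-3": 21, "2-4": 20,
                             "2-5": 10, "3-1": 26, "3-2": 51, "total": 77}
    for cid, expected in expected_clade_totals.items():
        haps = [
            h for h in design.haplotypes_of(cid) if h in counts.counts.index
        ]
        n = int(counts.counts.loc[haps].sum().sum())
        if n != expected:
            errors.append(f"clade {cid} holds {n}, expected {expected}")
    if errors:
        raise FixturePackagingError("; ".join(errors))
    return ReferenceFixture(
        haplotype_counts=counts,
        coordinates=sites,
        clade_memberships=design,
    )
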