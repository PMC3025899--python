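"""Reading, writing and bookkeeping of aligned cpDNA sequence data.

This module houses the three containers the rest of the package consumes —
:class:`SequenceAlignment`, :class:`PopulationMap` and :class:`HaplotypeTable` —
together with the plumbing every downstream statistic relies on: excluding
indel-bearing columns, collapsing identical sequences into haplotypes,
parsing degree–minute coordinates, and great-circle distances.

Conventions
-----------
* Alignment columns are indexed 0-based internally; user-facing reports are
  the only place 1-based indices appear.
* ``N`` is an ambiguity wildcard for haplotype identity (two sequences that
  differ only where one carries ``N`` collapse into one haplotype), but sites
  where either base is ``N`` are excluded from difference counts.
* Geographic distance is the haversine great-circle distance on a sphere of
  radius 6371.0 km.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import SeqIO

EARTH_RADIUS_KM = 6371.0

VALID_BASES = frozenset("ACGTN-")
UNAMBIGUOUS = frozenset("ACGT")


class AlignmentError(ValueError):
    """Raised when sequence records violate alignment invariants."""


class FormatError(ValueError):
    """Raised on malformed input files."""


class MappingError(KeyError):
    """Raised when a sample cannot be resolved to a population."""


class CoordinateError(ValueError):
    """Raised on malformed or out-of-range coordinates."""


@dataclass
class SequenceAlignment:
    """Equal-length sequences over ``{A,C,G,T,N,-}`` with unique sample ids."""

    records: list[tuple[str, str]]

    def __post_init__(self) -> None:
        if not self.records:
            raise AlignmentError("alignment contains no records")
        lengths = {len(s) for _, s in self.records}
        if len(lengths) != 1:
            bad = self._first_unequal()
            raise AlignmentError(
                f"sequences are not all the same length (offending record: {bad!r})"
            )
        if next(iter(lengths)) < 1:
            raise AlignmentError("alignment length must be >= 1")
        ids = [sid for sid, _ in self.records]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise AlignmentError(f"duplicate sample ids: {dup}")
        for sid, seq in self.records:
            extra = set(seq) - VALID_BASES
            if extra:
                raise AlignmentError(
                    f"record {sid!r} contains invalid characters {sorted(extra)}"
                )

    def _first_unequal(self) -> str:
        ref = len(self.records[0][1])
        for sid, seq in self.records:
            if len(seq) != ref:
                return sid
        return self.records[0][0]

    @property
    def length(self) -> int:
        return len(self.records[0][1])

    @property
    def n(self) -> int:
        return len(self.records)

    @property
    def sample_ids(self) -> list[str]:
        return [sid for sid, _ in self.records]

    @property
    def sequences(self) -> list[str]:
        return [seq for _, seq in self.records]

    def to_array(self) -> np.ndarray:
        """Alignment as an (n, L) array of single-byte strings."""
        return np.array([list(s) for _, s in self.records], dtype="U1")


@dataclass
class PopulationMap:
    """Sample → population assignment plus georeferenced sites.

    ``pop_to_site`` maps a population code to ``(lat, lon, elevation_m)`` in
    decimal degrees (N/E positive).
    """

    sample_to_pop: dict[str, str]
    pop_to_site: dict[str, tuple[float, float, float]]

    def __post_init__(self) -> None:
        for pop, (lat, lon, _elev) in self.pop_to_site.items():
            if not (-90.0 <= lat <= 90.0):
                raise CoordinateError(f"latitude out of range for {pop}: {lat}")
            if not (-180.0 <= lon <= 180.0):
                raise CoordinateError(f"longitude out of range for {pop}: {lon}")

    @property
    def populations(self) -> list[str]:
        return list(self.pop_to_site)

    def population_of(self, sample_id: str) -> str:
        try:
            return self.sample_to_pop[sample_id]
        except KeyError:
            raise MappingError(f"sample {sample_id!r} missing from population map")

    def site_of(self, pop: str) -> tuple[float, float]:
        lat, lon, _ = self.pop_to_site[pop]
        return (lat, lon)


@dataclass
class HaplotypeTable:
    """Distinct haplotypes with per-population counts.

    ``counts`` is a haplotype × population integer DataFrame; ``sequences``
    maps haplotype id to its (indel-free) sequence when sequence data were
    the source, else ``None``.
    """

    counts: pd.DataFrame
    sequences: dict[str, str] | None = None

    def __post_init__(self) -> None:
        c = self.counts
        if (c.values < 0).any():
            raise FormatError("haplotype counts must be non-negative")
        if not np.issubdtype(c.values.dtype, np.integer):
            raise FormatError("haplotype counts must be integers")
        if (c.sum(axis=1) < 1).any():
            empty = list(c.index[c.sum(axis=1) < 1])
            raise FormatError(f"haplotypes with zero total count: {empty}")
        if self.sequences is not None:
            seqs = list(self.sequences.values())
            if len(set(seqs)) != len(seqs):
                raise FormatError("haplotype sequences are not pairwise distinct")

    @property
    def haplotype_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def populations(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_total(self) -> int:
        return int(self.counts.values.sum())

    def pooled_counts(self) -> np.ndarray:
        """Per-haplotype counts summed over populations."""
        return self.counts.sum(axis=1).to_numpy()


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta_alignment(path) -> SequenceAlignment:
    """Read an aligned FASTA file.

    Characters are uppercased and ``U`` is mapped to ``T``. Records keep file
    order. Unequal record lengths raise :class:`AlignmentError` naming the
    offending record; an empty file raises :class:`FormatError`.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper().replace("U", "T")
        records.append((rec.id, seq))
    if not records:
        raise FormatError(f"no FASTA records found in {path}")
    ref_len = len(records[0][1])
    for sid, seq in records:
        if len(seq) != ref_len:
            raise AlignmentError(
                f"record {sid!r} has length {len(seq)}, expected {ref_len}"
            )
    return SequenceAlignment(records)


def write_fasta_alignment(a: SequenceAlignment, path) -> None:
    with open(path, "w") as fh:
        for sid, seq in a.records:
            fh.write(f">{sid}\n{seq}\n")


# ---------------------------------------------------------------------------
# Indel exclusion and haplotype collapsing
# ---------------------------------------------------------------------------

def drop_indel_columns(a: SequenceAlignment) -> tuple[SequenceAlignment, list[int]]:
    """Remove every column in which any sequence carries a gap.

    Returns the reduced alignment and the strictly increasing list of 0-based
    original column indices that were kept. Raises :class:`AlignmentError`
    when no columns survive.
    """
    arr = a.to_array()
    keep_mask = ~(arr == "-").any(axis=0)
    kept = [int(i) for i in np.nonzero(keep_mask)[0]]
    if not kept:
        raise AlignmentError("all columns contain gaps; nothing left to analyse")
    reduced = arr[:, keep_mask]
    records = [
        (sid, "".join(row)) for (sid, _), row in zip(a.records, reduced)
    ]
    return SequenceAlignment(records), kept


def sequences_match(x: str, y: str) -> bool:
    """True when two equal-length sequences agree at every non-N site."""
    return all(a == b or a == "N" or b == "N" for a, b in zip(x, y))


def collapse_haplotypes(a: SequenceAlignment, m: PopulationMap) -> HaplotypeTable:
    """Collapse identical sequences into haplotypes and tabulate by population.

    Two sequences share a haplotype when they agree at every site, with ``N``
    acting as a wildcard. Matching is greedy in input order against a class
    representative; when a concrete base meets an ``N`` in the representative
    the representative is refined, so the stored haplotype sequence carries
    the least ambiguity seen. Ids ``H01, H02, ...`` follow order of first
    appearance.
    """
    pops: list[str] = []
    for sid, _ in a.records:
        pops.append(m.population_of(sid))  # raises MappingError if absent

    reps: list[str] = []  # class representatives
    assign: list[int] = []
    for _, seq in a.records:
        for k, rep in enumerate(reps):
            if sequences_match(seq, rep):
                if "N" in rep:
                    reps[k] = "".join(
                        b if r == "N" else r for r, b in zip(rep, seq)
                    )
                assign.append(k)
                break
        else:
            reps.append(seq)
            assign.append(len(reps) - 1)

    n_h = len(reps)
    width = max(2, len(str(n_h)))
    hap_ids = [f"H{k + 1:0{width}d}" for k in range(n_h)]
    pop_order = [p for p in m.populations if p in set(pops)]
    # populations absent from the site table but present in samples keep order
    for p in pops:
        if p not in pop_order:
            pop_order.append(p)
    counts = pd.DataFrame(
        0, index=hap_ids, columns=pop_order, dtype=int
    )
    for k, p in zip(assign, pops):
        counts.loc[hap_ids[k], p] += 1
    sequences = dict(zip(hap_ids, reps))
    return HaplotypeTable(counts=counts, sequences=sequences)


# ---------------------------------------------------------------------------
# Tabular inputs
# ---------------------------------------------------------------------------

def read_haplotype_counts(path) -> HaplotypeTable:
    """Read a haplotype × population count table (TSV, header = populations)."""
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except pd.errors.EmptyDataError:
        raise FormatError(f"empty haplotype count table: {path}")
    if df.empty:
        raise FormatError(f"haplotype count table has no rows: {path}")
    df = df.fillna(0)
    values = df.to_numpy()
    if not np.all(values == np.floor(values)):
        raise FormatError("haplotype counts must be integers")
    if (values < 0).any():
        raise FormatError("haplotype counts must be non-negative")
    df = df.astype(int)
    df.index = df.index.astype(str)
    return HaplotypeTable(counts=df, sequences=None)


def write_haplotype_counts(t: HaplotypeTable, path) -> None:
    t.counts.to_csv(path, sep="\t")


def read_population_map(path) -> PopulationMap:
    """Read a TSV with columns sample, population, lat, lon, elevation.

    ``lat``/``lon`` cells accept decimal degrees or degree–minute tokens like
    ``39°25'N``; a single cell holding a full pair ("106°49'E 39°25'N") is
    also accepted in the lat column.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample", "population"}
    if not required.issubset(df.columns):
        raise FormatError(f"population map must have columns {sorted(required)}")
    sample_to_pop: dict[str, str] = {}
    pop_to_site: dict[str, tuple[float, float, float]] = {}
    for _, row in df.iterrows():
        sample_to_pop[str(row["sample"])] = str(row["population"])
        pop = str(row["population"])
        if pop in pop_to_site:
            continue
        lat_cell = str(row.get("lat", "")).strip()
        lon_cell = str(row.get("lon", "")).strip()
        elev = float(row.get("elevation", 0) or 0)
        if "°" in lat_cell and ("E" in lat_cell or "W" in lat_cell):
            lat, lon = parse_dms_coordinate(lat_cell)
        else:
            lat = _parse_coord_token(lat_cell, axis="lat")
            lon = _parse_coord_token(lon_cell, axis="lon")
        pop_to_site[pop] = (lat, lon, elev)
    return PopulationMap(sample_to_pop=sample_to_pop, pop_to_site=pop_to_site)


# ---------------------------------------------------------------------------
# Coordinates
# ---------------------------------------------------------------------------

_DMS_TOKEN = re.compile(r"^(\d+)\s*°\s*(\d+(?:\.\d+)?)\s*'?\s*([NSEW])$")


def _parse_coord_token(token: str, axis: str) -> float:
    token = token.strip()
    m = _DMS_TOKEN.match(token)
    if m:
        deg, minutes, hemi = int(m.group(1)), float(m.group(2)), m.group(3)
        if minutes >= 60:
            raise CoordinateError(f"minutes >= 60 in token {token!r}")
        value = deg + minutes / 60.0
        if hemi in "SW":
            value = -value
        expected = "NS" if axis == "lat" else "EW"
        if hemi not in expected:
            raise CoordinateError(
                f"hemisphere {hemi!r} not valid for {axis} in {token!r}"
            )
        return value
    try:
        return float(token)
    except ValueError:
        raise CoordinateError(f"cannot parse coordinate token {token!r}")


def parse_dms_coordinate(text: str) -> tuple[float, float]:
    """Parse a degree–minute pair like ``"106°49'E 39°25'N"``.

    Accepts longitude/latitude tokens in either order and returns
    ``(lat, lon)`` in signed decimal degrees (decimal = degrees + minutes/60,
    sign from the hemisphere letter).
    """
    tokens = text.split()
    if len(tokens) != 2:
        raise CoordinateError(f"expected two coordinate tokens in {text!r}")
    lat = lon = None
    for tok in tokens:
        m = _DMS_TOKEN.match(tok.strip())
        if not m:
            raise CoordinateError(f"malformed coordinate token {tok!r}")
        hemi = m.group(3)
        if hemi in "NS":
            lat = _parse_coord_token(tok, "lat")
        else:
            lon = _parse_coord_token(tok, "lon")
    if lat is None or lon is None:
        raise CoordinateError(f"need one N/S and one E/W token in {text!r}")
    return (lat, lon)


def great_circle_km(p1: tuple[float, float], p2: tuple[float, float]) -> float:
    """Haversine great-circle distance in km between (lat, lon) points."""
    lat1, lon1 = p1
    lat2, lon2 = p2
    for lat, lon in ((lat1, lon1), (lat2, lon2)):
        if not (-90.0 <= lat <= 90.0) or not (-180.0 <= lon <= 180.0):
            raise CoordinateError(f"coordinate out of range: ({lat}, {lon})")
    phi1, phi2 = math.radians(lat1), math.radians(lat2)
    dphi = phi2 - phi1
    dlam = math.radians(lon2 - lon1)
    a = math.sin(dphi / 2) ** 2 + math.cos(phi1) * math.cos(phi2) * math.sin(dlam / 2) ** 2
    return 2.0 * EARTH_RADIUS_KM * math.asin(min(1.0, math.sqrt(a)))
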