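"""Named demographic scenarios with known phylogeographic signatures.

Each scenario emits the same (alignment, population map) pair the I/O layer
reads, plus a provenance dict recording the generating history, so
inference-level tests can check that the analysis recovers the signature
that generated the data:

* ``ibd_stepping_stone`` — eight demes on a line, nearest-neighbor
  migration only (Nm = 2 between neighbors): restricted gene flow with
  isolation by distance.
* ``fragmentation`` — two four-deme clusters separated by an unoccupied
  gap, free-ish migration within clusters (Nm = 1), none between, clusters
  merged 8N generations ago: deep vicariant split.
* ``range_expansion`` — eight demes founded 0.05N generations ago from
  deme 1, weak migration since (Nm = 0.5): shallow, star-like genealogy.

Scenario parameters are fixed definitions, not tuning knobs; they encode
what each history means in coalescent units.
"""

from __future__ import annotations

import numpy as np

from ..seqio import PopulationMap, SequenceAlignment
from .coalescent import (
    DEFAULT_COMPOSITION,
    _emit,
    _structured_genealogy,
)

SCENARIOS = ("ibd_stepping_stone", "fragmentation", "range_expansion")

_N_DEMES = 8
_SAMPLES = 10
_L = 881
_THETA = 0.005


def make_scenario(
    name: str, seed: int | None = None
) -> tuple[SequenceAlignment, PopulationMap, dict]:
    """Simulate one replicate of a named scenario.

    Returns (alignment, population map, provenance) where provenance
    records the scenario name, seed and generating parameters. Unknown
    names raise a ValueError listing the available scenarios.
    """
    if name not in SCENARIOS:
        raise ValueError(f"unknown scenario {name!r}; choose from {SCENARIOS}")
    rng = np.random.default_rng(seed)
    samples = [_SAMPLES] * _N_DEMES
    names = [f"P{i + 1}" for i in range(_N_DEMES)]
    labels = [
        [f"{names[d]}_{i + 1:02d}" for i in range(k)]
        for d, k in enumerate(samples)
    ]
    mig = np.zeros((_N_DEMES, _N_DEMES))
    collapse = None
    ancestral_scale = 1.0
    positions = None
    meta: dict = {"scenario": name, "seed": seed, "n_demes": _N_DEMES,
                  "samples_per_deme": _SAMPLES, "theta": _THETA, "L": _L}

    if name == "ibd_stepping_stone":
        # nearest-neighbor Nm = 2; scaled per-lineage rate M = Nm per
        # neighboring deme (haploid maternal scaling)
        nm_neighbor = 2.0
        for i in range(_N_DEMES - 1):
            mig[i, i + 1] = nm_neighbor
            mig[i + 1, i] = nm_neighbor
        collapse = 50.0  # guarantee common ancestry at great depth
        meta["Nm_neighbor"] = nm_neighbor
    elif name == "fragmentation":
        nm_within = 1.0
        clusters = [list(range(4)), list(range(4, 8))]
        for cl in clusters:
            for i in cl:
                for j in cl:
                    if i != j:
                        mig[i, j] = nm_within * (len(cl) - 1) / len(cl) / (len(cl) - 1)
        collapse = 8.0  # deep split, 8N generations
        # geographic gap between the clusters
        positions = [0, 1, 2, 3, 10, 11, 12, 13]
        meta.update({"Nm_within": nm_within, "split_time_N": collapse})
    elif name == "range_expansion":
        nm = 0.5
        M = nm * (_N_DEMES - 1) / _N_DEMES
        mig[:] = M / (_N_DEMES - 1)
        np.fill_diagonal(mig, 0.0)
        collapse = 0.05  # all demes founded very recently from one source
        ancestral_scale = 1.0
        meta.update({"Nm": nm, "founding_time_N": collapse})

    root = _structured_genealogy(
        samples, mig, rng, labels,
        collapse_time=collapse, ancestral_scale=ancestral_scale,
    )
    aln, pmap = _emit(
        root,
        _THETA * _L / 2.0,
        _L,
        DEFAULT_COMPOSITION,
        rng,
        samples,
        deme_positions=positions,
        deme_names=names,
    )
    return aln, pmap, meta
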