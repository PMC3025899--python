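"""Neighbor-joining haplotype tree with bootstrap, then a skyline plot.

Builds a K2P/NJ tree over the haplotypes of a simulated dataset with
column-resampling bootstrap support, makes it ultrametric (midpoint root +
mean-path-length smoothing), and converts the coalescent intervals into a
classic skyline: a piecewise-constant history of effective population
size. With mutation rate mu (substitutions/site/year) the interval with i
lineages and duration tau years contributes N = i(i-1)*tau/2 (x generation
time).
"""

from haplogeo import seqio
from haplogeo.demography import (
    classic_skyline,
    coalescent_intervals,
    skyline_table,
    ultrametricize_tree,
)
from haplogeo.phylogeny import bootstrap_support
from haplogeo.synthetic import SimParams, simulate_island_coalescent

aln, pmap = simulate_island_coalescent(
    SimParams(n_demes=4, sample_sizes=(8, 8, 8, 8), seed=3)
)
table = seqio.collapse_haplotypes(aln, pmap)
hap_aln = seqio.SequenceAlignment(
    [(h, table.sequences[h]) for h in table.haplotype_ids]
)
tree, report = bootstrap_support(hap_aln, n_reps=200, seed=9)
supports = sorted(report["support"].values(), reverse=True)
print(
    f"NJ tree over {len(table.haplotype_ids)} haplotypes; "
    f"top bootstrap supports: {[round(s) for s in supports[:5]]} %"
)

ultra = ultrametricize_tree(tree)
ci = coalescent_intervals(ultra)
sky = classic_skyline(ci, mutation_rate=3e-9, L=aln.length, generation_time=1.0)
print("\nclassic skyline (most recent segments first):")
print(skyline_table(sky).head(8).to_string(index=False))
print(
    "\nEach row: a time slice (years before present) and the effective"
    "\npopulation size implied by the coalescent waiting time in it."
)
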