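"""Per-population diversity from the packaged haplotype count table.

Builds the reference haplotype-by-population matrix (77 cpDNA spacer
sequences, 38 haplotypes, 8 shrub populations) and prints Nei's unbiased
haplotype diversity h ± SD per population plus the pooled estimate.
h is the probability two randomly drawn individuals carry different
haplotypes; 0 means a monomorphic population, 1 means every sampled
individual is unique.
"""

from haplogeo.diversity import population_summary
from haplogeo.synthetic import make_reference_fixture

fixture = make_reference_fixture()
summary = population_summary(fixture.haplotype_counts)

print(summary[["n", "k", "h", "h_sd"]].round(3))
print(
    "\nPooled h =",
    round(summary.loc["Overall", "h"], 3),
    "- high species-wide diversity despite low within-population variation,"
    "\nthe signature of strong differentiation between populations.",
)
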