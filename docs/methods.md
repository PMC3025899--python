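# Methods

`haplogeo` implements the classic single-locus cpDNA phylogeography
workflow for intraspecific studies: haplotype collapsing, diversity
statistics, a minimum spanning network, nested clade analysis (NCA) with
permutation tests and an inference key, pairwise FST / island-model gene
flow with an isolation-by-distance test, a neighbor-joining phylogeny with
bootstrap, and deterministic skyline demography. This note records the
models, the defaults, and the design choices made where the procedure is
conventionally underspecified.

## Data model and preprocessing

The unit of analysis is an aligned set of equal-length sequences over
`{A,C,G,T,N,-}` from a single non-recombining, maternally inherited locus,
with each sample assigned to a georeferenced population. Columns containing
a gap in any sequence are removed before any statistic is computed
(indel exclusion); all downstream coordinates are reported against the
reduced alignment, 0-based internally.

Haplotype identity treats `N` as a wildcard: two sequences that differ only
where one carries `N` collapse into one haplotype, and the stored
representative keeps the least-ambiguous base seen. Matching is greedy in
input order, which makes collapsing deterministic; because wildcard
matching is not transitive, input order can in principle affect how
`N`-rich sequences group — irrelevant for data without ambiguity codes.
Sites involving `N` are excluded from all difference counts (per pair).

## Diversity statistics

* Haplotype diversity: Nei's unbiased estimator
  `h = n(1 − Σp_i²)/(n−1)`, with SD from the sampling variance
  `V(h) = (2/(n(n−1)))·{2(n−2)[Σp³ − (Σp²)²] + Σp² − (Σp²)²}`.
* Nucleotide diversity π: mean proportion of differing sites over all
  C(n,2) pairs, with a per-pair effective length that excludes
  `N`-involved sites. The "nucleotide difference" statistic conventionally
  reported next to h in cpDNA surveys is π; back-calculation from
  segregating-site counts shows it is not the Watterson estimate, which is
  therefore provided separately under its own name
  (`watterson_theta = S/a_{n−1}/L`).
* The SD of π is not computed: the variance formula differs across
  software versions and none is canonical.

## Minimum spanning network

Pairwise mutational steps count sites with differing unambiguous bases. A
primary minimum spanning tree is built by Kruskal with deterministic
tie-breaking (weight, then lexicographic node pair); every non-tree pair
whose direct distance equals the bottleneck (minimax) path weight between
its endpoints is added as an *alternative* edge. This reproduces the
classic minimum-spanning-network behavior: ties surface as loops, and the
emitted edge set is independent of how MST ties were broken (asserted by a
shuffle test). No median/inferred haplotypes are created; multi-step edges
carry their step count.

## Nested clade analysis

**Nesting.** The linking rules start at the tips: each tip unit is united
with its interior neighbor into a clade, united units are pruned, and the
procedure repeats on the residue; the same rules then apply one level up
with the new clades as units, until a level would contain a single
category, which becomes the total cladogram. Conventions for the cases the
rules do not cover:

* Loops are broken, for nesting only, at the edge joining the two
  lowest-frequency haplotypes (ties: lexicographic), the standard
  frequency criterion for reticulation ambiguity. Removed edges are
  recorded on the design.
* A stranded unit (all neighbors consumed by earlier passes) attaches to
  the adjacent formed clade with the fewest members; ties prefer the clade
  whose connecting unit was its uniting interior, then the
  lexicographically smallest clade.
* Tip/interior status counts mutational connections on the full network
  (loops included) from a unit to its siblings: exactly one connection →
  tip, otherwise interior. A two-member nesting clade gives both members
  one connection; there the higher-frequency member is called interior
  (older lineages are expected to be more frequent under the coalescent),
  with exact ties to the lexicographically first id.

**Geographic statistics.** Dc is the count-weighted mean great-circle
distance of a clade's individuals from the clade's geographic center; Dn
measures the same individuals from the center of the nesting (parent)
clade. Centers are count-weighted means of unit vectors on the sphere,
renormalized — well-defined at all longitudes (Dc/Dn are invariant to
longitude translation, tested numerically). Distances use the haversine
formula with Earth radius 6371.0 km.

**Permutation tests.** Within each nesting clade, individuals' population
labels are permuted among member clades with clade sizes fixed.
`p_small` (`p_large`) is the fraction of permuted statistics ≤ (≥) the
observed value with the observed arrangement included in numerator and
denominator, so p > 0 always. Interior-minus-tip contrasts (size-weighted)
are recomputed per permutation. Default `n_perm = 10,000`; a seed is
required wherever sampling occurs, and an exhaustive mode enumerates all
orderings for tiny clades (used by the tests against an independent
brute-force oracle). The nested contingency test uses the chi-square
statistic on the member-clade × population table with the same
permutation null.

**Inference key.** The key ships as an editable JSON decision table
(step id, predicate, yes/no/na transitions), defaulting to an encoding of
the classic 1995-style key, so alternative key versions can be swapped in.
Questions that are judgment calls in the original are operationalized as
computable predicates, at significance level α = 0.05:

* "occupies geographically distinct areas" ("completely or mostly
  nonoverlapping"): ≥ 90% of a member clade's individuals sit in
  populations no sibling clade occupies;
* "deep divergence": mean mutational steps on network edges between
  member clades exceeds twice the within-clade mean (and at least 2);
* sampling-adequacy questions: answered affirmatively.

Conclusions are limited to: restricted gene flow with isolation by
distance; restricted gene flow with some long-distance dispersal;
long-distance colonization; past fragmentation; contiguous range
expansion; inconclusive. Patterns outside the table end as inconclusive
with the partial key path recorded. The key is applied independently to
every nesting clade with ≥ 2 members; a dataset-level reading should
consider the full set of per-clade conclusions, since signatures (e.g. a
deep vicariant split) surface at the nesting level where the relevant
clades are siblings, not necessarily at the total cladogram.

## Population structure and isolation by distance

FST between two populations is the Hudson–Slatkin–Maddison estimator from
mean pairwise differences, `FST = 1 − Hw/Hb`, with Hw the unweighted mean
of the two within-population means and Hb the between-population mean —
the default for sequence data in standard polymorphism software. Negative
estimates are clamped to 0 and flagged; Hb = 0 yields `nan`
(not applicable). Gene flow is deduced from the haploid (maternal) island
model `FST = 1/(1 + 2Nm)`, i.e. `Nm = (1 − FST)/(2·FST)`, infinite at
FST = 0.

When averaging FST across replicates or loci, the package's tests use the
ratio of averages (`1 − mean(Hw)/mean(Hb)`) rather than the average of
per-replicate ratios: for a single non-recombining locus the genealogical
variance of Hb makes the mean of ratios noticeably downward-biased, while
the combined ratio converges to the island-model expectation.

Isolation by distance correlates pairwise Nm with great-circle distance
(pairs with infinite Nm excluded). Because the C(k,2) pairs are not
independent, significance comes from a Mantel permutation of population
identities (matrix rows/columns permuted together; two-sided on |r|); the
naive regression F-test over pairs is also reported for comparability
with older studies, clearly labeled.

## Phylogeny

Kimura two-parameter distances use pairwise deletion by default (per-pair
comparable sites; complete deletion by flag); a non-positive log argument
(saturation) flags the distance undefined. Neighbor joining follows
Saitou–Nei with the standard Q-criterion and deterministic tie-breaking;
negative branch lengths are clamped to 0 with the deficit shifted to the
sister branch. Bootstrap support resamples alignment columns with
replacement, rebuilds the NJ tree per replicate, and reports the
percentage of replicates containing each internal bipartition of the
full-data tree; replicates with saturated distances are dropped and
counted. Trees are dendropy objects; newick I/O preserves branch lengths
to 10 significant digits and supports as internal node labels.

## Skyline demography

The demographic reconstruction is the deterministic classic/generalized
skyline on a single ultrametric genealogy — a desk-testable analogue of
MCMC skyline methods, chosen because it requires no posterior sampling
and its estimates have closed forms the tests can verify. With i lineages
over an interval of τ years (branch lengths in substitutions/site divided
by the rate μ, default 3×10⁻⁹ substitutions/site/year), the classic
estimate is `N̂ = i(i−1)·τ/2` per generation time; when no generation time
is supplied the output is N × generation-time and labeled as such. The
generalized skyline pools adjacent intervals until each group spans ≥ ε
and uses the pooled MLE `Σ C(i_j,2)τ_j / (#coalescences)`; ε = 0 reduces
exactly to the classic estimator.

For real data the input genealogy comes from the haplotype NJ tree made
ultrametric by midpoint rooting plus mean-path-length smoothing
(`ultrametricize_tree`). This is an approximation, not a clock model:
skyline output on such trees supports qualitative trend reading
(decline vs. growth), not dating. Simulation tests check quantitative
recovery only on genuinely ultrametric coalescent trees.

## Synthetic data generator

The structured-coalescent generator is the package's test harness and
emulates the sampling design the pipeline targets: 8 demes, 8–10 samples
each, one non-recombining ~881-site locus, strong differentiation, many
private haplotypes.

* **Scaling.** Time is in units of N generations (haploid female deme
  size). Coalescence within a deme with k lineages occurs at rate C(k,2);
  each lineage migrates at scaled rate `M = Nm(d−1)/d` to a uniform other
  deme — the finite-island mapping under which pairwise Hudson FST has
  expectation `1/(1+2Nm)` (verified against theory and against msprime as
  an independent oracle).
* **Mutation.** Poisson events at rate θL/2 per lineage per time unit on
  a finite-sites sequence; each event hits a uniform site and redraws the
  base from the stationary composition restricted to the other three
  bases. Finite sites (not infinite sites) is deliberate: recurrent
  mutation produces the homoplasy and network loops the nesting rules
  must handle. Default composition is A/T-rich (0.368/0.132/0.132/0.368
  for A/C/G/T), echoing noncoding cpDNA spacers.
* **Defaults.** θ = 0.005/site (giving species-wide diversity of the
  order observed at such loci), L = 881, Nm = 0.25 (expected FST ≈ 0.67,
  inside the 0.2–0.9 range typical of maternally inherited markers in
  fragmented populations), sample sizes (10,10,10,10,8,10,10,9). Deme
  coordinates sit on a latitudinal transect at ~13 km spacing.
* **Scenarios.** Fixed histories in coalescent units, not tuning knobs:
  stepping-stone (nearest-neighbor Nm = 2), fragmentation (two 4-deme
  clusters, within-cluster Nm = 1, no exchange, merged 8N generations ago,
  geographic gap between clusters), range expansion (8 demes founded
  0.05N generations ago from one deme, Nm = 0.5 since).

What the generator does **not** emulate: recombination, selection,
sequencing/alignment error, unequal deme sizes, real geography beyond a
transect, and population-size change within scenarios other than the
instantaneous founding/merging events. Passing recovery tests therefore
demonstrates internal consistency of estimator and model scaling, not
robustness to the messiness of real data.

## Reproducibility and numerical choices

* Every stochastic routine takes an explicit seed; the pipeline derives
  per-stage child seeds from the master seed via
  `SeedSequence([master, stage_counter])` with fixed counters, so a run is
  byte-identical under a fixed configuration.
* Permutation p-values include the observed arrangement (never 0); ties
  in permutation comparisons use an absolute tolerance of 1e-9 km.
* Ultrametricity is accepted within a relative tolerance of 1e-6 of tree
  height; negative branch lengths are rejected.
* Problem sizes in the test suite's recovery experiments: 200 island-model
  replicates (2 demes × 20 samples) for FST, 500 single-deme replicates
  (n = 20) for Watterson θ, 100 coalescent trees (n = 20) for skyline
  recovery, and 20 replicates per scenario for the inference-key checks —
  sizes at which the Monte Carlo error is comfortably below the asserted
  tolerances.

## Known limitations

* NCA's inferential validity is debated; the package reproduces the
  procedure faithfully and treats its conclusions as hypotheses, not
  ground truth. The operationalized predicates (90% exclusivity, 2×
  divergence) are reasonable but necessarily sharper than the prose they
  encode.
* The two-member tip/interior frequency rule and the stranded-unit
  attachment rule are conventions; alternative choices shift clade
  boundaries in edge cases.
* Hudson FST from a single locus has large genealogical variance;
  per-pair values on real data should be read as noisy, and Nm as an
  equilibrium-model transform of FST rather than a demographic
  measurement.
* The skyline on an ultrametricized NJ tree inherits all the
  approximations above it (distance model, midpoint root, smoothing).
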