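"""Pairwise FST / island-model Nm and an isolation-by-distance test.

Simulates a stepping-stone world (migration only between neighboring
demes), estimates Hudson FST for every population pair, converts it to
gene flow under the haploid island model FST = 1/(1+2Nm), and tests
whether gene flow declines with distance (Mantel permutation on the Nm
vs. distance matrices). Under stepping-stone migration the correlation of
Nm with distance should be negative.
"""

from haplogeo.popstruct import combined_table, fst_nm_matrices, ibd_test
from haplogeo.synthetic import make_scenario

aln, pmap, meta = make_scenario("ibd_stepping_stone", seed=5)
fm = fst_nm_matrices(aln, pmap)
print("Nm below diagonal, FST above:")
print(combined_table(fm))

res = ibd_test(fm, pmap, n_perm=5000, seed=11)
print(
    f"\nIBD: Pearson r(Nm, distance) = {res.r:.3f}, "
    f"Mantel p = {res.p_perm:.4f} over {res.n_pairs} pairs"
)
print("(negative r: less gene flow between more distant demes)")
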