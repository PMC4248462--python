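"""Estimate the site frequency spectrum without calling genotypes.

Simulates 10 diploids at 2X / 0.2% error under a neutral spectrum, computes
sample-allele-frequency (SAF) likelihood vectors per site, and runs the EM
to recover the SFS. Compares the estimate with the spectrum the data were
generated from.
"""

import numpy as np

from glpop.gl_models import gl3_batch_from_counts
from glpop.saf_sfs import saf_batch, sfs_em_1d
from glpop.simulate import SimConfig, sim_onepop

cfg = SimConfig(n_individuals=10, n_sites=50_000, mean_depth=2.0,
                error_rate=0.002, seed=7)
truth = sim_onepop(cfg)
gl3 = gl3_batch_from_counts(truth.counts, 10 ** (-cfg.phred / 10),
                            truth.alleles)
safs = saf_batch(gl3)          # (sites, 2n+1) log p(X | D = j)
gamma, trace = sfs_em_1d(safs, return_trace=True)

true_sfs = cfg.resolved_sfs()
tv = 0.5 * np.abs(gamma - true_sfs).sum()
print(f"sites: {cfg.n_sites}, 2n+1 = {len(gamma)} frequency classes")
print(f"EM iterations: {len(trace)}, final loglik: {trace[-1]:.1f}")
print(f"total-variation distance to the true spectrum: {tv:.4f}")
print()
print("  j   true      estimated")
for j in range(len(gamma)):
    print(f" {j:2d}   {true_sfs[j]:.5f}   {gamma[j]:.5f}")
print()
print("Each derived-allele-count class is recovered from reads alone — at "
      "2X no individual genotype is confidently known, yet the sample-wide "
      "spectrum is accurate to a few percent.")
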