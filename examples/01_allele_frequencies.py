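"""Estimate per-site allele frequencies and test for variability.

Simulates 2000 low-coverage sites (2X, 0.2% error) for 10 diploids, computes
genotype likelihoods from the read counts, estimates each site's minor-allele
frequency by EM and flags SNPs with the likelihood-ratio test.
"""

import numpy as np

from glpop.allele_freq import snp_lrt_batch
from glpop.gl_models import gl3_batch_from_counts
from glpop.simulate import SimConfig, sim_onepop

cfg = SimConfig(n_individuals=10, n_sites=2000, mean_depth=2.0,
                error_rate=0.002, seed=1)
truth = sim_onepop(cfg)
gl3 = gl3_batch_from_counts(truth.counts, 10 ** (-cfg.phred / 10),
                            truth.alleles)
f_hat, lrt, p = snp_lrt_batch(gl3)

called = p < 1e-4
truly_variable = truth.derived_counts > 0
print(f"sites simulated:            {cfg.n_sites}")
print(f"truly variable:             {truly_variable.sum()}")
print(f"SNPs called (p < 1e-4):     {called.sum()}")
print(f"false discoveries:          {(called & ~truly_variable).sum()}")
rmse = np.sqrt(np.nanmean((f_hat - truth.frequencies) ** 2))
print(f"frequency RMSE vs truth:    {rmse:.4f}")
print()
print("site  f_true  f_hat   LRT      p")
for s in np.nonzero(called)[0][:5]:
    print(f"{s:4d}  {truth.frequencies[s]:.3f}   {f_hat[s]:.3f}  "
          f"{lrt[s]:7.2f}  {p[s]:.2e}")
print()
print("The EM frequency tracks the (unobserved) sample frequency despite "
      "2X coverage; the LRT separates variable sites from monomorphic "
      "ones without calling any genotype.")
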