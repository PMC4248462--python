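"""Joint two-population site frequency spectrum by EM.

Two populations of 6 diploids share sites drawn from a correlated spectrum
(invariant + shared + private polymorphism). SAF vectors are computed per
population and the joint (13 x 13) spectrum is estimated by EM.
"""

import numpy as np

from glpop.gl_models import gl3_batch_from_counts
from glpop.saf_sfs import saf_batch, sfs_em_2d
from glpop.simulate import SimConfig, correlated_joint_sfs, sim_twopop

joint = correlated_joint_sfs(6, 6)
cfg1 = SimConfig(n_individuals=6, n_sites=50_000, seed=23)
cfg2 = SimConfig(n_individuals=6, n_sites=50_000, seed=23)
t1, t2 = sim_twopop(cfg1, cfg2, joint)

s1 = saf_batch(gl3_batch_from_counts(t1.counts, 0.002, t1.alleles))
s2 = saf_batch(gl3_batch_from_counts(t2.counts, 0.002, t2.alleles))
gamma = sfs_em_2d(s1, s2, max_iter=2000)

tv = 0.5 * np.abs(gamma - joint).sum()
print(f"aligned sites: {len(s1)}; spectrum shape: {gamma.shape}")
print(f"joint total-variation distance to truth: {tv:.4f}")
print(f"mass invariant in both (0,0): true {joint[0, 0]:.3f}, "
      f"est {gamma[0, 0]:.3f}")
diag = np.trace(gamma) - gamma[0, 0]
diag_true = np.trace(joint) - joint[0, 0]
print(f"shared (diagonal) mass:      true {diag_true:.3f}, est {diag:.3f}")
priv = gamma[1:, 0].sum() + gamma[0, 1:].sum()
priv_true = joint[1:, 0].sum() + joint[0, 1:].sum()
print(f"private (row/col 0) mass:    true {priv_true:.3f}, est {priv:.3f}")
print()
print("The EM attributes polymorphism to shared vs private classes "
      "directly from read data of both populations at 2X coverage.")
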