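"""ABBA-BABA test for gene flow with a weighted block jackknife.

Simulates a four-taxon dataset with a 20% excess of ABBA patterns
(introgression between H2 and H3) plus a null dataset, classifies the
sampled bases, and reports D with its jackknife standard error and Z score.
"""

from glpop.abbababa import (accumulate_blocks, classify_site,
                            dstat_jackknife)
from glpop.simulate import sim_quartet


def analyse(truth, label):
    classified = [
        (truth.chroms[s], int(truth.positions[s]),
         classify_site(truth.bases[s, 0], truth.bases[s, 1],
                       truth.bases[s, 2], truth.anc[s]))
        for s in range(len(truth.anc))]
    blocks = accumulate_blocks(classified, block_size=1_000_000)
    r = dstat_jackknife(blocks, labels=("H1", "H2", "H3"))
    print(f"{label:14s} nABBA={r.n_abba:6d} nBABA={r.n_baba:6d} "
          f"D={r.d:+.4f} jackEst={r.jack_est:+.4f} SE={r.se:.4f} "
          f"Z={r.z:+.2f}")
    return r


print("dataset        counts                     D and jackknife")
gene_flow = sim_quartet(100_000, p_abba=0.06, p_baba=0.04, seed=1)
null = sim_quartet(100_000, p_abba=0.05, p_baba=0.05, seed=2)
r1 = analyse(gene_flow, "introgression")
r0 = analyse(null, "null")
print()
print(f"expected D under introgression: {gene_flow.expected_d:+.2f}")
print("A |Z| above ~3 rejects the tree without gene flow; the null "
      "dataset stays within sampling noise while the introgressed one "
      "is rejected decisively.")
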