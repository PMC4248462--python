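# Methods

`glpop` implements the statistical core of genotype-likelihood analysis of
low-coverage sequencing data: rather than calling genotypes per individual
and analysing the calls, every estimator integrates over genotype
uncertainty through per-site genotype likelihoods (GLs). This note records
the models, the numerical choices, and what the built-in simulator does and
does not emulate.

## Genotype likelihoods

For individual k at one site, the GL of genotype G is the probability of
that individual's read bases given G, up to a constant:

    log L_k(A1 A2) = sum_reads log( 1/2 P(b | A1) + 1/2 P(b | A2) )

Two substitution models are provided for P(b | A):

* **quality-based** (`gl10_gatk`): P(b | A) = 1 − ε if b = A, else ε/3,
  with ε = 10^(−q/10) from the read's phred quality, capped at 0.75 (at
  ε = 3/4 a base is uninformative over a 4-letter alphabet, and larger
  values would make "error" more likely than any specific misread).
* **type-specific** (`gl10_type_specific`): P(b | A) = E[A→b] for a
  row-stochastic 4×4 error matrix E. With a symmetric E at rate ε the two
  models coincide, which the tests use as an equivalence oracle.

All ten unordered diploid genotypes are kept in fixed alphabetical-pair
order (AA, AC, …, TT). Likelihoods are natural-log scaled and defined up to
a per-individual additive constant; every downstream estimator is invariant
to that constant (property-tested). Diallelic analyses project the ten
values onto (major-hom, het, minor-hom) after major/minor inference, which
maximises the sum over individuals of log(¼L(a1a1) + ½L(a1a2) + ¼L(a2a2))
over the six allele pairs and orients the pair by expected allele count.

Only these two GL models are implemented. Recalibration-table models used
by other callers depend on calibration internals that are out of scope
here; the CLI rejects their selectors with an explicit message.

## Allele frequencies and SNP discovery

The population minor-allele frequency f at a diallelic site maximises

    L(f) = prod_i sum_g L_i(g) HWE(g; f),   HWE = ((1−f)², 2f(1−f), f²),

estimated by EM on the latent genotypes: with posterior weights
w_i(g) ∝ L_i(g) HWE(g; f), the update is f' = Σ_i E[g_i]/(2N'), where N'
counts individuals with data (individuals with flat GLs — no reads —
contribute nothing and are excluded from N'). Start f = 0.1, tolerance
1e-8 on |f'−f|, 200 iterations; the likelihood is unimodal for this model
so any interior start works. The EM likelihood is asserted non-decreasing
in tests.

SNP discovery is the likelihood-ratio test of f = 0 versus f free:
LRT = 2[ll(f̂) − ll(0)], with the p-value from χ²(1). The null sits on the
boundary of [0, 1], so χ²(1) is conservative; the ½χ²(0)+½χ²(1) mixture is
available behind `boundary_mixture=True`. A boundary MLE reached to EM
tolerance can leave the LRT a hair below zero; values above −1e-6 are
clamped to 0, anything lower raises.

Case/control association compares frequencies by
LRT = 2[ll_cases(f̂_ca) + ll_controls(f̂_co) − ll_pooled(f̂_po)] against
χ²(1); with certain genotypes it reduces to the classical allele-count
G-test (oracle-tested).

## Sample allele frequency likelihoods and the SFS

The SAF vector at a site is p(X | D = j), the probability of all read data
given j derived alleles among the 2n sampled chromosomes, for j = 0..2n.
With GLs polarised so genotype g counts derived alleles, the dynamic
programme over individuals is

    h_0 = [1];   h_k(j) = sum_g h_{k−1}(j−g) L_k(g) w(g),  w = (1, 2, 1)
    p(X | D = j) = h_n(j) / C(2n, j).

w(g) = C(2, g) counts the chromosome arrangements within one diploid, and
the C(2n, j) divisor converts the configuration sum into a conditional
probability given the sample count. Each h_k is renormalised by its maximum
so the recursion cannot underflow even for hundreds of individuals; the
returned log vector is max-normalised to 0. Both normalisations are legal
because every SFS quantity below is invariant to per-site scaling of the
SAF vector. For n ≤ 4 the recursion is verified against the exhaustive sum
over all 3^n genotype configurations.

The SFS γ (probability vector over 0..2n, or a (2n1+1)×(2n2+1) matrix for
two populations) maximises the finite-mixture likelihood

    L(γ) = prod_s sum_j γ_j p(X_s | D = j)          (1D)
    L(γ) = prod_s sum_ij γ_ij p1_s(i) p2_s(j)       (2D, aligned sites)

via the standard mixture-weight EM: γ'_j = (1/S) Σ_s γ_j p_s(j) / L_s(γ).
The update keeps γ on the simplex and provably does not decrease the
likelihood; the trace is asserted monotone in tests and reported by the
acceptance script. Initialisation is uniform (mixture-weight EM from a
uniform start has no label ambiguity); convergence is a relative
log-likelihood gain below 1e-8 or 500 iterations (2000 for the 2D runs,
whose crawl along flat directions is slower), both configurable.
Two-population site alignment is by exact (chrom, pos) intersection.

With degenerate certain data (indicator SAF vectors) both EMs return the
empirical histogram of derived counts after one step — a fixed point used
as a trivial correctness check.

## Genotype posteriors and calling

Three priors over (anc-hom, het, der-hom):

* **uniform**: posterior ∝ exp(GL3);
* **allele frequency**: posterior ∝ exp(GL3) · HWE(g; f̂);
* **SFS**: the individual is conditioned on everyone's reads,
  P(G_i = g | X, γ) ∝ L_i(g) w(g) Σ_j γ_j h^(−i)(j−g) / C(2n, j),
  where h^(−i) is the SAF recursion over the other n−1 individuals.
  Each leave-one-out vector is computed by its own recursion (O(n²) per
  site) rather than by dividing h_n, which is numerically unsafe; at desk
  scale the cost is irrelevant, and the batch implementation vectorises
  over sites. Verified against exhaustive enumeration at n = 3.

Calls take the argmax posterior and are set to missing below a score
cutoff (cutoff 0 disables missingness); exact ties break to the lower
genotype index for determinism.

## ABBA-BABA

One base is sampled uniformly per individual per site among reads passing
the quality filter — sampling rather than majority vote removes the bias
that unequal depths would otherwise introduce. Against an outgroup-derived
ancestral base, a site is ABBA (H1 ancestral, H2 = H3 derived), BABA
(H2 ancestral, H1 = H3 derived), or uninformative; sites with more than two
alleles among the four bases are dropped, and optionally all transition
patterns (A↔G, C↔T) — the standard guard against post-mortem deamination
in ancient DNA. D = (nABBA − nBABA)/(nABBA + nBABA).

Counts are pooled within genomic blocks (index floor((pos−1)/blockSize),
default 5 Mb) and the standard error comes from the weighted delete-one-
block jackknife with block weight m_b = nABBA_b + nBABA_b (the
unequal-block delete-m estimator of Busing et al. 1999): with h_b = n/m_b,

    jackEst = B·D − Σ_b (1 − m_b/n) D_(−b)
    SE² = (1/B) Σ_b (θ̃_b − jackEst)² / (h_b − 1),
    θ̃_b = h_b·D − (h_b − 1) D_(−b).

For equal-weight blocks this reduces exactly to the classical delete-1
jackknife (tested at 1e-12). Z is reported as D/SE rather than jackEst/SE;
the two are numerically indistinguishable in practice and the choice is
recorded here for definiteness. The all-triples driver emits every ordered
(H1, H2, H3) of distinct individuals (M(M−1)(M−2) rows), or half that with
`reduced=True`, which drops the sign-redundant (H2, H1, H3) partner.

## Error-rate estimation

All three estimators consume one sampled base per site per individual, the
same depth-bias-free sampling as the D-statistic.

1. **Mismatch matrix**: counts of (outgroup base a, observed base b); its
   row-normalised rates conflate sequencing error with true divergence.
2. **Calibrated**: the high-quality individual's mismatch rates P against
   the same outgroup estimate the true divergence; the focal sample's
   counts are modelled row-wise as multinomial with probabilities (P·E)
   (divergence first, then error — first order, no back mutation, adequate
   at percent-scale rates) and E is the maximum-likelihood row-stochastic
   matrix. E is parametrised per row by softmax logits with the diagonal
   pinned at 0 and off-diagonals bounded ≤ 0, which enforces both row
   stochasticity and diagonal dominance exactly; L-BFGS-B, ftol 1e-10.
   Outgroup rows never observed in the sample are unidentifiable and
   returned as identity rows.
3. **Joint EM**: on polymorphic sites with known major/minor alleles,
   genotypes and true bases are latent; E-step computes genotype
   posteriors under HWE at current frequencies and splits heterozygote
   reads between the two alleles in proportion to E; M-step row-normalises
   expected true→observed counts and re-estimates frequencies with the
   warm-started frequency EM. The observed-data likelihood must be
   evaluated without per-individual GL normalisation (the scale depends on
   E); it is asserted non-decreasing. When the optimum lies on the simplex
   boundary (error-free data) EM approaches but never reaches it, so
   identity recovery is tested to 5e-3 rather than machine precision.

## Simulator

`sim_onepop` draws per-site derived counts from a configured SFS (default:
neutral 1/j spectrum for j = 1..2n−1 plus an invariant-site mass, default
0.5 at desk scale), places them on chromosomes by random permutation
("count" mode, the default — the realised sample spectrum is then exactly
the configured one, the right ground truth for SFS recovery) or by
binomial HWE sampling at f = j/2n ("hwe" mode), draws per-individual
depths Poisson(λ), samples one of the individual's two alleles per read
and flips it to a uniformly chosen other base with probability ε. Default
λ = 2 and ε = 0.002 — the low-coverage regime the estimators are designed
for and benchmarked in. Emitted phred is the constant round(−10 log10 ε).

`sim_twopop` draws aligned derived-count pairs from a joint spectrum. Two
canonical spectra are provided: `product_joint_sfs` (independent
populations) and `correlated_joint_sfs` (invariant mass 0.5, shared 1/k
mass 0.3 on the diagonal, private 1/k mass 0.2 on the first row/column —
a stylised pair of recently diverged populations). `sim_quartet` emits
four-taxon site patterns that are ABBA/BABA with configured probabilities,
with expected D = (p_ABBA − p_BABA)/(p_ABBA + p_BABA).

The error model matches the GL models' assumption by construction, so
recovery tests isolate estimator error from model misspecification. The
simulator does **not** emulate linkage or recombination (sites are
independent), realistic quality-score distributions (a single constant
phred), mapping error, indels, or ancestral misidentification. Passing
recovery tests therefore demonstrate correctness of the estimators under
their own model, not robustness to real-data artefacts. All randomness
flows from a single seeded generator; output is byte-identical across
runs.

## Benchmark conditions and what the checks show

The recovery and calibration figures (tests and `scripts/acceptance.py`)
use: 10 diploids × 5·10⁴ sites at 2X / ε = 0.2% for 1D SFS recovery
(total-variation error < 0.05); two populations of 6 diploids at the same
scale under the correlated spectrum for 2D recovery (joint TV < 0.08 —
note the joint 13×13 spectrum is only weakly identified at 2X for diffuse
spectra, where TV of the ML estimate itself approaches ~0.1; marginals
remain accurate, and the product-spectrum test checks marginals instead);
10⁴ monomorphic 20-individual sites for the SNP LRT null (rejection at
p < 0.05 stays below 0.06, conservative by boundary); 200 null quartets of
5000 sites in 50 blocks for jackknife calibration (|Z| < 3 in ≥ 95%).
These sizes were chosen as the smallest at which the statistical claims
are comfortably resolved.

## Known limitations

* Text mpileup only; no per-read mapping qualities in that dialect, so the
  `min_mapQ` argument is accepted but inert (documented in io_formats).
* The folded SFS, ancestral-misidentification corrections, >2-population
  spectra, θ/neutrality statistics and Fst are out of scope.
* The case/control LRT handles allele-frequency differences only (no
  covariates).
* `calibrated_error` assumes divergence and error are both small; the
  composition model is first order.
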