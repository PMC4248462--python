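"""Simulator for low-coverage diploid sequencing data.

Generates per-site genotypes under a configured site-frequency spectrum,
per-individual read depths from a Poisson law and read bases subject to a
symmetric substitution error (each wrong base with probability eps/3 — the
same substitution model the likelihood machinery assumes, so recovery tests
isolate estimator error from model misspecification). Defaults mirror the
conditions of the simulation studies the estimators are validated under:
mean depth 2X and a base error rate of 0.2%.

Genotype assignment: by default the drawn derived-allele count j is placed
on the 2n chromosomes by random permutation ("count" mode), so the realised
sample spectrum is exactly the configured one — the right truth for SFS
recovery. "hwe" mode instead draws genotypes binomially at frequency
f = j / 2n, the classical Hardy-Weinberg sampling.

All randomness flows from one numpy Generator seeded in the config; output
is byte-identical across runs with the same seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator, Optional

import numpy as np

from glpop.io_formats import PileupSite


def neutral_sfs(n_chromosomes: int, invariant_mass: float = 0.5) -> np.ndarray:
    """Neutral unfolded SFS over 0..n derived alleles.

    Variable classes j = 1..n-1 get mass proportional to 1/j (the standard
    neutral expectation); ``invariant_mass`` sits at j = 0 and the
    fixed-derived class j = n gets none.
    """
    if not 0 <= invariant_mass < 1:
        raise ValueError("invariant_mass must be in [0, 1)")
    gamma = np.zeros(n_chromosomes + 1)
    j = np.arange(1, n_chromosomes)
    gamma[1:n_chromosomes] = 1.0 / j
    gamma[1:n_chromosomes] *= (1.0 - invariant_mass) / gamma[1:].sum()
    gamma[0] = invariant_mass
    return gamma


def product_joint_sfs(sfs1: np.ndarray, sfs2: np.ndarray) -> np.ndarray:
    """Joint SFS of two independent populations: the outer product."""
    return np.outer(sfs1, sfs2)


def correlated_joint_sfs(n1: int, n2: int, invariant_mass: float = 0.5,
                         shared_mass: float = 0.3,
                         private_mass: float = 0.2) -> np.ndarray:
    """Two-population spectrum with shared and private polymorphism.

    Emulates a pair of recently diverged populations: a fraction of sites is
    invariant in both, shared polymorphism sits on the diagonal (equal
    derived counts, mass proportional to 1/k — strong frequency correlation
    through common ancestry), and private polymorphism on the first row and
    column (variable in only one population, again 1/k). The three masses
    must sum to 1.
    """
    if not math.isclose(invariant_mass + shared_mass + private_mass, 1.0,
                        abs_tol=1e-9):
        raise ValueError("masses must sum to 1")
    K1, K2 = 2 * n1 + 1, 2 * n2 + 1
    g = np.zeros((K1, K2))
    g[0, 0] = invariant_mass
    k = np.arange(1, min(K1, K2) - 1)
    w = 1.0 / k
    g[k, k] += shared_mass * w / w.sum()
    k1 = np.arange(1, K1 - 1)
    w1 = 1.0 / k1
    g[k1, 0] += private_mass / 2 * w1 / w1.sum()
    k2 = np.arange(1, K2 - 1)
    w2 = 1.0 / k2
    g[0, k2] += private_mass / 2 * w2 / w2.sum()
    return g / g.sum()


@dataclass
class SimConfig:
    """Conditions for one simulated dataset.

    ``mean_depth`` and ``error_rate`` default to the 2X / 0.2% regime the
    estimators are benchmarked in; the emitted constant phred quality is
    round(-10 log10(error_rate)).
    """

    n_individuals: int = 10
    n_sites: int = 10_000
    mean_depth: float = 2.0
    error_rate: float = 0.002
    seed: int = 0
    sfs: Optional[np.ndarray] = None          # over 0..2n derived alleles
    invariant_mass: float = 0.5
    genotype_mode: str = "count"              # "count" or "hwe"
    chrom: str = "chrSim"

    def __post_init__(self) -> None:
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")
        if not 0 <= self.error_rate < 0.75:
            raise ValueError("error_rate must be in [0, 0.75)")
        if self.genotype_mode not in ("count", "hwe"):
            raise ValueError("genotype_mode must be 'count' or 'hwe'")

    @property
    def phred(self) -> int:
        if self.error_rate == 0:
            return 93  # maximal encodable quality
        return round(-10.0 * math.log10(self.error_rate))

    def resolved_sfs(self) -> np.ndarray:
        if self.sfs is not None:
            gamma = np.asarray(self.sfs, dtype=float)
            if gamma.shape != (2 * self.n_individuals + 1,):
                raise ValueError("sfs must have length 2n + 1")
            if np.any(gamma < 0) or not math.isclose(gamma.sum(), 1.0,
                                                     abs_tol=1e-9):
                raise ValueError("sfs must be a probability vector")
            return gamma
        return neutral_sfs(2 * self.n_individuals, self.invariant_mass)


@dataclass
class SimTruth:
    """Ground truth accompanying a simulated dataset."""

    genotypes: np.ndarray        # (S, N) derived-allele copies 0/1/2
    derived_counts: np.ndarray   # (S,) sum over individuals
    frequencies: np.ndarray      # (S,) derived_counts / 2N
    alleles: np.ndarray          # (S, 2) ancestral and derived base index
    positions: np.ndarray        # (S,) 1-based
    counts: np.ndarray           # (S, N, 4) read base counts per individual


def _genotypes_from_counts(derived: np.ndarray, n: int, mode: str,
                           rng: np.random.Generator) -> np.ndarray:
    """Place per-site derived counts onto n diploids; (S, N) genotypes."""
    S = derived.shape[0]
    if mode == "hwe":
        f = derived / (2.0 * n)
        return rng.binomial(2, f[:, None], size=(S, n))
    geno = np.zeros((S, n), dtype=np.int64)
    chroms = np.arange(2 * n)
    for s in range(S):
        j = derived[s]
        if j == 0:
            continue
        carriers = rng.permutation(chroms)[:j]
        np.add.at(geno[s], carriers // 2, 1)
    return geno


def _reads_from_genotypes(geno: np.ndarray, alleles: np.ndarray,
                          cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Read base counts (S, N, 4): Poisson depth, allele sampling, errors."""
    S, N = geno.shape
    depth = rng.poisson(cfg.mean_depth, size=(S, N))
    counts = np.zeros((S, N, 4), dtype=np.int64)
    # derived-allele copies drawn per read: Binomial(depth, geno/2)
    n_der_reads = rng.binomial(depth, geno / 2.0)
    n_anc_reads = depth - n_der_reads
    for true_col, n_reads in ((0, n_anc_reads), (1, n_der_reads)):
        true_base = alleles[:, true_col][:, None]         # (S, 1)
        errs = rng.binomial(n_reads, cfg.error_rate)
        correct = n_reads - errs
        np.add.at(counts, (np.arange(S)[:, None], np.arange(N)[None, :],
                           np.broadcast_to(true_base, (S, N))), correct)
        if cfg.error_rate > 0:
            # distribute errors uniformly over the three other bases
            for s, i in zip(*np.nonzero(errs)):
                others = [b for b in range(4) if b != true_base[s, 0]]
                picks = rng.integers(0, 3, size=errs[s, i])
                for p in picks:
                    counts[s, i, others[p]] += 1
    return counts


def _draw_site_alleles(S: int, rng: np.random.Generator) -> np.ndarray:
    """Ancestral and derived base indices per site, distinct, uniform."""
    anc = rng.integers(0, 4, size=S)
    shift = rng.integers(1, 4, size=S)
    der = (anc + shift) % 4
    return np.stack([anc, der], axis=1)


def sim_onepop(cfg: SimConfig) -> SimTruth:
    """Simulate one population; returns truth with read counts included."""
    rng = np.random.default_rng(cfg.seed)
    gamma = cfg.resolved_sfs()
    S, N = cfg.n_sites, cfg.n_individuals
    derived = rng.choice(len(gamma), size=S, p=gamma)
    geno = _genotypes_from_counts(derived, N, cfg.genotype_mode, rng)
    alleles = _draw_site_alleles(S, rng)
    counts = _reads_from_genotypes(geno, alleles, cfg, rng)
    return SimTruth(genotypes=geno, derived_counts=geno.sum(axis=1),
                    frequencies=geno.sum(axis=1) / (2.0 * N),
                    alleles=alleles, positions=np.arange(1, S + 1),
                    counts=counts)


def sim_twopop(cfg1: SimConfig, cfg2: SimConfig,
               joint_sfs: np.ndarray, seed: Optional[int] = None
               ) -> tuple[SimTruth, SimTruth]:
    """Simulate two populations with aligned sites from a joint SFS.

    ``joint_sfs`` is (2n1+1) x (2n2+1); per site a derived-count pair (i, j)
    is drawn from it and placed within each population independently.
    Site lists (positions, site alleles) are identical across populations.
    """
    joint = np.asarray(joint_sfs, dtype=float)
    n1, n2 = cfg1.n_individuals, cfg2.n_individuals
    if joint.shape != (2 * n1 + 1, 2 * n2 + 1):
        raise ValueError("joint_sfs shape does not match the sample sizes")
    if cfg1.n_sites != cfg2.n_sites:
        raise ValueError("both configs must specify the same n_sites")
    rng = np.random.default_rng(cfg1.seed if seed is None else seed)
    S = cfg1.n_sites
    flat = rng.choice(joint.size, size=S, p=joint.ravel() / joint.sum())
    i_cnt, j_cnt = np.unravel_index(flat, joint.shape)
    alleles = _draw_site_alleles(S, rng)
    positions = np.arange(1, S + 1)
    truths = []
    for cfg, derived, n in ((cfg1, i_cnt, n1), (cfg2, j_cnt, n2)):
        geno = _genotypes_from_counts(np.asarray(derived), n,
                                      cfg.genotype_mode, rng)
        counts = _reads_from_genotypes(geno, alleles, cfg, rng)
        truths.append(SimTruth(
            genotypes=geno, derived_counts=geno.sum(axis=1),
            frequencies=geno.sum(axis=1) / (2.0 * n),
            alleles=alleles, positions=positions, counts=counts))
    return truths[0], truths[1]


@dataclass
class QuartetTruth:
    """Four-taxon sampled-base data with the generating pattern rates."""

    bases: np.ndarray        # (S, 3) bases for H1, H2, H3
    anc: np.ndarray          # (S,) outgroup/ancestral base
    chroms: list
    positions: np.ndarray
    expected_d: float
    p_abba: float
    p_baba: float


def sim_quartet(n_sites: int, p_abba: float, p_baba: float, seed: int = 0,
                chrom: str = "chrSim", spacing: int = 1000) -> QuartetTruth:
    """Four-taxon site patterns for the D-statistic.

    Each site is ABBA with probability ``p_abba``, BABA with ``p_baba`` and
    otherwise concordant (all three ingroup taxa derived — informative for
    nothing). Expected D = (p_abba - p_baba) / (p_abba + p_baba). Sites are
    laid out ``spacing`` bp apart so block partitioning is exercised.
    """
    if p_abba < 0 or p_baba < 0 or p_abba + p_baba > 1:
        raise ValueError("pattern probabilities must be a sub-probability pair")
    rng = np.random.default_rng(seed)
    S = n_sites
    anc_idx, der_idx = _draw_site_alleles(S, rng).T
    bases_str = np.array(list("ACGT"))
    anc = bases_str[anc_idx]
    der = bases_str[der_idx]
    u = rng.random(S)
    bases = np.empty((S, 3), dtype=object)
    abba = u < p_abba
    baba = (u >= p_abba) & (u < p_abba + p_baba)
    conc = ~(abba | baba)
    bases[abba, 0], bases[abba, 1], bases[abba, 2] = anc[abba], der[abba], der[abba]
    bases[baba, 0], bases[baba, 1], bases[baba, 2] = der[baba], anc[baba], der[baba]
    bases[conc, 0] = der[conc]
    bases[conc, 1] = der[conc]
    bases[conc, 2] = der[conc]
    total = p_abba + p_baba
    expected_d = (p_abba - p_baba) / total if total > 0 else 0.0
    positions = np.arange(1, S + 1) * spacing
    return QuartetTruth(bases=bases, anc=anc, chroms=[chrom] * S,
                        positions=positions, expected_d=expected_d,
                        p_abba=p_abba, p_baba=p_baba)


def pileup_sites(truth: SimTruth, cfg: SimConfig) -> Iterator[PileupSite]:
    """Materialise a SimTruth as PileupSite records (constant phred quality).

    The reference base is taken to be the ancestral allele, so '.' in the
    written mpileup denotes an ancestral read.
    """
    bases = "ACGT"
    q = cfg.phred
    for s in range(truth.counts.shape[0]):
        ref = bases[truth.alleles[s, 0]]
        reads = []
        for i in range(truth.counts.shape[1]):
            ind = []
            for b in range(4):
                ind.extend([(bases[b], q)] * int(truth.counts[s, i, b]))
            reads.append(ind)
        yield PileupSite(chrom=cfg.chrom, pos=int(truth.positions[s]),
                         ref_base=ref, anc_base=ref, reads=reads)
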