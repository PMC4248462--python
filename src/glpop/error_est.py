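"""Type-specific base-error-rate estimation.

Three routes, all consuming one sampled base per site per individual (the
same depth-bias-free sampling used by the D-statistic):

1. raw mismatch rates against an ancestral/outgroup sequence — an upper
   bound that conflates true divergence with sequencing error;
2. calibration against a high-quality individual: the high-quality sample's
   outgroup mismatches estimate the true divergence P, and the error matrix
   E of a focal sample is fit by maximum likelihood under the composition
   P @ E of divergence followed by error (first order, no back mutation);
3. joint EM over error matrix and per-site allele frequencies on
   polymorphic sites, treating genotypes and true bases as latent.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import optimize

from glpop.gl_models import BASE_INDEX, BASES, ErrorMatrix


@dataclass
class MismatchMatrix:
    """4x4 counts of (reference/ancestral base a, observed base b)."""

    counts: np.ndarray

    @property
    def rates(self) -> np.ndarray:
        """Row-normalised rates; all-zero rows stay zero."""
        totals = self.counts.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.where(totals > 0, self.counts / totals, 0.0)
        return r


def mismatch_matrix(observed: Sequence[Optional[str]],
                    anc: Sequence[Optional[str]]) -> MismatchMatrix:
    """Tabulate observed-vs-ancestral base counts over sites with both present."""
    counts = np.zeros((4, 4))
    for b, a in zip(observed, anc):
        if b in BASE_INDEX and a in BASE_INDEX:
            counts[BASE_INDEX[a], BASE_INDEX[b]] += 1
    return MismatchMatrix(counts=counts)


def _row_stochastic_from_logits(logits: np.ndarray) -> np.ndarray:
    """Map 12 off-diagonal logits (<= 0) to a diagonally dominant matrix."""
    m = np.zeros((4, 4))
    off = iter(logits)
    for a in range(4):
        row = np.zeros(4)
        for b in range(4):
            row[b] = 0.0 if a == b else next(off)
        e = np.exp(row - row.max())
        m[a] = e / e.sum()
    return m


def calibrated_error(sample_matrix: MismatchMatrix,
                     perfect_matrix: MismatchMatrix,
                     tol: float = 1e-10) -> ErrorMatrix:
    """Error matrix of a sample, calibrated by a high-quality individual.

    The high-quality individual's outgroup mismatch rates P are taken as the
    true divergence; the sample's counts C are modelled row-wise as
    multinomial with probabilities (P @ E), and E is the maximum-likelihood
    row-stochastic, diagonally dominant matrix (off-diagonal logits bounded
    at 0 so no off-diagonal entry can exceed its diagonal). Rows of the
    outgroup with no sample counts are unidentifiable and returned as
    identity.
    """
    counts = np.asarray(sample_matrix.counts, dtype=float)
    P = perfect_matrix.rates
    if np.all(P == 0):
        raise ValueError("perfect individual's mismatch matrix is empty")

    def negloglik(logits: np.ndarray) -> float:
        E = _row_stochastic_from_logits(logits)
        probs = P @ E
        with np.errstate(divide="ignore"):
            lp = np.log(np.clip(probs, 1e-300, None))
        return -float((counts * lp).sum())

    x0 = np.full(12, -6.0)  # start near identity (errors ~ exp(-6))
    res = optimize.minimize(negloglik, x0, method="L-BFGS-B",
                            bounds=[(-30.0, 0.0)] * 12,
                            options={"ftol": tol, "gtol": 1e-10, "maxiter": 2000})
    E = _row_stochastic_from_logits(res.x)
    row_seen = counts.sum(axis=1) > 0
    for a in range(4):
        if not row_seen[a]:
            E[a] = np.eye(4)[a]
    return ErrorMatrix(E)


def _type_specific_gl3(base_idx: np.ndarray, alleles: np.ndarray,
                       E: np.ndarray) -> np.ndarray:
    """Log GL3 per site/individual from one sampled base each.

    ``base_idx`` (S, N) with -1 for missing; ``alleles`` (S, 2) major/minor
    base indices. Missing individuals get flat (zero) log-likelihoods.
    """
    S, N = base_idx.shape
    a1 = alleles[:, 0][:, None]                      # (S, 1)
    a2 = alleles[:, 1][:, None]
    safe = np.clip(base_idx, 0, 3)
    p1 = E[a1, safe]                                 # (S, N) P(b | a1)
    p2 = E[a2, safe]
    lik = np.stack([p1, 0.5 * p1 + 0.5 * p2, p2], axis=-1)  # (S, N, 3)
    lik = np.clip(lik, 1e-300, None)
    gl = np.log(lik)
    gl[base_idx < 0] = 0.0
    return gl


def joint_error_freq_em(base_idx: np.ndarray, alleles: np.ndarray,
                        tol: float = 1e-6, max_iter: int = 100,
                        inner_maf_iter: int = 50, return_trace: bool = False):
    """Jointly estimate the error matrix and per-site minor-allele frequencies.

    ``base_idx`` is an (S, N) array of sampled-base indices (-1 = missing)
    at diallelic sites with known ``alleles`` (S, 2; major and minor base
    index). Genotypes and each read's true base are latent: the E step
    computes genotype posteriors under HWE at the current frequencies and
    splits each observed base between the two possible true alleles; the M
    step row-normalises the expected true->observed counts into a new error
    matrix and re-estimates the frequencies by EM. The observed-data
    log-likelihood is non-decreasing; iteration stops at relative gain
    ``tol``. Returns (ErrorMatrix, frequencies[, loglik trace]).
    """
    from glpop.allele_freq import maf_em_batch

    base_idx = np.asarray(base_idx, dtype=np.intp)
    alleles = np.asarray(alleles, dtype=np.intp)
    S, N = base_idx.shape
    E = ErrorMatrix.symmetric(0.01).rates
    freqs = np.full(S, 0.1)
    present = base_idx >= 0
    trace = []
    prev = -np.inf
    for _ in range(max_iter):
        gl3 = _type_specific_gl3(base_idx, alleles, E)
        # frequency update: warm-started inner EM given E (keeps the outer
        # coordinate ascent monotone)
        freqs = maf_em_batch(gl3, max_iter=inner_maf_iter, f0=freqs)
        freqs = np.nan_to_num(freqs, nan=0.0)
        # observed-data loglik; gl3 must stay unnormalised here because the
        # per-individual scale depends on E
        hwe = np.stack([(1 - freqs) ** 2, 2 * freqs * (1 - freqs),
                        freqs ** 2], axis=-1)
        per_ind = np.log(np.clip((np.exp(gl3) * hwe[:, None, :]).sum(-1),
                                 1e-300, None))
        ll = float(np.where(present, per_ind, 0.0).sum())
        trace.append(ll)
        if np.isfinite(prev) and ll - prev < tol * max(abs(ll), 1.0):
            break
        prev = ll
        # genotype posteriors under HWE(freqs)
        prior = np.stack([(1 - freqs) ** 2, 2 * freqs * (1 - freqs),
                          freqs ** 2], axis=-1)          # (S, 3)
        lik = np.exp(gl3)
        w = lik * prior[:, None, :]
        w /= np.clip(w.sum(axis=-1, keepdims=True), 1e-300, None)
        a1, a2 = alleles[:, 0][:, None], alleles[:, 1][:, None]
        safe = np.clip(base_idx, 0, 3)
        p1, p2 = E[a1, safe], E[a2, safe]
        # het reads split between true alleles in proportion to E[a -> b]
        frac1 = p1 / np.clip(p1 + p2, 1e-300, None)
        expected = np.zeros((4, 4))
        w_hom1 = np.where(present, w[..., 0], 0.0)
        w_het = np.where(present, w[..., 1], 0.0)
        w_hom2 = np.where(present, w[..., 2], 0.0)
        np.add.at(expected, (np.broadcast_to(a1, safe.shape), safe),
                  w_hom1 + w_het * frac1)
        np.add.at(expected, (np.broadcast_to(a2, safe.shape), safe),
                  w_hom2 + w_het * (1.0 - frac1))
        totals = expected.sum(axis=1, keepdims=True)
        E_new = np.where(totals > 0, expected / np.clip(totals, 1e-300, None),
                         np.eye(4))
        E = E_new
    em = _to_error_matrix(E)
    if return_trace:
        return em, freqs, np.array(trace)
    return em, freqs


def _to_error_matrix(E: np.ndarray) -> ErrorMatrix:
    """Coerce an estimated matrix into the ErrorMatrix contract.

    Numerical noise can leave a row marginally non-dominant; project by
    capping off-diagonals at the diagonal and renormalising.
    """
    E = np.clip(np.asarray(E, dtype=float), 0.0, 1.0)
    for a in range(4):
        cap = E[a, a]
        for b in range(4):
            if b != a and E[a, b] > cap:
                E[a, b] = cap
        E[a] /= E[a].sum()
    return ErrorMatrix(E)
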