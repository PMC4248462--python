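"""Sample-allele-frequency likelihoods and site-frequency-spectrum EM.

The SAF likelihood at a site is p(all read data | D = j derived alleles in
the sample), j = 0..2n, computed by a dynamic programme over individuals:

    h_0 = [1];  h_k(j) = sum_{g in 0,1,2} h_{k-1}(j - g) L_k(g) w(g)

with genotype multiplicities w = (1, 2, 1) = C(2, g), and finally
p(X | D = j) = h_n(j) / C(2n, j). Each h_k is renormalised by its maximum so
the recursion never underflows, and the returned log vector is normalised to
max 0 — legal because every SFS quantity is invariant to per-site scaling.

Given SAF vectors for many sites, the SFS gamma (a probability vector over
derived-allele counts, or a matrix for two populations) is the maximiser of

    L(gamma) = prod_s sum_j gamma_j p(X_s | D = j)

(a finite mixture), estimated with the standard mixture-weight EM whose
log-likelihood is non-decreasing at every iteration.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
from scipy.special import gammaln

_W = np.array([1.0, 2.0, 1.0])  # C(2, g): orderings of g derived alleles


def _log_binom(n: int) -> np.ndarray:
    """log C(n, j) for j = 0..n."""
    j = np.arange(n + 1)
    return gammaln(n + 1) - gammaln(j + 1) - gammaln(n - j + 1)


def saf_batch(gl3: np.ndarray) -> np.ndarray:
    """SAF log-likelihood vectors for a batch of sites.

    ``gl3`` is (S, N, 3): per-site, per-individual log genotype likelihoods
    polarised so genotype g counts derived alleles (anc-hom, het, der-hom).
    Returns (S, 2N + 1) log p(X | D = j), max-normalised to 0 per site.
    """
    gl3 = np.asarray(gl3, dtype=float)
    if gl3.ndim != 3 or gl3.shape[2] != 3:
        raise ValueError("expected a (S, N, 3) array")
    S, N, _ = gl3.shape
    if N == 0:
        raise ValueError("need at least one individual")
    lik = np.exp(gl3 - gl3.max(axis=2, keepdims=True)) * _W  # (S, N, 3)
    h = np.ones((S, 1))
    for k in range(N):
        new = np.zeros((S, 2 * k + 3))
        for g in range(3):
            new[:, g:g + 2 * k + 1] += h * lik[:, k, g][:, None]
        # renormalise to dodge underflow; constants cancel downstream
        new /= new.max(axis=1, keepdims=True)
        h = new
    with np.errstate(divide="ignore"):
        logp = np.log(h) - _log_binom(2 * N)[None, :]
    return logp - logp.max(axis=1, keepdims=True)


def saf_site(gl3s: np.ndarray) -> np.ndarray:
    """SAF log-likelihood vector (length 2n + 1) for one site; see saf_batch."""
    gl3 = np.asarray(gl3s, dtype=float)
    if gl3.ndim != 2 or gl3.shape[1] != 3:
        raise ValueError("expected an (N, 3) array of polarised GL3s")
    return saf_batch(gl3[None])[0]


def loglik_sfs_1d(safs: np.ndarray, gamma: np.ndarray) -> float:
    """Log-likelihood of an SFS given per-site SAF log vectors (S, 2n+1).

    Computed up to the per-site normalisation constants dropped by saf_site.
    """
    safs = np.asarray(safs, dtype=float)
    gamma = np.asarray(gamma, dtype=float)
    mix = np.exp(safs) @ gamma
    return float(np.log(mix).sum())


def sfs_em_1d(safs: np.ndarray, tol: float = 1e-8, max_iter: int = 500,
              return_trace: bool = False):
    """Maximum-likelihood 1D SFS by EM from SAF vectors.

    ``tol`` is the relative log-likelihood gain at which iteration stops.
    Returns the probability vector gamma (and the per-iteration log-likelihood
    trace when ``return_trace``).
    """
    safs = np.asarray(safs, dtype=float)
    if safs.ndim != 2 or safs.shape[0] == 0:
        raise ValueError("need a non-empty (S, 2n+1) SAF array")
    S, K = safs.shape
    p = np.exp(safs)
    gamma = np.full(K, 1.0 / K)
    trace = []
    prev = -np.inf
    for _ in range(max_iter):
        mix = p @ gamma                       # (S,)
        ll = float(np.log(mix).sum())
        trace.append(ll)
        if ll - prev < tol * max(abs(ll), 1.0) and np.isfinite(prev):
            break
        prev = ll
        post = p * gamma[None, :] / mix[:, None]
        gamma = post.mean(axis=0)
    gamma /= gamma.sum()
    if return_trace:
        return gamma, np.array(trace)
    return gamma


def loglik_sfs_2d(safs1: np.ndarray, safs2: np.ndarray,
                  gamma: np.ndarray) -> float:
    """Joint log-likelihood sum_s log sum_ij gamma_ij p1_s(i) p2_s(j).

    Sites must be aligned: row s of both arrays is the same (chrom, pos).
    """
    p1, p2 = np.exp(np.asarray(safs1)), np.exp(np.asarray(safs2))
    if p1.shape[0] != p2.shape[0]:
        raise ValueError("SAF arrays are not site-aligned")
    mix = np.einsum("si,ij,sj->s", p1, np.asarray(gamma, dtype=float), p2)
    return float(np.log(mix).sum())


def sfs_em_2d(safs1: np.ndarray, safs2: np.ndarray, tol: float = 1e-8,
              max_iter: int = 500, return_trace: bool = False):
    """Maximum-likelihood joint 2D SFS by EM.

    gamma is a (2n1+1) x (2n2+1) probability matrix; the update is the
    mixture-weight EM

        gamma_ij' = (1/S) sum_s gamma_ij p1_s(i) p2_s(j) / L(X_s | gamma)

    whose log-likelihood is non-decreasing every iteration.
    """
    safs1 = np.asarray(safs1, dtype=float)
    safs2 = np.asarray(safs2, dtype=float)
    if safs1.shape[0] != safs2.shape[0]:
        raise ValueError("SAF arrays are not site-aligned")
    S = safs1.shape[0]
    if S == 0:
        raise ValueError("zero aligned sites")
    p1, p2 = np.exp(safs1), np.exp(safs2)
    K1, K2 = p1.shape[1], p2.shape[1]
    gamma = np.full((K1, K2), 1.0 / (K1 * K2))
    trace = []
    prev = -np.inf
    for _ in range(max_iter):
        mix = np.einsum("si,ij,sj->s", p1, gamma, p2)
        ll = float(np.log(mix).sum())
        trace.append(ll)
        if ll - prev < tol * max(abs(ll), 1.0) and np.isfinite(prev):
            break
        prev = ll
        gamma = gamma * np.einsum("si,sj,s->ij", p1, p2, 1.0 / mix) / S
        gamma /= gamma.sum()
    gamma /= gamma.sum()
    if return_trace:
        return gamma, np.array(trace)
    return gamma


def align_sites(sites1: list[tuple[str, int]], safs1: np.ndarray,
                sites2: list[tuple[str, int]], safs2: np.ndarray
                ) -> tuple[np.ndarray, np.ndarray, list[tuple[str, int]]]:
    """Intersect two SAF site lists on exact (chrom, pos) and align rows."""
    index2 = {key: i for i, key in enumerate(sites2)}
    keep1, keep2, keys = [], [], []
    for i, key in enumerate(sites1):
        j = index2.get(key)
        if j is not None:
            keep1.append(i)
            keep2.append(j)
            keys.append(key)
    if not keys:
        raise ValueError("the two SAF inputs share no (chrom, pos) sites")
    return np.asarray(safs1)[keep1], np.asarray(safs2)[keep2], keys
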