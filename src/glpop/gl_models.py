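"""Genotype likelihoods from observed bases and base qualities.

Two models are provided: the classical independent-reads model in which each
read's error probability comes from its phred quality (symmetric across the
three alternative bases), and a type-specific model in which substitution
probabilities come from a 4x4 error matrix. Likelihoods are natural-log
scaled and defined only up to a per-individual additive constant; every
downstream estimator in this package is invariant to that constant.

The ten unordered diploid genotypes are fixed in alphabetical-pair order
AA, AC, AG, AT, CC, CG, CT, GG, GT, TT across the whole package.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

#: the 10 unordered genotypes as (allele1, allele2) index pairs, a1 <= a2
GENOTYPE_PAIRS: tuple[tuple[int, int], ...] = tuple(
    (a, b) for a in range(4) for b in range(a, 4))
GENOTYPE_NAMES = tuple(BASES[a] + BASES[b] for a, b in GENOTYPE_PAIRS)

#: epsilon above which a base carries no information over 4 symbols
MAX_ERROR = 0.75


class ErrorMatrix:
    """Row-stochastic 4x4 matrix of P(read base b | true base a).

    Rows index the true base, columns the observed base, both in ACGT order.
    """

    def __init__(self, rates: np.ndarray):
        rates = np.asarray(rates, dtype=float)
        if rates.shape != (4, 4):
            raise ValueError("error matrix must be 4x4")
        if np.any(rates < 0) or np.any(rates > 1):
            raise ValueError("error-matrix entries must lie in [0, 1]")
        row_sums = rates.sum(axis=1)
        if not np.allclose(row_sums, 1.0, atol=1e-8):
            raise ValueError(f"error-matrix rows must sum to 1, got {row_sums}")
        if np.any(rates.max(axis=1) > rates.diagonal() + 1e-12):
            raise ValueError("error-matrix diagonal must dominate each row")
        self.rates = rates

    @classmethod
    def symmetric(cls, eps: float) -> "ErrorMatrix":
        """Uniform substitution model: each wrong base with probability eps/3."""
        m = np.full((4, 4), eps / 3.0)
        np.fill_diagonal(m, 1.0 - eps)
        return cls(m)

    @classmethod
    def identity(cls) -> "ErrorMatrix":
        return cls(np.eye(4))

    def __repr__(self) -> str:
        return f"ErrorMatrix({self.rates!r})"


def phred_to_error(q: float) -> float:
    """Convert a phred quality to an error probability, capped at 0.75."""
    return min(10.0 ** (-q / 10.0), MAX_ERROR)


def _reads_to_arrays(reads: Sequence[tuple[str, float]]) -> tuple[np.ndarray, np.ndarray]:
    idx = np.array([BASE_INDEX[b] for b, _ in reads], dtype=np.intp)
    eps = np.array([phred_to_error(q) for _, q in reads], dtype=float)
    return idx, eps


def gl10_gatk(reads: Sequence[tuple[str, float]]) -> np.ndarray:
    """Log-likelihoods of the 10 genotypes under the independent-reads model.

    For a read with base b and error probability eps,
    P(b | true allele A) = 1 - eps if b == A else eps / 3, and the diploid
    contribution is the even mixture over the genotype's two alleles.
    Empty input returns an all-zero (uninformative) vector.
    """
    if not reads:
        return np.zeros(10)
    idx, eps = _reads_to_arrays(reads)
    # p_allele[r, a] = P(read r's base | true base a)
    p_allele = np.where(idx[:, None] == np.arange(4)[None, :],
                        1.0 - eps[:, None], eps[:, None] / 3.0)
    out = np.empty(10)
    for g, (a1, a2) in enumerate(GENOTYPE_PAIRS):
        out[g] = np.log(0.5 * p_allele[:, a1] + 0.5 * p_allele[:, a2]).sum()
    return out


def gl10_type_specific(reads: Sequence[tuple[str, Optional[float]]],
                       error_matrix: ErrorMatrix) -> np.ndarray:
    """As :func:`gl10_gatk` but with P(b | A) taken from an error matrix.

    Qualities in ``reads`` are ignored (the matrix already encodes the
    substitution process); with a symmetric matrix at rate eps this model
    coincides with the quality-based one at fixed eps.
    """
    if not reads:
        return np.zeros(10)
    idx = np.array([BASE_INDEX[b] for b, _ in reads], dtype=np.intp)
    p_allele = error_matrix.rates[:, idx].T  # [r, a] = E[a -> b_r]
    out = np.empty(10)
    for g, (a1, a2) in enumerate(GENOTYPE_PAIRS):
        with np.errstate(divide="ignore"):
            out[g] = np.log(0.5 * p_allele[:, a1] + 0.5 * p_allele[:, a2]).sum()
    return out


def gl10_gatk_counts(counts: np.ndarray, eps: float) -> np.ndarray:
    """Vectorised independent-reads GLs from per-base read counts.

    ``counts`` has shape (..., 4) giving how many reads carried each base at
    a common error rate ``eps`` (constant-quality data, as emitted by the
    simulator). Returns log-likelihoods of shape (..., 10), normalised so the
    maximum over genotypes is 0.
    """
    counts = np.asarray(counts, dtype=float)
    eps = min(eps, MAX_ERROR)
    # p[g, b] = P(base b | genotype g) = even mixture over the two alleles
    p_allele = np.full((4, 4), eps / 3.0)
    np.fill_diagonal(p_allele, 1.0 - eps)
    p = np.empty((10, 4))
    for g, (a1, a2) in enumerate(GENOTYPE_PAIRS):
        p[g] = 0.5 * p_allele[a1] + 0.5 * p_allele[a2]
    with np.errstate(divide="ignore"):
        logp = np.log(p)
    gl = counts @ logp.T  # (..., 10); 0 * -inf cannot occur for eps > 0
    return gl - gl.max(axis=-1, keepdims=True)


def infer_major_minor(gl10s: Sequence[np.ndarray]) -> tuple[str, str]:
    """Infer the diallelic (major, minor) pair from per-individual GL10s.

    Scores each unordered allele pair (a1, a2) by the log-likelihood of the
    data when every individual's genotype is marginalised over the pair with
    weights (1/4, 1/2, 1/4) — the allele-uniform prior — and returns the best
    pair with the major allele chosen by larger expected allele count.
    Ties break alphabetically.
    """
    gls = np.asarray(gl10s, dtype=float)  # (N, 10)
    lik = np.exp(gls - gls.max(axis=1, keepdims=True))  # rescale-invariant
    g_index = {pair: g for g, pair in enumerate(GENOTYPE_PAIRS)}
    best_score, best_pair = -np.inf, None
    for a1 in range(4):
        for a2 in range(a1 + 1, 4):
            l11 = lik[:, g_index[(a1, a1)]]
            l12 = lik[:, g_index[(a1, a2)]]
            l22 = lik[:, g_index[(a2, a2)]]
            score = np.log(0.25 * l11 + 0.5 * l12 + 0.25 * l22).sum()
            if score > best_score + 1e-12:
                best_score, best_pair = score, (a1, a2)
    a1, a2 = best_pair
    l11 = lik[:, g_index[(a1, a1)]]
    l12 = lik[:, g_index[(a1, a2)]]
    l22 = lik[:, g_index[(a2, a2)]]
    tot = 0.25 * l11 + 0.5 * l12 + 0.25 * l22
    # expected count of a1 per individual under the winning pair
    e1 = ((2 * 0.25 * l11 + 0.5 * l12) / tot).sum()
    e2 = ((2 * 0.25 * l22 + 0.5 * l12) / tot).sum()
    if e2 > e1 + 1e-9:
        a1, a2 = a2, a1  # a1 becomes major
    return BASES[a1], BASES[a2]


def gl3_from_gl10(gl10: np.ndarray, major: str, minor: str) -> np.ndarray:
    """Project a GL10 vector onto (major-hom, het, minor-hom)."""
    i, j = BASE_INDEX[major], BASE_INDEX[minor]
    if i == j:
        raise ValueError("major and minor allele must differ")
    lo, hi = min(i, j), max(i, j)
    g_index = {pair: g for g, pair in enumerate(GENOTYPE_PAIRS)}
    return np.array([gl10[g_index[(i, i)]],
                     gl10[g_index[(lo, hi)]],
                     gl10[g_index[(j, j)]]])


def gl3_batch_from_counts(counts: np.ndarray, eps: float,
                          alleles: np.ndarray) -> np.ndarray:
    """Diallelic GLs for many sites at once from per-base read counts.

    ``counts``: (S, N, 4) reads per site, individual and base;
    ``alleles``: (S, 2) base indices (first allele, second allele) so that
    genotype g in {0, 1, 2} counts copies of the second allele. Returns
    (S, N, 3) log-likelihoods normalised to max 0 per individual and site.
    """
    counts = np.asarray(counts, dtype=float)
    alleles = np.asarray(alleles, dtype=np.intp)
    S = counts.shape[0]
    eps = min(eps, MAX_ERROR)
    base_eye = np.eye(4)
    p1 = base_eye[alleles[:, 0]]  # (S, 4) indicator of allele 1
    p2 = base_eye[alleles[:, 1]]
    # P(b | hom1), P(b | het), P(b | hom2) per site: (S, 3, 4)
    probs = np.stack([
        (1.0 - eps) * p1 + (1.0 - p1) * eps / 3.0,
        0.5 * ((1.0 - eps) * p1 + (1.0 - p1) * eps / 3.0)
        + 0.5 * ((1.0 - eps) * p2 + (1.0 - p2) * eps / 3.0),
        (1.0 - eps) * p2 + (1.0 - p2) * eps / 3.0,
    ], axis=1)
    with np.errstate(divide="ignore"):
        logp = np.log(probs)
    gl = np.einsum("snb,sgb->sng", counts, logp)
    return gl - gl.max(axis=-1, keepdims=True)
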