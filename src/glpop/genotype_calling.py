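"""Genotype posterior probabilities under three priors, and calling.

Priors: uniform (posterior proportional to the likelihood), the HWE prior at
an estimated population frequency, and the sample-wide SFS prior in which an
individual's posterior is conditioned on the read data of all individuals
through the SAF machinery. Calls take the argmax posterior, set to missing
below a score cutoff; ties break toward the lower genotype index.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from glpop.saf_sfs import _W, _log_binom

MISSING = -1


def _normalise(lin: np.ndarray) -> np.ndarray:
    s = lin.sum(axis=-1, keepdims=True)
    return lin / s


def posterior_uniform(gl3: np.ndarray) -> np.ndarray:
    """Posterior proportional to exp(GL3): the raw maximum-likelihood view."""
    gl3 = np.asarray(gl3, dtype=float)
    lin = np.exp(gl3 - gl3.max(axis=-1, keepdims=True))
    return _normalise(lin)


def posterior_af(gl3: np.ndarray, f: float) -> np.ndarray:
    """Posterior under the HWE prior ((1-f)^2, 2f(1-f), f^2)."""
    gl3 = np.asarray(gl3, dtype=float)
    prior = np.array([(1 - f) ** 2, 2 * f * (1 - f), f ** 2])
    lin = np.exp(gl3 - gl3.max(axis=-1, keepdims=True)) * prior
    if np.any(lin.sum(axis=-1) == 0):
        raise ValueError("prior and likelihood have disjoint support")
    return _normalise(lin)


def posterior_sfs_batch(gl3: np.ndarray, gamma: np.ndarray) -> np.ndarray:
    """SFS-prior posteriors for every individual at every site.

    ``gl3`` is (S, N, 3) polarised to count derived alleles; ``gamma`` an SFS
    over 0..2N derived alleles. For individual i,

        P(G_i = g | X, gamma)  propto  L_i(g) w(g)
                                sum_j gamma_j h^(-i)(j - g) / C(2n, j)

    where h^(-i) is the SAF dynamic programme over the other N - 1
    individuals and w = (1, 2, 1). Each leave-one-out recursion is run
    separately (no numerically unsafe division). Returns (S, N, 3).
    """
    gl3 = np.asarray(gl3, dtype=float)
    gamma = np.asarray(gamma, dtype=float)
    S, N, _ = gl3.shape
    if gamma.shape != (2 * N + 1,):
        raise ValueError(f"gamma must have length {2 * N + 1}")
    lik = np.exp(gl3 - gl3.max(axis=2, keepdims=True)) * _W  # (S, N, 3)
    inv_binom = np.exp(-_log_binom(2 * N))                   # 1 / C(2n, j)
    weights = gamma * inv_binom                              # (2N+1,)
    out = np.empty((S, N, 3))
    for i in range(N):
        h = np.ones((S, 1))
        for k in range(N):
            if k == i:
                continue
            width = h.shape[1]
            new = np.zeros((S, width + 2))
            for g in range(3):
                new[:, g:g + width] += h * lik[:, k, g][:, None]
            new /= new.max(axis=1, keepdims=True)
            h = new                                          # (S, 2(N-1)+1)
        # prior factor for genotype g: sum_j weights[j] h(j - g)
        for g in range(3):
            out[:, i, g] = lik[:, i, g] * (h * weights[g:g + 2 * N - 1]).sum(axis=1)
    return _normalise(out)


def posterior_sfs(gl3s: np.ndarray, gamma: np.ndarray, individual: int) -> np.ndarray:
    """SFS-prior posterior triple for one individual at one site."""
    gl3 = np.asarray(gl3s, dtype=float)
    if gl3.ndim != 2 or gl3.shape[1] != 3:
        raise ValueError("expected an (N, 3) array of polarised GL3s")
    return posterior_sfs_batch(gl3[None], gamma)[0, individual]


def call_genotypes(triples: np.ndarray, cutoff: float = 0.0
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Call genotypes from posterior triples.

    Returns (calls, scores): call is the argmax genotype index (lowest index
    wins ties) or -1 (missing) when the best posterior is below ``cutoff``;
    ``cutoff = 0`` disables missingness. Works on any (..., 3) array.
    """
    triples = np.asarray(triples, dtype=float)
    calls = triples.argmax(axis=-1)
    scores = np.take_along_axis(triples, calls[..., None], axis=-1)[..., 0]
    calls = np.where(scores < cutoff, MISSING, calls)
    return calls, scores
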