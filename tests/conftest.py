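"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately avoid the package's own recursions: SAF and
posterior oracles enumerate every genotype configuration, the MAF oracle is
a dense grid search on the likelihood, and the jackknife oracle is the
classical delete-1 textbook formula. They are feasible only at tiny n, which
is the point.
"""

from itertools import product
from math import comb

import numpy as np
import pytest


def brute_force_saf(gl3: np.ndarray) -> np.ndarray:
    """p(X | D = j) by exhaustive enumeration over genotype configurations.

    gl3 is (N, 3) log likelihoods polarised to count derived alleles.
    Returns the log vector max-normalised to 0, like saf_site.
    """
    gl3 = np.asarray(gl3, dtype=float)
    n = gl3.shape[0]
    lik = np.exp(gl3 - gl3.max(axis=1, keepdims=True))
    w = (1.0, 2.0, 1.0)
    out = np.zeros(2 * n + 1)
    for config in product(range(3), repeat=n):
        j = sum(config)
        out[j] += np.prod([lik[i, g] * w[g] for i, g in enumerate(config)])
    out /= np.array([comb(2 * n, j) for j in range(2 * n + 1)])
    logp = np.log(out)
    return logp - logp.max()


def brute_force_posterior_sfs(gl3: np.ndarray, gamma: np.ndarray) -> np.ndarray:
    """Genotype posteriors under the SFS prior by full enumeration; (N, 3)."""
    gl3 = np.asarray(gl3, dtype=float)
    n = gl3.shape[0]
    lik = np.exp(gl3 - gl3.max(axis=1, keepdims=True))
    w = (1.0, 2.0, 1.0)
    post = np.zeros((n, 3))
    for config in product(range(3), repeat=n):
        j = sum(config)
        val = gamma[j] / comb(2 * n, j) * np.prod(
            [lik[i, g] * w[g] for i, g in enumerate(config)])
        for i, g in enumerate(config):
            post[i, g] += val
    return post / post.sum(axis=1, keepdims=True)


def grid_search_maf(gl3: np.ndarray, n_grid: int = 100_001) -> float:
    """argmax over an f-grid of sum_i log sum_g GL_i(g) HWE(g; f)."""
    gl3 = np.asarray(gl3, dtype=float)
    lik = np.exp(gl3 - gl3.max(axis=1, keepdims=True))
    f = np.linspace(0.0, 1.0, n_grid)
    hwe = np.stack([(1 - f) ** 2, 2 * f * (1 - f), f ** 2], axis=1)  # (F, 3)
    ll = np.log(np.einsum("ng,fg->fn", lik, hwe)).sum(axis=1)
    return float(f[np.argmax(ll)])


def classical_delete1_jackknife(values_per_block):
    """Textbook delete-1 jackknife (est, se) for equal-sized blocks.

    values_per_block is a list of (n_abba, n_baba) tuples.
    """
    arr = np.asarray(values_per_block, dtype=float)
    tot = arr.sum(axis=0)
    d = (tot[0] - tot[1]) / (tot[0] + tot[1])
    B = len(arr)
    d_del = np.array([((tot[0] - a) - (tot[1] - b)) / ((tot[0] - a) + (tot[1] - b))
                      for a, b in arr])
    pseudo = B * d - (B - 1) * d_del
    est = pseudo.mean()
    se = np.sqrt(((pseudo - est) ** 2).sum() / (B * (B - 1)))
    return est, se


def allele_count_g_test(counts_cases, counts_controls):
    """Classical 2x2 allele-count likelihood-ratio G statistic.

    counts_* = (n_minor, n_major) chromosomes.
    """
    def ll(k, n):
        if k == 0 or k == n:
            return 0.0
        p = k / n
        return k * np.log(p) + (n - k) * np.log(1 - p)

    k1, m1 = counts_cases
    k2, m2 = counts_controls
    n1, n2 = k1 + m1, k2 + m2
    return 2.0 * (ll(k1, n1) + ll(k2, n2) - ll(k1 + k2, n1 + n2))


def certain_gl3(genotype: int, scale: float = 60.0) -> np.ndarray:
    """Log GL3 for an (effectively) certain genotype."""
    gl = np.full(3, -scale)
    gl[genotype] = 0.0
    return gl


@pytest.fixture
def rng():
    return np.random.default_rng(20231125)
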