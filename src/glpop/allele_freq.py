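"""Population allele-frequency estimation and likelihood-ratio tests.

The frequency of the minor allele at a diallelic site is the maximiser of

    L(f) = prod_i sum_g GL_i(g) * HWE(g; f),    HWE = ((1-f)^2, 2f(1-f), f^2)

over individuals i with data, estimated by EM on the latent genotypes.
A likelihood-ratio test of f = 0 against f free provides the SNP-discovery
criterion; the null lies on the boundary of the parameter space, so the
plain chi-square(1) p-value used by default is conservative (a half-mixture
chi-square(0)/chi-square(1) alternative is available behind a flag).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

_FLAT_TOL = 1e-12


@dataclass
class MafResult:
    """Minor-allele-frequency estimate with the variability LRT."""

    f_hat: float
    n_used: int
    loglik_at_f_hat: float
    loglik_at_0: float
    lrt: float
    p_value: float


def _data_mask(gl3: np.ndarray) -> np.ndarray:
    """Individuals whose GL3 is non-flat (flat = no reads = no information)."""
    return (gl3.max(axis=-1) - gl3.min(axis=-1)) > _FLAT_TOL


def _hwe(f: np.ndarray) -> np.ndarray:
    """HWE genotype probabilities, shape (..., 3), for frequency f."""
    f = np.asarray(f, dtype=float)
    return np.stack([(1 - f) ** 2, 2 * f * (1 - f), f ** 2], axis=-1)


def loglik_at_f(gl3: np.ndarray, f: float | np.ndarray,
                mask: Optional[np.ndarray] = None) -> np.ndarray:
    """Log-likelihood sum_i log sum_g GL_i(g) HWE(g; f) over individuals with data.

    ``gl3`` is (..., N, 3) in log scale; broadcasting over leading axes.
    """
    gl3 = np.asarray(gl3, dtype=float)
    if mask is None:
        mask = _data_mask(gl3)
    lik = np.exp(gl3 - gl3.max(axis=-1, keepdims=True))
    prior = _hwe(f)
    if prior.ndim == gl3.ndim - 1:
        prior = prior[..., None, :]
    per_ind = np.log((lik * prior).sum(axis=-1))
    return np.where(mask, per_ind, 0.0).sum(axis=-1)


def maf_em_batch(gl3: np.ndarray, tol: float = 1e-8, max_iter: int = 200,
                 f0: float | np.ndarray = 0.1) -> np.ndarray:
    """EM minor-allele-frequency estimates for a batch of sites.

    ``gl3`` is (S, N, 3) log-scale; returns f_hat of shape (S,). Sites with
    no informative individual get NaN. ``f0`` may be a per-site warm start.
    """
    gl3 = np.asarray(gl3, dtype=float)
    S = gl3.shape[0]
    mask = _data_mask(gl3)                      # (S, N)
    n_used = mask.sum(axis=1)                   # (S,)
    lik = np.exp(gl3 - gl3.max(axis=-1, keepdims=True))
    f = np.broadcast_to(np.asarray(f0, dtype=float), (S,)).copy()
    f = np.nan_to_num(f, nan=0.1)
    active = n_used > 0
    for _ in range(max_iter):
        w = lik * _hwe(f)[:, None, :]           # (S, N, 3)
        w /= w.sum(axis=-1, keepdims=True)
        e_g = (w[..., 1] + 2.0 * w[..., 2])     # expected minor-allele copies
        e_g = np.where(mask, e_g, 0.0).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            f_new = np.where(active, e_g / (2.0 * n_used), np.nan)
        done = np.abs(f_new - f) < tol
        f = f_new
        if done[active].all():
            break
    return f


def estimate_maf_em(gl3s: Sequence[np.ndarray] | np.ndarray, tol: float = 1e-8,
                    max_iter: int = 200) -> float:
    """Minor-allele frequency of a single site by EM.

    Raises ValueError when every individual is uninformative (all-flat GLs).
    """
    gl3 = np.asarray(gl3s, dtype=float)
    if gl3.ndim != 2 or gl3.shape[1] != 3:
        raise ValueError("expected an (N, 3) array of per-individual GL3s")
    if not _data_mask(gl3).any():
        raise ValueError("no individual has data at this site")
    return float(maf_em_batch(gl3[None], tol=tol, max_iter=max_iter)[0])


def snp_lrt(gl3s: Sequence[np.ndarray] | np.ndarray, tol: float = 1e-8,
            max_iter: int = 200, boundary_mixture: bool = False) -> MafResult:
    """Likelihood-ratio test of the site being variable (f > 0 vs f = 0).

    With ``boundary_mixture`` the p-value uses the 1/2 chi2(0) + 1/2 chi2(1)
    boundary null; the default chi2(1) is conservative.
    """
    gl3 = np.asarray(gl3s, dtype=float)
    mask = _data_mask(gl3)
    if not mask.any():
        raise ValueError("no individual has data at this site")
    f_hat = estimate_maf_em(gl3, tol=tol, max_iter=max_iter)
    ll_hat = float(loglik_at_f(gl3, f_hat, mask))
    ll_0 = float(loglik_at_f(gl3, 0.0, mask))
    lrt = 2.0 * (ll_hat - ll_0)
    # a boundary MLE reached to EM tolerance can sit a hair below ll(0)
    if lrt < -1e-6:
        raise AssertionError(f"LRT negative beyond tolerance: {lrt}")
    lrt = max(lrt, 0.0)
    p = float(stats.chi2.sf(lrt, df=1))
    if boundary_mixture:
        p = 0.5 * p if lrt > 0 else 1.0
    return MafResult(f_hat=f_hat, n_used=int(mask.sum()),
                     loglik_at_f_hat=ll_hat, loglik_at_0=ll_0,
                     lrt=lrt, p_value=min(p, 1.0))


def snp_lrt_batch(gl3: np.ndarray, tol: float = 1e-8,
                  max_iter: int = 200) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised variability LRT: returns (f_hat, lrt, p_value) arrays."""
    gl3 = np.asarray(gl3, dtype=float)
    mask = _data_mask(gl3)
    f_hat = maf_em_batch(gl3, tol=tol, max_iter=max_iter)
    ll_hat = loglik_at_f(gl3, f_hat, mask)
    ll_0 = loglik_at_f(gl3, np.zeros_like(f_hat), mask)
    lrt = np.clip(2.0 * (ll_hat - ll_0), 0.0, None)
    return f_hat, lrt, stats.chi2.sf(lrt, df=1)


def maf_from_gp(gps: Sequence[Sequence[float]]) -> float:
    """Frequency from genotype posteriors: mean of (P(het) + 2 P(minor-hom))/2."""
    gp = np.asarray(gps, dtype=float)
    if gp.ndim != 2 or gp.shape[1] != 3:
        raise ValueError("expected an (N, 3) array of genotype probabilities")
    return float(((gp[:, 1] + 2.0 * gp[:, 2]) / 2.0).mean())


def case_control_lrt(gl3s_cases: np.ndarray, gl3s_controls: np.ndarray,
                     tol: float = 1e-8, max_iter: int = 200) -> tuple[float, float]:
    """Allele-frequency association test between cases and controls.

    LRT = 2 [ll_cases(f_cases) + ll_controls(f_controls) - ll_pooled(f_pooled)]
    against chi-square with one degree of freedom. Returns (statistic, p).
    """
    cases = np.asarray(gl3s_cases, dtype=float)
    controls = np.asarray(gl3s_controls, dtype=float)
    pooled = np.concatenate([cases, controls], axis=0)
    f_ca = estimate_maf_em(cases, tol=tol, max_iter=max_iter)
    f_co = estimate_maf_em(controls, tol=tol, max_iter=max_iter)
    f_po = estimate_maf_em(pooled, tol=tol, max_iter=max_iter)
    ll = (float(loglik_at_f(cases, f_ca)) + float(loglik_at_f(controls, f_co))
          - float(loglik_at_f(pooled, f_po)))
    lrt = max(2.0 * ll, 0.0)
    return lrt, float(stats.chi2.sf(lrt, df=1))
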