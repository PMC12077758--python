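"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's computational paths: nucleotide
diversity is recomputed by explicit enumeration of all unordered sequence
pairs, and the mixed-model likelihood is maximized by a dense grid search
over both variance components (with GLS coefficients from an explicit
per-point solve), so agreement is evidence rather than tautology.
"""

from __future__ import annotations

import numpy as np


def brute_force_pi(haplotypes, counts, L, unbiased=True):
    """Nucleotide diversity by explicit enumeration of all C(n,2) pairs."""
    seqs = []
    for hap, c in zip(haplotypes, counts):
        seqs.extend([hap] * c)
    n = len(seqs)
    total = 0.0
    npairs = 0
    for i in range(n):
        for j in range(i + 1, n):
            diff = sum(1 for a, b in zip(seqs[i], seqs[j]) if a != b)
            total += diff / L
            npairs += 1
    if unbiased:
        return total / npairs
    # plug-in: average over ordered pairs including self-pairs
    return 2.0 * total / (n * n)


def brute_force_hd(counts, unbiased=True):
    """Haplotype diversity by explicit enumeration of sequence pairs."""
    labels = []
    for k, c in enumerate(counts):
        labels.extend([k] * c)
    n = len(labels)
    diff = sum(
        1 for i in range(n) for j in range(i + 1, n) if labels[i] != labels[j]
    )
    hd = diff / (n * (n - 1) / 2)
    return hd if unbiased else hd * (n - 1) / n


def lmm_grid_loglik_max(y, X, groups, n_grid=200, span=(1e-4, 1e2)):
    """Best ML log-likelihood over a dense (sigma2_alpha, sigma2_eps) grid.

    For each grid pair the GLS coefficients (which depend only on the
    variance ratio) and the exact Gaussian log-likelihood are evaluated in a
    vectorized sweep.  The grid is log-spaced and scaled by var(y).
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    N, p = X.shape
    _, idx = np.unique(groups, return_inverse=True)
    G = idx.max() + 1
    n_g = np.bincount(idx).astype(float)
    sx = np.zeros((G, p))
    np.add.at(sx, idx, X)
    sy = np.bincount(idx, weights=y)
    Sxx, Sxy, Syy = X.T @ X, X.T @ y, float(y @ y)

    vy = float(np.var(y))
    scale = np.geomspace(span[0] * vy, span[1] * vy, n_grid)
    s_a, s_e = np.meshgrid(scale, scale, indexing="ij")
    s_a, s_e = s_a.ravel(), s_e.ravel()
    lam = s_a / s_e                                      # (M,)
    c = lam[:, None] / (1.0 + lam[:, None] * n_g[None, :])   # (M, G)

    A = Sxx[None] - np.einsum("mg,gp,gq->mpq", c, sx, sx)
    b = Sxy[None] - np.einsum("mg,gp->mp", c * sy[None, :], sx)
    beta = np.linalg.solve(A, b[..., None])[..., 0]      # (M, p)
    resid_g = sy[None, :] - beta @ sx.T                  # (M, G)
    Q = (Syy - 2.0 * np.einsum("mp,p->m", beta, Sxy)
         + np.einsum("mp,pq,mq->m", beta, Sxx, beta)
         - np.sum(c * resid_g**2, axis=1))
    logdet = np.sum(np.log1p(lam[:, None] * n_g[None, :]), axis=1)
    ll = -0.5 * (N * np.log(2.0 * np.pi * s_e) + logdet + Q / s_e)
    return float(np.max(ll))
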