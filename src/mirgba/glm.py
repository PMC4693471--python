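"""Negative-binomial generalized linear models for count matrices.

Per-feature NB regression with a log link and library-size offsets,
fitted by iteratively reweighted least squares (IRLS), batched across
all features at once (every feature shares the design matrix, so the
normal equations are solved as a stack of small p x p systems).
Inference is by likelihood-ratio tests with the dispersion held fixed,
either on a single coefficient or on an arbitrary contrast vector, the
contrast case handled by an orthogonal reparameterization that turns
the contrast into a coefficient of an equivalent design.

Parameterization: Var(Y) = mu + phi * mu^2 (phi is the dispersion; the
biological coefficient of variation is sqrt(phi)). phi = 0 recovers the
Poisson model. Coefficients are on the natural-log scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special, stats

__all__ = ["NBGLMFit", "fit_nbglm", "nb_loglik", "nb_deviance", "lrt", "contrast_design"]

_MU_MIN = 1e-10
_MU_MAX = 1e12


@dataclass
class NBGLMFit:
    """Result of a batched per-feature NB GLM fit.

    Attributes
    ----------
    coef : (G, p) array of natural-log-scale coefficients.
    fitted : (G, n) array of fitted means.
    deviance : (G,) residual deviances.
    converged : (G,) boolean convergence flags (non-converged features
        carry their last iterate).
    design : the (n, p) design matrix used.
    offsets : the (n,) or (G, n) log effective library sizes.
    dispersion : scalar or (G,) dispersion used.
    """

    coef: np.ndarray
    fitted: np.ndarray
    deviance: np.ndarray
    converged: np.ndarray
    design: np.ndarray
    offsets: np.ndarray
    dispersion: np.ndarray


def nb_loglik(y, mu, dispersion):
    """Row-sum NB log-likelihood; Poisson at dispersion 0.

    Accepts (G, n) arrays with scalar or (G,) dispersion; returns (G,).
    """
    y = np.asarray(y, dtype=float)
    mu = np.clip(np.asarray(mu, dtype=float), _MU_MIN, _MU_MAX)
    phi = np.asarray(dispersion, dtype=float)
    if phi.ndim == 1:
        phi = phi[:, None]
    if np.all(phi == 0):
        return np.sum(y * np.log(mu) - mu - special.gammaln(y + 1), axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(phi > 0, 1.0 / np.where(phi > 0, phi, 1.0), np.inf)
        ll_nb = (
            special.gammaln(y + r)
            - special.gammaln(r)
            - special.gammaln(y + 1)
            + r * np.log(r / (r + mu))
            + y * np.log(mu / (r + mu))
        )
    ll_pois = y * np.log(mu) - mu - special.gammaln(y + 1)
    ll = np.where(phi > 0, ll_nb, ll_pois)
    return np.sum(ll, axis=-1)


def nb_deviance(y, mu, dispersion):
    """Row-sum NB unit deviance (twice the saturated-minus-fitted ll)."""
    y = np.asarray(y, dtype=float)
    mu = np.clip(np.asarray(mu, dtype=float), _MU_MIN, _MU_MAX)
    phi = np.asarray(dispersion, dtype=float)
    if phi.ndim == 1:
        phi = phi[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        ylogy = np.where(y > 0, y * np.log(np.where(y > 0, y, 1.0) / mu), 0.0)
        dev_pois = 2.0 * (ylogy - (y - mu))
        dev_nb = 2.0 * (
            ylogy
            - (y + 1.0 / np.where(phi > 0, phi, 1.0))
            * np.log((1.0 + phi * y) / (1.0 + phi * mu))
        )
    dev = np.where(phi > 0, dev_nb, dev_pois)
    return np.sum(dev, axis=-1)


def _check_design(design: np.ndarray) -> np.ndarray:
    X = np.asarray(design, dtype=float)
    if X.ndim != 2:
        raise ValueError("design must be a 2-D matrix")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    return X


def fit_nbglm(
    counts,
    design,
    offsets,
    dispersion,
    max_iter: int = 50,
    tol: float = 1e-8,
) -> NBGLMFit:
    """Fit one NB GLM per feature (batched IRLS).

    Parameters
    ----------
    counts : (G, n) non-negative integer matrix.
    design : (n, p) full-rank design matrix, shared by all features.
    offsets : (n,) or (G, n) log effective library sizes.
    dispersion : scalar or (G,) NB dispersion, held fixed during the fit.
    max_iter, tol : IRLS stops when the relative deviance change drops
        below ``tol`` or after ``max_iter`` iterations (flagged).
    """
    y = np.asarray(counts, dtype=float)
    if y.ndim != 2:
        raise ValueError("counts must be a 2-D features x samples matrix")
    if np.any(y < 0):
        raise ValueError("counts must be non-negative")
    X = _check_design(design)
    G, n = y.shape
    if X.shape[0] != n:
        raise ValueError("design rows must match the number of samples")
    p = X.shape[1]
    o = np.asarray(offsets, dtype=float)
    o2 = np.broadcast_to(o, (G, n)) if o.ndim == 1 else o
    phi = np.broadcast_to(np.asarray(dispersion, dtype=float), (G,)).copy()

    # initial values: one weighted least-squares step on log counts
    z0 = np.log(np.maximum(y, 0.125)) - o2
    XtX = X.T @ X
    beta = np.linalg.solve(XtX, X.T @ z0.T).T  # (G, p)

    def mu_of(b):
        eta = b @ X.T + o2
        return np.clip(np.exp(np.clip(eta, -700, 700)), _MU_MIN, _MU_MAX)

    mu = mu_of(beta)
    dev = nb_deviance(y, mu, phi)
    converged = np.zeros(G, dtype=bool)
    active = np.ones(G, dtype=bool)

    for _ in range(max_iter):
        if not np.any(active):
            break
        idx = np.flatnonzero(active)
        mu_a = mu[idx]
        phi_a = phi[idx][:, None]
        w = mu_a / (1.0 + phi_a * mu_a)  # Fisher weights, log link
        z = np.log(mu_a) - o2[idx] + (y[idx] - mu_a) / mu_a
        # batched normal equations
        xtwx = np.einsum("gn,np,nq->gpq", w, X, X)
        xtwz = np.einsum("gn,np,gn->gp", w, X, z)
        xtwx += 1e-10 * np.eye(p)[None, :, :]
        beta_new = np.linalg.solve(xtwx, xtwz[..., None])[..., 0]

        # step halving where the deviance would increase
        step = beta_new - beta[idx]
        dev_old = dev[idx]
        frac = np.ones(len(idx))
        for _half in range(8):
            trial = beta[idx] + frac[:, None] * step
            mu_t = np.clip(
                np.exp(np.clip(trial @ X.T + o2[idx], -700, 700)), _MU_MIN, _MU_MAX
            )
            dev_t = nb_deviance(y[idx], mu_t, phi[idx])
            bad = dev_t > dev_old + 1e-8
            if not np.any(bad):
                break
            frac[bad] *= 0.5
        beta[idx] = beta[idx] + frac[:, None] * step
        mu[idx] = np.clip(
            np.exp(np.clip(beta[idx] @ X.T + o2[idx], -700, 700)), _MU_MIN, _MU_MAX
        )
        dev_new = nb_deviance(y[idx], mu[idx], phi[idx])
        rel = np.abs(dev_new - dev_old) / (np.abs(dev_old) + 1.0)
        dev[idx] = dev_new
        done = rel < tol
        converged[idx[done]] = True
        active[idx[done]] = False

    return NBGLMFit(
        coef=beta,
        fitted=mu,
        deviance=dev,
        converged=converged,
        design=X,
        offsets=o,
        dispersion=phi,
    )


def contrast_design(design, contrast):
    """Reparameterize so a contrast vector becomes the last coefficient.

    Returns an (n, p) design spanning the same column space as the input
    whose final column's coefficient equals ``contrast @ beta`` up to a
    positive scale, plus that design with the final column dropped (the
    reduced model for the LRT).
    """
    X = _check_design(design)
    c = np.asarray(contrast, dtype=float)
    if c.shape != (X.shape[1],):
        raise ValueError("contrast length must match the number of coefficients")
    if np.allclose(c, 0):
        raise ValueError("contrast must be non-zero")
    # orthonormal basis with the contrast direction last
    q, _ = np.linalg.qr(
        np.column_stack([c, np.eye(X.shape[1])])
    )
    # q's first column spans c (QR may flip its sign); rotate it last
    first = q[:, 0] if q[:, 0] @ c > 0 else -q[:, 0]
    Q = np.column_stack([q[:, 1:], first])
    X_new = X @ Q
    return X_new, X_new[:, :-1]


def lrt(counts, design, offsets, dispersion, coef=None, contrast=None, fit=None):
    """Likelihood-ratio test per feature with the dispersion fixed.

    Exactly one of ``coef`` (column index of the design) or ``contrast``
    (vector in the row space of the design) must be given. The reduced
    model drops the tested direction; the statistic is twice the
    log-likelihood difference, referred to chi-square with 1 df.

    Returns
    -------
    (statistic, p_value, log2fc) : each a (G,) array. ``log2fc`` is the
        tested coefficient (or contrast) of the *full* fit on the log2
        scale.
    """
    if (coef is None) == (contrast is None):
        raise ValueError("specify exactly one of coef or contrast")
    X = _check_design(design)
    p = X.shape[1]
    if coef is not None:
        if not 0 <= coef < p:
            raise ValueError("coefficient index out of range")
        X_full = X
        X_red = np.delete(X, coef, axis=1)
        if np.linalg.matrix_rank(X_red) < p - 1:
            raise ValueError("reduced design is rank deficient")
        full = fit if fit is not None else fit_nbglm(counts, X_full, offsets, dispersion)
        effect = full.coef[:, coef]
    else:
        X_full, X_red = contrast_design(X, contrast)
        full = fit_nbglm(counts, X_full, offsets, dispersion)
        # recover contrast @ beta on the original parameterization
        c = np.asarray(contrast, dtype=float)
        scale = np.linalg.norm(c)
        effect = full.coef[:, -1] * scale
        if fit is not None:
            effect = fit.coef @ c  # exact on the original basis
    reduced = fit_nbglm(counts, X_red, offsets, dispersion)
    ll_full = nb_loglik(counts, full.fitted, full.dispersion)
    ll_red = nb_loglik(counts, reduced.fitted, reduced.dispersion)
    stat = np.maximum(2.0 * (ll_full - ll_red), 0.0)
    pval = stats.chi2.sf(stat, df=1)
    return stat, pval, effect / np.log(2.0)
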