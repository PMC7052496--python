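"""Negative-binomial GLM fitting with a fixed dispersion.

A compact IRLS fitter for log-link NB2 models (var = mu + phi*mu^2) with
per-sample offsets, used by both time-course DE stages. Dispersion is
estimated per gene by method of moments within time-point groups and
shrunk toward the common value; exact empirical-Bayes equivalence with
dedicated DE packages is deliberately not attempted.
"""

from __future__ import annotations

import numpy as np
from scipy.special import gammaln

_ETA_MAX = 30.0


def nb_loglik(y: np.ndarray, mu: np.ndarray, phi: float) -> float:
    """NB2 log-likelihood (Poisson limit used for tiny dispersion)."""
    mu = np.maximum(mu, 1e-12)
    if phi < 1e-8:
        return float(np.sum(y * np.log(mu) - mu - gammaln(y + 1)))
    r = 1.0 / phi
    return float(np.sum(
        gammaln(y + r) - gammaln(r) - gammaln(y + 1)
        + y * np.log(phi * mu / (1.0 + phi * mu))
        - r * np.log1p(phi * mu)
    ))


def nb_deviance(y: np.ndarray, mu: np.ndarray, phi: float) -> float:
    """Residual deviance: twice the log-likelihood gap to saturation."""
    mu = np.maximum(mu, 1e-12)
    ypos = np.maximum(y, 1e-12)
    if phi < 1e-8:
        dev = 2.0 * np.sum(y * np.log(ypos / mu) - (y - mu))
    else:
        dev = 2.0 * np.sum(
            y * np.log(ypos / mu)
            - (y + 1.0 / phi) * np.log((1.0 + phi * y) / (1.0 + phi * mu))
        )
    return float(max(dev, 0.0))


def fit_nb_glm(
    y: np.ndarray,
    X: np.ndarray,
    offset: np.ndarray | None = None,
    phi: float = 0.1,
    max_iter: int = 60,
    tol: float = 1e-9,
) -> dict:
    """Fit a log-link NB GLM with known dispersion by IRLS.

    Returns beta, fitted mu, residual deviance, log-likelihood and a
    convergence flag.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if offset is None:
        offset = np.zeros(n)
    # initialize from a linear fit to log counts
    z0 = np.log(y + 0.5) - offset
    beta, *_ = np.linalg.lstsq(X, z0, rcond=None)
    dev_old = np.inf
    converged = False
    for _ in range(max_iter):
        eta = np.clip(X @ beta + offset, -_ETA_MAX, _ETA_MAX)
        mu = np.exp(eta)
        w = mu / (1.0 + phi * mu)
        z = (eta - offset) + (y - mu) / mu
        XtW = X.T * w
        try:
            beta_new = np.linalg.solve(XtW @ X, XtW @ z)
        except np.linalg.LinAlgError:
            beta_new, *_ = np.linalg.lstsq(XtW @ X, XtW @ z, rcond=None)
        beta = beta_new
        eta = np.clip(X @ beta + offset, -_ETA_MAX, _ETA_MAX)
        mu = np.exp(eta)
        dev = nb_deviance(y, mu, phi)
        if abs(dev - dev_old) < tol * (abs(dev) + 0.1):
            converged = True
            break
        dev_old = dev
    return {
        "beta": beta,
        "mu": mu,
        "deviance": dev,
        "loglik": nb_loglik(y, mu, phi),
        "converged": converged,
    }


def estimate_dispersions(
    counts: np.ndarray,
    groups: np.ndarray,
    effective_lib: np.ndarray,
    shrink_weight: float = 0.7,
    phi_min: float = 1e-4,
    phi_max: float = 5.0,
) -> np.ndarray:
    """Per-gene NB dispersion, method of moments shrunk to the common value.

    Counts are first rescaled to a common effective library size; within
    each group (time point) phi is estimated from the mean/variance
    relation var = mu + phi*mu^2, pooled across groups with df weights,
    then shrunk as ``shrink_weight*common + (1-shrink_weight)*per-gene``.
    """
    scale = effective_lib.mean() / effective_lib
    z = counts * scale[None, :]
    num = np.zeros(counts.shape[0])
    den = np.zeros(counts.shape[0])
    for g in np.unique(groups):
        cols = groups == g
        n_g = int(cols.sum())
        if n_g < 2:
            continue
        m = z[:, cols].mean(axis=1)
        v = z[:, cols].var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            phi_g = (v - m) / np.maximum(m, 1e-12) ** 2
        phi_g = np.clip(np.nan_to_num(phi_g), 0.0, phi_max)
        num += (n_g - 1) * phi_g
        den += n_g - 1
    per_gene = num / np.maximum(den, 1.0)
    common = float(np.median(per_gene[per_gene > 0])) if (per_gene > 0).any() else phi_min
    phi = shrink_weight * common + (1.0 - shrink_weight) * per_gene
    return np.clip(phi, phi_min, phi_max)
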