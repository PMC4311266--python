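"""Linear mixed model with a single family random intercept, fit by REML.

The marginal covariance of a sibship of size k is
``sigma2 * (I_k + lam * J_k)`` with ``lam = sigma_b^2 / sigma^2``.  Both the
GLS solve and the determinants have closed forms per block
(Sherman–Morrison on J), so REML reduces to a 1-D profiled optimisation over
``lam`` handled by a bracketed scalar minimizer.

Families are exchangeable blocks identified by an integer/str label; all
computations are grouped by family so the cost is O(n p^2) per candidate
``lam``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

__all__ = ["REMLFit", "reml_family_intercept", "whiten_family"]


@dataclass
class REMLFit:
    beta: np.ndarray
    cov_beta: np.ndarray  # sigma2 * (X' Sigma(lam)^-1 X)^-1
    sigma2: float  # residual variance
    sigma2_b: float  # family-intercept variance
    lam: float  # sigma2_b / sigma2
    resid: np.ndarray  # Y - X beta (marginal residuals)
    n: int
    p: int
    converged: bool
    n_iter: int
    reml_loglik: float


def _family_slices(family_ids: np.ndarray):
    """Group row indices by family label. Returns list of index arrays."""
    fam = np.asarray(family_ids)
    order = np.argsort(fam, kind="stable")
    sorted_fam = fam[order]
    boundaries = np.flatnonzero(np.r_[True, sorted_fam[1:] != sorted_fam[:-1]])
    groups = np.split(order, boundaries[1:])
    return groups


def _sigma_inv_apply(M: np.ndarray, groups, lam: float) -> np.ndarray:
    """Apply Sigma(lam)^-1 = blockdiag(I - lam/(1+k lam) J) to columns of M."""
    out = M.copy()
    for idx in groups:
        k = len(idx)
        # singletons keep their own intercept: 1x1 block 1+lam, not 1
        c = lam / (1.0 + k * lam)
        block = M[idx]
        out[idx] = block - c * block.sum(axis=0, keepdims=True)
    return out


def _logdet_sigma(groups, lam: float) -> float:
    return float(sum(np.log1p(len(idx) * lam) for idx in groups))


def whiten_family(M: np.ndarray, family_ids: np.ndarray, lam: float) -> np.ndarray:
    """Apply Sigma(lam)^{-1/2} to the columns of M.

    Per block, Sigma = I + lam J has eigenvalue 1 + k*lam on the constant
    vector and 1 elsewhere, so Sigma^{-1/2} = I + ((1+k lam)^{-1/2} - 1)/k J.
    """
    M = np.atleast_2d(np.asarray(M, dtype=float))
    squeeze = False
    if M.shape[0] == 1 and len(np.asarray(family_ids)) != 1:
        M = M.T
        squeeze = True
    out = M.copy()
    for idx in _family_slices(family_ids):
        k = len(idx)
        c = (1.0 / np.sqrt(1.0 + k * lam) - 1.0) / k
        block = M[idx]
        out[idx] = block + c * block.sum(axis=0, keepdims=True)
    return out[:, 0] if squeeze else out


def _profiled_reml(lam, X, Y, groups, n, p):
    """REML criterion (negated, for minimization) at variance ratio lam."""
    Si_X = _sigma_inv_apply(X, groups, lam)
    Si_Y = _sigma_inv_apply(Y[:, None], groups, lam)[:, 0]
    XtSiX = X.T @ Si_X
    XtSiY = X.T @ Si_Y
    beta = np.linalg.solve(XtSiX, XtSiY)
    r = Y - X @ beta
    Si_r = _sigma_inv_apply(r[:, None], groups, lam)[:, 0]
    rss = float(r @ Si_r)
    sigma2 = rss / (n - p)
    sign, logdet_XtSiX = np.linalg.slogdet(XtSiX)
    ll = -0.5 * (
        (n - p) * np.log(sigma2)
        + _logdet_sigma(groups, lam)
        + logdet_XtSiX
        + (n - p)
    )
    return -ll, beta, sigma2, XtSiX, r


def reml_family_intercept(
    Y: np.ndarray,
    X: np.ndarray,
    family_ids: np.ndarray,
    tol: float = 1e-8,
    max_ratio: float = 1e4,
) -> REMLFit:
    """Fit Y = X beta + b_family + eps by profiled REML over lam = sigma_b^2/sigma^2."""
    Y = np.asarray(Y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, p = X.shape
    if n <= p:
        raise ValueError("more parameters than observations")
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("singular covariate design")
    groups = _family_slices(family_ids)

    evals = {"count": 0}

    def objective(log_lam: float) -> float:
        evals["count"] += 1
        lam = np.exp(log_lam)
        return _profiled_reml(lam, X, Y, groups, n, p)[0]

    # include lam -> 0 boundary explicitly: compare interior optimum with OLS
    res = minimize_scalar(
        objective, bounds=(np.log(1e-8), np.log(max_ratio)), method="bounded",
        options={"xatol": tol},
    )
    lam_star = float(np.exp(res.x))
    nll_star = float(res.fun)
    nll_zero, *_ = _profiled_reml(0.0, X, Y, groups, n, p)
    if nll_zero <= nll_star:
        lam_star = 0.0
    nll, beta, sigma2, XtSiX, r = _profiled_reml(lam_star, X, Y, groups, n, p)
    return REMLFit(
        beta=beta,
        cov_beta=sigma2 * np.linalg.inv(XtSiX),
        sigma2=sigma2,
        sigma2_b=lam_star * sigma2,
        lam=lam_star,
        resid=r,
        n=n,
        p=p,
        converged=bool(res.success),
        n_iter=evals["count"],
        reml_loglik=-nll,
    )
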