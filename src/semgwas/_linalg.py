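"""Internal linear-algebra kernels shared by the mixed-model fitters.

Everything works in the eigenbasis of the relationship matrix K = U D U'.
After rotating phenotypes by U', the rows of the transformed data are
independent t-vectors with covariance V_i = d_i * Sigma_g + Sigma_e, which
reduces every likelihood evaluation and GLS solve to batched t x t
operations.
"""

from __future__ import annotations

import numpy as np

LOG2PI = float(np.log(2.0 * np.pi))


def pack_spd(a: np.ndarray) -> np.ndarray:
    """Log-Cholesky vector of a symmetric positive-definite matrix."""
    t = a.shape[0]
    l = np.linalg.cholesky(a + 1e-12 * np.eye(t))
    out = []
    for i in range(t):
        for j in range(i + 1):
            out.append(np.log(l[i, i]) if i == j else l[i, j])
    return np.array(out)


def unpack_spd(theta: np.ndarray, t: int) -> np.ndarray:
    l = np.zeros((t, t))
    k = 0
    for i in range(t):
        for j in range(i + 1):
            l[i, j] = np.exp(theta[k]) if i == j else theta[k]
            k += 1
    return l @ l.T


def batched_cov(d: np.ndarray, sigma_g: np.ndarray, sigma_e: np.ndarray) -> np.ndarray:
    """V_i = d_i * Sigma_g + Sigma_e, shape (n, t, t)."""
    return d[:, None, None] * sigma_g[None] + sigma_e[None]


def reml_loglik(d: np.ndarray, ystar: np.ndarray, xstar: np.ndarray,
                sigma_g: np.ndarray, sigma_e: np.ndarray) -> float:
    """Restricted log-likelihood of the rotated multi-trait model.

    ystar: (n, t) rotated phenotypes; xstar: (n,) rotated intercept column
    (the fixed-effect design is one intercept per trait).
    """
    n, t = ystar.shape
    v = batched_cov(d, sigma_g, sigma_e)
    try:
        vinv = np.linalg.inv(v)
        sign, logdet = np.linalg.slogdet(v)
        if (sign <= 0).any():
            return -np.inf
    except np.linalg.LinAlgError:
        return -np.inf
    w = np.einsum("i,iab->ab", xstar**2, vinv)
    b = np.einsum("i,iab,ib->a", xstar, vinv, ystar)
    try:
        beta = np.linalg.solve(w, b)
    except np.linalg.LinAlgError:
        return -np.inf
    r = ystar - xstar[:, None] * beta
    quad = float(np.einsum("ia,iab,ib->", r, vinv, r))
    signw, logdetw = np.linalg.slogdet(w)
    if signw <= 0:
        return -np.inf
    return -0.5 * (logdet.sum() + logdetw + quad + (n * t - t) * LOG2PI)


def gls_intercept(d, ystar, xstar, sigma_g, sigma_e):
    """GLS intercepts and residuals in the rotated basis."""
    v = batched_cov(d, sigma_g, sigma_e)
    vinv = np.linalg.inv(v)
    w = np.einsum("i,iab->ab", xstar**2, vinv)
    b = np.einsum("i,iab,ib->a", xstar, vinv, ystar)
    beta = np.linalg.solve(w, b)
    return beta, ystar - xstar[:, None] * beta, vinv, w


def gls_snp_scan(d: np.ndarray, ystar: np.ndarray, xstar: np.ndarray,
                 wstar: np.ndarray, sigma_g: np.ndarray,
                 sigma_e: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-SNP GLS with fixed variance components ("SNP Snappy" style scan).

    For each SNP column the fixed effects are (intercept, SNP dosage) per
    trait; estimates and standard errors come from the inverse coefficient
    matrix of the 2t x 2t normal equations.

    Returns (estimates, ses), each (p, t).  Columns of ``wstar`` with zero
    variance yield NaN rows.
    """
    n, t = ystar.shape
    p = wstar.shape[1]
    v = batched_cov(d, sigma_g, sigma_e)
    vinv = np.linalg.inv(v)

    a_xx = np.einsum("i,iab->ab", xstar**2, vinv)            # (t,t)
    rhs_x = np.einsum("i,iab,ib->a", xstar, vinv, ystar)     # (t,)
    a_xw = np.einsum("i,ij,iab->jab", xstar, wstar, vinv)    # (p,t,t)
    a_ww = np.einsum("ij,iab->jab", wstar**2, vinv)          # (p,t,t)
    rhs_w = np.einsum("ij,iab,ib->ja", wstar, vinv, ystar)   # (p,t)

    est = np.full((p, t), np.nan)
    se = np.full((p, t), np.nan)
    coef = np.empty((2 * t, 2 * t))
    rhs = np.empty(2 * t)
    for j in range(p):
        coef[:t, :t] = a_xx
        coef[:t, t:] = a_xw[j]
        coef[t:, :t] = a_xw[j].T
        coef[t:, t:] = a_ww[j]
        rhs[:t] = rhs_x
        rhs[t:] = rhs_w[j]
        try:
            cinv = np.linalg.inv(coef)
        except np.linalg.LinAlgError:
            continue
        sol = cinv @ rhs
        var = np.diag(cinv)[t:]
        if (var <= 0).any() or not np.isfinite(var).all():
            continue
        est[j] = sol[t:]
        se[j] = np.sqrt(var)
    return est, se


def gls_snp_scan_full_cov(d, ystar, xstar, wstar, sigma_g, sigma_e):
    """As :func:`gls_snp_scan` but also returning the (p, t, t) covariance
    blocks of the SNP coefficient estimates (needed for delta-method SEs of
    derived path effects)."""
    n, t = ystar.shape
    p = wstar.shape[1]
    v = batched_cov(d, sigma_g, sigma_e)
    vinv = np.linalg.inv(v)
    a_xx = np.einsum("i,iab->ab", xstar**2, vinv)
    rhs_x = np.einsum("i,iab,ib->a", xstar, vinv, ystar)
    a_xw = np.einsum("i,ij,iab->jab", xstar, wstar, vinv)
    a_ww = np.einsum("ij,iab->jab", wstar**2, vinv)
    rhs_w = np.einsum("ij,iab,ib->ja", wstar, vinv, ystar)

    est = np.full((p, t), np.nan)
    cov = np.full((p, t, t), np.nan)
    coef = np.empty((2 * t, 2 * t))
    rhs = np.empty(2 * t)
    for j in range(p):
        coef[:t, :t] = a_xx
        coef[:t, t:] = a_xw[j]
        coef[t:, :t] = a_xw[j].T
        coef[t:, t:] = a_ww[j]
        rhs[:t] = rhs_x
        rhs[t:] = rhs_w[j]
        try:
            cinv = np.linalg.inv(coef)
        except np.linalg.LinAlgError:
            continue
        sol = cinv @ rhs
        block = cinv[t:, t:]
        if not np.isfinite(block).all() or (np.diag(block) <= 0).any():
            continue
        est[j] = sol[t:]
        cov[j] = block
    return est, cov
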