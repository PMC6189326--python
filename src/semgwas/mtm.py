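"""Multi-trait mixed model: REML fit, Gibbs sampler, and per-SNP scan.

The model for t traits on n individuals is

    Y = 1 mu' + g + e,   vec(g') ~ N(0, K (x) Sigma_g),
                         vec(e') ~ N(0, I (x) Sigma_e),

with K a relationship matrix (pedigree or genomic).  Rotating by the
eigenvectors of K renders the rows independent with covariance
d_i Sigma_g + Sigma_e, so REML, Gibbs updates and the association scan all
reduce to batched t x t operations.

Two fitting routes are provided: EM-accelerated REML (with an L-BFGS polish)
for point estimates and likelihood-based model comparison, and a Gibbs
sampler (normal / inverse-Wishart full conditionals) whose stored draws of
the residual covariance feed the causal-network search.

The scan holds variance components fixed at their no-SNP estimates and
enters each SNP separately as a fixed covariate for every trait — the
"SNP Snappy" strategy — so a genome of markers costs one GLS solve each.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from ._linalg import (batched_cov, gls_snp_scan, gls_snp_scan_full_cov,
                      pack_spd, reml_loglik, unpack_spd)
from .kinship import KinshipMatrix
from .qc_io import GenotypeMatrix, PhenotypeTable

logger = logging.getLogger(__name__)

DEFAULT_SEED = 20181009


class ConvergenceError(RuntimeError):
    def __init__(self, message, trace=None, last=None):
        super().__init__(message)
        self.trace = trace
        self.last = last


@dataclass
class VarianceComponents:
    """Genetic (Sigma_g) and residual (Sigma_e) trait covariance matrices."""

    sigma_g: np.ndarray
    sigma_e: np.ndarray
    traits: list[str]
    kinship_kind: str = "genomic_G"

    def __post_init__(self) -> None:
        t = len(self.traits)
        self.sigma_g = np.asarray(self.sigma_g, float)
        self.sigma_e = np.asarray(self.sigma_e, float)
        for name, m in (("sigma_g", self.sigma_g), ("sigma_e", self.sigma_e)):
            if m.shape != (t, t):
                raise ValueError(f"{name} must be {t} x {t}")
            if not np.allclose(m, m.T, atol=1e-8):
                raise ValueError(f"{name} must be symmetric")
            if np.linalg.eigvalsh((m + m.T) / 2).min() < -1e-8:
                raise ValueError(f"{name} must be positive semi-definite")


@dataclass
class MixedModelFit:
    vc: VarianceComponents
    logl: float
    k: int
    n_records: int
    label: str = "MTM"
    logl_trace: np.ndarray = field(default_factory=lambda: np.array([]))
    intercepts: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.logl):
            raise ValueError("log-likelihood must be finite")
        if self.k < 1:
            raise ValueError("parameter count must be >= 1")


@dataclass
class PosteriorDraws:
    """Stored Gibbs draws of the two covariance components."""

    sigma_g: np.ndarray  # (S, t, t)
    sigma_e: np.ndarray  # (S, t, t)
    traits: list[str]
    iterations: int
    burn_in: int
    thin: int
    seed: int

    @property
    def n_draws(self) -> int:
        return self.sigma_g.shape[0]

    def posterior_mean(self) -> VarianceComponents:
        return VarianceComponents(self.sigma_g.mean(axis=0),
                                  self.sigma_e.mean(axis=0), list(self.traits))

    def to_frame(self) -> pd.DataFrame:
        """Long-format draws: one row per draw x component x matrix cell."""
        t = len(self.traits)
        rows = []
        for name, stack in (("sigma_g", self.sigma_g), ("sigma_e", self.sigma_e)):
            for a in range(t):
                for b in range(a, t):
                    for s, val in enumerate(stack[:, a, b]):
                        rows.append((s, name, self.traits[a], self.traits[b],
                                     val))
        return pd.DataFrame(rows, columns=["draw", "component", "trait_a",
                                           "trait_b", "value"])

    def write(self, path) -> None:
        """Columnar TSV of the draws plus a JSON metadata sidecar."""
        import json

        self.to_frame().to_csv(path, sep="\t", index=False)
        meta = {"iterations": self.iterations, "burn_in": self.burn_in,
                "thin": self.thin, "seed": self.seed, "traits": self.traits,
                "n_draws": self.n_draws}
        with open(f"{path}.json", "w") as fh:
            json.dump(meta, fh, indent=2)


@dataclass
class SnpScanResult:
    """Per SNP x trait association estimates; tabular, Manhattan-ready."""

    table: pd.DataFrame  # columns: snp, chrom, pos, trait, estimate, se, t, p

    def estimates(self) -> pd.DataFrame:
        return self.table.pivot(index="snp", columns="trait", values="estimate")

    def write(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# shared plumbing
# ---------------------------------------------------------------------------

def _complete_rows(pheno: PhenotypeTable, k: KinshipMatrix):
    """Listwise deletion of incomplete phenotype rows, K subset to match."""
    if pheno.samples != k.samples:
        k = k.subset(pheno.samples)
    ok = np.isfinite(pheno.values).all(axis=1)
    if not ok.all():
        keep = [s for s, o in zip(pheno.samples, ok) if o]
        logger.info("dropping %d incomplete phenotype rows", int((~ok).sum()))
        pheno = PhenotypeTable(keep, list(pheno.traits), pheno.values[ok])
        k = k.subset(keep)
    return pheno, k


def _rotate(pheno: PhenotypeTable, k: KinshipMatrix):
    d, u = k.eigendecomposition()
    ystar = u.T @ pheno.values
    xstar = u.T @ np.ones(len(pheno.samples))
    return d, u, ystar, xstar


# ---------------------------------------------------------------------------
# REML
# ---------------------------------------------------------------------------

def _em_reml_step(d, ystar, xstar, sigma_g, sigma_e):
    """One EM-REML update in the rotated basis (monotone in the REML logL)."""
    n, t = ystar.shape
    v = batched_cov(d, sigma_g, sigma_e)
    vinv = np.linalg.inv(v)
    w = np.einsum("i,iab->ab", xstar**2, vinv)
    winv = np.linalg.inv(w)
    b = np.einsum("i,iab,ib->a", xstar, vinv, ystar)
    beta = winv @ b
    r = ystar - xstar[:, None] * beta
    py = np.einsum("iab,ib->ia", vinv, r)                      # V^-1 (y - Xb)
    # P_ii = V_i^-1 - x_i^2 V_i^-1 W^-1 V_i^-1
    pii = vinv - np.einsum("i,iab,bc,icd->iad", xstar**2, vinv, winv, vinv)
    outer = np.einsum("ia,ib->iab", py, py)
    mg = np.einsum("i,iab->ab", d, outer - pii)
    me = (outer - pii).sum(axis=0)
    sg = sigma_g + sigma_g @ mg @ sigma_g / n
    se = sigma_e + sigma_e @ me @ sigma_e / n
    return (sg + sg.T) / 2, (se + se.T) / 2


def fit_mtm_reml(pheno: PhenotypeTable, k: KinshipMatrix,
                 max_iter: int = 500, tol: float = 1e-8,
                 polish: bool = True, label: str = "MTM",
                 init: tuple[np.ndarray, np.ndarray] | None = None) -> MixedModelFit:
    """REML estimates of Sigma_g and Sigma_e via EM with an L-BFGS polish.

    EM iterates until the relative log-likelihood change drops below ``tol``
    (or ``max_iter`` is hit, raising :class:`ConvergenceError` with the
    trace); a quasi-Newton polish on the log-Cholesky scale then tightens
    the optimum so likelihoods are comparable across model classes.
    The parameter count is k = t(t+1): two free t x t covariance matrices.
    """
    pheno, k = _complete_rows(pheno, k)
    d, _, ystar, xstar = _rotate(pheno, k)
    n, t = ystar.shape
    sample_cov = np.cov(pheno.values, rowvar=False).reshape(t, t)
    if init is not None:
        sigma_g, sigma_e = (np.asarray(m, float).copy() for m in init)
    else:
        sigma_g = 0.5 * sample_cov + 1e-6 * np.eye(t)
        sigma_e = 0.5 * sample_cov + 1e-6 * np.eye(t)

    trace = [reml_loglik(d, ystar, xstar, sigma_g, sigma_e)]
    converged = False
    for _ in range(max_iter):
        sigma_g, sigma_e = _em_reml_step(d, ystar, xstar, sigma_g, sigma_e)
        trace.append(reml_loglik(d, ystar, xstar, sigma_g, sigma_e))
        if abs(trace[-1] - trace[-2]) <= tol * (abs(trace[-2]) + 1.0):
            converged = True
            break
    if not converged and not polish:
        raise ConvergenceError(
            f"EM-REML did not converge in {max_iter} iterations",
            trace=np.array(trace), last=(sigma_g, sigma_e))

    if polish:
        m = t * (t + 1) // 2

        def neg(theta):
            return -reml_loglik(d, ystar, xstar,
                                unpack_spd(theta[:m], t), unpack_spd(theta[m:], t))

        theta0 = np.concatenate([pack_spd(sigma_g + 1e-8 * np.eye(t)),
                                 pack_spd(sigma_e + 1e-8 * np.eye(t))])
        res = optimize.minimize(neg, theta0, method="L-BFGS-B",
                                options={"maxiter": 2000, "ftol": 1e-14,
                                         "gtol": 1e-9})
        if -res.fun >= trace[-1]:
            sigma_g = unpack_spd(res.x[:m], t)
            sigma_e = unpack_spd(res.x[m:], t)
            trace.append(-res.fun)

    vc = VarianceComponents(sigma_g, sigma_e, list(pheno.traits), k.kind)
    return MixedModelFit(vc, logl=trace[-1], k=t * (t + 1), n_records=n,
                         label=label, logl_trace=np.array(trace))


# ---------------------------------------------------------------------------
# Gibbs sampler
# ---------------------------------------------------------------------------

def _batched_chol_psd(c: np.ndarray, eps: float = 1e-12) -> np.ndarray:
    t = c.shape[-1]
    return np.linalg.cholesky(c + eps * np.eye(t))


def fit_mtm_gibbs(pheno: PhenotypeTable, k: KinshipMatrix,
                  iterations: int = 10000, burn_in: int = 2000,
                  thin: int = 10, seed: int = DEFAULT_SEED,
                  prior_df: float | None = None,
                  prior_scale: np.ndarray | float = 0.5) -> PosteriorDraws:
    """Gibbs sampler for the multi-trait animal model.

    Location parameters (intercepts and rotated polygenic values) are drawn
    from their normal full conditionals; Sigma_g and Sigma_e from
    inverse-Wishart full conditionals.  Priors are weakly informative
    inverse-Wisharts with df = t + 2 and scale 0.5 I unless overridden.
    Draws are stored after ``burn_in`` at spacing ``thin``; the stored count
    is (iterations - burn_in) / thin.
    """
    if iterations <= 0 or thin <= 0 or burn_in < 0 or burn_in >= iterations:
        raise ValueError("need 0 <= burn_in < iterations and thin >= 1")
    pheno, k = _complete_rows(pheno, k)
    d, _, ystar, xstar = _rotate(pheno, k)
    n, t = ystar.shape
    nu0 = float(prior_df) if prior_df is not None else t + 2.0
    s0 = prior_scale * np.eye(t) if np.isscalar(prior_scale) else np.asarray(prior_scale, float)
    if np.linalg.eigvalsh((s0 + s0.T) / 2).min() <= 0:
        raise ValueError("inverse-Wishart prior scale must be positive definite")

    rng = np.random.default_rng(seed)
    sample_cov = np.cov(pheno.values, rowvar=False).reshape(t, t)
    sigma_g = 0.5 * sample_cov + 1e-6 * np.eye(t)
    sigma_e = 0.5 * sample_cov + 1e-6 * np.eye(t)
    # start the chain near the REML mode so burn-in only has to cover local
    # mixing, not the trek from a naive starting point
    for _ in range(100):
        new_g, new_e = _em_reml_step(d, ystar, xstar, sigma_g, sigma_e)
        if (np.abs(new_g - sigma_g).max() < 1e-6
                and np.abs(new_e - sigma_e).max() < 1e-6):
            break
        sigma_g, sigma_e = new_g, new_e
    sigma_g = sigma_g + 1e-8 * np.eye(t)
    sigma_e = sigma_e + 1e-8 * np.eye(t)
    pos = d > 1e-10
    n_pos = int(pos.sum())
    d_pos = np.where(pos, d, 1.0)
    a = np.zeros((n, t))
    sxx = float((xstar**2).sum())

    keep_g = np.empty(((iterations - burn_in) // thin, t, t))
    keep_e = np.empty_like(keep_g)
    stored = 0
    for it in range(1, iterations + 1):
        # intercepts | a, Sigma_e
        mu_hat = (xstar @ (ystar - a)) / sxx
        mu = mu_hat + np.linalg.cholesky(sigma_e / sxx) @ rng.standard_normal(t)
        r = ystar - xstar[:, None] * mu
        # rotated polygenic values | mu, Sigma_g, Sigma_e
        v = batched_cov(d, sigma_g, sigma_e)
        vinv = np.linalg.inv(v)
        dg = d[:, None, None] * sigma_g[None]
        mean_a = np.einsum("iab,ibc,ic->ia", dg, vinv, r)
        cov_a = dg - np.einsum("iab,ibc,icd->iad", dg, vinv, dg)
        cov_a = (cov_a + cov_a.transpose(0, 2, 1)) / 2
        la = _batched_chol_psd(cov_a)
        a = mean_a + np.einsum("iab,ib->ia", la, rng.standard_normal((n, t)))
        a[~pos] = 0.0
        # Sigma_g | a   (scaled outer products over informative eigenvalues)
        sg_scatter = np.einsum("ia,ib,i->ab", a, a, pos / d_pos)
        sigma_g = stats.invwishart.rvs(df=nu0 + n_pos, scale=s0 + sg_scatter,
                                       random_state=rng)
        # Sigma_e | residuals
        e = r - a
        se_scatter = e.T @ e
        sigma_e = stats.invwishart.rvs(df=nu0 + n, scale=s0 + se_scatter,
                                       random_state=rng)
        sigma_g = np.atleast_2d(sigma_g)
        sigma_e = np.atleast_2d(sigma_e)
        if it > burn_in and (it - burn_in) % thin == 0:
            keep_g[stored] = sigma_g
            keep_e[stored] = sigma_e
            stored += 1

    return PosteriorDraws(keep_g[:stored], keep_e[:stored], list(pheno.traits),
                          iterations, burn_in, thin, seed)


def _batch_means_var(x: np.ndarray) -> float:
    """Variance of the segment mean, autocorrelation-robust (batch means)."""
    n = len(x)
    n_batches = max(2, int(np.sqrt(n)))
    size = n // n_batches
    means = x[: n_batches * size].reshape(n_batches, size).mean(axis=1)
    return float(means.var(ddof=1) / n_batches)


def geweke_z(draws: np.ndarray, first: float = 0.1, last: float = 0.5) -> float:
    """Geweke convergence z-score comparing early and late chain means,
    with batch-means (autocorrelation-consistent) variance estimates."""
    x = np.asarray(draws, float)
    a = x[: max(4, int(first * len(x)))]
    b = x[-max(4, int(last * len(x))):]
    return float((a.mean() - b.mean())
                 / np.sqrt(_batch_means_var(a) + _batch_means_var(b)))


# ---------------------------------------------------------------------------
# scan
# ---------------------------------------------------------------------------

def mtm_snp_scan(pheno: PhenotypeTable, geno: GenotypeMatrix,
                 k: KinshipMatrix, vc: VarianceComponents,
                 return_cov: bool = False):
    """Per-SNP multi-trait association scan with fixed variance components.

    Each SNP enters the mixed model as one fixed covariate per trait; the
    estimate and its standard error come from the inverse coefficient matrix
    of the GLS normal equations, T = estimate / se, and two-sided p-values
    use the standard normal reference.
    """
    if pheno.samples != geno.samples:
        geno = geno.subset_samples(pheno.samples)
    pheno2, k2 = _complete_rows(pheno, k)
    if pheno2.samples != geno.samples:
        geno = geno.subset_samples(pheno2.samples)
    d, u, ystar, xstar = _rotate(pheno2, k2)
    wstar = u.T @ geno.mean_imputed()

    zero_var = geno.mean_imputed().std(axis=0) == 0.0
    if return_cov:
        est, cov = gls_snp_scan_full_cov(d, ystar, xstar, wstar,
                                         vc.sigma_g, vc.sigma_e)
        se = np.sqrt(np.einsum("jaa->ja", cov))
    else:
        est, se = gls_snp_scan(d, ystar, xstar, wstar, vc.sigma_g, vc.sigma_e)
        cov = None
    est[zero_var] = np.nan
    se[zero_var] = np.nan

    tval = est / se
    pval = 2.0 * stats.norm.sf(np.abs(tval))
    rows = []
    for j, snp in enumerate(geno.snps):
        for a, trait in enumerate(pheno2.traits):
            rows.append((snp.id, snp.chromosome, snp.position, trait,
                         est[j, a], se[j, a], tval[j, a], pval[j, a]))
    table = pd.DataFrame(rows, columns=["snp", "chrom", "pos", "trait",
                                        "estimate", "se", "t", "p"])
    result = SnpScanResult(table)
    if return_cov:
        return result, est, cov
    return result


def model_fit_stats(fit: MixedModelFit, n_records: int | None = None):
    """(logL, -AIC/2, -BIC/2) with AIC = -2 logL + 2k and
    BIC = -2 logL + k ln(n)."""
    n = fit.n_records if n_records is None else n_records
    if n <= 0 or fit.k <= 0:
        raise ValueError("need positive n_records and parameter count")
    half_neg_aic = fit.logl - fit.k
    half_neg_bic = fit.logl - 0.5 * fit.k * np.log(n)
    return fit.logl, half_neg_aic, half_neg_bic
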