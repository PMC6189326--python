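"""Structural equation mixed model GWAS: fit, scan, and effect decomposition.

Given a DAG over traits, the model is

    Y = Lambda Y + W s + g + e,   g ~ N(0, Sigma_g (x) K),  e ~ N(0, Psi (x) I)

with Lambda the structural-coefficient matrix (non-zero only on the DAG's
edges, strictly lower-triangular under a topological order) and Psi a
*diagonal* residual covariance — the restriction that renders the structural
coefficients likelihood-identifiable.  Premultiplying by (I - Lambda) turns
the system into a multi-trait mixed model on transformed responses, so the
REML machinery of :mod:`semgwas.mtm` applies directly; the reduced form
y = (I - Lambda)^-1 (W s + g + e) establishes the likelihood equivalence
with the ordinary multi-trait model.

A SNP's coefficient in a trait's equation is its *direct* effect.  Effects
transmitted through the trait network are recovered by path tracing: each
directed path from an upstream trait to the target contributes the product
of the structural coefficients along the path times the SNP's direct effect
on the path's head, the indirect effect is the sum over paths, and the total
effect is direct + indirect — equal to the reduced-form matrix product
(I - Lambda)^-1 applied to the vector of direct effects.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import optimize, stats

from ._linalg import pack_spd, reml_loglik, unpack_spd
from .kinship import KinshipMatrix
from .mtm import (MixedModelFit, SnpScanResult, VarianceComponents,
                  _complete_rows, _rotate, mtm_snp_scan)
from .netsearch import CausalStructure
from .qc_io import GenotypeMatrix, PhenotypeTable

logger = logging.getLogger(__name__)


class ConfigurationError(ValueError):
    pass


@dataclass
class StructuralCoefficients:
    """Structural-coefficient matrix Lambda with per-edge standard errors.

    ``lam[i, j]`` is the coefficient on the edge trait_j -> trait_i; entries
    off the DAG's edges are exactly zero.
    """

    traits: list[str]
    lam: np.ndarray
    se: np.ndarray
    edges: list[tuple[str, str]]  # (parent, child)

    def __post_init__(self) -> None:
        t = len(self.traits)
        self.lam = np.asarray(self.lam, float)
        if np.any(np.diag(self.lam) != 0):
            raise ValueError("Lambda must have a zero diagonal")
        idx = {x: i for i, x in enumerate(self.traits)}
        allowed = {(idx[c], idx[p]) for p, c in self.edges}
        nz = {tuple(ij) for ij in np.argwhere(self.lam != 0)}
        if not nz <= allowed:
            raise ValueError("Lambda has entries off the DAG's edges")
        if np.linalg.matrix_rank(np.eye(t) - self.lam) < t:
            raise ValueError("(I - Lambda) must be invertible")

    def gamma(self) -> np.ndarray:
        """(I - Lambda)^-1, the reduced-form multiplier."""
        return np.linalg.inv(np.eye(len(self.traits)) - self.lam)

    def to_frame(self) -> pd.DataFrame:
        idx = {x: i for i, x in enumerate(self.traits)}
        rows = [(p, c, self.lam[idx[c], idx[p]], self.se[idx[c], idx[p]])
                for p, c in self.edges]
        return pd.DataFrame(rows, columns=["from", "to", "coefficient", "se"])


@dataclass
class SEMFit:
    structure: CausalStructure
    coefficients: StructuralCoefficients
    sigma_g: np.ndarray
    psi: np.ndarray  # diagonal residual variances, shape (t,)
    logl: float
    k: int
    n_records: int
    traits: list[str]
    cov_lambda: np.ndarray = field(default_factory=lambda: np.zeros((0, 0)))
    label: str = "SEM"

    def __post_init__(self) -> None:
        if (np.asarray(self.psi) <= 0).any():
            raise ValueError("Psi must have positive diagonal entries")

    @property
    def vc(self) -> VarianceComponents:
        return VarianceComponents(self.sigma_g, np.diag(self.psi),
                                  list(self.traits))


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _dag_edges(dag: CausalStructure, traits: list[str]) -> list[tuple[str, str]]:
    if dag.status != "dag":
        raise ValueError("SEM requires a fully directed structure "
                         "(complete the PDAG with orient_with_order)")
    if set(dag.nodes) != set(traits):
        raise ValueError("structure nodes must match the phenotype traits")
    if not dag.is_acyclic():
        raise ValueError("structure must be acyclic")
    order = list(nx.topological_sort(dag.to_digraph()))
    rank = {x: i for i, x in enumerate(order)}
    return sorted(dag.directed, key=lambda e: (rank[e[1]], rank[e[0]]))


def fit_sem(pheno: PhenotypeTable, k: KinshipMatrix, dag: CausalStructure,
            psi_diagonal: bool = True, diag_sigma_g: bool = False,
            label: str = "SEM") -> SEMFit:
    """REML fit of the recursive structural equation mixed model.

    The structural coefficients, the genetic covariance Sigma_g, and the
    diagonal residual variances Psi are estimated jointly by maximizing the
    restricted likelihood of the transformed system
    (I - Lambda) Y = mu + g + e on the eigenbasis of K.  Standard errors of
    the coefficients come from the observed information (numerical Hessian).
    The parameter count is k = (#edges) + t(t+1)/2 + t.
    """
    if not psi_diagonal:
        raise ConfigurationError(
            "a diagonal residual covariance is required to render structural "
            "coefficients likelihood-identifiable")
    pheno, k = _complete_rows(pheno, k)
    traits = list(pheno.traits)
    t = len(traits)
    idx = {x: i for i, x in enumerate(traits)}
    edges = _dag_edges(dag, traits)
    e_idx = [(idx[c], idx[p]) for p, c in edges]
    n_lam = len(edges)
    m = t * (t + 1) // 2 if not diag_sigma_g else t

    d, _, ystar, xstar = _rotate(pheno, k)
    n = len(pheno.samples)

    def build(theta):
        lam = np.zeros((t, t))
        for val, (i, j) in zip(theta[:n_lam], e_idx):
            lam[i, j] = val
        if diag_sigma_g:
            sigma_g = np.diag(np.exp(theta[n_lam:n_lam + t]))
        else:
            sigma_g = unpack_spd(theta[n_lam:n_lam + m], t)
        psi = np.exp(theta[n_lam + m:])
        return lam, sigma_g, psi

    def neg(theta):
        lam, sigma_g, psi = build(theta)
        zstar = ystar @ (np.eye(t) - lam).T
        return -reml_loglik(d, zstar, xstar, sigma_g, np.diag(psi))

    # starting values: OLS of each child on its parents, halved sample variances
    lam0 = np.zeros(n_lam)
    y = pheno.values
    for e, (i, j) in enumerate(e_idx):
        pa = [jj for (ii, jj) in e_idx if ii == i]
        x = np.column_stack([np.ones(n)] + [y[:, jj] for jj in pa])
        beta, *_ = np.linalg.lstsq(x, y[:, i], rcond=None)
        lam0[e] = beta[1 + pa.index(j)]
    lam_mat0 = np.zeros((t, t))
    for val, (i, j) in zip(lam0, e_idx):
        lam_mat0[i, j] = val
    resid0 = y @ (np.eye(t) - lam_mat0).T
    v0 = resid0.var(axis=0, ddof=1)
    if diag_sigma_g:
        sg0 = np.log(0.5 * v0 + 1e-8)
    else:
        sg0 = pack_spd(np.diag(0.5 * v0) + 1e-8 * np.eye(t))
    theta0 = np.concatenate([lam0, sg0, np.log(0.5 * v0 + 1e-8)])

    res = optimize.minimize(neg, theta0, method="L-BFGS-B",
                            options={"maxiter": 3000, "ftol": 1e-14,
                                     "gtol": 1e-9})
    theta = res.x
    lam, sigma_g, psi = build(theta)
    logl = -res.fun
    if not np.isfinite(logl):
        raise RuntimeError("SEM REML optimization failed to produce a finite "
                           "log-likelihood")

    cov_lambda, lam_se = _lambda_covariance(neg, theta, n_lam, e_idx, t)
    se_mat = np.zeros((t, t))
    for s, (i, j) in zip(lam_se, e_idx):
        se_mat[i, j] = s
    coeffs = StructuralCoefficients(traits, lam, se_mat, edges)
    struct = CausalStructure(list(dag.nodes), set(), set(dag.directed),
                             dict(dag.sepsets), status="dag", lam=lam)
    k_params = n_lam + m + t
    return SEMFit(struct, coeffs, sigma_g, psi, logl, k_params, n,
                  traits, cov_lambda, label=label)


def _lambda_covariance(neg, theta, n_lam, e_idx, t):
    """Observed-information covariance of the lambda block via a central
    finite-difference Hessian over all free parameters."""
    if n_lam == 0:
        return np.zeros((0, 0)), np.zeros(0)
    p = len(theta)
    h = 1e-4 * np.maximum(np.abs(theta), 1.0)
    hess = np.empty((p, p))
    f0 = neg(theta)
    for a in range(p):
        for b in range(a, p):
            ta = np.zeros(p); ta[a] = h[a]
            tb = np.zeros(p); tb[b] = h[b]
            if a == b:
                val = (neg(theta + ta) - 2 * f0 + neg(theta - ta)) / h[a] ** 2
            else:
                val = (neg(theta + ta + tb) - neg(theta + ta - tb)
                       - neg(theta - ta + tb) + neg(theta - ta - tb)) / (4 * h[a] * h[b])
            hess[a, b] = hess[b, a] = val
    try:
        cov = np.linalg.inv(hess)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(hess)
    block = cov[:n_lam, :n_lam]
    var = np.clip(np.diag(block), 0.0, None)
    return block, np.sqrt(var)


# ---------------------------------------------------------------------------
# scan
# ---------------------------------------------------------------------------

def sem_snp_scan(pheno: PhenotypeTable, geno: GenotypeMatrix,
                 k: KinshipMatrix, fit: SEMFit, return_cov: bool = False):
    """Per-SNP scan for *direct* effects under a fitted SEM.

    With Lambda and the variance components held fixed at their no-SNP
    estimates, each trait equation is y_t = mu_t + sum_parents lambda y_p +
    w_j s_jt + g_t + e_t.  Premultiplying the system by (I - Lambda) reduces
    this to the fixed-component GLS scan on transformed phenotypes, so the
    machinery is shared with the multi-trait scan.
    """
    t = len(fit.traits)
    trans = PhenotypeTable(list(pheno.samples), list(pheno.traits),
                           pheno.values @ (np.eye(t) - fit.coefficients.lam).T)
    return mtm_snp_scan(trans, geno, k, fit.vc, return_cov=return_cov)


# ---------------------------------------------------------------------------
# path enumeration and decomposition
# ---------------------------------------------------------------------------

def total_effect_reduced_form(lam: np.ndarray, direct: np.ndarray) -> np.ndarray:
    """Total SNP effects from the reduced form, T = (I - Lambda)^-1 direct.

    Serves as the closed-form oracle for the path-by-path sum.
    """
    lam = np.asarray(lam, float)
    t = lam.shape[0]
    return np.linalg.solve(np.eye(t) - lam, np.asarray(direct, float))


def enumerate_indirect_paths(dag: CausalStructure, lam: np.ndarray,
                             direct: np.ndarray, target: str
                             ) -> list[tuple[tuple[str, ...], float]]:
    """All indirect contributions to ``target``: one entry per directed path
    from a trait with a non-zero direct effect down to the target, each worth
    (product of structural coefficients along the path) x (direct effect at
    the path's head).  The target's own direct effect is excluded."""
    g = dag.to_digraph()
    idx = {x: i for i, x in enumerate(dag.nodes)}
    out = []
    for source in dag.nodes:
        if source == target or direct[idx[source]] == 0.0:
            continue
        for path in nx.all_simple_paths(g, source, target):
            coef = 1.0
            for p, c in zip(path[:-1], path[1:]):
                coef *= lam[idx[c], idx[p]]
            out.append((tuple(path), coef * direct[idx[source]]))
    return out


def decompose_snp_effect(dag: CausalStructure, lam: np.ndarray,
                         direct: np.ndarray, cov_direct: np.ndarray | None = None,
                         cov_lambda: np.ndarray | None = None,
                         edges: list[tuple[str, str]] | None = None) -> pd.DataFrame:
    """Decompose one SNP's effects into direct, per-path indirect, and total.

    Standard errors use the first-order delta method over the direct-effect
    estimates and the structural coefficients, treated as independent blocks.
    Returns a tidy frame with one row per trait x effect type plus one row
    per indirect path.
    """
    traits = list(dag.nodes)
    t = len(traits)
    idx = {x: i for i, x in enumerate(traits)}
    lam = np.asarray(lam, float)
    direct = np.asarray(direct, float)
    gamma = np.linalg.inv(np.eye(t) - lam)
    total = gamma @ direct
    cov_d = np.zeros((t, t)) if cov_direct is None else np.asarray(cov_direct, float)
    e_idx = [(idx[c], idx[p]) for p, c in edges] if edges else []
    cov_l = (np.zeros((len(e_idx), len(e_idx))) if cov_lambda is None or not e_idx
             else np.asarray(cov_lambda, float)[:len(e_idx), :len(e_idx)])

    # jacobian of the total w.r.t. each structural coefficient:
    # dT/dlam_(i,j) = Gamma E_ij Gamma direct
    jac_l = np.zeros((t, len(e_idx)))
    for col, (i, j) in enumerate(e_idx):
        jac_l[:, col] = gamma[:, i] * (gamma @ direct)[j]

    var_total = np.einsum("ab,bc,ac->a", gamma, cov_d, gamma) \
        + np.einsum("ae,ef,af->a", jac_l, cov_l, jac_l)
    gm1 = gamma - np.eye(t)
    var_ind = np.einsum("ab,bc,ac->a", gm1, cov_d, gm1) \
        + np.einsum("ae,ef,af->a", jac_l, cov_l, jac_l)

    rows = []
    for trait in traits:
        a = idx[trait]
        d_val = direct[a]
        se_d = np.sqrt(max(cov_d[a, a], 0.0))
        paths = enumerate_indirect_paths(dag, lam, direct, trait)
        ind = float(sum(c for _, c in paths))
        tot = float(total[a])
        se_t = float(np.sqrt(max(var_total[a], 0.0)))
        se_i = float(np.sqrt(max(var_ind[a], 0.0)))
        for etype, est, se in (("direct", d_val, se_d), ("indirect", ind, se_i),
                               ("total", tot, se_t)):
            tval = est / se if se > 0 else np.nan
            pval = 2 * stats.norm.sf(abs(tval)) if np.isfinite(tval) else np.nan
            rows.append((trait, etype, est, se, tval, pval,
                         ";".join("->".join(p) for p, _ in paths)
                         if etype == "indirect" else ""))
        for path, contrib in paths:
            rows.append((trait, "path", float(contrib), np.nan, np.nan, np.nan,
                         "->".join(path)))
    return pd.DataFrame(rows, columns=["trait", "effect_type", "estimate",
                                       "se", "t", "p", "paths"])


def decomposition_scan(pheno: PhenotypeTable, geno: GenotypeMatrix,
                       k: KinshipMatrix, fit: SEMFit,
                       mtm_vc: VarianceComponents | None = None,
                       fdr_q: float = 0.05) -> pd.DataFrame:
    """Genome scan with full effect decomposition and per-type BH q-values.

    One row per SNP x trait x effect type (direct / indirect / total, plus
    ``mtm`` rows when the multi-trait variance components are supplied);
    ``paths`` holds the semicolon-joined indirect path strings.
    """
    scan, est, cov = sem_snp_scan(pheno, geno, k, fit, return_cov=True)
    traits = list(fit.traits)
    t = len(traits)
    dag = fit.structure
    lam = fit.coefficients.lam
    snp_meta = [(s.id, s.chromosome, s.position) for s in geno.snps]
    frames = []
    for j, (sid, chrom, pos) in enumerate(snp_meta):
        if not np.isfinite(est[j]).all():
            continue
        dec = decompose_snp_effect(dag, lam, est[j], cov[j], fit.cov_lambda,
                                   fit.coefficients.edges)
        dec = dec[dec.effect_type != "path"].copy()
        dec.insert(0, "pos", pos)
        dec.insert(0, "chrom", chrom)
        dec.insert(0, "snp", sid)
        frames.append(dec)
    table = pd.concat(frames, ignore_index=True)
    if mtm_vc is not None:
        mtm = mtm_snp_scan(pheno, geno, k, mtm_vc).table.copy()
        mtm["effect_type"] = "mtm"
        mtm["paths"] = ""
        table = pd.concat([table, mtm[table.columns]], ignore_index=True)
    table["q"] = np.nan
    for etype, grp in table.groupby("effect_type"):
        ok = np.isfinite(grp.p.to_numpy())
        if ok.any():
            qv, _ = bh_fdr(grp.p.to_numpy()[ok], q=fdr_q)
            table.loc[grp.index[ok], "q"] = qv
    return table


# ---------------------------------------------------------------------------
# multiple testing and model comparison
# ---------------------------------------------------------------------------

def bh_fdr(pvalues, q: float = 0.05) -> tuple[np.ndarray, float | None]:
    """Benjamini-Hochberg step-up q-values and the significance cutoff.

    Returns (q-values in input order, -log10 of the largest rejected
    p-value, or None when nothing is rejected at level ``q``).
    """
    p = np.asarray(pvalues, float)
    if ((p <= 0) | (p > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    m = len(p)
    order = np.argsort(p)
    ranked = p[order]
    qv = ranked * m / np.arange(1, m + 1)
    qv = np.minimum.accumulate(qv[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(qv, 1.0)
    rejected = ranked[ranked <= np.arange(1, m + 1) * q / m]
    cutoff = float(-np.log10(rejected[-1])) if rejected.size else None
    return out, cutoff


def compare_models(fits: list, n_records: int | None = None) -> pd.DataFrame:
    """Side-by-side (logL, -AIC/2, -BIC/2) table for fits on the same data."""
    ns = {f.n_records for f in fits}
    if len(ns) > 1:
        raise ValueError(f"fits were made on different record counts: {ns}")
    n = n_records if n_records is not None else ns.pop()
    rows = []
    for f in fits:
        rows.append((f.label, f.logl, f.logl - f.k,
                     f.logl - 0.5 * f.k * np.log(n), f.k))
    return pd.DataFrame(rows, columns=["model", "logL", "half_neg_aic",
                                       "half_neg_bic", "k"])
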