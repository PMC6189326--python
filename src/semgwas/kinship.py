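"""Relationship matrices: marker-based GRM (VanRaden) and pedigree NRM.

Both matrices play the same role in the mixed model: the covariance of the
polygenic effects is the Kronecker product of the genetic covariance between
traits and the relationship matrix between individuals.  The GRM measures
realized allele sharing, G = MM' / (2 * sum_j p_j q_j) with M the dosage
matrix centred by twice the allele frequency; the numerator relationship
matrix A holds expected additive relationships computed from the pedigree by
the tabular method.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .qc_io import UNKNOWN_PARENT, GenotypeMatrix, PedigreeTable

logger = logging.getLogger(__name__)

_EIG_FLOOR = -1e-8
_JITTER = 1e-8


@dataclass
class KinshipMatrix:
    """Symmetric PSD relationship matrix over an ordered sample list."""

    samples: list[str]
    values: np.ndarray
    kind: str = "genomic_G"
    _eig: tuple | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.samples)
        if self.values.shape != (n, n):
            raise ValueError("kinship matrix must be n x n for n samples")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("kinship matrix must be symmetric")
        diag = np.diag(self.values)
        if np.count_nonzero(self.values - np.diag(diag)) == 0:
            self._eig = (np.clip(diag, 0.0, None), np.eye(n))
            return
        d, u = np.linalg.eigh(self.values)
        if d.min() < _EIG_FLOOR:
            self.values = self.values + _JITTER * np.eye(n)
            d = d + _JITTER
            logger.info("kinship %s: smallest eigenvalue %.3e, added %.0e jitter",
                        self.kind, d.min() - _JITTER, _JITTER)
        self._eig = (np.clip(d, 0.0, None), u)

    @property
    def n(self) -> int:
        return len(self.samples)

    def eigendecomposition(self) -> tuple[np.ndarray, np.ndarray]:
        """(eigenvalues clipped at 0, eigenvectors); computed once."""
        return self._eig

    def subset(self, keep_ids: list[str]) -> "KinshipMatrix":
        idx = {s: i for i, s in enumerate(self.samples)}
        rows = np.array([idx[s] for s in keep_ids])
        return KinshipMatrix(list(keep_ids), self.values[np.ix_(rows, rows)],
                             self.kind)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.samples, columns=self.samples)

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t")

    @classmethod
    def read(cls, path, kind: str = "genomic_G") -> "KinshipMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(df.index.astype(str)), df.to_numpy(float), kind)


def grm_vanraden(g: GenotypeMatrix) -> KinshipMatrix:
    """Marker-based relationship matrix, G = MM' / (2 sum p_j q_j).

    M is the dosage matrix centred column-wise by 2 p_j, with p_j the
    observed A-allele frequency.  Monomorphic columns are centred to zero
    and excluded from the denominator sum.  Missing dosages must be imputed
    first (the per-SNP-mean imputation of :class:`GenotypeMatrix` is used).
    """
    if g.n_samples < 2 or g.n_snps < 1:
        raise ValueError("GRM needs at least 2 samples and 1 SNP")
    w = g.mean_imputed()
    p = w.mean(axis=0) / 2.0
    poly = (p > 0.0) & (p < 1.0)
    denom = 2.0 * float((p[poly] * (1.0 - p[poly])).sum())
    if denom == 0.0:
        raise ValueError("all SNPs monomorphic: VanRaden denominator is zero")
    m = w - 2.0 * p
    values = (m @ m.T) / denom
    return KinshipMatrix(list(g.samples), values, kind="genomic_G")


def nrm_from_pedigree(ped: PedigreeTable) -> KinshipMatrix:
    """Numerator relationship matrix by the tabular method.

    Individuals are processed parents-first; founders get diagonal 1, and
    for individual i with parents (s, d):
    A(i, j) = (A(j, s) + A(j, d)) / 2 for earlier j, and
    A(i, i) = 1 + A(s, d) / 2.  An unknown parent contributes zero.
    """
    order = ped.topological_order()
    n = len(ped)
    pos_in_order = {ped.individuals[i]: k for k, i in enumerate(order)}
    a = np.zeros((n, n))
    parent_idx: list[tuple[int, int]] = []
    for i in order:
        si = pos_in_order.get(ped.sires[i], -1) if ped.sires[i] != UNKNOWN_PARENT else -1
        di = pos_in_order.get(ped.dams[i], -1) if ped.dams[i] != UNKNOWN_PARENT else -1
        parent_idx.append((si, di))
    for k in range(n):
        si, di = parent_idx[k]
        rel = np.zeros(k)
        if si >= 0:
            rel += 0.5 * a[:k, si]
        if di >= 0:
            rel += 0.5 * a[:k, di]
        a[k, :k] = rel
        a[:k, k] = rel
        a[k, k] = 1.0 + (0.5 * a[si, di] if si >= 0 and di >= 0 else 0.0)
    # back to the pedigree's own individual order
    perm = np.argsort([pos_in_order[ind] for ind in ped.individuals])
    inv = np.empty(n, dtype=int)
    inv[perm] = np.arange(n)
    reorder = np.array([pos_in_order[ind] for ind in ped.individuals])
    values = a[np.ix_(reorder, reorder)]
    return KinshipMatrix(list(ped.individuals), values, kind="pedigree_A")
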