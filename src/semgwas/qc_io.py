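"""Genotype/phenotype/pedigree I/O, marker quality control, and phenotype pre-adjustment.

Genotypes are additively coded dosages (number of A alleles, 0/1/2) read
either from a plain tab-separated matrix (header = SNP ids, first column =
sample id) or from a PLINK ``.raw`` additive export (six leading columns
FID/IID/PAT/MAT/SEX/PHENOTYPE).  Marker QC applies the usual filters in a
fixed attribution order: minor-allele frequency, call rate, then a 1-df
Hardy-Weinberg chi-square test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: sentinel for an unknown parent in pedigree files
UNKNOWN_PARENT = "0"

PLINK_RAW_LEAD_COLUMNS = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]


class FormatError(ValueError):
    """Malformed input file (header or table shape)."""


@dataclass
class SnpRecord:
    id: str
    chromosome: str = "0"
    position: int = 0
    allele_a: str = "A"
    allele_b: str = "B"


@dataclass
class GenotypeMatrix:
    """n x p additive dosage matrix with SNP metadata.

    ``dosages`` is a float array holding counts of the A allele in
    {0, 1, 2}; missing calls are NaN.
    """

    samples: list[str]
    snps: list[SnpRecord]
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.samples), len(self.snps)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.samples)} samples x {len(self.snps)} SNPs"
            )
        ids = [s.id for s in self.snps]
        if len(set(ids)) != len(ids):
            raise ValueError("SNP identifiers must be unique")
        valid = np.isnan(self.dosages) | np.isin(self.dosages, (0.0, 1.0, 2.0))
        if not valid.all():
            i, j = np.argwhere(~valid)[0]
            raise ValueError(
                f"dosage {self.dosages[i, j]!r} outside {{0,1,2,NA}} at "
                f"sample {self.samples[i]!r}, SNP {self.snps[j].id!r}"
            )

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def snp_ids(self) -> list[str]:
        return [s.id for s in self.snps]

    def allele_frequencies(self) -> np.ndarray:
        """Observed A-allele frequency per SNP over non-missing calls."""
        return np.nanmean(self.dosages, axis=0) / 2.0

    def call_rate(self) -> np.ndarray:
        return 1.0 - np.isnan(self.dosages).mean(axis=0)

    def mean_imputed(self) -> np.ndarray:
        """Dosages with missing calls replaced by the per-SNP mean."""
        out = self.dosages.copy()
        mask = np.isnan(out)
        if mask.any():
            col_mean = np.nanmean(np.where(mask, np.nan, out), axis=0)
            col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
            out[mask] = np.broadcast_to(col_mean, out.shape)[mask]
        return out

    def subset_snps(self, keep: np.ndarray) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        return GenotypeMatrix(
            samples=list(self.samples),
            snps=[self.snps[j] for j in np.flatnonzero(keep)] if keep.dtype == bool
            else [self.snps[j] for j in keep],
            dosages=self.dosages[:, keep],
        )

    def subset_samples(self, keep_ids: list[str]) -> "GenotypeMatrix":
        idx = {s: i for i, s in enumerate(self.samples)}
        rows = [idx[s] for s in keep_ids]
        return GenotypeMatrix(list(keep_ids), list(self.snps), self.dosages[rows])


@dataclass
class PhenotypeTable:
    samples: list[str]
    traits: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.samples), len(self.traits)):
            raise ValueError("phenotype shape does not match samples x traits")
        if len(self.traits) < 1:
            raise ValueError("at least one trait required")

    @property
    def n_traits(self) -> int:
        return len(self.traits)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.samples, columns=self.traits)


@dataclass
class PedigreeTable:
    """Records of (individual, sire, dam); ``'0'`` marks an unknown parent."""

    individuals: list[str]
    sires: list[str]
    dams: list[str]

    def __post_init__(self) -> None:
        if not (len(self.individuals) == len(self.sires) == len(self.dams)):
            raise ValueError("pedigree columns must have equal length")
        if len(set(self.individuals)) != len(self.individuals):
            raise ValueError("duplicate individual in pedigree")

    def __len__(self) -> int:
        return len(self.individuals)

    def topological_order(self) -> list[int]:
        """Indices ordered parents-before-offspring; raises on a cycle."""
        pos = {ind: i for i, ind in enumerate(self.individuals)}
        state = np.zeros(len(self), dtype=int)  # 0 new, 1 active, 2 done
        order: list[int] = []

        def visit(i: int, trail: list[str]) -> None:
            if state[i] == 2:
                return
            if state[i] == 1:
                cycle = trail[trail.index(self.individuals[i]):] + [self.individuals[i]]
                raise ValueError(f"pedigree contains a cycle: {' -> '.join(cycle)}")
            state[i] = 1
            trail.append(self.individuals[i])
            for parent in (self.sires[i], self.dams[i]):
                if parent != UNKNOWN_PARENT and parent in pos:
                    visit(pos[parent], trail)
            trail.pop()
            state[i] = 2
            order.append(i)

        for i in range(len(self)):
            visit(i, [])
        return order


@dataclass
class QCReport:
    n_input: int
    removed_maf: int = 0
    removed_call_rate: int = 0
    removed_hwe: int = 0
    retained: int = 0
    removed_snps: dict[str, str] = field(default_factory=dict)

    @property
    def removed(self) -> int:
        return self.removed_maf + self.removed_call_rate + self.removed_hwe

    def check_conserved(self) -> bool:
        return self.removed + self.retained == self.n_input

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "filter": ["maf", "call_rate", "hwe", "retained"],
                "count": [self.removed_maf, self.removed_call_rate,
                          self.removed_hwe, self.retained],
            }
        )


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _parse_dosage_block(df: pd.DataFrame, samples: list[str]) -> np.ndarray:
    block = df.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    finite = block[np.isfinite(block)]
    bad = ~np.isin(finite, (0.0, 1.0, 2.0))
    if bad.any():
        mask = np.isfinite(block) & ~np.isin(block, (0.0, 1.0, 2.0))
        i, j = np.argwhere(mask)[0]
        raise ValueError(
            f"dosage {block[i, j]} outside {{0,1,2}} at sample "
            f"{samples[i]!r}, column {df.columns[j]!r}"
        )
    return block


def read_genotypes(path, dialect: str = "additive-tsv",
                   snp_map: pd.DataFrame | None = None) -> GenotypeMatrix:
    """Read an additive dosage matrix.

    dialect ``'additive-tsv'``: header row of SNP ids, first column sample id.
    dialect ``'plink-raw'``: PLINK --recode A export; the six leading columns
    are skipped and SNP ids keep their ``_ALLELE`` suffix stripped.
    An optional ``snp_map`` frame (columns chrom/id/cm/pos/a1/a2, .bim layout)
    attaches positions.
    """
    df = pd.read_csv(path, sep=r"\s+", dtype=str)
    if dialect == "additive-tsv":
        if df.shape[1] < 2:
            raise FormatError(f"{path}: expected a sample column plus SNP columns")
        samples = df.iloc[:, 0].tolist()
        snp_cols = list(df.columns[1:])
        block = _parse_dosage_block(df.iloc[:, 1:], samples)
    elif dialect == "plink-raw":
        if list(df.columns[:6]) != PLINK_RAW_LEAD_COLUMNS:
            raise FormatError(
                f"{path}: PLINK .raw header must start with "
                f"{' '.join(PLINK_RAW_LEAD_COLUMNS)}"
            )
        samples = df["IID"].tolist()
        snp_cols = [c.rsplit("_", 1)[0] if "_" in c else c for c in df.columns[6:]]
        block = _parse_dosage_block(df.iloc[:, 6:], samples)
    else:
        raise ValueError(f"unknown genotype dialect {dialect!r}")

    records = {r.id: r for r in _snp_records_from_map(snp_map)} if snp_map is not None else {}
    snps = [records.get(c, SnpRecord(id=c)) for c in snp_cols]
    logger.info("read %d samples x %d SNPs from %s", len(samples), len(snps), path)
    return GenotypeMatrix(samples, snps, block)


def _snp_records_from_map(bim: pd.DataFrame) -> list[SnpRecord]:
    cols = list(bim.columns)
    if len(cols) < 6:
        raise FormatError("SNP map needs 6 columns: chrom id cm pos A1 A2")
    return [
        SnpRecord(id=str(r[cols[1]]), chromosome=str(r[cols[0]]),
                  position=int(r[cols[3]]), allele_a=str(r[cols[4]]),
                  allele_b=str(r[cols[5]]))
        for _, r in bim.iterrows()
    ]


def write_genotypes(g: GenotypeMatrix, path, dialect: str = "additive-tsv") -> None:
    if dialect == "additive-tsv":
        df = pd.DataFrame(g.dosages, columns=g.snp_ids)
        df.insert(0, "sample", g.samples)
    elif dialect == "plink-raw":
        df = pd.DataFrame(g.dosages,
                          columns=[f"{s.id}_{s.allele_a}" for s in g.snps])
        for col, val in zip(reversed(PLINK_RAW_LEAD_COLUMNS),
                            reversed([g.samples, g.samples, ["0"] * g.n_samples,
                                      ["0"] * g.n_samples, ["0"] * g.n_samples,
                                      ["-9"] * g.n_samples])):
            df.insert(0, col, val)
    else:
        raise ValueError(f"unknown genotype dialect {dialect!r}")
    out = df.copy()
    dose_cols = out.columns[1:] if dialect == "additive-tsv" else out.columns[6:]
    for c in dose_cols:
        out[c] = out[c].map(lambda v: "NA" if pd.isna(v) else str(int(v)))
    out.to_csv(path, sep="\t", index=False)


def read_phenotypes(path) -> PhenotypeTable:
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    samples = df.iloc[:, 0].astype(str).tolist()
    traits = list(df.columns[1:])
    values = df.iloc[:, 1:].apply(pd.to_numeric, errors="coerce").to_numpy(float)
    return PhenotypeTable(samples, traits, values)


def write_phenotypes(pheno: PhenotypeTable, path) -> None:
    df = pheno.to_frame().reset_index(names="sample")
    df.to_csv(path, sep="\t", index=False)


def read_pedigree(path) -> PedigreeTable:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 3:
        raise FormatError(f"{path}: pedigree needs columns id, sire, dam")
    return PedigreeTable(df.iloc[:, 0].tolist(), df.iloc[:, 1].tolist(),
                         df.iloc[:, 2].tolist())


def write_pedigree(ped: PedigreeTable, path) -> None:
    pd.DataFrame({"id": ped.individuals, "sire": ped.sires,
                  "dam": ped.dams}).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------

def hwe_chisq(n_aa: int, n_ab: int, n_bb: int) -> tuple[float, float]:
    """1-df Hardy-Weinberg goodness-of-fit chi-square for genotype counts.

    Counts are (AA, Aa, aa).  The allele frequency is estimated from the
    counts; expected genotype frequencies are p^2, 2pq, q^2.  A monomorphic
    sample fits HWE perfectly and returns (0, 1).
    """
    counts = np.array([n_aa, n_ab, n_bb], dtype=float)
    if (counts < 0).any():
        raise ValueError("genotype counts must be non-negative")
    total = counts.sum()
    if total == 0:
        raise ValueError("cannot test HWE on zero genotype counts")
    p = (2 * counts[0] + counts[1]) / (2 * total)
    q = 1.0 - p
    if p == 0.0 or q == 0.0:
        return 0.0, 1.0
    expected = total * np.array([p * p, 2 * p * q, q * q])
    chi2 = float(((counts - expected) ** 2 / expected).sum())
    return chi2, float(stats.chi2.sf(chi2, df=1))


def _hwe_pvalues(dosages: np.ndarray) -> np.ndarray:
    out = np.ones(dosages.shape[1])
    for j in range(dosages.shape[1]):
        col = dosages[:, j]
        col = col[np.isfinite(col)]
        if col.size == 0:
            continue
        out[j] = hwe_chisq(int((col == 2).sum()), int((col == 1).sum()),
                           int((col == 0).sum()))[1]
    return out


def apply_qc(g: GenotypeMatrix, maf_min: float = 0.01,
             call_rate_min: float = 0.95,
             hwe_p_min: float = 1e-6) -> tuple[GenotypeMatrix, QCReport]:
    """Filter SNPs on MAF, call rate and HWE (in that attribution order).

    A SNP failing several filters is counted against the first one it fails,
    so the report's removal counts always add up to the input SNP count.
    """
    for thr in (maf_min, call_rate_min, hwe_p_min):
        if not 0.0 <= thr <= 1.0:
            raise ValueError("QC thresholds must lie in [0, 1]")
    report = QCReport(n_input=g.n_snps)
    freq = g.allele_frequencies()
    maf = np.minimum(freq, 1.0 - freq)
    maf = np.where(np.isnan(maf), 0.0, maf)
    call = g.call_rate()
    hwe_p = _hwe_pvalues(g.dosages)

    keep = np.ones(g.n_snps, dtype=bool)
    for j in range(g.n_snps):
        snp_id = g.snps[j].id
        if maf[j] < maf_min:
            report.removed_maf += 1
            report.removed_snps[snp_id] = "maf"
            keep[j] = False
        elif call[j] < call_rate_min:
            report.removed_call_rate += 1
            report.removed_snps[snp_id] = "call_rate"
            keep[j] = False
        elif hwe_p[j] < hwe_p_min:
            report.removed_hwe += 1
            report.removed_snps[snp_id] = "hwe"
            keep[j] = False
    report.retained = int(keep.sum())
    if report.retained == 0:
        logger.warning("QC removed every SNP (%d input)", g.n_snps)
    logger.info("QC: %d/%d SNPs retained (maf %d, call rate %d, hwe %d removed)",
                report.retained, g.n_snps, report.removed_maf,
                report.removed_call_rate, report.removed_hwe)
    return g.subset_snps(keep), report


# ---------------------------------------------------------------------------
# phenotype pre-adjustment
# ---------------------------------------------------------------------------

def preadjust_phenotypes(pheno: PhenotypeTable,
                         covariates: pd.DataFrame | None = None,
                         keep_mean: bool = False) -> PhenotypeTable:
    """Replace each trait by its OLS residual on the covariate design.

    Categorical (non-numeric) covariate columns are dummy-coded; an intercept
    is always included.  Aliased (rank-deficient) columns are dropped via the
    pseudo-inverse solve.  With ``covariates=None`` the table passes through
    unchanged; an empty frame centres each trait.  ``keep_mean`` adds the
    trait grand mean back onto the residuals.
    """
    if covariates is None:
        return PhenotypeTable(list(pheno.samples), list(pheno.traits),
                              pheno.values.copy())
    if len(covariates) != len(pheno.samples):
        raise ValueError("covariate rows must align with phenotype samples")
    parts = [np.ones((len(pheno.samples), 1))]
    for col in covariates.columns:
        s = covariates[col]
        if pd.api.types.is_numeric_dtype(s):
            parts.append(s.to_numpy(float)[:, None])
        else:
            parts.append(pd.get_dummies(s, drop_first=True).to_numpy(float))
    design = np.hstack(parts)
    if np.linalg.matrix_rank(design) < design.shape[1]:
        logger.warning("covariate design is rank deficient; aliased columns "
                       "resolved by least-norm fit")
    resid = np.empty_like(pheno.values)
    for k in range(pheno.n_traits):
        y = pheno.values[:, k]
        ok = np.isfinite(y)
        beta, *_ = np.linalg.lstsq(design[ok], y[ok], rcond=None)
        resid[:, k] = y - design @ beta
        if keep_mean:
            resid[:, k] += np.nanmean(y)
    return PhenotypeTable(list(pheno.samples), list(pheno.traits), resid)


def align_samples(*tables) -> list:
    """Subset genotype/phenotype objects to their common samples, in the
    order of the first table; unmatched samples are dropped with a log line."""
    common = None
    for t in tables:
        s = set(t.samples)
        common = s if common is None else common & s
    first = tables[0]
    keep = [s for s in first.samples if s in common]
    dropped = sum(len(t.samples) - len(keep) for t in tables)
    if dropped:
        logger.info("sample alignment dropped %d non-shared rows", dropped)
    out = []
    for t in tables:
        idx = {s: i for i, s in enumerate(t.samples)}
        rows = [idx[s] for s in keep]
        if isinstance(t, GenotypeMatrix):
            out.append(GenotypeMatrix(keep, list(t.snps), t.dosages[rows]))
        else:
            out.append(PhenotypeTable(keep, list(t.traits), t.values[rows]))
    return out
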