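"""Genotype loading, QC, and reference LD covariance matrices.

Two on-disk formats are understood:

* VCF (``GT`` or ``DS`` FORMAT fields, via :mod:`cyvcf2`); plain uncompressed
  files are streamed record by record, so no index is required.
* A tab-delimited dosage table with header
  ``CHROM POS REF ALT SNP_ID <sample> <sample> ...`` and dosage values in
  [0, 2] (``NA`` for missing).

SNP identifiers are canonicalised as ``chrom:pos:ref:alt``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "Region",
    "QCThresholds",
    "GenotypeMatrix",
    "LDMatrix",
    "load_genotype_matrix",
    "compute_ld_covariance",
    "hwe_pvalue",
    "parse_snp_id",
    "write_dosage_table",
    "write_ld_matrix",
    "read_ld_matrix",
]


def parse_snp_id(snp_id: str) -> tuple[str, int, str, str]:
    """Split a canonical ``chrom:pos:ref:alt`` identifier."""
    chrom, pos, ref, alt = snp_id.split(":")
    return chrom, int(pos), ref, alt


@dataclass(frozen=True)
class Region:
    """A gene region plus symmetric flank (1-based, inclusive coordinates)."""

    chrom: str
    start: int
    end: int
    flank: int = 1_000_000

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError("region start must be <= end")
        if self.flank < 0:
            raise ValueError("flank must be non-negative")

    @property
    def window(self) -> tuple[int, int]:
        return max(1, self.start - self.flank), self.end + self.flank

    def contains(self, chrom: str, pos: int) -> bool:
        lo, hi = self.window
        return str(chrom) == self.chrom and lo <= pos <= hi


@dataclass(frozen=True)
class QCThresholds:
    """SNP-level QC: minor-allele-frequency and Hardy-Weinberg filters."""

    maf_min: float = 0.05
    hwe_pmin: float = 1e-5


@dataclass
class GenotypeMatrix:
    """Samples x SNPs dosage matrix with per-SNP metadata.

    Invariants: dosages lie in [0, 2] with no missing entries (mean-imputed
    at load time); ``maf`` is recomputable from the dosage columns; SNP ids
    are unique and ordered by (position, ref, alt).
    """

    sample_ids: list[str]
    snp_ids: list[str]
    positions: np.ndarray
    dosages: np.ndarray
    maf: np.ndarray = field(default=None)

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.positions = np.asarray(self.positions, dtype=int)
        if self.dosages.shape != (len(self.sample_ids), len(self.snp_ids)):
            raise ValueError("dosage matrix shape does not match ids")
        if len(set(self.snp_ids)) != len(self.snp_ids):
            raise ValueError("duplicate SNP identifiers")
        if self.dosages.size and (np.isnan(self.dosages).any()):
            raise ValueError("dosages must be imputed before construction")
        if self.dosages.size and (self.dosages.min() < -1e-9 or self.dosages.max() > 2 + 1e-9):
            raise ValueError("dosages must lie in [0, 2]")
        if self.maf is None:
            self.maf = compute_maf(self.dosages)
        else:
            self.maf = np.asarray(self.maf, dtype=float)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def m_snps(self) -> int:
        return len(self.snp_ids)

    @property
    def is_empty(self) -> bool:
        return self.m_snps == 0

    def subset_snps(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            sample_ids=list(self.sample_ids),
            snp_ids=[self.snp_ids[i] for i in idx],
            positions=self.positions[idx],
            dosages=self.dosages[:, idx],
            maf=self.maf[idx],
        )

    def take_samples(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            sample_ids=[self.sample_ids[i] for i in idx],
            snp_ids=list(self.snp_ids),
            positions=self.positions.copy(),
            dosages=self.dosages[idx, :],
        )

    def centered_dosages(self) -> np.ndarray:
        return self.dosages - self.dosages.mean(axis=0, keepdims=True)


def compute_maf(dosages: np.ndarray) -> np.ndarray:
    """min(p, 1-p) with p = mean(dosage)/2 per SNP column."""
    if dosages.size == 0:
        return np.zeros(dosages.shape[1] if dosages.ndim == 2 else 0)
    p = dosages.mean(axis=0) / 2.0
    return np.minimum(p, 1.0 - p)


@dataclass
class LDMatrix:
    """Reference LD covariance Sigma of SNP dosages (divisor n_ref - 1)."""

    snp_ids: list[str]
    sigma: np.ndarray
    n_ref: int

    def __post_init__(self):
        self.sigma = np.asarray(self.sigma, dtype=float)
        m = len(self.snp_ids)
        if self.sigma.shape != (m, m):
            raise ValueError("sigma shape does not match snp_ids")
        if m and np.max(np.abs(self.sigma - self.sigma.T)) > 1e-10:
            raise ValueError("sigma must be symmetric")

    @property
    def m_snps(self) -> int:
        return len(self.snp_ids)

    def subset(self, idx) -> "LDMatrix":
        idx = np.asarray(idx)
        return LDMatrix(
            snp_ids=[self.snp_ids[i] for i in idx],
            sigma=self.sigma[np.ix_(idx, idx)],
            n_ref=self.n_ref,
        )


def hwe_pvalue(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Chi-square (1 df) goodness-of-fit test of Hardy-Weinberg proportions."""
    n = n_hom_ref + n_het + n_hom_alt
    if n == 0:
        return 1.0
    p = (2 * n_hom_ref + n_het) / (2.0 * n)
    q = 1.0 - p
    exp = np.array([n * p * p, 2 * n * p * q, n * q * q])
    obs = np.array([n_hom_ref, n_het, n_hom_alt], dtype=float)
    keep = exp > 0
    if keep.sum() <= 1:
        return 1.0
    stat = float(((obs[keep] - exp[keep]) ** 2 / exp[keep]).sum())
    return float(stats.chi2.sf(stat, 1))


def _finalize(
    sample_ids,
    records,
    qc: QCThresholds,
) -> GenotypeMatrix:
    """Impute, QC-filter, and order raw per-SNP records.

    ``records`` is a list of (pos, ref, alt, snp_id, dosage_vector, hwe_p)
    where ``hwe_p`` is None for dosage-only input (HWE skipped).
    """
    kept = []
    for pos, ref, alt, snp_id, dose, hwe_p in records:
        dose = np.asarray(dose, dtype=float)
        miss = np.isnan(dose)
        if miss.all():
            continue
        if miss.any():
            dose[miss] = dose[~miss].mean()
        p = dose.mean() / 2.0
        maf = min(p, 1.0 - p)
        if maf < qc.maf_min:
            continue
        if hwe_p is not None and hwe_p <= qc.hwe_pmin:
            continue
        kept.append((pos, ref, alt, snp_id, dose))
    kept.sort(key=lambda r: (r[0], r[1], r[2]))
    if not kept:
        return GenotypeMatrix(
            sample_ids=list(sample_ids),
            snp_ids=[],
            positions=np.zeros(0, dtype=int),
            dosages=np.zeros((len(sample_ids), 0)),
        )
    dosages = np.column_stack([r[4] for r in kept])
    return GenotypeMatrix(
        sample_ids=list(sample_ids),
        snp_ids=[r[3] for r in kept],
        positions=np.array([r[0] for r in kept], dtype=int),
        dosages=dosages,
    )


def _load_vcf(path: str, region: Region | None, qc: QCThresholds) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(path)
    sample_ids = list(vcf.samples)
    records = []
    for v in vcf:
        if len(v.ALT) != 1:
            continue  # multiallelic sites must be split upstream
        if region is not None and not region.contains(v.CHROM, v.POS):
            continue
        snp_id = f"{v.CHROM}:{v.POS}:{v.REF}:{v.ALT[0]}"
        hwe_p = None
        dose = None
        fmts = v.FORMAT
        if "DS" in fmts:
            ds = np.asarray(v.format("DS"), dtype=float).reshape(len(sample_ids), -1)[:, 0]
            dose = np.where(ds < 0, np.nan, ds)
        else:
            alleles = np.array([g[:2] for g in v.genotypes], dtype=float)
            alleles[alleles < 0] = np.nan
            dose = alleles.sum(axis=1)
            obs = dose[~np.isnan(dose)]
            counts = [(obs == k).sum() for k in (0, 1, 2)]
            hwe_p = hwe_pvalue(*counts)
        records.append((v.POS, v.REF, v.ALT[0], snp_id, dose, hwe_p))
    return _finalize(sample_ids, records, qc)


_TABLE_META = ["CHROM", "POS", "REF", "ALT", "SNP_ID"]


def _load_table(path: str, region: Region | None, qc: QCThresholds) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"CHROM": str})
    missing = [c for c in _TABLE_META if c not in df.columns]
    if missing:
        raise ValueError(f"dosage table missing columns: {missing}")
    sample_ids = [c for c in df.columns if c not in _TABLE_META]
    records = []
    for _, row in df.iterrows():
        pos = int(row["POS"])
        if region is not None and not region.contains(row["CHROM"], pos):
            continue
        dose = row[sample_ids].to_numpy(dtype=float)
        # dosage-only input: HWE test skipped (no hard genotype calls)
        records.append((pos, str(row["REF"]), str(row["ALT"]), str(row["SNP_ID"]), dose, None))
    return _finalize(sample_ids, records, qc)


def load_genotype_matrix(
    source,
    region: Region | None = None,
    qc: QCThresholds | None = None,
) -> GenotypeMatrix:
    """Load genotypes from a VCF or dosage table, applying QC.

    Returns an empty :class:`GenotypeMatrix` (``is_empty``) rather than
    raising when no SNP survives the region/QC filters.
    """
    qc = qc or QCThresholds()
    path = str(source)
    if path.endswith((".vcf", ".vcf.gz", ".bcf")):
        return _load_vcf(path, region, qc)
    return _load_table(path, region, qc)


def compute_ld_covariance(geno: GenotypeMatrix, ridge: float | None = None) -> LDMatrix:
    """Sample covariance of dosage columns (divisor n-1) plus a ridge term.

    ``ridge=None`` applies the default 1e-6 x mean(diagonal) regulariser,
    guaranteeing a PSD matrix; pass ``ridge=0`` for the raw covariance.
    """
    if geno.n_samples < 2:
        raise ValueError("LD covariance requires at least 2 samples")
    if geno.is_empty:
        return LDMatrix(snp_ids=[], sigma=np.zeros((0, 0)), n_ref=geno.n_samples)
    gc = geno.centered_dosages()
    sigma = gc.T @ gc / (geno.n_samples - 1)
    sigma = 0.5 * (sigma + sigma.T)
    if ridge is None:
        diag_mean = float(np.mean(np.diag(sigma)))
        ridge = 1e-6 * diag_mean if diag_mean > 0 else 1e-6
    if ridge < 0:
        raise ValueError("ridge must be non-negative")
    sigma = sigma + ridge * np.eye(sigma.shape[0])
    return LDMatrix(snp_ids=list(geno.snp_ids), sigma=sigma, n_ref=geno.n_samples)


def write_dosage_table(geno: GenotypeMatrix, path) -> None:
    meta = pd.DataFrame(
        [parse_snp_id(s) for s in geno.snp_ids],
        columns=["CHROM", "POS", "REF", "ALT"],
    )
    meta["SNP_ID"] = geno.snp_ids
    body = pd.DataFrame(geno.dosages.T, columns=geno.sample_ids)
    pd.concat([meta, body], axis=1).to_csv(path, sep="\t", index=False, float_format="%.17g")


def write_ld_matrix(ld: LDMatrix, path) -> None:
    df = pd.DataFrame(ld.sigma, index=ld.snp_ids, columns=ld.snp_ids)
    df.index.name = f"N_REF={ld.n_ref}"
    df.to_csv(path, sep="\t", float_format="%.17g")


def read_ld_matrix(path) -> LDMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    n_ref = 0
    if df.index.name and df.index.name.startswith("N_REF="):
        n_ref = int(df.index.name.split("=", 1)[1])
    return LDMatrix(snp_ids=list(df.columns), sigma=df.to_numpy(dtype=float), n_ref=n_ref)
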