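"""Variance-component TWAS from GWAS summary statistics.

Single-variant score statistics and the phenotype variance are reconstructed
from per-SNP effect estimates, standard errors, sample size, and a reference
LD covariance matrix:

    G_j' Y      = (n - 1) * beta_j * Sigma_jj
    sigma_Y^2   = median_j( Sigma_jj sigma_j^2 (n - 1) + Sigma_jj beta_j^2 )
    s_j         = G_j' Y / sigma_Y^2
    Q           = sum_j w_j^2 s_j^2

Under the null, Cov(s) = ((n - 1) / sigma_Y^2) * Sigma, so the mixture
weights are the eigenvalues of ((n - 1)/sigma_Y^2) W^{1/2} Sigma W^{1/2}.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg

from .genotype_io import LDMatrix, parse_snp_id
from .vc_individual import VCResult, _truncate_eigs, pvalue_mixture_chisq
from .weights import WeightSet, filter_weights

__all__ = [
    "SummaryStats",
    "estimate_phenotype_variance",
    "estimate_score_statistics",
    "compute_q_summary",
    "summary_null_eigenvalues",
    "vc_twas_ss_gene",
    "harmonize_gene",
    "read_summary_stats",
    "write_summary_stats",
]


@dataclass
class SummaryStats:
    """Per-SNP GWAS summary statistics (effect, SE, sample size)."""

    snp_ids: list[str]
    beta_hat: np.ndarray
    se: np.ndarray
    n_gwas: np.ndarray

    def __post_init__(self):
        self.beta_hat = np.asarray(self.beta_hat, dtype=float).ravel()
        self.se = np.asarray(self.se, dtype=float).ravel()
        self.n_gwas = np.atleast_1d(np.asarray(self.n_gwas, dtype=float))
        m = len(self.snp_ids)
        if self.n_gwas.size == 1:
            self.n_gwas = np.full(m, float(self.n_gwas[0]))
        if not (len(self.beta_hat) == len(self.se) == len(self.n_gwas) == m):
            raise ValueError("summary-statistic fields must share one length")
        if m and (np.any(self.se <= 0) or not np.all(np.isfinite(self.beta_hat))):
            raise ValueError("require finite beta_hat and strictly positive se")

    @property
    def m_snps(self) -> int:
        return len(self.snp_ids)

    def subset(self, idx) -> "SummaryStats":
        idx = np.asarray(idx)
        return SummaryStats(
            snp_ids=[self.snp_ids[i] for i in idx],
            beta_hat=self.beta_hat[idx],
            se=self.se[idx],
            n_gwas=self.n_gwas[idx],
        )


def estimate_phenotype_variance(ss: SummaryStats, ld: LDMatrix) -> float:
    """Median over SNPs of Sigma_jj sigma_j^2 (n-1) + Sigma_jj beta_j^2."""
    if ss.m_snps == 0:
        raise ValueError("cannot estimate phenotype variance from zero SNPs")
    if list(ss.snp_ids) != list(ld.snp_ids):
        raise ValueError("summary stats and LD matrix must be matched and ordered")
    d = np.diag(ld.sigma)
    per_snp = d * ss.se**2 * (ss.n_gwas - 1) + d * ss.beta_hat**2
    out = float(np.median(per_snp))
    if out <= 0:
        raise ValueError("non-positive phenotype variance estimate; inconsistent inputs")
    return out


def estimate_score_statistics(ss: SummaryStats, ld: LDMatrix, sigma2_y: float) -> np.ndarray:
    """s_j = (n - 1) beta_j Sigma_jj / sigma_Y^2 for each SNP."""
    if sigma2_y <= 0:
        raise ValueError("sigma2_y must be positive")
    if list(ss.snp_ids) != list(ld.snp_ids):
        raise ValueError("summary stats and LD matrix must be matched and ordered")
    return (ss.n_gwas - 1) * ss.beta_hat * np.diag(ld.sigma) / sigma2_y


def compute_q_summary(ws: WeightSet, scores: np.ndarray) -> float:
    """Q = sum_j w_j^2 s_j^2."""
    scores = np.asarray(scores, dtype=float).ravel()
    if len(scores) != ws.m_snps:
        raise ValueError("weights and scores have different lengths")
    return float(np.sum((ws.weights * scores) ** 2))


def summary_null_eigenvalues(
    ws: WeightSet, ld: LDMatrix, n_gwas: float, sigma2_y: float, flags: dict | None = None
) -> np.ndarray:
    """Eigenvalues of ((n-1)/sigma_Y^2) W^{1/2} Sigma W^{1/2}."""
    if sigma2_y <= 0:
        raise ValueError("sigma2_y must be positive")
    if list(ws.snp_ids) != list(ld.snp_ids):
        raise ValueError("weights and LD matrix must be matched and ordered")
    absw = np.abs(ws.weights)
    keep = np.flatnonzero(absw > 0)
    if keep.size == 0:
        return np.zeros(0)
    a = ld.sigma[np.ix_(keep, keep)] * absw[keep][:, None] * absw[keep][None, :]
    lam = linalg.eigh(a, eigvals_only=True)
    lam = (float(n_gwas) - 1.0) / sigma2_y * lam
    return _truncate_eigs(lam, flags)


def harmonize_gene(
    ss: SummaryStats, ld: LDMatrix, ws: WeightSet
) -> tuple[SummaryStats, LDMatrix, WeightSet, int]:
    """Intersect SNPs of ss/ld/ws by chrom:pos, orienting effects to the LD alleles.

    Effect signs (beta_hat and weight) are flipped when ref/alt are swapped
    relative to the LD orientation; allele mismatches and SNPs absent from
    any input are dropped.  Returns the aligned triple plus the number of
    summary SNPs dropped.
    """
    def by_pos(ids):
        out = {}
        for i, sid in enumerate(ids):
            c, p, r, a = parse_snp_id(sid)
            out[(c, p)] = (i, r, a)
        return out

    ld_ix = by_pos(ld.snp_ids)
    ws_ix = by_pos(ws.snp_ids)
    keep_ss, keep_ld, keep_ws = [], [], []
    flip_ss, flip_ws = [], []
    for i, sid in enumerate(ss.snp_ids):
        c, p, r, a = parse_snp_id(sid)
        hit_ld = ld_ix.get((c, p))
        hit_ws = ws_ix.get((c, p))
        if hit_ld is None or hit_ws is None:
            continue
        j, lref, lalt = hit_ld
        k, wref, walt = hit_ws
        if (r, a) == (lref, lalt):
            f_ss = 1.0
        elif (r, a) == (lalt, lref):
            f_ss = -1.0
        else:
            continue
        if (wref, walt) == (lref, lalt):
            f_ws = 1.0
        elif (wref, walt) == (lalt, lref):
            f_ws = -1.0
        else:
            continue
        keep_ss.append(i)
        keep_ld.append(j)
        keep_ws.append(k)
        flip_ss.append(f_ss)
        flip_ws.append(f_ws)
    n_dropped = ss.m_snps - len(keep_ss)
    order = np.argsort(np.asarray(keep_ld))
    keep_ss = np.asarray(keep_ss)[order]
    keep_ld = np.asarray(keep_ld, dtype=int)[order]
    keep_ws = np.asarray(keep_ws)[order]
    flip_ss = np.asarray(flip_ss)[order]
    flip_ws = np.asarray(flip_ws)[order]
    ld2 = ld.subset(keep_ld)
    ss2 = SummaryStats(
        snp_ids=list(ld2.snp_ids),
        beta_hat=ss.beta_hat[keep_ss] * flip_ss,
        se=ss.se[keep_ss],
        n_gwas=ss.n_gwas[keep_ss],
    )
    ws2 = WeightSet(
        gene_id=ws.gene_id,
        snp_ids=list(ld2.snp_ids),
        weights=ws.weights[keep_ws] * flip_ws,
        method_tag=ws.method_tag,
        cv_r2=ws.cv_r2,
    )
    return ss2, ld2, ws2, n_dropped


def vc_twas_ss_gene(
    ss: SummaryStats,
    ld: LDMatrix,
    ws: WeightSet,
    weight_filter: str | None = None,
    threshold: float = 1e-4,
) -> VCResult | None:
    """Summary-level variance-component test for one gene.

    Assumes phenotypes were covariate-adjusted upstream (mu_hat = 0).
    sigma_Y^2 is estimated gene-locally from the gene's own SNPs.  Returns
    ``None`` when no SNP survives harmonization/filtering.
    """
    ss2, ld2, ws2, n_dropped = harmonize_gene(ss, ld, ws)
    if ws2.m_snps == 0:
        return None
    if weight_filter in ("median", "per_gene_median"):
        ws2 = filter_weights(ws2, "per_gene_median")
    elif weight_filter in ("threshold", "magnitude_threshold"):
        ws2 = filter_weights(ws2, "magnitude_threshold", threshold)
    elif weight_filter not in (None, "none"):
        raise ValueError(f"unknown weight filter: {weight_filter!r}")
    nz = np.flatnonzero(ws2.weights != 0)
    if nz.size == 0:
        return None
    keep = [ld2.snp_ids.index(ws2.snp_ids[i]) for i in nz]
    ws2 = ws2.subset(nz)
    ld2 = ld2.subset(keep)
    ss2 = ss2.subset(keep)

    flags: dict = {"snps_dropped_harmonizing": n_dropped}
    sigma2_y = estimate_phenotype_variance(ss2, ld2)
    scores = estimate_score_statistics(ss2, ld2, sigma2_y)
    q = compute_q_summary(ws2, scores)
    n_eff = float(np.median(ss2.n_gwas))
    lam = summary_null_eigenvalues(ws2, ld2, n_eff, sigma2_y, flags)
    tail = pvalue_mixture_chisq(q, lam, details=True)
    if tail.fallback:
        flags["liu_fallback"] = True
    return VCResult(
        gene_id=ws.gene_id,
        q_stat=q,
        p_value=tail.p,
        m_snps_used=ws2.m_snps,
        eigenvalues=lam,
        method_flags=flags,
    )


_SS_COLS = ["CHROM", "POS", "REF", "ALT", "SNP_ID", "BETA", "SE", "N"]


def read_summary_stats(path) -> SummaryStats:
    df = pd.read_csv(path, sep="\t", dtype={"CHROM": str})
    missing = [c for c in _SS_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"summary-statistic file missing columns: {missing}")
    snp_ids = [
        f"{c}:{int(p)}:{r}:{a}"
        for c, p, r, a in zip(df["CHROM"], df["POS"], df["REF"], df["ALT"])
    ]
    return SummaryStats(
        snp_ids=snp_ids,
        beta_hat=df["BETA"].to_numpy(float),
        se=df["SE"].to_numpy(float),
        n_gwas=df["N"].to_numpy(float),
    )


def write_summary_stats(ss: SummaryStats, path) -> None:
    rows = []
    for sid, b, s, n in zip(ss.snp_ids, ss.beta_hat, ss.se, ss.n_gwas):
        c, p, r, a = parse_snp_id(sid)
        rows.append((c, p, r, a, sid, b, s, n))
    pd.DataFrame(rows, columns=_SS_COLS).to_csv(
        path, sep="\t", index=False, float_format="%.17g"
    )
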