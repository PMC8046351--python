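"""Weighted-burden TWAS comparator: GReX imputation and association tests.

The burden test regresses the phenotype on the imputed genetically regulated
expression GReX = G w_hat and Wald-tests the single coefficient; unlike the
variance-component test it is sensitive to the signs of the weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .genotype_io import GenotypeMatrix, LDMatrix
from .vc_summary import SummaryStats
from .weights import WeightSet

__all__ = [
    "GReXVector",
    "BurdenResult",
    "impute_grex",
    "burden_test_individual",
    "burden_test_summary",
    "burden_z_summary",
]


@dataclass
class GReXVector:
    """Imputed genetically regulated expression, linear in dosages."""

    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float).ravel()
        if len(self.values) != len(self.sample_ids):
            raise ValueError("values and sample_ids must have equal length")
        if self.values.size and not np.all(np.isfinite(self.values)):
            raise ValueError("GReX values must be finite")


@dataclass
class BurdenResult:
    gene_id: str
    p_value: float | None
    beta: float | None = None
    se: float | None = None
    reason: str | None = None  # set when the test is NA
    flags: dict = field(default_factory=dict)


def impute_grex(geno: GenotypeMatrix, ws: WeightSet) -> GReXVector | None:
    """GReX = dosage matrix @ weight vector (SNPs must be matched/ordered).

    Returns ``None`` for an empty gene (zero matched SNPs).
    """
    if geno.is_empty or ws.m_snps == 0:
        return None
    if list(geno.snp_ids) != list(ws.snp_ids):
        raise ValueError("genotypes and weights must be matched and ordered")
    return GReXVector(list(geno.sample_ids), geno.dosages @ ws.weights)


def burden_test_individual(
    grex: GReXVector, Y, Z, family: str = "gaussian", gene_id: str = "NA"
) -> BurdenResult:
    """Wald test of the GReX coefficient in a GLM of Y on GReX + covariates."""
    Y = np.asarray(Y, dtype=float).ravel()
    Z = np.asarray(Z, dtype=float)
    if Z.ndim == 1:
        Z = Z[:, None]
    g = grex.values
    if len(g) != len(Y) or Z.shape[0] != len(Y):
        raise ValueError("samples not aligned")
    if np.ptp(g) == 0:
        return BurdenResult(gene_id, None, reason="constant_grex")
    X = np.column_stack([g, Z])
    if family == "gaussian":
        fam = sm.families.Gaussian()
    elif family == "binomial":
        fam = sm.families.Binomial()
    else:
        raise ValueError(f"unknown family: {family!r}")
    res = sm.GLM(Y, X, family=fam).fit()
    return BurdenResult(
        gene_id,
        float(res.pvalues[0]),
        beta=float(res.params[0]),
        se=float(res.bse[0]),
    )


def burden_z_summary(
    ws: WeightSet, scores: np.ndarray, ld: LDMatrix, n_gwas: float, sigma2_y: float
) -> float:
    """Z = (sum_j w_j s_j) / sqrt(((n-1)/sigma_Y^2) w' Sigma w)."""
    w = ws.weights
    denom2 = (float(n_gwas) - 1.0) / sigma2_y * float(w @ ld.sigma @ w)
    if denom2 <= 0:
        raise ZeroDivisionError("degenerate burden denominator")
    return float(w @ scores) / np.sqrt(denom2)


def burden_test_summary(
    ws: WeightSet,
    ss: SummaryStats,
    ld: LDMatrix,
    sigma2_y: float | None = None,
    gene_id: str | None = None,
) -> BurdenResult:
    """Summary-level burden test from reconstructed score statistics.

    Inputs must already be harmonized to a shared SNP set and order (see
    :func:`vctwas.vc_summary.harmonize_gene`).
    """
    from .vc_summary import estimate_phenotype_variance, estimate_score_statistics

    gene_id = gene_id or ws.gene_id
    if ws.m_snps == 0:
        return BurdenResult(gene_id, None, reason="empty_gene")
    if sigma2_y is None:
        sigma2_y = estimate_phenotype_variance(ss, ld)
    scores = estimate_score_statistics(ss, ld, sigma2_y)
    n_eff = float(np.median(ss.n_gwas))
    try:
        z = burden_z_summary(ws, scores, ld, n_eff, sigma2_y)
    except ZeroDivisionError:
        return BurdenResult(gene_id, None, reason="degenerate_denominator")
    p = float(2.0 * stats.norm.sf(abs(z)))
    return BurdenResult(gene_id, max(p, 1e-300), beta=z)
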