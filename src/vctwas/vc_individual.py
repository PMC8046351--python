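"""Variance-component TWAS for individual-level data.

The test treats per-SNP phenotype effects as random with variance
proportional to the squared eQTL weight, and scores H0: tau = 0 with

    Q = (Y - mu_hat)' G W G' (Y - mu_hat),    W = diag(w_j^2).

Under the null Q follows a mixture of 1-df chi-squares whose weights are the
eigenvalues of the covariate-projected, weight-scaled genotype Gram matrix;
p-values come from :func:`vctwas._quadform.mixture_sf`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm

from ._quadform import mixture_sf
from .genotype_io import GenotypeMatrix
from .weights import WeightSet, align_weights, filter_weights

__all__ = [
    "NullModel",
    "VCResult",
    "ConvergenceError",
    "fit_null_model",
    "compute_q_individual",
    "q_score_form",
    "q_kernel_form",
    "null_mixture_eigenvalues",
    "pvalue_mixture_chisq",
    "vc_twas_gene",
]

#: eigenvalues below this fraction of the largest are numerical nullspace
EIGEN_TRUNCATION = 1e-8


class ConvergenceError(RuntimeError):
    """Logistic null model failed to converge (e.g. separation)."""


@dataclass
class NullModel:
    """Covariate-only phenotype model fitted under H0.

    ``dispersion`` is the scalar residual variance RSS/(n-q) for the
    gaussian family, and the per-sample variance function mu*(1-mu) for the
    binomial family.
    """

    family: str
    mu_hat: np.ndarray
    alpha_hat: np.ndarray
    resid: np.ndarray
    dispersion: np.ndarray | float
    covariates: np.ndarray
    sample_ids: list[str] | None = None

    @property
    def n_samples(self) -> int:
        return len(self.mu_hat)


@dataclass
class VCResult:
    """Outcome of the variance-component test for one gene."""

    gene_id: str
    q_stat: float
    p_value: float
    m_snps_used: int
    eigenvalues: np.ndarray
    method_flags: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.q_stat < 0:
            raise ValueError("q_stat must be non-negative")
        if not (0 < self.p_value <= 1):
            raise ValueError("p_value must lie in (0, 1]")


def _drop_collinear(Z: np.ndarray) -> np.ndarray:
    """Remove linearly dependent covariate columns (pivoted QR)."""
    if Z.ndim != 2:
        raise ValueError("covariate matrix must be 2-d")
    rank = np.linalg.matrix_rank(Z)
    if rank == Z.shape[1]:
        return Z
    warnings.warn("covariate matrix is rank deficient; dropping collinear columns")
    q, r, piv = __import__("scipy.linalg", fromlist=["qr"]).qr(Z, pivoting=True)
    keep = sorted(piv[:rank])
    return Z[:, keep]


def fit_null_model(Y, Z, family: str = "gaussian") -> NullModel:
    """Fit the covariate-only model of the phenotype under H0.

    ``Z`` must include an intercept column.  Gaussian fits use least squares
    with dispersion RSS/(n-q); binomial fits use logistic maximum likelihood.
    """
    Y = np.asarray(Y, dtype=float).ravel()
    Z = np.asarray(Z, dtype=float)
    if Z.ndim == 1:
        Z = Z[:, None]
    if len(Y) != Z.shape[0]:
        raise ValueError("phenotype and covariates have different lengths")
    if np.isnan(Y).any() or np.isnan(Z).any():
        raise ValueError("missing values must be resolved before fitting")
    if not np.any(np.all(Z == Z[0, :], axis=0) & (Z[0, :] != 0)):
        # require a constant nonzero column
        raise ValueError("covariate matrix must include an intercept column")
    Z = _drop_collinear(Z)
    n, q = Z.shape

    if family == "gaussian":
        alpha, *_ = np.linalg.lstsq(Z, Y, rcond=None)
        mu = Z @ alpha
        resid = Y - mu
        dispersion = float(resid @ resid / (n - q))
        return NullModel("gaussian", mu, alpha, resid, dispersion, Z)
    if family == "binomial":
        if not np.all(np.isin(Y, (0.0, 1.0))):
            raise ValueError("binomial phenotype must be coded 0/1")
        model = sm.GLM(Y, Z, family=sm.families.Binomial())
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("error", category=RuntimeWarning)
                res = model.fit(maxiter=200, tol=1e-10)
        except Exception as e:  # separation and the like
            raise ConvergenceError(f"logistic null model failed: {e}") from e
        if not res.converged:
            raise ConvergenceError("logistic null model did not converge")
        mu = np.asarray(res.fittedvalues)
        if np.any(mu <= 0) or np.any(mu >= 1):
            raise ConvergenceError("fitted probabilities hit the boundary (separation?)")
        return NullModel("binomial", mu, np.asarray(res.params), Y - mu, mu * (1 - mu), Z)
    raise ValueError(f"unknown family: {family!r}")


def q_score_form(G: np.ndarray, w: np.ndarray, resid: np.ndarray) -> float:
    """Q = sum_j w_j^2 (G_j' r)^2 — O(nm), no n x n kernel materialised."""
    s = G.T @ resid
    return float(np.sum((w * s) ** 2))


def q_kernel_form(G: np.ndarray, w: np.ndarray, resid: np.ndarray) -> float:
    """Q = r' G W G' r via explicit kernel construction (testing reference)."""
    K = G @ np.diag(w**2) @ G.T
    return float(resid @ K @ resid)


def compute_q_individual(geno: GenotypeMatrix, ws: WeightSet, null: NullModel) -> float:
    """Variance-component score statistic for one gene (score form)."""
    if geno.m_snps != ws.m_snps or list(geno.snp_ids) != list(ws.snp_ids):
        raise ValueError("genotypes and weights must be matched and ordered")
    if geno.n_samples != null.n_samples:
        raise ValueError("samples not aligned with the null model")
    if geno.is_empty:
        raise ValueError("empty gene: no matched SNPs")
    return q_score_form(geno.dosages, ws.weights, null.resid)


def _truncate_eigs(lam: np.ndarray, flags: dict | None = None) -> np.ndarray:
    lam = np.asarray(lam, dtype=float)
    if lam.size == 0:
        return lam
    lmax = float(lam.max(initial=0.0))
    if lmax <= 0:
        return np.zeros(0)
    neg = lam[lam < 0]
    if neg.size and flags is not None and float(-neg.min()) > 1e-6 * lmax:
        flags["indefinite_matrix"] = True
    lam = np.clip(lam, 0.0, None)
    return np.sort(lam[lam > EIGEN_TRUNCATION * lmax])[::-1]


def null_mixture_eigenvalues(
    geno: GenotypeMatrix, ws: WeightSet, null: NullModel, flags: dict | None = None
) -> np.ndarray:
    """Eigenvalues defining Q's null mixture of 1-df chi-squares.

    Gaussian: eigenvalues of sigma^2 * W^{1/2} G'(I - H) G W^{1/2} with H the
    covariate hat matrix.  Binomial: eigenvalues of
    W^{1/2} G'(V - V Z (Z'VZ)^{-1} Z'V) G W^{1/2} with V = diag(mu(1-mu)).
    Both are computed from singular values of a projected n x m factor, so
    the work is O(n m min(n, m)) and the result is non-negative by
    construction; eigenvalues below 1e-8 x max are dropped.
    """
    if geno.m_snps != ws.m_snps:
        raise ValueError("genotypes and weights must be matched")
    absw = np.abs(ws.weights)
    keep = np.flatnonzero(absw > 0)
    if keep.size == 0:
        return np.zeros(0)
    B = geno.dosages[:, keep] * absw[keep]
    Z = null.covariates
    if null.family == "gaussian":
        # project out covariates: (I - H) B with H = Z (Z'Z)^+ Z'
        coef, *_ = np.linalg.lstsq(Z, B, rcond=None)
        B = B - Z @ coef
        sv = np.linalg.svd(B, compute_uv=False)
        lam = null.dispersion * sv**2
    else:
        v = np.asarray(null.dispersion, dtype=float)
        sq = np.sqrt(v)
        U = Z * sq[:, None]
        Bv = B * sq[:, None]
        coef, *_ = np.linalg.lstsq(U, Bv, rcond=None)
        Bv = Bv - U @ coef
        sv = np.linalg.svd(Bv, compute_uv=False)
        lam = sv**2
    return _truncate_eigs(lam, flags)


def pvalue_mixture_chisq(q: float, lambdas, *, details: bool = False):
    """P(sum lambda_k chi2_1 > q); Davies-type inversion with Liu fallback."""
    return mixture_sf(q, lambdas, details=details)


def vc_twas_gene(
    geno: GenotypeMatrix,
    ws: WeightSet,
    null: NullModel,
    weight_filter: str | None = None,
    threshold: float = 1e-4,
) -> VCResult | None:
    """End-to-end variance-component test for one gene.

    Aligns weights to genotype columns (allele-aware), optionally filters
    them (``"median"`` or ``"threshold"``), and composes Q, the null
    eigenvalues, and the mixture p-value.  Returns ``None`` for an empty
    gene (no usable SNP after matching/filtering): the test is skipped.
    """
    matched, idx = align_weights(ws, geno)
    if matched.m_snps == 0:
        return None
    if weight_filter in ("median", "per_gene_median"):
        matched = filter_weights(matched, "per_gene_median")
    elif weight_filter in ("threshold", "magnitude_threshold"):
        matched = filter_weights(matched, "magnitude_threshold", threshold)
    elif weight_filter not in (None, "none"):
        raise ValueError(f"unknown weight filter: {weight_filter!r}")
    nz = np.flatnonzero(matched.weights != 0)
    if nz.size == 0:
        return None
    matched = matched.subset(nz)
    sub = geno.subset_snps([geno.snp_ids.index(s) for s in matched.snp_ids])
    flags: dict = {}
    q = compute_q_individual(sub, matched, null)
    lam = null_mixture_eigenvalues(sub, matched, null, flags)
    tail = pvalue_mixture_chisq(q, lam, details=True)
    if tail.fallback:
        flags["liu_fallback"] = True
    return VCResult(
        gene_id=ws.gene_id,
        q_stat=q,
        p_value=tail.p,
        m_snps_used=matched.m_snps,
        eigenvalues=lam,
        method_flags=flags,
    )
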