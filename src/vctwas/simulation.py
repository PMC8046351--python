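"""Synthetic-data generator and power / type-I-error experiment harness.

Genotypes are drawn from a latent-Gaussian threshold model with AR(1)
correlation blocks (a stand-in for real cis-region LD).  Expression traits
are ``E = G w + eps`` with the causal-SNP weight variance calibrated so the
realized genetic variance hits the target heritability.  Phenotypes follow
two architectures:

* Model I  — ``Y = r * E + eps``: SNP effects linear in the eQTL weights
  (the burden-test assumption).
* Model II — ``Y = G beta + eps`` with ``beta_i ~ N(0, r * w_i^2)``: effect
  magnitudes tied to squared weights, directions free.

The type-I harness counts exceedances of pre-inverted mixture critical
values, so a single eigen-decomposition per gene serves every replicate.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import stats

from ._quadform import mixture_quantile, mixture_sf
from .genotype_io import GenotypeMatrix
from .vc_individual import _truncate_eigs
from .weights import (
    ExpressionVector,
    WeightSet,
    _eb_fit,
    fit_eb_dense_weights,
    fit_elastic_net_weights,
    fit_ridge_standin_weights,
    filter_weights,
    ridge_lambda_grid,
)

__all__ = [
    "SimConfig",
    "SimResult",
    "rng_substream",
    "simulate_genotypes",
    "split_train_test",
    "simulate_expression",
    "simulate_phenotype",
    "run_type1_study",
    "run_power_study",
    "null_pvalues",
    "FastRidgeTrainer",
]


def rng_substream(seed: int, label: str) -> np.random.Generator:
    """Named, independent RNG substream: changing one scenario dimension
    does not reshuffle the draws of another."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), zlib.crc32(label.encode())]))


@dataclass(frozen=True)
class SimConfig:
    """One simulation scenario (fully determines every random draw)."""

    n_train: int = 499
    n_test: int = 1232
    m_snps: int = 2800
    p_causal: float = 0.2
    h2_expr: float = 0.1
    h2_pheno: float = 0.0
    model: str = "I"
    ld_rho: float = 0.5
    block_size: int = 100
    maf_range: tuple[float, float] = (0.05, 0.5)
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.p_causal <= 1:
            raise ValueError("p_causal must lie in [0, 1]")
        for h in (self.h2_expr, self.h2_pheno):
            if not 0 <= h < 1:
                raise ValueError("heritabilities must lie in [0, 1)")
        if self.model not in ("I", "II"):
            raise ValueError("model must be 'I' or 'II'")
        if not -1 < self.ld_rho < 1:
            raise ValueError("ld_rho must lie in (-1, 1)")


@dataclass
class SimResult:
    """Power or type-I-error outcome for one (scenario, method) pair."""

    scenario: SimConfig
    method: str
    power_or_t1e: float
    n_reps: int
    mc_se: float
    alpha: float = float("nan")
    n_test: int | None = None

    def __post_init__(self):
        if not 0 <= self.power_or_t1e <= 1:
            raise ValueError("proportion must lie in [0, 1]")


def _mc_se(p: float, n: int) -> float:
    return math.sqrt(p * (1 - p) / n)


def simulate_genotypes(cfg: SimConfig, n: int | None = None) -> GenotypeMatrix:
    """AR(1)-block latent-Gaussian genotypes thresholded to HWE frequencies.

    MAFs are drawn uniformly from ``cfg.maf_range`` (so every SNP passes the
    MAF > maf_range[0] screen by construction); dosages are in {0, 1, 2}.
    Deterministic given ``cfg.seed``.
    """
    n = n if n is not None else cfg.n_train + cfg.n_test
    rng = rng_substream(cfg.seed, "genotypes")
    m, rho, b = cfg.m_snps, cfg.ld_rho, cfg.block_size
    mafs = rng.uniform(cfg.maf_range[0], cfg.maf_range[1], size=m)
    z = np.empty((n, m))
    innov = math.sqrt(1.0 - rho**2)
    for start in range(0, m, b):
        stop = min(start + b, m)
        eps = rng.standard_normal((n, stop - start))
        z[:, start] = eps[:, 0]
        for j in range(1, stop - start):
            z[:, start + j] = rho * z[:, start + j - 1] + innov * eps[:, j]
    # HWE genotype frequencies: P(0)=(1-f)^2, P(1)=2f(1-f), P(2)=f^2
    p0 = (1.0 - mafs) ** 2
    t0 = stats.norm.ppf(p0)
    t1 = stats.norm.ppf(p0 + 2.0 * mafs * (1.0 - mafs))
    dosages = (z > t0).astype(float) + (z > t1)
    return GenotypeMatrix(
        sample_ids=[f"S{i:05d}" for i in range(n)],
        snp_ids=[f"1:{1000 * (j + 1)}:A:G" for j in range(m)],
        positions=np.arange(1, m + 1) * 1000,
        dosages=dosages,
    )


def split_train_test(geno: GenotypeMatrix, cfg: SimConfig) -> tuple[GenotypeMatrix, GenotypeMatrix]:
    if geno.n_samples < cfg.n_train + 1:
        raise ValueError("not enough samples to split")
    train = geno.take_samples(np.arange(cfg.n_train))
    test = geno.take_samples(np.arange(cfg.n_train, geno.n_samples))
    return train, test


def n_causal_snps(cfg: SimConfig) -> int:
    """Causal-set size: ceil(p_causal * m), guaranteeing >= 1 when p_causal > 0."""
    return int(math.ceil(cfg.p_causal * cfg.m_snps)) if cfg.p_causal > 0 else 0


def simulate_expression(
    geno: GenotypeMatrix,
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
    true_weights: np.ndarray | None = None,
    causal_idx: np.ndarray | None = None,
) -> tuple[ExpressionVector, np.ndarray, np.ndarray]:
    """Expression E = G w + eps with realized Var(Gw) calibrated to h2_expr.

    Returns (expression, full-length weight vector, causal index set).
    Pass ``true_weights``/``causal_idx`` to reuse a weight draw (e.g. to
    generate test-cohort expression consistent with the training cohort).
    """
    rng = rng if rng is not None else rng_substream(cfg.seed, "expression")
    m, n = geno.m_snps, geno.n_samples
    if causal_idx is None:
        k = n_causal_snps(cfg)
        causal_idx = np.sort(rng.choice(m, size=k, replace=False)) if k else np.zeros(0, dtype=int)
    if true_weights is None:
        w = np.zeros(m)
        if cfg.h2_expr > 0 and causal_idx.size:
            w[causal_idx] = rng.standard_normal(causal_idx.size)
            gw = geno.dosages @ w
            v = float(np.var(gw))
            if v > 0:
                w *= math.sqrt(cfg.h2_expr / v)
            else:
                w[:] = 0.0
    else:
        w = np.asarray(true_weights, dtype=float).copy()
    noise = rng.normal(0.0, math.sqrt(1.0 - cfg.h2_expr), size=n)
    values = geno.dosages @ w + noise
    return ExpressionVector(list(geno.sample_ids), values), w, causal_idx


def simulate_phenotype(
    geno: GenotypeMatrix,
    expr_bundle: tuple[ExpressionVector, np.ndarray, np.ndarray],
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Phenotype under Model I or II; realized genetic variance = h2_pheno."""
    rng = rng if rng is not None else rng_substream(cfg.seed, "phenotype")
    expr, w, causal_idx = expr_bundle
    n = geno.n_samples
    noise = rng.normal(0.0, math.sqrt(1.0 - cfg.h2_pheno), size=n)
    if cfg.h2_pheno == 0:
        return noise
    if cfg.model == "I":
        eg = expr.values
        v = float(np.var(eg))
        r = math.sqrt(cfg.h2_pheno / v) if v > 0 else 0.0
        return r * eg + noise
    # Model II: beta_i ~ N(0, r * w_i^2) on the causal eQTL set
    beta = np.zeros(geno.m_snps)
    if causal_idx.size:
        beta[causal_idx] = rng.standard_normal(causal_idx.size) * np.abs(w[causal_idx])
    gb = geno.dosages @ beta
    v = float(np.var(gb))
    if v > 0:
        gb *= math.sqrt(cfg.h2_pheno / v)
    return gb + noise


# ---------------------------------------------------------------------------
# weight-training helpers for the experiment harnesses
# ---------------------------------------------------------------------------


def _elastic_net_with_support(expr, geno, seed: int) -> WeightSet:
    """Elastic-net weights; if CV selects the empty model, step down the
    penalty path to the largest penalty with nonzero support (so the
    sparse-weight pathway remains exercisable in null studies)."""
    ws = fit_elastic_net_weights(expr, geno, seed=seed)
    if np.any(ws.weights != 0):
        return ws
    from sklearn.linear_model import enet_path

    e = expr.values - expr.values.mean()
    g = geno.centered_dosages()
    alphas, coefs, _ = enet_path(g, e, l1_ratio=0.5, alphas=50)
    nz = np.flatnonzero(np.any(coefs != 0, axis=0))
    if nz.size:
        ws = WeightSet(
            gene_id=ws.gene_id, snp_ids=list(ws.snp_ids),
            weights=coefs[:, nz[0]].copy(), method_tag="elastic_net", cv_r2=ws.cv_r2,
        )
    return ws


def _train_weight_variants(expr, geno, variants, seed: int) -> dict[str, WeightSet]:
    """Weight variants for the experiment harness.

    ``dense``/``filtered`` use the heavy-tailed empirical-Bayes stand-in for
    external dense Bayesian weight sets; ``ridge`` the CV-ridge stand-in;
    ``sparse`` elastic net.
    """
    out: dict[str, WeightSet] = {}
    if {"dense", "filtered"} & set(variants):
        dense = fit_eb_dense_weights(expr, geno, seed=seed)
        out["dense"] = dense
        if "filtered" in variants:
            out["filtered"] = filter_weights(dense, "per_gene_median")
    if "ridge" in variants:
        out["ridge"] = fit_ridge_standin_weights(expr, geno, seed=seed)
    if "sparse" in variants:
        out["sparse"] = _elastic_net_with_support(expr, geno, seed)
    return out


def _parse_methods(methods) -> list[tuple[str, str]]:
    """'vc:dense' -> ('vc', 'dense'); bare 'vc'/'burden' default to dense."""
    parsed = []
    for mth in methods:
        test, _, variant = mth.partition(":")
        if test not in ("vc", "burden"):
            raise ValueError(f"unknown test: {mth!r}")
        parsed.append((test, variant or "dense"))
    return parsed


class FastRidgeTrainer:
    """Replays :func:`fit_ridge_standin_weights` against a fixed genotype
    matrix, amortising the per-fold Gram eigendecompositions across many
    expression replicates.  Produces identical weights (same grid, same
    seeded folds)."""

    def __init__(self, geno: GenotypeMatrix, seed: int = 0, folds: int = 5):
        from sklearn.model_selection import KFold

        self.geno = geno
        g = geno.dosages
        self.g = g
        gc = g - g.mean(axis=0)
        self.gc = gc
        self.grid = ridge_lambda_grid(gc)
        self.folds = [
            (tr, te) for tr, te in KFold(folds, shuffle=True, random_state=seed).split(g)
        ]
        self._fold_pre = []
        for tr, te in self.folds:
            mu_g = g[tr].mean(axis=0)
            gtr = g[tr] - mu_g
            d, v = np.linalg.eigh(gtr.T @ gtr)
            self._fold_pre.append((mu_g, gtr, d, v, g[te] - mu_g))
        d_full, v_full = np.linalg.eigh(gc.T @ gc)
        self._full = (d_full, v_full)

    def _solve(self, d, v, gty, lam):
        return v @ ((v.T @ gty) / (d + lam))

    def fit(self, e: np.ndarray) -> WeightSet:
        e = np.asarray(e, dtype=float)
        mse = np.zeros(len(self.grid))
        fold_cache = []
        for (tr, te), (mu_g, gtr, d, v, gte) in zip(self.folds, self._fold_pre):
            mu_e = e[tr].mean()
            gty = gtr.T @ (e[tr] - mu_e)
            fold_cache.append((te, mu_e, gty, gte, d, v))
            for i, lam in enumerate(self.grid):
                w = self._solve(d, v, gty, lam)
                resid = e[te] - (mu_e + gte @ w)
                mse[i] += float((resid**2).sum())
        lam_star = float(self.grid[int(np.argmin(mse))])
        d_full, v_full = self._full
        w = self._solve(d_full, v_full, self.gc.T @ (e - e.mean()), lam_star)
        pred = np.empty(len(e))
        for te, mu_e, gty, gte, d, v in fold_cache:
            pred[te] = mu_e + gte @ self._solve(d, v, gty, lam_star)
        ss_tot = float(((e - e.mean()) ** 2).sum())
        r2 = 1.0 - float(((e - pred) ** 2).sum()) / ss_tot if ss_tot > 0 else 0.0
        return WeightSet(
            gene_id="NA", snp_ids=list(self.geno.snp_ids), weights=w,
            method_tag="ridge_standin", cv_r2=r2,
        )


# ---------------------------------------------------------------------------
# type-I error study
# ---------------------------------------------------------------------------


def _prepare_null_gene(cfg: SimConfig, variants):
    """Fixed synthetic gene: genotypes, training expression, trained weights."""
    geno = simulate_genotypes(cfg)
    train, test = split_train_test(geno, cfg)
    expr_all, w_true, causal = simulate_expression(geno, cfg)
    expr_train = ExpressionVector(list(train.sample_ids), expr_all.values[: cfg.n_train])
    weight_sets = _train_weight_variants(expr_train, train, variants, cfg.seed)
    return test, weight_sets


def run_type1_study(
    cfg: SimConfig,
    methods,
    n_reps: int = 100_000,
    alpha_levels=(1e-2,),
    chunk: int = 4096,
) -> list[SimResult]:
    """Empirical type-I error of each method at each alpha under Y ~ N(0, 1).

    Weights are trained once on the disjoint training split; VC critical
    values are obtained by inverting the null mixture once per weight set,
    then 10^5+ replicates reduce to quadratic forms and exceedance counts.
    """
    if n_reps <= 0:
        raise ValueError("n_reps must be positive")
    parsed = _parse_methods(methods)
    variants = {v for _, v in parsed}
    test, weight_sets = _prepare_null_gene(cfg, variants)
    n = test.n_samples
    G = test.dosages
    gc = test.centered_dosages()

    # per-method precomputation
    vc_pre = {}
    burden_pre = {}
    z_crit = {a: stats.norm.isf(a / 2.0) for a in alpha_levels}
    for kind, variant in parsed:
        ws = weight_sets[variant]
        w_full = np.zeros(test.m_snps)
        for sid, wv in zip(ws.snp_ids, ws.weights):
            w_full[test.snp_ids.index(sid)] = wv
        if kind == "vc":
            nz = np.flatnonzero(w_full)
            lam0 = _truncate_eigs(
                np.linalg.svd(gc[:, nz] * np.abs(w_full[nz]), compute_uv=False) ** 2
            )
            crit = {
                a: (mixture_quantile(a, lam0) if a < 1 else 0.0) for a in alpha_levels
            }
            vc_pre[(kind, variant)] = (w_full**2, crit)
        else:
            g = G @ w_full
            gcb = g - g.mean()
            burden_pre[(kind, variant)] = (gcb, float(gcb @ gcb))

    counts = {(k, v, a): 0 for k, v in parsed for a in alpha_levels}
    rng = rng_substream(cfg.seed, "null_phenotypes")
    done = 0
    while done < n_reps:
        b = min(chunk, n_reps - done)
        R = rng.standard_normal((n, b))
        Rc = R - R.mean(axis=0, keepdims=True)
        ssr = np.einsum("ij,ij->j", Rc, Rc)
        sigma2 = ssr / (n - 1)
        U2 = None
        for key, (w2, crit) in vc_pre.items():
            if U2 is None:
                U2 = (G.T @ Rc) ** 2
            q = w2 @ U2
            ratio = q / sigma2
            for a in alpha_levels:
                counts[key + (a,)] += int(np.sum(ratio > crit[a])) if a < 1 else b
        for key, (gcb, gss) in burden_pre.items():
            bnum = gcb @ Rc
            rss = ssr - bnum**2 / gss
            z2 = bnum**2 / (gss * rss / (n - 2))
            for a in alpha_levels:
                counts[key + (a,)] += int(np.sum(z2 > z_crit[a] ** 2)) if a < 1 else b
        done += b

    results = []
    for kind, variant in parsed:
        for a in alpha_levels:
            p = counts[(kind, variant, a)] / n_reps
            results.append(
                SimResult(cfg, f"{kind}:{variant}", p, n_reps, _mc_se(p, n_reps), alpha=a, n_test=n)
            )
    return results


def null_pvalues(cfg: SimConfig, method: str, n_reps: int = 2000) -> np.ndarray:
    """Per-replicate null p-values (exact tail evaluation per replicate);
    intended for distributional checks at modest replicate counts."""
    (kind, variant), = _parse_methods([method])
    test, weight_sets = _prepare_null_gene(cfg, {variant})
    ws = weight_sets[variant]
    n = test.n_samples
    G = test.dosages
    gc = test.centered_dosages()
    w_full = np.zeros(test.m_snps)
    for sid, wv in zip(ws.snp_ids, ws.weights):
        w_full[test.snp_ids.index(sid)] = wv
    rng = rng_substream(cfg.seed, "null_phenotypes")
    R = rng.standard_normal((n, n_reps))
    Rc = R - R.mean(axis=0, keepdims=True)
    ssr = np.einsum("ij,ij->j", Rc, Rc)
    sigma2 = ssr / (n - 1)
    out = np.empty(n_reps)
    if kind == "vc":
        nz = np.flatnonzero(w_full)
        lam0 = _truncate_eigs(
            np.linalg.svd(gc[:, nz] * np.abs(w_full[nz]), compute_uv=False) ** 2
        )
        q = (w_full**2) @ (G.T @ Rc) ** 2
        for i in range(n_reps):
            out[i] = mixture_sf(q[i], sigma2[i] * lam0)
    else:
        g = G @ w_full
        gcb = g - g.mean()
        gss = float(gcb @ gcb)
        bnum = gcb @ Rc
        rss = ssr - bnum**2 / gss
        z = bnum / np.sqrt(gss * rss / (n - 2))
        out = 2.0 * stats.norm.sf(np.abs(z))
    return out


# ---------------------------------------------------------------------------
# power study
# ---------------------------------------------------------------------------


def run_power_study(
    cfg_grid,
    methods,
    n_reps: int = 1000,
    alpha: float = 2.5e-6,
    test_sizes=None,
    return_pvalues: bool = False,
):
    """Power (proportion of replicates with p < alpha) per scenario/method.

    Genotypes are fixed per scenario (as when simulating from one real
    cis-region); expression, training weights, and phenotypes are
    re-simulated each replicate.  ``test_sizes`` evaluates nested test-cohort
    prefixes of each replicate, making the power monotonicity comparison
    paired.  With ``return_pvalues`` a dict keyed
    ``(scenario_index, method, n_test) -> p-value array`` is also returned.
    """
    if n_reps <= 0:
        raise ValueError("n_reps must be positive")
    parsed = _parse_methods(methods)
    variants = {v for _, v in parsed}
    if "sparse" in variants and n_reps > 50:
        raise ValueError("sparse (elastic-net) weights are too slow to retrain "
                         "per replicate at this n_reps; use dense/filtered")
    results = []
    details: dict = {}
    for s_idx, cfg in enumerate(cfg_grid):
        geno = simulate_genotypes(cfg)
        train, test = split_train_test(geno, cfg)
        sizes = tuple(test_sizes) if test_sizes else (test.n_samples,)
        if max(sizes) > test.n_samples:
            raise ValueError("test size exceeds simulated test cohort")
        ridge_trainer = FastRidgeTrainer(train, seed=cfg.seed) if "ridge" in variants else None
        gtrain_c = train.centered_dosages()
        grams = {}
        for s in sizes:
            gp = test.dosages[:s]
            gpc = gp - gp.mean(axis=0)
            grams[s] = (gp, gpc.T @ gpc)
        rng_e = rng_substream(cfg.seed, "expression")
        rng_y = rng_substream(cfg.seed, "phenotype")
        pvals = {(m, s): np.empty(n_reps) for m in methods for s in sizes}
        n_tr = cfg.n_train
        for rep in range(n_reps):
            expr_all, w_true, causal = simulate_expression(geno, cfg, rng_e)
            e_train = expr_all.values[:n_tr]
            wvar = {}
            if {"dense", "filtered"} & variants:
                wvar["dense"] = _eb_fit(gtrain_c, e_train - e_train.mean())
                if "filtered" in variants:
                    wf = wvar["dense"].copy()
                    wf[np.abs(wf) <= np.median(np.abs(wf))] = 0.0
                    wvar["filtered"] = wf
            if "ridge" in variants:
                wvar["ridge"] = ridge_trainer.fit(e_train).weights
            expr_test = ExpressionVector(
                list(test.sample_ids), expr_all.values[n_tr:]
            )
            y_full = simulate_phenotype(test, (expr_test, w_true, causal), cfg, rng_y)
            for s in sizes:
                gp, gram = grams[s]
                y = y_full[:s]
                r = y - y.mean()
                sigma2 = float(r @ r) / (s - 1)
                gtr = gp.T @ r
                for (kind, variant), name in zip(parsed, methods):
                    w = wvar[variant]
                    if kind == "vc":
                        nz = np.flatnonzero(w)
                        aw = np.abs(w[nz])
                        lam = _truncate_eigs(
                            np.linalg.eigvalsh(gram[np.ix_(nz, nz)] * np.outer(aw, aw))
                        )
                        q = float(np.sum((w[nz] * gtr[nz]) ** 2))
                        pvals[(name, s)][rep] = mixture_sf(q, sigma2 * lam)
                    else:
                        g = gp @ w
                        gcb = g - g.mean()
                        gss = float(gcb @ gcb)
                        if gss == 0:
                            pvals[(name, s)][rep] = 1.0
                            continue
                        bnum = float(gcb @ r)
                        rss = float(r @ r) - bnum**2 / gss
                        z = bnum / math.sqrt(gss * rss / (s - 2))
                        pvals[(name, s)][rep] = 2.0 * stats.norm.sf(abs(z))
        for name in methods:
            for s in sizes:
                pw = float(np.mean(pvals[(name, s)] < alpha))
                results.append(
                    SimResult(cfg, name, pw, n_reps, _mc_se(pw, n_reps), alpha=alpha, n_test=s)
                )
                if return_pvalues:
                    details[(s_idx, name, s)] = pvals[(name, s)]
    if return_pvalues:
        return results, details
    return results
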