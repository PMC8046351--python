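"""Cohort meta-analysis (Fisher's method), FDR control, and result tables."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MetaResult",
    "fisher_meta",
    "bh_fdr",
    "RESULT_COLUMNS",
    "write_results",
    "read_results",
    "results_frame",
]

P_CLIP = 1e-300


@dataclass
class MetaResult:
    gene_id: str
    per_study_p: list[float]
    fisher_stat: float
    df: int
    meta_p: float
    fdr: float = float("nan")
    flags: dict = field(default_factory=dict)


def fisher_meta(pvals, gene_id: str = "NA") -> MetaResult:
    """Combine per-cohort p-values: -2 sum(ln p) ~ chi-square with 2k df.

    Zero p-values are clipped to 1e-300 (flagged); p > 1 is an error.
    """
    pvals = list(np.asarray(pvals, dtype=float).ravel())
    if len(pvals) < 1:
        raise ValueError("need at least one p-value")
    flags = {}
    clipped = []
    for p in pvals:
        if p > 1 or np.isnan(p):
            raise ValueError(f"invalid p-value: {p}")
        if p <= 0:
            flags["clipped_zero_p"] = True
            p = P_CLIP
        clipped.append(p)
    stat = -2.0 * float(np.sum(np.log(clipped)))
    df = 2 * len(clipped)
    meta_p = float(stats.chi2.sf(stat, df))
    meta_p = min(max(meta_p, P_CLIP), 1.0)
    return MetaResult(gene_id, pvals, stat, df, meta_p, flags=flags)


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    Monotone in sorted order, each adjusted value >= its raw p and <= 1;
    invariant to input order.
    """
    p = np.asarray(pvals, dtype=float).ravel()
    if p.size == 0:
        return np.zeros(0)
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


RESULT_COLUMNS = ["GENE_ID", "CHROM", "START", "END", "N_SNPS", "Q", "PVALUE", "FDR", "FLAGS"]


def results_frame(records) -> pd.DataFrame:
    """Build a schema-conforming result table; FDR is (re)computed from PVALUE.

    ``records`` is an iterable of dicts with at least GENE_ID and PVALUE;
    missing optional fields are filled with NA / empty flags.
    """
    rows = []
    for rec in records:
        row = {c: rec.get(c) for c in RESULT_COLUMNS}
        row["FLAGS"] = rec.get("FLAGS") or "."
        rows.append(row)
    df = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    ok = df["PVALUE"].notna()
    fdr = np.full(len(df), np.nan)
    if ok.any():
        fdr[ok.to_numpy()] = bh_fdr(df.loc[ok, "PVALUE"].to_numpy(float))
    df["FDR"] = fdr
    return df


def write_results(df: pd.DataFrame, path) -> None:
    missing = [c for c in RESULT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"result table missing columns: {missing}")
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_results(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"CHROM": str, "FLAGS": str})
    missing = [c for c in RESULT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"result table missing columns: {missing}")
    return df
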