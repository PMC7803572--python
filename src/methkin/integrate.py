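"""Promoter methylation vs gene expression.

Promoter mean methylation is the unweighted per-sample mean of CpG
levels inside the -800..+200 window around the TSS, for promoters with
at least ten retained CpGs.  Coupling to expression is measured with
Spearman correlation (average ranks for ties, t-approximation p-value);
expression differences between sample groups use the two-sample
Mann-Whitney rank-sum test (exact for small groups without ties).
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .model import ExpressionTable, GeneModel, MethCountMatrix, RegionSet

log = logging.getLogger(__name__)


def promoter_mean_methylation(
    matrix: MethCountMatrix,
    promoters: RegionSet,
    min_cpgs: int = 10,
) -> pd.DataFrame:
    """Per-gene, per-sample mean promoter methylation.

    Promoter labels are gene ids.  A gene is retained only when its
    window holds >= min_cpgs sites of the (already filtered) matrix; a
    sample missing every promoter cell gets NaN.
    """
    lv = matrix.levels()
    rows, genes = [], []
    pos_by_chrom = {
        c: (sub.index.to_numpy(), sub["pos"].to_numpy())
        for c, sub in matrix.sites.reset_index(drop=True).groupby("chrom", sort=False)
    }
    for reg in promoters.df.itertuples(index=False):
        if reg.chrom not in pos_by_chrom:
            continue
        idx, pos = pos_by_chrom[reg.chrom]
        sel = idx[(pos >= reg.start) & (pos < reg.end)]
        if len(sel) < min_cpgs:
            continue
        with np.errstate(invalid="ignore"):
            means = np.nanmean(lv[sel], axis=0)
        genes.append((reg.label, reg.chrom, reg.start, reg.end, len(sel)))
        rows.append(means)
    meta = pd.DataFrame(genes, columns=["gene_id", "chrom", "start", "end", "n_cpgs"])
    values = pd.DataFrame(rows, columns=matrix.samples)
    return pd.concat([meta, values], axis=1)


def spearman_methylation_expression(
    meth: np.ndarray,
    expr: np.ndarray,
    alpha: float = 0.01,
    min_pairs: int = 5,
) -> dict:
    """Spearman correlation between one methylation and one expression vector.

    NaN pairs are dropped; a constant vector yields an NA result rather
    than an error.
    """
    meth = np.asarray(meth, dtype=float)
    expr = np.asarray(expr, dtype=float)
    ok = ~(np.isnan(meth) | np.isnan(expr))
    n = int(ok.sum())
    if n < min_pairs:
        raise ValueError(f"need >= {min_pairs} complete pairs, got {n}")
    m, e = meth[ok], expr[ok]
    if np.all(m == m[0]) or np.all(e == e[0]):
        return {"rho": np.nan, "p_value": np.nan, "sign": "NA",
                "n": n, "significant": False}
    rho, p = stats.spearmanr(m, e)
    return {
        "rho": float(rho),
        "p_value": float(p),
        "sign": "positive" if rho >= 0 else "negative",
        "n": n,
        "significant": bool(p < alpha),
    }


def promoter_expression_correlations(
    promoter_meth: pd.DataFrame,
    expression: ExpressionTable,
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Correlate each retained promoter's methylation with its gene's FPKM."""
    samples = [s for s in promoter_meth.columns if s in expression.samples]
    rows = []
    for _, g in promoter_meth.iterrows():
        if g["gene_id"] not in expression.values.index:
            continue
        meth = g[samples].to_numpy(dtype=float)
        expr = expression.values.loc[g["gene_id"], samples].to_numpy(dtype=float)
        try:
            res = spearman_methylation_expression(meth, expr, alpha=alpha)
        except ValueError:
            continue
        rows.append({"gene_id": g["gene_id"], **res})
    return pd.DataFrame(rows)


def assign_site_genes(
    context_table: pd.DataFrame, genes: Sequence[GeneModel]
) -> pd.Series:
    """Site-to-gene assignment: promoter owner first, else host gene, else ''."""
    spans = [(g.chrom, *g.span, g.gene_id) for g in genes]
    out = []
    for _, r in context_table.iterrows():
        if r.get("in_promoter_of"):
            out.append(str(r["in_promoter_of"]).split(",")[0])
            continue
        hit = ""
        for chrom, s, e, gid in spans:
            if chrom == r["chrom"] and s <= r["pos"] < e:
                hit = gid
                break
        out.append(hit)
    return pd.Series(out, index=context_table.index, name="assigned_gene")


def site_expression_correlation(
    matrix: MethCountMatrix,
    assigned_genes: pd.Series,
    expression: ExpressionTable,
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Per-site Spearman correlation with the assigned gene's expression."""
    lv = matrix.levels()
    samples = [s for s in matrix.samples if s in expression.samples]
    col_idx = [matrix.samples.index(s) for s in samples]
    rows, n_unassigned = [], 0
    for i in range(matrix.n_sites):
        gid = assigned_genes.iloc[i]
        if not gid or gid not in expression.values.index:
            n_unassigned += 1
            continue
        try:
            res = spearman_methylation_expression(
                lv[i, col_idx],
                expression.values.loc[gid, samples].to_numpy(dtype=float),
                alpha=alpha,
            )
        except ValueError:
            n_unassigned += 1
            continue
        site = matrix.sites.iloc[i]
        rows.append({"chrom": site["chrom"], "pos": site["pos"],
                     "strand": site["strand"], "gene_id": gid, **res})
    if n_unassigned:
        log.info("site_expression_correlation: %d sites skipped", n_unassigned)
    out = pd.DataFrame(rows)
    out.attrs["n_skipped"] = n_unassigned
    return out


def group_expression_test(
    values_a: np.ndarray, values_b: np.ndarray, paired: bool = False
) -> tuple[float, float]:
    """Rank-based two-sample expression test, two-sided.

    Default is the unpaired Mann-Whitney rank-sum test (exact for small
    samples without ties); ``paired=True`` switches to the Wilcoxon
    signed-rank test for genuinely paired designs.  All-tied data gives
    p = 1.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if paired:
        if len(a) != len(b):
            raise ValueError("paired test needs equal-length groups")
        d = a - b
        if np.all(d == 0):
            return 0.0, 1.0
        res = stats.wilcoxon(a, b)
        return float(res.statistic), float(res.pvalue)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs >= 2 samples")
    if np.all(np.concatenate([a, b]) == a[0]):
        return float(len(a) * len(b) / 2), 1.0
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


def dmr_gene_expression_tests(
    gene_ids: Sequence[str],
    expression: ExpressionTable,
    group_a: Sequence[str],
    group_b: Sequence[str],
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Differential-expression test per DMR gene between two sample groups."""
    rows = []
    for gid in gene_ids:
        if gid not in expression.values.index:
            continue
        va = expression.values.loc[gid, list(group_a)].to_numpy(dtype=float)
        vb = expression.values.loc[gid, list(group_b)].to_numpy(dtype=float)
        stat, p = group_expression_test(va, vb)
        rows.append({"gene_id": gid, "statistic": stat, "p_value": p,
                     "significant": p < alpha})
    return pd.DataFrame(rows)
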