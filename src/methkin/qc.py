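"""Site filtering, methylation levels, global summaries and enrichment tests.

The coverage filter keeps a cell when its total read count lies in
[min_cov, max_cov] and keeps a site when at least
ceil(min_presence_fraction x n_samples) cells pass; non-passing cells of
retained sites are masked missing.  Hypo-/hypermethylated CpGs are those
whose mean level across passing samples is below 10 % / above 90 %.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .model import MethCountMatrix

log = logging.getLogger(__name__)


@dataclass
class FilterPolicy:
    min_cov: int = 10
    max_cov: int = 300
    min_presence_fraction: float = 0.5

    def __post_init__(self) -> None:
        if not (0 < self.min_cov <= self.max_cov):
            raise ValueError("need 0 < min_cov <= max_cov")
        if not (0 < self.min_presence_fraction <= 1):
            raise ValueError("min_presence_fraction must be in (0, 1]")


def methylation_level(meth: int, total: int) -> float:
    """Simple proportion meth/total; total must be >= 1."""
    if total < 1:
        raise ValueError("methylation level undefined at total=0; treat as missing")
    return meth / total


def apply_site_filter(
    matrix: MethCountMatrix, policy: FilterPolicy = FilterPolicy()
) -> MethCountMatrix:
    """Coverage + presence filter; idempotent for a fixed policy."""
    passing = (
        ~matrix.missing
        & (matrix.total >= policy.min_cov)
        & (matrix.total <= policy.max_cov)
    )
    need = math.ceil(policy.min_presence_fraction * matrix.n_samples)
    keep = passing.sum(axis=1) >= need
    if not keep.any():
        log.warning("apply_site_filter: no sites retained")
    out = matrix.subset_sites(np.flatnonzero(keep))
    out.missing = out.missing | ~passing[keep]
    return out


def site_summaries(matrix: MethCountMatrix, lo: float = 0.10, hi: float = 0.90) -> pd.DataFrame:
    """Per-site mean level over non-missing cells plus hypo/hyper flags."""
    lv = matrix.levels()
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(lv, axis=1)
    n_pass = (~matrix.missing).sum(axis=1)
    out = matrix.sites.copy()
    out["mean_level"] = mean
    out["n_samples"] = n_pass
    out["flag"] = classify_hypo_hyper(mean, lo=lo, hi=hi)
    return out


def classify_hypo_hyper(mean_levels: np.ndarray, lo: float = 0.10, hi: float = 0.90) -> np.ndarray:
    """'hypo' iff mean < lo, 'hyper' iff mean > hi (both strict), else 'neither'."""
    mean_levels = np.asarray(mean_levels, dtype=float)
    out = np.full(mean_levels.shape, "neither", dtype=object)
    out[mean_levels < lo] = "hypo"
    out[mean_levels > hi] = "hyper"
    out[np.isnan(mean_levels)] = "neither"
    return out


def binary_entropy(levels: np.ndarray) -> np.ndarray:
    """Per-site binary entropy in bits, with 0·log0 := 0."""
    p = np.asarray(levels, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        h = -(p * np.log2(p) + (1 - p) * np.log2(1 - p))
    h = np.where((p <= 0) | (p >= 1), 0.0, h)
    return np.where(np.isnan(p), np.nan, h)


def global_stats(
    matrix: MethCountMatrix,
    groups: dict[str, list[str]] | None = None,
    hist_bins: int = 20,
) -> dict:
    """Per-sample mean level and mean entropy, level histogram, optional ANOVA.

    ``groups`` maps group name -> sample ids; a one-way ANOVA across
    groups is run separately on mean level and mean entropy.
    """
    lv = matrix.levels()
    with np.errstate(invalid="ignore"):
        mean_level = np.nanmean(lv, axis=0)
        mean_entropy = np.nanmean(binary_entropy(lv), axis=0)
    per_sample = pd.DataFrame(
        {
            "sample_id": matrix.samples,
            "mean_level": mean_level,
            "mean_entropy": mean_entropy,
        }
    )
    counts, edges = np.histogram(lv[~np.isnan(lv)], bins=hist_bins, range=(0.0, 1.0))
    result = {
        "per_sample": per_sample,
        "histogram": pd.DataFrame(
            {"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts}
        ),
    }
    if groups:
        anova = {}
        idx = {s: j for j, s in enumerate(matrix.samples)}
        for metric in ("mean_level", "mean_entropy"):
            vals = per_sample.set_index("sample_id")[metric]
            arrays = [vals.loc[ids].to_numpy() for ids in groups.values()]
            if any(len(a) < 2 for a in arrays):
                log.warning("global_stats: a group has <2 samples, ANOVA skipped")
                continue
            f, p = stats.f_oneway(*arrays)
            anova[metric] = {"F": float(f), "p": float(p)}
        result["anova"] = anova
    return result


def enrichment_fisher(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Two-sided Fisher exact test on the 2x2 table [[a, b], [c, d]].

    Returns the sample odds ratio (a·d)/(b·c) — with 0/0 -> nan,
    x/0 -> inf — and the exact p-value; any zero margin yields p = 1 by
    convention.
    """
    for x in (a, b, c, d):
        if x < 0 or int(x) != x:
            raise ValueError("table entries must be non-negative integers")
    ad, bc = a * d, b * c
    if bc == 0:
        odds = math.nan if ad == 0 else math.inf
    else:
        odds = ad / bc
    if min(a + b, c + d, a + c, b + d) == 0:
        return odds, 1.0
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return odds, float(p)
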