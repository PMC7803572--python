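"""Inheritable methylation regions between pedigrees.

A heritable region is a <=500-bp DMR containing at least 5 synclastic
(same-direction) pedigree DMCpGs that are consistent across every
individual of both pedigrees.  Chance occurrence is bounded with a
binomial model: the number of DMCpGs N in an L-bp window follows
X ~ Bin(ECG, p/2), where ECG = (#C x #G)/L is the window's expected CpG
count and p the genome-wide pedigree-DMC rate, and the genome-wide
corrected false-positive probability is

    P_fp(X >= N) = 2 (1 - P(X < N)) * GS / L

with GS the genome size.  P_fp is a Bonferroni-style bound and is
reported uncapped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .diffmeth import merge_dmrs, posterior_mindiff_test
from .model import GenomeSequence, MethCountMatrix, SampleRecord

log = logging.getLogger(__name__)


@dataclass
class HeritableParams:
    window_bp: int = 500          # L
    min_synclastic: int = 5       # minimum N
    dmc_ratio: Optional[float] = None  # p; estimated from data when None
    genome_size: Optional[int] = None  # GS; from the genome when None
    pfp_threshold: float = 0.01

    def __post_init__(self) -> None:
        if self.window_bp <= 0:
            raise ValueError("window_bp must be positive")
        if self.dmc_ratio is not None and not (0 < self.dmc_ratio < 1):
            raise ValueError("dmc_ratio must be in (0, 1)")


def expected_cpg_count(c_count: int, g_count: int, length: int) -> float:
    """Expected CpG count of a window: (#C x #G) / L."""
    if length <= 0:
        raise ValueError("length must be positive")
    if c_count < 0 or g_count < 0:
        raise ValueError("base counts must be non-negative")
    return c_count * g_count / length


def pfp(n_dmc: int, ecg: float, p: float, genome_size: float, window_bp: int) -> float:
    """Genome-wide corrected false-positive probability for a window.

    With X ~ Bin(round(ecg), p/2), returns 2 * P(X >= n_dmc) * GS / L,
    uncapped.  ECG is rounded to the nearest integer to form the binomial
    support; n_dmc beyond that support gives 0.
    """
    if not (0 < p < 1):
        raise ValueError("p must be in (0, 1)")
    if p / 2 >= 1:
        raise ValueError("p/2 must be < 1")
    if n_dmc < 0:
        raise ValueError("n_dmc must be >= 0")
    trials = int(round(ecg))
    if n_dmc > trials:
        return 0.0
    tail = float(stats.binom.sf(n_dmc - 1, trials, p / 2.0))  # P(X >= n_dmc)
    return 2.0 * tail * genome_size / window_bp


def pedigree_dmc(
    matrix: MethCountMatrix,
    samples: Sequence[SampleRecord],
    tissue: str,
    delta: float = 0.3,
    alpha: float = 0.01,
    prior: tuple[float, float] = (1.0, 1.0),
) -> pd.DataFrame:
    """Per-site pedigree DMC calls within one tissue.

    A site is a pedigree DMC iff (i) the pooled beta-posterior
    minimum-difference test between the two pedigrees passes (delta,
    alpha), and (ii) every cross-pedigree pair of individual posterior
    mean levels differs in the same direction — the strict reading of
    "detected for all individuals between pedigrees".

    Returns all tested sites with columns is_dmc, direction, p_small,
    consistent; the DMC rate needed by the window scan is
    is_dmc.sum() / len(result).
    """
    sheet = pd.DataFrame([vars(s) for s in samples]).set_index("sample_id")
    ids = [s for s in matrix.samples if s in sheet.index and sheet.loc[s, "tissue"] == tissue]
    sheet = sheet.loc[ids]
    peds = sorted(sheet["pedigree_id"].unique())
    if len(peds) < 2:
        raise ValueError(f"tissue {tissue!r} has samples from fewer than two pedigrees")
    if len(peds) > 2:
        raise ValueError("pedigree comparison requires exactly two pedigrees")
    sub = matrix.subset_samples(ids)
    in_b = (sheet["pedigree_id"] == peds[1]).to_numpy()
    for ped, sel in ((peds[0], ~in_b), (peds[1], in_b)):
        if sel.sum() < 2:
            raise ValueError(f"pedigree {ped!r} has <2 samples in tissue {tissue!r}")

    a0, b0 = prior
    rows = []
    for i in range(sub.n_sites):
        obs = ~sub.missing[i]
        a_cols = np.flatnonzero(obs & ~in_b)
        b_cols = np.flatnonzero(obs & in_b)
        if len(a_cols) < 2 or len(b_cols) < 2:
            continue
        ma = int(sub.meth[i, a_cols].sum()); ta = int(sub.total[i, a_cols].sum())
        mb = int(sub.meth[i, b_cols].sum()); tb = int(sub.total[i, b_cols].sum())
        res = posterior_mindiff_test((ma, ta - ma), (mb, tb - mb),
                                     delta=delta, alpha=alpha, prior=prior)
        # rule (ii): every cross-pedigree pair of individual posterior
        # means must share the sign of the pooled difference
        mean_a = (sub.meth[i, a_cols] + a0) / (sub.total[i, a_cols] + a0 + b0)
        mean_b = (sub.meth[i, b_cols] + a0) / (sub.total[i, b_cols] + a0 + b0)
        if res["direction"] == "up":
            consistent = bool(mean_b.min() > mean_a.max())
        else:
            consistent = bool(mean_b.max() < mean_a.min())
        rows.append((i, res["p_small"], res["direction"], res["level_diff"],
                     consistent, res["is_dmc"] and consistent))
    out = pd.DataFrame(rows, columns=["site_index", "p_small", "direction",
                                      "level_diff", "consistent", "is_dmc"])
    if len(out):
        out = pd.concat([sub.sites.iloc[out["site_index"]].reset_index(drop=True),
                         out.reset_index(drop=True)], axis=1)
    else:
        out = pd.DataFrame(columns=["chrom", "pos", "strand", "site_index", "p_small",
                                    "direction", "level_diff", "consistent", "is_dmc"])
    out.attrs["tissue"] = tissue
    return out


def scan_heritable_windows(
    dmc_table: pd.DataFrame,
    genome: GenomeSequence,
    params: HeritableParams = HeritableParams(),
) -> pd.DataFrame:
    """Merge pedigree DMCs into windows and bound their chance probability.

    DMC sites are merged with gap = window length; a candidate with
    max(n_up, n_down) >= min_synclastic gets ECG from the actual C and G
    counts over a span of max(L, region length) centred on the region
    (clipped at chromosome edges), then P_fp.  Windows with
    P_fp <= threshold are reported.
    """
    n_tested = len(dmc_table)
    dmcs = dmc_table[dmc_table["is_dmc"]] if "is_dmc" in dmc_table else dmc_table
    cols = ["chrom", "start", "end", "n_sites", "n_up", "n_down", "direction",
            "ecg", "p", "p_fp"]
    if len(dmcs) == 0:
        return pd.DataFrame(columns=cols)
    p = params.dmc_ratio
    if p is None:
        if n_tested == 0:
            raise ValueError("cannot estimate DMC ratio from an empty table")
        p = max(len(dmcs) / n_tested, 1.0 / max(n_tested, 2))
    gs = params.genome_size if params.genome_size is not None else genome.size
    L = params.window_bp

    regions = merge_dmrs(dmcs, gap=L)
    rows = []
    for _, reg in regions.iterrows():
        n_syn = int(max(reg["n_up"], reg["n_down"]))
        if n_syn < params.min_synclastic:
            continue
        chrom_len = genome.lengths[reg["chrom"]]
        span = max(L, reg["end"] - reg["start"])
        mid = (reg["start"] + reg["end"]) // 2
        s = max(0, min(mid - span // 2, chrom_len - span))
        e = min(chrom_len, s + span)
        seq = genome.fetch(reg["chrom"], s, e).upper()
        ecg = expected_cpg_count(seq.count("C"), seq.count("G"), e - s)
        p_fp = pfp(n_syn, ecg, p, gs, L)
        if p_fp <= params.pfp_threshold:
            rows.append((reg["chrom"], reg["start"], reg["end"], reg["n_sites"],
                         reg["n_up"], reg["n_down"],
                         "up" if reg["n_up"] >= reg["n_down"] else "down",
                         ecg, p, p_fp))
    out = pd.DataFrame(rows, columns=cols)
    out.attrs["n_tested_sites"] = n_tested
    out.attrs["dmc_ratio"] = p
    return out
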