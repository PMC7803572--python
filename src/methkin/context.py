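"""Sequence- and annotation-derived context for CpG sites.

CpG islands are detected de novo with the classical composition
criterion — segment length > 200 bp, GC content > 50 %, CpG
observed/expected ratio > 0.6 — by taking the union of all qualifying
200-bp sliding windows and re-verifying the criterion on each merged
segment (an approximation of the Gardiner-Garden/UCSC procedure; an
externally supplied CGI BED can bypass detection).  Shores are the 2-kb
bands flanking an island, shelves the next 2 kb; everything further is
open sea.  Genic context uses the precedence 5'UTR > exon > intron >
intergenic across all overlapping genes.
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .model import GeneModel, GenomeSequence, RegionSet

log = logging.getLogger(__name__)

ISLAND_CLASSES = ("CGI", "shore", "shelf", "open_sea")
GENIC_CLASSES = ("five_prime_UTR", "exon", "intron", "intergenic")


def obs_exp_ratio(sequence: str) -> float:
    """CpG observed/expected ratio: (#CpG × L) / (#C × #G).

    N bases are excluded from the base counts and from the effective
    length L.  Returns 0.0 when the sequence contains no C or no G.
    """
    if len(sequence) < 2:
        raise ValueError("sequence must have length >= 2")
    s = sequence.upper()
    n_c = s.count("C")
    n_g = s.count("G")
    n_cpg = s.count("CG")
    eff_len = len(s) - s.count("N")
    if n_c == 0 or n_g == 0:
        return 0.0
    return n_cpg * eff_len / (n_c * n_g)


def gc_fraction(sequence: str) -> float:
    s = sequence.upper()
    eff_len = len(s) - s.count("N")
    if eff_len == 0:
        return 0.0
    return (s.count("C") + s.count("G")) / eff_len


def _window_stats(seq: str, window: int, step: int):
    """Vectorised per-window (GC fraction, obs/exp) via cumulative sums."""
    b = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    is_c = b == ord("C")
    is_g = b == ord("G")
    is_n = b == ord("N")
    is_cpg = np.zeros(len(b), dtype=bool)
    if len(b) > 1:
        is_cpg[:-1] = is_c[:-1] & is_g[1:]

    def wsum(x, width):
        cs = np.concatenate([[0], np.cumsum(x)])
        return cs[width:] - cs[:-width]

    starts = np.arange(0, len(b) - window + 1, step)
    n_c = wsum(is_c, window)[starts]
    n_g = wsum(is_g, window)[starts]
    n_n = wsum(is_n, window)[starts]
    # a CpG is counted in a window if both bases lie inside it
    n_cpg = wsum(is_cpg, window - 1)[starts] if window >= 2 else np.zeros_like(n_c)
    eff = window - n_n
    with np.errstate(divide="ignore", invalid="ignore"):
        gc = np.where(eff > 0, (n_c + n_g) / np.maximum(eff, 1), 0.0)
        oe = np.where((n_c > 0) & (n_g > 0), n_cpg * eff / np.maximum(n_c * n_g, 1), 0.0)
    return starts, gc, oe


def detect_cgis(
    genome: GenomeSequence,
    min_len: int = 200,
    min_gc: float = 0.50,
    min_oe: float = 0.60,
    window: int = 200,
    step: int = 1,
) -> RegionSet:
    """Detect CpG islands by sliding-window union plus re-verification.

    A window qualifies when its GC fraction > min_gc and obs/exp > min_oe;
    qualifying windows are unioned into segments, and a segment is kept
    only if it still satisfies length > min_len (strict), GC > min_gc and
    obs/exp > min_oe when evaluated as a whole.
    """
    rows = []
    for chrom, seq in genome.chroms.items():
        if len(seq) < window:
            log.warning("detect_cgis: chromosome %s shorter than window, skipped", chrom)
            continue
        starts, gc, oe = _window_stats(seq, window, step)
        ok = (gc > min_gc) & (oe > min_oe)
        if not ok.any():
            continue
        # union of qualifying windows via a coverage diff array
        cover = np.zeros(len(seq) + 1, dtype=np.int32)
        np.add.at(cover, starts[ok], 1)
        np.add.at(cover, starts[ok] + window, -1)
        covered = np.cumsum(cover[:-1]) > 0
        edges = np.flatnonzero(np.diff(np.concatenate([[0], covered.view(np.int8), [0]])))
        for s, e in zip(edges[::2], edges[1::2]):
            sub = seq[s:e]
            if (e - s) > min_len and gc_fraction(sub) > min_gc and obs_exp_ratio(sub) > min_oe:
                rows.append((chrom, int(s), int(e), "CGI"))
    return RegionSet(pd.DataFrame(rows, columns=RegionSet.COLUMNS))


def classify_island_context(
    sites: pd.DataFrame,
    cgis: RegionSet,
    shore_bp: int = 2000,
    shelf_bp: int = 2000,
) -> pd.Series:
    """Classify each site as CGI / shore / shelf / open_sea.

    Distance is measured from the nearest island edge; the shore band is
    integer distances [1, shore_bp] and the shelf band
    (shore_bp, shore_bp + shelf_bp].  Ties go to the nearest feature,
    which the band arithmetic realises automatically.
    """
    orig_index = sites.index
    sites = sites.reset_index(drop=True)
    out = np.full(len(sites), "open_sea", dtype=object)
    cgi_df = cgis.merged().df
    for chrom, sub in sites.groupby("chrom", sort=False):
        ivs = cgi_df[cgi_df["chrom"] == chrom]
        if ivs.empty:
            continue
        pos = sub["pos"].to_numpy()
        starts = ivs["start"].to_numpy()
        ends = ivs["end"].to_numpy()
        # distance from each site to each island: 0 if inside
        d = np.maximum.reduce(
            [starts[None, :] - pos[:, None], pos[:, None] - (ends[None, :] - 1),
             np.zeros((len(pos), len(starts)), dtype=np.int64)]
        )
        dmin = d.min(axis=1)
        cls = np.full(len(pos), "open_sea", dtype=object)
        cls[dmin <= shore_bp + shelf_bp] = "shelf"
        cls[dmin <= shore_bp] = "shore"
        cls[dmin == 0] = "CGI"
        out[sub.index.to_numpy()] = cls
    return pd.Series(out, index=orig_index, name="island_class")


def classify_genic_context(sites: pd.DataFrame, genes: Sequence[GeneModel]) -> pd.Series:
    """Classify each site by genic position, precedence 5'UTR > exon > intron."""
    rank = {"five_prime_UTR": 0, "exon": 1, "intron": 2, "intergenic": 3}
    orig_index = sites.index
    sites = sites.reset_index(drop=True)
    best = np.full(len(sites), rank["intergenic"], dtype=np.int8)
    site_order = {c: (sub.index.to_numpy(), sub["pos"].to_numpy()) for c, sub in sites.groupby("chrom", sort=False)}
    for g in genes:
        if g.chrom not in site_order:
            continue
        idx, pos = site_order[g.chrom]
        span_s, span_e = g.span
        in_span = (pos >= span_s) & (pos < span_e)
        if not in_span.any():
            continue
        in_exon = np.zeros(len(pos), dtype=bool)
        for a, b in g.exons:
            in_exon |= (pos >= a) & (pos < b)
        in_utr5 = np.zeros(len(pos), dtype=bool)
        for a, b in g.utr5:
            in_utr5 |= (pos >= a) & (pos < b)
        cls = np.full(len(pos), rank["intergenic"], dtype=np.int8)
        cls[in_span] = rank["intron"]
        cls[in_exon] = rank["exon"]
        cls[in_utr5 & in_exon] = rank["five_prime_UTR"]
        sel = in_span
        best[idx[sel]] = np.minimum(best[idx[sel]], cls[sel])
    inv = {v: k for k, v in rank.items()}
    return pd.Series([inv[v] for v in best], index=orig_index, name="genic_class")


def promoter_window(
    gene: GeneModel,
    up: int = 800,
    down: int = 200,
    chrom_length: Optional[int] = None,
) -> tuple[int, int]:
    """Promoter interval around the TSS, 0-based half-open in genomic order.

    For a + strand gene with TSS t the window is [t-up, t+down); for a
    - strand gene it is the mirror image [t-down+1, t+up+1).  Clipped to
    chromosome bounds when a length is given.
    """
    t = gene.tss
    if gene.strand == "+":
        s, e = t - up, t + down
    else:
        s, e = t - down + 1, t + up + 1
    s = max(s, 0)
    if chrom_length is not None:
        e = min(e, chrom_length)
    return s, e


def promoter_regions(
    genes: Sequence[GeneModel],
    genome: Optional[GenomeSequence] = None,
    up: int = 800,
    down: int = 200,
) -> RegionSet:
    lengths = genome.lengths if genome is not None else {}
    rows = []
    for g in genes:
        s, e = promoter_window(g, up=up, down=down, chrom_length=lengths.get(g.chrom))
        if s < e:
            rows.append((g.chrom, s, e, g.gene_id))
    return RegionSet(pd.DataFrame(rows, columns=RegionSet.COLUMNS))


def upstream1k_first_exon_regions(
    genes: Sequence[GeneModel],
    genome: Optional[GenomeSequence] = None,
    up: int = 1000,
) -> RegionSet:
    """TSS-1kb-upstream plus first-exon span, used for promoter-DMR screening."""
    lengths = genome.lengths if genome is not None else {}
    rows = []
    for g in genes:
        first_exon = g.exons[0] if g.strand == "+" else g.exons[-1]
        t = g.tss
        if g.strand == "+":
            s, e = t - up, t + 1
        else:
            s, e = t, t + up + 1
        s, e = min(s, first_exon[0]), max(e, first_exon[1])
        s = max(s, 0)
        if g.chrom in lengths:
            e = min(e, lengths[g.chrom])
        if s < e:
            rows.append((g.chrom, s, e, g.gene_id))
    return RegionSet(pd.DataFrame(rows, columns=RegionSet.COLUMNS))


def annotate_sites(
    sites: pd.DataFrame,
    cgis: RegionSet,
    genes: Sequence[GeneModel],
    genome: Optional[GenomeSequence] = None,
    up: int = 800,
    down: int = 200,
) -> pd.DataFrame:
    """Full per-site context table: island class, genic class, promoter owner.

    The compound 5'UTR-CGI flag marks sites that are simultaneously in a
    five-prime UTR and a CpG island.
    """
    sites = sites.reset_index(drop=True)
    out = sites.copy()
    out["island_class"] = classify_island_context(sites, cgis)
    out["genic_class"] = classify_genic_context(sites, genes)
    promoters = promoter_regions(genes, genome, up=up, down=down)
    owner = np.full(len(sites), "", dtype=object)
    for chrom, sub in sites.groupby("chrom", sort=False):
        ivs = promoters.df[promoters.df["chrom"] == chrom]
        pos = sub["pos"].to_numpy()
        idx = sub.index.to_numpy()
        for r in ivs.itertuples(index=False):
            hit = (pos >= r.start) & (pos < r.end)
            for i in idx[hit]:
                owner[i] = owner[i] + ("," if owner[i] else "") + r.label
    out["in_promoter_of"] = owner
    out["utr5_cgi"] = (out["genic_class"] == "five_prime_UTR") & (
        out["island_class"] == "CGI"
    )
    return out
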