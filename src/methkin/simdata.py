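"""Synthetic WGBS study generator.

Emulates the structure of a two-tissue (muscle/testis), two-breed,
three-age (1/4/9 years), two-pedigree design with 20 samples: CpG-rich
islands on a CpG-depleted background genome, gene models with a
configurable fraction of island promoters, beta-binomial read counts at
configurable mean coverage, planted tissue/age/breed effects on the
logit scale, pedigree-shared heritable windows, a genetic random effect
with covariance sigma^2 K from the pedigree, and FPKM expression values
coupled (with either sign) to promoter methylation for a designated gene
subset.  Every generator is a pure function of (config, seed), with one
independent RNG stream per generator so adding one never perturbs the
others.  Ground truth for every planted signal is returned alongside.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from . import io as mio
from .model import (
    ExpressionTable,
    GeneModel,
    GenomeSequence,
    MethCountMatrix,
    RegionSet,
    SampleRecord,
)

BASES = np.array(list("ACGT"))


@dataclass
class SimulationConfig:
    seed: int = 0
    # genome
    n_chroms: int = 2
    chrom_length: int = 100_000
    background_gc: float = 0.38
    cpg_depletion: float = 0.5       # survival prob of a background CpG
    n_cgis_per_chrom: int = 8
    cgi_length: int = 500
    cgi_gc: float = 0.65
    # genes
    n_genes: int = 40
    gene_span: int = 1200
    frac_tss_in_cgi: float = 0.6
    # counts
    mean_coverage: float = 30.0
    coverage_dispersion: float = 8.0
    bb_concentration: float = 20.0
    # baseline methylation mixture
    cgi_level: float = 0.08
    noncgi_level: float = 0.85
    mu_logit_sd: float = 0.8
    # planted effects (logit scale)
    n_tissue_dmc: int = 100
    tissue_delta: float = 2.0
    frac_tissue_dmc_in_promoter: float = 0.3
    n_age_dmc: int = 100
    age_slope: float = 0.3           # per year
    n_breed_dmc: int = 100
    breed_delta: float = 2.0
    n_heritable_windows: int = 2
    heritable_window_bp: int = 130
    heritable_delta: float = 4.0
    heritable_tissue: str = "testis"
    # random effect
    sigma2_g: float = 0.5
    # expression coupling
    n_coupled_genes: int = 10
    coupling_intercept: float = 3.0
    coupling_slope: float = 4.0
    frac_negative: float = 0.5
    expr_noise_sd: float = 0.3

    def __post_init__(self) -> None:
        for name in ("background_gc", "cgi_gc", "cgi_level", "noncgi_level",
                     "frac_tss_in_cgi", "frac_negative", "cpg_depletion",
                     "frac_tissue_dmc_in_promoter"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.sigma2_g < 0:
            raise ValueError("sigma2_g must be >= 0")
        if self.chrom_length <= 10 * self.cgi_length:
            raise ValueError("chrom_length must exceed 10x cgi_length")

    def rng(self, stream: str) -> np.random.Generator:
        key = zlib.crc32(stream.encode()) & 0x7FFFFFFF
        return np.random.default_rng(np.random.SeedSequence([self.seed, key]))


@dataclass
class TruthTables:
    cgis: RegionSet
    dmc: dict[str, pd.DataFrame] = field(default_factory=dict)
    heritable_windows: pd.DataFrame = field(default_factory=pd.DataFrame)
    coupled_genes: pd.DataFrame = field(default_factory=pd.DataFrame)
    promoter_truth: Optional[pd.DataFrame] = None  # gene x sample true levels


# ---------------------------------------------------------------------------
# genome


def _sample_background(rng: np.random.Generator, length: int, gc: float,
                       depletion: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    seq = rng.choice(4, size=length, p=p)  # 0=A 1=C 2=G 3=T
    # CpG depletion: mutate the G of most CG dinucleotides to A/T.
    # Replacing a G by A/T can never create a new CG, so one pass suffices.
    cg = np.flatnonzero((seq[:-1] == 1) & (seq[1:] == 2))
    kill = cg[rng.random(len(cg)) > depletion]
    seq[kill + 1] = np.where(rng.random(len(kill)) < 0.5, 0, 3)
    return seq


def simulate_genome(
    config: SimulationConfig,
) -> tuple[GenomeSequence, RegionSet, list[GeneModel]]:
    """Background genome with planted CpG islands and gene models.

    Every planted island satisfies the detection criterion (length>200,
    GC>50 %, obs/exp>0.6) in isolation — verified at generation time,
    resampling island sequence if a draw narrowly misses.
    """
    from .context import gc_fraction, obs_exp_ratio  # local import, no cycle

    rng = config.rng("genome")
    chroms: dict[str, str] = {}
    cgi_rows = []
    margin = 5000
    for ci in range(config.n_chroms):
        chrom = f"chr{ci + 1}"
        seq = _sample_background(rng, config.chrom_length, config.background_gc,
                                 config.cpg_depletion)
        # stratified island slots with >=4 kb spacing for clean
        # shore/shelf classification: one island per equal-width stratum,
        # jittered within the room the spacing leaves
        slots: list[int] = []
        if config.n_cgis_per_chrom > 0:
            usable = config.chrom_length - 2 * margin - config.cgi_length
            stride = usable / config.n_cgis_per_chrom
            room = stride - config.cgi_length - 4200
            if room < 0:
                raise ValueError("CGIs do not fit the chromosome; reduce count or length")
            slots = [int(margin + i * stride + rng.integers(0, max(int(room), 1)))
                     for i in range(config.n_cgis_per_chrom)]
        p_cgi = np.array([(1 - config.cgi_gc) / 2, config.cgi_gc / 2,
                          config.cgi_gc / 2, (1 - config.cgi_gc) / 2])
        for s in sorted(slots):
            for _ in range(50):
                island = rng.choice(4, size=config.cgi_length, p=p_cgi)
                s_str = "".join(BASES[island])
                if (gc_fraction(s_str) > 0.50 and obs_exp_ratio(s_str) > 0.60
                        and s_str.count("CG") >= 10):
                    break
            else:  # pragma: no cover - astronomically unlikely
                raise RuntimeError("failed to sample a qualifying island")
            seq[s: s + config.cgi_length] = island
            cgi_rows.append((chrom, s, s + config.cgi_length, "CGI"))
        chroms[chrom] = "".join(BASES[seq])

    cgis = RegionSet(pd.DataFrame(cgi_rows, columns=RegionSet.COLUMNS))
    genes = _place_genes(config, rng, chroms, cgis)
    return GenomeSequence(chroms), cgis, genes


def _place_genes(config, rng, chroms, cgis) -> list[GeneModel]:
    genes: list[GeneModel] = []
    used: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    cgi_df = cgis.df
    n_in_cgi = int(round(config.frac_tss_in_cgi * config.n_genes))
    span = config.gene_span

    def build(chrom: str, a: int, strand: str, gid: str) -> GeneModel:
        exons = [(a, a + 300), (a + span - 400, a + span)]
        utr5 = [(a, a + 100)] if strand == "+" else [(a + span - 100, a + span)]
        tss = a if strand == "+" else a + span - 1
        return GeneModel(gid, chrom, strand, tss, exons, utr5)

    def free(chrom: str, a: int) -> bool:
        if a < 0 or a + span > len(chroms[chrom]):
            return False
        return all(e <= a or s >= a + span for s, e in used[chrom])

    gi = 0
    cgi_order = rng.permutation(len(cgi_df))
    for k in cgi_order:
        if gi >= n_in_cgi:
            break
        r = cgi_df.iloc[k]
        strand = "+" if rng.random() < 0.5 else "-"
        a = int(r["start"]) + 50 if strand == "+" else int(r["end"]) - 50 - span
        if free(r["chrom"], a):
            genes.append(build(r["chrom"], a, strand, f"gene{gi:03d}"))
            used[r["chrom"]].append((a, a + span))
            gi += 1
    attempts = 0
    while gi < config.n_genes and attempts < 50_000:
        attempts += 1
        chrom = f"chr{int(rng.integers(config.n_chroms)) + 1}"
        a = int(rng.integers(0, len(chroms[chrom]) - span))
        if free(chrom, a):
            genes.append(build(chrom, a, "+" if rng.random() < 0.5 else "-",
                               f"gene{gi:03d}"))
            used[chrom].append((a, a + span))
            gi += 1
    return sorted(genes, key=lambda g: (g.chrom, g.span[0]))


# ---------------------------------------------------------------------------
# pedigree / samples


def simulate_pedigree(config: SimulationConfig) -> list[SampleRecord]:
    """Two founder pairs, four male offspring each; 20 tissue samples.

    Muscle is sampled from all 12 animals and testis from the 8 male
    offspring, mirroring a 12-muscle + 8-testis design.  Offspring ages
    are 1/4/9/4 years per pedigree so each tissue keeps >=2 samples per
    age group; breed follows pedigree.
    """
    records: list[SampleRecord] = []
    offspring_ages = [1.0, 4.0, 9.0, 4.0]
    for p_i, (ped, breed) in enumerate([("P1", "BMX"), ("P2", "LW")]):
        sire, dam = f"{ped}_sire", f"{ped}_dam"
        animals = [(sire, 9.0, "M", None, None), (dam, 9.0, "F", None, None)]
        for k, age in enumerate(offspring_ages):
            animals.append((f"{ped}_o{k + 1}", age, "M", sire, dam))
        for aid, age, sex, s_id, d_id in animals:
            records.append(SampleRecord(
                sample_id=f"{aid}_muscle", tissue="muscle", breed=breed,
                age_years=age, sex=sex, pedigree_id=ped,
                sire_id=s_id, dam_id=d_id, animal_id=aid))
            if sex == "M" and s_id is not None:  # testes from male offspring
                records.append(SampleRecord(
                    sample_id=f"{aid}_testis", tissue="testis", breed=breed,
                    age_years=age, sex=sex, pedigree_id=ped,
                    sire_id=s_id, dam_id=d_id, animal_id=aid))
    return records


# ---------------------------------------------------------------------------
# methylomes


def _cpg_dinucleotides(genome: GenomeSequence) -> pd.DataFrame:
    rows = []
    for chrom, seq in genome.chroms.items():
        b = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        pos = np.flatnonzero((b[:-1] == ord("C")) & (b[1:] == ord("G")))
        rows.append(pd.DataFrame({"chrom": chrom, "pos": pos}))
    return pd.concat(rows, ignore_index=True)


def simulate_methylomes(
    genome: GenomeSequence,
    cgis: RegionSet,
    samples: Sequence[SampleRecord],
    config: SimulationConfig,
    genes: Optional[Sequence[GeneModel]] = None,
) -> tuple[MethCountMatrix, TruthTables]:
    """Beta-binomial counts from the logit-linear generative model.

    Per CpG dinucleotide i and sample j:
    logit pi_ij = mu_i + planted effects(design_j) + g_ij with
    g_.j ~ N(0, sigma^2 K); total_ij ~ NegBin(mean, dispersion)
    truncated >= 1; meth_ij ~ BetaBinomial(total_ij, pi_ij, conc).
    Both strands of a dinucleotide are distinct site records sharing mu
    and effects but with independent count draws.
    """
    from .context import promoter_regions
    from .diffmeth import kinship_from_pedigree

    rng = config.rng("methylomes")
    dinucs = _cpg_dinucleotides(genome)
    n_d = len(dinucs)
    sheet = pd.DataFrame([vars(s) for s in samples])
    n_s = len(sheet)

    # baseline mixture
    in_cgi = np.zeros(n_d, dtype=bool)
    for reg in cgis.df.itertuples(index=False):
        sel = (dinucs["chrom"] == reg.chrom) & (dinucs["pos"] >= reg.start) \
            & (dinucs["pos"] < reg.end - 1)
        in_cgi |= sel.to_numpy()
    mu = np.where(in_cgi, logit(config.cgi_level), logit(config.noncgi_level))
    mu = mu + rng.normal(0.0, config.mu_logit_sd, size=n_d)

    # design vectors
    x_tissue = (sheet["tissue"] == "testis").to_numpy(float)
    x_breed = (sheet["breed"] != sorted(sheet["breed"].unique())[0]).to_numpy(float)
    ages = sheet["age_years"].to_numpy(float)
    x_age = ages - ages.mean()
    peds = sorted(sheet["pedigree_id"].unique())
    x_ped = (sheet["pedigree_id"] == peds[-1]).to_numpy(float)

    # planted effect site selection (disjoint across factors)
    avail = rng.permutation(n_d)
    cursor = 0

    def take(n: int) -> np.ndarray:
        nonlocal cursor
        sel = avail[cursor: cursor + n]
        cursor += n
        return np.sort(sel)

    tissue_idx = take(config.n_tissue_dmc)
    if genes is not None and config.frac_tissue_dmc_in_promoter > 0 and len(tissue_idx):
        # retarget a fraction of tissue DMCs into promoter windows so the
        # promoter-DMR screen has true positives
        proms = promoter_regions(genes, genome).df
        in_prom = np.zeros(n_d, dtype=bool)
        for reg in proms.itertuples(index=False):
            in_prom |= ((dinucs["chrom"] == reg.chrom) & (dinucs["pos"] >= reg.start)
                        & (dinucs["pos"] < reg.end)).to_numpy()
        prom_pool = np.flatnonzero(in_prom)
        prom_pool = prom_pool[~np.isin(prom_pool, avail[:cursor])]
        n_retarget = min(int(config.frac_tissue_dmc_in_promoter * len(tissue_idx)),
                         len(prom_pool))
        if n_retarget:
            chosen = rng.choice(prom_pool, size=n_retarget, replace=False)
            tissue_idx = np.sort(np.concatenate(
                [tissue_idx[:len(tissue_idx) - n_retarget], chosen]))
    age_idx = take(config.n_age_dmc)
    breed_idx = take(config.n_breed_dmc)

    # heritable windows: planted inside CGIs dense enough in CpGs
    herit_rows = []
    herit_idx_list = []
    cgi_perm = rng.permutation(len(cgis.df))
    for k in cgi_perm:
        if len(herit_rows) >= config.n_heritable_windows:
            break
        reg = cgis.df.iloc[k]
        s = int(reg["start"]) + 20
        e = s + config.heritable_window_bp
        if e > int(reg["end"]):
            continue
        sel = np.flatnonzero(((dinucs["chrom"] == reg["chrom"])
                              & (dinucs["pos"] >= s) & (dinucs["pos"] < e)).to_numpy())
        if len(sel) < 8 or np.isin(sel, avail[:cursor]).any():
            continue
        herit_rows.append((reg["chrom"], s, e, len(sel)))
        herit_idx_list.append(sel)

    # tissue/breed effects are state switches: hypermethylated sites lose
    # methylation and hypomethylated sites gain it, so the implied group
    # level difference stays large (>= ~0.3 at the default delta); age
    # slopes drift in either direction
    signs_t = np.where(mu[tissue_idx] > 0, -1.0, 1.0)
    signs_a = rng.choice([-1.0, 1.0], size=len(age_idx))
    signs_b = np.where(mu[breed_idx] > 0, -1.0, 1.0)

    eta = np.tile(mu[:, None], (1, n_s))
    eta[tissue_idx] += np.outer(signs_t * config.tissue_delta, x_tissue)
    eta[age_idx] += np.outer(signs_a * config.age_slope, x_age)
    eta[breed_idx] += np.outer(signs_b * config.breed_delta, x_breed)
    herit_signs = []
    x_herit = x_ped * (sheet["tissue"] == config.heritable_tissue).to_numpy(float)
    for sel in herit_idx_list:
        # state switch for the whole window: the second pedigree flips the
        # window's dominant methylation state so every site shows a large,
        # same-direction level difference
        sign = 1.0 if np.mean(mu[sel]) < 0 else -1.0
        herit_signs.append(sign)
        eta[sel] += np.outer(np.full(len(sel), sign * config.heritable_delta), x_herit)

    # genetic random effect, independent per site as in the analysis model
    if config.sigma2_g > 0:
        K = kinship_from_pedigree(list(samples)).to_numpy()
        Lc = np.linalg.cholesky(K + 1e-8 * np.eye(n_s))
        g = np.sqrt(config.sigma2_g) * rng.standard_normal((n_d, n_s)) @ Lc.T
        eta = eta + g

    pi = expit(eta)

    # expand dinucleotides to both-strand site records
    plus = dinucs.assign(strand="+")
    minus = dinucs.assign(pos=dinucs["pos"] + 1, strand="-")
    sites = pd.concat([plus, minus], ignore_index=True)
    site_order = sites.sort_values(["chrom", "pos", "strand"], kind="stable")
    perm = site_order.index.to_numpy()
    dinuc_of_site = np.concatenate([np.arange(n_d), np.arange(n_d)])[perm]
    sites = site_order.reset_index(drop=True)

    n_sites = 2 * n_d
    disp = config.coverage_dispersion
    p_nb = disp / (disp + config.mean_coverage)
    total = rng.negative_binomial(disp, p_nb, size=(n_sites, n_s))
    while (total == 0).any():  # truncate to >= 1 by redrawing zeros
        zeros = total == 0
        total[zeros] = rng.negative_binomial(disp, p_nb, size=int(zeros.sum()))
    pi_site = pi[dinuc_of_site]
    conc = config.bb_concentration
    if np.isinf(conc):
        p_cell = pi_site
    else:
        p_cell = rng.beta(np.maximum(pi_site * conc, 1e-8),
                          np.maximum((1 - pi_site) * conc, 1e-8))
    meth = rng.binomial(total, p_cell)
    matrix = MethCountMatrix(
        sites[["chrom", "pos", "strand"]].reset_index(drop=True),
        list(sheet["sample_id"]),
        meth.astype(np.int64),
        total.astype(np.int64),
        np.zeros((n_sites, n_s), dtype=bool),
    )

    def truth_frame(idx: np.ndarray, signs: np.ndarray, delta: float) -> pd.DataFrame:
        level0 = expit(mu[idx])
        level1 = expit(mu[idx] + signs * delta)
        d = dinucs.iloc[idx]
        out = pd.concat([
            d.assign(strand="+"),
            d.assign(pos=d["pos"] + 1, strand="-"),
        ], ignore_index=True)
        out["direction"] = np.tile(np.where(signs > 0, "up", "down"), 2)
        out["logit_delta"] = np.tile(signs * delta, 2)
        out["level_delta"] = np.tile(level1 - level0, 2)
        return out.sort_values(["chrom", "pos", "strand"]).reset_index(drop=True)

    truth = TruthTables(cgis=cgis)
    truth.dmc["tissue"] = truth_frame(tissue_idx, signs_t, config.tissue_delta)
    # for age the meaningful contrast is the full observed span, not one year
    age_span = float(ages.max() - ages.min())
    truth.dmc["age"] = truth_frame(age_idx, signs_a, config.age_slope * age_span)
    truth.dmc["age"]["logit_delta_per_year"] = (
        truth.dmc["age"]["logit_delta"] / age_span)
    truth.dmc["breed"] = truth_frame(breed_idx, signs_b, config.breed_delta)
    hw = pd.DataFrame(herit_rows, columns=["chrom", "start", "end", "n_dinucs"])
    if len(hw):
        hw["direction"] = ["up" if s > 0 else "down" for s in herit_signs]
        hw["tissue"] = config.heritable_tissue
    truth.heritable_windows = hw

    if genes is not None:
        proms = promoter_regions(genes, genome)
        rows = {}
        for reg in proms.df.itertuples(index=False):
            sel = ((dinucs["chrom"] == reg.chrom) & (dinucs["pos"] >= reg.start)
                   & (dinucs["pos"] < reg.end)).to_numpy()
            if sel.sum() >= 5:
                rows[reg.label] = pi[sel].mean(axis=0)
        truth.promoter_truth = pd.DataFrame(rows, index=list(sheet["sample_id"])).T
    return matrix, truth


# ---------------------------------------------------------------------------
# expression


def simulate_expression(
    genes: Sequence[GeneModel],
    promoter_truth: pd.DataFrame,
    config: SimulationConfig,
    coupled_genes: Optional[Sequence[str]] = None,
) -> tuple[ExpressionTable, pd.DataFrame]:
    """FPKM table with a designated subset coupled to promoter methylation.

    Coupled genes follow log(FPKM + 1) = a + b * promoter level + eps
    with sign(b) split between positive and negative per config;
    uncoupled genes are independent log-normal noise.
    """
    rng = config.rng("expression")
    samples = list(promoter_truth.columns)
    eligible = [g.gene_id for g in genes if g.gene_id in promoter_truth.index]
    if coupled_genes is None:
        # couple the promoters whose methylation actually varies across
        # samples (those carrying planted differential sites) — coupling
        # to a flat promoter would be undetectable by construction
        n = min(config.n_coupled_genes, len(eligible))
        spread = promoter_truth.loc[eligible].std(axis=1)
        coupled_genes = list(spread.sort_values(ascending=False).index[:n])
    missing = [g for g in coupled_genes if g not in promoter_truth.index]
    if missing:
        raise ValueError(f"coupled genes lack promoter CpGs: {', '.join(missing)}")

    n_neg = int(round(config.frac_negative * len(coupled_genes)))
    signs = np.array([-1.0] * n_neg + [1.0] * (len(coupled_genes) - n_neg))
    rng.shuffle(signs)
    values = {}
    for g in genes:
        if g.gene_id in coupled_genes:
            k = list(coupled_genes).index(g.gene_id)
            meth = promoter_truth.loc[g.gene_id].to_numpy(dtype=float)
            b = signs[k] * config.coupling_slope
            a = config.coupling_intercept - b * meth.mean() + config.coupling_slope / 2
            log_expr = a + b * meth + rng.normal(0, config.expr_noise_sd, len(samples))
        else:
            log_expr = rng.normal(config.coupling_intercept, 1.0) \
                + rng.normal(0, 0.5, len(samples))
        values[g.gene_id] = np.expm1(np.maximum(log_expr, 0.0))
    table = ExpressionTable(pd.DataFrame(values, index=samples).T)
    coupling = pd.DataFrame({
        "gene_id": list(coupled_genes),
        "sign": ["negative" if s < 0 else "positive" for s in signs],
        "slope": signs * config.coupling_slope,
    })
    return table, coupling


# ---------------------------------------------------------------------------
# full dataset to disk


def write_dataset(out_dir, config: SimulationConfig) -> dict:
    """Run every generator and write the pipeline's input files.

    Produces genome.fa, genes.gtf, sample_sheet.tsv, per-sample plus- and
    minus-strand bedGraphs, expression.tsv, and truth/ BED+TSV tables.
    Returns the in-memory objects for convenience.
    """
    out_dir = Path(out_dir)
    (out_dir / "counts").mkdir(parents=True, exist_ok=True)
    (out_dir / "truth").mkdir(exist_ok=True)

    genome, cgis, genes = simulate_genome(config)
    samples = simulate_pedigree(config)
    matrix, truth = simulate_methylomes(genome, cgis, samples, config, genes=genes)
    expr, coupling = simulate_expression(genes, truth.promoter_truth, config)
    truth.coupled_genes = coupling

    mio.write_fasta(genome, out_dir / "genome.fa")
    mio.write_gtf_minimal(genes, out_dir / "genes.gtf")
    mio.write_sample_sheet(samples, out_dir / "sample_sheet.tsv")
    mio.write_expression(expr, out_dir / "expression.tsv")
    lv_pct = 100.0 * matrix.levels()
    for j, sid in enumerate(matrix.samples):
        for strand, suffix in (("+", "plus"), ("-", "minus")):
            sel = (matrix.sites["strand"] == strand).to_numpy() & ~matrix.missing[:, j]
            with open(out_dir / "counts" / f"{sid}.{suffix}.bedGraph", "w") as fh:
                for i in np.flatnonzero(sel):
                    site = matrix.sites.iloc[i]
                    m = matrix.meth[i, j]
                    t = matrix.total[i, j]
                    fh.write(f"{site.chrom}\t{site.pos}\t{site.pos + 1}\t"
                             f"{lv_pct[i, j]:.0f}\t{m}\t{t - m}\n")
    mio.write_regions_bed(truth.cgis, out_dir / "truth" / "cgis.bed")
    for factor, df in truth.dmc.items():
        mio.write_results_tsv(df, out_dir / "truth" / f"dmc_{factor}.tsv")
    mio.write_results_tsv(truth.heritable_windows, out_dir / "truth" / "heritable_windows.tsv")
    mio.write_results_tsv(coupling, out_dir / "truth" / "coupled_genes.tsv")
    return {"genome": genome, "cgis": cgis, "genes": genes, "samples": samples,
            "matrix": matrix, "truth": truth, "expression": expr}
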