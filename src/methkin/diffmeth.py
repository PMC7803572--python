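"""Differential-methylation engines and DMR construction.

Two per-site tests are provided:

* ``posterior_mindiff_test`` — the minimum-difference test.  Counts are
  pooled within each group and given a Beta posterior under a uniform
  prior; a site is differential when the posterior probability that the
  two group levels differ by less than ``delta`` (default 0.3) is at
  most ``alpha`` (default 0.01).

* ``fit_binomial_glmm_pql`` — a binomial generalized linear mixed model
  with a genetic random effect whose covariance is sigma^2 K for a
  pedigree kinship matrix K, fitted by penalized quasi-likelihood.  Each
  PQL step forms the usual working response and weights, then solves the
  induced linear mixed model exactly via an eigendecomposition, with the
  variance component profiled out by REML.  Wald p-values use a standard
  normal reference (PQL likelihoods are not true likelihoods, so no LRT).

DMRs are runs of differential CpGs in which consecutive sites lie within
500 bp of one another.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit, logit

from .model import MethCountMatrix, RegionSet, SampleRecord

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# beta-posterior minimum-difference test


@dataclass(frozen=True)
class BetaPosterior:
    alpha: float
    beta: float

    @property
    def mean(self) -> float:
        return self.alpha / (self.alpha + self.beta)


def beta_posterior(m: int, u: int, prior: tuple[float, float] = (1.0, 1.0)) -> BetaPosterior:
    """Posterior Beta(m + a0, u + b0) for a level with m methylated / u not."""
    if m < 0 or u < 0:
        raise ValueError("counts must be non-negative")
    a0, b0 = prior
    return BetaPosterior(m + a0, u + b0)


def _mindiff_integral(pa: BetaPosterior, pb: BetaPosterior, delta: float, grid_n: int) -> float:
    # E_{theta_A}[ F_B(theta_A + delta) - F_B(theta_A - delta) ] via a
    # midpoint rule on the probability scale of A (quantile grid):
    u = (np.arange(grid_n) + 0.5) / grid_n
    qa = stats.beta.ppf(u, pa.alpha, pa.beta)
    upper = stats.beta.cdf(np.minimum(qa + delta, 1.0), pb.alpha, pb.beta)
    lower = stats.beta.cdf(np.maximum(qa - delta, 0.0), pb.alpha, pb.beta)
    return float(np.mean(upper - lower))


def posterior_mindiff_test(
    group_a: tuple[int, int],
    group_b: tuple[int, int],
    delta: float = 0.3,
    alpha: float = 0.01,
    grid_n: int = 512,
    prior: tuple[float, float] = (1.0, 1.0),
) -> dict:
    """Minimum-difference test on pooled (meth, unmeth) counts per group.

    Returns p_small = P(|theta_A - theta_B| < delta) under independent
    Beta posteriors, computed by a deterministic symmetrized quantile
    grid; the site is differential when p_small <= alpha.  Direction is
    'up' when group B's posterior mean exceeds group A's.
    """
    ma, ua = group_a
    mb, ub = group_b
    if ma + ua <= 0 and mb + ub <= 0:
        raise ValueError("both groups empty")
    pa = beta_posterior(ma, ua, prior)
    pb = beta_posterior(mb, ub, prior)
    # symmetrize so that swapping groups is exact to floating point
    p_small = 0.5 * (
        _mindiff_integral(pa, pb, delta, grid_n)
        + _mindiff_integral(pb, pa, delta, grid_n)
    )
    diff = pb.mean - pa.mean
    return {
        "p_small": p_small,
        "is_dmc": p_small <= alpha,
        "direction": "up" if diff >= 0 else "down",
        "level_diff": diff,
    }


# ---------------------------------------------------------------------------
# kinship


def kinship_from_pedigree(records: Sequence[SampleRecord]) -> pd.DataFrame:
    """Additive relationship matrix between samples, by the tabular method.

    Relationships are computed between the underlying animals (founders
    have diagonal 1; A(i,j) = 0.5[A(j, sire_i) + A(j, dam_i)];
    diag(i) = 1 + 0.5 A(sire_i, dam_i)) and expanded to samples, so two
    samples from one animal are fully correlated off-diagonal.
    """
    parents: dict[str, tuple[Optional[str], Optional[str]]] = {}
    for r in records:
        known = parents.get(r.animal_id)
        cur = (r.sire_id, r.dam_id)
        if known is not None and known != cur:
            raise ValueError(f"inconsistent parents for animal {r.animal_id}")
        parents[r.animal_id] = cur

    # topological order: parents before offspring
    order: list[str] = []
    state: dict[str, int] = {}

    def visit(a: str) -> None:
        if state.get(a) == 2:
            return
        if state.get(a) == 1:
            raise ValueError(f"cyclic pedigree at animal {a}")
        state[a] = 1
        for p in parents.get(a, (None, None)):
            if p is not None:
                if p not in parents:
                    parents[p] = (None, None)  # phantom founder
                visit(p)
        state[a] = 2
        order.append(a)

    for a in list(parents):
        visit(a)

    idx = {a: i for i, a in enumerate(order)}
    n = len(order)
    A = np.zeros((n, n))
    for i, a in enumerate(order):
        s, d = parents[a]
        si = idx.get(s) if s is not None else None
        di = idx.get(d) if d is not None else None
        for j in range(i):
            val = 0.0
            if si is not None:
                val += 0.5 * A[j, si]
            if di is not None:
                val += 0.5 * A[j, di]
            A[i, j] = A[j, i] = val
        A[i, i] = 1.0 + (0.5 * A[si, di] if si is not None and di is not None else 0.0)

    sample_ids = [r.sample_id for r in records]
    animal_idx = [idx[r.animal_id] for r in records]
    K = A[np.ix_(animal_idx, animal_idx)]
    return pd.DataFrame(K, index=sample_ids, columns=sample_ids)


# ---------------------------------------------------------------------------
# binomial GLMM via PQL


@dataclass
class GlmmFit:
    beta_hat: np.ndarray
    se: np.ndarray
    sigma2_g: float
    converged: bool
    n_iter: int
    wald_p: np.ndarray
    scale: float = 1.0
    flags: list[str] = field(default_factory=list)


def _reml_gamma(
    z: np.ndarray,
    Xt: np.ndarray,
    lam: np.ndarray,
    gamma: float,
    scale: Optional[float],
):
    """REML pieces for V = phi * (gamma*diag(lam) + I) in rotated coordinates.

    ``scale=None`` profiles phi out in closed form (phi_hat = quadratic
    form / (n - p)); a number fixes it.
    """
    n, p = Xt.shape
    w = 1.0 / (gamma * lam + 1.0)
    XtW = Xt * w[:, None]
    G = Xt.T @ XtW
    try:
        cov_u = np.linalg.inv(G)
    except np.linalg.LinAlgError:
        return None
    beta = cov_u @ (XtW.T @ z)
    resid = z - Xt @ beta
    quad = float(resid @ (w * resid))
    sign, logdetG = np.linalg.slogdet(G)
    if sign <= 0:
        return None
    logdetS = float(np.sum(np.log(gamma * lam + 1.0)))
    if scale is None:
        # profiled REML scale, bounded below at 1: beta-binomial style
        # noise can only inflate variance relative to binomial
        phi = quad / (n - p)
        if phi >= 1.0:
            ll = -0.5 * ((n - p) * np.log(phi) + logdetS + logdetG + (n - p))
        else:
            phi = 1.0
            ll = -0.5 * (logdetS + logdetG + quad)
    else:
        phi = scale
        ll = -0.5 * ((n - p) * np.log(phi) + logdetS + logdetG + quad / phi)
    return ll, beta, cov_u * phi, w, phi


def fit_binomial_glmm_pql(
    y: np.ndarray,
    r: np.ndarray,
    X: np.ndarray,
    K: np.ndarray,
    tol: float = 1e-5,
    max_iter: int = 100,
    sigma2: Optional[float] = None,
    scale: Optional[float] = None,
    sigma2_max: float = 25.0,
) -> GlmmFit:
    """Fit y_i ~ Bin(r_i, pi_i), logit pi = X beta + g, g ~ N(0, sigma2 K).

    The working linear mixed model of each PQL step has residual
    variance scale * W^-1; by default both the genetic component and the
    quasi-likelihood scale are profiled out by REML (the scale absorbs
    extra-binomial dispersion such as beta-binomial counts).  Fixing
    ``sigma2`` (e.g. to 0) also fixes the scale at 1 unless ``scale`` is
    given, so that sigma2=0 with K=I reduces exactly to an ordinary
    binomial GLM fitted by IRLS.
    """
    y = np.asarray(y, dtype=float)
    r = np.asarray(r, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    K = np.asarray(K, dtype=float)
    n, p = X.shape
    if np.any(y > r) or np.any(y < 0) or np.any(r <= 0):
        raise ValueError("need 0 <= y <= r and r >= 1 elementwise")
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("X is rank deficient")

    flags = []
    if np.all(y == 0) or np.all(y == r):
        flags.append("quasi_separation")

    prop = (y + 0.5) / (r + 1.0)
    eta = logit(prop)
    g = np.zeros(n)
    beta = np.linalg.lstsq(X, eta, rcond=None)[0]
    eta = X @ beta + g

    fixed_s2 = sigma2 is not None
    if fixed_s2 and scale is None:
        scale = 1.0  # pure binomial model when the user pins the structure
    phi = scale if scale is not None else 1.0
    s2 = float(sigma2) if fixed_s2 else 0.1

    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        pi = np.clip(expit(eta), 1e-6, 1 - 1e-6)
        w = np.maximum(r * pi * (1 - pi), 1e-8)
        z = eta + (y - r * pi) / w

        # rotate: V = s2 K + phi W^-1 = phi D^1/2 (gamma M + I) D^1/2
        # with M = W^1/2 K W^1/2 and gamma = s2 / phi
        sw = np.sqrt(w)
        M = (sw[:, None] * K) * sw[None, :]
        lam, U = np.linalg.eigh(M)
        lam = np.maximum(lam, 0.0)
        zt = U.T @ (sw * z)
        Xt = U.T @ (sw[:, None] * X)

        if fixed_s2:
            gamma_new = s2 / phi if phi > 0 else 0.0
        else:
            res = optimize.minimize_scalar(
                lambda gm: -_reml_gamma(zt, Xt, lam, gm, scale)[0],
                bounds=(0.0, sigma2_max),
                method="bounded",
                options={"xatol": 1e-4},
            )
            gamma_new = float(res.x)
            # check the boundary explicitly: bounded Brent can miss gamma = 0
            at0 = _reml_gamma(zt, Xt, lam, 0.0, scale)
            atg = _reml_gamma(zt, Xt, lam, gamma_new, scale)
            if at0 is not None and (atg is None or at0[0] >= atg[0]):
                gamma_new = 0.0
        out = _reml_gamma(zt, Xt, lam, gamma_new, scale)
        if out is None:
            return GlmmFit(beta, np.full(p, np.nan), s2, False, it,
                           np.full(p, np.nan), phi, flags + ["singular"])
        _, beta_new, cov, wv, phi = out
        s2_new = gamma_new * phi

        # BLUP of g: s2 K V^-1 (z - X beta) = gamma K W^1/2 U S U' W^1/2 resid
        resid_t = zt - Xt @ beta_new
        g_new = gamma_new * (K @ (sw * (U @ (wv * resid_t))))

        d_beta = np.max(np.abs(beta_new - beta))
        d_s2 = abs(s2_new - s2)
        beta, s2, g = beta_new, s2_new, g_new
        eta = X @ beta + g
        if d_beta < tol and d_s2 < tol:
            converged = True
            break

    se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        zstat = np.where(se > 0, beta / se, np.nan)
    wald_p = 2.0 * stats.norm.sf(np.abs(zstat))
    if not converged:
        flags.append("not_converged")
    return GlmmFit(beta, se, s2, converged, it, wald_p, phi, flags)


# ---------------------------------------------------------------------------
# DMC scans


def _group_pooled_counts(matrix: MethCountMatrix, cols: np.ndarray):
    m = np.where(matrix.missing[:, cols], 0, matrix.meth[:, cols]).sum(axis=1)
    t = np.where(matrix.missing[:, cols], 0, matrix.total[:, cols]).sum(axis=1)
    return m, t - m


def dmc_scan(
    matrix: MethCountMatrix,
    samples: Sequence[SampleRecord],
    factor: str,
    method: str = "pql",
    alpha: float = 0.01,
    delta: float = 0.3,
    covariates: Sequence[str] = ("age_years",),
    kinship: Optional[pd.DataFrame] = None,
    min_group: int = 2,
) -> pd.DataFrame:
    """Scan every site for a differential effect of a binary design factor.

    method='pql' fits the binomial GLMM per site with the factor as the
    tested coefficient, the listed covariates (age by default) as fixed
    effects, and the pedigree kinship as random-effect covariance; a DMC
    is a site with Wald p <= alpha.  method='mindiff' pools counts per
    factor level and applies the beta-posterior minimum-difference test.

    Returns one row per tested site with p, direction (second factor
    level relative to the first), level- and logit-scale estimates.
    """
    if method not in ("pql", "mindiff"):
        raise ValueError(f"unknown method {method!r}")
    sheet = pd.DataFrame([vars(s) for s in samples]).set_index("sample_id")
    sheet = sheet.loc[[s for s in matrix.samples if s in sheet.index]]
    if list(sheet.index) != list(matrix.samples):
        matrix = matrix.subset_samples(list(sheet.index))
    values = sheet[factor]
    levels = sorted(values.unique())
    if len(levels) < 2:
        raise ValueError(f"factor {factor!r} is constant across samples")
    if len(levels) > 2:
        raise ValueError(f"factor {factor!r} has >2 levels; test pairs separately")
    ind = (values == levels[1]).to_numpy()
    if method == "pql":
        for lev, sel in ((levels[0], ~ind), (levels[1], ind)):
            if sel.sum() < min_group:
                raise ValueError(f"group {lev!r} has fewer than {min_group} samples")
        if kinship is None:
            kinship = kinship_from_pedigree(list(samples))
        kinship = kinship.loc[matrix.samples, matrix.samples]

    lv = matrix.levels()
    rows = []
    n_skipped = 0
    for i in range(matrix.n_sites):
        obs = ~matrix.missing[i]
        if method == "mindiff":
            a_cols = np.flatnonzero(obs & ~ind)
            b_cols = np.flatnonzero(obs & ind)
            if len(a_cols) == 0 or len(b_cols) == 0:
                n_skipped += 1
                continue
            ma = int(matrix.meth[i, a_cols].sum()); ta = int(matrix.total[i, a_cols].sum())
            mb = int(matrix.meth[i, b_cols].sum()); tb = int(matrix.total[i, b_cols].sum())
            res = posterior_mindiff_test((ma, ta - ma), (mb, tb - mb), delta=delta, alpha=alpha)
            if not res["is_dmc"]:
                continue
            rows.append((i, res["p_small"], res["direction"], res["level_diff"], np.nan))
        else:
            cols = np.flatnonzero(obs)
            if (obs & ind).sum() < min_group or (obs & ~ind).sum() < min_group:
                n_skipped += 1
                continue
            y = matrix.meth[i, cols].astype(float)
            r = matrix.total[i, cols].astype(float)
            if np.all(y == 0) or np.all(y == r) or np.all(lv[i, cols] == lv[i, cols][0]):
                n_skipped += 1
                continue
            Xcols = [np.ones(len(cols)), ind[cols].astype(float)]
            for cov_name in covariates:
                Xcols.append(sheet[cov_name].to_numpy(dtype=float)[cols])
            X = np.column_stack(Xcols)
            fit = fit_binomial_glmm_pql(y, r, X, kinship.to_numpy()[np.ix_(cols, cols)])
            if not fit.converged:
                n_skipped += 1
                continue
            p = fit.wald_p[1]
            if not (p <= alpha):
                continue
            diff = np.nanmean(lv[i, cols][ind[cols]]) - np.nanmean(lv[i, cols][~ind[cols]])
            rows.append((i, p, "up" if fit.beta_hat[1] >= 0 else "down", diff,
                         fit.beta_hat[1]))
    if n_skipped:
        log.info("dmc_scan(%s, %s): %d sites skipped", factor, method, n_skipped)
    out = pd.DataFrame(rows, columns=["site_index", "p_value", "direction",
                                      "level_diff", "beta_logit"])
    if len(out):
        site_cols = matrix.sites.iloc[out["site_index"]].reset_index(drop=True)
        out = pd.concat([site_cols, out.reset_index(drop=True)], axis=1)
    else:
        out = pd.DataFrame(columns=["chrom", "pos", "strand", "site_index",
                                    "p_value", "direction", "level_diff", "beta_logit"])
    out["factor"] = factor
    out["method"] = method
    return out


def merge_dmrs(dmcs: pd.DataFrame, gap: int = 500) -> pd.DataFrame:
    """Merge DMC sites within ``gap`` bp of one another into DMRs.

    Input needs columns chrom, pos, direction.  Returns one row per DMR
    with member count and per-direction counts; singleton DMRs allowed.
    """
    cols = ["chrom", "start", "end", "n_sites", "n_up", "n_down"]
    if len(dmcs) == 0:
        return pd.DataFrame(columns=cols)
    rows = []
    for chrom, sub in dmcs.sort_values(["chrom", "pos"]).groupby("chrom", sort=True):
        pos = sub["pos"].to_numpy()
        direction = sub["direction"].to_numpy()
        breaks = np.flatnonzero(np.diff(pos) > gap) + 1
        for seg in np.split(np.arange(len(pos)), breaks):
            d = direction[seg]
            rows.append((chrom, int(pos[seg[0]]), int(pos[seg[-1]]) + 1, len(seg),
                         int((d == "up").sum()), int((d == "down").sum())))
    return pd.DataFrame(rows, columns=cols)


def screen_promoter_dmrs(
    dmrs: pd.DataFrame, promoters: RegionSet, min_synclastic: int = 5
) -> pd.DataFrame:
    """Keep DMRs overlapping a promoter region with >= min_synclastic
    same-direction member DMCs; annotates the overlapped gene(s)."""
    if len(dmrs) == 0:
        return dmrs.assign(genes="")
    keep, genes = [], []
    prom = promoters.df
    for _, d in dmrs.iterrows():
        if max(d["n_up"], d["n_down"]) < min_synclastic:
            continue
        hits = prom[
            (prom["chrom"] == d["chrom"])
            & (prom["start"] < d["end"])
            & (prom["end"] > d["start"])
        ]
        if len(hits) == 0:
            continue
        keep.append(d)
        genes.append(",".join(hits["label"]))
    out = pd.DataFrame(keep).reset_index(drop=True)
    if len(out):
        out["genes"] = genes
    else:
        out = pd.DataFrame(columns=list(dmrs.columns) + ["genes"])
    return out


def pairwise_age_scan(
    matrix: MethCountMatrix,
    samples: Sequence[SampleRecord],
    delta: float = 0.3,
    alpha: float = 0.01,
) -> dict:
    """Minimum-difference comparisons between all age-group pairs per tissue.

    For each tissue, every older-vs-younger age pair is tested with the
    pooled beta-posterior test; direction 'hyper' means methylation
    increases with age.  Returns per-pair DMC tables and the sites shared
    between the two tissues for the same age pair.
    """
    sheet = pd.DataFrame([vars(s) for s in samples]).set_index("sample_id")
    sheet = sheet.loc[[s for s in matrix.samples if s in sheet.index]]
    matrix = matrix.subset_samples(list(sheet.index))
    results: dict[tuple[str, str], pd.DataFrame] = {}
    tissues = sorted(sheet["tissue"].unique())
    for tissue in tissues:
        in_tissue = (sheet["tissue"] == tissue).to_numpy()
        ages = sorted(sheet.loc[in_tissue, "age_years"].unique())
        if len(ages) < 2:
            log.warning("pairwise_age_scan: tissue %s has <2 age groups, skipped", tissue)
            continue
        for older in reversed(ages):
            for younger in ages:
                if younger >= older:
                    continue
                young_cols = np.flatnonzero(in_tissue & (sheet["age_years"] == younger).to_numpy())
                old_cols = np.flatnonzero(in_tissue & (sheet["age_years"] == older).to_numpy())
                rows = []
                for i in range(matrix.n_sites):
                    yc = young_cols[~matrix.missing[i, young_cols]]
                    oc = old_cols[~matrix.missing[i, old_cols]]
                    if len(yc) == 0 or len(oc) == 0:
                        continue
                    my = int(matrix.meth[i, yc].sum()); ty = int(matrix.total[i, yc].sum())
                    mo = int(matrix.meth[i, oc].sum()); to = int(matrix.total[i, oc].sum())
                    res = posterior_mindiff_test((my, ty - my), (mo, to - mo),
                                                 delta=delta, alpha=alpha)
                    if res["is_dmc"]:
                        rows.append((i, res["p_small"],
                                     "hyper" if res["direction"] == "up" else "hypo",
                                     res["level_diff"]))
                df = pd.DataFrame(rows, columns=["site_index", "p_small", "age_direction",
                                                 "level_diff"])
                if len(df):
                    df = pd.concat(
                        [matrix.sites.iloc[df["site_index"]].reset_index(drop=True),
                         df.reset_index(drop=True)], axis=1)
                results[(tissue, f"{older:g}v{younger:g}")] = df
    shared = {}
    pairs = {key[1] for key in results}
    if len(tissues) >= 2:
        for pair in pairs:
            tabs = [results.get((t, pair)) for t in tissues]
            tabs = [t for t in tabs if t is not None and len(t)]
            if len(tabs) >= 2:
                keys = [set(map(tuple, t[["chrom", "pos", "strand"]].to_numpy())) for t in tabs]
                shared[pair] = set.intersection(*keys)
    return {"per_pair": results, "shared_sites": shared}


def consensus_dmcs(tables: Sequence[pd.DataFrame], mode: str = "intersection") -> pd.DataFrame:
    """Combine DMC tables from multiple callers (e.g. external BGLMM tools).

    mode='intersection' keeps sites present in every table; mode='union'
    keeps all, deduplicated.  Tables need chrom/pos/strand columns.
    """
    if not tables:
        return pd.DataFrame(columns=["chrom", "pos", "strand"])
    keys = [set(map(tuple, t[["chrom", "pos", "strand"]].to_numpy())) for t in tables]
    sel = set.intersection(*keys) if mode == "intersection" else set.union(*keys)
    base = pd.concat(tables).drop_duplicates(["chrom", "pos", "strand"])
    mask = [tuple(x) in sel for x in base[["chrom", "pos", "strand"]].to_numpy()]
    return base[mask].sort_values(["chrom", "pos", "strand"]).reset_index(drop=True)
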