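# Methods

This package re-implements a whole-genome bisulfite sequencing (WGBS)
differential-methylation workflow for a family-structured, two-tissue
design, together with a synthetic-study generator used to validate every
stage. This note records the models, the defaults and why they were
chosen, the numerical conventions, and what the synthetic data does and
does not emulate.

## Data model and conventions

All intervals are 0-based half-open; GTF input (1-based inclusive) is
converted at the reader boundary. A CpG site is one cytosine in CpG
context on one strand: the dinucleotide at position *p* contributes two
distinct records, (*p*, +) and (*p*+1, −). Symmetric-pair merging is
available at load time but off by default. A cell with zero total reads
is treated as missing everywhere — a 0/0 proportion carries no level
information — and a site absent from a sample's file is missing, not
zero.

## Site filtering

A cell passes when its coverage lies in [`min_cov`, `max_cov`]
(defaults 10 and 300; extreme coverage indicates mapping artefacts or
PCR stacks) and a site is retained when at least
⌈`min_presence_fraction` × n⌉ cells pass (default 0.5, i.e. half the
samples; the ceiling makes odd n conservative). Failing cells of
retained sites are masked. Filtering is idempotent and the retained
count is monotone in both parameters. Hypo-/hypermethylated CpGs are
those with mean level strictly below 0.10 / strictly above 0.90 across
passing samples; per-site entropy is the binary entropy of the level in
bits (a pragmatic summary of intermediate methylation; read-level
epi-entropy is out of scope).

## CpG islands, shores, shelves, genic context

Islands are detected with the classical composition criterion — segment
length > 200 bp, GC fraction > 50 %, CpG observed/expected ratio > 0.6,
where obs/exp = #CpG × L / (#C × #G) — by sliding a 200-bp window at
1-bp steps, taking the union of qualifying windows, and re-verifying
the criterion on each merged segment (an approximation of the
Gardiner-Garden/UCSC procedure; a user-supplied island BED bypasses
detection). All three inequalities are strict; a merged segment of
exactly 200 bp is rejected. Shores are integer distances [1, 2000] from
the nearest island edge, shelves (2000, 4000]; distance is measured
from the edge, not the midpoint, which had to be fixed by convention.
Genic classes use the precedence 5'UTR > exon > intron > intergenic
across all overlapping genes; the compound 5'UTR-CGI flag marks sites in
both a 5'UTR and an island. The expression-correlation promoter is
[TSS−800, TSS+200) in transcription direction; the promoter-DMR screen
instead uses TSS−1000..TSS plus the first exon, as the two analyses
define their windows differently.

## Beta-posterior minimum-difference test

For a two-group comparison at one site, counts are pooled within each
group and the group level θ gets a Beta(m+1, u+1) posterior (uniform
prior — the package's declared convention; a per-sample hierarchical
model is out of scope). The statistic is

P_small = P(|θ_A − θ_B| < δ),  δ = 0.3 by default,

and the site is differential when P_small ≤ α (default 0.01): the data
must place at least 99 % posterior mass on a level difference of 0.3 or
more. P_small is computed deterministically on a 512-point quantile
(midpoint-in-probability) grid of one posterior, evaluating the other
posterior's CDF at ±δ, and symmetrized as the mean of the two
orderings so that swapping groups is exact to floating point. The grid
agrees with a 10⁶-draw Monte Carlo oracle to ~10⁻³. Because the
criterion demands the whole credible mass beyond δ, true differences
near δ are called only about half the time — that is the intended
behaviour of a minimum-difference test, not a power defect.

## Kinship and the binomial GLMM

The additive relationship matrix is built from the pedigree by the
tabular method (founders diagonal 1; A(i,j) = ½[A(j,s) + A(j,d)];
diagonal 1 + ½A(s,d)), computed between animals and expanded to
samples, so the muscle and testis samples of one animal are fully
correlated. Cyclic pedigrees are rejected; unknown parents become
phantom founders.

Counts are modelled as y_i ~ Bin(r_i, π_i) with

logit π = Xβ + g,  g ~ N(0, σ² K),

fitted by penalized quasi-likelihood: each step forms the working
response z = η + (y − rπ)/w and weights w = rπ(1−π), then solves the
linear mixed model z = Xβ + g + e with Var(e) = φ W⁻¹ exactly, using
one eigendecomposition of W^{1/2} K W^{1/2} per step so the variance
profile is a cheap one-dimensional REML search (in γ = σ²/φ, with the
scale φ available in closed form). Both σ² and the quasi-likelihood
scale φ are estimated by default; φ is bounded below at 1 because
beta-binomial-type noise can only inflate variance relative to
binomial. The scale matters: real (and simulated) WGBS counts are
overdispersed, and without φ the Wald test is anti-conservative.
Fixing σ² (e.g. to 0) also fixes φ = 1, so that σ² = 0 with K = I is
exactly an ordinary binomial GLM — verified against an independent IRLS
implementation to <10⁻³.

Wald p-values use a standard-normal reference (PQL objective values are
not true likelihoods, so no LRT). σ² is kept non-negative by the search
bounds; convergence requires max|Δβ| and |Δσ²| below 10⁻⁵ within 100
iterations. Non-converged, quasi-separated (all-0 or all-r) and
zero-variance sites are flagged and excluded from DMC lists with a
logged count. Under the null with σ² = 0.5 and the two-pedigree
kinship, the test at P < 0.01 rejects ≈0.6 % of sites.

The published analyses this mirrors intersected three BGLMM
implementations; this package ships one PQL solver plus a consensus
hook (`consensus_dmcs`) that can intersect result tables from external
callers.

## DMCs, DMRs, promoter screen

`dmc_scan` tests one binary factor per run (tissue, breed, sex), with
age as a fixed covariate in the GLMM, and emits sites with p ≤ α.
Age-group comparisons use the minimum-difference test pairwise within
tissue (9v1, 9v4, 4v1), reporting hyper-/hypomethylation with age and
the cross-tissue shared sites. DMRs merge differential sites on a
chromosome whenever consecutive sites are ≤ 500 bp apart (singletons
allowed; equivalent to transitive closure, verified by brute force).
The promoter screen keeps DMRs that overlap a TSS−1kb/first-exon region
and contain at least 5 synclastic (same-direction) member sites.

## Heritable methylation regions

Within one tissue, a site is a pedigree DMC when (i) the pooled
minimum-difference test between the two pedigrees passes (δ = 0.3,
α = 0.01) and (ii) every cross-pedigree pair of individual posterior
mean levels differs in the same direction — the strict reading of
"detected for all individuals", which is this package's explicit
convention. Pedigree DMCs are merged with a 500-bp gap; a candidate
region with N = max(n_up, n_down) ≥ 5 is scored with the binomial
model: X ~ Bin(round(ECG), p/2) with ECG = #C × #G / L from the
region's actual sequence over a span of max(L, region length), p the
genome-wide pedigree-DMC rate (estimated from the scan unless
overridden), and

P_fp(X ≥ N) = 2 (1 − P(X < N)) · GS / L,

a genome-wide Bonferroni-style bound reported uncapped (it may exceed
1). ECG is rounded to the nearest integer to form the binomial support,
which reproduces the canonical worked example: ECG = 125 × 125 / 500 =
31.25 ≈ 31 and P_fp(X ≥ 5) = 0.012 at p = 0.003, GS = 2.5 Gb. The
binomial tail matches exhaustive pmf summation to relative error 10⁻¹².

Two model caveats are inherited deliberately: the factor 2 and GS both
come from the printed formula (whether GS should count strands is not
resolvable from it), and the independence assumption ignores that the
two strand records of one dinucleotide are strongly correlated, making
the bound optimistic for paired sites.

## Expression integration

Promoter methylation is the unweighted per-sample mean level over the
promoter's retained CpGs, for promoters with ≥ 10 of them. Coupling
uses Spearman correlation (average ranks, t-approximation p, default
α = 0.01); constant vectors give an NA result. Site-level correlations
assign each site to its promoter owner first, else its host gene.
Group expression differences use the unpaired Mann-Whitney rank-sum
test, exact for small untied samples — the source analyses name a
signed-rank test for what is an unpaired comparison, which requires
pairing; the paired variant is available behind a flag for genuinely
paired designs. FPKM values enter rank statistics untransformed (ranks
are invariant to log).

## Synthetic-study generator

The generator emulates the study design end to end: 2 pedigrees × 2
breeds, founders plus four male offspring each (ages 1/4/9/4 years),
muscle from all 12 animals and testis from the 8 male offspring — 20
samples. Defaults, chosen once as a desk-scale analogue of the study:

| parameter | default | rationale |
|---|---|---|
| genome | 2 × 100 kb | desk scale; ~8 k site records |
| background GC / CpG survival | 0.38 / 0.5 | CpG-depleted background so island detection is non-trivial |
| islands per chromosome / length / GC | 8 / 500 bp / 0.65 | pass the detection criterion by construction (verified at generation) |
| mean coverage / NB dispersion | 30× / 8 | desk-speed analogue of deep WGBS |
| beta-binomial concentration | 20 | realistic overdispersion without destabilizing PQL at n = 20 |
| baseline levels (island / background) | 0.08 / 0.85 | bimodal methylome, global mean ≈ 0.7 |
| tissue / breed effect | 2.0 logits | state switch; implied level difference ≈ 0.35 |
| age slope | 0.3 logit/year | 2.4 logits over the 1-9 y span |
| heritable windows | 2 × 130 bp, 4 logits | dense island windows, ≥ 14 strand-site records |
| genetic variance σ² | 0.5 | moderate familial covariance |

Counts follow the analysis model: logit π = μ + planted effects + g
with g ~ N(0, σ²K) drawn independently per site, totals negative
binomial truncated ≥ 1, methylated counts beta-binomial. Planted
tissue/breed effects and heritable windows are *state switches*
(direction opposite to the baseline state), because an effect pushing
an already-saturated site further into saturation produces a level
difference near zero and would be undetectable by construction; age
slopes keep random signs. Expression for coupled genes follows
log(FPKM+1) = a + b·(promoter level) + ε with configurable |b| and
sign; coupled genes are the promoters with the largest across-sample
methylation spread, since coupling to a flat promoter is likewise
undetectable by construction. Every generator is a pure function of
(config, seed) with one RNG stream per generator, so adding a generator
never perturbs the others.

What the generator does not emulate: read-level data (no FASTQ,
conversion errors, mapping bias), sequence-dependent coverage,
correlated methylation along the chromosome beyond the planted
structure, SNP effects, or cell-type mixtures. Passing tests therefore
demonstrate correctness of the statistical machinery under the stated
model, not robustness to those real-data complications.

A note on nulls: with σ² > 0 the kinship random effect itself gives
sibs shared per-site effects, i.e. genuine pedigree-level methylation
differences (≈1.3 % of sites at σ² = 0.5) that the heritable scan
rightly detects. The clean null for inheritance therefore sets σ² = 0
in addition to planting no windows.

## Numerical choices and degenerate inputs

Probabilities are clipped to [10⁻⁶, 1−10⁻⁶] inside the PQL working
response; working weights are floored at 10⁻⁸. The REML search is
bounded (γ ∈ [0, 25], xatol 10⁻⁴) with an explicit boundary check at 0.
Fisher's exact test reports the sample odds ratio (declared; 0/0 → NaN,
x/0 → ∞) with p = 1 for any zero margin. Rank-sum tests on all-tied
data return p = 1. Regions at chromosome edges are clipped before
counting C/G. Problem sizes throughout the test-suite (40-200 kb
genomes, 500-8 000 sites, 2 000-site calibrations) are the package's
desk-scale defaults; all thresholds are config keys, never hard-coded.
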