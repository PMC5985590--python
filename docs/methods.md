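# Methods

`aspenscan` reimplements, end to end, the analysis style used to map a
single large-effect locus for a climate-adaptive phenology trait (bud
set) in a small forest-tree resequencing cohort, and to characterize
and date the selective sweep at that locus. Because the original
sequencing data are not redistributable, every stage is driven by a
synthetic-cohort generator with known ground truth; the package is
therefore verifiable without any external data.

## Study design being emulated

94 diploid individuals from 12 populations spanning roughly
56-66 degrees N. Population structure is extremely weak (genome-wide
Weir-Cockerham FST around 0.002) while one genomic region carries a
completed hard sweep restricted to the northern populations. The
derived allele at the causal SNP follows a steep latitudinal cline,
advances bud set by ~28 days in the derived homozygote with partial
dominance, and accounts for ~65% of the variance in the genetic value
of bud set.

## Synthetic data

**Background SNPs** come from the Balding-Nichols island model:
per-population allele frequencies are Beta-distributed around an
ancestral frequency `p ~ U(0.05, 0.95)` with parameters
`p(1-F)/F, (1-p)(1-F)/F`, `F = 0.0021`; genotypes are binomial draws.
This background is exchangeable across populations: it reproduces the
magnitude of differentiation but deliberately carries no spatial
autocorrelation, so isolation by distance and background clinality are
absent by design. Consequently PC1 of the full panel is carried by the
planted clinal region, not by the background, and a Mantel test on the
background alone is null. Tests that pass on this cohort demonstrate
the statistics' behaviour under the stated differentiation level, not
the full spatial texture of real data.

**Wright-Fisher trajectories.** The beneficial allele has genotype
fitnesses 1, 1+s/2, 1+s (additive selection on the allele). Forward
paths start from one copy, use deterministic selection followed by
binomial drift, and are rejection-conditioned on fixation; the
accepted path is reversed for the backward-time coalescent. The
trajectory core is JIT-compiled; the rejection budget (default
200,000 attempts) is an explicit failure mode.

**Trajectory-conditioned sweep coalescent.** A Hudson-style ancestral
recombination graph over a continuous region with infinite-sites
mutation. Backward in time: (i) a neutral phase of `T_fix * 4N`
generations after fixation; (ii) the sweep phase in discrete
generations along the trajectory, with two allelic classes - lineages
coalesce within their class at rate `C(k,2) / (2N x_t)` (frequency
`x_t` of their class), and recombination between a lineage's material
(extended to the selected site) moves the piece distal to the selected
site into a class drawn from the current frequency; (iii) a neutral
phase before the origin of the mutation, after the forced coalescence
of the derived class at the origin. Event times in the sweep phase use
cumulative per-generation hazards with binary search, so long
quasi-neutral trajectories cost O(events log T), not O(T). Each
lineage carries its ancestral material as segments tagged with the
bitmask of descendant samples; mutations are laid down
Poisson-by-lifetime when a lineage dies, and a segment that reaches
the full sample set (its local MRCA) is dropped. Consequently all
emitted sites are polymorphic in the sample; sample-fixed derived
sites are not produced, and the CLR background spectrum is used in its
polymorphic-classes-only form.

**Population-size rescaling.** The study-scale `Ne = 92,000` is
infeasible to simulate directly; the engine rescales to
`N_sim <= 5000` (configurable) multiplying s, mu and r by the same
factor, preserving `4Ns`, theta and rho. A configurable floor on
`4Ns` (default 1.0) guards against rescaling a sweep into effective
neutrality. A rescaling-invariance test checks that halving `N_sim`
with compensating rates leaves diversity within sampling error.

**Cohort assembly.** The swept region is simulated once as a northern
"sweep pool" and once as a southern "neutral pool" (same theta/rho,
region default 25 kb with `4Ne*mu = 0.0081/bp`, `rho/theta = 0.229`).
Each individual draws its two region haplotypes from the sweep pool
with probability following a logistic cline in latitude (midpoint at
the two central populations, slope 1 per degree - the cline shape is a
free design choice recorded in the truth record); sites private to one
pool are ancestral in the other. The causal site is inserted at the
selected position, derived on sweep-pool haplotypes.

**Phenotype.** Genotype means are `0, -28h, -28` days for the
ancestral homozygote, heterozygote and derived homozygote, with
dominance coefficient `h = 0.75` ("partial dominance" without a stated
coefficient). The non-causal variance (an equal split of a
background-SNP polygenic term and Gaussian noise) is solved so that
the causal SNP's variance share equals the configured 0.65. Two
definitions are supported: `additive` (default) targets the
regression/effect-size share - the quantity a single-SNP effect/se
estimate measures - while `genotypic` targets the one-way R^2 of the
three genotype classes. With `h = 0.75` the genotypic share exceeds
the additive one by the dominance variance (~0.71 vs 0.65 at the
defaults). The truth record stores both realized values, recomputed
from the emitted matrices.

## Variant QC

Site filters (depth < 400x or > 4500x, > 200 reads with mapping
quality 0, repeat-masked, scaffolds < 2 kb) use strict inequalities -
boundary values are kept. SNP filters: biallelic, > 5 bp from indels,
call rate >= 70% computed after masking genotypes with GQ < 10,
heterozygote-excess exact test p >= 1e-8, MAF > 5%. The excess-het
test is the exact conditional-on-allele-counts distribution restricted
to the upper (excess) tail; under Hardy-Weinberg sampling it removes
< 0.1% of SNPs at 1e-8. Polarization uses two outgroup genotypes with
a fixed precedence (more distant outgroup first; homozygous and
matching an ingroup allele), never emitting an allele absent from the
ingroup. LD pruning is greedy within 50-SNP windows slid by 5: of a
pair with r^2 > 0.2 the lower-MAF SNP is removed, ties dropping the
higher index.

## Population structure

PCA standardizes dosages by `sqrt(p(1-p))` after per-SNP
mean-imputation of missing calls; axis signs are fixed by the
largest-loading SNP. Axis significance uses the Tracy-Widom (GOE)
distribution with an effective-marker moment correction; the effective
marker count for axis j is estimated from the eigenvalues *below* it,
so a genuinely structured leading axis cannot mask itself (estimating
it from all eigenvalues destroys power once one eigenvalue dominates;
null calibration was verified by simulation, rejection rate ~2-5% at
alpha = 0.05). The TW1 CDF itself is computed numerically as the
Fredholm determinant of the Airy kernel `Ai((x+y)/2)/2`
(Nystrom/Gauss-Legendre); it reproduces the standard 95%/99% critical
values 0.9793/2.0234 to 1e-5. FST is Weir-Cockerham (1984) with
variance components a, b, c; windowed and pairwise-population values
are ratio-of-sums (multi-locus) estimates, recorded as such in the
output. The Mantel test permutes population labels with
`p = (1 + #(r_perm >= r_obs)) / (1 + n_perm)`. LD decay fits the
Hill-Weir expectation of r^2 with its sample-size correction by
nonlinear least squares.

## Adaptation scan

* **BLUP genetic values.** Bud-set records are modelled with site,
  block-in-site and year-in-site as fixed effects and clone as a
  random effect (REML via statsmodels MixedLM; the nested dummy design
  is reduced to full column rank by pivoted QR). A (site, year)
  exclusion list accommodates dropped trials. BLUPs are validated
  against a direct solve of the mixed-model equations.
* **PCA-loading outliers.** The squared SNP-PC1 correlation, rescaled
  by its genome-wide mean to match the chi-square(1) expectation.
* **Latent-factor environmental association.** A ridge/SVD analog of
  the latent-factor mixed model: K latent factors are the top left
  singular vectors of the genotype matrix residualized on the
  environment score; each SNP is regressed on (env, factors) and the
  env t-statistic is the z-score, with genomic-control median
  rescaling for the reported p. This deterministic formulation targets
  the same estimand as the original MCMC algorithm; at K = 0 it
  reduces exactly to per-SNP OLS.
* **Kinship LMM GWAS.** `y = mu + x b + u + e`, `u ~ N(0, sg^2 K)`,
  with the centered GRM `K = WW^T/m`. K is eigendecomposed once; the
  variance ratio is profiled per SNP by bounded 1-D REML optimization
  over `log10(delta) in [-5, 5]`; Wald tests use the t reference with
  n-2 df, so the identity-kinship case reproduces OLS exactly. In the
  pipeline the GRM is built from the background chromosome only
  (leave-one-chromosome-out): at desk scale the scanned region is a
  large fraction of the panel and a whole-panel GRM absorbs the causal
  signal itself (measured: PVE at the causal SNP drops from 0.65 to
  0.14). At the real study's marker density this distinction is
  negligible.
* **PVE** is the standard effect-size/standard-error formula
  `2b^2 f(1-f) / (2b^2 f(1-f) + se^2 * 2N f(1-f))`.
* **q-values** use the smoothed-lambda pi0 estimate (cubic polynomial
  over lambda = 0.05..0.95) with the monotone step-up transform.
* **Consensus** takes SNPs significant (q < 0.05) in at least two of
  the three scans and merges candidates within 50 kb into regions.
* **Fine-mapping** enumerates causal configurations up to size 2
  (configurable): z is multivariate normal with covariance
  `R + s_ncp^2 R_C R_C^T` under configuration C (non-centrality
  standard deviation 5.2, per-SNP prior 0.01, LD matrix regularized by
  +1e-4 on the diagonal); the reported set is the smallest covering
  99% of configuration mass (greedy by coverage).

Because the swept region is one recent haplotype block, the minimum-p
GWAS SNP is a SNP in near-perfect LD with the causal one rather than
reliably the causal SNP itself (rank 1 in ~30% of seeds); candidate
identification is at the region/haplotype level, which is what the
fine-mapper is for. PVE recovery at the causal SNP is unaffected
(mean 65.4% over 20 seeds).

## Sweep statistics

EHH is the exact pair-count definition (fraction of carrier pairs
identical from the core out to each flanking SNP). iHS integrates EHH
against physical distance by trapezoid, truncated where EHH < 0.05;
SNPs whose homozygosity tracts reach the region edge are skipped
(NaN + reason) unless edge truncation is explicitly enabled - useful
for small regions around incomplete sweeps. The sign convention is
`ln(iHH_ancestral / iHH_derived)`: sweeping derived alleles give
negative values. nSL replaces the integral with the mean pairwise
count of consecutive identical SNPs, making it coordinate-free.
Standardization subtracts the mean and divides by the SD within 100
equal derived-frequency bins. H1/H12/H2 come from exact haplotype
frequencies in 200-SNP windows (one window if the region is smaller),
averaged in 10-kb/5-kb sliding windows. Windowed pi divides summed
per-site heterozygosity (n/(n-1) corrected) by the callable window
length, excluding windows under 10% callable when a mask is supplied.

**CLR scan.** The composite likelihood ratio contrasts, at each 2-kb
grid point, the background site-frequency spectrum with its
sweep-transformed version: each of n lineages escapes the sweep
independently with probability `1 - exp(-alpha d)` at distance d;
escapees draw alleles without replacement from the pre-sweep sample
configuration and all hitchhikers share one further draw. This
without-replacement construction makes the full-escape limit reproduce
the background exactly (a tested nesting identity). The transform is
precomputed on an 80-point log grid of `alpha*d` and interpolated;
alpha is maximized over a log-spaced grid (64 points by default), and
sites with `alpha*d` beyond 10 contribute nothing (their transform is
numerically the background). CLR = 2(lnL_sweep - lnL_background),
floored at 0 by including the no-sweep limit in the maximization.
Spectra are smoothed with a 0.5 pseudo-count per observable class.

**Footprint experiment.** Sweep replicates (selected site centered,
`4Ne*mu = 0.0081/bp`, `rho/theta = 0.229`) are CLR-scanned; matched
neutral replicates supply both the background spectrum and the
significance threshold (99th percentile of pooled neutral grid-point
CLR values - the significance rule is a package definition, recorded
in the output, as no standard exists). A single sweep yields multiple
significant peaks scattered over the affected region, so the footprint
is the largest extent of significant grid points after merging points
closer than 50 kb; neutral controls yield single scattered points
(median span ~one grid cell).

## ABC dating

The age T (time since fixation, units of 4Ne generations) and strength
s are drawn from `log10 U(-4, -0.5)` priors; each draw is simulated
with the sweep coalescent and summarized by a fixed 20-statistic
vector: pi/bp, Watterson theta/bp and Tajima's D in 5 equal
subwindows; H1, H12, H2/H1 in the central subwindow; the number of
distinct haplotypes; and the maximum |unstandardized iHS| among the 5
informative SNPs nearest the center. (The summary set is this
package's definition; extending it with per-window haplotype-diversity
summaries was tested and did not improve recovery.) Rejection ABC
standardizes summaries by the table SDs, imputes failed statistics
with column means, and accepts the epsilon-quantile (default 0.005)
nearest draws by Euclidean distance; posterior medians and equal-
tailed 95% CIs are reported. No regression adjustment is applied.
T is reported in coalescent units; conversion to years multiplies by
`4 Ne g` with a configurable generation time (default 15 years) and is
never asserted as part of the inference.

At the defaults (25-kb region, computed theta = 345/rho = 67, 24
haplotypes, 10^4-row table) the posterior median for s generated at
s = 0.016 centers near 0.02-0.025 - a modest upward bias reflecting
footprint saturation: within a 25-kb window, sweeps with s above ~0.01
all carry the whole region, so discrimination rests on edge
recombinants. 95% CI coverage is nominal (50/50 in rehearsal) and
posterior medians are strongly rank-correlated with the generating s.

### The theta/rho printing conflict

The dating parameters as printed (`Ne = 92,000`, `mu = 3.75e-8`,
`r = 0.729e-8`, `L = 25,000`) imply `4*Ne*mu*L = 345` and
`4*Ne*r*L = 67.1`, yet the same source prints `Theta = 86.27` and
`rho = 19.76` - exactly one quarter, internally consistent with each
other and with `r/mu = 0.229`. The API exposes theta and rho directly
(`SweepModel.from_scaled`) so either convention is reproducible; the
dating defaults and the acceptance experiment use the
per-rate parameterization (mu, r, Ne as printed), and the footprint
experiment uses the separately stated per-bp rates
(`4Ne*mu = 0.0081/bp`).

## Problem sizes

Default desk-scale sizes, chosen so the whole suite and the
acceptance script each run in minutes on one core: ABC table 10^4
simulations (reference analyses used 5x10^5), 24 sampled haplotypes
for dating, 60 footprint sweep replicates + 24 neutral controls over
500 kb with 62 haplotypes, cohorts of 94 individuals with 5000
background SNPs. All are configurable upward.

## Known limitations

* The background cohort carries no linkage disequilibrium, spatial
  autocorrelation or genome-wide clinality; PC1-latitude correlation
  and candidate-region concentration are driven by the planted region.
* Sample-fixed derived sites are absent from simulated regions, so
  CLR runs polymorphic-only; with fixed-substitution counts supplied,
  the fixed class participates normally.
* iHS/nSL use physical distance only (no genetic map) and the
  700-kb-window enrichment test is only meaningful on data with
  multi-megabase extent, which the desk-scale generator does not
  produce.
* Rejection ABC without regression adjustment retains the
  saturation-driven upward bias in s described above.
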