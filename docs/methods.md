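# Methods

This note documents the statistical models implemented in `sceqtl`, the
choices made where the design was genuinely open, and what the synthetic
cohorts do and do not establish about behavior on real data.

## Study design the package targets

The pipeline is built for vaccination-challenge single-cell cohorts: tens of
donors sampled before (T0) and three months after (T3m) BCG vaccination,
each sample split into an unstimulated (RPMI) and an LPS-stimulated
fraction — a 4-level condition design (`T0-RPMI`, `T0-LPS`, `T3m-RPMI`,
`T3m-LPS`) — profiled by droplet scRNA-seq over the major PBMC lineages.
With 38 donors this yields ~152 samples per cell type. Because each donor
contributes up to four samples, and cohorts contain cryptically related
donors, every association model carries a kinship random effect.

## Pseudobulk phenotypes

Cells failing QC (mitochondrial fraction > 25%, detected genes < 100 or
> 5000; thresholds configurable) are removed and counts are normalized as
ln(1 + count·10⁴ / cell total). The eQTL phenotype is the mean normalized
value per (donor, condition, cell type); genes are retained per cell type
only if nonzero in ≥ 30% of donors. A donor counts as expressing a gene if
any of its samples is nonzero. Samples with zero cells are missing, not
zero — mapping drops them listwise. Before mapping, each gene is rank
inverse-normal transformed within its context (Blom offset 0.375); the
transform is a config switch (`transform="none"` reports effects in
log-expression units, which is what the effect-recovery checks use).

Latent expression covariates are the leading principal factors of the
covariate-residualized pseudobulk matrix (k = 5 by default), standardized
and mutually orthogonal. This is a PCA surrogate for PEER-style factor
models; for small k the two are near-equivalent, and the factor method sits
behind one function so a different estimator can be dropped in.

## Kinship

Variant QC drops records without an rsID and variants with fewer than three
donors carrying a non-major genotype. LD pruning follows the windowed
greedy scheme (250-variant windows, step 50, r² > 0.2 resolved by removing
the lower-MAF member, ties to the later position) after MAF > 0.05 and
exact-test HWE p > 1e-6 filters. The GRM is the allele-frequency
standardized relationship matrix K = Z Zᵀ/M with Z the centered, scaled
dosages; sample-level kinship is the donor kinship lifted through the
sample→donor indicator, which simultaneously encodes relatedness and
repeated sampling.

A practical caveat quantified during development: the per-test level of the
downstream LMM is sensitive to GRM estimation noise. With only a few
hundred pruned variants behind the GRM the nominal type-I error ran ~0.062
at α = 0.05; with a ~6000-variant background panel (still far below a real
genotyping array) it is 0.049–0.050. Synthetic cohorts therefore draw the
kinship from a separate background chromosome, for two reasons: realistic
GRM precision, and avoiding proximal contamination (at desk scale the
simulated cis region would otherwise be the entire genome the GRM is built
from, which visibly distorts the permutation null — a situation real
analyses do not face because the cis window is a negligible fraction of the
genome).

## The mixed model and the cis scan

Per gene: y = Wα + u + ε, u ~ N(0, σ²_g K_samples), ε ~ N(0, σ²_e I), with
W = intercept + age/sex (when available) + stimulation + vaccination +
latent factors. K is eigendecomposed once per context; the restricted
likelihood is profiled over h² = σ²_g/(σ²_g+σ²_e) on the rotated diagonal
system (64-point grid, bounded refinement, ties broken toward h² = 0 so an
uninformative K pins the fit at the OLS boundary). Per-variant tests hold
the gene's variance components fixed (the EMMAX-style single-fit
approximation) and reduce to weighted least squares in the rotated basis;
the Wald p uses df = n − rank(W) − 1. The plug-in test equals a dense
V⁻¹-weighted regression to 1e-8 and collapses exactly to OLS when K = I.
Cis windows are ±1 Mb around the TSS (inclusive) with MAF strictly > 0.05.

## Permutations, q-values, eGene calling

Gene-level multiplicity uses permutation minima: B permutations (1000 by
default), empirical p = (1 + #{min p_perm ≤ min p_obs})/(1 + B), Storey
q-values (π₀ from the λ-grid 0.05…0.95 with a cubic smoother evaluated at
λ = 0.95, falling back to π₀ = 1), eGenes at q < 0.05, and the maximum top
nominal p among eGenes as the global threshold defining eVariants.

The permutation scheme permutes the donor→genotype assignment, with a
donor's repeated samples moving together — but restricted to
*exchangeability blocks*: connected components of the donor relatedness
graph (pairwise kinship above 0.45) swap slots only with components of the
same size. Free donor permutation is conservative when strongly related
donors are present, because their identical genotypes stop being aligned
with the kinship-downweighted directions (measured: empirical-p mean 0.69
with two duplicate pairs among 40 donors); the blocked scheme restores
uniformity (KS p ≈ 0.15–0.9 in the calibration runs) and is exact when no
relatedness exceeds the threshold. A whitened-residual permutation
(`scheme="rotation"`) is available as a cross-check; it relies on the
fitted variance components whitening exactly and proved anticonservative
under GRM-estimated kinship, so it is not the default.

## Response eQTLs

Three contrasts: BCG (T3m-RPMI vs T0-RPMI), LPS (T0-LPS vs T0-RPMI) and
LPS-after-BCG (T3m-LPS vs T3m-RPMI). Step 1 tests the genotype×condition
coefficient per cis variant (fixed effects: covariates + condition +
dosage + dosage×condition; variance components from the null fit); per
gene the minimum interaction p is Bonferroni-corrected by the tested
variant count and Storey-q'ed across genes; candidates pass q < 0.05 or
raw p < 5e-6. Step 2 refits the candidate variant additively in each
condition separately (literally the cis scan on the condition subset, so
the two agree exactly); a pair is called iff the stimulated-condition fit
passes the step-1 thresholds and the baseline p ≥ 0.05. The baseline
"not significant" cut is a parameter (`baseline_p`): no principled value
exists, 0.05 is the conventional reading.

## Trained-immunity QTLs

TI-response genes come from differential expression between T3m-LPS and
T0-LPS monocytes (two-sided rank-sum by default, or a likelihood-ratio
detection test; BH-adjusted p < 0.05 and |log2FC| > 0.15). The TI
phenotype is the per-donor log2((pseudobulk_T3m-LPS + 1)/(pseudobulk_T0-LPS
+ 1)) of each panel gene, computed on *linear-scale* expression (the stored
log-normalized means are de-logged first; applying the ratio formula to
log-scale values divides any genetic effect by the log-expression magnitude
— roughly an eight-fold attenuation in our cohorts — and makes the fold
change uninterpretable). Donors must have both LPS visits. Mapping uses
the donor-level LMM with kinship and age/sex covariates, and BH adjustment
across all gene×variant pairs of the panel. The original analysis used a
cell-level likelihood whose exact form is not public; the donor-level
fold-change LMM preserves the estimand (genetic shift of the trained
response) and is the documented substitute.

## Colocalization

Wakefield log-ABFs per variant (prior effect SD 0.15 for quantitative and
0.2 for case-control traits), summed over single-causal configurations in
log space, with priors p1 = p2 = 1e-4, p12 = 1e-5. Harmonization aligns
the eQTL beta to the GWAS effect allele (strand complements handled),
drops strand-ambiguous A/T and C/G variants outright, and discards eQTL
rows with p ≥ 0.5 before matching. Loci are scanned only when the minimum
GWAS p in the cis window is < 5e-5, and PP4 ≥ 0.5 flags candidates. The
implementation matches a brute-force enumeration of all (m+1)² single-
causal configurations to 1e-10.

## SMR and HEIDI

b_xy = β_GWAS/β_eQTL at the top cis instrument (required p < 5e-8);
T = z²_e z²_g/(z²_e + z²_g) against χ²₁. HEIDI selects up to 20 non-top
variants with r² to the instrument in [0.05, 0.9] and eQTL p < 1.57e-3,
forms deviations d_i = b_xy(i) − b_xy(top), derives their covariance from
the delta method and the LD correlation matrix, and refers Σ z²_d to a
two-moment (Satterthwaite) scaled chi-square. Development measurements:
the Satterthwaite tail itself is accurate (rejection 0.048–0.052 on exact
chi-square-mixture nulls, including the near-singular correlation spectra
HEIDI produces), and the residual mild excess under a shared causal
(≈ 0.056 at α = 0.05 over 500 replicates) comes from plugging estimated
effects into the covariance — a property of the statistic itself, not the
tail approximation, so it is left as is.

## Effect sharing and allelic imbalance

Sharing uses an empirical-Bayes mixture over canonical covariance patterns
(null, identity, per-context singletons, equal-effects; scale grid
2^{−2..3}): weights by EM on a random effect subset, posterior means and
local false sign rates on the strong (top-eVariant) subset. Data-driven
covariances are out of scope. Sharing-by-magnitude between two contexts:
among effects significant (lfsr < 0.05) in at least one of the pair,
shared iff same sign and min/max magnitude ratio ≥ 0.6.

Allelic imbalance: a single overdispersion ρ is estimated by maximum
likelihood pooled across sites with the mean fixed at μ₀ = 0.5, then each
site with depth ≥ 10 gets a two-sided (tail-doubled) beta-binomial p and
BH adjustment. At ρ = 0 the test equals the exact binomial to 1e-12.
Pooling across *all* sites is the default: restricting the fit to the
central tertile of reference fractions (an option, `rho_sites=
"central-tertile"`) collapses ρ̂ under a homogeneous null (measured
ρ̂ ≈ 0.002 at true ρ = 0.2, type-I 0.58 versus 0.041 for the pooled fit)
because conditioning on small deviations removes precisely the dispersion
being estimated. The cost of the pooled default is conservatism when many
sites are truly imbalanced, since their signal inflates ρ̂.

## Variance partition

Per gene, normalized expression on a random subsample of 5000 cells is
decomposed into crossed random intercepts for cell type, condition and
donor plus residual. The default estimator is a method of moments on
pairwise products with *exact* grand-mean-centering corrections: centering
maps the covariance to MΣM (M = I − J/n), and the moment coefficients are
the sums of (M S_f M) over sharing patterns, computable from group counts
alone. Without the correction the smaller components are absorbed into
the mean (a planted donor fraction of 0.1 was estimated as 0); with it,
planted fractions (0.5, 0.2, 0.1) are recovered to ±0.03 in the median at
5000 cells. Negative estimates are clamped to zero and fractions
renormalized. A dense REML over the three variance ratios is available as
a slow cross-check for modest cell counts and agrees with the MoM within
0.05 per fraction on balanced designs.

## Synthetic cohorts

Genotypes: two latent AR(1) Gaussian haplotypes per donor (parameter
`ld_rho`, blocks of 50 variants) thresholded at the allele-frequency
quantile, giving Hardy–Weinberg hard calls with geometrically decaying
LD; duplicated donors create MZ-twin-like relatedness. Counts: negative
binomial (gamma–Poisson) with log-mean = base + cell-type + condition +
donor intercept + β·dosage + τ·dosage·stim + TI·dosage·(T3m-LPS) + log
library factor; gene-wise dispersion is log-normal. Drawn random-effect
vectors are rescaled to their target SD exactly so recovery tests estimate
a known truth. GWAS summary statistics follow z ~ N(R z_causal, R) with R
the sample LD (regularized 0.95R + 0.05I for the draw); the causal z has
noncentrality sqrt(n·h²/(1−h²)); `distinct` configurations place the trait
causal at r² below a cap to the eQTL causal. Allelic counts are
beta-binomial.

Problem sizes in the checks (chosen to exercise each property at desk
scale): null calibration uses 40 donors (two duplicate pairs) × 4
conditions × 15 cells, 400–500 genes, 300 permutations; additive recovery
200 donors × 50 genes; interaction recovery 40 donors × 20 genes; TI
recovery pools 8–10 cohorts of 100 donors × 20 fold-change QTLs at common
variants (MAF 0.4–0.5) in strong local LD (adjacent r ≈ 0.9, variants
300 kb apart) with effects of half a phenotype SD per allele — the
realistic regime for a targeted TI panel, and the one in which a 0.5-SD
effect (per-gene z capped at 0.5·√(n·var g) ≈ 3.5) is detectable after BH;
coloc and SMR/HEIDI use 100–400 summary-statistic replicates on 40–60
variant loci.

What the synthetic cohorts do not emulate: ambient RNA, doublets, batch
effects beyond what latent factors absorb, population stratification
(relatedness is duplicate pairs only), realistic gene–gene correlation, or
LD from demographic history. Passing tests establish the estimators'
internal correctness and calibration under the generative model, not
robustness to those real-data features.

## Known limitations

- The EMMAX-style plug-in test ignores variance-component uncertainty; at
  152 samples the residual inflation is within the [0.04, 0.06] band only
  when the GRM is precise (see Kinship above).
- HEIDI inherits the plug-in-covariance optimism of the original statistic
  (~0.056 at nominal 0.05).
- The EB sharing model restricts itself to canonical covariances; strongly
  structured cross-context effects will load on the closest canonical
  pattern rather than a data-driven one.
- The permutation exchangeability blocks assume relatedness is block-
  structured; a diffuse relatedness gradient (admixture) would need the
  rotation scheme or finer blocks.
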