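# Methods

This note records the statistical model, the numerical choices, and the
design decisions behind `ssgblup`, in the spirit of a software methods
supplement. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Relationship matrices

**Pedigree.** Pedigrees are topologically renumbered (parents before
offspring); an input already in valid order is preserved as-is so that
writing and re-reading a pedigree is a no-op. Unknown parents are treated as
draws from a single unrelated, non-inbred base population — no unknown-parent
groups or metafounders. Inbreeding coefficients use an exact Meuwissen &
Luo-style recursion (each animal's A-diagonal accumulated over its ancestor
closure via the LDL′ decomposition of A); `A⁻¹` uses Henderson's rules with
the within-family variance `b_i = 0.5 − 0.25(F_s + F_d)` and the convention
F = −1 for an unknown parent, which reproduces the textbook coefficients for
0, 1 or 2 known parents. `A₂₂` is computed by the tabular method on the
genotyped animals' ancestor closure and then subset — exact, and cheap at the
scales this package targets (10³–10⁴ genotyped animals); Colleau's indirect
method would only pay off far beyond that.

**Genomic.** `G = ZZ′ / (2Σ p_j(1−p_j))` with `Z` the allele-frequency-
centered dosage matrix (VanRaden method 1). Allele frequencies are the
observed post-QC frequencies; base-population frequencies are not estimable
without the base genotypes. Because the scaling of `G` and of `A₂₂` are on
different footings, `G` is then tuned as `a + b·G` so that both its mean
diagonal and mean off-diagonal match `A₂₂` (the common implementation; a
diagonal-only mode and an off switch are config options since only the
diagonal criterion is universal across software). The tuned matrix is
blended, `G_b = α·G + β·A₂₂` with α = 0.90, β = 0.10 by default, which also
guarantees invertibility when `G` is rank-deficient (more animals than
informative SNPs). Inversion is by Cholesky factorization; a non-positive-
definite matrix raises an informative error rather than applying a silent
ridge. `H⁻¹ = A⁻¹ + [0 0; 0 G_b⁻¹ − A₂₂⁻¹]` is assembled sparsely: the
correction only touches the genotyped block.

## Genotype quality control

Filter order (each removal attributed to its first failing filter):

1. unknown or duplicate map position, non-autosomal chromosome (all members
   of a duplicated (chromosome, position) group are removed — deterministic
   and order-independent);
2. SNP call rate ≥ 0.90;
3. animal call rate ≥ 0.90;
4. animal parent–progeny Mendelian-conflict rate ≤ 0.01, counting opposing
   homozygotes only (the unambiguous case for unphased dosages), pooled over
   genotyped parents;
5. minor allele frequency ≥ 0.05, computed on the cleaned sample;
6. observed-vs-expected heterozygosity deviation ≤ 0.15.

Frequency-based filters run last so they see the cleaned sample. Missing
calls that survive QC are imputed with the mean dosage `2p_j` only when the
GRM is built, never in the stored genotypes.

## Phenotype preparation

Testicular volume for the pair of testes is `2·(r²·π·L)/1000` dm³ with
r = width/2 by default — a radius is half a caliper width. Published Nellore
TV means (~0.25 dm³) are only reproduced with r = width/4, and the
literature's wording does not settle which was used, so both modes exist and
the choice is logged. Testicular format classes cut the width:length ratio
at 0.5 / 0.625 / 0.75 / 0.875 with boundary membership to the lower class
except the strict "> 0.875" top class. Calving-rest-interval classes are
closed integer bins [0,60], [61,90], [91,120], [121,150], [151,∞) — the
published class labels have one-day gaps and an inconsistent "< 91" variant,
so the bins here are a documented convention, with day 151 in the top class.
Binary outcomes are coded 1 = failure, 2 = success (configurable alias map);
the mapping to the 0/1 liability indicator happens inside the sampler.

Contemporary groups concatenate farm | birth year | birth season | sex |
management group; for traits whose model carries the weaning management
group (GMAND) as an uncorrelated random effect, the management group is
excluded from the CG key. Season comes from a configurable month→season map
(default: wet October–March, dry April–September, the usual split for
central-Brazil pastures). Record filters, applied once and in one pass:
±3.5 SD trimming around the CG mean (continuous traits only, never binary),
then removal of CGs with fewer than 5 records, with no phenotypic
variability (zero SD, or a single category for binary traits), with fewer
than 2 distinct sires, or containing unknown-pedigree animals.

## The Gibbs sampler

Location effects are updated single-site (matching the behavior of the
reference software family for this model class); variances from their
conjugate full conditionals — scaled inverse chi-square for single-trait
additive, residual and uncorrelated-group variances, inverse-Wishart for the
2×2 additive covariance. Systematic effects carry flat priors. Identifiable
full-rank fixed coding: no intercept, the first class factor (CG) keeps all
levels, later factors drop their first level; covariates are centered (age
centered before squaring), which keeps single-site updates well-mixed.
Threshold traits resample latent liabilities from one-sided truncated
normals (plain rejection in the bulk, Robert's translated-exponential
rejection in the tail) with residual variance pinned at 1 and the threshold
at 0.

Bi-trait systems are two record sets — separate measurement events, e.g. a
male BSE record and a female rebreeding record — so no record ever observes
both traits and the residual covariance is structurally unidentified; R is
therefore diagonal (each linear trait's residual sampled, each threshold
trait's fixed at 1). The genetic covariance, the quantity of interest, is
fully identified through H. Animal effects are updated as per-animal
2-vectors with precision `D_i + H⁻¹_ii G_a⁻¹`.

Variance priors default to weakly-informative scaled inverse chi-square /
inverse-Wishart with ν = dimension + 1 and scale from a 0.3/0.7 split of the
phenotypic variance (an ANOVA-style starting value); with thousands of
animals the data dominate. A flat mode (ν = −2, scale 0) exists and is what
the null-calibration tests use, since a weak prior adds a visible floor
(~0.03) to the null posterior mean of h². Chains are single, seeded, and
bit-reproducible; the kernels are numba-compiled and draw from numba's
global RNG, seeded once per chain. The production schedule is 800,000
iterations, 200,000 burn-in, thinning 100 (6,000 retained draws); recovery
experiments in the tests use 20,000 / 5,000 / 10, sized so a fit of ~2,000
records and ~3,000 pedigree animals takes a few seconds.

## Posterior summaries

The "HPD 5%–95%" interval is the 90%-content shortest window over the sorted
draws (leftmost on ties); an equal-tailed 5th/95th-quantile mode is provided
since that phrasing is ambiguous in the literature. Sample SDs use n−1
throughout. The Geweke Z compares the first 10% against the last 50% of the
chain with Bartlett-windowed spectral-density-at-zero variance estimates
(Newey–West lag `⌊4(m/100)^{2/9}⌋`; batch-means below 50 draws per window).
The reported SE divides the posterior SD by √(number of records) — the
field's reporting convention, flagged here as statistically unconventional
since it mixes Monte Carlo and data scales. Heritability includes the
uncorrelated-group variance in the phenotypic denominator by default
(a switch exists).

## Synthetic data

The generator emulates a seedstock recording scheme: discrete generations,
configurable sire:dam ratio producing large paternal half-sib families,
gene-dropped SNP genotypes (founder alleles at uniform-drawn frequencies,
Mendelian transmission, optional genotyping-error injection to exercise QC),
and multivariate breeding values by exact recursion — founders MVN(0, G_a),
descendants parent-average plus Mendelian sampling with the parental-
inbreeding correction ½(1 − (F_s+F_d)/2), so pedigree-mode BVs have exactly
the covariance H ⊗ G_a with H = A that the sampler assumes. Phenotypes add
contemporary-group effects, linear+quadratic age, an optional GMAND effect
and Gaussian residuals; binary traits threshold the latent liability at the
empirical quantile matching the target incidence. Sex-limited recording
(male andrological, female reproductive) makes cross-sex bi-trait runs link
only through the pedigree.

The study-like bundle ships two scales — tiny (~320 pedigree animals, for
smoke tests) and desk (5,000 pedigree animals, 1,000 genotyped, 2,000 SNPs)
— with a trait menu mirroring the study's headline structure: a male
continuous trait at h² = 0.75 (scrotal-circumference-like, with GMAND), a
male continuous trait at h² = 0.05 (ejaculate-volume-like), and two binary
female traits at liability h² 0.17 / incidence 0.28 (stayability-like) and
h² 0.39 / incidence 0.18 (heifer-pregnancy-like), with a configurable
cross-sex genetic correlation. What the generator does **not** emulate:
selection (matings are random, so no selection-induced disequilibrium),
genotype-by-environment interaction, measurement-error processes of semen
scoring, or the confidential distributions of the real farms. Passing
recovery tests therefore demonstrate sampler and pipeline correctness under
the assumed model, not robustness to violations of it.

## Verification experiments (problem sizes)

The acceptance checks run at sizes chosen for a single desk CPU: linear
recovery uses 20 replicates of ~2,000 records (true h² 0.40, reduced chain);
threshold recovery ~3,000 records (liability h² 0.30, incidence 0.30);
cross-sex correlation recovery uses two h² = 0.75 traits on ~2,100 records
per sex with ~50 sires per generation — high heritability is deliberate:
with poorly-estimated breeding values on either side the experiment would
measure identification noise rather than sampler fidelity, and the posterior
mean of r_g genuinely shrinks toward zero when the data carry little
cross-sex information (verified against an independent vectorized sampler).
The sign-recovery check runs 20 smaller replicates at r_g = 0.5. The
Gibbs-vs-REML cross-check uses a balanced design of 160 paternal half-sib
families of 6 (unrelated dams); its EM-REML oracle runs on the exactly
equivalent sire model (σ²_s = σ²_u/4, residual σ²_e + ¾σ²_u), which
converges in under a second where the animal-model EM needs minutes.

## Known limitations

- Single-site Gibbs mixes slowly for strongly confounded fixed effects;
  blocked updates are not implemented.
- No APY or other sparse G⁻¹ approximations: dense genomic algebra limits
  the genotyped set to ~10⁴ animals.
- Multi-trait models stop at two traits; correlation matrices for more
  traits are assembled from pairwise runs.
- Threshold models support binary outcomes; ordinal score traits are fitted
  as linear by default (as in the study's model roster) — the K−1-threshold
  ordinal sampler is not implemented.
- EM-REML is a desk-scale oracle (dense, O(n³) per iteration, slow linear
  convergence), not a production estimator.
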