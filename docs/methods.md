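# Methods

This note documents the statistical models in `sepqtl`, the choices made
where the design was genuinely open, and what the synthetic-cohort tests do
and do not demonstrate about real data.

## The random-intercept linear mixed model

Every association stage shares one engine: a Gaussian linear model with a
random intercept per individual,

    y_is = x_is' beta + u_i + e_is,   u_i ~ N(0, s2_u),  e_is ~ N(0, s2_e),

so that 1–3 serial blood samples per patient contribute without inflating
the effective sample size. All fits use full maximum likelihood (not REML):
nested fixed-effect specifications are then comparable by likelihood-ratio
test (LRT), and every reported eQTL / interaction / module-QTL p-value is a
1-df chi-square LRT.

Writing lambda = s2_u / s2_e, the marginal covariance is block diagonal and
the likelihood profiles down to a 1-D problem in lambda. For fixed lambda
the GLS estimate follows from quasi-demeaning each individual's rows
(`x~ = x − (theta/m) Σx`, `theta = 1 − (1+lambda m)^{−1/2}`); beta and s2_e
then have closed forms. We optimise over log10(lambda) with bounded Brent
search on [−8, 6] and compare against the boundary lambda = 0, where the
model collapses exactly to OLS (this also covers the one-sample-per-
individual case, where s2_u is unidentifiable and pinned to zero).

Numerics: all per-lambda quantities are assembled from fixed cross-product
matrices. With W = [X, y], the transformed Gram matrix is
`M(lambda) = W'W − Σ_u c_u(lambda) B_u`, where `B_u` sums the outer
products of within-group column sums over groups of size `u`. Group sizes
take ≤ 3 distinct values in a serial-sampling cohort, so one likelihood
evaluation costs O(p²) independent of n, and the `ProfiledScan` object
reuses the covariate block across thousands of candidate SNPs (each SNP
contributes only rank-one updates). The engine matches `statsmodels`
MixedLM (ML) to ~1e-6 in log-likelihood and a brute-force grid oracle to
well below 1e-4; both checks are in the test suite. Collinear design
columns are dropped deterministically (leftmost kept); zero residual
variance is flagged, never silently accepted. No boundary correction is
applied to the chi-square reference for fixed-effect LRTs.

## cis-eQTL mapping and hierarchical multiple testing

SNPs within 1 Mb of a gene's TSS are tested for an additive minor-allele
dosage effect with fixed covariates: 7 genotype PCs, 20 hidden expression
factors, rank-inverse-normal (INT) cell proportions (neutrophils,
lymphocytes, monocytes), SRS1 status and diagnosis (CAP/FP).

Multiple testing is hierarchical. Per gene, the peak p-value is Bonferroni-
adjusted by an effective test count M_eff estimated from the eigenvalues of
the local dosage correlation matrix: SNPs are split into consecutive
partitions of ≤ 200, each partition's correlation matrix is shrunk toward
the identity (Ledoit–Wolf) and M_eff is the smallest number of leading
eigenvalues reaching 99% of the trace, summed over partitions and capped at
the SNP count. Adjusted peaks are BH-corrected across genes (eGene: q <
0.05); the largest adjusted peak among passing genes, q*, defines each
eGene's nominal threshold q*/M_eff for additional significant SNPs.

Conditional signals use forward stepwise inclusion (rescan conditioning on
all previously accepted leads; accept the new peak while its nominal p
stays below the per-gene threshold, which is fixed at its first-pass value
throughout) followed by backward re-selection (re-test each signal
conditioning on all other leads; keep the best passing SNP as that signal's
lead or drop the signal) and one final joint model giving each lead's joint
effect, SE and 1-df LRT p. Equal p-values break ties toward the smaller
genomic position. Leads in perfect LD collapse during deduplication.

## Hidden expression factors and INT

The nuisance-factor covariates are the top 20 principal components (of 30
computed) of the expression matrix after regressing the held-out known
covariates (INT cell proportions, SRS1, diagnosis, genotype PCs) out of
each gene — a deterministic, dependency-free stand-in for a Bayesian factor
model used only to build covariates. Missing cell proportions are imputed
with the cohort median *before* the INT transform (the ordering is
ambiguous in the field's descriptions; imputing first keeps the transform's
rank semantics exact). INT uses the Blom offset: Phi^{-1}((r − 3/8)/(n +
1/4)), average ranks for ties.

## Genotype-by-context interactions

Each independent signal is tested for dosage-by-context interaction (model
covariates + other same-gene leads + G + E + G:E; E removed from the
covariate stack when already present). Context coding: SRS1 = 1, FP = 1,
female = 1, so a "magnifier" (sign(beta_G) = sign(beta_GxE)) means a larger
effect in SRS1/FP/female. Eligibility requires ≥ 2 distinct minor-allele-
homozygote individuals in each level of a binary context or each half of a
continuous context split at the sample median (ties to the lower half).
For sex — not a standard covariate — the main eQTL must first stay
significant with sex added. BH is applied within each context family.

The permutation null permutes SRS across samples, or diagnosis across
patients (constant within patient), recomputes the BH-significant count per
permutation, and reports the add-one empirical p. When every individual
contributes one sample, the LMM collapses to OLS and the permutation loop
runs through an O(n)-per-permutation projection identity; a test verifies
this fast path equals the general route. The count statistic is discrete,
so for calibration experiments we additionally form the randomised
(tie-broken) permutation p, which is exactly uniform under exchangeability;
the add-one estimator itself is reported for inference and is
conservative, as it should be.

## Effect sharing between conditions

Pairs of effect estimates (b1, b2) for the same SNP–gene pair in two
cohorts are modelled with an empirical-Bayes mixture of bivariate normal
priors `Σ_{k,w} pi_{k,w} N(0, w U_k + V_j)`. Covariance patterns: null,
equal effects, condition-1-only, condition-2-only, independent effects
(identity), and optionally a rank-1 data-driven matrix from the strong-set
SVD. The identity pattern is required: without it the mixture assigns
essentially zero likelihood to discordant pairs and neither the opposite-
direction category nor the small-SE no-shrinkage limit is reachable. The
scale grid is logarithmic from min(se²)/10 to 2·max(b²) (10 points).
Weights are fitted by EM on a "random" test subset (relative log-likelihood
tolerance 1e-6, ≤ 500 iterations; EM monotonicity is asserted in tests).

Posterior summaries per pair are mixture-of-normals means and local false
sign rates; lfsr counts point mass at exactly zero against both signs (so
null-dominated posteriors can exceed 0.5, which is the standard
definition). Categories for pairs significant in condition 1
(lfsr < 0.05): *opposite* (significant in both, opposite signs); *shared*
(same sign, magnitude ratio within [1/2, 2] — the "within a factor of 0.5"
band convention; the absolute-difference reading |b1 − b2| ≤ 0.5|b2| is
selectable via `rule="difference"`); *magnified* (above the band, or not
significant in condition 2); *dampened* otherwise.

## Regulatory drivers

**Motif alteration.** A transparent allele-aware scanner: log-odds PWM
scores (uniform background, pseudocount 0.25) maximised over both strands
and all windows covering the SNP, separately per allele; "hit" = score ≥
0.8 × the maximum achievable score (threshold configurable). A SNP
*interrupts* a motif when only the reference allele hits and *introduces*
one when only the alternate does. Query SNPs are each signal's lead plus
its LD proxies (r² ≥ 0.8 within ±1 Mb); per signal each motif collapses to
altered (≥ 1 site) or not. Enrichment among interaction signals uses a
one-sided Fisher test per motif (motifs never altered are excluded from the
BH family), with a 1000-fold interaction-label permutation giving the
expected number of enriched motifs by chance.

**Regulon activity.** Expression is z-scored across genes within each
sample; a TF's activity in a sample is the t-statistic of the slope from
regressing the sample's z-scores on the regulon mode vector (+1/−1 targets,
0 otherwise; regulons restricted to evidence levels A–C and ≥ 5 measured
targets). This is one deterministic member of the family of consensus
activity estimators; the estimator name is recorded in output metadata.
Differential activity between SRS groups uses the random-intercept LMM with
BH correction and an optional label-permutation estimate of the expected
significant count; activity–cell-proportion relationships use Spearman
correlation on each patient's first available sample.

## Co-expression modules

Pipeline: (1) regress the top 20 expression PCs out of the log-expression
matrix, then average each individual's samples (between-individual
correlation only); (2) biweight midcorrelation (median/MAD weights, Tukey
biweight, 9-MAD tuning; genes with zero MAD fall back to Pearson and are
flagged; constant genes are dropped); (3) spatial quantile normalisation:
genes ranked by mean expression into 21 contiguous blocks (defaults; last
block absorbs the remainder), each block-pair's off-diagonal correlation
distribution quantile-mapped onto the (ref, ref) block (default block 18),
diagonal preserved, upper triangle mirrored — rank order within a block
pair is preserved exactly; (4) unsigned adjacency |cor|^power with the
soft power chosen as the smallest in 1..20 whose binned connectivity
distribution fits a power law with R² ≥ 0.8 (10 logarithmic bins; falls
back to the best-fitting power with a warning); (5) topological overlap
TOM_ij = (L_ij + a_ij)/(min(k_i,k_j) + 1 − a_ij).

**Tree cut.** Average-linkage clustering of 1 − TOM with a *static* cut.
The adaptive hybrid tree-cut algorithm's exact parameters are not published
for this use, so a deterministic variant is used; but on TOM dendrograms
merge heights saturate just below 1 (unrelated genes are all almost equally
dissimilar), so a high *quantile* of merge heights lands on the noise
plateau and returns one giant cluster. The static cut is therefore placed
at the midpoint of the widest gap in the sorted merge heights (capped at
the 0.99 quantile): the gap between the last within-module merge and the
noise plateau is the natural static analogue of the dynamic cut. Planted
two-block structure is recovered with Jaccard ≈ 1.0 and pure-noise input
leaves ≥ 95% of genes unassigned. Clusters under 10 genes are unassigned
(module 0); modules whose eigengenes have dissimilarity 1 − cor < 0.1 merge
iteratively (closest pair first); labels are renumbered by decreasing size.

**Eigengenes.** First right singular vector of the standardised member-gene
matrix, sign-aligned to the module mean profile, with variance explained
s1²/Σs². Module annotation: eigengene ~ phenotype LMMs (SRS1, diagnosis,
time point, INT cell proportions), Cox proportional hazards on 28-day
survival (Efron ties, lifelines) using each patient's last-time-point
eigengene, and hypergeometric marker-set enrichment; BH within each family.

## Module QTLs and downstream

Lead cis-eSNPs with > 3 minor-allele homozygotes are tested against every
module eigengene (sample-level eigengenes, standard covariates, random
intercept). The genome-wide threshold is alpha/(n_SNPs × n_modules) — with
the study's counts, 0.05/(12,335 × 106) = 3.82e-8 — and loci are ±0.5 Mb
windows merged per module. Replication recomputes eigengenes from the
platform-B measurements of each module's gene set (≥ 5 genes), correlates
them with discovery eigengenes on overlapping samples (Spearman), retests
the lead SNP in independent samples (p < 0.05) and calls direction
concordance via sign(beta_A)·sign(rho)·sign(beta_B) = +1. The sensitivity
analysis removes member genes that are cis-eGenes of any modQTL SNP,
recomputes the eigengene and retests; "robust" means the association stays
below the genome-wide threshold, separating genuine trans networks from
associations carried purely by cis effects on member genes.

**Mediation** (SNP → cis mediator gene → eigengene) uses fixed-effect
linear models on one sample per individual (the quasi-Bayesian machinery is
defined for independent observations; the handling of repeated measures is
not specified in the protocols this follows): draw coefficient vectors from
the fitted models' asymptotic normals (1000 draws), per draw ACME = a·b and
ADE = c′, report simulation means, percentile CIs and two-sided empirical
p-values, per additional copy of the minor allele.

**Colocalization** uses Wakefield log approximate Bayes factors,
`0.5 log(V/(V+W)) + z²W/(2(V+W))`, with prior effect variance W = 0.15²
(standardised-trait scale, configurable) and default priors p1 = p2 = 1e-4,
p12 = 1e-5; hypothesis sums use log-sum-exp over single- and two-SNP
configurations and PP0..PP4 are normalised to 1. Alleles align by exact
(chrom, pos, ref, alt) match; strand flips are not inferred. Note the PP
vector is not invariant to a uniform rescaling of one trait's ABFs (H0 and
the other trait's single-association hypothesis carry no trait-1 term);
only the H1:H3:H4 ratios are, and that is what the tests assert.

## The synthetic cohort generator

`synthcohort` emulates the data this pipeline consumes, with every planted
parameter recorded:

* **Genotypes** — two haplotypes per individual under HWE; within an LD
  block each SNP copies the previous SNP's allele with probability
  `ld_rho`, else redraws at its own MAF (first-order autoregressive LD —
  enough to exercise LD-proxy and effective-test logic, not a coalescent).
  Dosage is oriented to the *observed* minor allele so VCF output
  round-trips bit-exactly.
* **Expression** — per gene: mean + planted cis effects + context main and
  interaction effects + module-factor loadings + individual intercept
  (sigma_u = 0.5) + residual (sigma_e = 0.5), plus 25 background latent
  factors with loading SD 0.25 shared by all genes. The background
  structure matters: real transcriptomes have pervasive shared variation,
  and without it the estimated nuisance factors lock onto individual
  planted genes and bias effect recovery — something that cannot happen at
  genome scale. Genotype "PCs" are drawn as independent standard normals
  per individual, as genome-wide ancestry axes would be; PCs of the small
  simulated panel itself would be collinear with individual test SNPs.
* **Design** — 1–3 serial samples per individual (defaults 55/25/20%),
  SRS1 prevalence 0.35, FP diagnosis 0.4, Dirichlet cell proportions
  (neutrophil-dominant, with the neutrophil concentration raised in SRS1 so
  interaction-overlap logic can be exercised), ~1% missing proportions,
  exponential 28-day survival whose log-hazard can be linked to a module
  factor.
* **Trans networks** — a module's factor can be tied to a cis mediator:
  the driver SNP acts on the mediator gene, and the module factor is
  `f·standardised(mediator) + sqrt(1−f²)·noise`, so `f = 1` is complete
  mediation and the sensitivity/mediation stages have exact ground truth.

What passing tests do **not** show about real data: the generator has no
population structure, no imputation uncertainty, no read-level noise, no
non-Gaussian expression heavy tails beyond what bicor is tested on, and its
latent factors are linear and Gaussian. Recovery rates here are statements
about the implementation's correctness and calibration, not about power in
any particular clinical cohort.

## Problem sizes used in tests and the acceptance script

Simulation scales were chosen to give stable pass/fail behaviour on a
single CPU: cohorts of 150–300 individuals, 20–40 SNPs per cis window,
100–400 genes (400 wherever estimated nuisance factors interact with
effect recovery), 100 replicates for the cis-recovery and conditional
checks in the test suite (30 in the acceptance script), 2000 null
simulations for LRT calibration (1000 in the script), 200 meta-experiments
× 100 permutations for permutation-null uniformity (100 in the script),
and 10–20 replicates for the module-QTL stages. The acceptance script
(`scripts/acceptance.py --seed <int> --out <path>`) reruns every stage
from scratch and writes the resulting quantities as JSON.

## Known limitations

* The effective-test estimator uses Ledoit–Wolf shrinkage with partition
  size 200 and a 0.99 variance threshold — the named tool's conventions;
  other parameterisations shift M_eff slightly.
* The forward pass keeps the first-pass per-gene threshold; re-estimating
  it per iteration would be slightly more conservative late in the path.
* The static widest-gap tree cut recovers well-separated modules; strongly
  nested module hierarchies would favour the adaptive hybrid algorithm.
* Mediation ignores the repeated-measures structure (first sample per
  individual) and assumes linear, homoscedastic mediator/outcome models.
* The sharing model learns mixture weights only; covariance patterns are
  fixed (plus one optional data-driven rank-1 matrix), not learned by
  extreme deconvolution.
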